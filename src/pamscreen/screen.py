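"""Screen read processing: quality filter, PAM extraction, count table.

Screen reads are amplicons with fixed flanking sequences around the 7-nt
degenerate region, so the degenerate k-mer is recovered by anchored matching
(substitutions allowed in the anchors, no indels) rather than by a
general-purpose aligner: for this read structure the two are equivalent, and
anchored matching is dependency-free and exact about the block position.

The central product is the :class:`PamCountTable` — per-PAM read counts in
the selected (depleted) sample and its matched control, with totals — which
downstream modules turn into depletion statistics and motifs.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

from .iupac import reverse_complement
from .simulate import ReadSet

_CODE_OF_BYTE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF_BYTE[_b] = _i


class MalformedRecordError(ValueError):
    """A FASTQ record whose quality string cannot be interpreted."""


@dataclass(frozen=True)
class ScreenContext:
    """Fixed sequence context flanking the degenerate PAM block."""

    upstream_anchor: str
    downstream_anchor: str
    pam_length: int = 7
    search_strand_policy: str = "forward_only"  # or "both"

    def __post_init__(self):
        if not self.upstream_anchor or not self.downstream_anchor:
            raise ValueError("anchors must be nonempty")
        if self.pam_length < 1:
            raise ValueError("pam_length must be >= 1")
        if self.search_strand_policy not in ("forward_only", "both"):
            raise ValueError("search_strand_policy must be forward_only or both")

    @classmethod
    def from_simulation_context(cls, context: str, anchor_length: int = 15, **kw) -> "ScreenContext":
        """Derive anchors from a simulation context string with an N block."""
        start = context.find("N")
        end = start
        while end < len(context) and context[end] == "N":
            end += 1
        up = context[max(0, start - anchor_length) : start]
        down = context[end : end + anchor_length]
        return cls(upstream_anchor=up, downstream_anchor=down, pam_length=end - start, **kw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "upstream_anchor": self.upstream_anchor,
                    "downstream_anchor": self.downstream_anchor,
                    "pam_length": self.pam_length,
                    "search_strand_policy": self.search_strand_policy,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "ScreenContext":
        with open(path) as fh:
            return cls(**json.load(fh))


class QCCounts(NamedTuple):
    kept: int
    discarded: int


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Stream (name, sequence, quality) records from a FASTQ file (.gz ok)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        yield from FastqGeneralIterator(fh)


def mean_phred(qual: str) -> float:
    raw = qual.encode("ascii", errors="strict")
    arr = np.frombuffer(raw, dtype=np.uint8).astype(np.int32) - 33
    if arr.size == 0 or (arr < 0).any():
        raise MalformedRecordError("quality string not Phred+33")
    return float(arr.mean())


def filter_by_mean_quality(
    reads: Iterable[tuple[str, str, str]], min_mean_q: float = 20.0
) -> tuple[list[tuple[str, str, str]], QCCounts]:
    """Keep reads whose arithmetic mean per-base Phred score is >= threshold.

    Order is preserved. A record with a truncated or non-ASCII quality string
    raises :class:`MalformedRecordError` naming the record.
    """
    kept: list[tuple[str, str, str]] = []
    discarded = 0
    for name, seq, qual in reads:
        if len(qual) != len(seq):
            raise MalformedRecordError(f"record {name!r}: quality length != sequence length")
        try:
            mq = mean_phred(qual)
        except (UnicodeEncodeError, MalformedRecordError) as exc:
            raise MalformedRecordError(f"record {name!r}: {exc}") from None
        if mq >= min_mean_q:
            kept.append((name, seq, qual))
        else:
            discarded += 1
    return kept, QCCounts(kept=len(kept), discarded=discarded)


# ---------------------------------------------------------------------------
# anchored PAM extraction


class Extraction(NamedTuple):
    pam: str | None
    reason: str | None  # None on success

    @property
    def ok(self) -> bool:
        return self.pam is not None


def _mismatches(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def _placements(seq: str, context: ScreenContext, max_mm: int) -> list[int]:
    """Start positions of valid anchored placements of the degenerate block."""
    up, down, k = context.upstream_anchor, context.downstream_anchor, context.pam_length
    lu, ld = len(up), len(down)
    hits = []
    last = len(seq) - (lu + k + ld)
    for i in range(last + 1):
        if _mismatches(seq[i : i + lu], up, max_mm) <= max_mm:
            j = i + lu + k
            if _mismatches(seq[j : j + ld], down, max_mm) <= max_mm:
                hits.append(i + lu)
    return hits


def extract_pam(
    seq: str, context: ScreenContext, max_anchor_mismatches: int = 1
) -> Extraction:
    """Extract the degenerate k-mer between the two anchors of one read.

    Anchors may carry up to ``max_anchor_mismatches`` substitutions each; any
    indel in an anchor shifts the block and leads to rejection. Placements
    are ranked best-first: exact anchor matches take precedence over
    mismatched ones, and ambiguity (two placements in the winning tier)
    rejects the read. Rejections are data (reasons), not errors.
    """
    seq = seq.upper()
    if context.search_strand_policy == "forward_only":
        # fast path: a unique exact anchor pair, the overwhelmingly common case
        up, down, k = context.upstream_anchor, context.downstream_anchor, context.pam_length
        i = seq.find(up)
        if i >= 0 and seq.find(up, i + 1) < 0:
            j = i + len(up) + k
            if seq[j : j + len(down)] == down:
                pam = seq[i + len(up) : j]
                if len(pam) == k:
                    if any(c not in "ACGT" for c in pam):
                        return Extraction(None, "non_acgt_in_pam")
                    return Extraction(pam, None)
    strands = [seq]
    if context.search_strand_policy == "both":
        strands.append(reverse_complement(seq))
    for mm in ([0, max_anchor_mismatches] if max_anchor_mismatches else [0]):
        hits = [
            (s_idx, pos)
            for s_idx, s in enumerate(strands)
            for pos in _placements(s, context, mm)
        ]
        if len(hits) > 1:
            return Extraction(None, "ambiguous_placement")
        if hits:
            s_idx, pos = hits[0]
            pam = strands[s_idx][pos : pos + context.pam_length]
            if any(c not in "ACGT" for c in pam):
                return Extraction(None, "non_acgt_in_pam")
            return Extraction(pam, None)
    return Extraction(None, "anchor_not_found")


def extract_pam_codes(
    reads: ReadSet, context: ScreenContext, max_anchor_mismatches: int = 1
) -> tuple[np.ndarray, Counter]:
    """Vectorised anchored extraction over a uniform-length read matrix.

    Returns base-4 integer codes of the extracted k-mers (lexicographic
    A<C<G<T index into the 4^k universe) plus a tally of rejection reasons.
    Equivalent to mapping :func:`extract_pam` over the reads, restricted to
    the forward strand.
    """
    mat = reads.matrix
    rejections: Counter = Counter()
    if mat.size == 0:
        return np.empty(0, dtype=np.int64), rejections
    up = np.frombuffer(context.upstream_anchor.encode(), dtype=np.uint8)
    down = np.frombuffer(context.downstream_anchor.encode(), dtype=np.uint8)
    k = context.pam_length
    n, L = mat.shape
    span = len(up) + k + len(down)
    n_offsets = L - span + 1
    if n_offsets <= 0:
        rejections["anchor_not_found"] = n
        return np.empty(0, dtype=np.int64), rejections

    valid = np.zeros((n, n_offsets), dtype=bool)  # within mismatch tolerance
    exact = np.zeros((n, n_offsets), dtype=bool)
    for off in range(n_offsets):
        mm_up = (mat[:, off : off + len(up)] != up).sum(axis=1)
        ok = mm_up <= max_anchor_mismatches
        if ok.any():
            j = off + len(up) + k
            mm_down = (mat[ok, j : j + len(down)] != down).sum(axis=1)
            ok_idx = np.flatnonzero(ok)
            valid[ok_idx[mm_down <= max_anchor_mismatches], off] = True
            exact[ok_idx[(mm_down == 0) & (mm_up[ok] == 0)], off] = True

    # best tier wins: reads with any exact placement are judged on exact
    # placements only, matching the per-read extractor
    has_exact = exact.any(axis=1)
    tier = np.where(has_exact[:, None], exact, valid)
    n_valid = tier.sum(axis=1)
    unique = n_valid == 1
    rejections["anchor_not_found"] = int((n_valid == 0).sum())
    rejections["ambiguous_placement"] = int((n_valid > 1).sum())

    offsets = tier[unique].argmax(axis=1) + len(up)
    rows = np.flatnonzero(unique)
    pam_bytes = mat[rows[:, None], offsets[:, None] + np.arange(k)]
    codes4 = _CODE_OF_BYTE[pam_bytes]
    clean = (codes4 != 255).all(axis=1)
    rejections["non_acgt_in_pam"] = int((~clean).sum())
    codes4 = codes4[clean].astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    rejections = Counter({r: c for r, c in rejections.items() if c})
    return codes4 @ powers, rejections


# ---------------------------------------------------------------------------
# count table


@dataclass
class PamCountTable:
    """Per-PAM read counts in the selected sample and its control."""

    counts_selected: dict[str, int]
    counts_control: dict[str, int]
    pam_length: int

    def __post_init__(self):
        for counts in (self.counts_selected, self.counts_control):
            for kmer, c in counts.items():
                if len(kmer) != self.pam_length or any(b not in "ACGT" for b in kmer):
                    raise ValueError(f"bad k-mer key {kmer!r}")
                if c < 0:
                    raise ValueError("counts must be nonnegative")

    @property
    def total_selected(self) -> int:
        return sum(self.counts_selected.values())

    @property
    def total_control(self) -> int:
        return sum(self.counts_control.values())

    def variants(self) -> list[str]:
        """K-mers present in either sample, sorted."""
        return sorted(set(self.counts_selected) | set(self.counts_control))

    def to_frame(self) -> pd.DataFrame:
        pams = self.variants()
        return pd.DataFrame(
            {
                "pam": pams,
                "count_selected": [self.counts_selected.get(p, 0) for p in pams],
                "count_control": [self.counts_control.get(p, 0) for p in pams],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PamCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"pam": str})
        if df.empty:
            return cls({}, {}, pam_length=7)
        k = len(df["pam"].iloc[0])
        sel = {r.pam: int(r.count_selected) for r in df.itertuples() if r.count_selected}
        ctl = {r.pam: int(r.count_control) for r in df.itertuples() if r.count_control}
        return cls(sel, ctl, pam_length=k)


def count_pams(selected_kmers: Iterable[str], control_kmers: Iterable[str]) -> PamCountTable:
    """Exact multiset counts of extracted k-mers in both samples.

    Variants absent from both samples do not appear in the maps; the universe
    size 4^k is known separately.
    """
    sel = Counter(selected_kmers)
    ctl = Counter(control_kmers)
    lengths = {len(k) for k in sel} | {len(k) for k in ctl}
    if len(lengths) > 1:
        raise ValueError(f"mixed k-mer lengths: {sorted(lengths)}")
    k = lengths.pop() if lengths else 7
    return PamCountTable(dict(sel), dict(ctl), pam_length=k)


def count_pams_from_codes(
    selected_codes: np.ndarray, control_codes: np.ndarray, pam_length: int
) -> PamCountTable:
    """Build the count table from base-4 integer codes (vectorised path)."""
    from .iupac import all_kmers

    n_var = 4**pam_length
    kmers = all_kmers(pam_length)
    sel_counts = np.bincount(selected_codes, minlength=n_var)
    ctl_counts = np.bincount(control_codes, minlength=n_var)
    sel = {kmers[i]: int(sel_counts[i]) for i in np.flatnonzero(sel_counts)}
    ctl = {kmers[i]: int(ctl_counts[i]) for i in np.flatnonzero(ctl_counts)}
    return PamCountTable(sel, ctl, pam_length=pam_length)


def screen_counts(
    control: ReadSet,
    selected: ReadSet,
    context: ScreenContext,
    min_mean_q: float = 20.0,
    max_anchor_mismatches: int = 1,
) -> tuple[PamCountTable, dict]:
    """QC + extraction + counting for a simulated or in-memory screen.

    Uniform-quality read sets are filtered wholesale (their constant quality
    either passes or fails the mean threshold); extraction is vectorised.
    Returns the count table and a summary of read tallies.
    """
    summary: dict = {}
    sets = {}
    for label, rs in (("control", control), ("selected", selected)):
        q = ord(rs.quality_char) - 33
        if q >= min_mean_q:
            kept, disc = len(rs), 0
        else:
            kept, disc = 0, len(rs)
            rs = ReadSet(matrix=rs.matrix[:0])
        summary[f"{label}_qc"] = {"kept": kept, "discarded": disc}
        sets[label] = rs
    codes = {}
    for label, rs in sets.items():
        c, rej = extract_pam_codes(rs, context, max_anchor_mismatches)
        codes[label] = c
        summary[f"{label}_extraction"] = {"extracted": int(c.size), "rejected": dict(rej)}
    table = count_pams_from_codes(codes["selected"], codes["control"], context.pam_length)
    return table, summary
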