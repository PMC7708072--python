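"""Editing quantification from targeted amplicon reads.

The chain mirrors the windowed quantification used for CRISPR editing
experiments: merge read pairs, drop reads with substitutions in the primer
footprints (primer regions contain no biological variation, so errors there
flag a bad read), globally align each merged read to the reference amplicon
with free end gaps, and call a read *modified* when at least one insertion
or deletion overlaps a 20-bp quantification window centred 3 nt from the
3' end of the guide (the Cas9 blunt-cut site). Substitutions never count as
modification. Sample-level editing is the modified-read percentage minus the
same percentage in untransfected control cells, and significance across
replicates uses an exact one-tailed Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from math import comb

import numpy as np
from Bio import Align

from .iupac import reverse_complement


@dataclass(frozen=True)
class AmpliconExperiment:
    """Reference amplicon plus guide and primer geometry."""

    reference: str
    guide_start: int
    guide_end: int
    guide_strand: str = "+"
    primer_regions: tuple[tuple[int, int], tuple[int, int]] | None = None
    window_halfwidth: int = 10
    cut_offset_from_guide_3prime: int = 3

    def __post_init__(self):
        ref_len = len(self.reference)
        if not (0 <= self.guide_start < self.guide_end <= ref_len):
            raise ValueError("guide interval must lie inside the reference")
        if self.guide_strand not in "+-":
            raise ValueError("guide_strand must be '+' or '-'")
        ws, we = self.window
        if ws < 0 or we > ref_len:
            raise ValueError("quantification window extends outside the reference")
        if self.primer_regions is not None:
            for s, e in self.primer_regions:
                if not (0 <= s < e <= ref_len):
                    raise ValueError("primer region outside reference")
                if s < we and ws < e:
                    raise ValueError("primer region overlaps the quantification window")

    @property
    def cut_site(self) -> int:
        """Blunt-cut boundary coordinate on the reference (0-based)."""
        if self.guide_strand == "+":
            return self.guide_end - self.cut_offset_from_guide_3prime
        return self.guide_start + self.cut_offset_from_guide_3prime

    @property
    def window(self) -> tuple[int, int]:
        """Half-open reference interval of the quantification window."""
        return self.cut_site - self.window_halfwidth, self.cut_site + self.window_halfwidth


@dataclass
class IndelResult:
    """Per-sample modified-read tally and indel size spectrum."""

    n_reads_analyzed: int = 0
    n_modified: int = 0
    spectrum: Counter = field(default_factory=Counter)  # signed size -> count
    n_merge_rejected: int = 0
    n_primer_filtered: int = 0
    n_unalignable: int = 0

    @property
    def indel_pct(self) -> float:
        if self.n_reads_analyzed == 0:
            return 0.0
        return 100.0 * self.n_modified / self.n_reads_analyzed


def merge_pair(
    r1_seq: str,
    r1_qual: str,
    r2_seq: str,
    r2_qual: str,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.10,
) -> tuple[str, str] | None:
    """Merge a read pair via its 3' overlap; None on rejection.

    The reverse mate is reverse-complemented, the maximal overlap of at
    least ``min_overlap`` nt with at most ``max_mismatch_frac`` mismatches
    is taken, and overlap mismatches are resolved in favour of the
    higher-quality base.
    """
    rc2 = reverse_complement(r2_seq)
    q2 = r2_qual[::-1]
    a1 = np.frombuffer(r1_seq.encode(), dtype=np.uint8)
    a2 = np.frombuffer(rc2.encode(), dtype=np.uint8)
    for ov in range(min(len(a1), len(a2)), min_overlap - 1, -1):
        tail = a1[len(a1) - ov :]
        head = a2[:ov]
        mism = np.flatnonzero(tail != head)
        if mism.size <= max_mismatch_frac * ov:
            seq = bytearray(r1_seq.encode() + rc2[ov:].encode())
            qual = bytearray(r1_qual.encode() + q2[ov:].encode())
            off = len(a1) - ov
            for m in mism:
                if q2[m] > r1_qual[off + m]:
                    seq[off + m] = a2[m]
                    qual[off + m] = ord(q2[m])
            return seq.decode(), qual.decode()
    return None


def filter_primer_errors(
    merged_seq: str,
    experiment: AmpliconExperiment,
    max_error_rate: float = 0.003,
) -> bool:
    """True if the read passes the primer-footprint substitution filter.

    Primer regions are compared end-anchored: the forward footprint against
    the read's 5' end and the reverse footprint against its 3' end (indels
    between them shift nothing inside the footprints themselves). The read
    is discarded when substitutions per primer base exceed the threshold
    rate — with default 0.30% and typical ~20-25 nt footprints, any
    substitution is disqualifying.
    """
    if experiment.primer_regions is None:
        return True
    ref = experiment.reference
    (fs, fe), (rs, re_) = experiment.primer_regions
    subs = 0
    bases = 0
    fwd_read = merged_seq[fs:fe]
    fwd_ref = ref[fs:fe]
    subs += sum(a != b for a, b in zip(fwd_read, fwd_ref))
    bases += len(fwd_ref)
    offset = len(merged_seq) - len(ref)
    rev_read = merged_seq[rs + offset : re_ + offset] if rs + offset >= 0 else ""
    rev_ref = ref[rs:re_]
    if len(rev_read) != len(rev_ref):
        return False  # read too short to cover the reverse primer
    subs += sum(a != b for a, b in zip(rev_read, rev_ref))
    bases += len(rev_ref)
    return subs <= max_error_rate * bases


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2.0
    a.mismatch_score = -1.0
    a.open_gap_score = -6.0
    a.extend_gap_score = -0.5
    # free end gaps: truncated reads are not penalised at the ends
    a.end_gap_score = 0.0
    return a


_ALIGNER = _aligner()


def _left_shift_deletion(ref: str, start: int, end: int) -> tuple[int, int]:
    """Shift a deleted reference interval left through equal bases."""
    while start > 0 and ref[start - 1] == ref[end - 1]:
        start -= 1
        end -= 1
    return start, end


def _left_shift_insertion(ref: str, pos: int, ins: str) -> tuple[int, str]:
    """Shift an insertion left while it stays sequence-equivalent."""
    while pos > 0 and ins and ref[pos - 1] == ins[-1]:
        ins = ref[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins


@dataclass
class ReadCall:
    modified: bool
    events: list[tuple[str, int, int]]  # (kind, ref_pos, signed size)
    identity: float
    alignable: bool = True


def align_and_call(merged_seq: str, experiment: AmpliconExperiment) -> ReadCall:
    """Align one merged read to the reference and call modification.

    Global alignment with free end gaps (match +2, mismatch -1, gap open
    -6, gap extend -0.5); every indel is left-normalised (shifted to its
    leftmost sequence-equivalent placement) before the window test, so
    calling is invariant to equivalent placements within homopolymers. A
    read is modified iff at least one insertion or deletion overlaps the
    quantification window. Alignment identity below 60% marks the read
    unalignable.
    """
    ref = experiment.reference
    if merged_seq == ref:
        return ReadCall(modified=False, events=[], identity=1.0)
    aln = _ALIGNER.align(ref, merged_seq)[0]
    ref_blocks, read_blocks = aln.aligned
    matches = 0
    aligned_cols = 0
    events: list[tuple[str, int, int]] = []
    for (rs, re_), (qs, qe) in zip(ref_blocks, read_blocks):
        block_ref = ref[rs:re_]
        block_read = merged_seq[qs:qe]
        matches += sum(a == b for a, b in zip(block_ref, block_read))
        aligned_cols += re_ - rs
    for i in range(1, len(ref_blocks)):
        r_gap = ref_blocks[i][0] - ref_blocks[i - 1][1]
        q_gap = read_blocks[i][0] - read_blocks[i - 1][1]
        if r_gap > 0:  # deletion in the read
            s, e = _left_shift_deletion(ref, ref_blocks[i - 1][1], ref_blocks[i][0])
            events.append(("del", s, -(e - s)))
            aligned_cols += r_gap
        if q_gap > 0:  # insertion in the read
            ins = merged_seq[read_blocks[i - 1][1] : read_blocks[i][0]]
            pos, _ = _left_shift_insertion(ref, ref_blocks[i - 1][1], ins)
            events.append(("ins", pos, q_gap))
            aligned_cols += q_gap
    identity = matches / aligned_cols if aligned_cols else 0.0
    if identity < 0.60:
        return ReadCall(modified=False, events=[], identity=identity, alignable=False)
    ws, we = experiment.window
    modified = False
    window_events = []
    for kind, pos, size in events:
        if kind == "del":
            hit = pos < we and ws < pos - size  # deleted interval [pos, pos-size)
        else:
            hit = ws < pos < we
        if hit:
            modified = True
            window_events.append((kind, pos, size))
    return ReadCall(modified=modified, events=window_events, identity=identity)


def quantify_sample(
    read_pairs,
    experiment: AmpliconExperiment,
    max_primer_error_rate: float = 0.003,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.10,
) -> IndelResult:
    """Full per-sample chain: merge -> primer filter -> align -> call.

    ``read_pairs`` yields ((name1, seq1, qual1), (name2, seq2, qual2)).
    """
    res = IndelResult()
    for (_, s1, q1), (_, s2, q2) in read_pairs:
        merged = merge_pair(s1, q1, s2, q2, min_overlap, max_mismatch_frac)
        if merged is None:
            res.n_merge_rejected += 1
            continue
        seq, _qual = merged
        if not filter_primer_errors(seq, experiment, max_primer_error_rate):
            res.n_primer_filtered += 1
            continue
        call = align_and_call(seq, experiment)
        if not call.alignable:
            res.n_unalignable += 1
            continue
        res.n_reads_analyzed += 1
        if call.modified:
            res.n_modified += 1
            for _kind, _pos, size in call.events:
                res.spectrum[size] += 1
    return res


def net_indel_pct(treated: IndelResult, untreated: IndelResult) -> float:
    """Editing percentage net of background: treated % minus untreated %.

    The raw difference is returned (it can be negative); summary reports
    floor it at zero.
    """
    if treated.n_reads_analyzed == 0 or untreated.n_reads_analyzed == 0:
        raise ValueError("cannot compute net indel % from an empty sample")
    return treated.indel_pct - untreated.indel_pct


def _midranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=values.__getitem__)
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def mann_whitney_one_tailed(
    group_treated: list[float], group_control: list[float]
) -> tuple[float, float]:
    """Exact one-tailed Mann-Whitney U test, alternative treated > control.

    U is reported as min(U_treated, U_control) — the classic convention
    under which complete separation in the expected direction gives U = 0.
    For total n <= 12 the p-value is exact: all C(n1+n2, n1) assignments of
    the pooled midranks are enumerated and p is the fraction with a
    treated rank sum at least as large as observed. Larger samples fall
    back to the tie-corrected normal approximation.
    """
    n1, n2 = len(group_treated), len(group_control)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = list(group_treated) + list(group_control)
    ranks = _midranks(pooled)
    r_treated = sum(ranks[:n1])
    u_treated = r_treated - n1 * (n1 + 1) / 2
    u_control = n1 * n2 - u_treated
    u = min(u_treated, u_control)
    n = n1 + n2
    if n <= 12:
        hits = 0
        for combo in itertools.combinations(range(n), n1):
            if sum(ranks[i] for i in combo) >= r_treated:
                hits += 1
        p = hits / comb(n, n1)
    else:
        mu = n1 * n2 / 2
        tie_counts = Counter(pooled).values()
        tie_term = sum(t**3 - t for t in tie_counts)
        var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
        if var == 0:
            return u, 1.0
        from scipy.stats import norm

        z = (u_treated - mu - 0.5) / var**0.5
        p = float(norm.sf(z))
    return u, p
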