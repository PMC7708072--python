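"""Synthetic data generation for every pipeline input.

Three generators with known ground truth:

* :func:`simulate_screen` — a randomized-PAM depletion screen. A 7N plasmid
  (or linear DNA) library is exposed to a Cas9 effector; library members whose
  degenerate region matches a hidden IUPAC recognition rule are removed with a
  set cleavage probability, the survivors are sequenced, and a matched control
  (no effector) is sequenced alongside. Two modes are supported: ``in_vitro``
  (cleave, recover uncleaved molecules, sequence) and ``interference``
  (transformation into bacteria, which adds a colony bottleneck before
  sequencing and hence overdispersion).
* :func:`simulate_amplicon` — paired-end reads over a targeted amplicon in
  which a set fraction of fragments carries one indel whose left edge sits at
  the nuclease cut site.
* :func:`simulate_small_rna` — aligned small-RNA fragment coordinates drawn
  around defined transcript units (processed crRNAs, tracrRNA).

Sequencing error is modelled as independent per-base substitutions, uniform
over the three alternative bases; quality strings are a constant Q30 and do
not flag error positions. Ground truth is always returned separately (and
written as a JSON sidecar), never leaked through read names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .iupac import all_kmers, is_iupac, pattern_mask, reverse_complement

_Q30 = chr(30 + 33)
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
# byte value -> 0..3 code (255 = non-ACGT)
_CODE_OF_BYTE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF_BYTE[_b] = _i


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class ReadSet:
    """An in-memory single-end read collection with uniform quality.

    Sequences are stored both as a byte matrix (for vectorised processing)
    and exposed as strings; FASTQ output is Phred+33.
    """

    matrix: np.ndarray  # (n_reads, read_len) uint8 of ASCII bases
    name_prefix: str = "read"
    quality_char: str = _Q30

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def read_length(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> list[str]:
        n, L = self.matrix.shape
        buf = self.matrix.tobytes()
        return [buf[i : i + L].decode("ascii") for i in range(0, n * L, L)]

    def __iter__(self):
        qual = self.quality_char * self.read_length
        for i, seq in enumerate(self.sequences()):
            yield (f"{self.name_prefix}_{i + 1}", seq, qual)

    def quality_strings(self) -> list[str]:
        return [self.quality_char * self.read_length] * len(self)

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq, qual in self:
                fh.write(f"@{name}\n{seq}\n+\n{qual}\n")

    @classmethod
    def from_sequences(cls, seqs, **kw) -> "ReadSet":
        if not seqs:
            return cls(matrix=np.empty((0, 0), dtype=np.uint8), **kw)
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("ReadSet requires uniform read length")
        arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
        return cls(matrix=arr.reshape(len(seqs), lengths.pop()).copy(), **kw)


@dataclass(frozen=True)
class PamRule:
    """Hidden PAM recognition rule driving the screen's selection step.

    A library member whose degenerate k-mer matches any of the IUPAC
    ``patterns`` is removed from the selected sample with probability
    ``cleave_prob``; non-matching members are removed with
    ``background_prob``.
    """

    patterns: tuple[str, ...]
    cleave_prob: float
    background_prob: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "patterns", tuple(self.patterns))
        if not self.patterns:
            raise ConfigError("PamRule needs at least one pattern")
        length = len(self.patterns[0])
        for p in self.patterns:
            if not is_iupac(p):
                raise ConfigError(f"not an IUPAC pattern: {p!r}")
            if len(p) != length:
                raise ConfigError("all rule patterns must share one length")
        if not (0.0 <= self.background_prob <= self.cleave_prob <= 1.0):
            raise ConfigError(
                "require 0 <= background_prob <= cleave_prob <= 1, got "
                f"{self.background_prob} / {self.cleave_prob}"
            )

    @property
    def length(self) -> int:
        return len(self.patterns[0])

    def match_mask(self) -> np.ndarray:
        return pattern_mask(self.patterns, self.length)


def _degenerate_block(context: str) -> tuple[int, int]:
    """Locate the single run of N's marking the degenerate region."""
    start = context.find("N")
    if start < 0:
        raise ConfigError("context contains no degenerate (N) block")
    end = start
    while end < len(context) and context[end] == "N":
        end += 1
    if "N" in context[end:]:
        raise ConfigError("context must contain exactly one degenerate N block")
    return start, end


# Fixed amplicon context used by default: 5' flank + 20-nt protospacer,
# then the 7N degenerate block, then a 3' flank. Arbitrary but constant.
DEFAULT_CONTEXT = (
    "ACGTTGCA"  # vector flank
    "GTCACCTCCAATGACTAGGG"  # protospacer
    "NNNNNNN"
    "CTTCGGAATGTCCAGAGCTT"  # vector flank
)


@dataclass
class ScreenSimConfig:
    """Conditions of one simulated depletion screen."""

    rule: PamRule
    mode: str = "in_vitro"  # or "interference"
    library_weights: np.ndarray | None = None  # lexicographic over 4^k
    depth_control: int = 2_000_000
    depth_selected: int = 2_000_000
    per_base_error_rate: float = 0.001
    context: str = DEFAULT_CONTEXT
    bottleneck: int = 50_000  # colonies washed off in interference mode
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("in_vitro", "interference"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        start, end = _degenerate_block(self.context)
        if end - start != self.rule.length:
            raise ConfigError(
                f"degenerate block length {end - start} != rule length {self.rule.length}"
            )
        if self.depth_control <= 0 or self.depth_selected <= 0:
            raise ConfigError("sequencing depths must be positive")
        if not (0.0 <= self.per_base_error_rate < 1.0):
            raise ConfigError("per_base_error_rate must be in [0, 1)")
        k = self.rule.length
        if self.library_weights is not None:
            w = np.asarray(self.library_weights, dtype=float)
            if w.shape != (4**k,):
                raise ConfigError(f"library_weights must have shape ({4**k},)")
            if (w < 0).any() or w.sum() <= 0:
                raise ConfigError("library_weights must be nonnegative, not all zero")
            self.library_weights = w
        if self.mode == "interference" and self.bottleneck <= 0:
            raise ConfigError("bottleneck must be positive")

    @property
    def pam_length(self) -> int:
        return self.rule.length

    @property
    def block(self) -> tuple[int, int]:
        return _degenerate_block(self.context)


@dataclass
class ScreenSimResult:
    control: ReadSet
    selected: ReadSet
    truth: dict

    def write(self, outdir, prefix: str = "screen") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "control": outdir / f"{prefix}_control.fastq",
            "selected": outdir / f"{prefix}_selected.fastq",
            "truth": outdir / f"{prefix}_truth.json",
        }
        self.control.write_fastq(paths["control"])
        self.selected.write_fastq(paths["selected"])
        truth = dict(self.truth)
        truth["control_variant_counts"] = [int(x) for x in truth["control_variant_counts"]]
        truth["selected_variant_counts"] = [int(x) for x in truth["selected_variant_counts"]]
        paths["truth"].write_text(json.dumps(truth))
        return paths


def _apply_errors(rows: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Substitute bases in place at the given per-base rate."""
    if rate <= 0 or rows.size == 0:
        return
    total = rows.size
    n_err = rng.binomial(total, rate)
    if n_err == 0:
        return
    # sampling positions with replacement; collisions are negligible at the
    # error rates of interest and harmless (a position is just redrawn)
    pos = rng.integers(0, total, size=n_err)
    flat = rows.reshape(-1)
    codes = _CODE_OF_BYTE[flat[pos]]
    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
    flat[pos] = _BASE_BYTES[(codes + shift) % 4]


def _reads_from_variant_counts(
    counts: np.ndarray,
    kmer_bytes: np.ndarray,
    context: str,
    block: tuple[int, int],
    error_rate: float,
    rng: np.random.Generator,
    name_prefix: str,
) -> ReadSet:
    depth = int(counts.sum())
    L = len(context)
    start, end = block
    template = np.frombuffer(context.replace("N", "A").encode("ascii"), dtype=np.uint8)
    rows = np.tile(template, (depth, 1))
    idx = np.repeat(np.arange(counts.shape[0]), counts)
    rows[:, start:end] = kmer_bytes[idx]
    _apply_errors(rows, error_rate, rng)
    return ReadSet(matrix=rows, name_prefix=name_prefix)


def _kmer_byte_table(k: int) -> np.ndarray:
    kmers = all_kmers(k)
    arr = np.frombuffer("".join(kmers).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(kmers), k)


def simulate_screen(config: ScreenSimConfig) -> ScreenSimResult:
    """Simulate matched control and selected samples of a PAM screen.

    Returns FASTQ-writable read sets plus a ground-truth record holding the
    rule, the per-variant true read counts of each sample, and the matching
    variant count — everything parameter-recovery tests need.
    """
    rng = np.random.default_rng(config.seed)
    k = config.pam_length
    n_var = 4**k
    w = config.library_weights
    w = np.full(n_var, 1.0 / n_var) if w is None else w / w.sum()
    kmer_bytes = _kmer_byte_table(k)

    mask = config.rule.match_mask()
    survive = np.where(mask, 1.0 - config.rule.cleave_prob, 1.0 - config.rule.background_prob)
    w_sel = w * survive

    if config.mode == "interference":
        # transformation bottleneck: finite colony draw before plasmid prep,
        # applied to both the locus-carrying and the empty-vector control cells
        colonies_ctrl = rng.multinomial(config.bottleneck, w)
        w_ctrl_eff = colonies_ctrl / colonies_ctrl.sum()
    else:
        w_ctrl_eff = w
    counts_ctrl = rng.multinomial(config.depth_control, w_ctrl_eff)

    if w_sel.sum() == 0:
        counts_sel = np.zeros(n_var, dtype=np.int64)
    else:
        p_sel = w_sel / w_sel.sum()
        if config.mode == "interference":
            colonies_sel = rng.multinomial(config.bottleneck, p_sel)
            if colonies_sel.sum() == 0:
                counts_sel = np.zeros(n_var, dtype=np.int64)
            else:
                counts_sel = rng.multinomial(
                    config.depth_selected, colonies_sel / colonies_sel.sum()
                )
        else:
            counts_sel = rng.multinomial(config.depth_selected, p_sel)

    control = _reads_from_variant_counts(
        counts_ctrl, kmer_bytes, config.context, config.block,
        config.per_base_error_rate, rng, "ctrl",
    )
    selected = _reads_from_variant_counts(
        counts_sel, kmer_bytes, config.context, config.block,
        config.per_base_error_rate, rng, "sel",
    )
    truth = {
        "rule_patterns": list(config.rule.patterns),
        "cleave_prob": config.rule.cleave_prob,
        "background_prob": config.rule.background_prob,
        "mode": config.mode,
        "pam_length": k,
        "n_matching_variants": int(mask.sum()),
        "control_variant_counts": counts_ctrl,
        "selected_variant_counts": counts_sel,
        "seed": config.seed,
    }
    return ScreenSimResult(control=control, selected=selected, truth=truth)


# ---------------------------------------------------------------------------
# amplicon simulation


DEFAULT_INDEL_SIZES = {
    -1: 0.30, 1: 0.25, -2: 0.15, -3: 0.10, 2: 0.05, -4: 0.05, -6: 0.05, -10: 0.05,
}


@dataclass
class AmpliconSimConfig:
    """Conditions of one simulated editing experiment on a targeted amplicon."""

    reference: str
    guide_start: int
    guide_end: int
    guide_strand: str = "+"
    modified_fraction: float = 0.0
    indel_size_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_SIZES)
    )
    n_read_pairs: int = 10_000
    per_base_error_rate: float = 0.001
    read_length: int = 150
    cut_offset_from_guide_3prime: int = 3
    primer_length: int = 20
    seed: int = 0

    def __post_init__(self):
        ref_len = len(self.reference)
        if not (0 <= self.guide_start < self.guide_end <= ref_len):
            raise ConfigError("guide interval must lie inside the reference")
        if self.guide_strand not in "+-":
            raise ConfigError("guide_strand must be '+' or '-'")
        if not (0.0 <= self.modified_fraction <= 1.0):
            raise ConfigError("modified_fraction must be in [0, 1]")
        probs = np.array(list(self.indel_size_distribution.values()), dtype=float)
        if probs.size == 0 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("indel size probabilities must be nonnegative and sum to 1")
        if any(s == 0 for s in self.indel_size_distribution):
            raise ConfigError("indel size 0 is not an indel")
        if self.read_length < self.primer_length:
            raise ConfigError("read length shorter than primer regions")
        if self.n_read_pairs <= 0:
            raise ConfigError("n_read_pairs must be positive")

    @property
    def cut_site(self) -> int:
        """Blunt-cut reference coordinate (a between-bases boundary)."""
        if self.guide_strand == "+":
            return self.guide_end - self.cut_offset_from_guide_3prime
        return self.guide_start + self.cut_offset_from_guide_3prime


@dataclass
class AmpliconSimResult:
    r1: list[tuple[str, str, str]]  # (name, seq, qual)
    r2: list[tuple[str, str, str]]
    truth: dict

    def write(self, outdir, prefix: str = "amplicon") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "r1": outdir / f"{prefix}_R1.fastq",
            "r2": outdir / f"{prefix}_R2.fastq",
            "truth": outdir / f"{prefix}_truth.json",
        }
        for key, reads in (("r1", self.r1), ("r2", self.r2)):
            with open(paths[key], "w") as fh:
                for name, seq, qual in reads:
                    fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
        paths["truth"].write_text(json.dumps(self.truth))
        return paths


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    _apply_errors(arr.reshape(1, -1), rate, rng)
    return arr.tobytes().decode("ascii")


def simulate_amplicon(config: AmpliconSimConfig) -> AmpliconSimResult:
    """Simulate paired-end reads over an edited amplicon.

    A ``modified_fraction`` of fragments carries exactly one indel whose left
    edge is at the cut site (insertions are inserted at the cut boundary,
    deletions remove bases immediately 3' of it on the reference strand).
    Mates are the two ends of the full amplicon, so they overlap whenever
    2 * read_length exceeds the fragment length.
    """
    rng = np.random.default_rng(config.seed)
    ref = config.reference.upper()
    cut = config.cut_site
    sizes = sorted(config.indel_size_distribution)
    size_p = np.array([config.indel_size_distribution[s] for s in sizes])

    n = config.n_read_pairs
    modified = rng.random(n) < config.modified_fraction
    size_choice = rng.choice(len(sizes), size=n, p=size_p)

    r1, r2 = [], []
    truth_sizes: list[int] = []
    qual_cache: dict[int, str] = {}
    for i in range(n):
        if modified[i]:
            size = sizes[size_choice[i]]
            if size < 0:
                frag = ref[:cut] + ref[cut - size :]
            else:
                frag = ref[:cut] + _random_bases(rng, size) + ref[cut:]
            truth_sizes.append(size)
        else:
            frag = ref
            truth_sizes.append(0)
        frag = _substitute(frag, config.per_base_error_rate, rng)
        s1 = frag[: config.read_length]
        s2 = reverse_complement(frag)[: config.read_length]
        for s in (s1, s2):
            if len(s) not in qual_cache:
                qual_cache[len(s)] = _Q30 * len(s)
        name = f"pair_{i + 1}"
        r1.append((name, s1, qual_cache[len(s1)]))
        r2.append((name, s2, qual_cache[len(s2)]))

    truth = {
        "modified_fraction": config.modified_fraction,
        "n_modified_true": int(modified.sum()),
        "n_read_pairs": n,
        "cut_site": cut,
        "indel_sizes": truth_sizes,
        "seed": config.seed,
    }
    return AmpliconSimResult(r1=r1, r2=r2, truth=truth)


# ---------------------------------------------------------------------------
# small-RNA fragment simulation


def simulate_small_rna(
    units,
    depth: int,
    end_jitter: int = 0,
    seed: int = 0,
    ref_length: int | None = None,
    ref_name: str = "locus",
):
    """Simulate aligned small-RNA fragment coordinates around transcript units.

    ``units`` is a sequence of mappings (or objects) with ``start``, ``end``,
    ``strand`` and a relative ``abundance``. Fragment 5'/3' ends are jittered
    independently and uniformly within ±``end_jitter``. Returns a pandas
    DataFrame with BED-like columns (chrom, start, end, strand).
    """
    import pandas as pd

    if depth <= 0:
        raise ConfigError("depth must be positive")
    if end_jitter < 0:
        raise ConfigError("end_jitter must be nonnegative")
    specs = []
    for u in units:
        get = u.get if hasattr(u, "get") else lambda k, _u=u: getattr(_u, k)
        start, end = int(get("start")), int(get("end"))
        strand = get("strand") if _has(u, "strand") else "+"
        abundance = float(get("abundance")) if _has(u, "abundance") else 1.0
        if start >= end:
            raise ConfigError("unit start must be < end")
        if ref_length is not None and end > ref_length:
            raise ConfigError("unit extends beyond the declared reference length")
        specs.append((start, end, strand, abundance))
    if not specs:
        raise ConfigError("no transcript units given")

    rng = np.random.default_rng(seed)
    ab = np.array([s[3] for s in specs])
    counts = rng.multinomial(depth, ab / ab.sum())
    rows = []
    for (start, end, strand, _), c in zip(specs, counts):
        if c == 0:
            continue
        j5 = rng.integers(-end_jitter, end_jitter + 1, size=c) if end_jitter else np.zeros(c, int)
        j3 = rng.integers(-end_jitter, end_jitter + 1, size=c) if end_jitter else np.zeros(c, int)
        starts = np.maximum(start + j5, 0)
        ends = end + j3
        if ref_length is not None:
            ends = np.minimum(ends, ref_length)
        for s, e in zip(starts, ends):
            rows.append((ref_name, int(s), int(e), strand))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return frame.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)


def _has(u, key) -> bool:
    return (hasattr(u, "get") and u.get(key) is not None) or hasattr(u, key)


def write_bed(frame, path) -> None:
    """Write a fragment table as 6-column BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t.\t0\t{row.strand}\n")
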