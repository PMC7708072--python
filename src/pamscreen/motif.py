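"""PAM motif models: position profile, IUPAC consensus, and the PAM wheel.

The depleted-PAM set (the variants a nuclease can cleave) is summarised
three ways:

* a position frequency matrix with per-position information content
  (2 - Shannon entropy in bits, the quantity a sequence logo draws),
* an IUPAC consensus string read off that profile, and
* a hierarchical "PAM wheel": a Krona-style nested ring chart over an
  ordered subset of PAM positions in which a sector's angular share encodes
  the relative depletion of the corresponding sub-k-mer. Rings run from the
  innermost position closest to the protospacer outwards.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .depletion import depletion_coefficient
from .iupac import BASES, code_for
from .screen import PamCountTable


@dataclass
class PositionProfile:
    """Per-position nucleotide frequencies and information content."""

    freq: np.ndarray  # (4, L), rows in ACGT order
    info_bits: np.ndarray  # (L,)
    n_sequences: int

    @property
    def length(self) -> int:
        return self.freq.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq.T, columns=list(BASES))
        df.insert(0, "position", np.arange(1, self.length + 1))
        df["info_bits"] = self.info_bits
        return df

    def to_json(self) -> str:
        return json.dumps(
            {
                "freq": {b: self.freq[i].tolist() for i, b in enumerate(BASES)},
                "info_bits": self.info_bits.tolist(),
                "n_sequences": self.n_sequences,
            }
        )


def position_profile(depleted_pams, weights=None) -> PositionProfile:
    """Position frequency matrix of a set of k-mers.

    Unweighted by default — each sequence counts once, as when feeding the
    set to a logo generator; optional nonnegative weights (e.g. depletion
    coefficients) are supported. Information content per column is
    2 - H(column) in bits, with 0*log(0) = 0.
    """
    pams = list(depleted_pams)
    if not pams:
        raise ValueError("no depleted PAMs")
    L = len(pams[0])
    if any(len(p) != L for p in pams):
        raise ValueError("k-mers must have uniform length")
    if weights is None:
        w = np.ones(len(pams))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(pams),) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative, one per sequence, not all zero")
    counts = np.zeros((4, L))
    base_row = {b: i for i, b in enumerate(BASES)}
    for pam, wt in zip(pams, w):
        for j, b in enumerate(pam):
            counts[base_row[b], j] += wt
    freq = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    info = 2.0 + plogp.sum(axis=0)
    return PositionProfile(freq=freq, info_bits=np.clip(info, 0.0, 2.0), n_sequences=len(pams))


def call_consensus(
    profile: PositionProfile,
    constrained_bits: float = 0.3,
    include_fraction: float = 0.5,
) -> str:
    """Read an IUPAC consensus string off a position profile.

    A position with information content below ``constrained_bits`` is
    unconstrained ('N'); otherwise the IUPAC code covers every nucleotide
    whose frequency is at least ``include_fraction`` times the column
    maximum. Deterministic.
    """
    out = []
    for j in range(profile.length):
        if profile.info_bits[j] < constrained_bits:
            out.append("N")
            continue
        col = profile.freq[:, j]
        keep = {BASES[i] for i in range(4) if col[i] >= include_fraction * col.max()}
        out.append(code_for(keep))
    return "".join(out)


def aggregate_subpam(table: PamCountTable, positions) -> PamCountTable:
    """Marginal count table over an ordered subset of PAM positions (1-based).

    Sums the full table over the unselected positions, separately for the
    selected and control samples; totals are conserved.
    """
    positions = tuple(int(p) for p in positions)
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate positions")
    if not positions or any(p < 1 or p > table.pam_length for p in positions):
        raise ValueError(f"positions must lie in 1..{table.pam_length}")
    idx = [p - 1 for p in positions]
    sel: Counter = Counter()
    ctl: Counter = Counter()
    for pam, c in table.counts_selected.items():
        sel["".join(pam[i] for i in idx)] += c
    for pam, c in table.counts_control.items():
        ctl["".join(pam[i] for i in idx)] += c
    return PamCountTable(dict(sel), dict(ctl), pam_length=len(positions))


@dataclass
class WheelNode:
    """One sector of the PAM wheel.

    ``depth`` is the ring index: 1 = innermost ring = the first position of
    the ordered subset (closest to the protospacer). ``angular_share`` is
    the node's fraction of the full circle; leaf shares sum to 1 and an
    internal node's share is the sum of its children's.
    """

    nucleotide: str  # "" for the root
    depth: int
    aggregated_dcoef: float = 0.0
    angular_share: float = 0.0
    children: dict[str, "WheelNode"] = field(default_factory=dict)

    def leaves(self) -> list["WheelNode"]:
        if not self.children:
            return [self]
        out = []
        for b in BASES:
            if b in self.children:
                out.extend(self.children[b].leaves())
        return out

    def to_dict(self) -> dict:
        d = {
            "nucleotide": self.nucleotide,
            "depth": self.depth,
            "aggregated_dcoef": self.aggregated_dcoef,
            "angular_share": self.angular_share,
        }
        if self.children:
            d["children"] = [self.children[b].to_dict() for b in BASES if b in self.children]
        return d


def build_wheel(subpam_dcoefs: dict[str, float]) -> WheelNode:
    """Build the PAM wheel tree from per-sub-k-mer depletion coefficients.

    Only sub-k-mers with a positive depletion coefficient contribute; a
    leaf's angular share is its coefficient divided by the sum of positive
    coefficients, and internal nodes aggregate their children. All
    coefficients nonpositive yields an empty wheel (root without children).
    """
    positive = {s: d for s, d in subpam_dcoefs.items() if d > 0}
    root = WheelNode(nucleotide="", depth=0)
    if not positive:
        return root
    total = sum(positive.values())
    for sub, d in sorted(positive.items()):
        node = root
        for depth, base in enumerate(sub, start=1):
            if base not in node.children:
                node.children[base] = WheelNode(nucleotide=base, depth=depth)
            node = node.children[base]
            node.aggregated_dcoef += d
            node.angular_share += d / total
    root.aggregated_dcoef = total
    root.angular_share = 1.0
    return root


def wheel_to_krona_text(subpam_dcoefs: dict[str, float]) -> str:
    """Krona-importable text: magnitude column then one column per ring."""
    lines = []
    for sub, d in sorted(subpam_dcoefs.items()):
        if d > 0:
            lines.append("\t".join([f"{d:.6g}", *sub]))
    return "\n".join(lines) + ("\n" if lines else "")


def subpam_dcoefs(
    table: PamCountTable, positions=(5, 6, 7), pseudocount: float = 0.5
) -> dict[str, float]:
    """Depletion coefficients of marginal sub-k-mer counts.

    Marginalises first, then computes the coefficient on the aggregated
    counts (not a mean of per-7-mer coefficients).
    """
    agg = aggregate_subpam(table, positions)
    tot_sel, tot_ctl = agg.total_selected, agg.total_control
    out = {}
    for sub in agg.variants():
        out[sub] = depletion_coefficient(
            agg.counts_selected.get(sub, 0),
            agg.counts_control.get(sub, 0),
            tot_sel,
            tot_ctl,
            pseudocount=pseudocount,
        )
    return out
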