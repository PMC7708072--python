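"""Per-PAM depletion statistics.

Depletion of a PAM variant from the selected sample relative to the control
is summarised by two quantities:

* the depletion coefficient, a normalised log2 ratio

      Dcoef = log2( (total_selected / total_control)
                    * (n_control / n_selected) )

  which is positive when the variant is under-represented in the selected
  sample, and

* a one-sided Pearson chi-square test on the 2x2 table
  [[n_selected, total_selected - n_selected],
   [n_control,  total_control - n_control]] (df = 1, no continuity
  correction), halved in the depleted direction. A variant is called
  depleted when the one-sided p-value falls below a raw threshold
  (default 1e-12) and its selected-sample proportion is below its control
  proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screen import PamCountTable


@dataclass(frozen=True)
class DepletionRecord:
    pam: str
    n_selected: int
    n_control: int
    dcoef: float
    chi2: float
    p_one_sided: float
    depleted: bool


def depletion_coefficient(
    n_selected,
    n_control,
    total_selected,
    total_control,
    pseudocount: float = 0.5,
):
    """Normalised log2 depletion coefficient; positive means depleted.

    The pseudocount (default 0.5) is added to both variant counts so the
    statistic stays finite when a variant drops to zero reads in the
    selected sample; it never enters the chi-square test. Accepts scalars or
    arrays.
    """
    n_selected = np.asarray(n_selected, dtype=float)
    n_control = np.asarray(n_control, dtype=float)
    if (n_selected < 0).any() or (n_control < 0).any():
        raise ValueError("counts must be nonnegative")
    if total_selected <= 0 or total_control <= 0:
        raise ValueError("totals must be positive")
    with np.errstate(divide="ignore"):
        out = np.log2(total_selected / total_control) + np.log2(
            (n_control + pseudocount) / (n_selected + pseudocount)
        )
    return out if out.ndim else float(out)


def _chi2_one_sided(n_selected, n_control, total_selected, total_control):
    """Vectorised Pearson chi-square with directional halving.

    Returns (chi2, p_one_sided) for the alternative "selected proportion is
    below control proportion". Tables with an expected zero cell are
    uninformative: chi2 = 0, p = 1.
    """
    ns = np.asarray(n_selected, dtype=float)
    nc = np.asarray(n_control, dtype=float)
    if (ns > total_selected).any() or (nc > total_control).any():
        raise ValueError("count exceeds its total")
    N = float(total_selected + total_control)
    row1 = ns + nc  # variant reads
    row2 = N - row1  # other reads
    e = np.empty(ns.shape + (4,), dtype=float)
    e[..., 0] = row1 * total_selected / N
    e[..., 1] = row2 * total_selected / N
    e[..., 2] = row1 * total_control / N
    e[..., 3] = row2 * total_control / N
    o = np.stack([ns, total_selected - ns, nc, total_control - nc], axis=-1)
    bad = (e == 0).any(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = ((o - e) ** 2 / e).sum(axis=-1)
    chi2 = np.where(bad, 0.0, chi2)
    p_two = stats.chi2.sf(chi2, df=1)
    less = ns / total_selected < nc / total_control
    p_one = np.where(less, p_two / 2.0, 1.0 - p_two / 2.0)
    p_one = np.where(bad, 1.0, p_one)
    return chi2, p_one


def depletion_test(n_selected, n_control, total_selected, total_control):
    """One-sided Pearson chi-square depletion test on a single 2x2 table."""
    if n_selected < 0 or n_control < 0:
        raise ValueError("counts must be nonnegative")
    if total_selected <= 0 or total_control <= 0:
        raise ValueError("totals must be positive")
    chi2, p = _chi2_one_sided(
        np.array([n_selected]), np.array([n_control]), total_selected, total_control
    )
    return float(chi2[0]), float(p[0])


def call_depleted(
    table: PamCountTable,
    alpha: float = 1e-12,
    pseudocount: float = 0.5,
    bonferroni: bool = False,
) -> list[DepletionRecord]:
    """Score every PAM variant present in either sample.

    Returns one record per variant, sorted by descending depletion
    coefficient (ties broken lexicographically by PAM). The ``depleted``
    flag requires the one-sided p below ``alpha`` (optionally Bonferroni
    scaled by the number of variants tested) and a strictly lower selected
    proportion. The default is the raw (uncorrected) threshold.
    """
    pams = table.variants()
    if not pams:
        return []
    tot_sel, tot_ctl = table.total_selected, table.total_control
    if tot_sel <= 0 or tot_ctl <= 0:
        # one sample empty: no test is informative
        records = [
            DepletionRecord(p, table.counts_selected.get(p, 0), table.counts_control.get(p, 0),
                            float("nan"), 0.0, 1.0, False)
            for p in pams
        ]
        return records
    ns = np.array([table.counts_selected.get(p, 0) for p in pams], dtype=np.int64)
    nc = np.array([table.counts_control.get(p, 0) for p in pams], dtype=np.int64)
    dcoef = depletion_coefficient(ns, nc, tot_sel, tot_ctl, pseudocount)
    chi2, p_one = _chi2_one_sided(ns, nc, tot_sel, tot_ctl)
    threshold = alpha / len(pams) if bonferroni else alpha
    less = ns / tot_sel < nc / tot_ctl
    depleted = (p_one < threshold) & less
    order = sorted(range(len(pams)), key=lambda i: (-dcoef[i], pams[i]))
    return [
        DepletionRecord(
            pam=pams[i],
            n_selected=int(ns[i]),
            n_control=int(nc[i]),
            dcoef=float(dcoef[i]),
            chi2=float(chi2[i]),
            p_one_sided=float(p_one[i]),
            depleted=bool(depleted[i]),
        )
        for i in order
    ]


def depleted_records(records: list[DepletionRecord]) -> list[DepletionRecord]:
    """The significantly depleted subset of :func:`call_depleted` output."""
    return [r for r in records if r.depleted]


def records_to_frame(records: list[DepletionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pam": [r.pam for r in records],
            "n_selected": [r.n_selected for r in records],
            "n_control": [r.n_control for r in records],
            "dcoef": [r.dcoef for r in records],
            "chi2": [r.chi2 for r in records],
            "p_one_sided": [r.p_one_sided for r in records],
            "depleted": [r.depleted for r in records],
        }
    )
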