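"""End-to-end orchestration: simulate/count/stats/model and indel chains.

These functions back the CLI's composite subcommands and the demo run. Each
writes a fixed set of files into an output directory; identical config plus
seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .depletion import call_depleted, depleted_records, records_to_frame
from .indel import AmpliconExperiment, net_indel_pct, quantify_sample
from .motif import (
    call_consensus,
    position_profile,
    subpam_dcoefs,
    wheel_to_krona_text,
)
from .screen import ScreenContext, screen_counts
from .simulate import (
    AmpliconSimConfig,
    PamRule,
    ScreenSimConfig,
    simulate_amplicon,
    simulate_screen,
)

log = logging.getLogger("pamscreen")


class PipelineError(RuntimeError):
    """A named pipeline stage failed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_screen_pipeline(
    rule_patterns: list[str],
    outdir,
    mode: str = "in_vitro",
    depth: int = 2_000_000,
    cleave_prob: float = 0.95,
    seed: int = 0,
    alpha: float = 1e-12,
    wheel_positions: tuple[int, ...] = (5, 6, 7),
) -> dict:
    """Simulated screen -> counts -> stats -> profile/consensus -> wheel.

    Returns a summary dict; writes counts.tsv, stats.tsv, profile.json,
    consensus.txt, wheel.txt, wheel.json and run.json under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = ScreenSimConfig(
        rule=PamRule(patterns=tuple(rule_patterns), cleave_prob=cleave_prob),
        mode=mode,
        depth_control=depth,
        depth_selected=depth,
        seed=seed,
    )
    log.info("simulating %s screen, depth %d, seed %d", mode, depth, seed)
    sim = simulate_screen(config)
    context = ScreenContext.from_simulation_context(config.context)
    table, tallies = screen_counts(sim.control, sim.selected, context)
    table.to_tsv(outdir / "counts.tsv")
    log.info("count table: %d variants", len(table.variants()))

    records = call_depleted(table, alpha=alpha)
    records_to_frame(records).to_csv(outdir / "stats.tsv", sep="\t", index=False)
    depleted = depleted_records(records)
    log.info("depleted variants at alpha=%g: %d", alpha, len(depleted))
    if depleted:
        profile = position_profile([r.pam for r in depleted])
        consensus = call_consensus(profile)
        (outdir / "profile.json").write_text(profile.to_json())
    else:
        consensus = "N" * table.pam_length
        (outdir / "profile.json").write_text(json.dumps(None))
    (outdir / "consensus.txt").write_text(consensus + "\n")

    dcoefs = subpam_dcoefs(table, positions=wheel_positions)
    (outdir / "wheel.txt").write_text(wheel_to_krona_text(dcoefs))
    from .motif import build_wheel

    (outdir / "wheel.json").write_text(json.dumps(build_wheel(dcoefs).to_dict()))

    summary = {
        "version": __version__,
        "rule_patterns": list(rule_patterns),
        "mode": mode,
        "depth": depth,
        "seed": seed,
        "alpha": alpha,
        "read_tallies": tallies,
        "n_variants": len(table.variants()),
        "n_depleted": len(depleted),
        "consensus": consensus,
    }
    (outdir / "run.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def run_indel_pipeline(
    outdir,
    reference: str,
    guide_start: int,
    guide_end: int,
    modified_fraction: float = 0.2,
    control_fraction: float = 0.0,
    n_read_pairs: int = 5_000,
    seed: int = 0,
) -> dict:
    """Simulated treated/untreated amplicon samples -> net editing percentage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    experiment = AmpliconExperiment(
        reference=reference,
        guide_start=guide_start,
        guide_end=guide_end,
        primer_regions=((0, 20), (len(reference) - 20, len(reference))),
    )
    results = {}
    for label, frac, s in (
        ("treated", modified_fraction, seed),
        ("untreated", control_fraction, seed + 1),
    ):
        sim = simulate_amplicon(
            AmpliconSimConfig(
                reference=reference,
                guide_start=guide_start,
                guide_end=guide_end,
                modified_fraction=frac,
                n_read_pairs=n_read_pairs,
                seed=s,
            )
        )
        results[label] = quantify_sample(zip(sim.r1, sim.r2), experiment)
        log.info(
            "%s: %d analyzed, %d modified (%.2f%%)",
            label,
            results[label].n_reads_analyzed,
            results[label].n_modified,
            results[label].indel_pct,
        )
    net = net_indel_pct(results["treated"], results["untreated"])
    summary = {
        "version": __version__,
        "n_read_pairs": n_read_pairs,
        "seed": seed,
        "treated_pct": results["treated"].indel_pct,
        "untreated_pct": results["untreated"].indel_pct,
        "net_indel_pct": max(0.0, net),
        "net_indel_pct_raw": net,
        "spectrum_treated": {str(k): v for k, v in sorted(results["treated"].spectrum.items())},
    }
    (outdir / "indel_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
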