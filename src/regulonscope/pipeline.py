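"""End-to-end convenience runner over synthetic inputs.

Chains the whole analysis — genome + operon generation, regulon
planting, ChIP track simulation, peak calling and operon-aware
assignment, expression simulation, fold changes, regulon classification,
direct-target annotation, scatter statistics — and reports the results
next to the planted truth.  Used by the recovery tests and the
acceptance script; real-data analyses call the module functions
directly on loaded tables instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import chip, transcriptome
from .annotation import GenomeAnnotation, OperonMap
from .simulate import (
    SimulationConfig,
    generate_genome,
    plant_regulon,
    simulate_chip_track,
    simulate_expression,
)


@dataclass
class PipelineResult:
    annotation: GenomeAnnotation
    operons: OperonMap
    truth: pd.DataFrame
    chip_flags: pd.DataFrame
    chip_summary: dict
    fold_changes: pd.DataFrame
    regulon: pd.DataFrame
    stats: dict = field(default_factory=dict)


def run_pipeline(
    config: SimulationConfig,
    n_up: int = 300,
    n_down: int = 80,
    n_direct: int = 180,
    peak_config: chip.PeakCallerConfig | None = None,
    classifier_config: transcriptome.ClassifierConfig | None = None,
) -> PipelineResult:
    """Simulate, analyse, and score one full study."""
    peak_config = peak_config or chip.PeakCallerConfig()
    classifier_config = classifier_config or transcriptome.ClassifierConfig()

    annotation, operons = generate_genome(config)
    truth = plant_regulon(annotation, operons, n_up, n_down, n_direct, config)

    track = simulate_chip_track(annotation, operons, truth, config)
    peaks = chip.call_peaks(track, peak_config)
    assignments = chip.assign_peaks_to_genes(peaks, annotation, peak_config)
    flags = chip.propagate_operons(assignments, operons, annotation)
    chip_summary = chip.summarize_enrichment(flags, truth)

    expr = simulate_expression(annotation, truth, transcriptome.CONDITIONS, config)
    fc = pd.DataFrame(
        {
            cond: transcriptome.fold_changes(expr, cond, "ref", classifier_config)
            for cond in transcriptome.CONDITIONS
            if cond != "ref"
        }
    )
    dep_call = transcriptome.classify_depletion_response(
        fc["dep6"], fc["dep9"], classifier_config
    )
    regulon = transcriptome.define_regulon(
        dep_call, fc["v56a"], fc["rpoHdel_dep6"], fc[classifier_config.anchor],
        classifier_config,
    )
    regulon = transcriptome.annotate_direct(regulon, flags)

    r2_v56a, m_v56a = transcriptome.scatter_stats(fc["dep6"], fc["v56a"])
    r2_del, m_del = transcriptome.scatter_stats(fc["dep6"], fc["rpoHdel_dep6"])
    stats = {
        **transcriptome.regulon_summary(regulon),
        "r2_dep6_vs_v56a": r2_v56a,
        "slope_dep6_vs_v56a": m_v56a,
        "r2_dep6_vs_rpoHdel": r2_del,
        "slope_dep6_vs_rpoHdel": m_del,
    }
    return PipelineResult(
        annotation=annotation,
        operons=operons,
        truth=truth,
        chip_flags=flags,
        chip_summary=chip_summary,
        fold_changes=fc,
        regulon=regulon,
        stats=stats,
    )


def score_against_truth(regulon: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Sensitivity / specificity / false-discovery proportion of the
    regulon call (direction != none) against the planted truth."""
    called = regulon["direction"] != "none"
    planted = truth["direction"].reindex(regulon.index) != "none"
    correct_dir = regulon["direction"] == truth["direction"].reindex(regulon.index)
    tp = int((called & planted & correct_dir).sum())
    fp = int((called & ~(planted & correct_dir)).sum())
    fn = int((~called & planted).sum())
    tn = int((~called & ~planted).sum())
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "fdp": fp / (tp + fp) if tp + fp else 0.0,
    }
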