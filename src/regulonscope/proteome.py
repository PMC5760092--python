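"""TMT proteome quantification: portions-of-100 normalization,
mean-ratio fold changes with Student's t-test on log2 abundances, the
1.5-fold / p<=0.05 regulated-protein calls, and the Venn-style
intersection with the transcriptional regulon.

No spectrum-level processing happens here — quantification starts from
vendor-reported per-sample relative protein abundances, and no multiple-
testing correction is applied (the calls use the raw p <= 0.05, by
design; treat the resulting sets as descriptive, not inferential).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ProteinAbundanceTable:
    """Protein x sample relative abundances with a (condition, replicate) map.

    ``samples`` is a DataFrame indexed by sample id with columns
    ``condition`` and ``replicate``.  After :func:`normalize_to_percent`
    every sample column sums to 100.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")

    def samples_for(self, condition: str) -> list:
        mask = self.samples["condition"] == condition
        return [s for s in self.values.columns if s in self.samples.index[mask]]


def normalize_to_percent(raw: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample column to portions of 100 %."""
    totals = raw.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"sample(s) with non-positive total abundance: {bad}")
    return raw * (100.0 / totals)


def protein_fold_changes(
    table: ProteinAbundanceTable,
    exp_condition: str,
    ctrl_condition: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Mean-ratio fold change and t-test per protein.

    mean_ratio = mean(exp replicates) / mean(ctrl replicates) on the
    normalized abundances; significance from a two-sample t-test
    (pooled-variance Student by default, Welch with ``equal_var=False``)
    on per-replicate log2 abundances.  Proteins absent (NaN or 0) from
    all samples of a group are reported with ``detected=False`` rather
    than raising.  Zero-variance groups yield an undefined (NaN) p-value.
    """
    es = table.samples_for(exp_condition)
    cs = table.samples_for(ctrl_condition)
    if not es or not cs:
        raise ValueError("both conditions need at least one sample")
    exp = table.values[es]
    ctrl = table.values[cs]

    mean_exp = exp.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    detected = (exp.notna() & (exp > 0)).any(axis=1) & (ctrl.notna() & (ctrl > 0)).any(axis=1)
    mean_ratio = mean_exp / mean_ctrl
    mean_ratio[~detected] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        log_exp = np.log2(exp.where(exp > 0))
        log_ctrl = np.log2(ctrl.where(ctrl > 0))
    pvals = np.full(len(table.values), np.nan)
    if len(es) >= 2 and len(cs) >= 2:
        a = log_exp.to_numpy(float)
        b = log_ctrl.to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(
                a, b, axis=1, equal_var=equal_var, nan_policy="omit"
            )
        pvals = np.asarray(res.pvalue, dtype=float)
        # degenerate zero-variance groups: p is undefined, not 0
        zero_var = (np.nanvar(a, axis=1) == 0) & (np.nanvar(b, axis=1) == 0)
        pvals[zero_var] = np.nan
    out = pd.DataFrame(
        {
            "mean_ratio": mean_ratio,
            "log2_fc": np.log2(mean_ratio),
            "p_value": pvals,
            "n_exp": exp.notna().sum(axis=1),
            "n_ctrl": ctrl.notna().sum(axis=1),
            "detected": detected,
        },
        index=table.values.index,
    )
    return out


@dataclass(frozen=True)
class ProteinCallConfig:
    fold_threshold: float = 1.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def call_regulated_proteins(
    pfc: pd.DataFrame, config: ProteinCallConfig | None = None
) -> tuple[pd.Index, pd.Index]:
    """Split proteins into (up, down) sets by fold threshold and p-value.

    Proteins with an undefined p-value (not detected, <2 replicates, or
    zero variance) never pass the significance gate.
    """
    config = config or ProteinCallConfig()
    sig = pfc["p_value"] <= config.alpha  # NaN compares False
    up = pfc.index[(pfc["mean_ratio"] >= config.fold_threshold) & sig]
    down = pfc.index[(pfc["mean_ratio"] <= 1 / config.fold_threshold) & sig]
    return up, down


def integrate_with_regulon(
    up_proteins: pd.Index,
    down_proteins: pd.Index,
    regulon: pd.DataFrame,
    mapping: pd.Series | None = None,
) -> dict:
    """Venn summary of protein calls against the transcriptional regulon.

    ``mapping`` translates protein ids to gene ids (identity when None).
    Returns the intersection counts and, for the downregulated side, the
    fraction of called proteins with transcriptional support.
    """
    if mapping is not None:
        up_genes = pd.Index(mapping.reindex(up_proteins).dropna())
        down_genes = pd.Index(mapping.reindex(down_proteins).dropna())
    else:
        up_genes, down_genes = pd.Index(up_proteins), pd.Index(down_proteins)
    reg_up = regulon.index[regulon["direction"] == "up"]
    reg_down = regulon.index[regulon["direction"] == "down"]
    up_overlap = len(up_genes.intersection(reg_up))
    down_overlap = len(down_genes.intersection(reg_down))
    return {
        "n_proteins_up": len(up_genes),
        "n_proteins_down": len(down_genes),
        "n_transcripts_up": len(reg_up),
        "n_transcripts_down": len(reg_down),
        "up_overlap": up_overlap,
        "down_overlap": down_overlap,
        "down_overlap_fraction": down_overlap / len(down_genes) if len(down_genes) else float("nan"),
    }
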