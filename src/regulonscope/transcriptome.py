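"""Fold-change computation and heat-shock-regulon classification.

The regulon is defined purely by fold-change set logic across genetic
perturbations of the heat shock sigma factor:

* at least ``fold_threshold``-fold up- or downregulated after *both* 6 h
  and 9 h of chaperone (DnaKJ) depletion in the wild-type background;
* a concordant >= threshold response upon overproduction of the
  constitutively active sigma variant (V56A);
* a "milder or absent" response in the sigma-factor deletion background:
  either the deletion fold change stays below the threshold altogether,
  or it is at least ``milder_factor``-fold smaller (on the log scale, with
  concordant sign) than the wild-type depletion response.

Genes passing all three filters in the same direction are called regulon
members; upregulated members carrying promoter ChIP evidence (their own
peak or one inherited through their operon) are flagged direct targets.
No dispersion-based testing is involved — the criterion is a fold-change
filter by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: condition labels understood by the pipeline
CONDITIONS = (
    "ref", "dep6", "dep9", "v56a",
    "rpoHdel_dep6", "rpoHdel_dep9", "d252g_dep6", "d252g_dep9",
)


@dataclass
class ExpressionTable:
    """Gene x sample matrix of normalized expression plus a sample map."""

    values: pd.DataFrame                    # genes (index) x samples (columns)
    conditions: pd.Series                   # sample -> condition label

    def __post_init__(self) -> None:
        if (self.values < 0).any().any():
            raise ValueError("expression values must be non-negative")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
        missing = [s for s in self.values.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")

    def samples_for(self, condition: str) -> list:
        return [s for s in self.values.columns if self.conditions[s] == condition]


@dataclass(frozen=True)
class ClassifierConfig:
    """Constants of the regulon definition.

    fold_threshold: linear fold change a gene must reach (default 2).
    milder_factor: how many fold smaller the deletion-background response
        must be for the "milder" arm (default 2).
    absent_threshold: fold change below which the deletion-background
        response counts as "no response" (default 2).  A constant of its
        own, deliberately not tied to ``fold_threshold``: the
        no-response bound describes the deletion background, so raising
        the regulon threshold must never loosen it (and regulon
        membership stays monotone in ``fold_threshold``).
    pseudocount: added to normalized expression before ratios.
    absent_arm / milder_arm: the two interpretations of "milder or no
        response", individually switchable.
    anchor: which wild-type depletion contrast anchors the milder
        comparison ("dep6" or "dep9").
    """

    fold_threshold: float = 2.0
    milder_factor: float = 2.0
    absent_threshold: float = 2.0
    pseudocount: float = 1.0
    absent_arm: bool = True
    milder_arm: bool = True
    anchor: str = "dep6"

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.milder_factor < 1:
            raise ValueError("milder_factor must be >= 1")
        if self.absent_threshold <= 1:
            raise ValueError("absent_threshold must be > 1")
        if not (self.absent_arm or self.milder_arm):
            raise ValueError("at least one of the absent/milder arms must be enabled")


def normalize_library(
    raw_counts: pd.DataFrame, mode: str = "cpm", target: float = 1e6
) -> pd.DataFrame:
    """Equalize column sums (counts-per-million-style library scaling).

    ``mode='identity'`` passes pre-normalized input through unchanged.
    """
    if mode == "identity":
        return raw_counts.copy()
    sums = raw_counts.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    return raw_counts * (target / sums)


def fold_changes(
    expr: ExpressionTable,
    condition: str,
    reference: str = "ref",
    config: ClassifierConfig | None = None,
) -> pd.Series:
    """Linear fold change of ``condition`` over ``reference`` per gene.

    Replicate samples of a condition are averaged on the linear scale
    before the ratio; a pseudocount guards against division by zero.
    """
    config = config or ClassifierConfig()
    cs, rs = expr.samples_for(condition), expr.samples_for(reference)
    if not cs:
        raise ValueError(f"no samples for condition {condition!r}")
    if not rs:
        raise ValueError(f"no samples for reference {reference!r}")
    num = expr.values[cs].mean(axis=1) + config.pseudocount
    den = expr.values[rs].mean(axis=1) + config.pseudocount
    fc = num / den
    fc.name = f"{condition}_vs_{reference}"
    return fc


def classify_depletion_response(
    fc_dep6: pd.Series, fc_dep9: pd.Series, config: ClassifierConfig | None = None
) -> pd.Series:
    """Three-way call from the two depletion time points.

    'up' requires FC >= threshold at both 6 h and 9 h; 'down' requires
    FC <= 1/threshold at both; everything else is 'none'.
    """
    config = config or ClassifierConfig()
    if not fc_dep6.index.equals(fc_dep9.index):
        fc_dep9 = fc_dep9.reindex(fc_dep6.index)
    t = config.fold_threshold
    up = (fc_dep6 >= t) & (fc_dep9 >= t)
    down = (fc_dep6 <= 1 / t) & (fc_dep9 <= 1 / t)
    out = pd.Series("none", index=fc_dep6.index, name="direction")
    out[up] = "up"
    out[down] = "down"
    return out


def _milder_or_absent(
    fc_del: pd.Series, fc_anchor: pd.Series, direction: pd.Series,
    config: ClassifierConfig,
) -> pd.Series:
    """The deletion-background filter, per gene, for the called direction."""
    log_del = np.log2(fc_del)
    log_anchor = np.log2(fc_anchor)
    log_a = np.log2(config.absent_threshold)
    log_m = np.log2(config.milder_factor)
    ok = pd.Series(False, index=fc_del.index)
    if config.absent_arm:
        ok |= log_del.abs() < log_a
    if config.milder_arm:
        sign = direction.map({"up": 1.0, "down": -1.0}).fillna(0.0)
        concordant = (sign * log_del) >= 0
        milder = (log_anchor.abs() - log_del.abs()) >= log_m
        ok |= concordant & milder
    return ok


def define_regulon(
    dep_call: pd.Series,
    fc_v56a: pd.Series,
    fc_rpoHdel_dep: pd.Series,
    fc_dep_anchor: pd.Series,
    config: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Combine the three filters into the final regulon call.

    Returns a DataFrame indexed by gene with ``direction`` in
    {up, down, none}, a ``direct`` column initialized to False (filled by
    :func:`annotate_direct`), and the triggering fold changes as evidence
    columns.
    """
    config = config or ClassifierConfig()
    idx = dep_call.index
    fc_v56a = fc_v56a.reindex(idx)
    fc_rpoHdel_dep = fc_rpoHdel_dep.reindex(idx)
    fc_dep_anchor = fc_dep_anchor.reindex(idx)
    t = config.fold_threshold

    v_up = fc_v56a >= t
    v_down = fc_v56a <= 1 / t
    del_ok = _milder_or_absent(fc_rpoHdel_dep, fc_dep_anchor, dep_call, config)

    direction = pd.Series("none", index=idx, name="direction")
    direction[(dep_call == "up") & v_up & del_ok] = "up"
    direction[(dep_call == "down") & v_down & del_ok] = "down"
    return pd.DataFrame(
        {
            "direction": direction,
            "direct": False,
            "fc_dep_anchor": fc_dep_anchor,
            "fc_v56a": fc_v56a,
            "fc_rpoHdel": fc_rpoHdel_dep,
        }
    )


def annotate_direct(regulon: pd.DataFrame, chip_flags: pd.DataFrame) -> pd.DataFrame:
    """Flag upregulated regulon members that carry promoter ChIP evidence.

    ``chip_flags`` is the per-gene table from
    :func:`regulonscope.chip.propagate_operons` (boolean ``direct`` and
    ``via_operon`` columns).  Only upregulated genes can be direct
    targets — the binding evidence models sigma-factor *activation*.
    """
    out = regulon.copy()
    flags = chip_flags["direct"].reindex(out.index).fillna(False).astype(bool)
    out["direct"] = (out["direction"] == "up") & flags
    if "via_operon" in chip_flags.columns:
        out["via_operon"] = (
            out["direct"]
            & chip_flags["via_operon"].reindex(out.index).fillna(False).astype(bool)
        )
    return out


def scatter_stats(fc_x: pd.Series, fc_y: pd.Series) -> tuple[float, float]:
    """R² and slope of the log2 fold-change scatter (OLS of y on x)."""
    common = fc_x.index.intersection(fc_y.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared genes for a regression")
    x = np.log2(fc_x.reindex(common).to_numpy(float))
    y = np.log2(fc_y.reindex(common).to_numpy(float))
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.slope)


def regulon_summary(regulon: pd.DataFrame) -> dict:
    """Headline counts: up, down, and direct targets."""
    return {
        "n_up": int((regulon["direction"] == "up").sum()),
        "n_down": int((regulon["direction"] == "down").sum()),
        "n_direct": int(regulon["direct"].sum()),
    }
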