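"""Proteomap-style accounting of the proteome's "molecular investment".

A protein's investment is its relative molecular count (the normalized
TMT abundance, portions-of-100 scale) multiplied by its sequence length
in residues — a proxy for the amino acids a cell has sunk into that
protein.  Investments are renormalized to mass fractions summing to
100 % per condition and aggregated over a hierarchical functional
classification (e.g. KEGG/GO-derived level1/level2/level3 paths).  The
headline statistic is the relative percent change of a category's mass
fraction between two conditions.  Only the tables are computed here;
Voronoi-treemap rendering is out of scope and the nested export is
renderer-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .proteome import ProteinAbundanceTable


@dataclass
class CategoryHierarchy:
    """protein_id -> ordered category path (level1 ... levelK).

    ``paths`` is a DataFrame indexed by protein_id whose columns are the
    hierarchy levels in order (each protein maps to exactly one leaf
    path).
    """

    paths: pd.DataFrame

    def __post_init__(self) -> None:
        if self.paths.index.duplicated().any():
            dups = self.paths.index[self.paths.index.duplicated()].tolist()
            raise ValueError(f"protein(s) with multiple hierarchy paths: {dups}")

    @property
    def levels(self) -> list:
        return list(self.paths.columns)

    @classmethod
    def from_tsv(cls, path: str) -> "CategoryHierarchy":
        df = pd.read_csv(path, sep="\t")
        return cls(paths=df.set_index(df.columns[0]))


def compute_investment(
    table: ProteinAbundanceTable,
    lengths: pd.Series,
    condition: str,
) -> pd.Series:
    """Per-protein mass fraction (%) for one condition.

    investment(p) = mean relative abundance over the condition's
    replicates x length(p), renormalized to sum to 100.  Proteins
    without a length are dropped with a warning.
    """
    samples = table.samples_for(condition)
    if not samples:
        raise ValueError(f"no samples for condition {condition!r}")
    mean_abund = table.values[samples].mean(axis=1)
    have_len = mean_abund.index.isin(lengths.dropna().index)
    if not have_len.all():
        missing = mean_abund.index[~have_len].tolist()
        warnings.warn(f"excluding {len(missing)} protein(s) without a length: {missing[:5]}...")
    inv = mean_abund[have_len] * lengths.reindex(mean_abund.index[have_len])
    total = inv.sum()
    if total <= 0:
        raise ValueError("total investment is non-positive")
    frac = 100.0 * inv / total
    frac.name = f"mass_fraction_{condition}"
    return frac


def aggregate_by_category(
    investments: pd.Series,
    hierarchy: CategoryHierarchy,
    level: str | int = 0,
) -> pd.DataFrame:
    """Sum member mass fractions per category at one hierarchy level.

    ``level`` is a column name or positional index into the hierarchy.
    Returns a DataFrame indexed by category with ``investment`` (summed
    member fractions) and ``mass_fraction`` (%, renormalized over the
    proteins that have a hierarchy path).
    """
    if isinstance(level, int):
        level = hierarchy.levels[level]
    cats = hierarchy.paths[level].reindex(investments.index)
    if cats.isna().any():
        missing = investments.index[cats.isna()].tolist()
        raise ValueError(f"protein(s) without a hierarchy path: {missing[:5]}")
    grouped = investments.groupby(cats).sum()
    out = pd.DataFrame({"investment": grouped})
    out["mass_fraction"] = 100.0 * grouped / grouped.sum()
    out.index.name = level
    return out


def category_change(report_a: pd.DataFrame, report_b: pd.DataFrame) -> pd.DataFrame:
    """Relative percent change of each category's mass fraction, a -> b.

    change(c) = 100 x (fraction_b - fraction_a) / fraction_a; the
    absolute percentage-point difference is reported alongside.
    """
    cats = report_a.index.union(report_b.index)
    fa = report_a["mass_fraction"].reindex(cats).fillna(0.0)
    fb = report_b["mass_fraction"].reindex(cats).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * (fb - fa) / fa
    return pd.DataFrame(
        {
            "fraction_a": fa,
            "fraction_b": fb,
            "percent_change": rel,
            "point_change": fb - fa,
        }
    )


def export_treemap_data(
    investments: pd.Series,
    hierarchy: CategoryHierarchy,
    changes: pd.Series | None = None,
) -> list[dict]:
    """Nested category/size/change records for any treemap renderer.

    Each node carries ``name``, ``size`` (summed mass fraction),
    ``change`` (signed percent change of the node's fraction, when
    per-protein changes are supplied; red/blue color semantics are the
    renderer's business) and ``children``.
    """
    if investments.empty:
        return []
    paths = hierarchy.paths.reindex(investments.index)

    def build(sub_inv: pd.Series, sub_paths: pd.DataFrame, depth: int) -> list[dict]:
        nodes = []
        if depth >= len(hierarchy.levels):
            for pid, size in sub_inv.items():
                node = {"name": pid, "size": float(size), "children": []}
                if changes is not None and pid in changes.index:
                    node["change"] = float(changes[pid])
                nodes.append(node)
            return nodes
        col = hierarchy.levels[depth]
        for cat, members in sub_paths.groupby(col, sort=True).groups.items():
            inv = sub_inv.reindex(members)
            node = {
                "name": cat,
                "size": float(inv.sum()),
                "children": build(inv, sub_paths.loc[members], depth + 1),
            }
            nodes.append(node)
        return nodes

    return build(investments, paths, 0)


def allocation_report(
    table: ProteinAbundanceTable,
    lengths: pd.Series,
    hierarchy: CategoryHierarchy,
    condition_a: str,
    condition_b: str,
    level: str | int = 0,
) -> pd.DataFrame:
    """One-call convenience: per-category fractions in two conditions and
    their percent change (a = reference, b = perturbed)."""
    inv_a = compute_investment(table, lengths, condition_a)
    inv_b = compute_investment(table, lengths, condition_b)
    common = inv_a.index.intersection(inv_b.index).intersection(hierarchy.paths.index)
    rep_a = aggregate_by_category(inv_a.reindex(common), hierarchy, level)
    rep_b = aggregate_by_category(inv_b.reindex(common), hierarchy, level)
    return category_change(rep_a, rep_b)
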