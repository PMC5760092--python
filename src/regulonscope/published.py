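"""Loaders for the article-style processed supplementary tables and a
one-call reproduction of the headline counts.

The expected input is the processed-data workbook distributed with the
study (or a directory of equivalent TSV exports): per-gene fold changes
for the depletion (6 h, 9 h), active-sigma overproduction and
sigma-deletion contrasts together with a promoter ChIP-enrichment flag,
per-protein mean-ratio fold changes with t-test p-values, and the
hierarchical functional classification with sequence lengths.  Column
names are matched case-insensitively against the aliases below, so
reasonable export variants load without editing.
"""

from __future__ import annotations

import os
import re

import numpy as np
import pandas as pd

from . import proteome, transcriptome

#: canonical column -> accepted aliases (matched on lowercased, squashed names)
_ALIASES = {
    "gene_id": ["gene_id", "gene", "locus_tag", "locus", "id"],
    "fc_dep6": ["fc_dep6", "dep6", "fold_change_6h", "fc_6h", "dnakj_dep_6h"],
    "fc_dep9": ["fc_dep9", "dep9", "fold_change_9h", "fc_9h", "dnakj_dep_9h"],
    "fc_v56a": ["fc_v56a", "v56a", "rpoh_v56a", "v56a_overexpression"],
    "fc_rpoHdel": ["fc_rpohdel", "rpohdel", "delta_rpoh", "rpoh_del_6h", "fc_rpohdel_dep6"],
    "chip_enriched": ["chip_enriched", "chip", "chip_signal", "sigma32_enrichment"],
    "protein_id": ["protein_id", "protein", "gene_id", "gene", "locus_tag"],
    "mean_ratio": ["mean_ratio", "fold_change", "ratio", "fc"],
    "p_value": ["p_value", "pvalue", "p", "ttest_p"],
    "length": ["length", "sequence_length", "aa_length", "protein_length"],
}


def _squash(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


def _find_column(df: pd.DataFrame, canonical: str) -> str:
    wanted = {_squash(a) for a in _ALIASES[canonical]}
    for col in df.columns:
        if _squash(col) in wanted:
            return col
    raise KeyError(f"no column matching {canonical!r} among {list(df.columns)}")


def _standardize(df: pd.DataFrame, canonicals: list[str]) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for c in canonicals:
        out[c] = df[_find_column(df, c)]
    return out


def load_supplementary_tables(path: str) -> dict[str, pd.DataFrame]:
    """Load the processed supplementary data from an XLSX workbook or a
    directory of TSVs named ``transcriptome``, ``proteome`` and
    ``hierarchy`` (any extension).  Raises FileNotFoundError when the
    path does not exist."""
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"supplementary data not found at {path!r}; download the "
            "article's processed-data workbook (S3 Table) and point here"
        )
    sheets: dict[str, pd.DataFrame] = {}
    if os.path.isdir(path):
        for fn in sorted(os.listdir(path)):
            key = _squash(os.path.splitext(fn)[0])
            sheets[key] = pd.read_csv(os.path.join(path, fn), sep="\t")
    else:
        for name, df in pd.read_excel(path, sheet_name=None).items():
            sheets[_squash(name)] = df

    def pick(*needles):
        for key, df in sheets.items():
            if any(n in key for n in needles):
                return df
        raise KeyError(f"no sheet matching {needles} in {sorted(sheets)}")

    tables = {}
    tx = pick("transcript", "rnaseq", "rna")
    tables["transcriptome"] = _standardize(
        tx, ["gene_id", "fc_dep6", "fc_dep9", "fc_v56a", "fc_rpoHdel", "chip_enriched"]
    ).set_index("gene_id")
    pr = pick("proteom", "protein", "tmt")
    tables["proteome"] = _standardize(
        pr, ["protein_id", "mean_ratio", "p_value"]
    ).set_index("protein_id")
    try:
        hi = pick("hierarch", "categor", "function")
        hi = hi.set_index(hi.columns[0])
        tables["hierarchy"] = hi
    except KeyError:
        pass
    return tables


def reproduce_published_counts(
    tables: dict[str, pd.DataFrame],
    classifier_config: transcriptome.ClassifierConfig | None = None,
    protein_config: proteome.ProteinCallConfig | None = None,
) -> dict:
    """Run the full classifier stack on loaded supplementary tables.

    Returns the regulon sizes, the direct-target count (up genes with a
    ChIP flag), the regulated-protein counts, the transcript-protein
    overlaps, and the log2 scatter R^2 values — the quantities whose
    published values a reproduction is checked against.
    """
    classifier_config = classifier_config or transcriptome.ClassifierConfig()
    protein_config = protein_config or proteome.ProteinCallConfig()
    tx = tables["transcriptome"]

    dep_call = transcriptome.classify_depletion_response(
        tx["fc_dep6"], tx["fc_dep9"], classifier_config
    )
    anchor = tx["fc_dep6"] if classifier_config.anchor == "dep6" else tx["fc_dep9"]
    regulon = transcriptome.define_regulon(
        dep_call, tx["fc_v56a"], tx["fc_rpoHdel"], anchor, classifier_config
    )
    chip_flags = pd.DataFrame({"direct": tx["chip_enriched"].astype(bool)})
    regulon = transcriptome.annotate_direct(regulon, chip_flags)

    pr = tables["proteome"]
    pfc = pd.DataFrame(
        {
            "mean_ratio": pr["mean_ratio"].astype(float),
            "log2_fc": np.log2(pr["mean_ratio"].astype(float)),
            "p_value": pr["p_value"].astype(float),
        }
    )
    up, down = proteome.call_regulated_proteins(pfc, protein_config)
    venn = proteome.integrate_with_regulon(up, down, regulon)

    r2_v56a, m_v56a = transcriptome.scatter_stats(tx["fc_dep6"], tx["fc_v56a"])
    r2_del, _ = transcriptome.scatter_stats(tx["fc_dep6"], tx["fc_rpoHdel"])
    return {
        **transcriptome.regulon_summary(regulon),
        "n_proteins_up": len(up),
        "n_proteins_down": len(down),
        "up_overlap": venn["up_overlap"],
        "down_overlap_fraction": venn["down_overlap_fraction"],
        "r2_dep_vs_v56a": r2_v56a,
        "slope_dep_vs_v56a": m_v56a,
        "r2_dep_vs_rpoHdel": r2_del,
    }
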