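"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the shape of the real study inputs without any
sequencing-read simulation: a bacterial genome annotation with strand
and translation starts, an operon map with members in transcription
order, a binned ChIP read-density track with unimodal bumps planted over
the promoters of direct targets (or their operon leaders), gene x
condition expression tables with multiplicative fold-change structure
and lognormal noise, triplicate TMT-style protein abundances summing to
100 % per sample, and exponential protein-decay time courses.  Every
generator is a pure function of a :class:`SimulationConfig` seed, so all
outputs are bit-for-bit reproducible.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GENE_COLUMNS, GenomeAnnotation, OperonMap, translation_start
from .chip import DensityTrack
from .decay import DecayCourse
from .proteome import ProteinAbundanceTable, normalize_to_percent
from .transcriptome import CONDITIONS, ExpressionTable

# distinct stream per generator so operations stay independent under one seed
_STREAM = {"genome": 0, "regulon": 1, "chip": 2, "expression": 3, "proteome": 4,
           "hierarchy": 5}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults are scaled to the real system: ~3000 annotated ORFs on a
    ~4 Mb circular chromosome, planted effects of |log2 fold| = 3 for
    regulon members, 20 % multiplicative noise, a ChIP background well
    below the calling threshold of 10 with planted bumps of height 50,
    and biological triplicates for the proteome.
    """

    seed: int = 0
    n_genes: int = 3000
    n_operons: int = 300
    genome_length: int | None = None     # None: sized to fit the packing
    bin_width: int = 10
    fraction_minus_strand: float = 0.5
    effect_up: float = 8.0               # linear fold, > 1
    effect_down: float = 0.125           # linear fold, in (0, 1)
    noise_cv: float = 0.2                # coefficient of variation, >= 0
    chip_background_mean: float = 2.0
    chip_peak_height: float = 50.0
    n_replicates: int = 3
    proteome_concordance: float = 0.7    # fraction of regulon genes whose protein follows the transcript
    protein_response_damping: float = 0.5  # protein |log2 fold| = damping x transcript |log2 fold|

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_operons < 0 or self.n_genes < self.n_operons:
            raise ValueError("need n_genes >= n_operons >= 0")
        if self.effect_up <= 1:
            raise ValueError("effect_up must be > 1")
        if not 0 < self.effect_down < 1:
            raise ValueError("effect_down must be in (0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.fraction_minus_strand <= 1:
            raise ValueError("fraction_minus_strand must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# genome + operons

def generate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, OperonMap]:
    """Place non-overlapping ORFs grouped into transcription units.

    Operon members are contiguous, same-strand and listed in
    transcription order (rank 1 = leader = the promoter-proximal gene).
    Transcription units are separated by 450-800 bp of intergenic space;
    genes inside an operon sit 20-120 bp apart.
    """
    if config.n_genes == 0:
        return (
            GenomeAnnotation(
                genes=pd.DataFrame(columns=GENE_COLUMNS),
                genome_length=config.genome_length or 0,
            ),
            OperonMap(),
        )
    rng = config.rng("genome")
    sizes = rng.integers(2, 5, size=config.n_operons) if config.n_operons else np.array([], int)
    n_single = config.n_genes - int(sizes.sum())
    if n_single < 0:
        raise ValueError(
            f"cannot fit {config.n_operons} operons of >=2 genes into {config.n_genes} genes"
        )
    unit_sizes = list(sizes) + [1] * n_single
    order = rng.permutation(len(unit_sizes))
    unit_sizes = [unit_sizes[i] for i in order]

    gene_lengths = rng.integers(100, 500, size=config.n_genes) * 3
    unit_gaps = rng.integers(450, 800, size=len(unit_sizes))
    unit_strands = np.where(rng.random(len(unit_sizes)) < config.fraction_minus_strand, "-", "+")

    rows, members = [], []
    pos = 1
    gi = 0
    op_idx = 0
    for u, size in enumerate(unit_sizes):
        pos += int(unit_gaps[u])
        strand = unit_strands[u]
        unit_rows = []
        for j in range(size):
            if j:
                pos += int(rng.integers(20, 121))
            L = int(gene_lengths[gi])
            start, end = pos, pos + L - 1
            unit_rows.append(
                dict(gene_id=f"g{gi + 1:04d}", start=start, end=end, strand=strand,
                     translation_start=translation_start(start, end, strand))
            )
            pos = end + 1
            gi += 1
        rows.extend(unit_rows)
        if size > 1:
            op_idx += 1
            # transcription order: left-to-right on '+', right-to-left on '-'
            ordered = unit_rows if strand == "+" else unit_rows[::-1]
            for rank, r in enumerate(ordered, start=1):
                members.append(dict(operon_id=f"op{op_idx:03d}", gene_id=r["gene_id"], rank=rank))
    needed = pos + 500
    if config.genome_length is None:
        genome_length = needed
    else:
        if config.genome_length < needed:
            raise ValueError(
                f"genome_length={config.genome_length} too small: packing "
                f"{config.n_genes} ORFs with intergenic spacing needs >= {needed} bp"
            )
        genome_length = config.genome_length
    annotation = GenomeAnnotation(genes=pd.DataFrame(rows, columns=GENE_COLUMNS),
                                  genome_length=genome_length)
    operons = OperonMap(members=pd.DataFrame(members, columns=["operon_id", "gene_id", "rank"]))
    return annotation, operons


# ---------------------------------------------------------------------------
# regulon truth

def plant_regulon(
    annotation: GenomeAnnotation,
    operons: OperonMap,
    n_up: int = 300,
    n_down: int = 80,
    n_direct: int = 180,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Plant the ground-truth regulon.

    Returns a DataFrame indexed by gene_id with ``direction`` (up / down
    / none), ``direct`` (bool) and ``planted_fold`` (linear fold; exactly
    1 for unaffected genes).  Direct targets are planted as whole
    transcription units: a chosen operon contributes the promoter peak at
    its leader and *all* its members count as direct (the binding site
    drives the complete unit), so downstream peak propagation recovers
    exactly this set.  Direct targets are always upregulated.
    """
    config = config or SimulationConfig()
    n_genes = len(annotation)
    if not (0 <= n_direct <= n_up <= n_genes - n_down):
        raise ValueError(
            f"infeasible counts: need n_direct <= n_up <= n_genes - n_down "
            f"(got {n_direct}, {n_up}, {n_genes} - {n_down})"
        )
    rng = config.rng("regulon")
    gene_ids = list(annotation.gene_ids)
    truth = pd.DataFrame(
        {"direction": "none", "direct": False, "planted_fold": 1.0}, index=pd.Index(gene_ids, name="gene_id")
    )
    if n_genes == 0:
        return truth

    in_operon = set(operons.members["gene_id"])
    units: list[list[str]] = [m for _, m in operons.iter_operons()]
    units += [[g] for g in gene_ids if g not in in_operon]
    units = [units[i] for i in rng.permutation(len(units))]

    direct: list[str] = []
    for unit in units:
        if len(direct) + len(unit) <= n_direct:
            direct.extend(unit)
        if len(direct) == n_direct:
            break
    if len(direct) != n_direct:
        raise ValueError(
            f"could not plant exactly {n_direct} direct genes as whole "
            "transcription units; adjust n_direct or the operon structure"
        )
    remaining = [g for g in gene_ids if g not in set(direct)]
    extra_up = list(rng.choice(remaining, size=n_up - n_direct, replace=False))
    up = direct + extra_up
    pool = [g for g in remaining if g not in set(extra_up)]
    down = list(rng.choice(pool, size=n_down, replace=False))

    truth.loc[up, "direction"] = "up"
    truth.loc[up, "planted_fold"] = config.effect_up
    truth.loc[down, "direction"] = "down"
    truth.loc[down, "planted_fold"] = config.effect_down
    truth.loc[direct, "direct"] = True
    return truth


def binding_site_carriers(truth: pd.DataFrame, operons: OperonMap) -> list[str]:
    """Genes whose promoter carries a planted binding site: direct
    singletons plus the leaders of operons containing direct genes."""
    op_of = operons.operon_of()
    leaders = operons.leaders()
    carriers: list[str] = []
    seen_ops: set = set()
    for g in truth.index[truth["direct"]]:
        if g in op_of.index:
            oid = op_of[g]
            if oid not in seen_ops:
                seen_ops.add(oid)
                carriers.append(leaders[oid])
        else:
            carriers.append(g)
    return carriers


# ---------------------------------------------------------------------------
# ChIP track

def simulate_chip_track(
    annotation: GenomeAnnotation,
    operons: OperonMap,
    truth: pd.DataFrame,
    config: SimulationConfig | None = None,
) -> DensityTrack:
    """Binned read-density track: sub-threshold background plus one
    unimodal Gaussian bump (height = chip_peak_height, sd 40 bp) centred
    60-100 bp upstream of each planted binding site's translation start."""
    config = config or SimulationConfig()
    rng = config.rng("chip")
    genome_length = annotation.genome_length or config.bin_width
    n_bins = math.ceil(genome_length / config.bin_width)
    bg = config.chip_background_mean * _lognormal_noise(rng, config.noise_cv, n_bins)
    # background must stay below the default calling threshold of 10
    values = np.clip(bg, 0.0, 9.5)

    tss = annotation.translation_starts()
    strands = annotation.strands()
    centers = 1 + np.arange(n_bins) * config.bin_width + config.bin_width // 2
    sd = 40.0
    for g in binding_site_carriers(truth, operons):
        offset = int(rng.integers(60, 101))
        center = tss[g] - offset if strands[g] == "+" else tss[g] + offset
        lo = np.searchsorted(centers, center - 5 * sd)
        hi = np.searchsorted(centers, center + 5 * sd)
        x = centers[lo:hi]
        values[lo:hi] += config.chip_peak_height * np.exp(-((x - center) ** 2) / (2 * sd * sd))
    return DensityTrack(values=values, bin_width=config.bin_width, origin=1)


# ---------------------------------------------------------------------------
# expression

#: planted condition multiplier, as a function of the gene's linear fold f
_CONDITION_EFFECT = {
    "ref": lambda f: 1.0,
    "dep6": lambda f: f,
    "dep9": lambda f: f,
    "v56a": lambda f: f,
    "rpoHdel_dep6": lambda f: 1.0,
    "rpoHdel_dep9": lambda f: 1.0,
    # attenuated response: half the log2 fold ("similar but less pronounced")
    "d252g_dep6": lambda f: math.sqrt(f),
    "d252g_dep9": lambda f: math.sqrt(f),
}


def simulate_expression(
    annotation: GenomeAnnotation,
    truth: pd.DataFrame,
    conditions: list[str] | tuple[str, ...] = CONDITIONS,
    config: SimulationConfig | None = None,
) -> ExpressionTable:
    """Gene x condition normalized expression with planted fold structure.

    expression(g, c) = baseline(g) x multiplier(c, planted_fold(g)) x
    mean-one lognormal noise(cv).  Regulon genes respond with their full
    planted fold in the depletion and V56A conditions, not at all in the
    sigma-deletion background, and with half the log2 fold in the
    attenuated-mutant (D252G) conditions.
    """
    config = config or SimulationConfig()
    unknown = [c for c in conditions if c not in CONDITIONS]
    if unknown:
        raise ValueError(f"unknown condition label(s): {unknown}")
    if "ref" not in conditions:
        raise ValueError("conditions must include the 'ref' reference")
    rng = config.rng("expression")
    n = len(annotation)
    baseline = rng.lognormal(mean=math.log(500.0), sigma=1.0, size=n)
    folds = truth["planted_fold"].reindex(annotation.gene_ids).to_numpy(float)
    cols, labels = {}, {}
    counts: dict[str, int] = {}
    for cond in conditions:
        counts[cond] = counts.get(cond, 0) + 1
        sample = cond if conditions.count(cond) == 1 else f"{cond}_r{counts[cond]}"
        mult = np.array([_CONDITION_EFFECT[cond](f) for f in folds])
        cols[sample] = baseline * mult * _lognormal_noise(rng, config.noise_cv, n)
        labels[sample] = cond
    values = pd.DataFrame(cols, index=annotation.gene_ids)
    return ExpressionTable(values=values, conditions=pd.Series(labels))


# ---------------------------------------------------------------------------
# proteome

def protein_lengths_from_annotation(annotation: GenomeAnnotation) -> pd.Series:
    """Protein lengths in residues, ORF length / 3 (incl. stop)."""
    genes = annotation.genes.set_index("gene_id")
    return ((genes["end"] - genes["start"] + 1) // 3).rename("length")


def simulate_proteome(
    truth: pd.DataFrame,
    protein_lengths: pd.Series,
    config: SimulationConfig | None = None,
    exp_condition: str = "dep12",
) -> tuple[ProteinAbundanceTable, pd.DataFrame]:
    """Triplicate TMT-style abundances for a control and a depleted condition.

    A configurable fraction of regulon genes (``proteome_concordance``)
    responds at the protein level; their protein log2 fold is the
    transcript log2 fold scaled by ``protein_response_damping``
    (default 0.5 — protein responses are buffered relative to mRNA by
    translation and protein turnover; set 1.0 for undamped folds).  All
    other proteins stay flat.  Each sample column is normalized to
    portions of 100 %.  Returns the table and a per-protein truth frame
    (``protein_fold`` — the realized protein-level fold — and
    ``concordant``).
    """
    config = config or SimulationConfig()
    rng = config.rng("proteome")
    proteins = truth.index
    n = len(proteins)
    regulated = (truth["direction"] != "none").to_numpy()
    concordant = regulated & (rng.random(n) < config.proteome_concordance)
    damped = truth["planted_fold"].to_numpy(float) ** config.protein_response_damping
    protein_fold = np.where(concordant, damped, 1.0)
    baseline = rng.lognormal(mean=math.log(100.0), sigma=1.5, size=n)

    cols, meta = {}, []
    for cond, fold in (("ref", np.ones(n)), (exp_condition, protein_fold)):
        for r in range(1, config.n_replicates + 1):
            sample = f"{cond}_r{r}"
            cols[sample] = baseline * fold * _lognormal_noise(rng, config.noise_cv, n)
            meta.append(dict(sample=sample, condition=cond, replicate=r))
    raw = pd.DataFrame(cols, index=proteins)
    table = ProteinAbundanceTable(
        values=normalize_to_percent(raw),
        samples=pd.DataFrame(meta).set_index("sample"),
    )
    protein_truth = pd.DataFrame(
        {"protein_fold": protein_fold, "concordant": concordant}, index=proteins
    )
    return table, protein_truth


# ---------------------------------------------------------------------------
# functional hierarchy (for the allocation stage)

_UP_PATHS = [
    ("maintenance", "folding_export_degradation", "chaperones"),
    ("maintenance", "folding_export_degradation", "proteases"),
    ("maintenance", "stress_response", "other_stress"),
]
_DOWN_PATHS = [
    ("proliferation", "translation", "ribosome"),
    ("proliferation", "translation", "elongation_factors"),
    ("proliferation", "dna_replication", "replisome"),
]
_NEUTRAL_PATHS = [
    ("metabolism", "central_carbon", "glycolysis"),
    ("metabolism", "central_carbon", "tca_cycle"),
    ("metabolism", "amino_acids", "biosynthesis"),
    ("transport", "membrane_transport", "small_molecule"),
    ("cell_envelope", "membrane_biogenesis", "lipids"),
]


def simulate_hierarchy(truth: pd.DataFrame, config: SimulationConfig | None = None):
    """Three-level functional classification correlated with the planted
    regulon: upregulated genes are mostly maintenance (folding/export/
    degradation), downregulated ones mostly translation/replication,
    the rest metabolism/transport.  Emulates a curated hierarchy file."""
    from .allocation import CategoryHierarchy

    config = config or SimulationConfig()
    rng = config.rng("hierarchy")
    rows = []
    for g, row in truth.iterrows():
        if row["direction"] == "up":
            pool = _UP_PATHS if rng.random() < 0.8 else _NEUTRAL_PATHS
        elif row["direction"] == "down":
            pool = _DOWN_PATHS if rng.random() < 0.8 else _NEUTRAL_PATHS
        else:
            pool = _NEUTRAL_PATHS
        path = pool[int(rng.integers(len(pool)))]
        rows.append(dict(protein_id=g, level1=path[0], level2=path[1], level3=path[2]))
    return CategoryHierarchy(paths=pd.DataFrame(rows).set_index("protein_id"))


# ---------------------------------------------------------------------------
# decay

def simulate_decay(
    true_half_life: float,
    timepoints,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> DecayCourse:
    """Chase course: intensity(t) = 100 x 2^(-t / t_half) x noise.

    ``true_half_life`` may be ``inf`` for a stable protein.
    """
    timepoints = np.asarray(list(timepoints), dtype=float)
    if timepoints[0] != 0:
        raise ValueError("timepoints must start at 0")
    if not (true_half_life > 0):
        raise ValueError("true_half_life must be positive (may be inf)")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(1, n_replicates + 1):
        decay = np.ones_like(timepoints) if math.isinf(true_half_life) else \
            np.power(2.0, -timepoints / true_half_life)
        intensity = 100.0 * decay * _lognormal_noise(rng, noise_cv, len(timepoints))
        for t, i in zip(timepoints, intensity):
            rows.append(dict(replicate=r, time_min=float(t), intensity=float(i)))
    return DecayCourse(data=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# disk output (CLI `regulonscope simulate`)

def write_simulation(outdir: str, config: SimulationConfig,
                     n_up: int = 300, n_down: int = 80, n_direct: int = 180) -> dict:
    """Generate every input and write it in plain-text formats."""
    os.makedirs(outdir, exist_ok=True)
    annotation, operons = generate_genome(config)
    truth = plant_regulon(annotation, operons, n_up, n_down, n_direct, config)
    track = simulate_chip_track(annotation, operons, truth, config)
    expr = simulate_expression(annotation, truth, CONDITIONS, config)
    lengths = protein_lengths_from_annotation(annotation)
    prot, prot_truth = simulate_proteome(truth, lengths, config)
    hierarchy = simulate_hierarchy(truth, config)
    course = simulate_decay(23.5, (0, 10, 20, 40, 80), config.noise_cv, config.seed,
                            config.n_replicates)

    paths = {
        "annotation": os.path.join(outdir, "annotation.gff3"),
        "operons": os.path.join(outdir, "operons.tsv"),
        "chip_track": os.path.join(outdir, "chip.bedgraph"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "expression_samples": os.path.join(outdir, "expression_samples.tsv"),
        "proteome": os.path.join(outdir, "proteome.tsv"),
        "proteome_samples": os.path.join(outdir, "proteome_samples.tsv"),
        "lengths": os.path.join(outdir, "protein_lengths.tsv"),
        "hierarchy": os.path.join(outdir, "hierarchy.tsv"),
        "decay": os.path.join(outdir, "decay.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "protein_truth": os.path.join(outdir, "protein_truth.tsv"),
    }
    annotation.to_gff3(paths["annotation"])
    operons.to_tsv(paths["operons"])
    track.to_bedgraph(paths["chip_track"])
    expr.values.to_csv(paths["expression"], sep="\t")
    expr.conditions.rename("condition").rename_axis("sample").to_csv(
        paths["expression_samples"], sep="\t")
    prot.values.to_csv(paths["proteome"], sep="\t")
    prot.samples.to_csv(paths["proteome_samples"], sep="\t")
    lengths.rename_axis("protein_id").to_csv(paths["lengths"], sep="\t")
    hierarchy.paths.rename_axis("protein_id").to_csv(paths["hierarchy"], sep="\t")
    course.to_tsv(paths["decay"])
    truth.rename_axis("gene_id").to_csv(paths["truth"], sep="\t")
    prot_truth.rename_axis("protein_id").to_csv(paths["protein_truth"], sep="\t")
    return paths
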