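# regulonscope

Mapping a bacterial sigma-factor regulon from heterogeneous functional
genomics data, and accounting for what that regulon does to the cell's
protein budget.

`regulonscope` is aimed at microbial systems biologists studying
alternative sigma factors — the exchangeable RNA-polymerase subunits
that redirect transcription during stress. The motivating system is the
heat shock sigma factor σ³² (RpoH) of *Caulobacter crescentus*, whose
activity is normally repressed by the DnaK/DnaJ chaperone; depleting the
chaperone unleashes σ³² and reprograms gene expression genome-wide. The
package turns that style of study into a tested, reusable pipeline:

1. **ChIP-seq peak calling and promoter assignment** (`regulonscope.chip`).
   Peaks are maximal runs of bins in a read-density track with density
   strictly above a threshold (default 10); each peak is summarised by
   the position of its maximum (bin-centre resolution, ±bin width) and
   its area (sum of bin densities). A peak is assigned to an ORF when
   the translation start lies within 200 bp upstream to 60 bp downstream
   of the peak maximum, measured along the gene's strand. Genes inside
   an operon inherit peaks assigned to upstream members (transcription
   order), because a promoter-proximal site drives the whole unit.
2. **Multi-condition regulon classification** (`regulonscope.transcriptome`).
   Fold changes FC = (x_cond + c) / (x_ref + c) on normalized expression.
   A gene joins the regulon in direction *d* iff it is ≥2-fold regulated
   in *d* after both 6 h and 9 h of chaperone depletion, concordantly
   ≥2-fold regulated upon overproduction of constitutively active
   σ³²(V56A), and shows a milder or absent response in the Δ*rpoH*
   deletion background (|log₂ FC_ΔrpoH| < log₂ 2, or a sign-concordant
   response ≥2-fold smaller on the log scale than the wild-type
   depletion response). Upregulated members with promoter ChIP evidence
   are flagged *direct* targets. Cross-condition agreement is summarised
   by R² and slope *m* of the log₂ fold-change scatter.
3. **TMT proteomics** (`regulonscope.proteome`). Per-sample abundances
   normalized to portions of 100 %; fold change = mean(exp)/mean(ctrl)
   over replicates; Student's *t*-test (pooled variance, Welch optional)
   on log₂ abundances; regulated-protein calls at ≥1.5-fold, p ≤ 0.05;
   Venn-style intersection with the transcriptional regulon.
4. **Proteome mass-fraction allocation** (`regulonscope.allocation`).
   Molecular investment = relative molecular count × sequence length,
   renormalized to mass fractions summing to 100 % and aggregated over a
   hierarchical functional classification; percent change between
   conditions is Δfraction / fraction_ref × 100.
5. **Protein half-lives** (`regulonscope.decay`). First-order decay
   fitted by log-linear OLS with a shared rate across replicates
   (t½ = ln 2 / k); estimates slower than the chase window are reported
   censored, e.g. "t1/2 > 360 min".
6. **Synthetic data with planted truth** (`regulonscope.simulate`).
   Every input above can be generated with known regulon membership,
   direct-target structure, effect sizes and half-lives, so the whole
   pipeline is testable end to end without downloads.

## Worked example

```python
from regulonscope.simulate import SimulationConfig
from regulonscope.pipeline import run_pipeline, score_against_truth

cfg = SimulationConfig(seed=42, n_genes=1000, n_operons=100, noise_cv=0.2)
res = run_pipeline(cfg, n_up=100, n_down=25, n_direct=60)
print(res.chip_summary)
print(res.stats)
print(score_against_truth(res.regulon, res.truth))
```

prints (abridged):

```
{'n_genes': 1000, 'n_flagged': 60, 'tp': 60, 'fp': 0, 'fn': 0,
 'sensitivity': 1.0, 'specificity': 1.0}
{'n_up': 98, 'n_down': 25, 'n_direct': 58,
 'r2_dep6_vs_v56a': 0.861, 'slope_dep6_vs_v56a': 0.912,
 'r2_dep6_vs_rpoHdel': 0.027, 'slope_dep6_vs_rpoHdel': 0.059}
{'tp': 123, 'fp': 0, 'fn': 2, 'sensitivity': 0.984, 'specificity': 1.0, 'fdp': 0.0}
```

Reading: all 60 planted promoter peaks were called and assigned to the
intended genes or operon leaders (ChIP sensitivity and specificity 1.0).
At 20 % multiplicative noise the fold-change classifier recovers 123 of
the 125 planted regulon members with no false positives; the depletion
and active-sigma contrasts correlate strongly in log₂ space (R² 0.86,
slope ≈ 0.9) while the deletion background is uncorrelated (R² 0.03) —
the contrast structure the classifier exploits. Half-life fitting on a
simulated chase (true t½ 23.5 min, 5 % noise, triplicate) returns
`t1/2 = 23.2 min` with fit R² 0.998.

A CLI mirrors the stages (`regulonscope simulate | chip | regulon |
proteome | allocate | decay`); run `regulonscope --help`.

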