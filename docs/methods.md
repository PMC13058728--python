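# Methods

## Turnover model

The estimator assumes first-order protein degradation at steady state:
synthesis balances degradation, so over a heavy pulse of length
*t*<sub>s</sub> the light (pre-existing) channel of a peptide decays as
e<sup>−k·ts</sup> and the heavy channel accumulates as 1 − e<sup>−k·ts</sup>.
The heavy-to-light ratio is then Ψ = e<sup>k·ts</sup> − 1 (always
positive), and inverting gives the single-timepoint half-life

t½ = ts · ln 2 / ln(1 + Ψ),

a strictly decreasing function of Ψ. The identity is exact only under
steady state; growth, label recycling and incomplete label incorporation
all bias Ψ, which is why the raw-report filters below matter.

Per-record Ψ is the heavy/light ratio of that single peptide × sample
measurement — no pooling of ratios across replicates before the half-life
transform. Filters are applied in order, with per-rule removal counts
logged: contaminant accessions (flag column plus an optional id list — the
original contaminant library is a FASTA whose content is out of scope
here, so contaminants are declared by accession); rows where either
channel's raw intensity falls below the floor (default 1,000); rows with
Ψ above 100 or below 0.02. Retention at the exact bounds is inclusive,
reading "above"/"below" strictly.

Protein half-life per sample is the harmonic mean over unique peptides —
peptides observed under more than one protein accession are dropped
entirely. The harmonic mean of half-lives equals inverting the mean
degradation rate, so it weights fast-turnover peptides appropriately; it
never exceeds the arithmetic mean. The minimum peptide support is 1 by
default (configurable); the support count is always reported.

## Differential turnover

Each protein is tested with a one-way fixed-effects ANOVA across the three
genotypes within one condition, on **log2** half-lives: half-lives are
ratio-scale and right-skewed, and the 2× effects of interest are additive
on the log scale (raw scale available via `log_scale=False`). Proteins
with fewer than two non-missing replicates in any genotype are excluded
from the test and from the BH family — untested features carry no p-value.
BH adjustment runs across all tested proteins of that condition. Direction
per mutant is the sign of (mutant group mean − isogenic group mean),
reported only where p_adj < α; the collapsed per-protein call uses
either-mutant agreement by default with a stricter both-mutant mode.
Zero residual variance with unequal means (possible with constant
synthetic inputs) is reported as the smallest positive double and flagged
degenerate rather than as p = 0.

## Lipidomics

Species intensities are divided by their class-matched internal standard
measured in the same analytical run, which cancels run-level scale
(injection amount, instrument response) exactly; technical duplicate runs
are then averaged per biological sample. Tests run on log2(x + ε) with
ε = half the smallest nonzero value of that species, so occasional zeros
are usable without dominating the fold change.

Variance moderation follows the standard empirical-Bayes construction:
per-species residual variances are modeled as scaled chi-square draws
around species variances with a scaled inverse-chi-square prior
(s0², d0); the prior is fitted by method of moments on the observed
variances (marginally s²/s0² ~ F(df, d0)), the posterior variance is the
precision-weighted blend, and the moderated F gains d0 denominator degrees
of freedom. d0 = ∞ (observed spread no larger than sampling alone)
collapses to complete pooling; as d0 → 0 the moderated p-values converge
to the plain ANOVA, which is also available directly (`moderate=False`).
A species is "significantly altered" when p_adj < 0.05 **and**
|log2 fold change| > 1 in at least one mutant ("fold change > 2" in either
direction).

## Preranked GSEA

Features are ranked by sign(effect) × −log10(p) (ties broken by feature
id). The enrichment score of a set is the extremum of the weighted KS
running sum: hits add |stat|^w normalized by the summed hit weights
(w = 1 by default), misses subtract 1/(N − N_hits); the extremum is
resolved to the earliest list position on exact ties. The null re-scores
random member sets of the same size (gene-label permutation — the
preranked convention, since only statistics, not per-sample data, enter).
p = (b + 1)/(n_same_sign + 1), pseudocounted so no p is zero, with b the
same-sign null scores at least as extreme; NES divides ES by the mean
|null ES| of matching sign so positive and negative scores are comparable.
BH runs across sets. Multiple gene-set databases are just multiple GMT
inputs. The adaptive multilevel estimation of very small p-values used by
fast fgsea-style implementations is intentionally not reproduced; the
permutation count bounds the resolution.

## Integration and client nomination

Interactors are entries with pulldown enrichment ratio strictly greater
than 10. Cross-referencing classifies each interactor per condition as
prolonged/accelerated (p_adj < α plus direction call) and aggregates into
both/first-only/second-only counts; interactors absent from both tested
sets are reported as unquantified, and a protein prolonged in one
condition but accelerated in the other counts as prolonged (partition
stays disjoint).

Feature selection keeps features whose MAD (unscaled median absolute
deviation) reaches the 75th percentile of the MAD distribution
(linear-interpolation quantile); constant features are never kept.
Cross-layer association is Pearson correlation on log2 values over the
shared samples (Spearman available), with complete-observation handling
per pair and a 3-observation minimum. The candidate rule applies the
threshold to |r| with the sign preserved in all reports: the r > 0.6
convention is read as magnitude because biologically meaningful partners
include negatively correlated ones (lipid species depleted as the client
accumulates). Candidacy requires significance under the glucose-starvation
condition by default (the condition where the client biology is expected);
a both-conditions mode exists. Raising the enrichment cutoff or the
correlation threshold can only shrink the candidate set.

The latent-variable (sPLS-DA) multi-block integration used in some
multi-omic workflows is deliberately replaced by direct pairwise
correlation: the nomination rule is stated in terms of a correlation
threshold, and pairwise r is transparent and testable against planted
ground truth.

## Synthetic data generator

The generator emulates the study conditions: 3 genotypes (isogenic
reference + P497H + P506T) × 2 media conditions (CM, GS) × 4 biological
replicates, 2-day pulse. Defaults: 200 proteins × 6 peptides, median
half-life 2.5 days (log-sd 0.5), 15% of proteins prolonged 2× in the
mutants and 3% shortened (affected in both or one condition), 120 lipid
species in 6 classes with TAG and CE multiplied by 0.25 in mutants, 400
transcripts (10% with a 2× mutant effect), 20 interactors (ratio > 10)
of which 5 are planted clients, 60 sub-threshold decoy entries.

Peptide channel intensities are abundance × ionization factor × channel
fraction × lognormal noise (σ = 0.2 per channel). The two channels of one
record share a common-mode noise component (correlation ρ = 0.5 of the
log-variance): sample handling and spray variation act on both isotope
channels of a peptide equally and partially cancel in the ratio, which is
why SILAC ratio CVs run below intensity CVs; the ratio log-sd is
σ·sqrt(2(1−ρ)). Records with total intensity below 1,000 are emitted as
missing — missingness is intensity-dependent (MNAR), mirroring how an
intensity floor interacts with low abundance. Contaminant decoys are
included and flagged.

Internal standards are constant spikes with only a small residual
measurement error of their own (σ = 0.05): extraction and instrument
drift are shared with the analytes of the run (the run-scale factor,
σ = 0.3) and cancel under normalization.

Planted clients are interactors whose prolonged half-life co-varies with
designated partner features: the shared genotype effect (client half-life
up 2×, partner lipid/transcript down) carries most of the coupling, and a
per-sample latent factor z ~ N(0,1) — added with loading 0.15 to the
client's log half-life and −0.5 to each partner — aligns replicate-level
deviations, giving |r| ≥ 0.8 before measurement noise while leaving the
clients clearly significant. All randomness derives from one seed through
named child streams, so individual generators are reproducible standalone
and mutually consistent.

What the generator does **not** emulate: peptide detectability and
retention-time structure, shared peptides between real protein groups,
isotope impurity and label recycling, lipid annotation ambiguity,
count-level RNA-seq noise, batch effects. Passing tests therefore
demonstrate the correctness and calibration of the pipeline under the
stated model, not robustness to those real-data pathologies.

## Problem sizes and numerical choices

The proteome-scale calibration studies run on a pure-array path
(`simulate_turnover_arrays` → `half_life_from_intensity_arrays` →
matrix ANOVA) that shares its arithmetic with the DataFrame pipeline:
false-discovery calibration uses 500 null data sets of 2,000 proteins
(3 × 4 design), and power uses 1,000 proteins with 15% prolonged 2×.
These sizes give stable empirical rates while keeping the whole suite
fast. Tables are written with 13 significant digits so write→read
round-trips are stable to 1e-12 relative. Seeds are explicit everywhere;
the CLI derives stage streams deterministically from one master seed.

## Known limitations

- The single-timepoint equation is exact only at steady state; dividing
  cells or strong global synthesis changes violate it.
- One pulse length cannot resolve half-lives far from t_s: at 2 days,
  both very fast (Ψ > 100) and very slow (Ψ < 0.02) turnover is censored
  by the ratio filter, which is the intended behavior.
- The method-of-moments prior fit is cruder than a likelihood fit on
  log-variances; it errs toward weaker moderation on heavy-tailed
  variance distributions.
- Permutation GSEA p-values are floor-limited at 1/(n_perm + 1).
- With class-shared internal standards, p-values of species in the same
  class are correlated; BH still controls FDR, but dispersion of
  rejection counts across data sets is larger than under independence.
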