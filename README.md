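# turnomix

Protein turnover from single-timepoint dynamic SILAC, with downstream
multi-omic prioritization of the client proteins of a degradation adaptor.

## The problem

In pulse SILAC, cells are switched to media containing heavy isotope-labeled
amino acids; after a fixed sampling time *t*<sub>s</sub>, newly synthesized
protein carries the heavy label while pre-existing protein remains light.
Under first-order turnover at steady state, the heavy-to-light peptide
abundance ratio Ψ = H/L measured by LC–MS/MS encodes the degradation rate
*k* of the parent protein:

    L ∝ e^(−k·ts),   H ∝ 1 − e^(−k·ts)   ⟹   Ψ = e^(k·ts) − 1

so a protein's half-life follows from a single timepoint:

    t½ = ts · ln 2 / ln(1 + Ψ)

`turnomix` implements this estimator together with the full analysis
pipeline built around it, as used to study motor neurons carrying mutations
(P497H, P506T) in the proteostasis factor UBQLN2 against their isogenic
control, under basal (CM) and glucose-starvation (GS) conditions:

1. **turnover** — report filters (contaminants, raw intensity < 1,000,
   Ψ outside [0.02, 100]), per-peptide half-lives, harmonic-mean
   aggregation over unique peptides per protein and sample, and per-protein
   one-way ANOVA on log2 half-lives across genotypes with
   Benjamini–Hochberg correction.
2. **lipidomics** — internal-standard normalization per analytical run,
   technical-duplicate averaging, and a moderated one-way ANOVA
   (empirical-Bayes variance shrinkage) per lipid species, with
   significance defined as p_adj < 0.05 and fold change > 2.
3. **enrichment** — preranked GSEA: weighted Kolmogorov–Smirnov running-sum
   enrichment scores, gene-label permutation null, sign-stratified NES,
   BH across sets.
4. **integration** — pulldown interactors (heavy/light enrichment ratio
   strictly > 10) cross-referenced with differential turnover in both
   conditions; MAD feature selection (75th percentile) on the lipid and
   transcript layers; cross-layer Pearson correlation; client candidates =
   interactors with altered turnover and at least one partner at |r| ≥ 0.6.
5. **synthetic data** — a generator that emulates the whole study design
   (3 genotypes × 2 conditions × 4 replicates, 2-day pulse) with known
   ground truth, including planted client proteins, so every stage is
   testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1) and write their tables under `results/`:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_protein_half_lives.py
python analysis/03_lipid_differential.py
python analysis/04_enrichment.py
python analysis/05_prioritize_clients.py
```

`02_protein_half_lives.py` prints

```
quantified 200 proteins across 24 samples
median half-life 2.54 days
[CM] 28 of 200 tested proteins altered (p_adj < 0.05); 23 prolonged, 4 shortened in the mutants
[GS] 29 of 200 tested proteins altered (p_adj < 0.05); 24 prolonged, 5 shortened in the mutants
```

— most altered proteins have *longer* half-lives in the mutants, matching
the generator's truth (15% of proteins prolonged 2×, 3% shortened). The
lipid stage finds the planted depletion of storage lipids:

```
[GS] 40 species significantly altered (p_adj < 0.05, fold change > 2); by class: {'CE': 20, 'TAG': 20}
```

and the final stage nominates clients and checks them against the planted
truth:

```
5 client candidates (p_adj < 0.05 under GS, |r| >= 0.6):
  P0101: enrichment 25.3, p_adj 1.26e-05, best r -0.98 (lipid:TAG_000, 68 edges)
  ...
planted-client recovery: 5/5 recovered, 0 false positives (precision 1.00, recall 1.00)
```

The negative correlations (candidate half-lives up, partner lipid species
down) are exactly the planted multi-omic coupling.

The same stages are available as a CLI for arbitrary input tables:

```sh
turnomix simulate --seed 1 --out-dir data
turnomix halflife --peptides data/peptides.tsv --out-dir results
turnomix all --seed 1 --out-dir results   # chain everything
```

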