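# popfit

Barcode-lineage fitness inference and population-genetic tests for pooled
variant screens.

Massively parallel editing screens measure the fitness effects of natural
genetic variants by competing thousands of barcoded, individually edited
lineages in one pool and sequencing the barcode region over serial batch
transfers.  `popfit` implements the downstream computational pipeline:

1. **Fitness inference** — a hierarchical Bayesian model of barcode count
   trajectories.  Lineage frequencies follow
   `f_{t+1}(j) = f_t(j) exp((s(j) − s̄_t) τ)`, with per-replicate fitness
   `s(j,n) ~ N(φ(j), σ_hyper²)` drawn around an edit-level *hyperfitness*
   `φ(j)`, and the mean-fitness nuisance series `s̄_t` identified by
   non-editing neutral anchor barcodes (`s = 0` by construction).  The
   observation model is Gaussian on log-frequency increments with the full
   delta-method read-noise covariance plus a count-scaled drift term;
   conditional on three noise hyperparameters the model is exactly
   Gaussian, and the default engine solves it in closed form (an MCMC
   engine over the hyperparameters is available).  A variant is called
   non-neutral in a condition when the 95% credible interval of `φ`
   excludes zero.
2. **Population statistics** — carrier-strain allele frequencies,
   singletons and per-strain singleton counts (a strain-age proxy),
   frequency-matched neutral controls (nearest allele frequency, Jaccard
   tie-break), co-occurrence tests on the mean pairwise Jaccard similarity
   `J(A,B) = |A∩B| / |A∪B|` of carrier sets, and Fitch parsimony /
   retention index of variants on the strain tree.
3. **Enrichment** — per-strain `N_beneficial − N_control`, Wilcoxon
   comparisons between domesticated / wild / other clades and industrial /
   natural ecologies, an allele-frequency threshold sweep, and the linear
   mixed model `diff ~ ecology + (1 | clade)`.
4. **Structure annotation** — residue packing density (other Cα atoms
   within 10 Å) from PDB/mmCIF coordinates, plus SIFT / ΔΔG threshold
   flags and property comparisons.
5. **Synthetic data** — generators for competition count tables
   (multinomial bottleneck + sequencing noise, hitchhiker outlier
   barcodes) and clade-structured strain panels with known ground truth,
   so every stage is testable without external data.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a screen with known truth, fit the hierarchical model, and
classify variants:

```python
import numpy as np
from popfit import (CompetitionDesign, ModelConfig, aggregate, classify,
                    fit_hierarchical, remove_outlier_barcodes,
                    replicate_concordance, simulate_competition)

design = CompetitionDesign(
    n_edits=60, barcodes_per_edit=5, n_neutral_barcodes=15,
    n_replicates=3, conditions=("2D",), n_timepoints=7,
    reads_per_timepoint=1_000_000, bottleneck_cells=2_000_000, seed=42,
)
counts, truth = simulate_competition(design)
neutral = set(design.neutral_ids)
agg = aggregate(remove_outlier_barcodes(counts, neutral_ids=neutral))
post, mean_fitness, diagnostics = fit_hierarchical(agg, neutral,
                                                   ModelConfig(), tau=design.tau)
post = classify(post, 0.95)

calls = post.summary[~post.summary.is_neutral_anchor]
print(calls.classification.value_counts().to_dict())
s_true = truth.s_vector("2D", design.edit_ids)
est = calls.set_index("edit_id").loc[design.edit_ids, "phi_mean"].to_numpy()
print("pearson r vs truth:", round(float(np.corrcoef(s_true, est)[0, 1]), 4))
print(calls.sort_values("phi_mean").head(3)[
    ["edit_id", "phi_mean", "ci_lower", "ci_upper", "classification"]
].to_string(index=False))
```

prints

```
{'beneficial': 28, 'deleterious': 26, 'neutral': 6}
pearson r vs truth: 1.0
  edit_id  phi_mean  ci_lower  ci_upper classification
edit00054 -0.142177 -0.144391 -0.139962    deleterious
edit00013 -0.134998 -0.137346 -0.132650    deleterious
edit00029 -0.133880 -0.136118 -0.131642    deleterious
```

Of the 60 edited variants, 54 are called non-neutral at the 95% interval
and the posterior-mean hyperfitness tracks the simulated truth (r = 1.0 at
this read depth); the three strongest deleterious variants cost ~0.14 per
generation.  Replicates agree in rank
(`replicate_concordance(post)` → Spearman ρ ≈ 0.9998 for every pair).

The end-to-end pipeline (simulation → fitness → matching → co-occurrence →
enrichment → summary) runs from a config:

```
popfit run --outdir out --seed 7
```

and writes counts/fitness/matched-pairs/enrichment tables, a VCF, a newick
tree and a run manifest into `out/`.  Individual stages are exposed as
subcommands (`popfit fit-fitness`, `match-controls`, `cooccur`,
`strain-age`, `tree-stats`, `enrichment`, `sweep`, `ecology-model`,
`packing-density`).

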