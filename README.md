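# cqbatch

Two-stage batch-effect correction for microbiome OTU count tables, with a
built-in evaluation suite and a synthetic-data generator.

Microbiome counts collected across studies, sequencing runs or plates carry
non-biological variation — *batch effects* — that distorts beta-diversity
analyses and downstream inference.  Counts are awkward for classical
correction tools: heavily zero-inflated, over-dispersed, and tied to
per-sample sequencing depth.  `cqbatch` addresses both kinds of batch
effect:

- **Systematic effects** (a consistent per-batch mean shift) are removed
  with per-OTU negative-binomial regression on the nonzero counts,
  `log mu_ijg = sigma_j + X_i' beta_j + gamma_jg + log N_i`, followed by
  quantile-matching each count from its fitted batch distribution
  NB(mu_ijg, theta_jg) onto the batch-free distribution
  NB(mu_ij*, theta_j*), where `log mu_ij* = log mu_ijg − gamma_jg` and
  `theta_j*` averages the per-batch dispersions.
- **Nonsystematic effects** (batch-specific dispersion and zero-rate
  distortions) are aligned to a data-driven reference batch with a
  zero-inflated composite quantile regression: a logistic model for the
  nonzero probability `q_ij`, a composite quantile fit
  `Q(tau) = b(tau) + X_i' alpha + B_i' delta` with shared slopes over a
  19-level grid, and the two-branch zero-inflated quantile function
  `Qc(tau) = 0` below `1 − q_ij` and the rescaled positive branch above.
  Each sample's value is transported to the reference batch's conditional
  distribution at its own quantile level.

The reference batch is chosen by Kruskal-Wallis homogeneity screening plus
the lowest Robust CV (100 × MAD/median).  The evaluation suite reports
one-factor PERMANOVA R² with permutation p-values, PCoA coordinates and the
batch-labelled average silhouette on Bray-Curtis, Aitchison, Canberra and
Manhattan dissimilarities.  See `docs/methods.md` for the full model.

Intended users: bioinformaticians integrating 16S/metagenomic count tables
across studies, plates or runs before beta-diversity or association
analyses.

## Worked example

```python
import dataclasses
import cqbatch as cb

# a 4-batch study-shaped simulation: 232/43/23/62 samples, 200 OTUs,
# ~31% zeros, injected mean shifts + batch-specific dispersions/zero rates
cfg = dataclasses.replace(cb.presets()["hivrc_like"], seed=1)
table, design, truth = cb.generate(cfg)

result, reports = cb.run_pipeline(table, design, cb.RunConfig(n_perm=499, seed=1))
print("reference batch:", result.provenance["reference_batch"])
for which in ("before", "after"):
    print(which)
    print(reports[which].to_frame().to_string(index=False))
```

prints

```
reference batch: B3
before
     metric  permanova_r2  permanova_p  avg_silhouette
bray_curtis      0.177695        0.002        0.056834
  aitchison      0.011964        0.002       -0.042599
   canberra      0.157540        0.002        0.038216
  manhattan      0.141293        0.002       -0.151487
after
     metric  permanova_r2  permanova_p  avg_silhouette
bray_curtis      0.029687        0.002       -0.046449
  aitchison      0.006894        1.000       -0.009058
   canberra      0.036740        0.002       -0.018914
  manhattan      0.017007        0.008       -0.125428
```

Reading: the fraction of distance-based variance explained by batch
(PERMANOVA R²) drops about six-fold on Bray-Curtis and eight-fold on
Manhattan after correction, and the average silhouette of batch labels
moves toward 0 —
batches that were separable before correction are intermingled afterwards.
(The exact numbers above are reproduced by the same seed; see below.)

The same pipeline runs from the shell:

```sh
cqbatch simulate --preset hivrc_like --seed 1 --out sim/
cqbatch run --counts sim/counts.tsv --metadata sim/metadata.tsv \
            --covariates x1,x2 --seed 1 --out results/
```

`results/` then holds the corrected table (`corrected.tsv`), the
stage-1-only table, a per-OTU fit summary, PCoA coordinates per metric, the
evaluation table and a provenance JSON that suffices to reproduce the run.

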