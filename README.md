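# permacomm

Community-ecology inference for permafrost vertical profiles: who assembles
the bacterial community (selection vs. drift), how connected and stable the
community is, and whether that stability is linked to soil carbon storage.

Deep permafrost cores yield taxa-by-sample count tables spanning strong
vertical gradients — an active layer that thaws seasonally, a frozen fringe,
and permafrost proper — replicated across sites that differ in degradation
stage. `permacomm` implements the full inference chain such studies run on
those tables:

* **Diversity** — richness, Shannon *H* = −Σ *p* ln *p*, Bray–Curtis
  β-diversity, PCoA, PERMANOVA, β-dispersion, and distance–decay of
  similarity against environmental distance.
* **Assembly processes** — a richness-preserving occurrence-frequency null
  model and the normalised stochasticity ratio (boundary 0.5: above =
  drift-dominated, below = selection-dominated); the Sloan neutral community
  model, fitting *Nm* in occupancy = 1 − BetaCDF(*d*; *Nm p*, *Nm*(1−*p*))
  to estimate the migration rate *m*; Levins niche overlap
  Σ*p*<sub>ij</sub>*p*<sub>ik</sub>/Σ*p*<sub>ij</sub>²; and a
  modified Mantel test that picks the best of Y~X, Y~ln(X), ln(Y)~X,
  ln(Y)~ln(X) per variable pair.
* **Co-occurrence networks** — SparCC basis correlations from the log-ratio
  variance system (ρ<sub>ij</sub> = (ω<sub>i</sub>²+ω<sub>j</sub>²−T<sub>ij</sub>)/2ω<sub>i</sub>ω<sub>j</sub>),
  permutation pseudo-*p*, threshold presets (|r| > 0.35 for layer networks,
  |r| > 0.65 for site networks, *p* < 0.05), topology summaries, robustness
  under random edge attack scored by natural connectivity
  NC = ln((1/N) Σ e<sup>λᵢ</sup>), depth-averaging sample alignment,
  leave-one-out single-sample networks, and core-taxa edge analytics.
* **Stability and core taxa** — community stability = 1 − standardised
  average variation degree (AVD = mean |x−μ|/σ per sample), and core taxa =
  top 5% of species by mean relative abundance occurring in >70% of samples.
* **Degradation and carbon** — a permafrost degradation index (PC1 of
  active-layer thickness and mean annual ground temperature), species-level
  Spearman trend analysis (0.01% abundance floor, top 20 responders),
  Kruskal–Wallis group comparisons with BH correction and compact letters,
  consecutive-group percent change in permafrost organic-carbon density
  (POCD), and a stratum-adjusted permutation test for the stability–POCD
  association.
* **Synthetic profiles** — a generator producing the full study design
  (5 sites × 25 depths, two main layers / five sub-layers, depth-decaying
  covariates, mixed filtering/neutral assembly with known parameters, core
  taxa, and a POCD variable with a tunable stability slope) so every stage
  can be validated against ground truth.

## Worked example

Simulate a three-site profile and run the assembly, stability and gradient
stages:

```bash
permacomm simulate --outdir demo --seed 11 --n-sites 3 --depths-per-site 16 \
    --species-pool-size 150 --reads-per-sample 2000 --migration 0.3
permacomm assembly  --table demo/table.tsv --metadata demo/metadata.tsv \
    --outdir demo_assembly --n-null 50 --seed 1
permacomm stability --table demo/table.tsv --metadata demo/metadata.tsv \
    --outdir demo_stab
permacomm gradient  --table demo/table.tsv --metadata demo/metadata.tsv \
    --outdir demo_grad --seed 1
```

which prints:

```
wrote 150 taxa x 48 samples to demo
active: ratio=0.439 m=0.4183 R2=0.843
permafrost: ratio=0.557 m=0.4122 R2=0.955
8 core taxa; stability in [0.000, 1.000]
stability-POCD slope=-0.718 p=0.0300
```

Read: the active layer sits below the 0.5 stochasticity boundary (selection-
leaning; its default selection strength is higher than the permafrost
layer's), the permafrost layer above it; the neutral-model migration
estimates (~0.41) are near the simulated *m* = 0.3 given the non-neutral
admixture; 8 of the 150 simulated species qualify as core taxa; and the
stratum-adjusted stability–POCD slope (−0.72, permutation *p* = 0.03)
recovers the sign and rough magnitude of the simulated slope of −1.

`permacomm run-all --config cfg.yaml` executes the whole chain
(simulate/load → rarefy → diversity → assembly → stability → networks →
gradient) from one YAML config and writes TSV outputs plus a `manifest.json`
recording parameters, seeds, warnings and per-file checksums; a rerun with
the same config reproduces every checksum.

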