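# Methods

This note records the models behind each stage, the defaults that matter,
the reasoning behind choices that were genuinely open, and what the
synthetic-data tests do and do not demonstrate about real permafrost data.

## Data model and preprocessing

Counts are stored as integers throughout; relative abundances are computed
on demand and never persisted, so nothing can be normalised twice.
Threshold comparisons are inclusive (≥ / ≤) everywhere except the core-taxa
occupancy rule, which is strict (>) because "occurring in more than 70% of
samples" is a strict statement. The frozen fringe layer (FFL) straddles the
active/permafrost junction, so each FFL sample carries an explicit
`ffl_active` flag alongside its main-layer label.

Rarefaction draws without replacement (multivariate hypergeometric), which
conserves per-sample totals exactly and keeps the expected per-taxon
proportion equal to the pre-rarefaction proportion; the test suite checks
that expectation by averaging 250 seeds against a 3-standard-error band.

## Diversity

Shannon diversity uses the natural logarithm (the base is a convention;
ours is stated here and in the docstring). Bray–Curtis is computed on
(rarefied) counts. PCoA is classical scaling of the Gower-centred matrix;
negative eigenvalues — unavoidable for non-Euclidean dissimilarities — are
retained in the eigenvalue vector but excluded from the
`proportion_explained` denominator, which is the sum of positive
eigenvalues only: simple, common, and directly testable. β-dispersion
handles negative-eigenvalue axes the standard way (their squared
contributions are subtracted and the result floored at zero). PERMANOVA
permutes sample labels freely; stratified questions are answered by running
the test inside each stratum, not by restricted permutations.
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), so the resolution is
1/(n_perm+1); scikit-bio's implementations serve as independent
cross-checks in the tests.

## Assembly inference

**Null model.** Each null sample keeps its observed richness and total
count. Which taxa are present is redrawn with inclusion probability
exactly proportional to pool occurrence frequency, via systematic
probability-proportional-to-size sampling; sequential weighted draws
without replacement were rejected because they systematically flatten
inclusion probabilities (a χ² calibration against proportionality fails
decisively at 1000 nulls). Abundance is reassigned to the drawn taxa
proportionally to pool mean relative abundance *by drawing individuals*
(one guaranteed per drawn taxon, the remainder multinomial). A
deterministic expected-value allocation was rejected because it produces
nulls with no counting noise; observed communities then look more variable
than the null for purely statistical reasons and even neutral data score as
"deterministic".

**Stochasticity ratio.** For each within-group pair, similarity =
1 − Bray–Curtis. Where observed similarity exceeds the null expectation
(selection pulling communities together) the ratio is
E[sim_null]/sim_obs; where it falls below (selection pushing them apart)
the ratio is E[dis_null]/dis_obs. Both forms are 1 under pure
stochasticity, shrink with selection, and are clamped to [0, 1] (the raw
value is kept for audit); the group value is the mean over pairs. The 0.5
boundary separates predominantly stochastic (>0.5) from predominantly
deterministic (<0.5) assembly. Pairs with zero observed similarity cannot
be scored on the similarity scale and are set to 1 with a warning.
Defaults: 200 nulls (desk scale), configurable upward.

**Neutral model.** Occupancy is predicted as
1 − BetaCDF(d; Nm·p, Nm·(1−p)) with detection limit d = 1/(mean reads per
sample); Nm is fitted by unweighted nonlinear least squares on the
unbinned per-taxon (p, occupancy) points, in log-Nm from four starting
points to avoid local minima, and m = Nm / mean reads. R² = 1 − SSE/SST is
reported unclipped (it may be negative for non-neutral data); m > 1 is
flagged rather than hidden.

**Modified Mantel.** Y is the community distance vector, X the pairwise
absolute difference of a scalar covariate. Before any log, a series with
zeros or negatives is shifted by its minimum and residual zeros replaced by
0.05× the minimum positive value (ln ≈ −3.00). Four model forms are scored
by Pearson |r| and the best reported. The permutation reference replays the
entire selection — the statistic is max |r| over the four forms — because
permuting under a transformation chosen on the observed pairing is
anti-conservative (measured: 7.5% of null runs below p = 0.05); with the
selection replayed, null p-values are uniform (KS-checked in the tests).

## Networks

**SparCC.** T_ij = var(ln x_i/x_j) over samples, averaged over 20
Dirichlet resamples of each sample's composition (pseudocount 1); basis
variances solve the sparsity-assuming linear system
t_i = (D−2)ω_i² + Σ_j ω_j², and ρ_ij follows from the law of cosines on
log-scale variances, clipped to [−1, 1]. Up to 10 exclusion iterations
remove the strongest pair above |ρ| = 0.1 from the sums. Each sample's
Dirichlet resamples are seeded from that sample's own counts, which makes
the estimate exactly invariant to sample order and keeps leave-one-out
re-estimates mutually consistent — properties the sample-specific network
construction relies on. A cross-method oracle (Pearson correlation of
clr-transformed counts) agrees within 0.1 mean absolute difference on
50-taxon test beds. Pseudo-p values shuffle each taxon's counts across
samples independently; p = (1+hits)/(1+n_boot), default n_boot = 99.

**Thresholds and topology.** Layer networks keep |r| > 0.35, site networks
|r| > 0.65, both with p < 0.05. Isolated nodes are dropped after
thresholding (node counts before pruning are recorded) so density and
degree describe the connected vocabulary. Modularity uses deterministic
greedy modularity maximisation; eigenvector centrality is computed on the
largest component; linkage density (complexity) = 2E/N.

**Robustness.** Natural connectivity NC = ln((1/N) Σ exp λ_i) over
adjacency eigenvalues, computed by symmetric eigendecomposition with a
log-sum-exp guard; an edgeless graph gives exactly 0. The default attack
is uniform random edge removal; a deterministic targeted attack
(descending edge betweenness) is available behind a flag. The curve
reports mean NC over replicates and NC(f)/NC(0).

**Sample alignment.** Groups are equalised to the minimum group size by
repeatedly averaging the two adjacent-depth samples with the smallest depth
gap (counts = rounded mean, depth = mean), preserving depth order.

**Single-sample networks.** The per-sample association of a core pair is
the leave-one-out linear perturbation N·ρ_all − (N−1)·ρ_without_s on the
core submatrix; a sample's interaction is the number of core pairs whose
score magnitude exceeds the edge threshold. This construction is validated
against internal-consistency properties (duplicated samples score
identically; i.i.d. samples show no outliers; a planted single-sample
excursion is attributed to the right sample), not against an external
reference — treat its absolute values as relative, not calibrated.

## Stability and core taxa

AVD for sample s averages |x_is − μ_i|/σ_i over the group's taxa with
σ_i > 0, computed on relative abundances so depth-of-sequencing differences
cannot masquerade as instability. "Standardised" AVD is min–max over the
analysis set, so stability = 1 − standardised AVD lies in [0, 1] and is
strictly decreasing in AVD; z-scoring is a reasonable alternative and the
standardisation tag is carried in the output. σ uses ddof = 1, with a
1e-12 floor so identical proportions (float residue ~1e-16) count as
zero-variance. Core taxa are the intersection of the top
ceil(0.05·S) species by mean relative abundance (ties broken by taxon id)
and occupancy strictly above 70%.

## Degradation gradient and carbon

PDI is PC1 of z-standardised site-level ALT and MAGT, sign-oriented so
corr(PDI, ALT) > 0 (larger = more degraded); z-standardisation makes the
ranking invariant to affine rescaling of either input. Species trends
filter at 0.01% mean relative abundance, correlate each species with the
ordinal gradient (Spearman), BH-adjust, and rank by |r|. Group comparisons
are Kruskal–Wallis omnibus plus pairwise two-sided Mann–Whitney with BH
correction; compact letters come from a greedy insert–absorb assignment
with deterministic ordering. POCD percent change is
100·(next − prev)/prev per consecutive ordered group, which composes
multiplicatively back to the final mean.

The stability–POCD association regresses POCD on stability with one
fixed-effect indicator per stratum level (sub-layer by default, site as an
option), reporting the stability coefficient, the partial correlation
t/√(t²+df), and a p-value from permuting stability within strata. This is
a deliberate replacement for a random-intercept mixed model: with five
levels the fixed-effect estimand is the same, and the permutation gives
exact finite-sample inference with no convergence machinery. Singleton
strata are merged into the level with the nearest mean POCD and flagged.

## Synthetic-data generator

The generator emulates a degraded-permafrost coring campaign: K = 5 sites
ordered by degradation, 25 depths each from 0.1 to 15 m (dense near the
surface), per-site active-layer thickness (ALT) rising 1.25 → 2.65 m and
MAGT −2.2 → −0.6 °C along the site index, and covariates with
depth-decaying (Tp, PWC, POM, TN) or depth-rising (pH) deterministic parts
plus Gaussian noise (strictly monotone when the noise scale is zero).
Sub-layers: TAL ≤ 0.5 m; FFL within ±0.25 m of ALT; SAL between; TPL to
12 m; SPL below.

Community composition per sample is α·w(E) + (1−α)·π_neutral:

* **Filtering part.** The environmental axis is a single standardised
  log-depth coordinate — the measured covariates are strongly collinear
  with depth, and one axis suffices for ground-truth tests. Species have
  Gaussian niches exp(−(E−opt)²/2σ²) with σ = `niche_breadth`
  (default 0.4), multiplied by metacommunity weight; core taxa get
  mid-profile optima so they remain generalists.
* **Neutral part.** π_neutral is drawn i.i.d. per sample from
  Dirichlet(Nm_true·metacommunity) with Nm_true = migration × reads. This
  is the stationary distribution of a Wright–Fisher local community with
  immigration, so neutral data are Sloan-neutral *by construction* and the
  migration rate is recoverable by the fitting code — parameter recovery
  tests a correspondence, not a simulation accident.
* **Metacommunity.** Log-normal with σ_ln = 2.0 — the dominance-skewed
  species-abundance distribution typical of soil communities; a flatter
  pool makes every null-model comparison insensitive. The top 5% of
  species (the designated cores) receive uniformly high weights drawn from
  the pool's 90th–99.5th percentile band, which guarantees ≥70% occupancy
  at the default read depth.
* **Counts.** Dirichlet-multinomial with concentration θ defaulting to the
  read depth, i.e. roughly twice-multinomial variance — enough
  overdispersion to exercise SparCC without drowning the Sloan structure
  (θ must stay well above Nm_true for the migration rate to remain
  identifiable from occupancy).
* **POCD.** Attached as baseline + slope·stability + noise, where the
  latent is the realised AVD stability of the generated table and the
  baseline is piecewise-constant over the five sub-layer bands. A smooth
  depth baseline was rejected: no stratum adjustment can absorb it, the
  association's slope-0 null is then wildly biased, and the generator
  would make its own headline test meaningless. With the banded baseline
  the slope-0 null is unbiased (≈5% false positives) and a truth slope of
  −1 is estimated at −0.93 on average.

Defaults: 5×25 = 125 samples, 300 species, 20 000 reads, migration 0.05
(Nm_true = 1000), selection strength {active: 0.6, permafrost: 0.3} —
the active layer is modelled as more selection-driven. Scaled-down test
configurations (2 sites × 12 depths, 150 species, 2000 reads) raise
migration to 0.3 so Nm_true stays near 1000 and the system remains in the
same dynamical regime; these are the problem sizes the acceptance script
uses. All randomness flows from one master seed through named substreams
(metadata / community / pocd).

**What the generator does not emulate:** phylogenetic structure (no tree,
so no βNTI-style inference), multi-axis environmental filtering,
taxon-specific read-length or copy-number biases, temporal dynamics, and
archaea/fungi/viruses. Passing tests therefore demonstrate that the
inference chain recovers known structure from data obeying its model
assumptions — not that real permafrost metagenomes obey them.

## Numerical conventions

Permutation p-values are (1 + hits)/(1 + n), never zero. Basis variances
from the SparCC linear system are floored at 1e-12 before the square root.
Eigendecompositions use symmetric (`eigh`) routines. Dirichlet draws are
standard-gamma ratios with concentrations floored at 1e-8. Ties in
abundance ranking break by taxon id; compact-letter assignment and greedy
modularity use deterministic orderings. The pipeline manifest records
per-file SHA-256 checksums; two runs with the same config are
byte-identical.

## Known limitations

The stochasticity ratio's absolute level depends on the null model's
variance structure, which the literature does not pin down uniquely; the
implementation here is declared (PPS occurrence draws + multinomial
abundance), and conclusions should rest on contrasts (between layers,
between regimes), not on absolute ratios. The single-sample network
construction is a linear perturbation heuristic. SparCC correlations
attenuate toward zero for taxa near the counting-noise floor, so edge
absence among rare taxa is weak evidence. The fixed-effect association is
an approximation to a mixed model that is exact only in estimand, not in
variance partitioning.
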