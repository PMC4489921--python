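# Methods

## 1. The generative model

The simulator produces one chromosome (default 60 Mb at 2-Kb bins)
annotated with topological domains, cohesin/CTCF sites and genes, and
draws Hi-C, 4C-seq and expression data for a wild-type and a
cohesin-knockout condition from the same annotation. Its purpose is to
plant, at realistic sequencing depth, exactly the statistical structure
the estimators are meant to recover, so that every analysis can be
scored against known truth.

### Annotation

- **Domains.** The bin range is partitioned into `n_domains` intervals
  (default 60, mean 1 Mb) with gamma-distributed sizes (shape 4, at
  least 400 Kb) and a Bernoulli(active_fraction) activity class; both
  classes are guaranteed to occur.
- **Cohesin/CTCF (COH) sites.** A Poisson point process per domain with
  mean spacing 60 Kb in active and 90 Kb in passive domains (co-occupied
  Rad21/CTCF sites number ~30–40k per mammalian genome, and active
  chromatin carries them more densely). Every internal domain border
  additionally carries a COH site — borders in real maps are strong
  binding sites.
- **Accessory site classes.** CTCF-without-cohesin, cohesin-without-CTCF
  and putative-enhancer positions are placed genome-wide (spacings 250,
  350 and 200 Kb) with *no* structural role; they are the negative
  controls for the class-selectivity analyses.
- **Loop anchors.** Loops are planted between intra-domain COH pairs
  with at most `loop_max_skip = 3` intervening sites (consecutive plus
  nested/skipping pairs, as extrusion between flanking sites produces),
  plus each domain's border-most pair. Pairs are tagged by kind;
  anchor-pair analyses pool the consecutive kind.
- **Genes.** TSS density is 20 per Mb, three-fold elevated in active
  domains. Each gene carries a baseline log2 expression
  ~ N(5, 2) and a planted knockout response (below).

### Contact intensity

For bins i < j at offset k the expected intensity is

    λ_ij = s · b_i · b_j · k^α · S_ij · B_ij

with

- α the condition's **decay exponent** (−1.0 wild type, −1.15 knockout),
- b per-bin log-normal **technical biases** (sd 0.3 in log, geometric
  mean 1, drawn independently per condition),
- S_ij the **local structure factor**: ×2 (active_intensity_ratio) when
  both bins share an active domain; ×site_attenuation per crossed COH
  site for pairs closer than `site_insulation_range` = 300 Kb, capped
  at 6 effective crossings; ×2 (anchor_enrichment, wild type) within
  one bin of a planted anchor pair, ×1 in the knockout;
- B_ij the **border factor**: ×border_attenuation per domain border
  crossed (0.5 wild type, 0.75 knockout).

Three structural conventions matter and are deliberate:

1. **S is renormalized to unit mean on every diagonal.** Local structure
   *redistributes* contacts within a genomic separation; consequently the
   marginal contact probability follows k^α exactly and the decay
   exponent is an honest, recoverable knob. Without this, insulation
   strength leaks into the fitted exponent and the wild-type map would
   spuriously decay faster than the knockout.
2. **B is applied raw.** Domain demarcation genuinely removes
   cross-border contacts from the library rather than conserving
   per-distance totals; relaxing borders in the knockout therefore adds
   inter-domain contacts in absolute terms, which is what a difference
   map should see.
3. **Site insulation is local** (≤ 300 Kb): cohesin sites shape their
   local contact environment at the 10–80 Kb scales even when they are
   not domain borders, while borders act at all scales. This preserves
   the scale hierarchy that large-band border calling relies on.

Per-site attenuation is quoted for passive-domain sites (0.4 wild type,
0.85 knockout) and rescaled for active-domain sites so the per-bp
insulation rate (1 − a)/spacing matches across classes; otherwise the
denser active sites would attenuate active domains more and confound the
planted two-fold activity ratio.

`depth` (2×10⁷) is the library's expected chromosome-wide cis pair
count. Contacts are stored in a banded matrix up to `max_distance`
(3 Mb; every analysis here uses separations ≤ 2 Mb), and the band
receives the share of the library that the condition's decay places
within it — the knockout's sharper decay concentrates more of the same
library at short range, a real global signal. Counts are independent
Poisson draws; `expected_band_total` returns the exact expected band
total for conservation checks. All outputs (both Hi-C conditions, each
4C viewpoint, expression) use separate child streams of one root seed.

### 4C and expression

A 4C profile is a Poisson draw of the viewpoint's row of λ (structure
and decay included, without the per-diagonal renormalization, which is a
whole-map construct; 4C statistics are positional contrasts at matched
distances and are unaffected), zeroed within ±10 Kb of the viewpoint and
scaled to `fourc_depth` = 10⁶ expected reads.

The planted knockout response of gene g is

    shift_g = σ · ( w·u_I(g) + √(1−w²)·ε_g ) + direct_g − γ·σ·z_base(g)

with σ = `interval_effect_sd` (0.5 log2 units), u_I a shared standard
normal per inter-COH-site interval, and w set analytically so that the
correlation of shifts for genes sharing an interval equals
`response_within_interval_corr` (0.4) *after* accounting for the
direct-effect variance. Direct effects of ±3 log2 units hit genes with
probability 25% if their TSS lies within 1 Kb of a COH site and 1%
otherwise. γ (`baseline_coupling`, default 0) plants a mean-reverting
response for the baseline-trend analysis. Replicates (3 per condition)
add log-normal noise of 0.25 log2 units.

### What the generator does not emulate

No trans contacts, no restriction-fragment resolution or ligation
artefacts, no PCR duplicates or mappability structure, no cell-cycle
heterogeneity, and a single chromosome. Technical biases are purely
per-bin multiplicative. Passing tests therefore demonstrate estimator
correctness and power under this model, not robustness to every
real-data pathology.

## 2. Estimators and numerical choices

**Distance decay.** f(d) = (Σ counts in shell)/(# pairs in shell) over
log-spaced shells with ratio 2^0.25 from one bin to the band edge; the
exponent is a log-log least-squares slope over shell geometric
midpoints. The main diagonal (d = 0) is excluded everywhere.

**Biases.** Damped iterative proportional fitting:
b ← b · (m/E)^0.5 with E_i = b_i Σ_j b_j f(|i−j|) (FFT convolution),
geometric-mean renormalization each iteration, convergence at max
relative change < 1e-4 (cap 200; the undamped update oscillates). Bins
with marginals below 20% of the median are masked. The fitted log-biases
are then high-pass filtered by subtracting a centered 300-Kb rolling
median: marginal matching alone also absorbs domain-scale biological
intensity (an active domain inflates all its marginals), which would
cancel the very compartment signal the enrichment map is meant to show;
technical biases are bin-scale and independent, so the rolling median
cleanly separates the two. Plain IPF is available via
`detrend_window=None`.

**Enrichment.** e = log2((c+1)/(b_i b_j f(d)+1)); defined off-diagonal
on unmasked bins. The observed counts and the expectation are retained
on the matrix because several downstream statistics aggregate them
directly.

**Count-sum aggregation.** At 2×10⁷ pairs per 60-Mb chromosome, cells at
100–200 Kb hold counts of order 1, and the mean of log2((c+1)/(exp+1))
is biased toward zero (pseudocount plus Jensen): it under-reads a true
two-fold planted enrichment by ~30%. Window statistics therefore default
to log2(Σobs/Σexp) (insulation) and to the mean of per-pair obs/exp
ratios (pooling) — unbiased, and standard practice for insulation scores
and aggregate pileups. The literal per-cell mean of e is available as
`mode="log"`/`mode="mean"` and is what the exact brute-force oracles
also cover.

**Insulation.** I(x, w) aggregates pairs (i, j) with i ∈ [x−w, x),
j ∈ [x, x+w) — every contributing pair crosses x — with a minimum of 10
contributing pairs. Meta-profiles average I(s+o, w) over sites at
offsets |o| ≤ 2w; the peak-to-trough ratio is
2^(max P on (w/2, 2w] − min P on |o| ≤ w/2); trough and peak windows are
parameters. Quartile grouping ranks sites by I at the 80-Kb band,
breaking ties by coordinate.

**Border calling.** Borders are local minima of the 640-Kb track with
prominence ≥ 0.5 log2 units, at least 400 Kb apart (deeper minima win),
optionally below a global percentile. Prominence rather than a global
threshold because activity compartments shift the track's baseline by
±1 log2: active-side borders would sit above any global percentile. A
wide band localizes only coarsely (its trough bottom is flat over tens
of bins), so each coarse border is snapped to the 80-Kb-track minimum
within ±100 Kb. Domain classification standardizes two features per
domain — log2(Σobs/Σexp) over intra-domain pairs at 60–180 Kb and TSS
density — and runs k-means (k = 2, 10 seeded restarts, domains sorted by
coordinate first so the result is order-invariant); the TSS-dense
cluster is labelled active, and an all-identical feature matrix sets a
`degenerate` flag instead.

**Pair pooling.** Submatrices of ±40 Kb at 2-Kb bins are aligned on
coordinate-ordered pairs and averaged per cell. The center fold
compares the 3×3 center to the *inter-anchor quadrant* beyond ±20 Kb
from both anchors: those cells cross the same intervening material as
the center, so the fold isolates the anchor-point preference. An
all-quadrant ring background (`background="ring"`) sits in territory
attenuated by the anchors' own insulation and overstates the fold (~2.8
where 2.0 is planted). Distance-matched rigid-shift control pairs are
available (`shifted_control_pairs`) but off by default — with the
generator's per-diagonal renormalization the pooled baseline is already
flat, and the control only adds variance. Overlapping pair footprints
are allowed: pooling is a mean, not a test.

**Difference maps.** δ = e_B − e_A with the decay curve estimated from
condition A only and each condition's own bias vector, so that a global
decay change appears as signal. Scale matching defaults to
`match="library"`: each band total is extrapolated to a chromosome-wide
total using that condition's own fitted exponent before B is rescaled,
emulating sequencing-depth normalization of full libraries. Matching the
in-band totals directly (`match="band"`) forces the banded means to
agree and hides part of the knockout's short-range gain.

**4C.** RPM normalization over bins outside the exclusion zone (default
±10 Kb — the convention of 4C practice); 5-Kb centered sliding median;
domainograms as centered rolling means over ~20 geometrically spaced
windows from 2 to 50 Kb, quantile-rank scaled to [0, 1] per window
(midrank for ties) so scales are comparable. Rank scaling is for display
and cross-scale comparison; no statistic is computed from the ranks
except orderings.

**Expression.** Δ = log2((ko_mean+1)/(wt_mean+1)); genes with both means
below 1 are excluded. z = (Δ − median)/(1.4826·MAD) over included genes
— a robust cross-gene standardization (replicate-variance modelling is
deliberately out of scope); up/down calls at |z| > 2. "Downregulated"
means z < −2 (the symmetric reading; the threshold pair is otherwise
overlapping). Pair correlation uses TSS separations of 100–200 Kb,
"separating" means at least one COH site strictly between the TSSs, and
the same-vs-separated difference gets a 95% bootstrap CI (1000
resamples, independent within sets, seeded).

## 3. Default problem sizes

The test suite and the acceptance script run the full default
configuration: one 60-Mb chromosome, 2-Kb bins, contacts banded to 3 Mb,
2×10⁷ library pairs, ~870 COH sites, 1200 genes. A complete wild-type
pipeline (simulate, normalize, insulate, pool) takes ~25 s on one CPU;
the acceptance script averages five such studies in under a minute.
Large banded arrays are held in float32 (float64 below 2×10⁷ cells, so
the exact-equality oracle comparisons on toy maps run at full
precision); all reductions accumulate in float64.

## 4. Known limitations

- The per-bin IPF bias model cannot represent fragment-level covariates;
  with strong bin-scale *biological* signal of sub-300-Kb extent, the
  rolling-median high-pass would partially absorb it.
- The center-fold background assumes the inter-anchor region is
  representative; for pairs spanning strong heterogeneity (e.g., a
  border), intra/inter comparisons remain valid but absolute folds mix
  anchor preference with the crossed structure.
- Border calling assumes borders at least `min_domain` apart; nested or
  split domains are out of the model.
- The knockout decay exponent (−1.15) and the structural relaxations are
  jointly chosen so the difference map shows the intra-domain loss and
  the adjacent-domain gain together with a measurably sharper knockout
  decay; these are aspects of one underlying phenotype and the defaults
  keep all three visible at the default depth.
- Expression analyses treat genes as points (TSS) and ignore strand and
  gene length.
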