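# Methods

`paoscope` analyzes soil polyphosphate-accumulating-organism (PAO) communities
under a warming x clipping field factorial: it identifies the PAO
sub-community from FACS-sorted 16S OTU tables, quantifies taxonomic and
functional (single-cell Raman) diversity and functional redundancy, builds
RMT-thresholded co-occurrence networks with a full complexity/stability
metric suite, and links community metrics to ecosystem fluxes. Because the
original single-cell spectra and soil chemistry are not publicly deposited,
every stage is validated against a synthetic study generator with planted,
configurable effects. This note records the models, the defaults and why,
and what passing the synthetic validations does and does not show.

## The study design

Four treatments — CC (clipped control), UC (unclipped control), CW (clipped
warmed), UW (unclipped warmed) — with six replicates each (24 soil samples),
replicates assigned to six blocks round-robin so each block holds one
replicate of every treatment. For single-cell work the six replicates per
treatment are randomly pooled into three, and each pooled sample is measured
in two drops of 100 phenotypically confirmed cells (4 treatments x 6
replicates-worth x 2 drops x 100 = 4800 cells).

## Synthetic data generator (`paoscope.synth`)

**Counts.** Each sample's composition has a PAO block and a bulk block. A
block's composition is a log-normal base profile power-tilted to a planted
Shannon target

    H_target = base + beta_w*warming + beta_c*clipping + beta_wc*w*c
               + block intercept + noise,

with 15% of the block's mass held as a uniform abundance floor so no planted
taxon is driven below downstream abundance filters. Defaults: PAO base 2.6
(60 taxa), warming effect +0.5; bulk base 4.6 (240 taxa), warming effect
-0.3; block sd 0.04, residual sd 0.03 (nats). Counts are
Dirichlet-multinomial draws (concentration 1e5, depth 50 000). The
concentration was calibrated once so the count layer does not distort the
planted Shannon effects; over-dispersion and co-occurrence structure come
from the log-normal latent-factor layer below.

**Co-occurrence structure.** A per-sample latent factor perturbs taxon
abundances multiplicatively through taxon loadings, then the composition is
re-tilted to restore the Shannon target (a near-power transform, which
preserves the factor structure). Loadings sit on low-abundance taxa only, so
their small total mass keeps compositional compensation negligible. Under
warming the loaded set is large (~55% of eligible taxa), loadings are graded
and all positive, their strength varies by block (log-normal sd 0.8 —
replicate plots differ in how cooperatively the community behaves), and the
PAO share of the whole community co-varies with the factor: warming dynamics
are mutualistic biomass recruitment. Ambient loadings are few (~20%),
uniformly strong and mixed-sign with a fixed share: ambient dynamics are
competitive and zero-sum. This is the stress-gradient hypothesis written as
a generative model, and it is what plants the directional network responses
(higher positive-edge ratio, density, robustness; lower vulnerability under
warming).

**Spectra.** Cells live on a 1 cm^-1 grid, 400-2000 cm^-1 (1601 points).
Seven archetype phenotypes share the PAO signature bands — peptidoglycan
(726, 1421, 1577), amide I-III (1002, 1220, 1657), PHA (840, 1725), polyP
(695, 1174), glycogen (481), fatty acids (1450) — with varying balance, plus
three strong unique fingerprint bands each so archetypes sit farther than
the 0.6 cosine cutoff apart. Warming multiplies tagged band amplitudes:
glycogen x1.6, PHA x1.3, polyP x0.7, fatty acids x0.5 (directions from the
study system; magnitudes are free parameters chosen once). Each cell gets
log-normal band jitter (sd 0.15), a smooth random polynomial baseline, and
white noise (sd 0.05). Archetype mixtures per sample are either
treatment-based (ambient concentrates on the first three archetypes,
warming spreads over all seven) or tilted to a target OPU Shannon when the
functionality-biodiversity coupling H_fun = 0.3 + 1.1*ln(H_tax) + noise is
planted.

**Environment.** Every variable is intercept + warming/clipping path
coefficients + Gaussian noise; default signs follow the field system
(warming: +2 degC soil temperature, -moisture, -total P, +alkaline
phosphatase, +plant biomass; clipping: -C4 biomass). NEE is derived as
ER - GPP, so GPP = ER - NEE holds exactly.

**What the generator does not emulate.** Sequencing error, chimeras and
compositional zeros beyond the multinomial; phylogenetic correlation between
taxa; cosmic-ray spikes and instrument drift in spectra; temporal dynamics.
Passing the validations shows the estimators recover what was planted under
this model, not that the field conclusions are certain.

## Analysis stages

**Filtering** (`community`). OTUs are kept when overall relative abundance
(mean of per-sample relative abundances; robust to uneven depth) >= 0.01%,
e-score >= 99, and a genus is present; removals get one first-failing reason
in the fixed order abundance -> e-score -> genus. PAO candidacy additionally
requires all four of ppk1, ppx (polyP synthesis/degradation) and phaC, phaZ
(PHA synthesis/degradation). Enrichment efficiency is the per-taxon ratio of
sorted to bulk overall relative abundance (the source's exact formula is in
supplementary material we do not consume; the ratio is a documented
stand-in).

**Diversity** (`diversity`). Shannon H = -sum p ln p (natural log; base
configurable). `shannon_mm` adds the Miller-Madow correction (K-1)/(2N),
which matters for 100-cell OPU compositions where the plug-in bias is
diversity-dependent. Functional redundancy is per function category the sum
of contributions over the number of unique contributing taxa, averaged
unweighted across categories (aggregation was unstated at the source; both
the mean and the per-category table are available). Treatment effects come
from Y ~ warming*clipping + (1|block) fitted by REML; Wald p-values use a t
reference with between-within degrees of freedom n - p - (n_blocks - 1)
(the large-sample normal reference is a config option but inflates type-I
error to ~0.068 at n=24). A degenerate block variance falls back to OLS.
Renormalized effect sizes divide by the max |beta| within the compared
panel, which maps any panel into [-1, 1] sign-preservingly.

**Raman / OPUs** (`raman`). Asymmetric-least-squares baseline (lambda=1e5,
p=1e-3, pentadiagonal banded solver), nonnegative clip, 6 cm^-1 binning
anchored on the 400 cm^-1 lattice (final partial bin kept; 267 bins from the
default grid; anchoring makes re-binning exactly idempotent), then vector
normalization. Biomarkers are trapezoid band areas after subtracting a local
linear background anchored 8 cm^-1 outside the window edges (anchors on the
flanks, not the band). The PAO phenotype call requires peptidoglycan, amide,
PHA and polyP all above threshold (3x a robust noise estimate is the
conventional choice). OPUs come from average-linkage clustering of cosine
distances cut at 0.6, labels ordered by descending size with first-member
tie-breaks.

**Networks** (`network`). Pearson correlations between PAO taxa across one
condition's samples, on the whole-community abundance scale (subset
renormalization manufactures closure anti-correlations). The RMT threshold
is the smallest grid value (0.30-0.99 by 0.01) whose thresholded adjacency
has a nearest-neighbour spacing distribution consistent with Poisson
(chi-square GOF on the unfolded spectrum, p > 0.05, two consecutive grid
steps). Unfolding uses a Gaussian-smoothed empirical cumulative spectral
density after collapsing duplicate eigenvalues; spectra with fewer than 16
distinct eigenvalues are untestable and treated as non-accepting. Edges
require |r| >= s* and p < 0.05 and carry sign(r). The complexity suite
(clustering C, mean degree, degree centralization, density/connectance,
edge counts, positive-edge ratio L+, geodesic efficiency E_g and its
aliases, centralities, transitivity), Louvain modularity (seeded, 10
restarts) with degree-preserving rewiring nulls for relative
modularity/nestedness (NODF), Zi/Pi node roles (thresholds 2.5 / 0.62),
abundance-weighted cohesion, robustness (mean fraction of survivors keeping
an edge after removing 50% of nodes, 100 repetitions) and vulnerability
(max relative geodesic-efficiency drop on single-node deletion, largest
component) follow the standard definitions; small-graph brute-force oracles
pin each one down in the tests. E and E_g are reported as aliases (the
source distinguishes them only in supplementary material we do not
consume). Per-condition metric ensembles use 12 block-jackknife subsets
(drop two blocks, rerun the whole pipeline), which aligns the resampling
with the blocked design.

**Cohesion nulls.** Connectedness is the mean of observed-sign pairwise
correlations after subtracting the expected |r| under independent column
permutation; per-sample cohesion is the abundance-weighted sum clipped to
its contract sign (positive cohesion >= 0 >= negative). The clip leaves a
small positive residual under pure-noise data; the tests therefore check
that null cohesion is an order of magnitude below a co-varying community's
signal rather than exactly zero-centred.

**Linkage** (`linkage`). %OM = 0.7*%LOI - 0.23 (floored at zero), GPP =
ER - NEE, and correlation screens flagging |r| >= 0.6 with p < 0.05
(Pearson or Spearman; raw p-values by default, Benjamini-Hochberg by flag).

## Validation studies (`validation`) and problem sizes

The test suite and the reproduction script run: 200 random connected graphs
of <= 8 nodes against brute-force metric oracles; 20 planted block-structure
correlation matrices (100 taxa, within-block r ~ 0.8 over background ~ 0.2)
for RMT threshold recovery; 500 null simulations (type-I error and p-value
uniformity) plus 100 recovery seeds (planted warming effect 0.5, 20
replicates) and a 500-permutation oracle for the mixed model; 20 seeds of
7-archetype spectra (30 cells per drop) for OPU recovery; 50 seeds of the
default study for the directional warming responses, with 12 jackknife
networks per condition; and 50 seeds of a diversity-gradient configuration
(`pao_shannon_gradient = 1.3`, drop-level observations) for the
log-versus-linear functionality-biodiversity comparison. The gradient
configuration exists because over the narrow Shannon range the treatments
alone induce, logarithmic and linear fits are numerically indistinguishable
for any estimator; the saturating shape is only testable across a wide
diversity span. Cell counts in the validation studies are smaller than the
full 100-cells-per-drop design; the full design is exercised by the design-
count check and the pipeline.

## Known limitations

- The complexity-to-stability correlation screen contrast (more flagged
  pairs under warming than ambient) is the least robust planted direction:
  density mechanically couples to robustness and vulnerability in any
  varying network ensemble, so the ambient screen count has a floor.
- RMT thresholding on very sparse graphs accepts Poisson early (sparse
  random graphs are locally Poisson too); with few samples the p < 0.05
  edge filter, not s*, is usually binding.
- Negative Pearson correlations between log-normal abundances are bounded
  away from -1; with strong multiplicative noise, negative associations are
  intrinsically harder to detect than positive ones, in the generator as in
  real count data.
- With six blocks the REML block-variance estimate is noisy; the
  between-within t reference keeps type-I error at nominal level in the
  validations, but exotic unbalanced designs should be checked before trust.
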