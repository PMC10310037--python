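# Methods

This note documents the models implemented in `bronchoscreen`, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that matter.

## Screen simulation

`simulate_screen` emulates a 384-well primary screen: a deck of 301
compounds (default) at 1 and 10 uM with 3 replicate wells per compound x
concentration, plus DMSO + 0% CSE and DMSO + 3% CSE control wells on
every plate. All six wells of a compound are placed on one plate (so
per-plate control statistics always apply to whole compounds); well
positions are randomized within plate and recorded.

Well readouts are drawn per condition mean with **additive Gaussian noise
on the readout scale** — the same SD for control and compound wells — so
planted effects shift means without changing spread and every
threshold-exceedance probability is analytic. Defaults:

| quantity | 0% CSE | 3% CSE | noise SD |
|---|---|---|---|
| mean spheroid area (px) | 1500 | 900 (shrink factor 0.6) | 135 |
| mean MUC5AC ratio | 0.10 | 0.20 | 0.02 |
| spheroid count / well | 40 | 50 | 3 (rounded) |
| total nuclear intensity | 1.2e6 | 1.0e6 | 8e4 |

The count and intensity orderings (0% wells have *fewer* spheroids; 3%
wells have *lower* nuclear intensity) match the orderings that justify
using each control as the "healthy" toxicity reference. Per-well spheroid
counts and intensity scales are not published for this assay; these values
are assumptions, not calibrated numbers. The area and mucin SDs put the
per-plate control MADs of the normalized readouts near 0.1 — the regime
the hit rules are meant to operate in. An optional linear column drift
(`row_col_drift`) supports robustness experiments; it is off by default.

Planted effect classes are mutually exclusive per compound (the remainder
of `effect_class_fractions` is inactive) and act multiplicatively on the
3%-CSE condition mean, parameterized on log2 scale so 0 means no effect:
swell-restoring x1.5 area; mucus-reducing x0.5 MUC5AC ratio; toxic shows
the same apparent area/mucin effects but halves counts and nuclear
intensity (so only the toxicity filters can reject it); opposite-effect
swells while doubling the MUC5AC ratio (rejected by the cross-readout
filter).

**Control wells per plate: 48 per role** (three 384-well columns each).
Every rule clause is scaled by an estimated control MAD, and the
per-replicate pass probability of a "within 2 MAD" clause on an unaffected
Gaussian readout is Phi(2 x 0.6745) ~= 0.91 *regardless of the noise
level*, which caps ideal mucus-hit recovery near 0.976; with few control
wells, MAD-estimation noise costs several further points. A dense control
layout keeps that estimation loss small and is standard practice for
control-anchored threshold screens.

`render_well_image` draws 2D single-plane wells (the maximum-intensity
projection consumed by the analysis, not a 3D volume): a bright annulus
with a dimmer lumen per spheroid, mucin clusters as disks confined to the
lumen with an exact area fraction of the spheroid, punctate nuclei on the
rim, constant background plus optional Gaussian noise, and exact
ground-truth label and mucin masks. It makes no attempt at photorealism —
no blur/PSF, no intensity gradients, no touching or deformed spheroids in
the default no-overlap mode.

## Image quantification

Segmentation is global Otsu on the live-dye channel, morphological hole
filling (keeping the dim lumen inside the object), 8-connected components
and a minimum-area filter (default 50 px). `expected_diameter`, when set,
controls a light Gaussian pre-smoothing (sigma = diameter/20). This is a
deterministic classical stand-in at the interface where a learned
segmenter would plug in: `measure_spheroids`/`quantify_well` accept any
external label map. Touching spheroids are not split; the generator's
no-overlap mode keeps tests unambiguous.

Mucin "active area" uses an Otsu threshold computed *within* each spheroid
mask — the thresholding rule inside the original analysis chain is not
published, so this data-relative choice is an assumption; a configurable
absolute fallback covers degenerate within-mask contrast (a constant mucin
signal yields zero active area unless a fallback is given). Because both
thresholds are data-relative, areas and mucin ratios are invariant to
multiplying all intensities by a positive constant.

Well aggregation: arithmetic means over contributing spheroids ("average"
is read as the arithmetic mean), spheroid count, and total nuclear
intensity summed over the union of spheroid masks. Zero-spheroid wells
carry count 0 and NaN means.

## Normalization and MAD

`mad` is the raw median absolute deviation; the 1.4826 consistency factor
is opt-in (`scaled=True`) and unused by default, since the screening rules
are stated in raw MADs.

Plate normalization divides each well's mean area by the per-plate
*median* of the DMSO + 3% control areas; the MUC5AC log2 fold change is
`log2(ratio) - median(log2 ratio of 3% controls)`. Taking the mucin
reference median on the log scale is what makes the control median of
`mucin_log2fc` exactly 0 for any control count (for an odd count it is
identical to using the ratio median; for an even count the ratio-median
reference would leave a residual of order the middle-pair spread).
Controls are normalized alongside compound wells so the downstream MADs
are computed on the same scale as compound fold changes. Donor
normalization (characterization mode) divides by the arithmetic *mean* of
the donor x timepoint 0%-CSE wells — mean and median are deliberately not
interchanged between the two modes.

## Hit calling

Per plate (never pooled), from the normalized table:
median and MAD of 3%-control area fold change, MUC5AC log2FC and nuclear
intensity, and of 0%-control spheroid counts. Rules, with defaults
`effect_k = 2`, `tox_k = 3`, `cross_k = 2`, `min_passing_replicates = 2`:

* **swell**: >= 2 replicates with `FC > median + effect_k * MAD`
  (strict, ties fail); *all* usable replicates with
  `count >= median_0% - tox_k * MAD_0%` (one-sided lower by default — the
  0% control is the low-count healthy reference; a two-sided band is
  available); >= 2 replicates with
  `log2FC <= median + cross_k * MAD` (no MUC5AC increase).
* **mucus**: >= 2 replicates jointly satisfying
  `log2FC < median - effect_k * MAD` *and*
  `nuclear >= median - tox_k * MAD` (referenced to the 3%-CSE controls,
  the low-intensity healthy side); the
  same all-replicate count bound; >= 2 replicates with
  `FC >= median - cross_k * MAD` (no area decrease). No replicate
  convention is prescribed for this cross-filter; the 2-of-3 convention
  of the swell cross-filter is reused.

Stating the effect threshold as a bare MAD multiple (fold change above
`2 * MAD`) is degenerate — control fold changes center at 1, so any MAD
below 0.5 passes nearly everything. The default `centered` interpretation
measures exceedance from the control median; `interpretation="literal"`
keeps the bare-multiple reading auditable. The cross-readout multiplier is a
separate parameter (`cross_k`, default 2) rather than reusing
`effect_k`: the effect threshold and the cross filter move in opposite
directions as the multiplier grows, and separating them keeps hit calls
monotone in `effect_k` (raising it can only remove hits).

Compounds with missing wells: all available wells must pass toxicity,
>= `min_passing_replicates` must pass the effect clause, and fewer than 2
usable wells makes the compound uncallable (flagged, never a hit). Every
non-hit carries at least one failing flag. Manual (visual-inspection)
exclusions are applied last in `consolidate_hits` and recorded in an audit
column.

## Validation statistics

`anova_oneway` is the standard one-way decomposition; its within-group
mean square is the pooled variance reused by Dunnett.
`dunnett_many_to_one` computes `t_i = (x̄_i - x̄_0)/sqrt(s²(1/n_i+1/n_0))`
and two-sided family-wise adjusted p-values as tail probabilities of
`max_j |T_j|` under the equicorrelated multivariate t induced by the
shared control (`corr_ij = sqrt(n_i n_j / ((n_i+n_0)(n_j+n_0)))`, df =
N - #groups). For one comparison the adjusted p reduces analytically to
the pooled two-sample t-test; for k >= 2 it is Monte-Carlo with 200,000
draws (accuracy ~1e-3), cached per group-size structure under a fixed
internal seed, which supports unequal group sizes without critical-value
tables. Zero pooled variance with unequal means reports p = 0 with a
degeneracy warning. Validation uses raw (un-normalized) readouts, and
comparisons run per concentration family by default.

Validated-hit classification: swell requires a significant area increase
with no significant count decrease and no significant MUC5AC increase;
mucus requires a significant MUC5AC decrease with no significant nuclear,
count or area decrease; manual exclusions apply last.

## Differential expression

Per gene, `y = Xβ + u_donor + ε`, `u ~ N(0, τ²)`, `ε ~ N(0, σ²)`,
REML-estimated by profiling `γ = τ²/σ²`: for fixed γ the per-donor
marginal covariance `σ²(I + γJ)` has a closed-form inverse square root, so
β is a transformed least-squares fit and the REML criterion is scanned on
a log-γ grid (0 plus 1e-4..1e4) and refined by bounded scalar
minimization; the τ = 0 boundary is allowed and reproduces OLS exactly.
This is robust with as few as 2-3 donors. Aliased design columns (e.g.
sex when it is constant within donor, or alcohol when all donors share a
status) are dropped with a warning, earlier columns taking precedence.

Per-timepoint scopes regress on intercept + CSE indicator + alcohol + age;
the pooled scope adds days treated (numeric days = 7 x weeks by default;
categorical weeks behind `days_coding="categorical"`). The CSE coefficient
is the log2 fold change. Coefficient p-values are Wald tests against a
**t reference with residual df = n - rank(X)**: with a ~36-sample,
3-donor design the plain normal reference is visibly anticonservative
(|z| > 1.96 has tail mass ~0.06-0.07 at these df), while the residual-df t
keeps the null rejection rate nominal and coincides with the OLS t-test at
the τ = 0 boundary; `use_t=False` restores the normal approximation.
Satterthwaite/Kenward-Roger df corrections are out of scope. BH
(`bh_adjust`) is the exact step-up; DEGs are `q < 0.05` and |log2FC| >
log2(2) by default.

`pca_qc` decomposes the gene-centered matrix (samples as observations);
variance fractions sum to 1. The residualization mode projects out donor
dummies per gene — with donor-constant age/alcohol covariates this also
removes them — exposing the treatment axes that donor variation otherwise
dominates.

The expression generator defaults to 3 donors x 12 samples (2 CSE doses x
3 weeks x 2 replicates), β_CSE = 1.5 on half-up/half-down DE genes
(fraction 0.1), donor SD 0.5, residual SD 0.3, donor ages uniform on
12-38 years and a Bernoulli(0.5) alcohol status. It does not emulate
count-level sampling noise, library-size effects, gene-gene correlation,
or mean-variance trends; passing tests demonstrate correct inference under
a Gaussian random-intercept model, not robustness to count-data artifacts.

## Enrichment

`enrichment_score` is the weighted Kolmogorov-Smirnov running sum: hits
add `|stat|^w / sum_hits |stat|^w` (w = 1 by default), misses subtract
`1/(N - n_hits)`; the ES is the maximum-magnitude deviation, attained at a
hit position (maximum) or immediately before one (minimum), which is how
the implementation evaluates it in O(set size) — equal-magnitude
positive/negative peaks resolve to the positive side. Ranking ties break
lexicographically by gene id. All-zero hit statistics fall back to uniform
hit weights.

`gsea_preranked` filters sets to overlap sizes in [5, 500], draws
same-size random gene sets from the ranking (50,000 permutations by
default, mandatory seed, null shared between sets of equal size within a
call), computes p as the add-one-smoothed tail probability on the side
matching the ES sign (never exactly 0; uniform under the null),
NES = ES / mean |null ES of matching sign|, and BH q across retained sets.
The permutation scheme is gene sampling (preranked-style), not phenotype
permutation.

`concordance_summary` scores external up/down signature sets against the
model ranking (signed log2FC by default; orientation follows the
convention that a concordant external *up* set enriches at NES > 0 and the
*down* set at NES < 0, with q < 0.05); the flipped orientation can be
obtained by building the ranking from the external statistics and the sets
from model DEGs.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 100-seed / 20-screen
Monte-Carlo batches of 40-301 compound screens, 10,000 / 4,000 Dunnett
null simulations, 2,000-2,500-gene expression studies, and 1,000-set /
2,000-50,000-permutation enrichment runs — sizes at which each Monte-Carlo
estimate is stable to well under its test tolerance on a single CPU.

## Known limitations

* The segmenter assumes bright, roughly convex, non-touching objects on a
  flat background; no illumination correction or watershed splitting.
* MAD-threshold hit rules have an intrinsic per-compound null rate (a few
  percent at the defaults) and an intrinsic recovery ceiling (~0.976 at
  the default multipliers) set by the "within k MAD" clauses; these are
  properties of the rule itself, not of this implementation.
* Wald-t inference ignores uncertainty in τ̂²; with very few donors,
  per-timepoint scopes (6 samples per donor subset) run close to the
  identifiability floor.
* Dunnett p-values are Monte-Carlo (~1e-3 accuracy) for k >= 2.
* Permutation GSEA shares one null per set size within a call; p-values
  for sets of the same size are therefore correlated across sets (not
  within a set's own inference).
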