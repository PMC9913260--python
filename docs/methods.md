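# Methods

## Data model and conventions

A panel is a table of signed fold changes FC per (breed, tissue, gene).
The signed convention stores an x-fold downregulated gene as −x and the
housekeeping reference (*TBP*) at FC = 1; the reference gene may be
omitted from a table and is then implied. FC = 0 is invalid, and
|FC| < 1 triggers a warning because it is ambiguous under this
convention. Input row order is preserved and used as the deterministic
tie-breaker wherever magnitudes are sorted; an average-rank alternative
was considered and rejected because ranks must stay a permutation of
1..n for the exponential regressor e^N to be well defined.

## Model 1: rank-exponential fits

The magnitude transform m = |FC − 1| treats a 6-fold up- and a −4-fold
downregulated gene as equally far (5 units) from the reference level,
deliberately discarding direction while preserving effect size. Within
one breed/tissue the magnitudes are ranked ascending (housekeeping gene
excluded, leaving 7 ranks in the reference panel) and modelled as
m(N) = a + K·e^N.

Because the model is linear in e^N it is solved by linear least squares,
never by a nonlinear optimizer: through the origin the slope has the
closed form K = Σ(m·e^N)/Σ(e^{2N}), and the free-intercept variant is a
two-column OLS. This is exact, deterministic and reproduces the
reference slopes to all printed digits. R² for through-origin fits uses
the uncentered total sum of squares (the standard no-intercept
convention, with denominator n − 1 in the adjusted variant); this
convention choice only affects reporting, not the fits.

Rank cuts: the pooled fits use ranks 1–6 (breast) and 1–4 (thigh) —
beyond those ranks the largest magnitudes leave the exponential regime —
and the per-breed fits inherit the same cuts. Both are configurable.

Intercept modes are configuration, not logic: the bundled map uses a
free intercept for Broiler (both tissues), White Cornish breast and
Uzbek Game thigh, and the through-origin fit everywhere else. This map
reproduces the reference per-breed slopes; no rule stated at breed level
fully determines it, so it is data, overridable per (breed, tissue).

MGEI = K(breast)/K(thigh) is computed from unrounded slopes and is
undefined when the thigh slope is zero. It is invariant to rescaling all
magnitudes of both tissues by a common positive factor.

## Model 1: fractal dimensions

Over a contiguous rank window the same ranked magnitudes are fitted as
log10(m) = D·log10(N) + log10(c) by OLS with intercept; D is the fractal
dimension and c = 10^intercept. Logs are base-10: the slope is
base-invariant but c is only interpretable against the power-law form in
that base. A pointwise ratio log10(m)/log10(N) exists in the literature
as a simplification; it does not equal the regression slope and is kept
only as a deprecated utility.

Windows are per-breed configuration with a minimum length of 3 (two
points always fit a line exactly). The bundled windows are the reference
choices; `select_window` automates the selection by enumerating every
contiguous window of length ≥ 3 inside the default range extended by one
rank and maximising r², with ties preferring longer windows then lower
start ranks. The automated search is a convenience generalisation and is
off by default, since the bundled windows are authoritative for the
reference panel. MGEFDI = D(breast)/D(thigh) mirrors MGEI.

The regression of a breed trait on D (e.g. 28-day body weight on
D(breast)) is reported with slope, intercept and r² but not asserted
against any particular value: with eight breeds it is descriptive.

## Model 2: portraits and bioconsolidation

The LG transform maps FC > 0 to −log2(FC) and FC < 0 to +log2(|FC|).
Taking log2 of the magnitude for downregulated genes is the only reading
that keeps the transform finite; it makes LG antisymmetric in the sign
of FC at equal magnitude. The portrait shifts the panel by its minimum
LG (so min y = 0 exactly) and plots each gene at (frac(y), y). A y that
is an exact integer has fractional part 0.

Two detectors identify expression fractals:

* **Arithmetic:** subsets of ≥ 3 shifted values whose sorted successive
  differences have spread (max − min) ≤ `tol_ap`, default 0.1 log2
  units — chosen as roughly three times the spread of the reference
  worked progression (0.03), loose enough for measurement noise and
  tight enough that a 0.1 spread still looks like one progression at the
  panel's typical differences of ~1.1.
* **Collinear** (pipeline default): for every point pair, all points
  within perpendicular distance `tol_line` of the line through the pair;
  sets of ≥ 3 are kept, subsets deduplicated, output ordered by size
  then member names. On panels this small the enumeration is exact.

One construction artifact needs handling: every point with y < 1
satisfies x = frac(y) = y and so lies exactly on the diagonal x = y.
A candidate set whose members all have y < 1 is collinear purely by
construction and is discarded (`exclude_trivial_diagonal=True`). Without
this rule no single tolerance reproduces the reference member counts,
because the forced diagonal absorbs low-y genes before genuine
progression lines resolve.

`tol_line` defaults to 0.015, calibrated once on the White Cornish
panels so that both tissues yield their six reference member genes (any
value in [0.013, 0.016] does); it is not tuned per breed. Collinearity
is evaluated in raw portrait coordinates with no axis normalisation,
matching how the portraits are drawn.

Membership per tissue is the union of genes over all detected sets (a
gene on two lines counts once). Ind = sqrt(N_B·N_T)/N_G with N_G the
panel size including the housekeeping gene (8 for the reference panel);
it is symmetric in the two tissues, monotone in each count, 0 when
either tissue has no fractal and 1 when every gene participates in both.

## Phenotype statistics

Growth rates are bw14/bw1 and bw28/bw1; the NO oxidation rate is
100·nitrate/(NOD + nitrate), the percentage of embryonic NO metabolites
already oxidised to nitrate. Both are exact arithmetic on their inputs.

With only eight breeds, the battery is small-sample-minded. A
Shapiro–Wilk gate computes per-variable normality p-values and
recommends rank correlation when any variable rejects at 0.05 (breed
traits do). Spearman p-values are exact two-sided permutation
probabilities, enumerating all n! orderings for n ≤ 8 (40 320 at n = 8)
rather than relying on large-sample approximations that are unreliable
at this size. Correlation of K coefficients can optionally be done after
natural-log transformation (exposed as a flag, default off; the
breed-type ANOVA comparison conventionally uses the ln scale, where the
meat-vs-other contrast of K(breast) reaches p < 0.05). The one-way ANOVA
is the standard fixed-effects F test. Benjamini–Hochberg q-values can be
annotated but nothing is ever filtered by them.

## Synthetic panels

Three generators produce panels with known latent structure, each fully
determined by a seed (`numpy.random.default_rng`):

* `rank_exponential`: magnitudes a + K·e^N with optional additive
  Gaussian noise (redrawn on the rare negative excursions, so magnitudes
  stay valid);
* `power_law`: magnitudes c·N^D with multiplicative log-normal noise,
  which keeps positivity;
* `portrait_ap`: per-tissue LG panels with a planted arithmetic
  progression of a given common difference among a given number of
  member genes, the progression base anchored at the panel minimum so
  the min-shift leaves it intact, and the remaining genes redrawn until
  the collinear detector reproduces exactly the planted membership.
  The fractional part of the common difference must satisfy
  frac(d) < 1/(n_members − 1), otherwise the x-coordinate wraps within
  the progression and collinearity is structurally impossible.

Magnitudes are encoded back to signed FC as 1 + m (up) or, when m > 2,
optionally 1 − m (down), so the forward transforms recover the latent
values exactly; the up/down coin carries no model structure. What the
generators do *not* emulate: qPCR measurement error at the Ct level,
replicate structure, inter-gene correlation and biological batch
effects. Passing recovery tests therefore demonstrates the estimators'
correctness on their assumed structure, not robustness to real assay
noise.

## Problem sizes and numerics

All reference computations are desk-scale (112 FC values) and run in
milliseconds. The Monte-Carlo check of slope unbiasedness uses 1 000
replicate panels of 6 genes at noise sd 0.05, comparing the mean
estimate against the truth within three standard errors. Comparisons
against published values use the precision those values were printed
with; two printed cells are internally inconsistent with their own
derived columns (one per-breed slope, one last digit of a pooled slope)
and are checked against the consistent unrounded values, as noted in the
test docstrings.

## Known limitations

* The rank-exponential regressor treats discrete ranks as a continuous
  predictor; this is conventional in rank-abundance work but the slopes
  should be read comparatively, not mechanistically.
* Expression-fractal membership depends on the calibrated tolerance;
  member identities for panels other than the calibration breed are
  computed but should be treated as exploratory.
* With eight breeds, every cross-breed statistic is descriptive;
  p-values are exact but power is minimal.
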