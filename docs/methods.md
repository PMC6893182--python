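# Methods

## Model

A biallelic locus in a panmictic population of `Ne` haploids evolves by
Wright-Fisher resampling: given frequency `x`, the next generation's count of
the alternative allele is `Binomial(Ne, f(x))`, where

    f(x) = x (1 + sh + s(1-h)x) / (1 + 2shx + s(1-2h)x²)

is the deterministic change due to diploid selection with coefficient `s` and
dominance `h` (genotype fitnesses 1, 1+sh, 1+s).  Mutation is not modelled;
0 and 1 are absorbing.  `h` defaults to 0.5 (additive selection), the value
used in all shipped evaluations.

Observations are binomial draws `Y_k ~ B(n_k, X(t_k))` at dates
`t_1 = 0 < … < t_n` (generations).  The initial frequency has a uniform
prior on [0,1].  The forward algorithm of the resulting HMM yields the exact
likelihood up to quadrature; inference on `s` (with `Ne`, `h` fixed) uses
the grid MLE and the likelihood-ratio statistic `λ = 2(l(ŝ) − l(0))` with
χ²(1) p-values.

## Transition kernels

The WF kernel over `dt` generations is the one-step matrix raised to the
power `dt` (repeated squaring; practical for `Ne` up to a few hundred).  The
binomial rows are computed in log space so `Ne ≥ 300` does not underflow.

The four parametric kernels match a distribution to the approximate WF
moments.  The mean/variance recursion is the second-order Taylor expansion
of `f` around the current mean:

    μ' = f(μ) + ½ f''(μ) σ²,
    σ²' = μ̃(1−μ̃)/Ne + (1 − 1/Ne) f'(μ)² σ²,   μ̃ = μ',

applied once per generation; `f` is rational so its derivatives are exact
closed forms.  Under neutrality `f` is the identity and the recursion
reproduces `Var = x₀(1−x₀)(1 − (1−1/Ne)^t)` to machine precision.  No
higher-order correction terms are used.

The Beta-with-spikes kernel additionally tracks absorption masses.  Each
generation, the segregating part of the distribution is matched to a
Beta(a*, b*) via the conditional moments

    m* = (m − p1)/(1 − p0 − p1),   z²* = (z² + m² − p1)/(1 − p0 − p1) − m*²,

and the absorption masses grow by Beta-function ratios,
`Δp0 = (1−p0−p1)·B(a*, b*+Ne)/B(a*, b*)` (symmetrically for `p1`), evaluated
as log-gamma differences.  For a Beta variable X the ratio equals
`E[(1−X)^Ne]`, i.e. the probability of drawing zero copies in the next
binomial round, which is why the recursion mirrors WF absorption.

## Numerical choices

* **Frequency grid.** 129 evenly spaced points on [0,1] with trapezoid
  weights; the likelihood is evaluated on a grid of 600 `Nes` values on
  [−100, 300] whose nearest point is snapped to exactly 0 so that `l(0)` is
  computed at `s = 0` itself.  `s` is floored at `−1 + 1e−6`: `f` has a
  removable 0/0 at `(s = −1, h = ½, x = 1)` that floating point cannot cancel.
* **Cell masses, not pointwise densities.** The continuous part of a kernel
  is converted to per-grid-point masses by exact CDF differences at the
  half-interval edges (analytic Beta/Normal CDFs).  This conserves total
  mass exactly, remains finite when the Beta density diverges at a boundary
  (shape parameter < 1), and agrees with the trapezoid rule to the same
  order in the grid spacing.  Atoms at 0/1 are added to the boundary cells,
  so the forward vector treats spikes and continuous mass uniformly.
* **Clamps.** Means entering Beta matching are clamped to
  `[1e−9, 1 − 1e−9]` and variances to `[1e−8, (1 − 1e−6)·m(1−m)]`.  The
  variance floor keeps Beta shape parameters below ~1e7, where log-gamma
  differences retain ~1e−8 absolute accuracy; it is *not* applied inside the
  plain moment recursion, where genuinely tiny variances (one generation at
  `Ne = 10⁴` is ~8e−7) must survive.  Kernels whose variance falls below
  1e−12 collapse to a point mass.  A state whose segregating mass drops
  below 1e−12 is frozen (fully fixed).
* **MLE ties** break toward the smallest |s| (conservative toward the null).
* **Per-step rescaling** of the forward vector with an accumulated log
  normaliser prevents underflow across sparse sampling dates.
* **Wasserstein distance.** `∫|F₁ − F₂|` is integrated piecewise between the
  union of both kernels' atom locations (the whole lattice for WF), with the
  left limit used at each interval's right endpoint; each interval is
  subdivided 8-fold (doubling changes results by < 1e−3).

## Quadrature accuracy of closed forms

With the uniform prior, a single observation has likelihood exactly
`1/(n+1)`.  On the 129-point trapezoid grid this holds to machine precision
for interior counts `y` (all Euler-Maclaurin boundary corrections vanish),
but for `y` near 0 or `n` the quadrature error is of order `n·h²/12 ≈ 1e−4`.
This is a property of the evenly spaced trapezoid rule itself, not of the
implementation.

## Simulation studies

The simulator draws exact WF trajectories (binomial resampling through the
fitness function) and binomial observations.  The default design mirrors
standard experimental-evolution series: 30 alleles at 10 evenly spaced
dates spanning `T ∈ {9, 45, 90, 180}` generations, start frequency 0.1 or
0.5.  Trajectories whose observed counts are all 0 (or all `n_k`) from the
second date onward ("one-step fixations") make the likelihood monotone in
`s` and are excluded before testing, with the exclusion fraction reported.
In power evaluations where the true `s ≥ 0`, a significant result with
`ŝ < 0` counts as `wrong_sign`, not as a detection.

The generator emulates drift, selection and binomial sampling noise only;
real data additionally carry genotyping error, linkage between loci and
demographic changes, so passing tests bound numerical and statistical
correctness of the method, not robustness to those effects.

Shipped problem sizes: the null-calibration study uses 2,000 neutral
replicates, the recovery study 500 replicates at `Nes = 10`, and the
WF-concordance study 102 trajectories spread over six (Nes, T) scenarios —
sizes chosen so the whole suite runs on a single CPU in a few minutes while
keeping Monte-Carlo error well inside the asserted bands.

## Calibration caveat

The χ²(1) approximation to the null distribution of λ is accurate for
trajectories that stay polymorphic, but neutral trajectories that fix
*during* the series (about 11% of neutral paths from x₀ = 0.5 at
`T/Ne = 0.45`) legitimately receive large λ: once an allele has fixed,
a directional `s` explains the constant tail far better than `s = 0`.
In this package's exact-WF evaluation that subset carries a ~70% rejection
rate at the nominal 5% level, while the non-fixed bulk is conservative
(~0.4%), giving an overall two-sided rejection near 9–10% and an upper-tail
QQ slope of ~1.36 at `T/Ne = 0.45` (it is well calibrated at small `T/Ne`,
e.g. 5.8% and slope 0.98 at `T/Ne = 0.045`).  Counting only positive-ŝ
rejections — the convention used for power — the null rate is ~5%.  The
effect is identical under the WF and BwS kernels (it is a property of the
likelihood, not of the approximation).  For scans of long series relative
to `Ne`, empirical p-value calibration by neutral simulation is advisable;
the χ²(1) p-values remain the default for comparability.

## Scan protocol

Loci are read per population line; monomorphic loci (uninformative) and
one-step fixations are excluded and flagged distinctly.  p-values from all
lines are pooled into a single Storey q-value computation by default (a
per-line option exists); `π0` is estimated by the smoother method —
`π0(λ̃) = #{p > λ̃}/(m(1−λ̃))` over `λ̃ = 0.05 … 0.95`, fitted with a cubic
polynomial and evaluated at 0.95 — and forced to 1 below 100 tests, where
the estimate is unstable.  With `π0 = 1` the q-values coincide with
Benjamini-Hochberg.  Significant sets under the WF and BwS kernels agree in
practice; calls whose q-value sits exactly at the FDR threshold can flip
between kernels, since the two λ values differ at the 0.1 level.  Region
clustering of significant SNPs is out of scope; output is per-SNP.

## Known limitations

* `Ne` and `h` are inputs, not estimated; joint (Ne, s) inference and
  time-varying parameters are not implemented.
* The uniform initial prior is a deliberate neutral choice; informative
  priors change borderline inferences.
* Exact WF inference is quadratic in `Ne` per transition and intended for
  `Ne` up to a few hundred.
* χ²(1) p-values are anticonservative for series long relative to `Ne`
  (see the calibration caveat above).
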