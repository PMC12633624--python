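# Methods

## Model

`levynet` simulates discrete-time recurrent rate networks

    x_i(t+1) = tanh( sum_j W_ij x_j(t) + I_i(t) ),      i = 1..N,

whose synaptic weights `W_ij` are i.i.d. draws from the symmetric, centered
Lévy alpha-stable family `L_alpha(sigma)` with characteristic function

    E[exp(i k X)] = exp( -|sigma k|^alpha ),     alpha in (0, 2].

The scale is tied to a single control parameter, the gain `g`, through
`sigma = g / N^(1/alpha)`.  Two conventions are locked package-wide and
matter for every downstream constant:

* **Scale convention.** Under the characteristic-function definition above,
  `alpha = 2` is a Gaussian with variance `2 sigma^2` (not `sigma^2`), and
  `alpha = 1` is the Cauchy law with half-width `sigma`.  Any external
  sampler used for cross-checks (e.g. `scipy.stats.levy_stable`, which uses
  the same convention at `beta = 0`) must be mapped into it.
* **Tail behavior.** For `alpha < 2` the density has power-law tails
  `~ |x|^(-1-alpha)`; sample statistics are dominated by rare, huge entries
  ("mega-synapses").  No truncation is applied by default; an optional clip
  is available but off, because the phenomena of interest are driven by the
  outliers.

Sampling uses the Chambers–Mallows–Stuck transform.  The Gaussian endpoint
is `sqrt(2) * N(0,1)`; the Cauchy endpoint is generated as a ratio of two
independent standard normals in a numba-compiled kernel (equal in
distribution to the tangent of a uniform angle, and about 4x faster than
the stock generator — weight-matrix generation at `alpha = 1` dominates the
cost of the large annealed simulations).

## Finite-size transition theory

Mean-field theory of the infinite heavy-tailed network predicts that the
quiescent state `x = 0` is always unstable: chaos everywhere, no
transition.  Finite networks behave differently, and the finite-size
correction is the core quantity of this package.

Linearizing around the quiescent state gives `eps(t+1) = W(t) eps(t)`.  In
the **annealed** approximation the matrix is redrawn each step, making this
a Kesten-type product of random matrices.  For i.i.d. stable entries the
stability property gives an exact scalar reduction: conditional on
`eps(t)`, the vector `W eps(t)` has i.i.d. stable components with scale
`(g/N^(1/alpha)) * ||eps(t)||_alpha`, so the log alpha-norm performs a
random walk with i.i.d. increments

    ln g + (1/alpha) * ln( (1/N) * sum_j |z_j|^alpha ),   z_j ~ L_alpha(1).

Perturbations die out iff the mean increment is negative, so the critical
gain is

    g*(N, alpha) = exp( -Xi_{N,alpha} ),
    Xi_{N,alpha} = E[ (1/alpha) * ln( (1/N) sum_j |z_j|^alpha ) ].

Two reading choices deserve a prominent flag, because typeset versions of
these formulas are easy to garble:

* **The expectation sits outside the logarithm.**  With it inside,
  `E|z|^alpha` diverges for every `alpha < 2` and the expression is
  undefined.  The outside reading is also what the norm-process derivation
  produces, and it reproduces both checks below.
* **The Gaussian limit carries a radical.**  At `alpha = 2`,
  `(1/N) sum z_j^2` is `(2/N) * chi2_N` in distribution, and
  `E[ln chi2_N] = ln 2 + digamma(N/2)`, giving the exact closed form
  `Xi_{N,2} = (digamma(N/2) + ln(4/N)) / 2 -> ln sqrt(2)`, hence
  `g*(inf, 2) = 1/sqrt(2)`.  One sometimes sees these constants printed as
  `ln 2` and `1/2`; those values are inconsistent with `<z^2> = 2` under
  the scale convention above and with the classical Gaussian edge-of-chaos
  condition `N E[W^2] = 1`, which `1/sqrt(2)` satisfies exactly
  (`N * 2 * (g*/sqrt(N))^2 = 2 g*^2 = 1`).

`Xi` is estimated by Monte Carlo (default 10^4 replicates, batched to bound
memory, standard errors always reported); the `alpha = 2` path uses the
digamma closed form by default so that downstream comparisons carry no
Monte-Carlo noise.  The closed form doubles as an independent oracle for
the Monte-Carlo path in the tests.  For `alpha < 2` the predicted
large-size decay is `g* ~ (ln N)^(-1/alpha)`; `asymptotic_gain_check`
regresses `ln g*` on `ln ln N`.  Slowly varying corrections make the fitted
slope approach `-1/alpha` only over several decades of `N`, hence the wide
default grids and the generous tolerance (±0.25) in the acceptance test.

When averaging over Monte-Carlo replicates, `Xi` is averaged first and then
exponentiated (rather than averaging `g*` draws); the two differ at
`O(stderr^2)` and the `Xi`-average is the quantity the theory controls.

## Linear (Kesten) simulations and the order parameter

Away from the transition, `||eps(T)||` spans hundreds of orders of
magnitude within ~100 steps, far beyond double range.  `simulate_linear`
therefore carries a unit 2-norm direction vector plus an accumulated
natural-log magnitude; renormalization happens every step, and the exact
zero vector (gain 0) is encoded as `log_magnitude = -inf`.

Because the map is linear, the gain enters only as a global factor:
`eps_g(T) = g^T * (product of unit-gain matrices) * eps(0)`.  All gain
sweeps exploit this identity — one unit-gain base path per realization
serves the entire gain grid exactly, in both annealed and quenched modes.
This is the same realization-sharing protocol used for quenched sweeps
(draw the base matrix from `L_alpha(N^(-1/alpha))` once, rescale by each
`g`), extended along the gain axis.

The transition is detected with the order parameter `f_<eps`: the
*fraction* of final-state components within `eps` of zero (default
`eps = 0.1`), evaluated in log space (`ln|d_i| + log_magnitude < ln eps`)
so that astronomically large or small magnitudes never overflow.  It is a
fraction, not a count, so its limits are 1 (quiescent) and 0 (escaped)
independent of `N`.  Initial conditions default to i.i.d. uniform(-1, 1)
components; the initial-condition law is an implementation choice, and the
transition location is insensitive to it because the growth rate, not the
starting magnitude, decides escape for `T` large.

In annealed mode the per-step log growth of the alpha-norm is recorded
alongside the 2-norm: the alpha-norm is the quantity the scalar recursion
above controls, and the acceptance suite checks the two routes —
full-matrix simulation vs the scalar recursion — for *distributional*
agreement with a two-sample KS test, not just agreement in the mean.

## Lyapunov spectra

The spectrum is computed with the standard QR (Benettin) method: an
orthonormal frame of `m <= N` tangent vectors is propagated by the exact
Jacobian `diag(1 - x(t+1)^2) W` and re-orthonormalized by QR every step;
`ln R_ii` is accumulated after a warmup during which the state evolves but
nothing is accumulated.  Numerical conventions:

* R's diagonal is forced positive by column sign flips (otherwise
  `ln R_ii` is ill-defined).
* A per-step floor of `ln(machine epsilon)` is applied to `ln R_ii`; deep
  in the quiescent phase (or at gain 0) trajectories hit exact floating
  zeros, and the floor keeps estimates finite.  Floored results are
  flagged.
* The state and the frame are advanced by one fused matrix product per
  step (`W @ [x, Q]`), which halves memory traffic; the `m = 1` maximal-
  exponent path replaces QR by plain normalization.
* A tangent frame of `m = 1` is used for maximal-exponent sweeps, the full
  frame for `N <= 1000`, and a top-100 frame above that (the full-frame
  cost is `O(N^3)` per step).
* In the linear test mode (`tanh` replaced by identity) the state is not
  evolved at all — the Jacobian is the constant `W` and the exponents
  converge to `ln|eig(W)|`, which is the package's main oracle for the QR
  machinery.

Maximal-exponent sweeps follow the protocol: `T = 3000` steps with
exponents accumulated over the last `K = 100` (warmup `T - K`), 10 trials
per gain, each trial drawing a fresh matrix, initial condition and input
stream.  Realization averaging is the default for autonomous runs;
input-stream averaging over a fixed matrix is available behind a flag.
Full-spectrum runs use an explicit warmup (default 500 steps).  The
transition gain is the first upward zero crossing of the trial-mean maximal
exponent, refined by linear interpolation between the bracketing grid
points; if the curve starts nonnegative the first grid gain is returned.

Near the transition the 10-trial mean exponent sits within a few 1e-3 of
zero over a wide gain stretch (for the Gaussian network the rise above
threshold is roughly quadratic in `g - g*`).  Two practical consequences,
both visible in the test suite:

* the *sign* of the mean exponent at, say, 1.05 g* is not a stable
  observable at these sizes — tests bracket the transition at 0.5 g* and
  1.4 g* instead;
* the interpolated crossing carries a few-percent, seed-dependent
  uncertainty, which is well inside the 15% consistency band checked
  against the annealed prediction.

The *edge-of-chaos width* is measured as the gain interval on which
`|mean MLE| <= 0.05`, between interpolated crossings of -0.05 and +0.05
(censored at the grid edges).  Note what this absolute measure is
sensitive to: the subcritical slope, the location of the crossing, and the
supercritical rise all enter.  The Gaussian network's slow quadratic rise
above its (large) critical gain produces a wide absolute band even though
its transition sits at a much larger gain than the heavy-tailed network's;
widths measured *relative to each network's own critical gain* weigh the
heavy-tailed network's plateau more heavily.  The acceptance suite asserts
the absolute-width ordering at N = 500 as specified; see the test output
for the verdict at those study conditions.

## Dimensionality measures

**Kaplan–Yorke dimension.**  With exponents sorted nonincreasing and `k`
the largest index keeping the cumulative sum nonnegative,
`D_KY = k + (sum_{i<=k} lambda_i)/|lambda_{k+1}|`.  Edge conventions (the
definition is silent on them): `D_KY = 0` when the leading exponent is
negative; `D_KY = m` when the full tracked sum is still nonnegative.  The
absolute value in the denominator is required for `D_KY >= k`
(`lambda_{k+1} < 0` by construction of `k`).  With a top-`m` frame the
value is capped at `m`; at the sizes used here the cumulative sum turns
negative well before rank 100.

**Participation ratio.**  `PR = (sum lambda~)^2 / sum lambda~^2` over the
eigenvalues of the steady-state covariance — the only reading of this
ratio consistent with its stated range 1 (one mode) to N (uniform).  The
covariance uses the last `K` retained states with divisor `K - 1`;
`K > N` is recommended for a full-rank estimate and violating it warns
rather than errors.  Eigenvalues are clipped to zero below `1e-12` of the
largest (numerical noise in rank-deficient regimes), and the ratio is
computed on the spectrum normalized by its largest eigenvalue, which makes
scale invariance exact in floating point.

**Comparison protocol across tail indices.**  Dimensionality is compared
at a *common* gain inside the near-chaotic regime — in the acceptance
suite, 1.7x the measured Gaussian crossing at N = 300, a point above both
networks' transitions — matching the common gain axis on which the
dimensionality-versus-gain curves are defined.  Exactly *at* each
network's own crossing the comparison is degenerate: there the Gaussian
network has barely detached from quiescence, roughly half its trials still
have a negative leading exponent, and both measures sit near their floors.
The tradeoff claim (heavier tails give lower `D_KY` and lower `PR`, with
the `PR` drop the shallower of the two) is a statement about the chaotic
neighborhood of the transition, not about that degenerate point.

## Reservoir task

The delayed-XOR task drives the network with a ±1 stream through a fixed
random input vector and a static random bias, and trains a ridge readout
(normal equations, intercept included) on the post-washout states to
predict the XOR of the bits at lags `delay` and `delay + 1`; accuracy is
evaluated on a held-out continuation.

The bias is structural, not cosmetic: with symmetric ±1 inputs, zero
initial state and an odd activation, the network state is an odd function
of the input history, while XOR of two bits is an even function — a linear
readout of a bias-free tanh reservoir is stuck at chance on this task
regardless of gain.  All task parameters (delay 1, 2000/1000 train/test
steps, ridge 1e-4, input scale 0.5, bias scale 0.2, washout 50) are
package choices exposed in `ReservoirTaskSpec`.

## Mega-synapse ablation

`ablate_top_weights` zeroes the `n_remove` largest-|w| entries (ties broken
in row-major order); the experiment wrapper measures the maximal exponent
before and after on the same realization, with the removed count reported
both absolutely and as a fraction of `N^2`.  For heavy tails, removing a
handful of entries out of `N^2` collapses most of the operator norm — the
outlier dominance that drives the low-dimensionality results.

## Synthetic data: what the generator does and does not emulate

All inputs are generated internally; there is no external data.  The
generator realizes exactly the statistical ensemble of the model: i.i.d.
symmetric stable weights with scale `g/N^(1/alpha)`, uniform(-1,1) initial
states, optional i.i.d. Gaussian drive (variance 0.01) and ±1 task
streams.  It does *not* emulate features of biological circuits outside
the model class: no Dale's law or sign-segregated populations, no
cell-type structure or connectivity motifs, no sparsity constraints, no
synaptic dynamics or plasticity, no correlated or log-normal (rather than
stable) weight statistics.  Passing tests therefore validate the theory
and its simulators on the stated ensemble; they do not by themselves
establish the behavior of biological connectomes, for which the stable
family is a modeling choice.

## Problem sizes and runtime choices

Everything is desk-runnable on one core: transition checks at `N = 3000`,
`T = 100`, 10 seeds; maximal-exponent sweeps at `N = 200..1000` with 10
trials per gain; top-100 spectrum runs at `N = 300` with horizon 1500
(warmup 500, so the covariance retains 1000 > N steps); theory grids up to
`N = 10^6` with per-size Monte-Carlo budgets.  Paper-scale sizes
(`N = 10^4`, full spectra at `N = 1000+`) run through the same interfaces
when more time is available.  Monte-Carlo replicate counts at very large
`N` are reduced (150–2000) because each replicate costs `O(N)`; reported
standard errors make the precision explicit.

## Known limitations

* Only `tanh` and the linear map are implemented; other activations
  (ReLU, non-odd saturating functions) change the supercritical behavior.
* The quenched transition point is characterized empirically; no quenched
  analytic theory is provided (the annealed `g*` is its large-N anchor).
* For `alpha < 1` the maximal exponent is non-monotone in the gain; the
  simulators handle this regime but no quantitative claims are tested.
* Finite-`K` exponent accumulation (K = 100) leaves a small bias near the
  transition; crossing estimates inherit it (the annealed prediction is
  known to sit slightly below the measured chaos onset).
* `D_KY` from a top-`m` frame is exact only while the cumulative sum turns
  negative before rank `m`; the suite's sizes satisfy this.
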