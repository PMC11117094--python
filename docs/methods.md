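# Methods

## Problem setting

Three aligned sample vectors are analysed as i.i.d. draws of random
variables: two sources X, Y and a target Z (in a trial-based recording,
the samples are trials at a fixed time point, which is what makes the
i.i.d. assumption defensible). The relation of (X, Y) to Z is decomposed
into four information atoms: unique U(X→Z|Y), unique U(Y→Z|X), redundant
R(X:Y→Z) and synergistic S(X:Y→Z). The package's concern is the
*statistical testing* of these atoms when the observables carry noise.

## Simulation models

Ground-truth models draw latent variables T_x, T_y, T_z — standard normal
(continuous) or fair Bernoulli coins (discrete) — and expose exactly one
atom:

* mRed: X\* = Y\* = Z\* = T_x (pure redundancy);
* mUnq: X\* = Z\* = T_x, Y\* = T_y (pure unique information);
* mXOR: discrete Z\* = XOR(T_x, T_y); continuous sign-XOR
  Z\* = |T_z|·sign(T_x)·sign(T_y), so |Z\*| is half-normal and the target
  sign is the product of source signs (pure synergy; sign(0) is treated as
  +1, a probability-zero event);
* mSum: Z\* = T_x + T_y, discrete target alphabet {0, 1, 2}. Its PID ground
  truth is contested (mutual information is additive in log-variance, not
  variance, so PID finds synergy where variance partitioning finds two
  unique relations); the registry therefore refuses PID × mSum pairings and
  mSum is used only to validate variance partitioning.

Observable models corrupt each variable with a noise fraction p ∈ [0, 1].
Continuous: amplitude mixing X = (1−p)·X\* + p·ν with ν ∼ N(0,1) — the
mixing is on amplitudes, exactly as the sweeps are parameterised; the
variance-share quantity p²/(p² + (1−p)²) is exposed separately as
`nominal_noise_fraction`. Discrete: with probability p the sample is
replaced by an independent fair coin (the switching probability equals the
mean of the switching variable, hence is itself the noise fraction). Three
single-parameter strategies reduce (p_x, p_y, p_z) to one knob: PureSrc
(0, 0, ν), NoisyX (ν, 0, ν), Noisy (ν, ν, ν).

Noisy observables are *not* re-standardised before measure computation:
the measures used are either scale-free (correlations, information) or
normalised internally (variance partitioning by SST), so standardisation
would be a no-op in population and only add sampling noise.

Randomness policy: every experiment takes one root seed; latents, noise
draws, switching draws, permutations, null/test/search repetitions each get
an independent deterministic substream (numpy `SeedSequence` spawning).
Identical seeds give bit-identical tables.

## Measures

**Partial correlation.** Y is regressed out of X and of Z by least squares
with intercept; the atom is the Pearson correlation of the residuals
(swap the source roles for the second unique atom). If a residual variance
is numerically zero (below 1e−12 of the total — e.g. noiseless mRed, where
X, Y, Z are identical), the value is 0 by convention with a
degenerate-input warning. As relations can carry either sign, the test
statistic is |PCorr|.

**Variance partitioning.** The quadratic interacting model
Z ≈ aX + bY + cXY is fitted by least squares after centring all variables
including the product predictor (equivalent to modelling an intercept).
Unique and synergistic atoms are partial R² terms — the residual sum of
squares lost when the aX, bY or cXY term is removed and the reduced model
*re-fitted from scratch* (partial R² is defined through the reduced model's
own optimum, not through zeroing a coefficient of the full fit). Redundancy
is the classical commonality R·SST = SST − SSR_x − SSR_y + SSR_{x,y} over
the three purely linear sub-models; this symmetric form is the only
rendering that is invariant under source swap and reduces to shared
explained variance. In-sample commonality can be negative (suppression);
the atom is defined nonnegative and negative values truncate to zero.
Collinear designs (noiseless mRed) are handled by minimum-norm least
squares — the atoms depend only on residual sums of squares, which remain
well defined. All atoms are normalised by SST_Z; only relative statements
about them are meaningful.

**MMI PID.** Redundancy is min(I(X:Z), I(Y:Z)); unique atoms are the
excesses of the pairwise informations, synergy the remainder of I(XY:Z).
Conservation U_x + U_y + R + S = I(XY:Z) holds by construction, and on
exact pmfs synergy is nonnegative because I(XY:Z) ≥ max(I(X:Z), I(Y:Z)).
The definition is valid when redundancy depends only on the pairwise
source–target marginals — true for the corner models used here; no
general-case guard is possible and none is attempted. Discrete MMI runs on
exact or empirical joint pmfs (empirical tables use the declared model
alphabet, not the observed support). The exact observable pmf is computed
in closed form by summing over latent and switching configurations and
serves as the infinite-data oracle in tests.

**Continuous MMI.** The three mutual informations are estimated with the
Kraskov–Stögbauer–Grassberger k-nearest-neighbour estimator (algorithm 1):
max-norm neighbourhoods, ψ(k) + ψ(n) − ⟨ψ(n_a+1) + ψ(n_b+1)⟩, converted to
bits. k defaults to 3 and is exposed as a parameter. Ties are broken by a
deterministic seeded jitter of amplitude 1e−10 of each column's scale, so
permutation nulls are reproducible. Atoms are reported unclipped and may be
slightly negative. Differential mutual information diverges for
deterministic relations, so each variable must have sample variance above
1e−12; emulating noiseless continuous models requires at least ~1 % source
noise. Known estimator behaviour to keep in mind: the joint-space estimate
I(XY:Z) carries a finite-sample negative bias for strongly structured
relations — on the sign-XOR model (population synergy exactly 1 bit) the
estimate is ≈0.86 bits at n = 5,000 and ≈0.91 at n = 20,000. Tests
therefore band this value at 1.0 ± 0.2 and additionally require synergy to
dominate the other atoms by an order of magnitude.

**BROJA PID.** The unique information of X is the minimum of I_Q(X:Z|Y)
over the polytope of joint laws Q sharing the data's (X,Z) and (Y,Z)
pairwise marginals. Because I_Q(X:Z) and I_Q(Y:Z) are fixed on that
polytope, minimising I_Q(XY:Z) is an equivalent objective and yields all
four atoms from one optimum: U_x = I_Q\*(X:Z|Y), U_y = I_Q\*(Y:Z|X),
R = I(X:Z) − U_x, S = I(XY:Z) − I_Q\*(XY:Z). The program is solved over the
null-space coordinates of the marginal constraints (cells with a zero
pairwise marginal are eliminated first), starting from the strictly
interior conditional-independence point Q0 = p(x,z)p(y,z)/p(z), with
analytic gradients, SLSQP as the primary solver (objective tolerance 1e−10)
and trust-constr as fallback; failure of both raises an estimation error
carrying the solver status. The test suite cross-checks the solver against
an independent brute-force grid search over the polytope (one free cell per
target slice for binary sources) to 1e−3 bits on the AND gate and random
pmfs; on the three corner models the polytope is a single point and the
atoms are exact.

## Significance testing

**Permutation test.** The null distribution is built by drawing a fresh
model dataset per repetition and permuting it along the *target only* —
permuting sources as well would perturb estimators that are sensitive to
source correlation even under the null. (A fixed-dataset mode that permutes
one dataset many times is provided as an option.) The critical value at
level α is the conservative empirical upper quantile: the order statistic
of rank ⌈(1−α)(m+1)⌉, capped at m; the same convention is used everywhere a
quantile is taken, including the adversarial screening percentiles. The
significant fraction over fresh datasets is compared against
Binomial(n_test, α) one-sided at threshold 0.01. Critical values are
re-estimated per noise and data-size context.

**Adjusted (conservative) test.** The composite null is "the data came
from some model with zero true value of this atom". The adversarial-set
registry lists those models per measure/atom: unq_x → {mRed, mXOR};
unq_y → {mRed, mUnq, mXOR}; red → {mUnq, mXOR}; syn → {mRed, mUnq} (mXOR is
excluded for synergy since its synergy is real); for variance partitioning,
mSum joins the red and syn sets (its VP ground truth is purely unique). The
registry is an editable module-level table. For unique atoms the search
runs along the diagonal p_x = p_y = p_z only — with asymmetric source noise
the spurious unique atom grows without bound and the inference problem is
genuinely unidentifiable, so the symmetric-noise subproblem is what is
tested. For redundancy and synergy, *both* candidate lines (the diagonal,
and p_x = p_y with p_z = 0) are always searched and the maximum taken —
slightly more conservative than classifying the noise-dependence pattern by
eye and picking one line, and automation-safe. Each line search screens a
grid of equispaced noise fractions (default 100 steps, 200 resamples each,
upper-α order statistic), then re-estimates the critical value at the
argmax with many more resamples (default 10,000). Continuous searches floor
all noise fractions at 0.01 (configurable) because the continuous
information estimators diverge as noise → 0; the continuous synergy
critical value is maximal at that floor and would grow without bound below
it. Exceeding the conservative critical value rejects every model in the
adversarial set. The known cost is an elevated false-negative rate,
worst for continuous MMI synergy, where the conservative threshold can
swallow the true positives entirely.

One departure from a literal reading of the source material: its CV table
prose reports the highest "false positive redundant atoms" under mRed —
but redundancy is *true* in mRed, so by the composite-null definition mRed
cannot be adversarial for the red atom. The CV table built here computes
critical values for all legal model/atom combinations (so such comparisons
remain available), while the operative conservative CV maximises over the
zero-atom set only.

## Problem sizes and profiles

Defaults follow the study conditions: α = 0.01, n_samples = 10,000,
n_null = n_test = 10,000, adversarial search 100 × 200 with 10,000-resample
refinement ("paper" profile). The "desk" profile (n_null = n_test = 500,
search 20 × 50 with 1,000-resample refinement) is for interactive use;
quantile estimates from 500 draws carry a relative error of a few tens of
percent in the extreme tail, so desk-profile fractions come with
correspondingly wide Monte-Carlo bands. The bundled test suite runs
permutation checks at n_samples = 10,000 with 300–500 repetitions, and the
conservative-specificity property at n_samples = 1,000 (400 for the
nearest-neighbour estimator) with a 10 × 50 search and 500-resample
refinement — the specificity guarantee is scale-free, since critical value
and test draws always share one sample size. BROJA sweeps cap per-point
resamples (default profile values) for tractability.

When pooling significant fractions across a sweep, per-grid-point
repetitions use independent seed substreams; otherwise the critical-value
estimation error is common to all points and the pooled mean does not
average down. A related subtlety: a critical value estimated from m null
draws makes the exceedance probability of fresh draws Beta(m+1−r, r)
distributed (r the order-statistic rank), so calibration checks compare
significant counts against the beta-binomial compound, not a fixed-α
binomial.

## What the simulators do and do not emulate

The generators produce i.i.d. triplets with independent additive
(continuous) or switching (discrete) noise — the setting in which the
false-positive mechanism (noise decorrelating redundant sources) is
cleanly isolated. They do not produce autocorrelated time series,
non-Gaussian or multiplicative noise, or models with more than one atom
present at a time (mSum excepted). Passing tests therefore demonstrate the
biases and their correction under these idealised conditions; on real
recordings, autocorrelation alone can invalidate permutation nulls in ways
this package does not model, and unequal noise between redundant sources
makes unique-versus-redundant attribution fundamentally ambiguous (two
generative designs with different atom interpretations can induce the
same data distribution).

## Numerical choices

* Degenerate inputs: zero residual variance → partial correlation 0 with a
  warning; zero SST → all VP atoms 0 with a warning; constant continuous
  variables → domain error from the KSG-based PID.
* Tiny negative partial-R² differences from rounding are clipped at 0;
  pmf validity is enforced at 1e−12 (sum) and −1e−15 (entries).
* 0·log 0 ≡ 0 throughout; logs are base 2 (atoms in bits).
* `n_null · α < 5` triggers an unstable-quantile warning rather than an
  error.
* The noise-sweep default grid is 0 plus 30 log-spaced points on
  [0.001, 1], matching the decades over which the false-positive onsets
  occur; pooled-fraction summaries depend on this weighting (the pooled
  spurious VP-redundancy fraction is ≈0.67 under this grid).
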