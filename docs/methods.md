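# Methods

This note documents the models, conventions and numerical choices behind
`crossrec`, in the order of the analysis pipeline.

## Series and categorical coding

A `TimeSeries` is a one-dimensional array tagged `continuous` (floats,
all finite) or `categorical` (integer state codes).  When two
categorical series are analysed together, their labels are coded over a
*shared* alphabet so that equal codes mean equal states; states common
to both series receive the first codes (in order of first appearance
scanning series 1 then series 2), followed by states unique to either.
Recurrence between categorical series is exact state matching, obtained
by thresholding at a near-zero radius (default 0.001): integer codes
differ by at least 1, so only identical states fall within the radius.

## Embedding, distances, thresholding

`embed_series` unfolds x into delay coordinates
(x(t), x(t+τ), …, x(t+(m−1)τ)), giving T − (m−1)τ rows; m = 1
reproduces the raw series.  Distances between the two embedded
trajectories are Euclidean (the only metric provided).  Optional
preprocessing: `normalize="zscore"` standardizes each series before
embedding (population SD); `rescale="mean"` or `"max"` divides the
distance matrix by its mean or maximum and expresses it as a
percentage, so the radius becomes a percentage of the typical (maximal)
distance.  Defaults are `none` for both: for categorical data rescaling
is meaningless, and for continuous data the appropriate convention
depends on how the radius was chosen.  Both rescaling modes exist
because radii quoted for z-scored behavioral data are sometimes only
interpretable as percentages of the mean distance; which convention a
given external value assumes is often undocumented, so none is asserted
as canonical here.

Thresholding keeps (i, j) with D[i, j] ≤ ε (so ε = 0 admits exact
matches).  Indexing is 1-based in all exports: i indexes series 1
(horizontal plot axis), j indexes series 2 (vertical); a point at
j = i + 1 sits one diagonal *above* the line of coincidence (LOC).
The recurrent set is stored as sparse coordinates; dense
materialization is guarded (default limit 4000×4000).

The Theiler window removes the band |j − i| ≤ tw − 1 around the LOC:
tw = 0 (default) is the identity and is the right setting for
cross-recurrence, where the two series are genuinely synced along the
LOC; tw = 1 removes exactly the main diagonal, useful for
auto-recurrence of a series with itself, where trivial short-lag
autocorrelation inflates the plot.  tw ≥ 1 requires a square matrix,
and a window that would remove every diagonal is an error.

## The seven measures

With n₁×n₂ the full matrix area and |R| the recurrent-point count:

- RR = 100·|R| / (n₁n₂).  The denominator is always the full area;
  Theiler-masked cells simply count as non-recurrent.
- Diagonal lines are maximal runs of consecutive points along a fixed
  offset d = j − i; vertical lines are maximal runs of consecutive
  series-1 indices i at fixed j (dwelling of series 1 near one moment
  of series 2).
- DET (LAM) = 100 × points on diagonal (vertical) lines of length
  ≥ `minline` / |R|.  Default `minline` = 2; lengths ≥ 2 qualify.
- L, Lmax (TT): mean and max over qualifying diagonal (vertical) run
  lengths.
- ENTR: Shannon entropy, natural log, of the relative frequency of
  qualifying diagonal run lengths.  Exactly one distinct length gives
  ENTR = 0.

Degenerate cases never raise: an empty plot reports RR = 0; an empty
qualifying set reports DET = LAM = ENTR = 0 and L = Lmax = TT = NaN.
NaN (not 0) for the undefined means is deliberate, so that averaging
windowed results cannot be silently diluted.  One boundary consequence
of the definitions: a fully saturated n×n plot has DET =
100·(n²−2)/n², not 100, because the two corner diagonals have length 1
and fall below `minline`.

## Profiles and sign convention

The diagonal-wise recurrence profile compares x(t) with y(t−ℓ) for each
lag ℓ ∈ [−W, +W]: rr(ℓ) = 100·#matches / (T−|ℓ|).  The denominator is
the number of valid comparisons at that lag, not the fixed series
length, so edge lags are not artificially deflated.  Under this
convention a *negative* peak lag means series 1 leads series 2 (if
y(t) = x(t−k) exactly, the profile peaks at −k), and lag ℓ corresponds
to the diagonal at offset d = −ℓ of the recurrence matrix.  Ties for
the argmax resolve to the smallest |lag|, then to the negative lag, so
output is deterministic.  `exclude_nonevent` names a state (typically 0
in event series) whose joint occurrence in both series is dropped from
the numerator only — recurrence then counts co-visitation of events,
not of shared silence.  Unequal-length series are truncated to their
overlap for all profile operations; the full rectangular plot is used
everywhere else.

Windowed variants slide a window (start indices advancing by `step`
from the beginning of the overlap; trailing partial windows dropped,
not padded).  `windowed_diagonal_profile` averages rr over lags
[−lag_window, +lag_window] within each window (lag_window must be
smaller than the window); the per-lag denominator within a window is
again the number of valid comparisons.  `windowed_full_crqa` runs the
complete measure set per window; windows that degenerate (e.g. too
short for the embedding) yield all-NaN measures instead of aborting the
sweep.

## Contingency tables and phi

For categorical pairs, the lag-ℓ table counts CTℓ[a, b] = #{t :
x(t) = a, y(t−ℓ) = b} over valid t — the same sign convention as the
profiles.  Tables are built over the *union* alphabet, so each per-lag
total equals T − |ℓ| exactly; the states *common* to both series define
the recurrence diagonal, and rr(ℓ) = 100·trace/total over the common
states reproduces the diagonal recurrence profile lag for lag (asserted
in tests).  Having no common state at all is an error that lists both
alphabets.

phi(k) collapses each table to 2×2 over {k, not-k} — a = (k,k),
b = (k,¬k), c = (¬k,k), d = (¬k,¬k) — and applies the Pearson phi
coefficient (ad − bc)/√((a+b)(c+d)(a+c)(b+d)).  This is the standard
2×2 association coefficient with exactly the qualitative behavior
wanted: it grows with matched visits to k and matched avoidance of k,
and shrinks with mismatches.  States occurring in only one series
contribute not-k mass.  A zero margin leaves phi undefined at that lag
(NaN, with the count of such lags reported).  k must itself be a common
state.

## Parameter selection for continuous series

`optimize_params` composes three steps; all diagnostics (AMI curves,
FNN fractions, radius trace) are retained in the result.

**Delay (AMI).**  The series is discretized once into 10 equal-width
bins over its full range (bins fixed across lags), and AMI(ℓ) is the
mutual information, in nats, of the joint histogram of (x(t), x(t+ℓ)).
Selection: if AMI(1) ≤ 10% of AMI(0) the delayed copy is already
uninformative and delay 1 is returned (structureless data).  Otherwise
the first *persistent* local minimum is returned: a lag the curve
decreases into and that no lag within the next 5 steps undercuts.  The
persistence check exists because histogram AMI estimates of
deterministic signals wiggle lag to lag, and a plain first-local-minimum
rule fires on those wiggles several lags early.  If no such minimum
exists, the first lag whose one-step relative decrease falls below 5%
is returned (the curve has levelled off), then max_lag as a last
resort.  The per-series delays are combined: if one is more than twice
the other, the longer wins (both series must gain new information);
otherwise the rounded mean.

**Embedding dimension (FNN).**  Kennel-style false nearest neighbors:
in dimension d, each point's nearest neighbor is false if the extra
(d+1)-th-coordinate separation exceeds 10× the d-dimensional distance
(plus an absolute floor of 1e−9×SD, which keeps float-precision jitter
between exact revisits from registering as false).  The first dimension
with under 5% false neighbors — or where the fraction stops decreasing
— is selected per series, and the larger of the two answers is used.

**Radius.**  Candidate radii are a deterministic grid of 20 equally
spaced values between 0 and the radius yielding roughly 25% recurrence
(estimated from a strided ≤1500-point subsample of the distance
distribution), evaluated *exactly* in a single blockwise pass over the
full distance set.  Candidates are scanned in ascending order and the
first whose recurrence rate lands in the target band (2–5% by default)
is returned; ascending order makes the result monotone — widening the
band never increases the returned radius.  If the grid steps over the
band, it is refined between the bracketing candidates, up to 3 rounds;
a band that remains unreachable (e.g. discrete-valued data whose RR
jumps across it) raises an error carrying the full (radius, RR) trace.
The grid is deterministic, so radius selection is seed-free.

## The coupled binary-agent simulator

The generator emulates a minimal confederate-drives-participant dyad:
per step, C emits an event with probability p_c, else repeats with
probability p_cc after its own event; S emits with probability p_sc if
C emitted on the *previous* step, else at base rate p_s, else repeats
with probability p_ss.  The one-step reaction is what makes C lead S by
one sample, so both the cross-correlation profile and the diagonal
recurrence profile of a simulated pair peak at lag −1; a same-step
variant is available behind `coupling="same"`.  Each decision consumes
its own uniform draw from a seeded generator, so equal seeds reproduce
pairs bit for bit.  The default condition (p_c = 0.25, p_s = 0.05,
p_cc = p_ss = 0.05, p_sc = 0.33, 1000 steps) is the high-coupling
condition used throughout the examples and acceptance script; the low
condition sets p_c = 0.05.  C's stationary event rate follows from its
two-state Markov chain: p_c/(1 − (1−p_c)·p_cc) ≈ 0.2597 in the high
condition, which the calibration test checks within 3 standard errors
over 20 runs.

What the simulator does *not* emulate: real behavioral event series are
non-stationary (coupling waxes and wanes), have autocorrelated gaps,
multiple interacting states, and measurement noise.  Passing tests on
simulated dyads therefore demonstrate that the estimators recover
known, stationary, single-channel coupling — not that any particular
behavioral dataset satisfies those assumptions.

## Problem sizes and runtime choices

The test suite and acceptance script run at desk scale: 20 dyads ×
1000 steps for the coupling-lag and calibration checks, 20 random pairs
of length ≤ 200 (dimensions 1–3) for the exact naive-oracle
equivalence, 10,000-point standard-normal pairs for the closed-form
radius-band check (RR(r) = 2Φ(r/√2) − 1 maps the 2–5% band to radii in
[0.0355, 0.0887]), and 1000-point signals for delay/dimension recovery.
These sizes make every check reproducible in seconds while leaving the
estimators' asymptotics visible.

## Known limitations

- Euclidean distances only; no joint recurrence, recurrence networks,
  order-pattern recurrence, or measures beyond the seven listed
  (no Vmax, divergence, or recurrence-time statistics).
- The radius search targets a recurrence-rate band; it is a calibration
  heuristic, not a theoretically optimal radius.
- phi is the only lag-sequential statistic provided (no adjusted
  residuals or Yule's Q).
- The profile functions embed before lag comparison, but the typical
  categorical use is unembedded (delay = embed = 1); embedded
  categorical profiles are supported but rarely meaningful.
- Inference (surrogate/virtual-pair baselines, shuffling, growth-curve
  modeling of profiles) is out of scope; the package computes
  descriptive quantities.
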