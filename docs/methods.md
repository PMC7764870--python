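# Methods

This note records the models, numerical methods and design choices behind
`filmrheo`, and what the synthetic-data tests do and do not demonstrate
about measured data.

## The stress–relaxation model

A film subjected to a small, rapid relative area compression ΔA/A₀ responds
with a pressure jump that relaxes toward a plateau.  We model the response
in the linear (small-deformation) regime as a generalized Maxwell material:

    Δπ(t) = Σᵢ Aᵢ e^(−t/τᵢ) + Δπ_EQ,

where each exponential term is a spring-and-dashpot element with elasticity
Eᵢ = Aᵢ/(ΔA/A₀) [mN/m] and dilatational viscosity ηᵢ = τᵢ·Eᵢ [mN·s/m]
(τᵢ = ηᵢ/Eᵢ holds identically), and Δπ_EQ is an equilibrium spring
E_eq = Δπ_EQ/(ΔA/A₀).  The assumptions are the usual ones for the
small-deformations method: strain small enough for linearity (the protocol
uses 5 ± 1%; the data model accepts (0, 0.2]), the step fast relative to
the fastest relaxation of interest, and a film that actually relaxes
downward after a compression (amplitudes are constrained non-negative by
default; a flag lifts this).

### The frequency-domain transform

The complex dilatational modulus is the transfer function from relative
area strain to surface pressure.  For a step strain it reduces to

    E*(ν) = [Δπ_EQ + i·2πν ∫₀^∞ (Δπ(t) − Δπ_EQ) e^(−i·2πν·t) dt] / (ΔA/A₀).

Two numerical points matter:

* **Normalization.**  Dimensional analysis fixes the strain as a divisor
  (E* must carry mN/m; the Fourier transform of d ln A/dt for a step is
  ΔA/A₀).  Some typeset forms of this equation read as if multiplying by
  the strain; we divide.  2π is used exactly.

* **Plateau handling.**  The one-sided integral of the plateau does not
  converge numerically, so Δπ_EQ is split off and transformed analytically;
  only the decaying remainder is integrated.  Δπ_EQ defaults to the mean of
  the last 10% of samples (`tail_fraction`), overridable with a known
  value.  On a record lasting ten times the slowest relaxation time, the
  residual bias of the tail-mean estimate propagates to the low-frequency
  end of E_R at below the half-percent level, inside the 1% oracle
  tolerance enforced by the tests.

* **Quadrature.**  The integral uses a Filon-type rule that is *exact for
  the piecewise-linear interpolant* of the samples: per interval,
  ∫(a+bt)e^(−iωt)dt in closed form, with a Taylor branch below |ωh| = 0.5
  to avoid catastrophic cancellation (both branches agree to ~1e−15 at the
  crossover).  This makes the transform robust on irregular sampling and
  second-order accurate in the sampling step on smooth signals.  An
  optional exponential tail extension continues the decaying remainder
  beyond the last sample; it is off by default because a 10·τ_max record
  leaves a negligible truncated tail, and the post-plateau residual is
  generally not single-exponential (it can be negative).

The resolvable band of a record is taken as [1/(10·T_record), Nyquist of
the sampling]; requested frequencies outside it are rejected.  The default
analysis grid is 60 log-spaced points per decade over 10⁻⁴–1 Hz, clipped to
the resolvable band — the decade 10⁻⁴–10⁻³ Hz is where storage and loss
moduli of surfactant-laden films come closest, so the default
classification band is set there.

### Cole–Cole peaks and model order

Each relaxation process contributes one Debye peak to E_IM; the number of
peaks in the Cole–Cole plot (E_IM vs E_R; equivalently E_IM vs log ν, since
E_R is monotone for a passive film) sets the number of exponential terms to
fit.  Peak detection uses `scipy.signal.find_peaks` with a prominence
threshold defaulting to 5% of max E_IM, ties broken toward lower
frequency.

On *measured* (noisy) transients the transform amplifies white pressure
noise proportionally to frequency, so the raw spectrum is noise-dominated
at the top of the band.  The automatic order estimator therefore:

1. averages the transient into logarithmic time bins (40 per decade)
   before transforming — slow processes live at late times where thousands
   of samples fall into each bin, shrinking white noise by √n, while early
   samples pass through untouched, preserving fast processes;
2. estimates the noise level robustly from first differences of the trace
   (median absolute difference / (0.6745·√2));
3. propagates that level *exactly* through the quadrature weights to a
   per-frequency 1σ curve for E_IM, and requires peaks to clear 5σ in both
   height and prominence (4σ still leaked occasional false peaks
   family-wise over a ~300-point grid);
4. uses a reduced fractional prominence (2% of max) in this path: the
   noise floor already rejects spurious wiggles, and the 5% default would
   suppress genuinely present weak slow processes;
5. spans the full resolvable band down to 1/(10·T) so a peak just above
   the band edge does not lose its prominence to grid truncation.

**Resolution limit.**  Peak counting cannot resolve a weak process next to
a strong one when the strong process's Debye tail fills the valley between
them: at a relaxation-time ratio of ~30–100 and an amplitude skew of 3:1 or
more, the weak peak's true prominence drops to ~1–2% of max E_IM — below
any reasonable noise floor at 1% measurement noise, and it vanishes
entirely at larger skew.  The order-consistency property is therefore
guaranteed (and tested, ≥95% over 100 seeded runs) for time ratios of
100–1000 and amplitude ratios within [1/3, 3]; outside that envelope the
estimator degrades gracefully to the dominant order.  Resolving closer
processes would require inverse-spectrum methods, which are out of scope.

### Fitting

Sum-of-exponentials least squares is ill-conditioned, so the fitter:

* initializes relaxation times log-spaced across the record
  (geometric mean of 3·dt and T/2 for one component),
* solves amplitudes by non-negative linear least squares at fixed times,
* refines all parameters jointly with bounded trust-region least squares
  (amplitudes ≥ 0 by default, log-τ ∈ [log dt, log 10T], plateau free),
* restarts from jittered initializations (default 5, deterministic seed)
  only if the first attempt fails, raising a fit-failure error carrying
  the best attempt if none converges,
* merges numerically coincident times (ratio < 1.005) by amplitude
  summation and flags fits whose neighboring times are closer than 3×
  as unresolved,
* reports per-parameter standard errors from the Gauss–Newton covariance
  (delta method for τ = e^x).

Weighting is uniform; replicate-based inverse-variance weighting can be
emulated by fitting averaged transients.

## Isotherm analytics

Recordings are split at area extrema (prominence filter, default 5% of the
area range, so jitter near a turning point does not create spurious
branches); each sample belongs to exactly one branch, so re-concatenation
restores the recording.  Compression branches are used for shifts and
squeeze-out — penetration is read off the compression leg — with the
branch choice exposed.

* **Stationarity**: smallest cycle index from which every pair of
  consecutive compression branches differs by less than `tol` (default 2%
  of max π, echoing typical replicate spread) in maximum absolute π on the
  common area grid.
* **Averaging**: linear interpolation to the intersection range at the
  finest sampling; pointwise mean ± sd plus the maximum pairwise deviation
  relative to max |mean| as a QC figure against the ~2% replicate spread
  expected of good trough work.
* **Pressure shift**: Δπ(A) = π_test − π_ref on the overlap grid; area
  units are carried opaquely and must match (per-molecule areas cannot be
  converted to trough areas without molecule counts).
* **Squeeze-out**: scanning toward smaller area, the lowest test-branch π
  at and above which Δπ < threshold *for the whole remaining compression*
  — a sustained criterion, not a single crossing, for noise robustness.
  Threshold default 0.5 mN/m (no community-standard numeric criterion for
  "the shift disappears" exists; the value is exposed as a flag).  Returns
  absent when the shift never dies (persistent incorporation).  The
  detected value is monotone in the threshold when the shift decays more
  gently than the film pressure rises (|dΔπ/dπ| < 1 along compression);
  steeper transitions make the test branch locally non-monotone in π and
  the detected value can move by up to the threshold difference — an
  intrinsic property of reading the squeeze-out point off the shifted
  branch.
* **Hysteresis**: |∮π dA| by trapezoidal integration on the union of both
  branches' sample areas over the common range — exact for the
  piecewise-linear interpolants of the recorded points.

## Kinetics features

Δπ_max = max π − π₀, its time, and the first time at/after the peak from
which |π − π₀| < tol holds to the end of the record (default tol
0.5 mN/m).  The sustained-return scan includes the peak sample, so a flat
trace reports re-equilibration at its first sample.  π₀ comes from the
stored baseline or the mean of pre-injection (t < 0) samples.  No
adsorption model (Ward–Tordai or otherwise) is fitted; the features are
deliberately descriptive.

## Synthetic data: what it emulates, and what it does not

The generators produce the statistical structure the analysis assumes, with
defaults chosen to mirror the meibomian-film protocol:

* relaxation: strain 0.05, baseline 18 mN/m, two processes with times 33×
  apart (15 s, 500 s; amplitudes 4 and 3 mN/m) and a 4 mN/m plateau —
  two Cole–Cole peaks and a predominantly elastic spectrum;
* isotherms: monotone-cubic (PCHIP) base curve through waypoints spanning
  5–38 mN/m on a 40–135 cm² trough, ten triangular cycles, a logistic
  incorporation shift of 8 mN/m with an optional vanish pressure
  (default 23 mN/m, width 1 mN/m), hysteresis gap tapering to zero at the
  turning points so loops close, and a baseline drift decaying
  exponentially in time so consecutive compression branches differ by
  4·(1/2)^k mN/m — stationary from cycle 3 at a 1 mN/m tolerance;
* kinetics: π₀ + 15·(1 − e^(−t/20 s))·e^(−t/300 s), which peaks near 55 s
  (inside the first 100 s) and returns to within 0.5 mN/m of baseline
  near 1000 s.

Noise is iid Gaussian on π only.  Real trough data additionally show
drift from evaporation and leakage, autocorrelated sensor noise,
temperature coupling, and non-exponential (stretched or continuous-
spectrum) relaxation; none of these are emulated, so passing recovery
tests demonstrates correctness of the algorithms under the stated model,
not robustness to every instrumental artifact.  Every generator records
its true parameters in a sidecar (`meta["truth"]`, a JSON file from the
CLI), and all recovery tests read truth only from that sidecar.

## Reports and determinism

The pipeline writes CSV tables and JSON documents plus a manifest carrying
the tool version and a hash of the full configuration; all thresholds in
use are echoed there.  Output is plain text with full-precision floats and
sorted keys, so identical configuration and inputs reproduce the bundle
byte for byte — checked by test and by the acceptance script.  An HTML
rendering was deliberately not added: the CSV/JSON bundle is the auditable
artifact.

## Problem sizes used by the test suite

Oracle comparisons use records of 10 samples per fastest relaxation time
up to 10× the slowest (1 Hz sampling, 10⁴–4×10⁴ samples); the recovery
study uses 100 seeded transients of 10⁴ samples; isotherm checks use ten
400-point-per-branch cycles; kinetics uses 2001 samples against a 2×10⁶-
point dense oracle.  These sizes resolve every feature the methods claim
to detect while keeping the full suite fast enough to run habitually.
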