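# Methods

This note documents the models implemented in `poreblock`, the numerical
choices behind the fitters, what the synthetic-data generators do and do not
emulate, and the design decisions taken where more than one reasonable
construction existed.

## Physical constants and units

All voltage-dependent expressions use the thermal voltage RT/F, 25.693 mV at
the default temperature of 298.15 K (the temperature is configurable; room
temperature is the conventional assumption for oocyte recordings when none
is specified). Unit conventions are fixed package-wide: voltages in mV with
depolarization positive, toxin concentrations in µM inside rate equations,
dissociation constants reported in nM (K_D [nM] = 1000·k_off/k_on with k_on
in µM⁻¹s⁻¹), external K⁺ in mM, energies in kJ/mol with kT conversion via
RT (2.479 kJ/mol at 298.15 K). An effective valence z is positive when the
rate or equilibrium constant grows with depolarization; "k_off grows e-fold
per ~50 mV" therefore corresponds to z ≈ +0.5.

## Relaxation kinetics

**Two-state binding.** For a 1:1 blocker at concentration [Tx], occupancy
relaxes with rate k_on[Tx] + k_off toward equilibrium block
k_on[Tx]/(k_on[Tx] + k_off). Wash experiments observe both phases:
τ_off = 1/k_off and τ_on = 1/(k_on[Tx] + k_off). The inversion
(`rates_from_on_off`) is exact algebra; it requires 1/τ_on > 1/τ_off, else
the implied association rate would be non-positive.

**Trace ratios.** On a voltage step, channels open within milliseconds while
toxin binding re-equilibrates over tens to hundreds of milliseconds, so the
+toxin/control current ratio isolates the binding relaxation:
U(t) = U_∞ + (U_0 − U_∞)e^(−t/τ) with U_0 the resting unblocked fraction
and (τ, U_∞) the open-channel two-state solution. `rates_from_relaxation`
inverts (τ, U_∞) per voltage in closed form: k_off = U_∞/τ,
k_on = (1 − U_∞)/(τ[Tx]).

Numerical choices for the exponential fitter (`fit_monoexponential`):

* deterministic starts — baseline from the last-decile mean, amplitude from
  a robust (median-of-first-five) early estimate, τ from the (1 − 1/e)
  crossing time;
* trust-region least squares with τ bounded in [dt, 100×span], relative
  tolerances 1e−10 or better, ≤2000 evaluations;
* standard errors from the Gauss–Newton covariance at the optimum;
* a *no-relaxation* flag instead of a crash when the fitted amplitude is
  indistinguishable from zero. The noise scale is 1.4826×MAD of the
  residuals about a constant fit; the comparison uses the *observable*
  amplitude |A|·(1 − e^(−span/τ)), because when τ runs far beyond the
  window the raw amplitude degenerates into an arbitrary split between a
  drift term and the baseline.

**Ratio-window and weighting.** The start of the analyzable ratio window is
not an observable; the package masks samples until the control current
first reaches a guard fraction (default 0.10) of its steady-state
magnitude, which excludes the capacitive/early-activation segment where the
quotient is ill-defined. Within the window the ratio noise still scales as
the inverse of the control current, so `relaxation_from_pair` weights the
residuals by |control|/steady-state — inverse-standard-deviation weighting
for additive trace noise. For noiseless input the weights are immaterial
and the fit reproduces the generating parameters to machine precision.

**Multi-cell aggregation.** Replicate cells can be combined two ways, both
exposed: `average_then_solve` (mean ± SEM of τ and U_∞ per voltage, then
one closed-form solve at the means — the default) and `solve_then_average`.
`average_trace_pairs` additionally supports the common practice of
averaging replicate sweeps pointwise before ratioing, which reduces trace
noise by √n and avoids selection effects when relaxation amplitudes sit
near the no-relaxation threshold; the demonstration pipeline and the
recovery tests use this route for the 30–60 mV trace families, where the
10-K⁺ parameter set (K_DC ≈ K_DO(0)) makes single-sweep amplitudes as small
as 0.03–0.08.

**Voltage dependence.** k(V) = k(0)e^(zδFV/RT) is fitted by linear
regression in log-rate space; with exactly two voltages the fit is the
exact two-point solution and standard errors are undefined.

## Ion titration

Both the dissociation-enhancement site (half-saturation K_K1, toxin-bound
channel) and the association-antagonism site (K_K2, toxin-free channel) use
one canonical Langmuir form,
value([K⁺]) = at_sat + (at_zero − at_sat)·K_half/(K_half + [K⁺]),
algebraically identical to at_zero + (at_sat − at_zero)·[K⁺]/(K_half+[K⁺]).
Fits are unweighted by default (an optional 1/value² relative weighting is
available, matched to multiplicative noise); starts are the values at the
smallest and largest concentrations and the geometric mean of the span.
A design that stops short of saturation leaves K_half poorly constrained —
a real property of 0–100 mM titrations of a ~135 mM site — so the fit
attaches a `poorly_identified` flag when se(K_half)/K_half > 1 rather than
failing. The default synthetic concentration grid spans 0–100 mM with
log-spaced interior points; Na⁺ substitution to hold ionic strength is
bookkeeping only and is not modeled mechanistically.

K_K2/K_K1 (`s1_availability`) is reported as a *lower bound* on the
fractional time the S1 site is externally available in the blocked channel:
both toxin association and the local re-binding of the pore-plugging side
chain compete with external K⁺ for S1, so the apparent K⁺ affinity of the
blocked channel is diluted by at most the fraction of time the site is
exposed.

## State model

The four-state cycle has equilibrium constants K_DC (closed-state binding),
K_DO(V) = K_DO(0)e^(zFV/RT) (open-state binding), K_V1 = Po/(1 − Po)
(gating of free channels, single Boltzmann with valence Z and midpoint Vo),
and K_V2 fixed by microscopic reversibility, K_V2 = K_V1·K_DC/K_DO. The
toxin-free fraction U/Umax = 1/(1 + [Tx]/K_DO·Po + [Tx]/K_DC·(1 − Po)) is
voltage independent in the resting limit and follows K_DO(V) in the open
limit; in between it is biphasic, dipping as channels begin to open and
recovering as depolarization weakens open-state binding. The K_V1 form and
the Po form are kept as separate functions and property-tested for
equality.

`fit_tonic_inhibition` fits resting-regime points (V ≤ −60 mV) and open
asymptotes (V ≥ −30 mV) jointly, unweighted, with Levenberg–Marquardt
(lmfit); the regime label is bookkeeping, not a model switch. Bounds:
dissociation constants in [1e−3, 1e3] nM, valences in [0, 8], Vo in
[−150, +50] mV. Starts are data driven for the two affinities (resting
plateau → K_DC; most positive point → K_DO) with a deterministic 3×3
multi-start over (Z, Vo) to avoid a known ridge: at a few percent noise the
likelihood occasionally prefers a shallow-gating solution (small Z, K_DC at
its bound) in individual synthetic datasets. Median recovery across seeds
is unbiased; single-dataset fits should be inspected via the reported
standard errors and, where gating is known, run with (Z, Vo) fixed through
the `fixed` argument. Slow inactivation (a ~10% amplitude scale at
depolarized holding) is ignored by the model — block and slow inactivation
are treated as mutually insensitive — and the generator's
`inactivation_scale` exists to confirm the ratio analysis cancels it.

`gating_shift` reports the cycle-closure prediction
ΔV = (RT/ZF)·ln(K_DO/K_DC) for the midpoint displacement of toxin-bound
gating (about +2.4 mV for K_DO/K_DC = 3.9/2.81 at Z = 3.5). The package
reports both the tonic-fit Vo and the G–V midpoint without adjudicating
the large observed offset between them.

## Unbinding energetics

Eyring inversion ΔG‡ = RT·ln(A₀/k_off) uses A₀ = 6×10¹² s⁻¹ (the
transition-state frequency factor at transmission coefficient 1,
overridable). Equal partition over n contacts gives per-contact energies
ΔG‡/(n·RT) in kT and unbound fractions e^(−energy); for n = 1 this
composes with the Eyring forward map to the identity k_off/A₀.

The wobbling model treats the bound complex as n independent two-state
contact equilibria K_j = k_joff/k_jon plus a final escape taken at
frequency A while *all* contacts are simultaneously unbound (the sole exit
condition). Independence and energy additivity make the macroscopic rate a
product, k_off = A·∏K_j·e^(ΣzⱼFV/RT), in the small-K limit; the exact
equilibrium all-unbound probability is ∏K_j/(1+K_j). Voltage acts on
designated contacts through the re-binding rate
(k_jon·e^(−zⱼFV/RT), voltage-independent local off rate) — re-binding of an
already-bound toxin's side chain is not diffusion limited, so a
voltage-dependent association there is unobjectionable; an alternate mode
applies the factor to the local off rate for sensitivity analysis, leaving
all equilibrium quantities unchanged.

The simulator is a Gillespie walk on the 2ⁿ contact configurations with an
absorbing exit, chunked-RNG for speed, seed mandatory and bit-reproducible.
Its exact counterpart (`mean_first_passage_lifetime`) solves (−Q)τ = 1 on
the dense generator, feasible to n ≈ 12. Two scale choices matter:

* **Scaled-down escape frequency.** Desk-scale event counts cannot touch
  A₀ = 6×10¹² s⁻¹ lifetimes (10¹³–10¹⁵ attempts per dissociation); the
  simulated networks use escape frequencies around 10³–10⁴ s⁻¹ with
  correspondingly reduced per-contact energies. The relations under test —
  product formula, mean-first-passage agreement, occupancy fractions — are
  scale invariant, so this preserves what the tests demonstrate.
* **Separation of timescales.** The analytic product description holds only
  when local contact exchange is much faster than dissociation. The
  simulator enforces min(local rates) ≥ 10× the predicted composite rate
  (overridable); at 10× the product formula is accurate to roughly the sum
  of the (1+K) corrections and the escape/re-binding competition, and the
  default test network (two contacts, K = 0.05, local off 2×10³ s⁻¹, escape
  10³ s⁻¹, separation ≈ 900×) agrees with the product formula to ~10% and
  with the exact oracle to sampling error. Requiring a much larger fixed
  factor (e.g. 10³×) would exclude networks for which the formula is
  already accurate to a few percent.

The per-contact exposure fraction K/(1+K) of a selectivity-filter contact
with an ordinary share of the binding energy (a few kT, i.e. a few percent
unbound) sits well above the titration lower bound K_K2/K_K1 ≈ 0.004,
a consistency check asserted as an inequality, not an equality.

## Synthetic data

The generators produce exactly what the fitters assume, plus controlled
noise:

* time courses integrate the two-state ODE piecewise-analytically over a
  perfusion schedule (optional first-order solution-exchange lag by
  numerical integration), sampled every 3 s; additive Gaussian noise,
  default sd 0.01;
* trace families multiply a delayed activation (1 − e^(−t/τ_act))⁴ (power
  configurable; the ratio analysis is tested to be insensitive to it) by
  the binding relaxation U(t), with the start U_0 taken from the state
  model at the holding voltage and (τ, U_∞) from the open-channel solution
  at K_DO(V); the association rate is voltage independent and the entire
  voltage dependence of k_off carries the toxin valence;
* titration tables apply multiplicative log-normal noise (default relative
  sd 0.10), keeping rates positive;
* tonic tables evaluate the state model at holding voltages (resting
  regime) and step voltages (open asymptotes) with additive noise clipped
  to [0, 1].

Every generator is bit-reproducible under a fixed seed, and a zero-noise
generator composed with its fitter is the identity on parameters — the
round-trip tests. What the generators do **not** emulate: leak and
capacitive transients, series-resistance error, endplate drift, slow
inactivation kinetics (only a static amplitude scale), stochastic
single-channel gating, or any mechanistic competition between Na⁺ and K⁺.
Passing recovery tests therefore demonstrates estimator correctness and
noise robustness under the stated noise model, not robustness to every
artifact of real recordings.

Recovery-test problem sizes: trace families at 30–60 mV, 0.5 ms sampling
over 250 ms, five replicate sweeps averaged per voltage, 20 seeds;
titrations with three replicates per concentration on the default grid,
20 seeds; tonic curves on a 7+10-voltage grid, 20 seeds; contact-network
comparisons at 300–1000 events. These sizes put the Monte Carlo error of
each median comfortably below the tolerance it is compared against while
the whole suite runs in seconds.

## Known limitations

* The ratio-fit guard fraction is a construction of this package; the
  underlying window choice is not identifiable from published figures.
* The tonic fit's five parameters are close to ridge-degenerate when noise
  exceeds a few percent on sparse voltage grids (see above); medians are
  reliable, single fits need their standard errors.
* Per-contact local rates in the wobbling simulator are free parameters:
  without a per-contact frequency factor only their ratios (the K_j) are
  constrained by data, so simulated absolute lifetimes are meaningful only
  relative to the chosen escape frequency.
* Heterogeneous contact energies are supported by the simulator but have no
  reference values to test against; the identical-contact decomposition is
  a stated simplification.
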