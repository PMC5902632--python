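# Methods

## The physical model

A spin in duplex DNA is assumed to exchange between two chemical states: a
Watson-Crick ground state (GS, population `p_a = 1 - p_b`) and a sparsely
populated excited state (ES, population `p_b`), e.g. a transient Hoogsteen
base pair. The exchange is first order with forward rate `k1 = p_b * k_ex`
and backward rate `k_-1 = k_ex - k1`, and the two states differ in chemical
shift by `delta_omega` (ppm, ES minus GS, downfield positive). Under a
radiofrequency spinlock of amplitude `omega_SL` (Hz, stored as omega/2pi)
applied at offset `Omega` (Hz) from the GS resonance, the six-component
magnetization vector `[Gx, Gy, Gz, Ex, Ey, Ez]` evolves under the two-state
Bloch-McConnell generator: precession about z at the state-specific offset
(ES offset = GS offset + delta_omega), rotation about x at `2*pi*omega_SL`,
relaxation (R2 on transverse, R1 on longitudinal components), and exchange
coupling. Assumptions baked into the generator:

* **R1 and R2 are shared between states.** ES-specific rates are not
  identifiable at populations below ~10% and nothing in the data model
  distinguishes them.
* **No equilibrium-recovery term.** Magnetization decays toward zero; over
  heteronuclear spinlock delays of at most ~120 ms the recovered equilibrium
  polarization is negligible on the observable scale.
* **Two states only.** No minor third state, no TROSY/multiple-quantum or
  cross-correlation effects, no B1 inhomogeneity averaging.

Chemical-shift sign convention: `delta_omega` in ppm maps to positive rad/s
through the nucleus Larmor frequency (`|gamma_X/gamma_H|` times the 1H
spectrometer frequency; gyromagnetic-ratio magnitudes 0.2514495 for 13C and
0.1013664 for 15N). The physical sign of gamma(15N) is ignored — only
relative offsets enter the generator. With this convention the exchange
contribution of a slow-exchange ES peaks near `Omega = -delta_omega`, which
is what signs the shift difference from dispersion asymmetry.

## Forward simulation and R1rho extraction

The initial state is unit magnetization split `p_a : p_b`, with both state
vectors aligned along the effective field of either the ground state
(tilt from the GS offset) or the average state (tilt from the
population-averaged offset `Omega + p_b * delta_omega`); the observable at
each delay is the projection of the propagated state, summed over both
states, back onto that axis. Propagation is exact (eigendecomposition of the
6x6 generator), batched over conditions.

R1rho is extracted two ways:

* `expfit` (default): an equal-weight two-parameter monoexponential fit
  `I0 * exp(-R * t)` over the condition's delay list, mirroring how
  experimental intensities are reduced. Fits with relative rms residual
  above 1e-3 are flagged as non-monoexponential; above 5e-2 the fit counts
  as broken and the eigenvalue rate is substituted. The two thresholds are
  deliberately distinct: substituting at the flag level would silently mix
  extraction methods between simulated tables and refitted decays and break
  the exact inverse consistency of the synthetic chain.
* `eigen`: the negated real part of the generator eigenvalue whose mode
  dominates the projection of the initial state onto the detection axis.
  The *globally* slowest eigenvalue is the wrong choice: for R1 < R2 the
  off-axis oscillating modes decay at ~(R1+R2)/2, slower than the locked
  mode, but carry essentially zero observable amplitude.

The two methods agree within 1% across the tested exchange regimes; the
monoexponential route is the default because it is what the experiment
measures.

## Dispersion fitting

`fit_bm` minimizes `sum(((R1rho_obs - R1rho_sim)/sigma)^2)` over
`(p_b, k_ex, delta_omega, R1, R2)` with a bounded trust-region least-squares
solver (`scipy.optimize.least_squares`, method `trf`, tolerances 1e-12).
`p_b` and `k_ex` are fitted in log10 for conditioning. Default bounds:
`p_b` in [1e-5, 0.5], `k_ex` in [10, 1e5] 1/s, `|delta_omega|` <= 15 ppm,
`R1` in [0.01, 10] 1/s, `R2` in [0.5, 150] 1/s.

The multi-start grid is deterministic, not random: 8 starts spanning
slow/fast exchange (`p_b` in {0.003, 0.05} x `k_ex` in {500, 8000} 1/s) and
both signs of a `delta_omega` magnitude guessed from the offset of maximal
R1rho. Determinism means the fit is reproducible without a seed; seeds only
govern Monte-Carlo noise. Parameters that land on a bound are reported with
a warning. One R1/R2 pair is fitted per spin x temperature (an option fits
per-spinlock-power pairs, but those are unidentifiable for
on-resonance-only power groups on the default grid and the synthetic truth
carries a single pair). Profiles lacking per-point errors are fitted
unweighted; information criteria then use the Gaussian RSS form with a small
floor so that noiseless data still rank models by parsimony.

Parameter uncertainties use the Monte-Carlo child-data method: 1000 child
data sets are drawn from the parent fit's simulated profile, noise-corrupted
per the parent's per-point R1rho errors, and refit starting from the parent
solution; the one-s.d. uncertainty of each parameter is its standard
deviation about the parent value. Jacobian-based (linearized) errors are
also reported; they agree with the Monte-Carlo values in well-conditioned
fits and serve as the cheap tie-break in model selection.

Model selection compares {no-exchange, two-state} x {ground, average
alignment} by BIC (AIC reported alongside). Candidates within delta-BIC < 2
are both reported; ties are broken by an external van't Hoff consistency
check when multi-temperature data exist (the route relevant for
slow-exchange spins, where the two alignment protocols can genuinely
disagree), else by the smaller relative parameter uncertainty.

## Thermodynamics

`vant_hoff` fits `ln(p_b/(1-p_b))` against 1/T (weighted by
`sd_p / (p(1-p))` when population errors exist): slope = -dH/R, intercept =
dS/R, with R = 1.98720425 cal/mol/K and temperatures converted from Celsius
in exactly one place. `eyring_barrier` fits `ln(k/T)` against 1/T:
dH_barrier = -R * slope; the transmission coefficient is fixed at 1, which
shifts only the reported dS_barrier (flagged in the output note). For any
series generated from a single free-energy surface the thermodynamic cycle
dH = dH_forward - dH_backward closes exactly, and this identity is used both
as a correctness test and as the adjudication principle between alignment
protocols.

## Synthetic studies

The generator stands in for the unavailable raw data and encodes the study
conditions: a 700 MHz (16.4 T) field; delays of 6 points in 0-60 ms for
carbon probes (C8/C1') and 0-120 ms for nitrogen (N1/N3); a default grid of
8 on-resonance powers log-spaced over 150-3500 Hz plus off-resonance series
at 150/400/1000 Hz with 12 offsets spanning +/-3.5x the power — 44
conditions, matching the "more than 40 data points" scale of a single
dispersion measurement. Gaussian noise is applied at the intensity level
(fractional s.d. 1% by default — the physical noise source, propagated
through the exponential fits into R1rho errors); an R1rho-level shortcut
exists for tests that refit thousands of replicates. The bundled scenarios
carry the printed populations and exchange rates of the free and bound
duplexes (echinomycin at 10 and 25 C; actinomycin D populations with
representative rates flagged `nominal` because the main text prints no rate
for those spins), with site relaxation rates R1 = 2.5, R2 = 25 1/s (carbon)
and 1.5/15 1/s (nitrogen) chosen as typical for DNA aromatic carbons and
imino nitrogens at this field and likewise flagged nominal. The exact
published spinlock/offset lists live in supplementary material not
reproduced here; the default grid is a declared emulation of their
structure, not a transcription.

What the generator does *not* emulate: spectral artifacts (overlap, phase,
baseline), B1 inhomogeneity, temperature-dependent R1/R2, pH-dependent
protonation equilibria, or correlated noise. Passing the recovery tests
therefore shows the fitting chain is correct and well-conditioned under the
stated noise model, not that real spectra of arbitrary quality would yield
the same precision.

The detection-limit scan bisects (geometrically) the smallest `p_b` at which
BIC model selection picks the two-state model in >= 80% of noisy replicates;
with favorable parameters and small noise the limit reaches the 1e-4
(0.01%) population scale quoted for this experiment class.

## Toy biased dynamics

The ratchet module is an explicit toy. The "structure" is a smooth map from
the glycosidic flipping angle chi and base-opening angle theta (degrees) to
six pseudo-atom ordered-pair distances; the unbiased surface is a harmonic
opening restraint minus Gaussian wells at the Watson-Crick (-110, 8) and
Hoogsteen (70, 22) states, 7 and 4 kcal/mol deep. The collective distance
`rho = 1/(N(N-1)) * sum_{i, j != i} (r_ij - r_ij^R)^2` (the inner sum is
implemented as j != i; the printed "j != 1" is read as a typo) vanishes at
the Hoogsteen reference. The half-harmonic bias `W = alpha/2 (rho - rho_a)^2`
ships in two conventions: `toward_reference` (default; rho_a = running
minimum, penalty when rho rises above it — the standard ratchet-and-pawl)
and `as_printed` (rho_a = running maximum, penalty when rho falls below it,
the literal published inequality, which drives the system *away* from the
reference). Dynamics are overdamped Langevin at 300 K with dt = 0.05 (step
checked against the landscape stiffness), friction 1, and per-seed noise
streams so that runs at different alpha are paired. On this toy the rho
gradient is ~0.06 A^2/deg, so alpha of order 50-200 kcal/mol/A^4 is needed
to overcome the 7 kcal/mol well; transition fractions over a 30-seed
ensemble rise monotonically from 0 (alpha = 0) to 1 (alpha = 200). Reported
interaction energies always exclude the bias. Landscape analysis bins
(chi, theta, E) onto a fixed 50x50 grid with empty bins marked missing. No
quantitative comparison with all-atom transition counts is meaningful from
this module.

## Problem sizes and numerical choices

Unit tests use a reduced 20-condition grid where many replicates are refit
(Monte-Carlo scaling, detection scans, model-selection error rates) and the
full 44-condition grid for the round-trip and full-chain checks; the
full-chain suite runs 20 noise seeds at 1% intensity noise with the parent
Monte-Carlo uncertainty (100 children) computed once and reused across
seeds. Monte-Carlo seed-stability is checked at the full 1000 children.
Degenerate inputs: delay-0-only curves and profiles with fewer than 2
powers/5 offsets are rejected; populations exactly 0 are fitted by the
2-parameter no-exchange model; child fits failing to converge beyond 10%
abort the uncertainty estimate. All randomness flows through
`numpy.random.default_rng` seeds recorded in every output.

## Known limitations

* No 3-state or multi-spin global fits; each spin x temperature is fitted
  independently.
* The alignment tie-break without multi-temperature data uses linearized
  uncertainties, which can understate errors for strongly correlated
  parameters near the slow-exchange degeneracy.
* Eyring dS_barrier is meaningful only up to the assumed unit transmission
  coefficient.
* The toy bias landscape is two-dimensional and force-field-free; only the
  biasing equations and the binning analysis carry over to real systems.
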