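# hoogfit

Analysis of **R1ρ relaxation-dispersion NMR data for Watson-Crick ⇌ Hoogsteen
exchange in duplex DNA**, for spectroscopists and modellers who need to
quantify sparsely populated "excited-state" base-pair conformations and how
they change upon ligand binding (e.g. intercalators such as echinomycin and
actinomycin D).

A–T and G–C Watson-Crick base pairs transiently flip into Hoogsteen
geometries with populations well below 1% and millisecond lifetimes —
invisible in spectra, but measurable through the exchange contribution
R<sub>ex</sub> they add to rotating-frame relaxation. Under a spinlock of
power ω<sub>SL</sub> applied at offset Ω, magnetization of an exchanging
spin decays at

R<sub>1ρ</sub> = R<sub>1</sub> cos²θ + R<sub>2</sub> sin²θ + R<sub>ex</sub>(ω<sub>SL</sub>, Ω; p<sub>B</sub>, k<sub>ex</sub>, Δω),

where θ is the effective-field tilt and the exchange parameters are the
excited-state population p<sub>B</sub>, the exchange rate
k<sub>ex</sub> = k<sub>1</sub> + k<sub>−1</sub>, and the chemical-shift
difference Δω. This package provides:

* the **forward model** — exact propagation of the two-state
  Bloch–McConnell equations for any spinlock condition, with both
  monoexponential-fit and eigenvalue R1ρ extraction (`hoogfit.core`);
* the **fitting chain** — intensity decays → R1ρ with Monte-Carlo errors →
  bounded multi-start dispersion fits of (p<sub>B</sub>, k<sub>ex</sub>, Δω,
  R<sub>1</sub>, R<sub>2</sub>), 1000-child Monte-Carlo uncertainties, and
  AIC/BIC selection between no-exchange/two-state models and ground/average
  initial-alignment protocols (`hoogfit.fitting`);
* **thermodynamics** — van't Hoff ΔH°/ΔS° from temperature-dependent
  populations and Eyring barriers from rates, with exact cycle closure
  (`hoogfit.thermo`);
* a **synthetic-study generator** with bundled scenarios carrying the
  published exchange parameters of the free and intercalator-bound duplexes,
  used for parameter-recovery validation (`hoogfit.synthetic`);
* a **toy ratchet-dynamics module** implementing the adaptive half-harmonic
  biasing potential that drives Watson-Crick → Hoogsteen flips on a 2D
  (χ, θ) landscape, plus the 50×50 landscape-binning analysis
  (`hoogfit.bias`);
* CSV/JSON **I/O, dispersion plots and a CLI** (`hoogfit.io`, `hoogfit`
  console script with subcommands `simulate`, `fit`, `mc`, `vanthoff`,
  `biasdemo`, `report`).

See `docs/methods.md` for the model assumptions, conventions and numerical
choices.

## Worked example

Simulate one spin of the echinomycin-bound duplex at 10 °C (the A3–T10 base
pair flanking the drug's CG binding step, observed via the adenine C8 at
700 MHz) with 1% intensity noise, then refit it blind:

```sh
$ hoogfit simulate --scenario echinomycin_bound_10C --intensity-noise 0.01 \
      --seed 7 --out demo
wrote demo/decays.csv, profiles_truth.csv, truth.json

$ hoogfit fit --input demo/decays.csv --temperature 10 --mc 200 --seed 7 \
      --out demo/fit
A3C8: p_b=2.072% k_ex=745/s dw=+2.97 ppm chi2_red=0.762
wrote demo/fit.json and demo/fit.csv
```

The fitter recovers the generating truth (p<sub>B</sub> = 2.07%,
k<sub>ex</sub> = 743 s⁻¹, Δω = +3 ppm) from 44 noisy decay series: a
Hoogsteen population of ~2%, exchanging at ~745 s⁻¹, with the excited state
~3 ppm downfield of the ground state — the signature of a transient
Hoogsteen base pair that has become an order of magnitude more populated in
the drug complex than in free DNA (0.24%). `demo/fit.json` carries the full
provenance (seed, bounds, version) and `demo/fit.csv` one summary row per
spin × temperature.

The same chain in Python:

```python
from hoogfit import (scenario_truth, default_grid, r1rho_profile,
                     RDProfile, fit_bm)

truth = scenario_truth("echinomycin_bound_10C")
grid = default_grid("C13")                       # 44 spinlock conditions
rates = r1rho_profile(truth.model, grid)         # forward Bloch-McConnell
profile = RDProfile("A3C8", tuple(grid), tuple(rates))
fit = fit_bm(profile)                            # blind multi-start refit
print(f"{100 * fit.model.p_b:.2f}%  {fit.model.k_ex:.0f}/s")
# 2.07%  743/s
```

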