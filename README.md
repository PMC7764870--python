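# filmrheo

Dilatational rheology and Langmuir-isotherm analytics for interfacial films
(tear-film lipid layers, meibum, lung surfactant, and other surfactant films
at the air–water interface).

A Langmuir-trough study of a film under blink-like deformation produces
three kinds of time series, and `filmrheo` turns each into the quantities a
film-biophysics paper reports:

* **Stress–relaxation transients** — after a small rapid area step
  ΔA/A₀ ≈ 5%, the surface pressure π(t) relaxes toward a plateau.  The
  complex dilatational viscoelasticity modulus follows by one-sided Fourier
  transformation of the transient,

      E*(ν) = E_R(ν) + i·E_IM(ν)
            = [Δπ_EQ + i·2πν ∫₀^∞ (Δπ(t) − Δπ_EQ) e^(−i·2πν·t) dt] / (ΔA/A₀),

  with Δπ(t) = π(t) − π₀ and Δπ_EQ its long-time plateau.  E_R is the
  storage (elastic) modulus, E_IM the loss modulus (E_IM = 2πν·η_d with η_d
  the dilatational viscosity).  Each peak of the Cole–Cole plot (E_IM vs
  E_R) marks one relaxation process; the transient is then fitted with the
  matching number of decaying exponentials plus a plateau,

      Δπ(t) = Σᵢ Aᵢ e^(−t/τᵢ) + Δπ_EQ,

  the generalized-Maxwell form whose elements are Eᵢ = Aᵢ/(ΔA/A₀),
  ηᵢ = τᵢ·Eᵢ (so τᵢ = ηᵢ/Eᵢ), plus an equilibrium spring
  E_eq = Δπ_EQ/(ΔA/A₀).

* **Compression–expansion cycle recordings** — repeated barrier cycling
  yields π(A) isotherms.  The package splits recordings into per-cycle
  compression/expansion branches, detects when the cycles become
  stationary, averages replicates with a quality-control spread figure,
  computes the pressure shift Δπ(A) of a test condition against a control
  (the signature of surfactant incorporation into the film), and locates
  the squeeze-out pressure: the pressure above which the shift vanishes for
  the rest of the compression, meaning the incorporated surfactant is
  expelled from the film.

* **Penetration-kinetics traces** — π(t) after injecting a surfactant
  beneath a pre-formed film: maximum pressure rise, time to peak, and
  re-equilibration time.

Because raw trough recordings are rarely published, a first-class synthetic
data module generates all three input kinds from known ground truth
(recorded in a sidecar), so the whole pipeline is testable end to end.

## Worked example

```python
import filmrheo as fr

# a meibum-like film: two relaxation processes (15 s and 500 s) plus an
# equilibrium plateau, probed with a 5% area step from pi0 = 18 mN/m
t = fr.gen_relaxation([(4.0, 15.0), (3.0, 500.0)], plateau=4.0,
                      strain=0.05, pi0=18.0, sampling=(1.0, 5000.0))

spec = fr.compute_spectrum(t)            # E*(nu) on 1e-4..1 Hz
cc = fr.cole_cole(spec)                  # peak count = number of processes
fit = fr.fit_relaxation(t, "auto")       # order taken from the peak count
elems = fr.maxwell_elements(fit)
verdict = fr.classify_film(spec, (1e-4, 1e-3))
```

This prints, via the obvious loops:

```
n_peaks: 2
  peak: nu = 3.415e-04 Hz, E_R = 112.2, E_IM = 32.5 mN/m
  peak: nu = 1.000e-02 Hz, E_R = 177.6, E_IM = 41.9 mN/m
fit components: [(4.0, 15.0), (3.0, 500.0)]   plateau: 4.0
  element: E = 80.0 mN/m, eta = 1200 mN s/m, tau = 15.0 s
  element: E = 60.0 mN/m, eta = 30000 mN s/m, tau = 500.0 s
E_eq: 80.0
classification: predominantly_elastic (elastic fraction 1.0)
```

Two Cole–Cole peaks → two exponential terms; the fit recovers the
generating amplitudes and relaxation times exactly on this noiseless
trace, and the film is predominantly elastic (E_R > E_IM) across the
10⁻⁴–10⁻³ Hz band, as lipid films with a large equilibrium elasticity are.

The same operations are available from the shell:

```
filmrheo synth relaxation --seed 42 --out data/
filmrheo spectrum data/relaxation.csv --strain 0.05 --pi0 18 --out spectrum.csv
filmrheo fit data/relaxation.csv --strain 0.05 --pi0 18 --n auto --out fit.json
filmrheo compare ref.csv test.csv --threshold 0.5 --out cmp.json
filmrheo kinetics trace.csv --pi0 18 --tol 0.5 --out features.json
filmrheo report --config run.yaml
```

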