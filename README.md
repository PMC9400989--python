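# ufdexsy

Simulation and analysis of **single-scan (ultrafast) diffusion exchange
spectroscopy (DEXSY)** on single-sided, low-field NMR magnets, built around
the measurement of intra-/extracellular water exchange in a cell
suspension.

DEXSY correlates a molecule's diffusion coefficient before and after a
mixing time τ_M: molecules that switch pool (e.g. leave a cell) appear as
off-diagonal *cross peaks* of a 2D map. In the single-scan variant on a
single-sided magnet, the strong built-in constant gradient (here
G = 7.28 T m⁻¹ at B₀ = 0.3 T, f₀ ≈ 13 MHz) serves both as diffusion
weighting and as an imaging gradient: a frequency-swept (chirp) pulse in a
stimulated-echo block writes the indirect diffusion decay across a
93 kHz / 300 μm slab of sample, and a CPMG train reads the whole 2D data
set in one shot — fast enough to be combined with hyperpolarized (dDNP)
water, where the signal survives only for seconds.

This package is for NMR methodologists and biophysicists who want to
simulate such measurements, validate analysis pipelines against known
ground truth, or fit two-site exchange parameters to exchange maps. It
provides:

* **Forward model** (`encoding`, `mixing`, `readout`): per-depth
  stimulated-echo b-values b(z) = (2πγ̄)²G²δ_eff(z)²(Δ − δ_eff(z)/3) with
  δ_eff(z) = δ_max·z/L, coil sensitivity and chirp-edge weighting,
  operator-split evolution through τ_M (two-site exchange via the rate
  matrix exponential, per-pool Gaussian diffusion blurring with free
  in/outflow of unencoded magnetization), and per-echo constant-gradient
  CPMG attenuation exp(−n[(2πγ̄)²G²t_E³D/12 + t_E/T₂]).
* **Inversion** (`inversion`): with the two diffusivities fixed from
  reference measurements, the raw matrix is decomposed by nonnegative
  least squares into four simulated basis surfaces indexed by
  (start pool, end pool); the normalized weights are the 2×2 exchange map.
* **Kinetics** (`kinetics`): the maps across mixing times are fitted with
  the two-site joint-probability model
  I_jj = p_j(p_j + (1−p_j)e^{−kτ_M}), I_jk = p_j p_k(1−e^{−kτ_M}),
  yielding the exchange rate k, intracellular fraction p_intra, the
  derived rates k_intra = p_intra·k, k_extra = (1−p_intra)·k and the
  intracellular residence time τ_intra = 1/k_intra.
* **Synthetic studies** (`synthetic`): seeded scenario generation
  (reference conditions: D = 1.4/3.6×10⁻⁹ m² s⁻¹, p_intra = 0.24,
  k = 14 s⁻¹, τ_M = 10/30/100 ms, SNR = 280, fresh hyperpolarization
  amplitude per acquisition) and closed-loop parameter-recovery
  experiments with bias/RMSE/coverage reporting.

## Worked example

```python
from ufdexsy import Scenario, analyze_scenario

_, maps, fit = analyze_scenario(Scenario.reference(seed=1))
for m in maps:
    print(m.tau_M, m.weights.ravel())
print(fit.k, fit.p_intra, fit.tau_intra)
```

Running `python examples/03_kinetics_fit.py` (the same computation,
annotated) prints:

```
two-site exchange fit over tau_M = 10, 30, 100 ms:
  k        =  13.94 +- 0.18 1/s   (overall exchange rate; truth 14)
  p_intra  =  0.240 +- 0.001   (intracellular pool fraction; truth 0.24)
  k_intra  =   3.35 +- 0.04 1/s
  k_extra  =  10.60 +- 0.14 1/s
  tau_intra =   299 +- 4 ms   (intracellular residence time)
```

i.e. one simulated three-mixing-time experiment at SNR 280, inverted and
fitted, recovers the generating parameters (k = 14 s⁻¹, p_intra = 0.24)
within a few percent; the residence time of a water molecule inside a cell
comes out at ≈0.3 s. The other scripts in `examples/` show the raw-data
simulation, the exchange maps and a multi-repetition recovery study.

A thin CLI wraps the same pipeline for shell use
(`ufdexsy simulate|invert|kinetics|recover|profile`, see `--help`).

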