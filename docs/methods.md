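# Methods

This note documents the physical model, the numerical choices and the
known limitations of the `ufdexsy` pipeline.

## Model overview

The sample is two well-mixed water pools (labelled *intra* and *extra*)
with diffusion coefficients D₁, D₂, equilibrium fractions (p, 1−p) and
first-order exchange at overall rate k. The exchange kinetics are governed
by the rate matrix

    K = [[−k·p₂, k·p₁], [k·p₂, −k·p₁]],

whose column sums vanish (conservation), whose stationary vector is
(p₁, p₂) (detailed balance) and whose nonzero eigenvalue is −k. The
propagator over any interval is the closed form
P(τ) = P∞ + e^{−kτ}(I − P∞), with both columns of P∞ equal to the
stationary populations; it is tested against scaling-and-squaring `expm`
and a 10⁵-particle jump simulation.

### Spatial encoding

The stimulated-echo block with a chirp refocusing pulse makes the
effective gradient-pulse length linear in depth, δ_eff(z) = δ_max·z/L over
the encoded extent L = Δf/(γ̄G) (93 kHz ↔ 300 μm at 7.28 T m⁻¹). The
per-depth diffusion weighting is the Stejskal–Tanner stimulated-echo form

    b(z) = (2πγ̄)² G² δ_eff(z)² (Δ − δ_eff(z)/3),

so the longitudinal profile stored at the start of the mixing time is
M_j(z) = H·p_j·e^{−b(z)D_j}·C(z)·e(z): H is the (hyperpolarized)
amplitude, C the coil excitation sensitivity, and e(z) two Gaussian dips
of depth a and width σ_edge at the region edges where the swept pulse acts
non-ideally. The b-value model is validated against a Brownian
phase-accumulation simulation of the actual two-window timing.

Orientation convention: z = 0 is the *unencoded* end of the region
(δ_eff = 0) and depth increases toward full weighting at z = L; the
frequency axis is γ̄Gz. Measured data whose decay runs the other way along
the frequency axis simply need the axis flipped before comparison — the
analysis is orientation-invariant because forward model and bases share
the convention.

### Mixing: exchange + spatial diffusion with open boundaries

During τ_M three things happen: pool exchange, diffusive blurring of the
encoded layers, and in/outflow of unencoded magnetization across the edges
of the (300 μm) encoded region — displacements √(2Dτ_M) reach ~27 μm at
τ_M = 100 ms, a tenth of the region. The coupled dynamics are approximated
by Lie operator splitting with `n_substeps = 32` equal substeps of
(blur, exchange); self-convergence (32 vs 64 substeps agree to <1 % at the
study's hardest case) is test-enforced. The state is resolved by
(start pool, current pool), so each component blurs with the D of the pool
it is *currently* in, and detection later applies the current pool's CPMG
decay.

Two numerical choices matter here:

* **Discrete Gaussian kernel.** Blurring uses the discrete diffusion
  semigroup kernel e^{−2θ}I_n(2θ), θ = Dτ/dz² (modified Bessel
  functions), not a sampled or cell-integrated Gaussian. This kernel has
  exactly the continuous variance 2Dτ and composes exactly — n substep
  blurs equal one blur over the total time — at any ratio of blur width
  to grid spacing. Sampled/integrated kernels gain ~dz²/12 of spurious
  variance per application, which after 32 substeps visibly distorts the
  profile and biases the inversion. Kernels are truncated at 5σ (plus a
  guard) and renormalized; truncation residuals are ~10⁻⁸.
* **Explicit reservoir.** The profile is evolved on a grid extended by a
  5σ guard band initialized to the unencoded reservoir value H·p_j.
  In/outflow across the encoded-region edges is then genuine free
  diffusion. (Re-padding the boundary every substep instead acts like a
  Dirichlet clamp and overfeeds the edges.)

T1 is infinite by default (the per-experiment normalization removes
overall longitudinal decay); a finite-T1 option exists, with a flag
controlling whether the inflowing reservoir decays too.

### Readout

The CPMG train under the constant gradient attenuates echo n by
exp(−n[(2πγ̄)²G²t_E³D/12 + t_E/T₂]); with G = 7.28 T m⁻¹ diffusion
dominates T₂ for free water. The acquisition Fourier transform is not
simulated — the model works directly in the depth/frequency domain, where
each echo is a 1D image weighted by the coil detection profile. Additive
Gaussian noise at σ = max|S|/SNR models the measurement noise of the
real-valued post-FT data.

## Inversion and kinetics

With D₁, D₂ fixed (as in the reference analysis, where they came from
independent CPMG diffusion measurements), the raw matrix is linear in the
four (start, end) pool weights. The basis surface for pair (j, k) is:
encode with D_j → blur over τ_M → detect with D_k. Diagonal bases blur
with their own D_j; **cross bases blur with (D_j+D_k)/2**, since a
molecule observed in different pools at encoding and detection spends, in
expectation, roughly half the mixing time in each (kτ_M ≲ 1 here).
Start-site-only blurring was measured to leave a systematic −0.9 s⁻¹ bias
on the recovered k in closed-loop tests; the mean-D choice reduces it to
−0.2 s⁻¹. Weights are solved by nonnegative least squares (convex,
deterministic, seed-free) and normalized to unit sum, which also removes
the hyperpolarization amplitude. Cross-term symmetry is *not* imposed at
this stage; it emerges from the data and is a property of the kinetics
model.

The two-site kinetics model for the normalized intensities,

    I_jj(τ) = p_j (p_j + (1−p_j) e^{−kτ}),   I_jk(τ) = p_j p_k (1 − e^{−kτ}),

sums to one identically and equals p_j·[e^{Kτ}]_{kj} entrywise (tested to
1e-12). It is fitted to all intensities over all mixing times with equal
weights (each experiment is separately normalized, so no experiment is
more trustworthy than another), bounds k ∈ [0, 10³] s⁻¹ and
p ∈ (0, 1), via Levenberg–Marquardt (lmfit); uncertainties come from the
Jacobian-based covariance and propagate to the derived quantities by the
first-order delta method:

    k_intra = p_intra·k,  k_extra = (1−p_intra)·k,  τ_intra = 1/k_intra.

This decomposition convention reproduces the standard reported triplet
(with k = 14 s⁻¹ and p_intra = 0.24: k_intra ≈ 3.4 s⁻¹,
k_extra ≈ 11 s⁻¹, τ_intra ≈ 0.3 s). Note a naming tension inherent in
that convention: k_intra = p_intra·k equals the rate constant *into* the
intracellular pool (the off-diagonal element K₁₂ feeding site 1), while
its reciprocal is conventionally read as the intracellular residence
time. The package follows the reported arithmetic and keeps the
convention explicit rather than resolving the nomenclature.

## Default parameters

| parameter | default | why |
|---|---|---|
| B₀, G | 0.3 T, 7.28 T m⁻¹ | the single-sided instrument modelled |
| γ̄ | 42.577478461 MHz T⁻¹ | CODATA proton value |
| Δf (chirp) | 93 kHz | gives the 300 μm encoded extent |
| δ_max, Δ | 160 μs, 5 ms | bottom-layer attenuation e^{−b(L)D_extra} ≈ 0.18: the encoded decay spans most of the dynamic range |
| t_E, n_echoes | 150 μs, 256 | 38 ms train (within the tens-of-ms total budget of a hyperpolarized scan) with end-of-train diffusion attenuation 0.68/0.37 for the two pools — visible contrast in the direct dimension |
| points/echo, dwell | 128, 1 μs | 1 MHz bandwidth covers the 93 kHz region; 128 depth points resolve the 15 μm edge Gaussians with ≥6 points |
| edge a, σ_edge | 1.0, 0.05·L | full edge dips of plausible width; both configurable |
| coil profile | synthetic bell (0.3 + 0.7·Gaussian) | stand-in for a measured coil image; replace via `coil.file` |
| grid | 128 points over L | see above |
| n_substeps | 32 | <1 % splitting error at τ_M = 100 ms (test-enforced) |
| scenario | D = 1.4/3.6×10⁻⁹ m² s⁻¹, p = 0.24, k = 14 s⁻¹, τ_M = 10/30/100 ms, SNR 280 | the reference study conditions |
| amplitude variability | log-uniform ×[0.5, 2] | fresh hyperpolarized sample per acquisition; amplitude-only, removed by normalization |

## What the generator does and does not emulate

The synthetic data reproduce: the encoded two-component diffusion decay,
coil and chirp-edge weighting, mixing-time-dependent exchange and spatial
blurring with reservoir in/outflow, per-pool CPMG diffusion decay,
acquisition-to-acquisition amplitude variation, and additive Gaussian
noise at SNR ≈ 280. They do **not** emulate: restricted/compartmental
diffusion geometry (free Gaussian propagators only), B₁-dependent flip
angle errors beyond the amplitude profile, chirp waveform ripple,
receiver/ringdown effects, Rician noise, exchange during the CPMG train
itself, or T1 decay between dissolution and scan (available only as a
fixed amplitude factor). Passing closed-loop tests therefore demonstrates
the *analysis* is unbiased and well-calibrated for data generated by this
physics — not that the physics captures every artefact of a real
single-sided hyperpolarized measurement. In particular the forward model
and the inversion bases share the coil/edge parameters; on real data those
would have to be calibrated (coil from a water-image, edges from a
non-exchanging reference).

## Degenerate inputs and edge cases

* D_intra = D_extra makes the four bases rank-deficient: a warning at
  basis construction, a conditioning error in the fit if the Gram
  condition exceeds 10¹².
* Maps all at the fully-mixed limit leave k unidentifiable; the fit
  flags this (`identifiable=False`) instead of failing.
* k = 0 is a valid sample (no exchange); τ_intra is then undefined and
  `derive_rates` refuses it.
* SNR = ∞, τ_M = 0, and zero-depth edges are exact identity paths, used
  heavily by the tests.

## Problem sizes

Defaults are desk-scale by design: a 128×256 matrix per acquisition,
three acquisitions per experiment, 50 repetitions for recovery studies
(~3 s total); the stochastic oracles use 10⁵ walkers/particles. All sizes
are parameters, so heavier configurations are a constructor argument away.
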