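# Methods

## Model

`ratenet` implements excitatory–inhibitory rate networks in which each of
the N units carries an input current x_i and one hidden slow variable.
The firing rate is φ(x) = min(max(x − γ, 0), φ_max), a saturating
threshold-linear transfer function; linearizations are only applied at
fixed points strictly inside one of its three branches, and the derivative
at the two kinks is defined as 0.

Two single-unit mechanisms are contrasted:

* **Adaptation** — a hidden variable w low-pass filters the linearized
  rate (x − γ) with time constant τ_w and feeds back into the current with
  negative coupling g_w:

      τ_m dx_i/dt = −x_i + Σ_j J_ij φ(x_j) − g_w w_i + I_i + η_i
      τ_w dw_i/dt = −w_i + x_i − γ

  The linearized adaptation drive (x − γ rather than φ(x)) is the model
  analyzed throughout; the fully nonlinear variant is available in the
  simulator behind an off-by-default flag and is excluded from every
  calibrated analysis.

* **Synaptic filtering** — the summed synaptic input is low-pass filtered
  with time constant τ_s before driving the current:

      τ_m dx_i/dt = −x_i + s_i
      τ_s ds_i/dt = −s_i + Σ_j J_ij φ(x_j) + I_i + η_i

External input and intrinsic noise enter where synaptic input enters the
model: the current equation for adaptation, the s-equation for synaptic
filtering (so for filtering the noise is itself filtered). The intrinsic
white noise convention is ⟨η_i(t) η_j(t′)⟩ = δ_ij (σ_η²/2) δ(t − t′).

Connectivity is sparse, random and constant in-degree: every unit receives
exactly C_E excitatory inputs of weight +J and C_I inhibitory inputs of
weight −gJ, drawn uniformly without replacement per row (self-connections
excluded by default; an `allow_self` switch exposes the alternative, which
the ensemble definition leaves open). Each presynaptic unit is purely
excitatory or inhibitory (Dale's principle); the excitatory pool size is
N_E = round(N·C_E/C) so expected out-degree is uniform. Two ensemble
summaries control everything: the common row sum J_eff = J(C_E − g C_I)
(the outlier eigenvalue, order parameter of the population-averaged mode)
and the bulk spectral radius J_cs = J√(C_E + g² C_I) (order parameter of
the heterogeneous modes).

Default constants: N = 3000, C_E = 80, C_I = 20, g = 4.1, γ = −0.5,
φ_max = 2; time is measured in units of τ_m = 1 throughout, though τ_m is
an explicit parameter everywhere.

## Single-unit filters

An isolated unit is a 2-variable linear system; its impulse response is a
sum of exponential modes h(t) = Σ_k a_k t^{p_k} e^{λ_k t} obtained from
the closed-form eigendecomposition of the 2×2 dynamic matrix. The
degenerate equal-rate case (τ_s = τ_m, or the adaptive discriminant
exactly zero) is represented exactly with an explicit polynomial-in-t
mode rather than by perturbing rates. The package reports

* the amplitude-weighted timescale τ_corr = Σ|a_k| τ_k / Σ|a_k| with
  τ_k = −1/Re λ_k (members of a conjugate pair share one decay time), and
* the white-noise variance gain ∫h² dt, in closed form from the modes.

"Unit-variance white noise" is normalized as unit spectral density,
⟨I(t)I(t′)⟩ = δ(t − t′): this is the only normalization under which the
output variance is finite and parameter-dependent in the way the theory
describes, and the absolute scale of the gain follows from it.

## Fixed points and population-averaged stability

Fixed points are scanned over all three transfer branches (silent, linear,
saturated) and every self-consistent solution is returned; the
linear-branch one is primary. Closed forms: synaptic
x₀ = −J_eff γ/(1 − J_eff); adaptive x₀ = γ(g_w − J_eff)/(1 + g_w − J_eff);
saturated adaptive x₀ = (J_eff φ_max + g_w γ)/(1 + g_w), valid when
x₀ > γ + φ_max.

Homogeneous perturbations reduce to a single 2×2 system whose only
coupling parameter is φ′·J_eff. Classification uses the trace/determinant
rules: synaptic networks are stable iff J_eff < 1 (saddle-node at 1,
independent of τ_s); adaptive networks are stable iff
J_eff < min(1 + g_w, 1 + τ_m/τ_w), the Hopf branch (trace crossing) being
the active boundary exactly when τ_m/τ_w < g_w. Boundary equalities
within 1e−9 are reported as `marginal`. The default classification
assumes the equilibrium is in the linear branch (φ′ = 1), which is where
the phase-diagram boundaries live; passing `phi_prime=None` derives the
slope from the actual fixed point instead.

Slow-hidden-variable closed forms (τ_s or τ_w ≫ τ_m) for the two response
timescales and the filter are taken from the leading-order expansion of
the exact eigenvalues: synaptic τ⁺ = τ_s/(1 − J_eff),
τ⁻ = τ_m/(1 + J_eff τ_m/τ_s); adaptive τ⁺ = τ_m/(1 − J_eff),
τ⁻ = τ_w(1 − J_eff)/(1 + g_w − J_eff), with the adaptive slow-mode area
tending to −g_w/((J_eff − 1)(J_eff − 1 − g_w)). Tests assert that these
converge to the exact eigensystem at rate O(τ_m/τ_slow).

## Heterogeneous stability

Each connectivity eigenvalue λ_J maps onto two Jacobian eigenvalues
through a quadratic; the stability line λ = iω maps back to a boundary
curve in the λ_J plane,

* synaptic: λ_J^sb(ω) = (1 + iτ_mω)(1 + iτ_sω),
* adaptive: λ_J^sb(ω) = 1 + iτ_mω + g_w/(1 + iτ_wω).

The adaptive curve is evaluated from the exact forward mapping rather
than an expanded closed form; it reproduces both real-axis crossings
(1 + g_w at ω = 0, and 1 + τ_m/τ_w at ω = √(g_w τ_w/τ_m − 1)/τ_w when
τ_w g_w > τ_m). The critical radius is R* = min_ω |λ_J^sb(ω)|, located on
a logarithmic grid over [1e−4/τ_slow, 1e2/τ_m] (1e5 points) refined by
bounded scalar minimization to 1e−8. The bifurcation is zero-frequency
iff τ_m/τ_w > g_w + √(2 g_w(g_w + 1)) (curvature criterion; this also
implies only Hopf is possible for g_w > √5 − 2 ≈ 0.236); in that case the
minimum sits exactly at ω = 0 and is reported as such. Synaptic filtering
gives R* = 1 at ω* = 0 for every τ_s; adaptation gives R* ≥ 1.

`full_jacobian_spectrum` assembles the dense 2N×2N Jacobian (guard
N ≤ 1500) and verifies that every eigenvalue maps through the forward
mapping onto the connectivity spectrum (≤ 1e−6 in practice, limited only
by the dense eigensolver).

## Direct simulation

Explicit Euler–Maruyama with default dt = 0.05 τ_m (guard: dt ≤ 0.1 of
the fastest time constant). The hidden dynamics are linear and non-stiff
at the parameter ratios of interest, and the explicit scheme keeps the
noise convention transparent: the noisy equation receives per-step
increments of standard deviation (σ_η/τ)√(dt/2). Default initial state is
the fixed point plus i.i.d. uniform(−0.01, 0.01) current perturbations.
Large networks can record a subset of units (`record_units`) and thin
samples (`record_every`); integration always uses the full state.

Finite-size behaviour worth knowing about: at bulk radii slightly above
1, samples of this ensemble with N ≲ 1000 frequently settle into *frozen*
heterogeneous fixed points (units pinned at the transfer bounds stabilize
the realized Jacobian) instead of sustaining rate chaos; by N ≈ 3000 the
fluctuating state dominates, with a residual frozen variance component
that shrinks with N. Tests that probe the chaotic state therefore use
N = 800–8000 with long burn-ins, sizes chosen as the smallest at which
the intended regime is robust across connectivity seeds.

## Dynamical mean-field theory

The recurrent drive is replaced by a Gaussian process ξ(t) with

    [ξ] = J_eff ⟨φ⟩,
    [ξ(t)ξ(t+τ)] = J_cs² (C(τ) − ⟨φ⟩²) + (σ_η²/2) δ(τ),

where C(τ) = ⟨φ(t)φ(t+τ)⟩ is the raw rate second moment. The solver is a
damped fixed-point iteration (damping α = 0.6): simulate the two-variable
stochastic prototype unit under the current ξ statistics (trial-
vectorized Euler–Maruyama; trials = 100 and T = 200·max(τ_m, τ_slow) by
default, burn-in 20 slow time constants), re-estimate (μ, Δ, ⟨φ⟩, C),
update the moments, repeat.

Noise synthesis is done in the Fourier domain: the target autocovariance
is embedded symmetrically into a circulant covariance, its discrete
spectral density is clipped at zero (the clipped fraction is logged and
recorded; > 1% raises a warning entry), and the amplitude of each
frequency bin is the *square root* of the spectral density with i.i.d.
uniform phases, Hermitian-symmetrized. Without the square root the
synthesized process provably fails to reproduce the target (a unit test
demonstrates this on an Ornstein–Uhlenbeck target). Two further numerical
choices matter:

* **Static component.** The long-lag plateau of the target autocovariance
  (mean of the last 5% of lags) is synthesized as a per-trial frozen
  Gaussian offset rather than through the circulant embedding, which
  would otherwise force the drive to decorrelate at the lag-window edge
  and suppress the frozen across-units variability of the self-consistent
  solution.
* **Stopping rule.** The iteration stops when the sup-norm change of both
  moments stays below max(2e−3, 1.5%·peak autocovariance) for three
  consecutive iterations. The zero-frequency mode of the chaotic state
  grows slowly (gain just above 1 near onset), so looser tolerances stop
  the scheme visibly short of the fixed point; the 1.5% figure was set
  from convergence-history diagnostics at J_cs = 1.2 and leaves the
  threshold just above the Monte-Carlo estimator noise at the default
  trial counts. Non-convergence returns the full residual history rather
  than raising — near bifurcations the smooth-dependence assumption
  behind the scheme genuinely fails.

The Gaussian closures ⟨φ⟩ = ∫Dz φ(μ + √Δ(0) z) and the three-Gaussian
expression for C(τ) are implemented with adaptive quadrature split at the
transfer-function kinks (the kinked integrand defeats fixed-order
Gauss–Hermite at the 1e−8 level) plus an erf closed form; the nested
C(τ) quadrature uses the closed form inside a Gauss–Hermite sum over the
shared Gaussian component, with the printed sign convention
sgn(Δ(τ)) on the shared component of the first factor, and the
perfectly-(anti)correlated edge |Δ(τ)| = Δ(0) handled as a single
adaptive integral. These closures serve as an independent audit of the
converged state; they are never used inside the iteration itself.

With intrinsic noise the converged current autocovariance develops a kink
at zero lag; for τ_m = 1 the two-sided derivative jump is σ_η²/2, which
the tests check at 20% tolerance (the discrete one-sided slope carries
O(dt) curvature error).

## Timescale estimation

For fluctuating regimes τ_corr is twice the first lag at which the
envelope of the baseline-removed autocorrelation decays to e^{−1/2} of
its lag-0 value (linear interpolation between lag samples). The baseline
(plateau) is the mean of the last 10% of lags. The envelope is the
modulus of the analytic signal (Hilbert transform) computed on the
mirror-extended signal when the autocorrelation is oscillatory (sign
changes after baseline removal); for a monotone decay the signal is its
own envelope — the analytic-signal modulus of a one-sided decay is biased
upward by its Hilbert component, which would break the estimator's own
calibration (exponential → τ₀, Gaussian envelope → 2σ, both held at 2% in
tests; a damped cosine recovers its envelope constant within 10%). If the
envelope never reaches the threshold inside the lag window a failure flag
is returned instead of extrapolating.

## Problem sizes used in the validation suite

The suite favours the smallest sizes at which each regime is robust:
dense-spectrum checks at N = 200–1000; the chaotic-state comparison
between the mean-field solution and direct simulation uses three N = 8000
networks with T = 4500 τ_m (burn-in 700, 3000 recorded units) averaged
against a solver run with 60 trials and T = 2500 — the matrix average is
deliberate, since the theory describes the connectivity ensemble and a
single draw carries slow common-mode estimator fluctuations of 5–10% of
the variance scale; timescale trend scans use 40–80 trials with
T = 100–150 slow time constants per point. Network-vs-theory agreement is
assessed on the scale of the rate variance C(0) − ⟨φ⟩².

## Known limitations

* The iterative DMFT scheme is unreliable within a few percent of the
  bifurcation radius (slow critical modes, estimator noise amplification).
* Finite-size multistability (frozen vs fluctuating states) means single
  small networks need not match the thermodynamic-limit theory; see the
  simulation section above.
* The envelope timescale assumes the autocorrelation reaches its plateau
  inside the stored lag window; choose `max_lag` of at least several
  expected correlation times.
* Euler–Maruyama is first-order; quantities sensitive at O(dt) (e.g. the
  zero-lag slope check) should be run at reduced dt.
* Because intrinsic noise is filtered at the synapse in the
  synaptic-filtering model, every component of the current
  autocorrelation carries the scale τ_s; strong noise therefore shortens
  but cannot decouple the network timescale from τ_s (it does decouple it
  from τ_w in the adaptive model, where the noise drives the current
  directly).
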