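# Model and methods

## The network

`conjgrid` simulates a rate network whose units tile an abstract neural
manifold of position and velocity. In one dimension each unit carries a
periodic spatial label θ ∈ [0, 2π) and a bounded velocity label
v ∈ [−v_max, v_max]. The recurrent coupling from unit j to unit i is

    W_ij = (1/N) [ J0 + J1 cos(k(θ_i − θ_j) − β v_j) cos(v_i − v_j) ]

- **J0 ≤ 0** — uniform inhibition. It sets the effective activity threshold;
  it must be sufficiently negative or the bump amplitude diverges.
- **J1 > 0** — strength of the structured interaction; with threshold-linear
  units of gain G a localised pattern requires roughly G·J1 above the
  linear-stability boundary of the uniform state.
- **β** — velocity-tuning strength. The spatial cosine received from a unit
  with label v is phase-advanced by βv, i.e. its outgoing weight profile is
  rotated βv/k radians toward positive θ.
- **k** — integer number of activity bumps along θ (default 2, matching the
  multi-bump configuration the 2D network needs for grid fields).
- The broad factor cos(v_i − v_j) makes units with similar velocity labels
  co-active; it is what confines the bump along the velocity axis and hence
  what produces conjunctive (position × direction) tuning.

Rates follow τ dm/dt = −m + g(I + W m) with τ = 10 ms, integrated by RK4 at
dt = 0.5 ms (dt ≤ τ/10 enforced). Transfer functions: threshold-linear
g(u) = G·[u]₊ (default, G = 1), threshold-sigmoid g(u) = Θ(u) tanh(G u)
(maximal rate 1), and the binary G → ∞ limit Θ(u) (value 0 exactly at
threshold).

## Exact order-parameter reduction

The recurrent input depends on the state only through five real numbers:
the mean rate M and two complex harmonic projections
Za = ⟨m e^{−i(kθ+(β+1)v)}⟩, Zb = ⟨m e^{−i(kθ+(β−1)v)}⟩. The input field is

    u(θ, v) = I(v) + J0 M + Re[ e^{ikθ} c(v) ],   c(v) = (J1/2)(Za e^{iv} + Zb e^{−iv})

so the (M, Za, Zb) dynamics closes exactly; with quadrature on the manifold
grid the reduced ODE reproduces the full network to machine precision. The
five physically named order parameters are the envelope amplitude
A = (J1/2)(|Za|+|Zb|), the bump positions ψ_θ (spatial phase) and ψ_v
(envelope peak on the velocity axis), the slant
Γ = −(|Za|−|Zb|)/(|Za|+|Zb|) (tilt of the bump ridge in the θ×v plane;
the spanning static pattern has Γ near −1, i.e. ridge along kθ + v), and
the dimensionless threshold x0 = −(I0 + J0 M)/A.

## Intrinsic bump speed

On a ring at fixed label v (asymmetry phase ψ = βv) a travelling solution
m(θ − Ωt) must satisfy the phase-lag condition arctan(τkΩ) = ψ: the
activity, low-pass filtered by the membrane, lags the recurrent input by
exactly the phase the asymmetric coupling advances it. Hence

    Ω = tan(β v) / (τ k)     [rad/ms]

independent of the transfer function — which is why the same law holds for
threshold-linear, sigmoid and binary units. For threshold-linear gain G the
localised solution exists while G·J1·cos(ψ) > 2, giving the admissible label
range |βv| < arccos(2/(G J1)); in the binary limit simply |ψ| < π/2. The
first-harmonic amplitude of the travelling profile decreases with |v| and
collapses toward zero at the range limit while the mean activity stays
finite. Both the speed law and the amplitude formulas are validated against
direct ring simulations (relative error ~1e−4 for the speed).

On the full manifold, a bump detached from the velocity-axis boundaries is a
member of an (approximately) neutral family parameterised by ψ_v: released
bumps hold their velocity-axis position on the second time scale and drift
at tan(β ψ_v)/(τk) within a few tenths of a percent. The family exists for
|ψ_v| up to ≈ 0.35 at the stock parameters; beyond that the bump touches the
boundary and re-attaches.

## Regimes

With the stock inhibition (J0 = −50) the phase plane (J1, β) contains the
homogeneous regime (J1 below the linear boundary of the uniform state,
computed from a 2×2 channel matrix with discrete-grid overlap factors), the
amplitude instability (J0 insufficiently negative; located by bisection on
divergence of the static solve), a static regime in which the pattern spans
the velocity axis and a displaced bump relaxes back, and the traveling
regime in which the displaced bump stays detached and drifts. The
static/traveling distinction is operationalised identically in the theory
route (exact reduced dynamics) and the simulation route (full network):
displace a bump to 0.2·v_max, release under uniform input, and call the
configuration traveling when the drift exceeds 1e−4 rad/τ **and** the
velocity-axis envelope is detached (boundary activity < 50% of peak). The
two routes agree on 96–97% of a 10×10 (J1, β) grid, with disagreements only
adjacent to the boundaries.

One reconstruction-specific feature: because the velocity-selective factor
cos(v_i − v_j) has a fixed width, increasing β does not itself localise the
activity along v; instead, large β folds the second (antiphase) lobe of the
two-channel interference envelope back into the label range, so the
traveling window closes again at large β. `traveling_onset_beta` therefore
reports the regime boundary found along the β axis, which can be an upper
edge of the traveling window.

Two regimes outside the enumerated four exist at extreme couplings and are
avoided by the defaults: a breathing (amplitude-oscillating) narrow-bump
state at very large J1, and a parity-breaking runaway drift of nominally
static bumps when the asymmetry is strong.

## Velocity input and path integration

For grid spacing S the bump pattern must advance one period 2π/k while the
animal covers S cm, i.e. Ω = 2πV/(kS·1000). Inverting the ring law gives the
mapping Λ(V) = arctan(2πτV/(1000·S))/β; at S = 30 cm the 100 cm/s peak speed
maps to v̂ ≈ 0.41, and the path-integration manifold reduces the label range
to v_max = 0.5 to cover exactly the speeds the animal can reach. The
external input is uniform in θ and Gaussian in v around Λ(V) (baseline
I0 = 1, strength α_v = 2, width σ_v = 0.12 — chosen so the bump is pinned
within half a velocity bin at 100 cm/s on the 51-bin full grid).

The finite bump width and its speed-dependent wake skew the activity mass
along v, so the full network's closed-loop speed deviates from the ring law
by up to ~10% at low speeds. The mapping can therefore also be **calibrated**:
the bump speed is measured at a grid of input-pinned positions (a
warm-started continuation) and inverted by interpolation — this mirrors how
the mapping would be learned during development, and it is the default for
the closed-loop experiments. With it the bump-speed/animal-speed regression
has unit normalised slope to ~0.1% with R² > 0.999, and the decoded position
(S cm per 2π of unwrapped k·θ phase, anchored once at t = 0) tracks the
animal within a few cm over minutes.

A lookup-table variant of the mapping with 201 equal bins over
[−100, 100] cm/s (queries return the stored value of the containing bin)
serves the nonlinear network, whose connections are scaled 20× to
compensate for the saturating transfer (J0 = −1000, J1 = 400).

## Two-dimensional environment

Units carry (θx, θy, vx, vy). The kernel is the radial cosine of the wrapped
spatial displacement, displaced by (β/k) times the presynaptic velocity
label vector, times cos of the velocity-label distance. Per-axis signed
circular differences enter a Euclidean norm, which is why an explicit
circular-distance function is needed even though k is an integer. On the
periodic sheet this kernel's spectrum peaks on the (±1,±2)/(±2,±1) ring plus
(±2,0)/(0,±2), and the resonant triad (2,0), (−1,2), (−1,−2) produces four
bumps (two per spatial axis) on an offset-row, quasi-triangular lattice: the
six autocorrelogram peak directions match a rotated ideal hexagon to within
3.5° (exact hexagonal symmetry is incommensurate with a square torus).
Because mode competition from featureless initial conditions can instead
select single-mode stripes, all 2D protocols seed the triad pattern at low
amplitude — the 2D analogue of the bump-seeded initialisation used in 1D —
after which it is a stable attractor that tracks velocity.

The 1/N pooling over nv² velocity slices dilutes per-slice feedback, so the
2D couplings are correspondingly larger (desk preset J0 = −150, J1 = 140 on
a 16×16×7×7 manifold with v_max = 0.6; the parameters are chosen so the
lattice is stable both at rest, pinned at v = (0,0), and while moving). The
per-axis velocity mappings are calibrated from a measured 2D speed curve
exactly as in 1D. Pattern phase is decoded from the Fourier phases of two
triad modes (the lattice has no (0, k) component, so axis-marginal
population vectors are blind along y). Unequal grid scales Sx = 30 cm,
Sy = 24 cm compress the rate-map lattice along y; the per-axis scales are
recovered by least-squares fitting the offset-lattice template (in either of
its two degenerate orientations) to the two shortest independent
autocorrelogram peaks, giving spacing ratio ≈ 1.2.

## Synthetic trajectories

Speed relaxes with τ_v = 250 ms toward a piecewise-constant target drawn
uniformly in [0, 100] cm/s every second. Within the boundary zone (default
v_peak·τ_v = 25 cm, the distance needed to decelerate) the target is zero,
and once the speed falls below 5 cm/s the direction flips and a fresh target
is drawn. The 2 m track hosts one walker; the 100 cm square arena two
independent ones (per-axis speeds uncorrelated, |r| < 0.05 over minutes).
The generator is deterministic given its seed. It does not emulate real
rodent statistics (no heading persistence, no wall-following, no speed-
direction coupling), so passing tests demonstrate path integration under
idealised self-motion input, not robustness to behavioural structure.

## Numerical choices

- RK4 throughout; dt = 0.5 ms (1.0 ms for the desk 2D preset, still ≤ τ/10).
- θ-uniform states are exactly invariant under the deterministic dynamics,
  so every protocol starts from a seeded bump/lattice or a jittered state.
- Order-parameter quadrature uses the manifold grid itself, making the
  reduction exactly the full network's projection.
- Static fixed points: Newton (hybr) from a stripe seed, falling back to
  relaxation of the reduced dynamics plus a final polish; configurations
  whose static state is weakly oscillatory are reported as errors rather
  than silently averaged. Tolerances 1e−10 (iteration), 1e−8 (residual).
- Phase unwrapping assumes per-step increments below π/k (guaranteed at the
  recording intervals used for speeds ≤ 100 cm/s); violations raise an
  error instead of being patched.
- Bump/field detection: local maxima above 20% of the map peak with a
  minimum separation of half the expected spacing; rate-map bins 2 cm (1D),
  5 cm (2D), 10 cm/s (velocity), 15° (direction); bins with fewer than two
  samples are marked unsampled.
- Direction selectivity: mean resultant length of the direction-binned
  rates > 0.2 counts as conjunctive (configurable).

## Problem sizes

Desk-scale presets are used by the test suite and the acceptance script:
1D 128×31 units (full scale 200×51 = 10,200), 2D 16×16×7×7 = 12,544 units
(full scale 25×25×9×9 = 50,625), runs of 2–4 simulated minutes (full scale
20 minutes). The robustness sweeps (`run_robustness_1d/2d`) support the full
protocol — Gaussian weight noise at 2%/10% of the weight range, dilution at
20%/40% with 1/(1−ρ) rescaling, eight seeds, drift and time-to-half-spacing
— and are exercised at miniature scale in the tests; full-scale dense-matrix
sweeps are run via the CLI.

## Known limitations

- The reconstruction fixes the coupling's functional form from the contracts
  it must satisfy; constants such as J0, J1, β were calibrated from the
  package's own regime analysis rather than copied from a reference.
- Marginality along the velocity axis is approximate: released bumps slide
  by ≲ 0.05 label units per second near the edge of the admissible range,
  and the closed loop relies on the velocity input to pin ψ_v.
- The quasi-triangular lattice is the torus-commensurate approximation of a
  hexagonal lattice; angular deviations up to ~3.5° are intrinsic.
- Elliptical-grid runs may select either degenerate lattice orientation;
  only orientation-robust per-axis spacing estimates are meaningful.
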