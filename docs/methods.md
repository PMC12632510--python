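# Methods

## The model

`pyrecond` simulates the regulation of a pyrenoid-like biomolecular
condensate by phosphorylation. A single multivalent linker protein (EPYC1 in
*Chlamydomonas*) is represented by two interconverting species on a 2-D
domain: unphosphorylated, *sticky* molecules with volume fraction φs that
self-attract and phase separate, and phosphorylated, *non-sticky* molecules
φns that behave like solvent. Solvent fills the rest: φsol = 1 − φs − φns
(equal molecular volumes, incompressible mixture).

The Flory–Huggins free-energy density (energies in kBT, lengths in units of
the cross interfacial coefficient √κ′s−ns) is

    f = φs ln φs + φns ln φns + φsol ln φsol − χ φs²
        + (κ̃s/2)|∇φs|² + (κ̃ns/2)|∇φns|² + ∇φs·∇φns .

Here χ > 0 is the magnitude of the sticky–sticky attraction (it stands in
for EPYC1–Rubisco binding), and the exchange chemical potentials are the
exact functional derivatives

    μs − μsol  = ln(φs/φsol) − 2χφs − κ̃s ∇²φs − ∇²φns ,
    μns − μsol = ln(φns/φsol) − ∇²φs − κ̃ns ∇²φns .

With this convention the uniform state is spinodally unstable when
2χ > 1/φs + 1/φsol, i.e. χ must exceed 2 at φs = 1/2. (Note the pairing:
a free energy written with −(χ/2)φs² would produce −χφs in μs; the −χφs²
form is required for consistency with the −2χφs chemical potential that
the dynamics, the dispersion relation, and the demixing behaviour at the
default χ = 7 all rely on. The functional-derivative consistency is
enforced by an oracle test.)

Dynamics are conserved diffusion with degenerate mobility D̃φi plus
first-order switching (kinase phosphorylates at rate k̃·φs, phosphatase
dephosphorylates at rate 1·φns; time is measured in phosphatase units):

    ∂t φs  = ∇·[D̃ φs ∇(μs − μsol)]  − k̃(t) φs + φns ,
    ∂t φns = ∇·[D̃ φns ∇(μns − μsol)] + k̃(t) φs − φns .

Switching conserves total protein; transport is in flux form, so total
protein is conserved exactly. k̃(t) may follow a piecewise-linear protocol
(e.g. a division-like activity wave).

### Default parameters

| symbol | meaning | default | origin |
| --- | --- | --- | --- |
| χ | sticky self-attraction (kBT) | 7 (5.5 / 8 for the ectopic variants) | published simulation set |
| D̃ | diffusivity, D/(κ′s−ns·kns→s) | 10 | published |
| k̃ | kinase/phosphatase ratio ks→ns/kns→s | scenario-dependent (0 – 1) | published per scenario |
| κ̃s, κ̃ns | interfacial ratios κ′s/κ′s−ns, κ′ns/κ′s−ns | 5, 1 | published |
| φtot | total protein volume fraction | 0.1 | published |
| θs, θns | wall contact angles | 5π/6 | published (dewetting) |

The dimensional anchors D = 60 μm²/s, chloroplast major semiaxis 5 μm ↔ 35
dimensionless units give κ′s−ns = (5/35)² ≈ 0.0204 μm² and kns→s = D/(κ′s−ns
D̃) ≈ 294 s⁻¹; `model_core.dimensionalize`/`nondimensionalize` are exact
inverses.

### Geometry

Two domains: a periodic square, and a cup-shaped "chloroplast" mask — the
interior of an ellipse (semiaxes a = 35, b = 29.17) minus a circle (r =
16.67) whose center is offset along the minor axis. The published shape
constants fix only a, b and r; the offset is our reconstruction (default
b − r − 2, keeping the circle strictly inside; offset 0 gives an
annular-elliptic domain). On the mask boundary, fluxes obey a no-flux
closure and each species' normal derivative carries wetting Neumann data

    ∇φi·n = (√2 / 2√κ̃i) cos θi (1 − φi)² ,

imposed as ghost-cell data in the finite-volume stencil. Two numerical
guards apply: the prefactor scales as 1/√κ̃i (interfacial gradients widen
with κ), and the Neumann data passes through a smooth limiter so the ghost
value never demands concentrations outside [0, 1] — on coarse grids the raw
dewetting condition would otherwise drive near-empty boundary cells
negative (and a *hard* clip makes those cells stiffly nonsmooth and stalls
adaptive stepping). The limiter is active only in dilute boundary skins
where wetting is immaterial.

## Numerics

Spatial discretization is a cell-centered finite-volume scheme: fluxes live
on faces (mobility = arithmetic face mean, zero flux into empty cells), so
the discrete divergence theorem — and hence mass conservation — holds to
round-off. The 5-point Laplacian is the exact variational partner of the
face-difference gradient energy, so chemical potentials equal discrete
functional derivatives of the discrete free energy (tested at 1e-6).

Time stepping is first-order semi-implicit with two interchangeable
implicit operators:

* **stabilized** (default on periodic domains): the full nonlinear
  right-hand side is explicit; a constant-coefficient operator
  −S∇² + A∇⁴ is implicit (spectrally, using the discrete stencil symbol).
  S adapts to the stiffest local diffusivity D̃·φi(1/φi + 1/φsol): the
  solvent-entropy term makes the *dense* phase very stiff (φsol ~ 1e-3 at
  χ = 7), and S must cover it for stability. S uses a high quantile (99.5%)
  of the local stiffness rather than the max — a handful of extreme cells
  at curved interfaces would otherwise overdamp the whole domain; rare
  under-stabilized outliers are caught by step rejection. The price of the
  scheme is artificial damping of slow modes when dt·S·q² ≫ 1: equilibria
  are exact, but rates are retarded at large steps. Quantitative rate
  checks therefore run at small dt.
* **jacobian** (default on masked domains): linearized backward Euler with
  the true variable-coefficient Jacobian, including the 2×2 species
  coupling through 1/φsol and the interfacial biharmonic terms, factorized
  sparsely and refreshed only when the composition drifts (> 0.005) or dt
  changes. Slow modes then evolve at their correct rates even at large dt.
  The row space [1,1] is an exact left eigenvector of the implicit
  operator, so the solve conserves total protein exactly.

dt adapts to keep max |Δφ| per step below a target (1e-3 default; the
scenario presets use 4e-3), halving on overshoot and doubling after quiet
streaks. Fields are clipped to [1e-9, 1−1e-9] inside logarithms only; small
negative undershoots after a step (stabilizer ringing next to steep
interfaces) are clipped to zero with the species total renormalized — an
exactly mass-conserving operation — and a step is rejected if the clipped
mass exceeds 1e-5 of the *total* protein content (measuring against the
species' own total would hold a nearly-empty species to a vanishing
allowance). Clip events are counted and reported; they signal an over-long
step, not accepted physics.

### Resolution, pinning and scenario scale

The equilibrium interface is ~1.5–2 dimensionless units wide. Desk-scale
grids (h = 0.4–0.76, i.e. 2–5 cells per interface) resolve condensate
formation, dissolution and size relaxation well, but *translation* of a
near-equilibrium droplet is subject to grid pinning: forces weaker than the
discrete depinning threshold leave the interface locked. Consequences for
the scenario presets (all deliberately desk-scale; production studies of
this model clearly require much finer grids and longer horizons):

* size control, repulsion, ectopic dissolution: driven by strong flux
  imbalances; run on periodic 64²–96² grids at h = 0.5.
* self-centering: two confounds rule out a literal desk-scale replica.
  The drift force at the published k̃ = 0.01 is below the pinning
  threshold at these resolutions, and on the cup geometry a droplet
  parked in an arm sits so close to the walls that passive wall-dewetting
  relaxation moves the centroid as much as the active mechanism does.
  The preset therefore runs on the half-scale *elliptical* domain
  (a = 17.5, b = 14.58, inner circle removed), with the droplet away
  from the walls and k̃ = 0.12 — stronger activity, still below the
  dissolution threshold. There the active run drifts steadily toward the
  center (metric decrease ≈ 0.7 over t = 400) while the k̃ = 0 control is
  exactly static. The control runs under the constant-coefficient scheme:
  the k = 0 limit makes the variable-coefficient solve reject-bound, and
  a null comparison needs no rate fidelity.
* division protocol: half-scale chloroplast at h ≈ 0.34 (≈5 cells per
  interface). The first four phases — single condensate, fragmentation
  during the activity rise, full dissolution at peak, re-condensation
  during the decline — complete reliably. The final re-coarsening into a
  *single* condensate does not: the re-condensed multi-condensate state
  is the model's own arrested-coarsening attractor, and it remained
  static for >1300 time units across every activity hold (k̃ = 0.01 to
  0.12), domain scale (1.0/0.5/0.35) and resolution (h = 0.76 to 0.26)
  tried. Passive ripening at χ = 7 (dilute coexistence ~1e-3) has an
  estimated timescale of 1e4–1e5 time units — beyond desk scale — so the
  division verdict honestly reports the four-phase pattern and a final
  "multiple" state at this scale.

## Linear stability

Perturbing the uniform state (φs0, φns0) = (φtot/(1+k̃), φtot·k̃/(1+k̃)) and
linearizing gives ω(q) as eigenvalues of an analytically assembled 2×2
Jacobian M(q) (products φi0·∂μi/∂φj are expanded so the k̃ = 0, φns0 = 0
limit is regular). The printed closed-form dispersion polynomial is
typographically unreliable in our source; the Jacobian route is validated
instead by its exact limits — branches {0, −(1+k̃)} at q = 0 — and by a
brute-force oracle that numerically differentiates the full nonlinear
right-hand side at single Fourier modes. Classification: `uniform_stable`
(ωmax ≤ 0 for q > 0), `arrested_candidate` (ωmax > 0 with d²ω/dq² < 0 at
q = 0, i.e. long waves suppressed — finite-wavelength selection), else
`continued_coarsening`. The curvature uses Richardson-extrapolated finite
differences (h = 1e-3) anchored at ω(0) = 0. For the default parameter set
the dissolution threshold (ωmax crossing zero) is k̃* ≈ 0.1415 — the
published intermediate value k̃ = 0.14 sits just below it, consistent with
small, arrested condensates. Note k̃* is the *spinodal* threshold: existing
condensates survive somewhat above it and dissolve quickly only once the
switching ratio approaches order one (conversion-dominated dissolution);
the division preset's peak (k̃ = 1) exploits this.

## Reduced droplet model

A quasi-steady single droplet with sharp interface: inside and outside, the
linearized screened-diffusion equation 0 = ∇²φ − φ + k_drop(1 − φ), in
units of ℓ = √(D/ks→ns). **Convention trap**: the droplet model's
k_drop = kns→s/ks→ns is the *reciprocal* of the PDE model's k̃; the package
keeps two named fields and explicit converters. Profiles are screened
exponentials (sinh/exp in 3-D; modified Bessel I₀/K₀ in the 2-D variant
provided for comparison with the 2-D PDE). The interface mass balance gives
dR/dt; its fixed points are found by bracketed root-finding (the printed
equilibrium-radius closed form is not reproducible from our source and is
not used). Below k_c ≈ (φ+ + φ−)/(2 − φ+ − φ−) a stable radius exists
(size control); above it growth is unbounded. The closed form is the
R ≫ 1 limit and agrees with the numeric boundary to within ~10% over
φ+ ∈ [0.8, 0.95], φ− ∈ [0.005, 0.05]. Flux scalings: the interior
(conversion) flux scales as R³ at small R; the exterior (supply) flux is
∝ √(1+k) R² + R, so its R² surface scaling holds for √(1+k)·R ≫ 1 and
degrades to ~R¹ at small radius — the two asymptotic windows are fitted
separately.

## Quantification

Mirrors a confocal condensate-analysis pipeline on either simulated fields
or synthetic image stacks: intensity threshold (fixed, or the midpoint of a
two-means estimate of the dilute/dense modes) → connected components (8- in
2-D / 26-connectivity in 3-D, periodic-aware merging on periodic domains) →
minimum-size filter (4 cells default) → per-condensate size, centroid
(circular mean on periodic domains), mean intensity, equivalent radius;
per-frame count, largest size, condensed volume fraction (dense volume /
compartment volume), total intensity. Photobleach correction is the ratio
method (frame × total₀/totalₜ), assuming constant protein; it is exactly
idempotent. Partition ratio = mean in / mean out (1 = no enrichment).
Spatial metrics: the canonical position is the Euclidean-distance-transform
argmax of the domain mask (for the default cup this lies in an arm, not on
the symmetry axis — a property of the reconstructed shape); self-centering
is scored by the distance of the largest condensate's centroid to it, and
repulsion by the minimum pairwise centroid separation (minimum-image on
periodic domains).

## Synthetic data

The generators produce exactly what the pipeline consumes and nothing more:
noise-seeded uniform states (i.i.d. perturbations, amplitude 1e-3·φtot,
mass renormalized exactly, bit-reproducible per seed); placed tanh droplets
between dilute and dense levels (defaults near the relaxed phase
compositions, φ+ ≈ 0.99 / φ− ≈ 0.006 at χ = 7, so simulations start close
to coexistence rather than spending steps on a stiff initial transient;
placed material is fully sticky by default, matching the picture that the
dense phase is unphosphorylated); and confocal-like timelapse z-stacks with
intensity ∝ concentration, scaled-Poisson shot noise, Gaussian read noise
and exponential photobleaching, returned together with exact ground truth.
The stacks emulate the statistical structure the quantification stage
assumes — two intensity modes, tanh interfaces, multiplicative bleaching —
and none of the optics of a real microscope (no PSF, no z-anisotropy, no
chlorophyll channel); recovery tests on them validate the pipeline's logic,
not its behaviour on real images.

## Known limitations

* First-order time accuracy; the stabilized scheme retards under-resolved
  dynamics (energy decrease is only guaranteed at resolved step sizes) and
  the jacobian scheme's factorization cost limits it to masked/small grids.
* Grid pinning at desk resolutions suppresses weak droplet drift; scenario
  scales and activity levels are chosen accordingly and documented above.
* The reduced droplet model converts the whole bath (solvent included) at
  the phosphatase rate, so its k_drop maps onto the PDE model only through
  the measured dilute-phase composition, and only approximately.
* 2-D fields only; no hydrodynamics; no thermal noise during integration;
  switching rates are spatially uniform by construction.
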