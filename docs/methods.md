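# Methods

This note documents the models implemented in `vascusim`, the assumptions
behind them, the default parameters and why they were chosen, the numerical
choices, and what the bundled synthetic inputs do and do not represent.
Internal units are μm, s, Pa, nM throughout; config files may use
unit-suffixed strings ("30 min", "1.33 kPa") which are converted at load.

## Vessel networks

A network is a graph of nodes (3D positions, μm) and straight segments
(single scalar radius — no tapering, no wall surface). The canonical
on-disk form is a CSV pair (`nodes.csv`: id, position, boundary role and
pressure; `segments.csv`: id, endpoints, radius); legacy VTK polydata ASCII
with a per-point `Radius` array is read and written as the interchange
format for imaging-derived skeletons. Preprocessing merges nodes closer
than a tolerance by union–find (merged node at the cluster centroid —
deterministic and order-independent), removes zero-length and duplicate
segments, and drops connected components below a size threshold.
Clipping against an implicit region truncates boundary-crossing segments
at the surface (membership probed along the segment and refined by
bisection to 10⁻⁶ of the segment length, so curved surfaces need no
per-shape intersection code).

Characterization maps on a regular lattice: the *line density* map splits
segments exactly at voxel faces and reports centerline length per voxel
volume (μm⁻²), conserving total length; the *occupancy* map marks a site
when a centerline passes within h/2 of the site center. Occupancy is the
rule that localizes the vascular exchange term of the transport equation;
the h/2 center-distance criterion makes it invariant to subdividing
segments.

## Hemodynamics

The 1D resistor-network reduction: per-segment conductance
G = πR⁴/(8μL), nodal pressures from the sparse linear conservation system
(direct factorization; components without a prescribed pressure are flagged
and set to the mean prescribed pressure with zero flow), flows stored
signed. With μm/s/Pa units conductances are μm³/(Pa·s) and flows μm³/s with
no conversion factors.

*Rheology.* The apparent viscosity is plasma viscosity times the empirical
in-vitro relative viscosity μ_rel(d, H) with
μ₀.₄₅(d) = 220e^(−1.3d) + 3.2 − 2.44e^(−0.06d^0.645) and the standard
hematocrit-shape exponent C(d). These constants are conventions from the
rheology literature, not fitted here; they reproduce the
Fåhræus–Lindqvist minimum near d ≈ 7 μm (verified by the test suite over
d ∈ [3, 1000] μm). The fit diverges at H = 1, so H is evaluated at ≤ 0.99;
a `constant` law (plasma viscosity only) is available for testing.

*Plasma skimming.* At diverging bifurcations the red-cell flux fraction to
a daughter follows the empirical logit law
logit(F_α) = A + B·logit((ψ_α − X₀)/(1 − 2X₀)) with
B = 1 + 6.98(1−H)/D, A = −13.29((D_α²/D_β²−1)/(D_α²/D_β²+1))(1−H)/D and
X₀ = 0.964(1−H)/D; daughters below the threshold flow fraction X₀ receive
no red cells. Hematocrit propagates from inlets in topological order of
the flow digraph (iterative relaxation, tolerance 1e-8, at most 1000
sweeps, if the digraph is cyclic); converging nodes mix by flux weighting;
junctions with more than two outflows split recursively pairwise in
descending flow order (the empirical law is binary). Clamping at H = 1
returns the excess flux to the sibling branch, so Q·H is conserved exactly
at every node. Zero-flow segments carry H = 0 (they transport no cells).
A `proportional` law (red cells split like plasma) is provided for tests.

*Adaptation.* The wall-shear set-point model
R ← clamp(R·exp(dt·k_growth·(log(τ_w/τ_ref + ε) − k_s)), R_min, R_max) with
ε = 10⁻¹² guarding the logarithm. The fixed point is τ_w = τ_ref·e^{k_s};
unperfused segments take the τ_w = 0 branch and shrink to R_min. Metabolic
and conducted stimuli are deliberately out of scope.

## Transport

One steady solve per species per coupling step (no parabolic term — the
tissue-diffusion timescale over one lattice cell is far shorter than the
30-min coupling step); time dependence enters only through coefficient
updates. Discretization: 7-point stencil; zero-flux closure by a reflected
(mirror) ghost, which keeps second-order accuracy at Neumann boundaries —
the plain dropped-neighbor closure degrades to first order, which the slab
benchmark in the test suite would catch. The mirror closure makes the
matrix mildly nonsymmetric, so the solver is sparse-direct up to 4×10⁵
unknowns and Jacobi-preconditioned BiCGSTAB (rtol 1e-10, ≤ 10N iterations)
beyond. Negative concentrations beyond −10⁻⁹·max|c| raise an error rather
than being clipped: the continuous problem obeys a maximum principle, so
material negativity means the coefficients are wrong.

The printed reaction term is linear (k·c), but constant hypoxic VEGF
release cannot be expressed that way from c = 0, so both a signed linear
coefficient and a zeroth-order source are exposed: oxygen uses
k_lin = −k_O₂ on cell sites, VEGF uses k_const = k_VEGF on hypoxic sites.
VEGF exchanges toward a vascular concentration of zero (vessels as sinks).
For the cornea, the shell is masked on the lattice (stair-step zero-flux
boundary rather than a fitted mesh; one solver code path), the pellet
region is a Dirichlet patch, and mask islands disconnected from the pellet
by stair-stepping are dropped so the decay-free problem stays well posed.
Point sampling is trilinear; gradients are central differences (one-sided
at faces) interpolated trilinearly — exact for linear fields.

## Cells

One cell per site; cells and vessels co-occupy sites and only cell–cell
exclusion is enforced. The cycle model is the minimal oxygen-limited phase
ODE dφ/dt = c/(T_min(c + c_φ)) (explicit Euler, 5-min substeps — the rate
is bounded by 1/T_min, so the division-time error is below one substep),
a deliberate two-parameter reconstruction of oxygen-dependent
proliferation. Initial phases are uniform on [0, 1) to stagger divisions.
At most one division per cell per global step; daughters take a uniform
empty von Neumann neighbor, tumor daughters replace a uniform normal
neighbor when none is empty (the invasion mechanism), otherwise the
division aborts with the phase already reset. Hypoxia (c < c_hypoxia)
switches on constant VEGF release; a clock accumulates while c < c_death
and resets otherwise; cells exceeding t_death are removed immediately
(no inert corpse occupancy). All stochastic choices draw from one seeded
generator, so runs are bit-reproducible.

## Angiogenesis

Sprout initiation converts a saturating VEGF hazard to a per-step
probability, p = 1 − exp(−dt·P_max·c/(c + c₅₀)) — step-size robust.
Eligible nodes are non-tip, non-boundary nodes farther than d_min from
every tip/new sprout base. The initial sprout direction is perpendicular
to the parent vessel on the gradient-facing side (random perpendicular for
zero gradient). Tip headings blend persistence, unit VEGF gradient, the
direction to the nearest non-adjacent vessel within a sharp attraction
radius (suppressed within one step length of the tip to avoid refusing
with its own trail), and an isotropic unit noise vector; weights are
renormalized to sum to 1 at load. Tips do not branch; secondary sprouts
arise only from matured sprout nodes via the initiation rule. Anastomosis:
a tip landing within r_a of a non-adjacent segment snaps onto it, the
segment is split, and the tip deactivates permanently. Confinement is
nearest-point projection into the domain (applied to migration steps and
to initial sprout placement). Geometry queries run against a per-call
network snapshot, so same-step siblings become targets only next step.

## Coupling

Tumor scenario, per 30-min global step: (1) occupancy/perfusion mapping;
(2) viscosity → flow → hematocrit → perfusion flags → wall shear;
(3) oxygen solve; (4) cell substeps, daughter placement, hypoxia/death;
(5) VEGF solve; (6) sprouting + one migration move; (7) radius adaptation.
The intra-step order (flow before transport before cells before vessels)
is a choice — each consumer sees current-state fields — and is documented
here because the coupling literature fixes only the step sizes, not the
order. Pressure conditions: nodes on the low-z face are inlets and high-z
face outlets with a 1.33 kPa drop across the 200 μm depth. The cornea
scenario solves its VEGF field exactly once and then only sprouts and
migrates tips against the frozen field.

## Default parameters

| Parameter | Default | Why |
|---|---|---|
| lattice spacing h | 40 μm | one cell diameter scale; tumor-scenario standard |
| Δt_global / Δt_ode | 30 min / 5 min | coupling and cell-ODE steps of the tumor scenario |
| end time | 25 h (50 steps) | scenario duration |
| inlet/outlet pressure | 3330 / 2000 Pa | 1.33 kPa drop across the depth axis |
| plasma viscosity | 1.2 mPa·s | plasma at 37 °C |
| inlet hematocrit | 0.45 | systemic value |
| perfusion threshold | 1 μm³/s | separates numerically-zero dead-end flows from through-flow (~10⁶–10⁷ μm³/s) |
| adaptation k_growth, k_s, τ_ref | 10⁻⁶ s⁻¹, 1.0, 1 Pa | slow remodelling (percent-level per step); τ_ref at the physiological WSS scale |
| R_min, R_max | 1, 50 μm | capillary floor, arteriole ceiling |
| O₂: D, ρ, c_b | 2000 μm²/s, 5 s⁻¹, 30 nM | D standard for O₂ in tissue; ρ strong vascular coupling; c_b a nominal oxygenation scale against which the thresholds below are set |
| O₂ consumption k_O₂ | 0.08 (tumor), 0.05 (normal) s⁻¹ | diffusion-limited length √(D/k) ≈ 160–200 μm: hypoxia appears in poorly vascularized pockets, not everywhere |
| VEGF: D, λ, ρ, k_release | 100 μm²/s, 10⁻³ s⁻¹, 0.01 s⁻¹, 0.01 nM/s | growth-factor-scale diffusivity; decay length ≈ 300 μm localizes the field around hypoxic regions; vessels weakly sink it |
| cornea VEGF λ | 10⁻⁵ s⁻¹ | the micropocket assay works because pellet VEGF reaches the limbus: decay length ≳ cornea radius |
| cell cycle T_min | 8 h (tumor), 24 h (normal) | fast-cycling tumor line vs slow normal turnover |
| c_φ | 15 nM | half-saturation at ~half of c_b: proliferation visibly oxygen-limited |
| c_hypoxia | 10 nM | one third of vascular oxygen |
| c_death, t_death | 1 nM / 8 h (tumor), 3 nM / 2 h (normal) | tumor cells tolerate hypoxia far better than normal cells, as in the hybrid-CA literature |
| sprout P_max, c₅₀ | 10⁻⁵ s⁻¹, 0.5 nM | ≈ 2% per node per 30-min step at saturation — sprout initiation is a rare event |
| tip speed | 20 μm/h | endothelial tip migration scale |
| weights α, β, γ, σ | 0.5, 0.3, 0.1, 0.1 | persistence-dominated walk with clear chemotactic bias |
| attraction radius, r_a, d_min | 50, 5, 40 μm | attraction at the inter-capillary scale; fusion on contact; one lattice cell of sprout exclusion |
| cornea geometry | R 1.4 mm, t 0.1 mm; pellet 0.3×0.3×0.1 mm at 3.0 nM | cornea scenario dimensions |
| tumor seed | 300 μm central cylinder | tumor scenario initial condition |

Concentrations are nominal model units (nM); the oxygen scale is defined
relative to c_b, and thresholds should be read as fractions of it.

## The synthetic vessel fixture

`synthetic_tumor_network` emulates an imaging-derived tumor skeleton so the
full tumor scenario runs with no external data: 12 tortuous backbone
vessels traverse a 1.2 mm diameter × 200 μm cylinder depth-wise (lateral
Gaussian jitter of 15 μm per 40 μm axial step), dangling side branches
attach with probability 0.1 per interior node, and radii are lognormal
(median 10 μm, σ_log 0.25, clamped to [2, 30] μm). Every backbone connects
the inlet face (z = 0) to the outlet face (z = depth), so the fixture is
perfused end-to-end, while side branches carry no flow and exercise the
perfusion logic. These statistics are plausibility choices — the fixture
is *not* fitted to any real microvascular dataset, and it lacks real
features such as hierarchical branching order, spatially correlated radii,
anastomotic loops, and imaging noise. Tests passing on it demonstrate the
machinery (conservation, coupling, determinism, qualitative
hypoxia→VEGF→sprouting dynamics), not quantitative agreement with any
in-vivo network. In the default run the fixture is well-perfused enough
that the death pathway stays quiescent over 25 h: hypoxic pockets form and
recruit vessels, tumor growth proceeds by invasion. Sparser networks (fewer
backbones) push the same model into the apoptosis regime.

## Known limitations

- No pulsatile flow, vessel compliance, metabolic/conducted adaptation.
- Stair-step (not fitted-mesh) curved boundaries for the masked cornea
  solve; boundary-layer accuracy is first-order in the stair-step region.
- Tips do not branch; on-lattice migration is not implemented.
- Dead cells free their sites immediately; no mechanics, no subcellular
  signalling.
- The cornea VEGF field is frozen after one solve by design; pellet
  depletion and cellular consumption are not modelled.
- Checkpointing is in-process (incremental `step()` on a live simulation
  object reproduces a single run exactly); there is no on-disk resume
  format beyond the CSV/VTK state dumps.
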