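# Methods

## Model

`phasecell` simulates a two-dimensional confluent cell monolayer in which
every cell *i* = 1…N carries its own phase field φ_i(x, t) on a common
periodic square domain [0, L)². The bulk values φ ≈ +1 and −1 mark the
cell's interior and exterior; the cell boundary is the diffuse transition
layer of width set by ε. Each field evolves by conserved (mass-preserving)
dynamics driven by a free energy and an advection velocity:

    ∂_t φ_i + v_i · ∇φ_i = Δ (δF/δφ_i),            F = F_CH + F_INT,

    F_CH  = (1/Ca) Σ_i ∫ (ε/2)|∇φ_i|² + (1/4ε)(φ_i² − 1)² dx,
    F_INT = (1/In) Σ_i ∫ B(φ_i) Σ_{j≠i} w(φ_j) dx,

with B(φ) = (φ+1)/2 and w(φ) = 1 − (a+1)u² + a u⁴, u = (φ−1)/2. The
Cahn–Hilliard term penalises interface length (line energy (2√2/3)/Ca per
unit length for the 1D minimiser tanh(x/√2ε)); the interaction term makes
cell overlap costly. For a = 1 the potential w is non-negative (pure
repulsion); for a > 1 it develops a shallow well (min w = −1/24 at a =
1.5, near φ ≈ −0.83), i.e. adhesion between adjacent diffuse interfaces.

Activity enters through v_i = v0 B(φ_i) e_i with e_i = (cos θ_i, sin θ_i)
and

    dθ_i = √(2 D_r) dW_i + α (β_i − θ_i) dt,

where β_i is the representative of the cell's elongation axis closest to
θ_i. The axis comes from the shape deformation tensor S_i (components
S_0 = (1/8)∫[(∂_yφ)² − (∂_xφ)²], S_1 = −(1/4)∫ ∂_xφ ∂_yφ), whose
principal-axis angle is ½·atan2(S_1, S_0). Because the axis is nematic,
"closest representative" means the one within a quarter turn of θ_i; the
literal sign form β = ±arg(η⁺) is available behind
`select_beta(..., rule="literal")`. A passive mode replaces the active
advection by the fixed shear profile of magnitude 0.5|x₁ − L/2| directed
along x₂ (the direction is a package choice; only the magnitude is part
of the model definition).

Default physical constants: τ = 0.005, τ_save = 0.5, T = 150, L = 100,
ε = 0.15, v0 = 0.5, a = 1.5, Ca = 0.2, In = 0.1, D_r = 0.1, α = 0.1.

## Discretisation

Space is a uniform n×n periodic grid (n a power of two) with the interface
resolution requirement dx ≤ ε/2 enforced at parameter validation. Time
stepping is a first-order stabilised semi-implicit splitting: the stiff
linear Cahn–Hilliard operator −(ε/Ca)Δ²φ and a stabilising term σΔφ are
implicit and inverted exactly in Fourier space; the cubic bulk force, the
interaction force and the advection are explicit, evaluated with
conservative centred differences. The advection is applied in flux form —
the active term is v0 e_i · ∇G(φ) with G' = B, the shear term is
∂_{x₂}(v(x₁) φ) — so every telescoping sum vanishes identically and
per-cell mass is conserved to round-off (verified < 10⁻¹⁵ relative per
1000 steps). The stabiliser is σ = 2/(Ca ε) + 6/In, covering the maximal
stiffness of the explicit bulk term on |φ| ≤ 1 plus the curvature of the
localised interaction (below).

The scheme is first-order in time (halving τ changes the relaxed energy of
a single-cell test by < 1%) and dissipates the free energy along passive
relaxation up to its O(τ²) splitting error; the tests assert per-step
monotonicity with a 10⁻⁵ relative slack plus a strict net decrease.

## Interaction localisation

Reference implementations of this model solve each φ_i on an adaptively
refined subdomain around its own cell, so a field simply does not exist —
and does not interact — far from the cell. On a single global grid that
localisation must be made explicit, for two reasons:

1. Outside the physical range [−1, 1] the polynomial extensions of B and w
   are anti-restoring; interaction terms therefore evaluate B and w on
   clamped fields, with their derivatives vanishing off-range (the exact
   variation of the clamped functional).
2. For a > 1 the potential has w'(−1) = 1 − a ≠ 0, so N fields sharing the
   exterior couple pairwise at their bulk value; the resulting quadratic
   form has an unstable collective mode whenever N(a−1)/(2 In) exceeds the
   Cahn–Hilliard curvature 2/(Ca ε) — which holds at the default
   parameters for any realistic N. The interaction therefore carries a
   smooth presence factor s(φ) (cubic smoothstep from 0 at φ = −1 to 1 at
   φ = −0.7) multiplying w: a field contributes no interaction where it is
   absent. The switch is deliberately wide; a narrow switch has curvature
   exceeding what the stabilised splitting damps and produces a spurious
   stiff band (observed as a τ-independent energy limit cycle). With the
   wide switch the repulsive range (φ > −0.63) is untouched and the
   adhesive well keeps roughly half its depth.

A residual of this regularisation: a cell's exterior tail inside a
neighbour's halo can carry a small "ghost" contribution, so the energy of
multi-cell configurations is monotone only up to ~10⁻⁵ relative per-step
wiggles. Monolayer-scale statistics are unaffected.

## Initial conditions

Monolayers are seeded from a Lloyd-relaxed periodic Voronoi tessellation
of N points (perturbed hexagonal lattice when N is an even perfect square,
otherwise uniform), each cell taking φ = tanh(d/√2ε) of the signed
distance to its inward-offset Voronoi boundary — the 1D minimiser profile,
so dynamics starts near the energy's slow manifold. The offset is set
either per cell so that the mass ∫B dx equals a coverage fraction c of
L²/N (bisection, exact to the stated 1% and better), or globally by
bisecting to a target measured gap fraction (the area fraction where
Σ_i B < 0.2). Gap-fraction targets such as the reference values 0.00048
("low gap") and 0.00212 ("high gap") correspond to tiny boundary offsets
when cells are hundreds of interface widths across; at desk-scale cell
sizes the same measured gap implies strongly over-shrunk cells, so the
default initial condition is the coverage route with c = 0.97 — nearly
confluent with enough slack for rearrangements. The calibration route
remains available and is exercised by the tests.

Signed distances use the Euclidean distance transform with a half-pixel
correction on both sides so the field is continuous at the boundary; a
freshly initialised straight interface matches tanh(x/√2ε) to < 0.02.

## Desk-scale study conditions

All desk analyses keep every dynamical constant at its default (Table
above) and shrink only the geometry: N = 10 cells, L = 9.5, 128² grid
(dx = 0.074 ≤ ε/2), T = 60. The controlling dimensionless number for this
scaling is the cell radius in interface widths, r/(√2ε): compact cells in
this model are metastable against spreading into the adhesive mean-field
state, and direct experiments show two-cell clusters dissolve at r/(√2ε) ≈
4 while monolayers need ≈ 8 (the desk profile sits at 8.0; the reference
geometry sits at 27, far from the threshold). The pooled T1 study
(`run_t1_study`) runs three independent monolayers (seeds seed + 1000k,
matching the reference practice of pooling several simulations for
duration statistics) and yields roughly 15–20 spontaneous neighbour
exchanges at the default conditions.

Because the desk tissue has an order of magnitude fewer, relatively more
active cells, absolute event rates, durations and energy scales are not
comparable with the full-scale reference values (e.g. mean durations here
are of order 10–20 time units rather than ~3.5); the qualitative
statistics — the asymmetric event-aligned energy profile, the negative
duration–peak-energy rank correlation, the elevated shape index and CoM
speed at the exchange — are the reproducible content at this scale.

## T1 detection and statistics

Two cells are in contact when max over the grid of min(B_i, B_j) ≥ 0.15
(below the gap threshold 0.2, so a forming gap breaks contact); graphs are
sampled at every save time. A neighbour exchange is the signature
5 → 4 → 5 of the relation count among a quadruple: when a pair (B, D)
disappears, its common neighbours at the last time it was present are
candidate partners, and the event closes at the first snapshot where a
previously unbonded pair (A, C) of them bonds with the four perimeter
relations intact at both endpoints. Reappearance of (B, D) first discards
the candidate (reversal); with more than two common neighbours
(rosette-like) the completing pair is whichever bonds first. Event times
are the bracketing save times: t_start is the last save with the lost pair
present, t_end the first save with the gained pair present, so the
duration is a positive multiple of τ_save and the relation counts at
t_start/t_end are exactly 5. (A midpoint-between-saves convention would
halve the quantisation bias but places event times where no graph exists;
the save-time convention is used throughout.)

The epicenter is the geometric median — under the torus metric — of the
four cell centres (B-weighted circular-mean centroids) at the save nearest
the event's temporal midpoint, computed by a torus-aware Weiszfeld
iteration (points re-unwrapped around the current iterate each step, with
the Vardi–Zhang correction when the iterate lands on a data point) started
from each data point, the circular mean, and the best point of a coarse
16×16 scan; the multistart matters because the periodic objective can have
distant local minima.

The event-aligned profiles sample the coarse-grained energy f_{r_avg}
(periodic disk-average of the total energy density, radius r_avg = 0.02 L,
exactly mean-preserving) at the fixed epicenter: times before t_start map
to t_rel < 0, times after t_end to t_rel > 0, and in-event samples are
excluded except for the two values at t_rel = 0 (start/end), producing the
characteristic discontinuity; in-event values are separately resampled
onto a fixed 21-point 0–100% normalised-duration grid. The alignment
window defaults to 20 time units per side; bins track their event counts.
Asymmetry is quantified by the times at which the mean profile last rises
through, and first falls back to, baseline + ¼(peak − baseline), and by
the 75%-of-peak crossings; a profile that never returns to the reference
level inside the window has a decay time bounded below by the window
length. At desk-scale event counts the peak-at-the-event property is
judged against the pre-/post-window means (single far bins are easily
contaminated by neighbouring, chained exchanges; with hundreds of pooled
events bin-wise comparisons would be appropriate). max_energy is the peak of f_{r_avg} at the
epicenter over the event's saved times; duration–energy monotonicity uses
Spearman rank correlation (the claim is monotone, not linear). Durations
get a maximum-likelihood Gamma fit with the location fixed at zero
(shape recovered within ±10% on synthetic samples of n = 2000).

Shape indices are perimeter/√area of the φ = 0 level contour (marching
squares after recentring the cell, so periodic wrapping is safe); the
diffuse estimate ∫|∇B| dx is kept as a cross-check diagnostic. Reference
values: disk 2√π, regular pentagon 3.813, square 4, all reproduced within
0.5% using sub-pixel polygon rasterisation (tanh of the exact signed
distance). The tissue flow field averages each cell's CoM velocity with
its contact-graph neighbours and interpolates periodically (3×3 tiling,
linear, nearest-neighbour fallback for degenerate geometry). Chains of
events are single-linkage clusters under (epicenter distance < r_chain,
0 < Δt_start < dt_chain).

## Four-cell exchange fixture

The deterministic fixture places four equal disks in a diamond: the lost
pair (B, D) in light contact on one diagonal, the gained pair (A, C)
separated on the other, surrounded by a frozen ring field (a non-evolving
interaction partner standing in for the surrounding tissue — without it, a
free adhesive pair equilibrates just outside the contact threshold and the
island disperses). Propulsion angles point B, D apart and A, C together;
with D_r = α = 0 the trajectory is fully deterministic and produces
exactly one detected T1 with the correct diagonals after a short passive
pre-relaxation of the assembled overlaps. Driving the same island with the
passive shear profile was tested and rejected: the linear flow disperses
the perimeter contacts before the new bond forms.

## Numerical choices and limitations

- RNG: one seed spawns independent per-cell substreams (by cell index), so
  trajectories are independent of iteration order; saved states include
  the substream states and resume bit-reproducibly up to transform
  round-off (~10⁻¹⁰).
- Isotropic cells (λ⁺ below 10⁻¹² × cell area) receive no alignment
  torque. The nematic representative is genuinely discontinuous when θ is
  exactly a quarter turn from the axis; trajectories near that set are
  sensitive to round-off (expected physics, noted for reproducibility
  tests).
- Angle differences in the orientation SDE are wrapped to (−π, π] before
  multiplying by α; θ is stored wrapped.
- Blow-up guard: |φ|_max > 5 or non-finite values abort with a diagnostic
  pointing at the time step.
- The plotted/analysed "energy" includes both the Cahn–Hilliard and the
  interaction density by default; `include_interaction=False` restricts to
  the former.
- Known limitations: the presence-factor ghost wiggle (above); desk-scale
  absolute rates are not comparable to full-scale reference values; no
  solvent hydrodynamics, growth, division or death; only T1 rearrangements
  are tracked (no T2/rosette resolution beyond the quadruple rule).
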