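# Methods

## The physical model

The *Drosophila* egg chamber is treated as a rigid ellipsoid of revolution:
the follicle cells adhere apically to the germ-cell cluster, which suppresses
neighbor exchange on the timescale of rotation initiation, so a single
angular velocity describes the whole tissue.  Lengths are measured in units
of the equatorial radius and the long (anterior–posterior, AP) axis lies
along the body-frame `z` axis, so a surface point satisfies
`x² + y² + (z/e)² = 1` with aspect ratio `e ≥ 1`.  Time is measured in units
of the characteristic rotation-initiation time; forces and concentrations
are likewise non-dimensional.

Each of the `N` cells is an anchor point `r_i` carrying

* a crawling force `b_i` tangent to the surface (protrusive activity against
  the basement membrane), and
* a Fat2 concentration field `c_i(β)` on the circle of tangent directions,
  discretized into `M` bins; `β` is measured from the meridional tangent
  `t1` (toward the anterior) to the azimuthal tangent `t2 = t1 × n̂`.

The dynamics close a three-part feedback loop:

1. **Torque balance** (overdamped, basement membrane provides the drag):
   `Π(e)·ω₃ = Σᵢ (rᵢ × bᵢ)·ẑ`, with `Π(e) = Nπ(40 + 26(e−1))/15`, so
   `Π(1) = 8Nπ/3`.  For `e > 1` elastic confinement by the basement membrane
   restricts rotation to the long axis and `ω₃` is the only degree of
   freedom.
2. **Protrusion alignment**: each cell draws a protrusion direction `β_i`
   from the distribution ∝ `c_i(β)` (inverse CDF over bins), sets
   `η_i = (cos β_i, sin β_i)` in its tangent frame, and relaxes
   `db_i/dt = −τ₁(η_i + b_i)`: the force points *away* from the
   Fat2-enriched edge (fixed point `b_i = −η_i`), because Fat2 sits at each
   cell's trailing edge and stabilizes protrusions of the cell behind.
3. **Mechanosensitive Fat2**: with rigid-body velocity `v_i = ω₃ ẑ × r_i`,
   `∂c_i(β)/∂t = −τ₂[τ₃ v_i·m(β) + c_i(β)]·c_i(β)` where
   `m(β) = cos β t1 + sin β t2`.  Fat2 grows on the trailing side
   (`v·m < 0`), saturating at `c* = −τ₃ v·m`, and decays elsewhere.

From the unpolarized state (`c = 1/2π`, `b = 0`, `ω₃ = 0`) the loop
amplifies stochastic torque fluctuations; linearizing about the decaying
uniform state shows the dipole mode of `c` grows at rate
`≈ τ₂(τ₃·Π⁻¹·N⟨ℓ²⟩/2 − 2c_iso(t))` (`ℓ` the azimuthal lever arm), which is
positive for the default parameters from `t = 0`.  The chamber settles into
sustained clockwise (`ω₃ < 0`) or counterclockwise (`ω₃ > 0`) rotation with
equal probability, with the cell-averaged Fat2 distribution peaked at
`β = −π/2` (trailing) for counterclockwise runs and `+π/2` for clockwise
runs.

### Numerical scheme

Forces and Fat2 fields are stored in each cell's *co-rotating* tangent frame
(components along `t1`, `t2`), so the advection term `ω × b` is carried by
the frame itself and never appears explicitly; tangency of `b` is exact by
construction.  Explicit Euler is used throughout — the stochasticity enters
only through the discrete resampling of `β_i`, not as white noise, so no
stochastic integrator is needed.  `dt·τ₁ ≥ 1` is rejected as unstable.
The Fat2 equation does not conserve mass; instead of renormalizing (which
would alter the dynamics) the field is floored at `c_floor = 1e-8` so the
sampling distribution stays well defined.

The β bins are built as exact mirror pairs (`β_{M−1−k} = −β_k` bitwise,
likewise their sines and cosines), which makes the reflection `β → −β` an
exact symmetry of the discretization: running the model with mirrored
protrusion draws and an identical random stream flips the sign of `ω₃`
bitwise.  This is used as a correctness check of the chiral symmetry.

Cells are placed on a deterministic Fibonacci lattice on the unit sphere,
stretched onto the ellipsoid, which gives a reproducible, approximately
equi-areal covering; a seeded tangential jitter is available but off by
default.  At the poles, where the AP axis is normal to the surface, `t1`
falls back to the body `x` axis projected onto the tangent plane.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| `e` | 1.2 | long/equatorial aspect ratio (slightly elongated chamber) |
| `N` | 200 | follicle cells |
| `τ₁` | 1 | force relaxation rate |
| `τ₂` | 1 | Fat2 turnover rate |
| `τ₃` | 20 | mechanosensitive gain |
| `dt` | 0.01 | Euler step |
| `T` | 200 | run length (rotation-time units) |
| `M` | 64 | Fat2 bins per cell |
| `resample_every` | 1 | steps between protrusion redraws |

The τ values are chosen so that the linear gain of the feedback loop exceeds
the saturation decay and symmetry breaks well within `T` (onset is typically
at `t ≈ 12–25`); symmetry breaking persists when each τ is varied four-fold
in either direction, which the acceptance suite checks.  The protrusion
persistence time is not constrained by available data; redrawing every step
is the default and the cadence is exposed as `resample_every`.

## 3-D rotation and axis selection

For a sphere (`e = 1`) the full orientation is integrated: a unit quaternion
(body→lab) advanced by the exponential map of `ω·dt` and renormalized every
step, with `ω = Σ(Rrᵢ)×(Rbᵢ)/Π(1)`.  Symmetry still breaks, but the axis is
unconstrained and an ensemble of runs produces axis directions spread over
the sphere (mean resultant length ~ `1/√n_runs`).

The stage-1 pre-stalk interface is modeled by two couplings acting on the
polar cap of half-angle `θ_s` around the fixed lab axis `e₃`:

* an elastic restoring torque `k_s (d̂₃ × ê₃)` (normal direction of the
  flattened interface behaves elastically), pinning the co-moving AP axis;
* a viscous cap drag `−μ_s Σ_cap r′ × (ω × r′)` over the cells currently in
  the cap (tangential sliding against the stationary pre-stalk cells),
  entering the mobility operator `[Π(1)·I + μ_s Σ_cap(I − r′r′ᵀ)]·ω = T`.

These functional forms are this package's own discretization of the stated
qualitative physics (elastic normal, viscous tangential, stationary
pre-stalk cells); only direction and monotonicity are treated as testable
claims, not numeric equality to any reference.  Because the crawling-force
pattern co-moves with the body while the elastic torque pins `d̂₃`, the only
rotation compatible with a stationary `d̂₃` is spin about `ê₃`; the
spontaneous rotation axis therefore converges onto the pre-stalk axis at a
rate set by `k_s/Π` (and secondarily by the drag anisotropy `∝ μ_s`).
Defaults `θ_s = π/6`, `k_s = 200`, `μ_s = 10` give alignment within a few
tens of time units; doubling `k_s` does not slow alignment, which the
acceptance suite checks as a paired comparison of ensemble median alignment
times (a single-seed comparison of this stochastic quantity would be
noise-fragile).  Runs start with `d̂₃ = ê₃`, since the flattened interface
itself defines the AP axis.

## Track and edge quantification

The analysis layer consumes plain CSV tables (one row per cell per frame;
one row per cell–cell edge) and mirrors standard live-imaging
quantifications:

* **Filtering** — per cell, only the longest run of consecutive frames is
  kept; cells with fewer than 10 consecutive frames and boundary-flagged
  cells are discarded.  "Boundary" is a caller-supplied flag (the synthetic
  generator sets it for cells within one lattice spacing of the field edge).
* **Polar order** — `α = |Σ p| / Σ|p|` over per-minute centroid
  displacements for 30 minutes; 15-second tracks are decimated to the
  one-minute grid by frame selection, not averaging.  `α` is invariant under
  global rotation and uniform rescaling of the displacements.
* **Migration rate** — per-cell path-integrated displacement divided by
  elapsed time, averaged over cells (net-displacement variant available as
  `method="net"`; which one a given reference analysis used is usually
  ambiguous, so both are exposed).
* **Planar polarity** — mean edge intensity at 0–10° to the AP axis divided
  by the mean at 80–90°, both bins closed; angles are undirected and folded
  into [0°, 90°].

`center_tracks` subtracts the per-frame mean cell position as a proxy for
tissue-mask centering.  This proxy removes *any* common translation —
including the common drift that constitutes the rotation signal itself —
whereas mask-based centering in an imaging pipeline removes only stage
drift.  It is therefore applied only on request (CLI `--center`), for
tables that still contain global field drift, and never before computing
polar order or migration rate on drift-containing data.

## Synthetic data: what it does and does not emulate

The generator produces three regimes on a jittered hexagonal lattice
(spacing 8 µm, 30-minute movies at 15-second intervals): `rotating` (common
drift of 0.2 µm/min — the typical early-stage rotation speed — plus 0.05 µm
jitter per frame), `pre_rotation` (no drift, 0.15 µm jitter: dynamic but
uncoordinated centroids) and `null_like` (no drift, 0.02 µm jitter).  A 10%
dropout fraction appears only for 3–9 consecutive frames to exercise the
track filters.  Edge tables use lognormal intensities with a prescribed
leading/lateral mean ratio and uniform edge angles.

The jitter is white and isotropic; real pre-rotation motility is
protrusion-driven and temporally correlated, boundary detection comes from
tissue masks rather than a lattice margin, and no segmentation noise or
intensity profiles along edges are modeled.  Passing tests therefore show
that the statistics recover known ground truth under clean conditions and
that the regimes separate as expected — not that the pipeline is robust to
every imaging artifact.

## Problem sizes used in the test suite

The symmetry-breaking ensemble runs 200 seeds at the default study scale
(N = 200 cells, T = 200); axis-selection ensembles use 30 seeds per
condition.  These sizes make the binomial direction test and the axis
dispersion/alignment statistics decisive while keeping the whole suite in
the tens of minutes on one core.

## Known limitations

* The tissue cannot deform; elastic confinement for `e > 1` is imposed as a
  hard 1-DOF constraint rather than a soft restoring torque.
* Fat2 acts cell-autonomously here, with no trans-cellular coupling and no
  neighbor topology.
* The pre-stalk couplings are qualitative constructions; their magnitudes
  (`k_s`, `μ_s`, `θ_s`) are not calibrated against measurements.
* Steady `|ω₃|` of the model is not calibrated to an experimental rotation
  rate; only its existence, sign statistics and parameter robustness are
  asserted.
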