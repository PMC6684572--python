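# Methods

`lrbend` simulates how a newly emerged lateral root (LR) establishes its
gravitropic set-point angle (GSA) during the ~9-hour window after emergence
(stage II), and provides the statistics used to quantify GSA phenotypes.
The premise is purely biomechanical: cells on the upper flank of the young
organ elongate up to three times faster than cells on the lower flank
(about 15 versus 5 µm/h at the epidermis), and this differential growth by
itself bends the organ from its horizontal emergence angle (90° to the
gravity vector) down toward the observed set-point angle of roughly 63°.
No gravity force, hormone field or signalling acts inside the model — the
hormone input (cytokinin-controlled cell elongation and cell number) is
encoded entirely as the asymmetry of the growth-rate field and as the
perturbation scenarios.

## The mechanical model

The organ is a rectangular grid of `n_cols × n_rows` quadrilateral cells
(default 20 × 7 cells of 10 µm × 10 µm; the tip at x = 0, the base at
x = 200 µm where the LR joins the parent root). Each cell wall is a linear
spring between two vertices. The force a wall (u, v) with resting length
L_uv and stiffness k_x exerts on u is

    F_spring = k_x (L_uv − |p_u − p_v|) (p_u − p_v)/|p_u − p_v|,

positive (pushing outward) under compression. Each cell also carries a
turgor pressure p_const that loads every one of its walls with a force
p_const · |wall| along the wall's outward normal, lumped half-and-half onto
the wall's endpoints. On interior walls the two flanking cells' pressure
contributions cancel exactly; the residual load acts on the tissue boundary
and keeps cells inflated, which is what stabilises cell shape in the
absence of diagonal shear springs. Vertices obey damped Newtonian dynamics,

    dVel_u/dt = F_u/m − β Vel_u,        dp_u/dt = Vel_u,

with point mass m = 1, damping β = 0.2, stiffness k_x = 0.9 and
p_const = 0.05 — the model's mechanical constants. The base column of
vertices is clamped in x (free in y) to represent the attachment to the
main root; the clamp is enforced by zeroing the x-components of force and
velocity, which injects no energy.

The equations are integrated with a forward Euler scheme, by default in
semi-implicit order (velocity first, then position with the new velocity)
for its better stability on oscillatory systems; pure forward order is
available behind `MechanicsParams(euler_order="forward")`. The mechanics
step `dt_mech` must satisfy the conservative stability bound
`dt < 2·min(β/k_x, 1/β)` (0.444 model-hours at the default constants),
checked at construction.

### Relaxation between growth increments

Growth and mechanics alternate: after each growth increment the mesh is
relaxed until the largest per-vertex force residual |F|/m and velocity both
drop below `equilibrium_tol` (default 1e-5). The fixed point of the update
is exact force balance regardless of `dt_mech`, so the step size affects
only how fast equilibrium is reached, not where it is. The organ's softest
mode — the overdamped swinging of the whole cantilevered strip — decays at
a rate of order ω²/β ≈ 0.01 per model-hour, which makes small mechanics
steps extremely slow to converge. The default is therefore
`dt_mech = 0.4`, just inside the stability bound; a full 9-h wild-type run
relaxed at dt = 0.1 and at dt = 0.4 gives identical results to the
reported precision (angle at 8 h 63.49° in both, fold change 2.222 in
both), confirming the step size is a pure efficiency knob. The relaxation
loop is JIT-compiled with numba; a pure-numpy reference path implements the
identical update and the test suite asserts step-level agreement between
the two.

At t = 0 the pressure slightly inflates the freshly built mesh, so the
tissue is relaxed once before the first growth step and that equilibrium is
the reference configuration: the first recorded angle is measured at
mechanical balance (and equals 90° by symmetry).

## The growth law and its calibration

Growth extends the resting length of axial wall springs only (anisotropic
growth; transverse walls and tip-zone walls never grow):

    dL/dt = L · γ(d),     γ(d) = r(d) / reference_length,
    r(d)  = r_min + d (r_max − r_min),   r_min = 5, r_max = 15 µm/h,

where d = (wall level)/n_rows is the relative flank coordinate, a material
(Lagrangian) label assigned at build time — bending therefore does not feed
back into the rate field. The instantaneous upper/lower rate ratio is
exactly r_max/r_min = 3. Each growth step multiplies the resting length by
(1 + γ dt_growth) with dt_growth = 0.003 h; a 9-h run is 3000 growth
steps.

The measured rates are absolute speeds (µm/h) while the growth law is
relative (per hour), so a conversion scale is unavoidable;
`reference_length` is that scale, and together with the grid it is the
model's only calibrated quantity. Calibration was done once, against the
two published outcomes of the wild-type organ — a set-point angle of
63 ± 3° at ~8 h and a >2-fold upper/lower cell-length asymmetry at 9 h —
and then frozen: a sweep over `n_rows` ∈ {6, 7}, `reference_length`
∈ [92, 107] and `tip_zone_length` ∈ {170, 180} showed the two targets pull
in opposite directions on a 60-µm-wide organ (6 rows), while the 70-µm
organ (7 rows) with `reference_length = 95` µm and `tip_zone_length =
180` µm meets both with margin (63.5° at 8 h, 2.22-fold at 9 h). These are
the shipped defaults; tests never re-tune them. An absolute-rate variant
(dL/dt = r(d), `mode="absolute"`) is retained for sensitivity analysis.

The `tip_zone_length` default deserves a note: 180 µm leaves two elongating
cell columns adjacent to the base. A short elongation zone is not a
numerical convenience but a geometric necessity — any growth law in which
the whole 17-column zone elongated differentially at 10 µm/h per cell
would accumulate a differential flank length of ΔS ≈ 1.4 mm by 8 h and
turn the organ through ΔS/width ≈ 20 radians. The observed ~27° of chord
rotation requires n_elong · L0 ≲ width/2, i.e. one to two 10-µm cell
columns — consistent with direct imaging of young LRs, where only the
first couple of cells behind the junction are elongating at this stage.

## Perturbation scenarios

* `wildtype` — the default field.
* `reduced_upper_elongation` — the uppermost wall level's rate scaled by
  0.9 (a 10% cut of r_max on the upper flank only; the number of affected
  levels is configurable). Final bending is reduced.
* `fewer_upper_cells` — the k tip-most elongation-zone cells of the top
  row stop elongating (k = 1 by default, configurable), emulating a
  reduced upper-flank cell number. Bending is reduced at least as much as
  wild type is bent.
* `graded_cell_number` — the cleared-cell count decreases linearly from k
  in the top row to zero in the bottom row (asymmetric meristem input).
* `symmetric` — r_max set equal to r_min; the control. The organ elongates
  but never bends (the trace stays at 90° to numerical precision).

## Angle quantification and statistics

The simulated organ's GSA is the angle between the base-to-tip axis
(centroid of the clamped vertex column to centroid of the tip column) and
the gravity vector; the flank asymmetry is the ratio of mean current axial
cell length, top elongation-zone row over bottom. For measured data, per-LR
angles are binned into the six standard categories 0–30, 31–50, 51–70,
71–90, 91–110, 111–180 degrees. Continuous angles need a boundary
convention for the printed integer labels: bins are half-open (lo, hi]
with 0 assigned to the first bin, fixed so boundary behaviour is
deterministic. Percentages are computed within each plate — the plate is
the experimental replicate unit — and summarised as mean ± SEM
(sd/√n_plates) across plates.

Distributions are compared with the two-sample Kolmogorov–Smirnov test: D
is the exact supremum of the ECDF difference over the pooled sample, and
the p-value uses the asymptotic Kolmogorov distribution at effective size
n1·n2/(n1+n2), the standard form at these sample sizes. Under the null
(both samples of 50 from one truncated normal, 2000 replicates) the
measured rejection rate at α = 0.05 is 0.036 — slightly conservative, as
expected of the asymptotic form at moderate n. A Student's t contrast of
mean GSA is included as a routine convenience wrapper.

## Synthetic phenotyping data

The generator emulates the replicate structure of plate-based GSA screens:
5 plates per accession, 16 seedlings per plate, 30–120 LRs per plate, with
per-LR angles drawn from a normal distribution truncated to [0°, 180°].
The truncated normal is the simplest unimodal family on a bounded angle
range consistent with observed category histograms; the reference-like
default (mean 62°, sd 12°) puts ≈59% of LRs in the 51–70° category.
Hypo-/hyper-responsive accessions are location shifts (e.g. ±15°). One
integer seed fully determines a dataset, including per-plate counts.

What the generator does **not** emulate: within-plate seedling effects and
plate-to-plate variance components beyond binomial sampling, measurement
error from manual angle annotation, multimodality (e.g. mixed LR stages),
and any genotype structure beyond a mean shift. Tests passing on synthetic
cohorts therefore validate the statistical machinery (binning, SEM
aggregation, KS calibration and power), not the biology of any particular
accession panel.

## Numerical choices and degenerate inputs

* Equilibrium tolerance 1e-5 on both force and velocity residuals;
  relaxation iteration cap 1e5 (a cap hit raises a non-convergence error
  reporting the residual rather than returning a half-relaxed state).
* Coincident wall endpoints and non-positive cell areas raise degenerate-
  geometry errors — a zero-length spring has no defined direction and is
  never silently treated as force-free. Cell areas are checked at every
  recorded time; all shipped scenarios keep them positive through 9 h.
* Pressure is applied per cell to every wall (interior contributions
  cancel analytically); the per-wall force is split equally between the
  two endpoints, the standard two-node lumping.
* The zone threshold compares built (material) cell-centre coordinates, so
  zone assignment is idempotent and deformation-independent.
* Growth requires a relaxed tissue (enforced; bypassable explicitly for
  unit-level use) and is multiplicative, so one step of 2·dt and two steps
  of dt agree to second order, (γ·dt)² relative.
* Bin edges at 30/50/70/90/110 are exact floats; the binning is exact for
  boundary values by construction.

## Problem sizes used by the shipped checks

The acceptance-level checks run the four scenarios at the full default
configuration (140 cells, 3000 growth steps, ~10⁷ relaxation steps per
run; ≈20–60 s per run on one core). Statistical calibration checks use
2000 null replicates at n = 50 per group (KS type-I), 200 seeded
replicates at ~200 LRs per group (power), and 10⁴-LR cohorts
(truncated-normal interval mass, ±2%).

## Known limitations

* The model is 2D and topology-fixed: no cell division, no stage III–IV
  behaviour (e.g. renewed bending after the stage II window), no contact
  with a substrate, no gravity body force.
* Cell shape stability relies on turgor alone; at much larger growth
  asymmetries than shipped, cells shear visibly before any error triggers.
* The calibration constant `reference_length` absorbs what is really a
  cell-autonomous relationship between measured elongation speed and
  relative wall extension; it is honest about being a fitted scale, and
  conclusions should rest on the comparative scenario ordering (which is
  robust to it), not on the absolute degree value alone.
* The KS p-value is asymptotic; for very small samples (n < ~10 per
  group) an exact method would be preferable.
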