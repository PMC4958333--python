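# Methods

## The division-number estimator

The trunk is approximated as a cylinder: total volume `V = π r² h` with
`r = width/2` and `h` the trunk length, and the dermis as the shell between
the surface and depth `dd`, `dv = π h (2 r·dd − dd²)`. Total fibroblast
number is taken proportional to `dv · ρ`, where ρ is the areal density
measured on fixed-thickness (60 µm) whole-mount sections in the regions
between hair follicles. A cm³ volume times a per-mm² areal density is not an
absolute cell count — the constant of proportionality is the effective
optical-section thickness — so `relative_cell_number` is documented as
returning *relative units*. The constant cancels in every `N/N0` ratio, and
the division number

```
n = log2(N / N0) = log2((dv1 · ρ1) / (dv0 · ρ0))
```

is invariant to it. Negative `n` (net cell loss) is allowed.

Aggregation follows the study design: dermis volumes are computed per animal,
averaged within each (age, sex) group of three animals, and group means are
averaged over the sexes present at an age (the adult time point is the
male/female average). Densities default to the total-dermis layer; the
`layer` parameter exposes the layer-resolved alternative because the source
reports both total and per-layer densities without stating which enters the
calculation. An optional bootstrap resamples animals within groups (and
density replicates within age × layer) and reports a percentile interval;
with n = 3 animals per group such an interval is necessarily coarse, and the
test suite only requires ≥ 80% empirical coverage at nominal 95%.

"Fold" values are reported both raw (12.889 for 2.32/0.18) and rounded to the
nearest integer (13-fold), with the raw ratio always retained.

## The expansion simulator

State is a set of cells with positions (µm) in a rectangular box whose x/y
plane is the whole-mount plane and whose z axis spans the dermal layers
(papillary, reticular, DWAT as ordered, disjoint intervals). Initialisation
is a homogeneous spatial Poisson process per layer at configurable areal
densities.

**Advection.** Tissue growth is an affine per-axis rescaling given by an
`ExpansionSchedule` (piecewise-linear scale factors vs age, normalised to 1
at the start age). Cells store reference coordinates at the schedule origin;
current coordinates are `reference × scale(age)`, so pure advection is exact
(no accumulation of per-step rounding). When a schedule is derived from
measurement tables, the axial scale is the trunk-length ratio and the lateral
scale the width ratio; the depth scale is chosen as
`(dermis-volume ratio)/(axial × lateral)` so that the box volume tracks the
cylinder-shell dermis volume exactly. The raw dermis-depth ratio would
overshoot the shell volume by ~6% (the `dd²` term), which would contaminate
closed-loop estimates of `n` with a purely geometric bookkeeping error. An
isotropic fallback (cube root of the volume ratio per axis) is provided.

**Division.** The division budget `division_rate = n` is the expected number
of doublings (log2 fold increase) per cell over the simulated interval. It is
spent at `G` evenly spaced division epochs (`G = ceil(n)` by default): at each
epoch every cell divides independently with probability
`q = 2^(n/G) − 1`, so the expected growth factor is `(1+q)^G = 2^n` exactly.
Near-synchronous epochs were chosen over a memoryless per-step hazard
deliberately: a memoryless (Yule) process makes clone sizes geometrically
distributed, and no rate choice can put more than ~35% of clones in the 4–8
cell band, whereas embryonic lineage data concentrate there. Synchronous
rounds reflect the relatively clocked cell cycles of embryonic growth while
keeping the growth law exact in expectation. Daughters inherit the clone
identity and label of the mother and are placed uniformly in a 10 µm ball
around her (about one cell diameter), clipped to the box; their layer is
re-derived from z (no active migration between layers is modelled).

**Death.** `death_rate` is the expected number of deaths per cell over the
interval, applied as a constant per-day exponential hazard in steps of at
most one day, so founder survival is `exp(−death_rate)` in expectation.

**Labelling.** At `label_age_days` the box is tiled into squares of side
`region_pitch_um` (330 µm, the scale of the dermis between adjacent hair
follicles); each tile independently labels `Poisson(labels_per_region)` of
its cells, chosen without replacement, and labelled founders receive
`clone_id = own cell_id`. If a tile holds fewer cells than drawn, all are
labelled and a warning is issued.

**Presets.** Two configurations encode the study's labelling designs.
*Neonatal (P2→P50):* division budget 1.3, death 0.02 (apoptotic fibroblasts
are nearly undetectable at any age), 12.89-fold volume expansion apportioned
from the paper-matched measurement tables, 1.5 expected labels per region
(the design labels 1–2 cells per inter-follicle region). *Embryonic
(E12.5→P2):* ages −7 to 2 days relative to birth, division budget 2.7 over
three epochs (two to three doublings, giving 4–8-cell clones), zero death,
20-fold isotropic volume growth (embryo-to-pup mass gain of this order), and
sparse labelling of 0.2 expected founders per region (well under 1% of
cells), so that founders remain separated after expansion and clone calls
rarely merge neighbouring clones. Default box sizes (1 mm² at P2, 4 mm² at
E12.5) are chosen to give a few thousand background cells and tens of clones
per run — large enough for stable statistics, small enough that the whole
test suite runs in about a minute; all sizes are configurable.

## Clone calling

The scoring rule treats labelled cells as clonally related when they are
mutually within a characteristic dermal distance. Two readings of that
criterion circulate — "260 ± 50 µm radius" and "an area of 260 µm diameter" —
so the cutoff mode is explicit: `diameter` (default, every pairwise distance
≤ 260 µm) or `radius` (≤ 2 × 260 µm), with the ±50 µm band exposed as
`tolerance_um` for sensitivity sweeps. Distances are computed in the
horizontal whole-mount (xy) plane by default, matching horizontal whole-mount
imaging; xyz is selectable.

"Contained within an area of diameter D" is implemented as a constraint on
pairwise distances (max within-group distance ≤ D), not minimum-enclosing-
circle membership; by Jung's theorem any group passing the pairwise bound
fits in a circle of diameter ≤ 2D/√3, so the rule is slightly conservative.
The partition computed is the *maximal merging* one: labelled cells are split
into connected components of the distance-threshold graph, and within each
component of up to 12 cells the exact minimum clique cover is found by
bitmask dynamic programming, with deterministic tie-breaks (fewest clones,
then smallest total within-clone pairwise distance with sums compared after
rounding to 1e-6 µm, then lexicographically smallest canonical form by cell
id). This makes the call order-independent and identical to exhaustive
enumeration on small instances — a property greedy complete-linkage
clustering cannot guarantee (chain configurations exist where the greedy cut
yields one cluster more than optimal). Components larger than 12 cells fall
back to scipy complete-linkage cut at the cutoff, which still guarantees the
pairwise bound; with the sparse labelling designs such components are rare.
Clone-call ids are the smallest member cell id.

Per-compartment clone sizes count every clone in every compartment
(papillary, reticular, DWAT, dermal papilla), including zeros, and report
mean ± sd (ddof = 1) plus a `total` row.

## Other statistics

Densities are counts in rectangular inter-follicle regions divided by region
area (mm²), averaged over regions, per layer and in total; the total equals
the sum over layers by construction. Snapshot densities for closed-loop
estimation count only cells within one 60 µm section thickness of the
surface, the same observable the whole-mount protocol measures, which keeps
the density comparable across ages as the dermis thickens. Marker fractions
are percentages with an explicit NaN for empty denominators; NaN in a marker
column is a data error. Background normalisation of mean fluorescence offers
ratio (default) and subtraction modes. Wound-section summaries report
per-wound mean ± sd of new-follicle counts and warn when a wound has fewer
than the protocol's eight sections.

## Synthetic data

Generators are pure functions of (parameters, seed) and always emit truth
labels. The paper-matched measurement preset fixes group-mean dermis volumes
at 0.18 cm³ (P2) and 2.32 cm³ (P50 male/female average) by back-solving the
shell formula for depth given plausible trunk dimensions (P2: 2.5 × 1.2 cm;
P50 male: 6.2 × 3.0 cm, female: 5.8 × 2.8 cm), and fixes the density ratio at
`2^1.3128 / (2.32/0.18) ≈ 0.19274`. Absolute densities are free parameters
(set to 1200 cells/mm² total at P2 with a 45/35/20% layer split — plausible
order of magnitude, not source values, since the source reports densities
only graphically). Noise is multiplicative Gaussian per animal and field with
the given CV. Whole-mount generation places Poisson background cells per
layer plus labelled clones whose founders keep a minimum mutual separation
(300 µm default, emulating one founder per inter-follicle region) and whose
members scatter with a configurable Gaussian spread; wound-section counts are
Poisson with configurable mean (default five per section, the neonatal wound
phenotype scale).

What the generators do *not* emulate: hair-follicle anatomy and the dermal
papilla compartment (DP columns exist but simulated clones never enter a
condensate, so DP means are zero), fibroblast heterogeneity and migration,
boundary effects of real wounds, anisotropic or spatially varying density,
and imaging artefacts (segmentation errors, optical attenuation with depth).
Passing tests therefore demonstrate internal consistency of the estimators
and simulator under the stated statistical assumptions, not fidelity to any
particular imaging dataset.

## Inference

`DivisionRateFitter` recovers the simulator's division budget from an
observed per-compartment mean-clone-size summary by 1-D grid search: each
candidate rate is simulated `reps` times with seeds derived from the fitter
seed, summaries are produced by the same clone-calling path applied to data,
and the replicate-mean summary is scored by the sum of squared differences
over shared compartments. Grid search was preferred to gradient methods
because the objective is stochastic and one-dimensional, and reporting the
full grid keeps the result exact and auditable. A bootstrap over replicate
summaries yields a CI of the argmin (bounds lie on the grid). Least squares
on compartment means is used because the observed summaries are means ± sd
with no likelihood available.

## Numerical choices and degenerate inputs

Geometry functions reject negative inputs and depths exceeding the radius;
`depth_for_volume` refuses volumes exceeding the full cylinder. Division-
estimate construction enforces `cell_ratio = volume_ratio × density_ratio`
(tolerance 1e-9 relative) and `n = log2(cell_ratio)`. Clone calling rejects
NaN coordinates and duplicated cell ids and returns an empty table for empty
input. Simulation steps are capped at one day; the per-epoch division
probability must not exceed 1 (increase `division_epochs` for large budgets).
Seeds are explicit everywhere and default to 0; identical configuration and
seed reproduce byte-identical outputs.

## Known limitations

- The cylinder model ignores limbs, tail and head curvature; it is a
  deliberate first-order geometry whose error largely cancels in ratios.
- Clone calling merges genuinely distinct clones whose founders sit within
  the cutoff; the embryonic preset keeps founders sparse so this affects only
  a few percent of calls, but dense labelling designs would need the
  tolerance sweep.
- The division budget is a single scalar shared by all layers; layer-resolved
  proliferation differences (e.g. the faster papillary turnover of young
  skin) are not modelled.
- Exact clone calling is exponential in component size and capped at 12
  cells per component; beyond that the complete-linkage fallback may produce
  slightly more clones than the optimum.
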