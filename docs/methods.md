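# Methods

This note documents the geometric definitions, the simulator's generative
model, the numerical choices, and what the synthetic data can and cannot
establish about real OCT volumes.

## Coordinate conventions and input model

A segmented volume is two node-registered height grids (ILM and anterior
LC) on the lateral raster of the scan plus an ordered BMO ring of 3D
points, all in micrometres. Node `(i, j)` sits at
`x = j·ascan_spacing`, `y = i·bscan_spacing`; larger `z` is more posterior.
Defaults describe a 73 × 384 raster with 62 µm between B-scans over a
15°×15° field. The lateral A-scan spacing is not part of the instrument
report; it defaults to 11.6 µm (making the two field extents nearly equal)
and is an explicit input rather than a hard-coded eye model, since scan
scaling varies with axial length and is often left uncorrected. Missing
delineation is NaN; the LC grid is expected to be partial (the LC is only
visible where shadowing permits).

## Morphometry

**BMO reference plane.** Orthogonal least squares (total least squares via
SVD) through all ring points; this minimizes perpendicular, not vertical,
misfit, and is deterministic. The normal is oriented toward +z (posterior),
with ties broken toward +y then +x. Fewer than 3 points or a collinear ring
(second singular value ≤ 1e−9 of the first) is a degenerate-geometry error.
The RMS perpendicular residual is recorded as a delineation-quality
diagnostic.

**BMO area.** Ring projected into the plane, expressed in an orthonormal
in-plane basis, vertices ordered by angle about the projected centroid, and
measured as polygon area (shapely), µm² → mm². Angular ordering assumes a
star-shaped ring, which holds for anatomical BMO shapes; a
self-intersecting projected ring is rejected. An inscribed n-gon
underestimates a smooth convex boundary at second order (~0.3 % at 48
vertices for an ellipse); the area converges at O(n⁻²) as the ring is
refined, which the suite verifies. Area is computed in the reference plane,
not the enface projection; the two differ by the cosine of the plane tilt.

**LCD.** For every delineated LC node whose orthogonal projection onto the
plane falls inside the BMO polygon (boundary-inclusive), the signed
perpendicular distance (positive = posterior); the mean and the sample
count are reported. Anterior excursions contribute negative distances and
are deliberately not clamped — this preserves exact linearity: shifting the
LC posteriorly by d µm moves the mean by exactly d. Missing LC is never
interpolated. Zero qualifying nodes is an error, not a zero.

**MRW.** The ILM grid is triangulated two triangles per cell, skipping any
cell touching a missing node. The neuroretinal-rim constraint is an
admissibility predicate: a triangle participates iff its centroid projects
inside the BMO polygon. Per ring point, the minimum exact point-to-triangle
distance (vectorized closest-point classification over the face, three
edge, and three vertex regions — no sampling) over admissible triangles;
the mean over the ring is reported. The centroid rule is one reasonable
mechanization of "stay within the rim" and is isolated in a single
predicate so alternatives (any-vertex, whole-triangle clipping) can be
substituted; its granularity is one grid cell, so a perpendicular foot
exactly on the rim boundary can be displaced inward by at most one cell
(≤ ~0.2 % of a 150 µm rim at default resolution). If more than 25 % of
within-BMO ILM nodes are missing, a warning is attached to the result.

**LC visibility.** The enface (lateral-projection) BMO polygon is
rasterized with cell-centre inclusion; each in-polygon cell contributes the
fraction (0, ¼, …, 1) of its four corner LC nodes that are delineated, and
visibility is the covered area as a percentage of the polygon area, clamped
to [0, 100]. The fractional-corner weighting keeps cells cut by a shadow
edge from being counted all-or-nothing; residual rasterization bias is
below 0.2 percentage points at default resolution.

All polygon membership tests in the package count boundary points as
inside (a deterministic tie-break).

## Phantoms

Phantom surfaces are perpendicular-offset fields from a tilted BMO plane:
`z(x, y) = z_plane(x, y) + D(x, y)/cos θ`, which makes the signed
plane-to-surface distance of every stored node exactly `D`. The BMO ring
lies exactly on a tilted ellipse (semi-axes a, b; tilt about the A-scan
axis). The ILM is a rim plateau `D = −rim_height` with an optional smooth
cosine cup; the LC is flat (`D = lc_depth`), tilted (an in-plane linear
gradient), or a bowl (`D = lc_depth + sag·(1 − ρ²)` with ρ the normalized
elliptical radius). LC is delineated out to ρ = 1.15 — beyond the BMO, as
in real eyes where the LC inserts into the peripapillary sclera — and LC
invisibility is one contiguous angular wedge (in the elliptic parametric
angle, so any wedge of parameter width Δt removes exactly Δt/2π of the
area), mimicking vascular shadowing rather than i.i.d. dropout.

Ground truth: BMO area = πab exactly; LCD = lc_depth for flat offsets
(every node exact, so recovery is machine-precision), lc_depth + sag/2 for
the bowl (E[1−ρ²] = ½ over any angular sector of the ellipse, so the shadow
wedge does not move it), and a dense numerical integral over the *visible*
region for the tilted LC (whose mean does depend on the wedge); MRW =
rim_height for a flat ILM and otherwise a 10×-oversampled point-cloud
minimum-distance oracle that applies the same in-plane rim restriction.
Surface noise, when enabled, perturbs only the height grids; recorded truth
always refers to the noise-free geometry. Identical seeds give bit-identical
volumes.

## Cohort simulator

The simulator reproduces the *design* of a two-group primate microbead
study and the effect sizes of its printed summaries; it is a statistical
emulator, not an aqueous-outflow model.

**IOP.** Each eye draws a baseline level (default N(13, 2²) mmHg). An
injection at week w_i contributes `injection_effect·(1 − e^{−(w−w_i)/τ})`
mmHg — beads occlude the trabecular meshwork with a first-order delay
(τ = 2.5 weeks, injection_effect = 6 mmHg) — and the summed response is
capped at the group plateau (43 mmHg group 1, 31 mmHg group 2). An
injection is scheduled whenever the previous week's *measured* IOP is below
the group re-injection threshold (30 / 20 mmHg), at most once per week,
matching the weekly tonometry cadence. The delayed response is what makes
induction take ~6 injections over ~4–5 weeks in both groups even though
group 2's threshold sits only a few mmHg above baseline; an
instantaneous-effect staircase cannot reproduce both groups with one
per-injection effect. Weekly readings add Gaussian noise with
`SD = tonometry_noise_sd + cv·(level − baseline)` (defaults 1 mmHg and
0.25): hypertensive eyes fluctuate strongly week to week, which is what
separates the monthly-maximum from the monthly-mean IOP (≈50 vs ≈42 mmHg in
simulated group-1 eyes) and matches the order of the per-animal weekly SDs.
Untreated fellow eyes get a consensual rise saturating at +6 mmHg
(switchable off). OHT onset is the first week starting a run of
`run_length` readings above 20 mmHg; "more than two consecutive readings"
is read as run_length = 3 (configurable, since ≥ 2 is also defensible).
Raising the threshold can never give an earlier onset (a tested
invariant).

**Structure.** Monthly MRW/LCD start at per-eye baselines (278.8 ± 39.2 and
203.0 ± 44.2 µm) and evolve by interval increments
`Δ = shape(m) + slope·(eye's monthly mean IOP − arm's noise-free expected
IOP) + ε`. The deterministic shape is concentrated entirely in the
month-1→2 interval of OHT eyes (−93 µm MRW, +86 µm LCD — the interval in
which onset falls), making those parameters direct Monte-Carlo recovery
targets; the IOP-deviation coupling (−2 µm/mmHg MRW, +1.5 µm/mmHg LCD,
concurrent month by default with an optional lag) ties an individual eye's
structural course to its own pressure history, which is what the partial
correlation detects. ε uses the interval-specific SDs (42 / 79.6 µm at
month 1→2; 25 / 30 µm drift elsewhere). Setting the shape means, the
slopes, and the noise SDs to zero yields trajectories constant at baseline.
Both OHT groups share the same shape; the study's smaller group-2
magnitudes are not a calibration target. Monthly IOP summaries come from
the same weekly series via the 4-week aggregation below. A global seed fans
out to per-eye substreams (SeedSequence spawning), so cohorts are
bit-reproducible and adding eyes does not perturb earlier ones.

## Longitudinal statistics

Months are fixed 4-week blocks anchored at the first post-baseline week
(week 0 is the baseline visit and becomes month 0); the monthly mean and
maximum are taken over the readings present, and empty months are omitted.
The sustained-OHT summary averages the monthly means and monthly maxima
over months 2–7. Per-interval change statistics use per-eye differences
with sample SD (n−1) and a two-sided paired t-test; a zero-variance
interval reports p = 1 with a flag. Group summaries are mean and sample SD
of the selected rows (SD = 0 for a single row, flag-free by convention).

The partial correlation residualizes x and y on subject indicators
(equivalently within-subject centring) and correlates the residuals;
df = n_obs − n_subjects − 1, collapsing to the ordinary Pearson df of n − 2
for one subject. Fisher's z uses n_controls = n_subjects − 1 indicator
covariates: `z = atanh(ρ̂)·√(n_obs − n_controls − 3)`, two-sided normal
p-value; |ρ̂| = 1 is reported as infinite z with p = 0 and a saturation
flag. Under a simulated null (16 subjects × 7 visits) the empirical type-I
error at α = 0.05 is nominal within Monte-Carlo tolerance (verified at
2000 replicates). The source study fit repeated-measures mixed models for
its group contrasts; this package substitutes paired t-tests, so printed
mixed-model p-values are not reproduction targets — sign and ordering
patterns are. Tests are two-sided throughout and no multiplicity
correction is applied, matching the study's analysis.

## Problem sizes and determinism

Default verification sizes, chosen to keep the full suite fast while
leaving Monte-Carlo error well inside the asserted bands: 100 seeds for
IOP-series calibration, 200 cohorts for the month-1→2 parameter recovery
(SE of the mean ≈ 0.7 µm) and the correlation-sign check, 2000 replicates
for the type-I calibration (SE ≈ 0.005), 10× oversampling for the
brute-force morphometry oracles. The acceptance script derives every
stream from its `--seed` via stage-hashed substreams.

## What the synthetic data does not show

Phantoms are smooth, noise-controlled surfaces with an exactly elliptical
BMO: passing parameter recovery bounds discretization and algorithmic
error, but says nothing about segmentation error, motion artefact, shadow
compensation, or anatomically irregular rings. The cohort simulator
reproduces summary-level structure (inter-eye variance, onset timing,
effect sizes), not bead biophysics, diurnal IOP cycles, or the
within-month correlation structure of real tonometry; its trajectories are
piecewise-stationary apart from the month-1→2 step, whereas real eyes show
(smaller) continuing drift. Fellow-eye baselines are drawn independently
per eye, so within-primate baseline correlation is not emulated.
Accordingly, agreement of the simulator-derived statistics with the study's
printed tables validates the *pipeline*, not the biology.
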