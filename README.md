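# onh — optic nerve head morphometry and longitudinal OHT analysis

Tools for quantifying pressure-induced structural change at the optic nerve
head (ONH), written for researchers working with segmented OCT volumes from
experimental ocular-hypertension (OHT) studies — in particular the
non-human-primate microbead model, where repeated intracameral microbead
injections elevate intraocular pressure (IOP) and the ONH is imaged monthly.

Glaucomatous damage begins at the ONH: the neuroretinal rim thins and the
lamina cribrosa (LC) bows posteriorly before any visual-field loss is
measurable. The package computes the two OCT measures that capture this,
plus the longitudinal statistics used to relate them to IOP:

* **BMO-MRW** (minimum rim width): for each point of the Bruch's membrane
  opening (BMO) ring, the shortest Euclidean distance to the internal
  limiting membrane (ILM), constrained to stay within the neuroretinal rim;
  the per-volume value is the mean over the ring,
  `MRW = (1/N) Σᵢ min_{q ∈ ILM∩rim} ‖bᵢ − q‖`.
* **LCD** (lamina cribrosa depth): the mean signed perpendicular distance
  from the BMO reference plane (orthogonal least-squares fit through the
  ring) to the delineated anterior LC surface, positive = posterior.
* **BMO area** (shoelace polygon area of the ring projected into the
  reference plane) and **LC visibility** (delineated fraction of the enface
  BMO area, in percent).
* **Cohort statistics**: weekly tonometry aggregated to monthly mean/max
  IOP, per-interval structural-change statistics, and the Pearson partial
  correlation `ρ̂_{XY·primate}` between IOP summaries and structure,
  residualizing on primate to respect the repeated-measures design, with
  Fisher's z test `z = atanh(ρ̂)·√(n − k − 3)` of `ρ = 0`.

Because delineated primate OCT volumes are not publicly distributable, the
package ships two fully synthetic data sources that make every stage
testable end to end: analytic **phantoms** (elliptical BMO in a tilted
plane, rim+cup ILM, flat/tilted/bowl LC with a shadow wedge) whose four
measures have closed-form or densely integrated ground truth, and a
two-group **cohort simulator** (10 unilateral-OHT primates with fellow-eye
controls + 6 bilateral-OHT primates, 28 weekly visits, injection scheduling
against per-group re-injection thresholds). The per-animal summary tables
of the source study are packaged as checksum-pinned CSV fixtures.

## Worked example

```python
from onh import PhantomParams, make_phantom_volume, measure_volume

params = PhantomParams(bmo_tilt_deg=5.0, lc_shape="bowl", cup_depth=300.0, seed=1)
volume, truth = make_phantom_volume(params)
print(measure_volume(volume))
```

Running `python examples/phantom_morphometry.py` (the same computation,
formatted) prints:

```
measure                   estimate       truth   rel err
mean MRW (um)              279.519     279.727    -0.07%
mean LCD (um)              233.221     233.000    +0.09%
BMO area (mm^2)              2.634       2.641    -0.29%
LC visibility (%)           89.834      90.000    -0.18%
```

The estimates recover the phantom's analytic truth to a fraction of a
percent: the MRW via exact point-to-triangle distances on the triangulated
ILM, the LCD as the mean plane-to-surface distance (233 µm = 203 µm depth
+ half the 60 µm bowl sag), the BMO area up to the polygon-inscription
deficit of the 48-vertex ring, and visibility up to rasterization of the
10%-missing shadow wedge.

`python examples/longitudinal_analysis.py` simulates a cohort and prints the
per-interval changes and primate-controlled correlations, e.g.

```
   1 -> 2        -86.7    50.6   0.0000          74.3    67.1   0.0005
  ...
  mean_iop vs mrw:  rho = -0.649   z = -7.49   p = 6.80e-14   (n_obs=112, df=95)
```

— the rim thins most between months 1 and 2 (the interval in which OHT
onset falls) and monthly IOP correlates negatively with rim width and
positively with LC depth across the 16 OHT right eyes × 7 months.

Other entry points: `examples/cohort_simulation.py` (weekly IOP traces,
injection scheduling, onset detection), `examples/study_tables.py` (group
summaries recomputed from the packaged per-animal tables), and the `onh`
CLI (`onh simulate-cohort`, `onh measure`, `onh run`, ...) for shell
pipelines; every CLI run writes a manifest with the config digest and seed.

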