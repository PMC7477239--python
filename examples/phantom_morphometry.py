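"""Measure an analytic ONH phantom and compare against its known truth.

Builds a phantom eye (elliptical BMO, flat lamina cribrosa 203 um behind
the BMO plane, 90% LC visibility), runs the full morphometry chain, and
prints estimate vs truth for the four structural measures.
"""

from onh import PhantomParams, make_phantom_volume, measure_volume

params = PhantomParams(bmo_tilt_deg=5.0, lc_shape="bowl", cup_depth=300.0, seed=1)
volume, truth = make_phantom_volume(params)
result = measure_volume(volume)

print(f"{'measure':<22}{'estimate':>12}{'truth':>12}{'rel err':>10}")
rows = [
    ("mean MRW (um)", result.mean_mrw, truth.true_mean_mrw),
    ("mean LCD (um)", result.mean_lcd, truth.true_mean_lcd),
    ("BMO area (mm^2)", result.bmo_area, truth.true_bmo_area),
    ("LC visibility (%)", result.lc_visibility, truth.true_lc_visibility),
]
for name, est, ref in rows:
    print(f"{name:<22}{est:>12.3f}{ref:>12.3f}{(est - ref) / ref:>+10.2%}")
print(
    f"\n{result.n_lcd_samples} LC nodes inside the BMO polygon, "
    f"{result.n_bmo_points} BMO ring points."
)
print(
    "Sub-percent agreement on every measure is what the parameter-recovery\n"
    "suite asserts; the BMO-area deficit is the polygon inscribed in the\n"
    "true ellipse."
)
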