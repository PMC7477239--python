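"""Monthly structural-change statistics and primate-controlled correlations.

Simulates a cohort, tabulates per-interval MRW/LCD changes of the OHT right
eyes, and computes the Pearson partial correlation (controlling for primate)
between monthly IOP summaries and the structural measures, with Fisher z
inference.
"""

import dataclasses

from onh import CohortParams, generate_cohort, monthly_change, partial_correlation

table = generate_cohort(dataclasses.replace(CohortParams(), seed=11))

print("monthly change, OHT right eyes (n = 16):")
print(f"{'interval':>10}{'d MRW (um)':>12}{'sd':>8}{'p':>9}   {'d LCD (um)':>11}{'sd':>8}{'p':>9}")
mrw = monthly_change(table, "mrw", "oht_right")
lcd = monthly_change(table, "lcd", "oht_right")
for m, l in zip(mrw, lcd):
    print(
        f"{m.interval[0]:>4} -> {m.interval[1]:<3}"
        f"{m.mean_change:>11.1f}{m.sd_change:>8.1f}{m.p_value:>9.4f}   "
        f"{l.mean_change:>11.1f}{l.sd_change:>8.1f}{l.p_value:>9.4f}"
    )

oht = table[(table.treatment == "OHT") & (table.eye == "OD") & table.month.between(1, 7)]
print("\npartial correlation over months 1-7 (16 right OHT eyes, controlling for primate):")
for x in ("mean_iop", "max_iop"):
    for y in ("mrw", "lcd"):
        r = partial_correlation(oht[x], oht[y], oht["primate_id"])
        print(f"  {x:>8} vs {y:>3}:  rho = {r.rho_hat:+.3f}   z = {r.z_stat:+.2f}   "
              f"p = {r.p_value:.2e}   (n_obs={r.n_obs}, df={r.df})")
print("\nNegative rho for MRW (rim thins as pressure rises), positive for LCD")
print("(lamina bows posteriorly); the largest mean change sits in month 1->2.")
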