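"""Compute CERT1 and CERT2 risk scores for a simulated cohort.

Each score sums quartile points over lipid components: CERT1 over six
ceramide concentrations/ratios (0/0/1/2 points per quartile), CERT2 over
four ceramide- and phosphatidylcholine-based components (0/1/2/3 points).
Both totals live on a 0-12 scale and map to four CVD risk categories.
"""

import certscore as cs

cohort = cs.simulate_cohort(cs.default_finrisk_config(n_subjects=5000, seed=1))

for name in ("CERT1", "CERT2"):
    scores, bounds = cs.score_cohort(cohort, name)
    print(f"{name}: mean total {scores['total'].mean():.2f}, "
          f"range {scores['total'].min()}-{scores['total'].max()}")
    shares = scores["category"].value_counts(normalize=True)
    print("  categories:",
          ", ".join(f"{c} {100 * shares.get(c, 0):.1f}%"
                    for c in ("low", "moderate", "increased", "high")))
    first = next(iter(bounds.values()))
    print(f"  e.g. quartile cuts for {first.component_name}: "
          f"{first.cuts[0]:.3f} / {first.cuts[1]:.3f} / {first.cuts[2]:.3f}")
# Quartile boundaries are fitted on this cohort; pass
# bounds_source="external_reference" to apply frozen published cut-points.
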