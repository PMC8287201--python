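"""Reproduce the published per-subject coordinate-table statistics.

Loads the packaged cohort tables (13 patients, 8 elderly controls), checks
every printed distance column for Euclidean consistency by trilateration,
repairs the one control row whose printed coordinate contradicts its own
distance cells, and recomputes the pairwise-distance medians and the exact
one-sided Wilcoxon focality tests (12 mm conservative / 20 mm lenient).
"""

import json

from netarget.coord_eval import wilcoxon_one_sample
from netarget.tables import distance_column, load_target_table, reproduce_tables

report = reproduce_tables()

for group, name in (("ad", "patients"), ("hc", "controls")):
    for target in ("ipl", "dlpfc"):
        entry = report[group][target]
        print(f"{name} {target.upper()}: pairwise median "
              f"{entry['pairwise_median']} mm (printed {entry['printed_median']}, "
              f"match={entry['median_matches']})")
        for row in entry["repaired_rows"]:
            print(f"   repaired {row['subject']}: {row['printed']} -> "
                  f"{row['repaired']} (from columns {row['columns_used']})")
        for ref, col in entry["columns"].items():
            print(f"   vs {ref}: {col['status']}", end="")
            if col["status"] != "inconsistent":
                print(f", recomputed median {col['recomputed_median']} mm, "
                      f"reference {col['reference_mm']}", end="")
            print()

ad = load_target_table("ad")
for mu in (12.0, 20.0):
    res = wilcoxon_one_sample(distance_column(ad, "P3"), mu=mu,
                              alternative="greater")
    print(f"patients vs P3, focality {mu:.0f} mm: exact one-sided "
          f"p = {res.p_value:.4f} (W+ = {res.statistic:.0f}, n = {res.n})")

print()
print("Interpretation: a distance column is 'consistent' when a single")
print("reference point reproduces every printed cell to <0.01 mm rms; the")
print("patient BA46 column must appear 'inconsistent' (five of its cells")
print("duplicate the 5-cm column). p < 0.05 at 12 mm means the individual")
print("targets sit farther from the group coordinate than a conservative")
print("TMS focality, i.e. group-level targeting would miss them.")
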