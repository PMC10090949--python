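"""Proteomics-side validation statistics on a synthetic spectral-count set.

Generates a small salinity experiment (two groups of three samples),
normalizes the counts Scaffold-style, screens for differential expression
with one-way ANOVA, and reports a category weight fraction.
"""

from natrigem.proteomics import (category_weight_fraction,
                                 differential_expression, normalize_counts)
from natrigem.synthetic import make_synthetic_proteome

table = make_synthetic_proteome(
    shares={"ectA": 0.05, "rplA": 0.20, "enzB": 0.75},
    masses={"ectA": 30.0, "rplA": 25.0, "enzB": 50.0},
    lengths={"ectA": 270.0, "rplA": 225.0, "enzB": 450.0},
    categories={"rplA": "translational machinery"},
    total_counts=20_000, n_samples=6,
    group_effects={"ectA": 4.0},  # osmolyte-pathway induction at 300 mM
    seed=7)

norm = normalize_counts(table)
print("sample totals after normalization:",
      [f"{t:.0f}" for t in norm.counts.sum(axis=1)])

de = differential_expression(norm, "salinity_mM", 0, 300)
low = norm.counts[norm.sample_meta["salinity_mM"] == 0].mean()
high = norm.counts[norm.sample_meta["salinity_mM"] == 300].mean()
for prot, row in de.iterrows():
    print(f"  {prot}: F = {row['F']:8.2f}  p = {row['p']:.2e}  "
          f"fold = {high[prot] / low[prot]:.2f}")
print("the induced protein shows the expected ~4-fold shift; the others "
      "move slightly the opposite way because spectral counts are "
      "compositional (shares must sum to one), which is why they also "
      "reach small p at this depth. The ANOVA is applied per protein "
      "without multiple-testing correction.")

frac = category_weight_fraction(norm, "sample0", "translational machinery")
print(f"\ntranslational machinery weight fraction in sample0: {frac:.1f}% "
      "(generated from a 20% mass share)")
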