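"""ADME-screen the packaged four-herb component table and summarize descriptors.

Loads the 114-row component table shipped with the package, applies the
OB >= 30% / DL >= 0.14 activity screen, and prints per-herb retention and
descriptor means. The unique-name count is lower than the row count because
several components (berberine, coptisine, quercetin, ...) occur in more
than one herb.
"""

from formularank import herb_property_summary, load_formula_fixture, screen_adme

records = load_formula_fixture()
result = screen_adme(records, ob_min=30.0, dl_min=0.14)

print(f"components: {len(records)} rows, {result.n_retained} retained, "
      f"{len(result.unique_retained_names)} unique active names")
for herb, count in sorted(result.per_herb_retained.items()):
    print(f"  {herb:10s} {count:3d} retained")

summary = herb_property_summary(records)
print("\nmean OB% / DL per herb (n rows):")
for herb in sorted(summary.means):
    m = summary.means[herb]
    print(f"  {herb:10s} OB {m['ob']:6.2f}  DL {m['dl']:.3f}  (n={summary.counts[herb]['ob']})")
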