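"""Hypergeometric pathway enrichment with BH-FDR on a synthetic bundle.

Generates the default four-herb bundle, enriches the union of all herb
targets against its pathway collection, and reports each herb's target
contribution to the top enriched pathways — the fraction of the herb's
targets that fall inside the union of those pathways' genes.
"""

from formularank import (build_ct, default_formula_spec, hypergeom_enrich,
                         make_toy_formula, merge_ctp, screen_adme,
                         top_pathway_contribution)

bundle = make_toy_formula(default_formula_spec(seed=7))
screen = screen_adme(bundle.components)
ctp = merge_ctp(build_ct(screen.retained, bundle.target_map), bundle.ppi)

all_targets = frozenset().union(*ctp.herb_targets.values())
results = hypergeom_enrich(all_targets, bundle.gene_sets)
print("pathway        k/K      p          q")
for r in results[:6]:
    print(f"{r.pathway:12s} {r.k:3d}/{r.K:<3d}  {r.p:9.3g}  {r.q:9.3g}")

contrib = top_pathway_contribution(ctp.herb_targets, results, bundle.gene_sets, k_top=4)
print("\ntarget contribution to top enriched pathways:")
for herb, frac in contrib.items():
    print(f"  {herb}: {100 * frac:.1f}% of targets inside the top-pathway union")
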