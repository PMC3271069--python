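"""Classify alignment hits by phylum and modularize a reference network.

Reproduces the six-query ribosomal example (3 Proteobacteria, 1 each of
Cyanobacteria, Planctomycetes, Bacteroidetes) at the 1e-50 E-value
threshold, then reduces a small all-vs-all similarity graph to its
module representatives.
"""

from ecomics.eclass import assign_queries, modularize, summarize_composition
from ecomics.fixtures import gen_hit_table, gen_similarity_graph

hits, taxa = gen_hit_table(
    {"Proteobacteria": 3, "Cyanobacteria": 1, "Planctomycetes": 1, "Bacteroidetes": 1},
    seed=0,
)
assigned = assign_queries(hits, taxa, e_threshold=1e-50, rank="phylum")
summary = summarize_composition(assigned)
print("phylum composition of the 6 queries:")
for label in summary.ordered_labels():
    print(f"  {label:15s} {summary.counts[label]}  ({100 * summary.fractions()[label]:.1f}%)")
# half the queries land in Proteobacteria, matching the planted 3:1:1:1 mix.

graph, _ = gen_similarity_graph([6, 4, 3, 1, 1], hub_per_module=True, seed=1)
mods = modularize(graph)
print(f"\nmodularization: {mods.n_nodes} sequences -> {mods.n_modules} modules "
      f"(reduction ratio {mods.reduction_ratio:.3f})")
print("representatives:", ", ".join(mods.representatives))
# each representative is its module's most-connected member (the planted
# hub); querying against representatives instead of all sequences is what
# makes the reduced database fast.
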