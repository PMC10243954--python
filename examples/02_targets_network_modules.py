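"""From target lists to a PPI network, key targets and dense modules.

Builds drug and disease target sets from synthetic association tables,
intersects them, assembles the confidence-filtered interaction network, and
extracts key targets (degree and betweenness both above twice the median)
plus densely connected modules with the MCODE procedure.
"""

from netpharm.mcode import mcode_find_complexes
from netpharm.netcore import build_network, centralities, key_targets, network_stats
from netpharm.synth import (SyntheticConfig, gen_disease_genes, gen_ppi,
                            gen_target_associations)
from netpharm.targets import common_targets, disease_targets, drug_targets
from netpharm.io import EdgeRecord

config = SyntheticConfig(seed=7)

drug = drug_targets(gen_target_associations(config))
disease = disease_targets(gen_disease_genes(config), genecards_top_fraction=0.5)
common = common_targets(drug, disease)
print(f"{len(drug)} drug targets, {len(disease)} disease targets, "
      f"{len(common)} in common")

planted = gen_ppi(config)
edges = [EdgeRecord(u, v, d["confidence"])
         for u, v, d in planted.network.edges(data=True)]
network = build_network(edges, min_confidence=0.4)
stats = network_stats(network)
print(f"network: {stats['n_nodes']} nodes, {stats['n_edges']} edges, "
      f"average degree {stats['average_degree']:.1f}, "
      f"clustering {stats['average_clustering']:.3f}")

keys = key_targets(centralities(network))
print(f"key targets ({len(keys)}): {sorted(keys)[:10]} ...")

complexes = mcode_find_complexes(network)
print(f"\nMCODE found {len(complexes)} complexes; top three:")
for i, c in enumerate(complexes[:3], 1):
    print(f"  #{i} score={c.score:.2f} size={len(c.members)} "
          f"members={sorted(c.members)}")
print(f"planted 5-clique: {sorted(planted.clique)}")
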