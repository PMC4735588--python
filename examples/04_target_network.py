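"""Build the anti-correlated miRNA-mRNA regulatory network.

Simulates an integrated target-prediction export (true planted regulations
mixed with decoys), applies the three filters — >= 3 predicting sources,
integrated score >= 40, target expressed in blood — plus the opposite-fold-
change filter, and assembles the annotated bipartite graph.
"""

from sncmirror import (
    CohortConfig, anticorrelation_filter, build_network, expression_filter,
    filter_predictions, simulate_cohort, simulate_predictions,
)

cfg = CohortConfig(
    n_patients=13, n_controls=13, n_probes=300, sex_ratio=1.0,
    n_de_relapse_f=10, n_de_remission_f=10, n_de_remission_m=0, n_mirror=8,
    effect_log2=2.0, noise_sd=0.3, seed=42,
)
_, truth = simulate_cohort(cfg)
records = simulate_predictions(truth, n_decoys=200, seed=1)
print(f"prediction table: {len(records)} records "
      f"({len(truth.regulation_pairs)} true, 200 decoys)")

kept = filter_predictions(records, min_sources=3, min_score=40)
print(f"after source/score filters: {len(kept)}")
expressed = set(truth.gene_log2_fc)
kept = expression_filter(kept, expressed)
print(f"after blood-expression filter: {len(kept)}")
kept = anticorrelation_filter(kept, truth.mirna_log2_fc, truth.gene_log2_fc)
print(f"after opposite-fold-change filter: {len(kept)}")

genes = sorted(expressed)
net = build_network(kept, tf_set=set(genes[::5]), gwas_set=set(genes[::7]),
                    mirna_fc=truth.mirna_log2_fc, gene_fc=truth.gene_log2_fc)
nt = net.node_table
print(f"\nnetwork: {net.n_nodes} nodes ({int((nt.kind == 'miRNA').sum())} miRNA, "
      f"{int((nt.kind == 'TF').sum())} TF, {int((nt.kind == 'gene').sum())} gene), "
      f"{net.n_edges} edges, {net.n_components} components")
print("most connected nodes:")
print(nt.sort_values('degree', ascending=False).head(5).to_string())
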