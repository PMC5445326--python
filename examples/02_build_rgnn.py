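"""From a synthetic enzyme family to a refined genome neighborhood network.

Generates two planted sequence clusters (200 sequences each) whose genomes
carry cluster-specific operon Pfams near the target gene, then runs the
full pipeline: threshold profile -> S-Th -> clustering -> neighborhood
extraction -> GNN at a 20% co-occurrence limit -> uniqueness statistics.
"""

from rgnn import (
    SyntheticSpec,
    apply_threshold,
    build_gnn,
    cluster_components,
    compute_s_th,
    compute_threshold_profile,
    compute_uniqueness,
    extract_neighborhoods,
    generate,
)

spec = SyntheticSpec(seed=1)  # 2 clusters x 200 sequences, operon inclusion 0.6
data = generate(spec)
print(f"SSN: {data.ssn.n_nodes} nodes, {data.ssn.n_edges} edges")

profile = compute_threshold_profile(data.ssn)
s_th = compute_s_th(profile)
print(f"S-Th = {s_th} (intra-cluster scores span 90-100, inter-cluster 20-40)")

assignment = cluster_components(apply_threshold(data.ssn, s_th))
print(f"clusters: {{id: SeqCount}} = { {c.id: c.seq_count for c in assignment.clusters.values()} }")

records = extract_neighborhoods(data.genomes, set(data.truth.cluster_of), nb=3)
gnn = build_gnn(assignment, records, cooccurrence_limit=20)
report = compute_uniqueness(gnn, assignment)

print("\ncluster  pfam     k    coverage  uniqueness")
for (cid, pfam), edge in sorted(gnn.edges.items()):
    print(f"{cid:<8} {pfam}  {edge.supporting_count:<4} {edge.coverage:<9.3f} {edge.uniqueness:.1f}")
print("\nEach cluster links only to its own planted operon Pfams; coverage")
print("scatters around the planted inclusion probability 0.6, and the large")
print("uniqueness values reflect Pfams occurring exclusively in one cluster.")
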