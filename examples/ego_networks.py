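"""Local (ego) and intersection networks around seed genes.

Builds a small table where three genes share the seed's mutation profile
exactly, thresholds the distance matrix at 0 ("very similar": identical
conditional profiles), and exports the local network for Gephi.
"""

from pathlib import Path

from cooccnet import (
    MutationRecord,
    MutationTable,
    build_network,
    ego_network,
    export_network,
    intersection_network,
    pairwise_distance_matrix,
)

rows = []
for g in ["SEED", "ALG8", "KAT7", "ZNF34"]:  # identical profiles
    rows += [(g, "Missense", "G>C"), (g, "Missense", "G>C")]
rows += [("ACAN", "Silent", "A>G")]  # a gene with a different profile
rows += [("OTHR", "Silent", "A>G")]  # ... shared with one more gene

table = MutationTable(
    records=[
        MutationRecord(g, {"mutation_type": m, "nucleotide_change": n})
        for g, m, n in rows
    ],
    attribute_names=["mutation_type", "nucleotide_change"],
)
matrix = pairwise_distance_matrix(table)

ego = ego_network(matrix, "SEED", threshold=0.0, include_neighbor_edges=True)
print(f"ego network of SEED at threshold 0: nodes={ego.nodes}, edges={ego.n_edges}")
# ALG8, KAT7 and ZNF34 have exactly SEED's profile, so they join the
# local network; ACAN and OTHR (silent A>G) do not.

inter = intersection_network(matrix, "ACAN", "OTHR", threshold=0.0)
print(f"genes similar to both ACAN and OTHR: {[g for g in inter.nodes if g not in ('ACAN', 'OTHR')]}")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
export_network(ego, out / "ego_seed.gexf", "gexf")
export_network(build_network(matrix, 0.5), out / "global_t0.5.tsv", "tsv")
print(f"wrote {out / 'ego_seed.gexf'} (open in Gephi) and {out / 'global_t0.5.tsv'}")
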