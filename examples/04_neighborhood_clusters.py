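"""Recover the conserved locus around secondary SecA_DEAD genes.

Extracts the +/-10-gene window around each planted secondary copy,
single-linkage clusters the window proteins at 25% identity / 0.60
coverage, and tabulates which clusters recur across neighborhoods.
"""

from pathlib import Path

from seclocus import (
    ClusteringParams,
    SimulationConfig,
    conservation_report,
    extract_windows,
    generate_pangenome,
    generate_similarity_table,
    single_linkage,
)
from seclocus.io_formats import read_gene_order

cfg = SimulationConfig(rng_seed=42)
bundle, truth = generate_pangenome(cfg)
outdir = Path("scratch/example_bundle")
bundle.write(outdir)

order = read_gene_order(outdir / "genes.gff")
windows = extract_windows(order, truth.secondary_ids, w=10)
members = sorted(set().union(*(w.member_ids for w in windows)))
edges = generate_similarity_table(truth, cfg)

clusters = single_linkage(members, edges, ClusteringParams(25.0, 0.60))
report = conservation_report(clusters, windows, {m: m.split("|")[0] for m in members})

print(f"windows extracted: {len(windows)}; window proteins: {len(members)}")
print(f"clusters formed:   {len(clusters)}")
print(report.head(4).to_string(index=False))
# The three leading clusters recur in every one of the 12 focal
# neighborhoods (n_windows = 12) — the planted partner families; the
# offset column shows where each member sits relative to the focal gene.
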