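"""Gene-neighborhood windows and threshold-graph single-linkage clustering.

The genomic neighborhood of a focal gene is the up to 10 genes on each
side of it by rank on the same replicon (strand-agnostic; windows truncate
at the ends of linear replicons and wrap on circular ones). Proteins drawn
from many such windows are grouped by single-linkage clustering of a
pairwise-similarity threshold graph: an edge survives iff its percent
identity and alignment coverage both meet the thresholds (inclusive), and
clusters are the connected components — so any above-threshold link merges
two groups, mirroring blastclust.

Two threshold presets matter in practice: 25% identity / 0.60 coverage for
neighborhood proteins, and 80% identity / 0.85 coverage for dereplicating
genomes by a single-copy marker gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import GeneOrder, ProteinRecord, SimilarityEdge

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWYX"


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborhoodWindow:
    """A focal protein and its rank-offset neighbors on one replicon."""

    focal_protein_id: str
    genome_id: str
    replicon_id: str
    neighbors: tuple[tuple[str, int], ...]  # (protein_id, signed offset)

    def __post_init__(self) -> None:
        offsets = [off for _pid, off in self.neighbors]
        if len(set(offsets)) != len(offsets):
            raise ValueError("duplicate offsets in window")
        if any(off == 0 for off in offsets):
            raise ValueError("offset 0 is the focal protein itself")
        if len(self.neighbors) > 20:
            raise ValueError("more than 20 neighbors in a +/-10 window")

    @property
    def member_ids(self) -> set[str]:
        return {pid for pid, _off in self.neighbors}


@dataclass(frozen=True)
class ClusteringParams:
    """Inclusive identity/coverage thresholds for the edge filter."""

    identity_threshold: float = 25.0
    coverage_threshold: float = 0.60
    coverage_rule: str = "both"

    def __post_init__(self) -> None:
        if not 0 <= self.identity_threshold <= 100:
            raise ValueError("identity_threshold outside [0, 100]")
        if not 0 <= self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold outside [0, 1]")
        if self.coverage_rule not in {"both", "either"}:
            raise ValueError("coverage_rule must be 'both' or 'either'")

    def keeps(self, edge: SimilarityEdge) -> bool:
        if edge.percent_identity < self.identity_threshold:
            return False
        if self.coverage_rule == "both":
            return min(edge.coverage_a, edge.coverage_b) >= self.coverage_threshold
        return max(edge.coverage_a, edge.coverage_b) >= self.coverage_threshold


DEREPLICATION_PARAMS = ClusteringParams(80.0, 0.85, "both")


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    members: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_windows(
    gene_order: GeneOrder,
    focal_proteins: Iterable[str],
    w: int = 10,
) -> list[NeighborhoodWindow]:
    """Extract the +/-``w``-gene window around each focal protein occurrence.

    Windows truncate at the ends of linear replicons; on circular replicons
    they wrap around, with each neighboring gene counted at most once (at
    its smallest-|offset| position, upstream winning ties).
    """
    per_rep = gene_order.by_replicon()
    location: dict[str, tuple[str, int]] = {}
    for rep, members in per_rep.items():
        for pos, rec in enumerate(members):
            location[rec.protein_id] = (rep, pos)
    windows: list[NeighborhoodWindow] = []
    for focal in focal_proteins:
        if focal not in location:
            raise KeyError(f"focal protein {focal!r} absent from gene-order table")
        rep, pos = location[focal]
        members = per_rep[rep]
        m = len(members)
        neighbors: list[tuple[str, int]] = []
        seen: set[str] = set()
        if gene_order.is_circular(rep):
            for dist in range(1, w + 1):
                for off in (-dist, dist):
                    pid = members[(pos + off) % m].protein_id
                    if pid != focal and pid not in seen:
                        seen.add(pid)
                        neighbors.append((pid, off))
        else:
            for off in range(-w, w + 1):
                if off == 0 or not 0 <= pos + off < m:
                    continue
                neighbors.append((members[pos + off].protein_id, off))
        neighbors.sort(key=lambda t: t[1])
        windows.append(
            NeighborhoodWindow(
                focal_protein_id=focal,
                genome_id=members[pos].genome_id,
                replicon_id=rep,
                neighbors=tuple(neighbors),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# Pairwise similarity (in-package aligner)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "local"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity_coverage(
    protein_a: str, seq_a: str, protein_b: str, seq_b: str
) -> SimilarityEdge:
    """Local BLOSUM62 alignment (gap open 11 / extend 1) as a SimilarityEdge.

    Percent identity is identical columns over all alignment columns
    (gap columns included); coverage on each side is the aligned span
    divided by that sequence's length. A pair with no positive-scoring
    local alignment yields a zero edge.
    """
    for name, seq in ((protein_a, seq_a), (protein_b, seq_b)):
        if not seq:
            raise ValueError(f"empty sequence for {name}")
        bad = set(seq.upper()) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-amino-acid characters {sorted(bad)} in {name}")
    alignments = _aligner().align(seq_a.upper(), seq_b.upper())
    if len(alignments) == 0 or alignments.score <= 0:
        return SimilarityEdge(protein_a, protein_b, 0.0, 0.0, 0.0)
    aln = alignments[0]
    counts = aln.counts()
    columns = aln.length
    identity = 100.0 * counts.identities / columns if columns else 0.0
    span_a = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
    span_b = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
    edge = SimilarityEdge(
        protein_a, protein_b, identity, span_a / len(seq_a), span_b / len(seq_b)
    )
    return edge


def all_pairs_similarity(records: Sequence[ProteinRecord]) -> list[SimilarityEdge]:
    """Align every unordered pair of records with the in-package aligner."""
    edges: list[SimilarityEdge] = []
    for i, ra in enumerate(records):
        for rb in records[i + 1:]:
            edges.append(
                pairwise_identity_coverage(
                    ra.protein_id, ra.sequence, rb.protein_id, rb.sequence
                )
            )
    return edges


# ---------------------------------------------------------------------------
# Single-linkage clustering
# ---------------------------------------------------------------------------

def single_linkage(
    proteins: Iterable[str],
    edges: Iterable[SimilarityEdge],
    params: ClusteringParams = ClusteringParams(),
) -> list[Cluster]:
    """Connected components of the threshold graph, singletons included.

    Clusters are sorted by size (descending) then by lexicographically
    smallest member, and numbered C1, C2, ... in that order, so the output
    is invariant to the input order of nodes and edges.
    """
    graph = nx.Graph()
    graph.add_nodes_from(proteins)
    for edge in edges:
        if edge.protein_a not in graph or edge.protein_b not in graph:
            raise ValueError(f"edge endpoint outside protein set: {edge.pair}")
        if params.keeps(edge):
            graph.add_edge(edge.protein_a, edge.protein_b)
    components = [tuple(sorted(c)) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    return [Cluster(f"C{i + 1}", members) for i, members in enumerate(components)]


# ---------------------------------------------------------------------------
# Conservation report
# ---------------------------------------------------------------------------

def conservation_report(
    clusters: Sequence[Cluster],
    windows: Sequence[NeighborhoodWindow],
    genome_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate how widely each cluster recurs across focal neighborhoods.

    One row per cluster: size, distinct genomes, the signed-offset multiset
    of its members across windows, and the number of distinct windows
    containing at least one member (``n_windows``, the co-occurrence count
    with the focal gene). Rows are sorted by n_windows then n_genomes,
    both descending.
    """
    offset_of: dict[str, list[int]] = {}
    window_of: dict[str, set[int]] = {}
    for w_idx, window in enumerate(windows):
        for pid, off in window.neighbors:
            offset_of.setdefault(pid, []).append(off)
            window_of.setdefault(pid, set()).add(w_idx)
    rows = []
    for cluster in clusters:
        offsets: list[int] = []
        covered_windows: set[int] = set()
        genomes: set[str] = set()
        for pid in cluster.members:
            offsets.extend(offset_of.get(pid, []))
            covered_windows |= window_of.get(pid, set())
            if genome_of is not None and pid in genome_of:
                genomes.add(genome_of[pid])
        rows.append(
            {
                "cluster_id": cluster.cluster_id,
                "size": cluster.size,
                "n_genomes": len(genomes) if genome_of is not None else pd.NA,
                "n_windows": len(covered_windows),
                "offsets": ",".join(str(o) for o in sorted(offsets)),
            }
        )
    report = pd.DataFrame(rows)
    if not report.empty:
        report = report.sort_values(
            ["n_windows", "n_genomes", "size", "cluster_id"],
            ascending=[False, False, False, True],
            na_position="last",
        ).reset_index(drop=True)
    return report


def cluster_size_histogram(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Cluster-size distribution: one row per size with its cluster count."""
    sizes = pd.Series([c.size for c in clusters], dtype=int)
    hist = sizes.value_counts().sort_index()
    return pd.DataFrame({"cluster_size": hist.index, "n_clusters": hist.values})


# ---------------------------------------------------------------------------
# Genome dereplication by marker gene
# ---------------------------------------------------------------------------

def dereplicate(
    marker_records: Sequence[ProteinRecord],
    params: ClusteringParams = DEREPLICATION_PARAMS,
    edges: Sequence[SimilarityEdge] | None = None,
) -> list[str]:
    """Reduce genomes to one representative per marker-sequence cluster.

    Each record is one genome's single-copy marker protein (record
    ``genome_id`` identifies the genome). Markers are clustered by single
    linkage at the dereplication thresholds (80% identity / 0.85 coverage
    by default); the representative of each cluster is the genome with the
    longest marker, ties broken by lexicographic genome id. Precomputed
    ``edges`` (keyed by protein id) may replace the in-package aligner.
    Records without a sequence are dropped with a warning.
    """
    usable = [r for r in marker_records if r.sequence]
    dropped = [r.genome_id for r in marker_records if not r.sequence]
    if dropped:
        warnings.warn(f"genomes without marker sequence dropped: {dropped}")
    if not usable:
        return []
    if edges is None:
        edges = all_pairs_similarity(usable)
    by_id = {r.protein_id: r for r in usable}
    clusters = single_linkage([r.protein_id for r in usable], edges, params)
    representatives = []
    for cluster in clusters:
        best = min(
            cluster.members,
            key=lambda pid: (-by_id[pid].length, by_id[pid].genome_id),
        )
        representatives.append(by_id[best].genome_id)
    return sorted(representatives)
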