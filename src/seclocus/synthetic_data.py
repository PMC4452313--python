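"""Seeded synthetic pangenome bundles with full ground truth.

The generator emulates, at desk scale, the statistical structure of a
multi-genome comparative analysis of the Sec pathway:

* a panel of genomes, half of which carry a binary phenotype (an
  intracellular-membrane-like trait), each with one replicon of
  rank-ordered genes;
* background gene families with one member per genome, a designated
  subset of which is trait-associated and draws signal peptides at an
  elevated per-protein probability;
* one canonical SecA gene per genome carrying the full SecA_DEAD +
  SecA_SW domain pair, plus — in a subset of genomes — a planted
  *secondary* SecA_DEAD gene whose SecA_SW domain is missing or reduced
  to a fragment covering less than half of the model;
* a conserved multi-gene locus: three partner families (cluster1..3)
  planted at random offsets within the +/-10-gene window around each
  secondary copy;
* a pairwise-similarity table in which within-family pairs among the
  planted locus draw identities far above the 25% clustering threshold
  and background pairs far below it.

Sequences are random amino-acid strings: the similarity table is drawn
directly from the configured identity distributions rather than computed
by alignment, which separates clustering-logic testing from alignment
testing (the neighborhoods module has its own alignment path). All
randomness flows from one counter-based Philox generator seeded by
``rng_seed``, so a fixed seed yields byte-identical bundles on any
platform.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .enrichment import EnrichmentResult, GeneFamily, classify_family_sp, enrich
from .io_formats import (
    DomainHit,
    GeneOrder,
    ProteinRecord,
    SignalPeptideCall,
    SimilarityEdge,
    read_domain_annotations,
    read_fasta,
    read_gene_order,
    read_phenotypes,
    read_sp_calls,
    write_domain_annotations,
    write_fasta,
    write_gene_order_gff,
    write_phenotypes,
    write_sp_calls,
)

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

SECA_DEAD = "SecA_DEAD"
SECA_SW = "SecA_SW"
#: model lengths (aa) used for planted domain envelopes
SECA_DEAD_LEN = 390
SECA_SW_LEN = 150
SECA_SW_FRAGMENT_LEN = 40  # < 0.5 * SECA_SW_LEN, i.e. a "small fragment"

CLUSTER_DOMAINS = {
    "cluster1": "Peptidase_M50",
    "cluster2": "HlyD",
    "cluster3": "GAF",
}


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_genomes: int = 40
    genes_per_genome: int = 200
    n_families: int = 200
    trait_prevalence: float = 0.5
    n_trait_families: int = 20
    sp_prob_trait: float = 0.9
    sp_prob_background: float = 0.15
    locus_genomes: int = 12
    locus_families: tuple[str, ...] = (
        "focal_secondary", "cluster1", "cluster2", "cluster3",
    )
    within_cluster_identity_mean: float = 60.0
    within_cluster_identity_sd: float = 2.0
    background_identity_mean: float = 10.0
    background_identity_sd: float = 2.0
    coverage_mean: float = 0.9
    coverage_sd: float = 0.03
    background_edge_fraction: float = 0.05
    na_fraction: float = 0.0
    window: int = 10
    seq_length_mean: float = 300.0
    seq_length_sd: float = 50.0
    min_seq_length: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trait_prevalence", "sp_prob_trait", "sp_prob_background",
                     "background_edge_fraction", "na_fraction"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.locus_genomes > self.n_genomes:
            raise ValueError("locus_genomes exceeds n_genomes")
        for name in ("within_cluster_identity_mean", "background_identity_mean"):
            if not 0 <= getattr(self, name) <= 100:
                raise ValueError(f"{name} outside [0, 100]")
        if self.n_trait_families > self.n_families:
            raise ValueError("n_trait_families exceeds n_families")
        if self.genes_per_genome < self.n_families:
            raise ValueError("genes_per_genome must be >= n_families")
        if not (self.within_cluster_identity_mean > 25 > self.background_identity_mean):
            warnings.warn(
                "identity means do not straddle the 25% clustering threshold; "
                "planted clusters may not be recoverable"
            )

    def rng(self) -> np.random.Generator:
        return np.random.Generator(np.random.Philox(self.rng_seed))


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    family_of_protein: dict[str, str]
    trait_of_genome: dict[str, int | None]
    trait_families: list[str]
    sp_label: dict[str, str]
    locus_positions: dict[str, dict]  # genome -> replicon/focal_rank/cluster_ranks
    intended_cluster: dict[str, str]  # window protein -> planted label
    canonical_ids: list[str]
    secondary_ids: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


@dataclass
class PangenomeBundle:
    """In-memory synthetic dataset; ``write`` emits the full file bundle."""

    proteins: list[ProteinRecord]
    gene_order: GeneOrder
    domain_hits: list[DomainHit]
    sp_calls: list[SignalPeptideCall]
    phenotypes: dict[str, int | None]
    family_rows: list[tuple[str, str, str, int]]  # family, protein, genome, trait_assoc

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.faa",
            "gff": outdir / "genes.gff",
            "domains": outdir / "domains.tsv",
            "sp_calls": outdir / "sp_calls.tsv",
            "phenotype": outdir / "phenotype.tsv",
            "families": outdir / "families.tsv",
        }
        write_fasta(self.proteins, paths["fasta"])
        write_gene_order_gff(self.gene_order, paths["gff"])
        write_domain_annotations(self.domain_hits, paths["domains"])
        write_sp_calls(self.sp_calls, paths["sp_calls"])
        write_phenotypes(self.phenotypes, paths["phenotype"])
        with open(paths["families"], "w") as fh:
            fh.write("family_id\tprotein_id\tgenome_id\ttrait_associated\n")
            for fam, pid, genome, assoc in self.family_rows:
                fh.write(f"{fam}\t{pid}\t{genome}\t{assoc}\n")
        return paths


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, mean: float, sd: float, minimum: int) -> str:
    length = max(minimum, int(round(rng.normal(mean, sd))))
    return "".join(AA_ALPHABET[rng.integers(0, len(AA_ALPHABET), size=length)])


# ---------------------------------------------------------------------------
# Pangenome generation
# ---------------------------------------------------------------------------

def generate_pangenome(config: SimulationConfig) -> tuple[PangenomeBundle, GroundTruth]:
    """Generate the complete synthetic bundle and its ground truth."""
    rng = config.rng()
    focal_family, *cluster_family_names = config.locus_families
    genomes = [f"G{i:03d}" for i in range(config.n_genomes)]
    families = [f"F{i:04d}" for i in range(config.n_families)]
    trait_families = families[: config.n_trait_families]

    # genome-level trait: exact prevalence, random assignment, optional NAs
    n_trait = int(round(config.trait_prevalence * config.n_genomes))
    order = rng.permutation(config.n_genomes)
    trait_of_genome: dict[str, int | None] = {
        genomes[idx]: (1 if pos < n_trait else 0) for pos, idx in enumerate(order)
    }
    n_na = int(round(config.na_fraction * config.n_genomes))
    for idx in rng.permutation(config.n_genomes)[:n_na]:
        trait_of_genome[genomes[idx]] = None

    locus_set = {genomes[i] for i in rng.choice(config.n_genomes, config.locus_genomes, replace=False)}

    proteins: list[ProteinRecord] = []
    order_records: list[ProteinRecord] = []
    domain_hits: list[DomainHit] = []
    sp_calls: list[SignalPeptideCall] = []
    family_rows: list[tuple[str, str, str, int]] = []
    family_of_protein: dict[str, str] = {}
    sp_label: dict[str, str] = {}
    locus_positions: dict[str, dict] = {}
    canonical_ids: list[str] = []
    secondary_ids: list[str] = []

    w = config.window
    for g_idx, genome in enumerate(genomes):
        replicon = f"{genome}_c1"
        has_locus = genome in locus_set
        total = config.genes_per_genome + 1 + (4 if has_locus else 0)
        if has_locus and total < 2 * w + 1:
            raise ValueError(
                f"replicon of {total} genes cannot host a +/-{w} locus window"
            )

        special: dict[int, str] = {}  # rank -> family label
        if has_locus:
            focal_rank = int(rng.integers(w, total - w))
            offsets = rng.choice(
                np.concatenate([np.arange(-w, 0), np.arange(1, w + 1)]),
                size=len(cluster_family_names), replace=False,
            )
            special[focal_rank] = focal_family
            cluster_ranks = {}
            for fam, off in zip(cluster_family_names, offsets):
                special[focal_rank + int(off)] = fam
                cluster_ranks[fam] = focal_rank + int(off)
            locus_positions[genome] = {
                "replicon": replicon,
                "focal_rank": focal_rank,
                "cluster_ranks": cluster_ranks,
            }
        free = [r for r in range(total) if r not in special]
        seca_rank = int(free[rng.integers(0, len(free))])
        special[seca_rank] = "secA"

        # background families: one member each, then filler drawn uniformly
        background_ranks = [r for r in range(total) if r not in special]
        fam_labels = list(range(config.n_families))
        n_extra = len(background_ranks) - config.n_families
        if n_extra > 0:
            fam_labels += list(rng.integers(0, config.n_families, size=n_extra))
        fam_labels = [fam_labels[i] for i in rng.permutation(len(fam_labels))]
        fam_of_rank = dict(zip(background_ranks, fam_labels))

        for rank in range(total):
            pid = f"{genome}|g{rank:04d}"
            label = special.get(rank)
            if label == "secA":
                seq = _random_sequence(rng, 900, 30, 600)
                family = "secA"
                domain_hits += [
                    DomainHit(pid, SECA_DEAD, 1, SECA_DEAD_LEN, 1e-150, 520.0, True),
                    DomainHit(pid, SECA_SW, SECA_DEAD_LEN + 10,
                              SECA_DEAD_LEN + 9 + SECA_SW_LEN, 1e-40, 160.0, True),
                ]
                canonical_ids.append(pid)
            elif label == focal_family:
                seq = _random_sequence(rng, 600, 30, 500)
                family = focal_family
                domain_hits.append(
                    DomainHit(pid, SECA_DEAD, 1, SECA_DEAD_LEN, 1e-120, 430.0, True)
                )
                if rng.random() < 0.5:  # fragment vs complete loss of the wing domain
                    domain_hits.append(
                        DomainHit(pid, SECA_SW, SECA_DEAD_LEN + 10,
                                  SECA_DEAD_LEN + 9 + SECA_SW_FRAGMENT_LEN,
                                  1e-4, 18.0, False)
                    )
                secondary_ids.append(pid)
            elif label in CLUSTER_DOMAINS:
                seq = _random_sequence(
                    rng, config.seq_length_mean, config.seq_length_sd, config.min_seq_length
                )
                family = label
                dom_len = min(len(seq) - 10, 120)
                domain_hits.append(
                    DomainHit(pid, CLUSTER_DOMAINS[label], 5, 4 + dom_len, 1e-20, 90.0, True)
                )
            else:
                seq = _random_sequence(
                    rng, config.seq_length_mean, config.seq_length_sd, config.min_seq_length
                )
                fam_idx = fam_of_rank[rank]
                family = families[fam_idx]
                dom_len = min(len(seq) - 10, 100)
                domain_hits.append(
                    DomainHit(pid, f"DOM{fam_idx:04d}", 5, 4 + dom_len, 1e-15, 70.0, True)
                )

            # per-protein signal peptide: elevated in trait-associated families
            p_sp = (
                config.sp_prob_trait if family in trait_families
                else config.sp_prob_background
            )
            if rng.random() < p_sp:
                sp_class = "SPI" if rng.random() < 0.8 else "SPII"
            else:
                sp_class = "none"
            sp_calls.append(SignalPeptideCall(pid, sp_class, "lipoP"))
            sp_label[pid] = sp_class

            strand = "+" if rng.random() < 0.5 else "-"
            proteins.append(ProteinRecord(pid, genome, sequence=seq))
            order_records.append(
                ProteinRecord(pid, genome, replicon_id=replicon,
                              index_on_replicon=rank, strand=strand, length=len(seq))
            )
            family_of_protein[pid] = family
            family_rows.append((family, pid, genome, int(family in trait_families)))

    gene_order = GeneOrder(records=order_records)

    # intended cluster labels over the union of window members around
    # each planted secondary copy (the substrate for similarity drawing)
    intended: dict[str, str] = {}
    per_rep = gene_order.by_replicon()
    for genome, pos_info in locus_positions.items():
        members = per_rep[pos_info["replicon"]]
        focal_rank = pos_info["focal_rank"]
        for off in range(-w, w + 1):
            if off == 0 or not 0 <= focal_rank + off < len(members):
                continue
            pid = members[focal_rank + off].protein_id
            fam = family_of_protein[pid]
            intended[pid] = fam if fam in config.locus_families else f"singleton:{pid}"

    family_rows.sort()
    truth = GroundTruth(
        family_of_protein=family_of_protein,
        trait_of_genome=trait_of_genome,
        trait_families=list(trait_families),
        sp_label=sp_label,
        locus_positions=locus_positions,
        intended_cluster=intended,
        canonical_ids=sorted(canonical_ids),
        secondary_ids=sorted(secondary_ids),
    )
    bundle = PangenomeBundle(
        proteins=proteins,
        gene_order=gene_order,
        domain_hits=domain_hits,
        sp_calls=sp_calls,
        phenotypes=trait_of_genome,
        family_rows=family_rows,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Similarity table
# ---------------------------------------------------------------------------

def generate_similarity_table(
    truth: GroundTruth,
    config: SimulationConfig,
) -> list[SimilarityEdge]:
    """Draw the pairwise table over window proteins from the planted labels.

    Every within-cluster pair (same intended non-singleton label) receives
    an edge with identity ~ Normal(within_cluster mean, sd) and coverage
    ~ Normal(coverage mean, sd), both truncated to their ranges; a
    ``background_edge_fraction`` of the remaining pairs receives
    low-identity edges from the background distribution. Uses its own
    Philox stream (config seed + 1) so the table is reproducible
    independently of pangenome generation.
    """
    rng = np.random.Generator(np.random.Philox(config.rng_seed + 1))
    members = sorted(truth.intended_cluster)
    label = truth.intended_cluster

    def draw_edge(a: str, b: str, ident_mean: float, ident_sd: float) -> SimilarityEdge:
        ident = float(np.clip(rng.normal(ident_mean, ident_sd), 0.0, 100.0))
        cov_a = float(np.clip(rng.normal(config.coverage_mean, config.coverage_sd), 0.0, 1.0))
        cov_b = float(np.clip(rng.normal(config.coverage_mean, config.coverage_sd), 0.0, 1.0))
        return SimilarityEdge(a, b, ident, cov_a, cov_b)

    edges: list[SimilarityEdge] = []
    for a, b in itertools.combinations(members, 2):
        if label[a] == label[b] and not label[a].startswith("singleton:"):
            edges.append(draw_edge(a, b, config.within_cluster_identity_mean,
                                   config.within_cluster_identity_sd))
        elif rng.random() < config.background_edge_fraction:
            edges.append(draw_edge(a, b, config.background_identity_mean,
                                   config.background_identity_sd))
    return edges


# ---------------------------------------------------------------------------
# Marker sets for dereplication
# ---------------------------------------------------------------------------

def generate_marker_set(
    n_genomes: int,
    n_groups: int,
    seed: int = 0,
    length: int = 300,
    divergence_within: float = 0.02,
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """One marker protein per genome, planted as ``n_groups`` clone groups.

    Genomes are assigned to groups round-robin; within a group each marker
    is the group's base sequence with ~``divergence_within`` of positions
    substituted (well above the 80% dereplication identity threshold),
    while different groups are unrelated random sequences (far below it).
    Returns the records and the genome-to-group ground truth.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    bases = [
        "".join(AA_ALPHABET[rng.integers(0, len(AA_ALPHABET), size=length)])
        for _ in range(n_groups)
    ]
    records: list[ProteinRecord] = []
    group_of: dict[str, int] = {}
    for i in range(n_genomes):
        genome = f"G{i:03d}"
        group = i % n_groups
        seq = list(bases[group])
        n_mut = rng.binomial(length, divergence_within)
        for pos in rng.choice(length, size=n_mut, replace=False):
            seq[pos] = str(AA_ALPHABET[rng.integers(0, len(AA_ALPHABET))])
        records.append(ProteinRecord(f"{genome}|leuS", genome, sequence="".join(seq)))
        group_of[genome] = group
    return records, group_of


# ---------------------------------------------------------------------------
# Fast family-level replicates for calibration studies
# ---------------------------------------------------------------------------

def simulate_enrichment_replicate(
    config: SimulationConfig, seed: int, primary_convention: str = "inclusive"
) -> EnrichmentResult:
    """One enrichment analysis on a fresh family-level realization.

    Draws per-protein signal-peptide indicators for ``n_families`` families
    of ``n_genomes`` members each (trait-associated families at
    ``sp_prob_trait``, the rest at ``sp_prob_background``), classifies the
    families through the real classification code and runs the real
    enrichment test. Sequence and gene-order machinery is skipped, which
    makes large seed sweeps cheap while still exercising the downstream
    statistics end to end.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    families: list[GeneFamily] = []
    sp_map: dict[str, str] = {}
    for f in range(config.n_families):
        trait_assoc = f < config.n_trait_families
        p = config.sp_prob_trait if trait_assoc else config.sp_prob_background
        members = [f"F{f:04d}|m{g:03d}" for g in range(config.n_genomes)]
        draws = rng.random(config.n_genomes) < p
        for pid, has_sp in zip(members, draws):
            sp_map[pid] = "SPI" if has_sp else "none"
        fam = GeneFamily(family_id=f"F{f:04d}", members=members,
                         is_trait_associated=trait_assoc)
        families.append(classify_family_sp(fam, sp_map))
    return enrich(families, primary_convention=primary_convention)


# ---------------------------------------------------------------------------
# Benchmark inputs
# ---------------------------------------------------------------------------

def generate_benchmark_tables(
    n_proteins: int = 40,
    n_complexes: int = 6,
    n_pathways: int = 5,
    group_size: int = 5,
    score_max: float = 905.0,
    signal_strength: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, set[str]], dict[str, set[str]], dict[tuple[str, str], float]]:
    """Random complex/pathway memberships and a pair score table.

    Scores are uniform on [0, score_max]; with ``signal_strength`` > 0 the
    scores of true (shared-membership) pairs are pushed toward the top by
    that fraction of the range, so ROC behavior can be tuned from random
    (0.0, AUC ~ 0.5) to informative.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    proteins = [f"p{i:03d}" for i in range(n_proteins)]

    def draw_groups(prefix: str, count: int) -> dict[str, set[str]]:
        groups = {}
        for i in range(count):
            idx = rng.choice(n_proteins, size=group_size, replace=False)
            groups[f"{prefix}{i}"] = {proteins[j] for j in idx}
        return groups

    complexes = draw_groups("cplx", n_complexes)
    pathways = draw_groups("pwy", n_pathways)
    truth_pairs = set()
    for groups in (complexes, pathways):
        for members in groups.values():
            truth_pairs.update(itertools.combinations(sorted(members), 2))
    scores: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(proteins, 2):
        s = float(rng.uniform(0, score_max))
        if signal_strength > 0 and (a, b) in truth_pairs:
            s = min(score_max, s + signal_strength * score_max)
        scores[(a, b)] = s
    return complexes, pathways, scores


# ---------------------------------------------------------------------------
# Self-audit
# ---------------------------------------------------------------------------

def audit_bundle(outdir: str | Path, truth: GroundTruth) -> list[str]:
    """Re-parse an emitted bundle and check it against the ground truth.

    Returns a list of human-readable discrepancies (empty when the bundle
    and the truth agree on every audited field).
    """
    outdir = Path(outdir)
    problems: list[str] = []

    records = read_fasta(outdir / "proteins.faa")
    if {r.protein_id for r in records} != set(truth.family_of_protein):
        problems.append("FASTA protein ids differ from ground truth")

    order = read_gene_order(outdir / "genes.gff")
    rank_of = {r.protein_id: (r.replicon_id, r.index_on_replicon) for r in order.records}
    for genome, info in truth.locus_positions.items():
        focal_pid = f"{genome}|g{info['focal_rank']:04d}"
        if rank_of.get(focal_pid) != (info["replicon"], info["focal_rank"]):
            problems.append(f"focal rank mismatch in {genome}")
        for fam, rank in info["cluster_ranks"].items():
            pid = f"{genome}|g{rank:04d}"
            if truth.family_of_protein.get(pid) != fam:
                problems.append(f"planted {fam} not at rank {rank} in {genome}")

    calls = {c.protein_id: c.sp_class for c in read_sp_calls(outdir / "sp_calls.tsv")}
    if calls != truth.sp_label:
        problems.append("signal-peptide calls differ from ground truth")

    phenotypes = read_phenotypes(outdir / "phenotype.tsv")
    if phenotypes != truth.trait_of_genome:
        problems.append("phenotype table differs from ground truth")

    hits = read_domain_annotations(outdir / "domains.tsv", mode="evalue_le_1")
    dead_carriers: dict[str, set[str]] = {}
    for h in hits:
        if h.domain_name == SECA_DEAD:
            genome = h.protein_id.split("|", 1)[0]
            dead_carriers.setdefault(genome, set()).add(h.protein_id)
    multi = {g for g, pids in dead_carriers.items() if len(pids) >= 2}
    locus_set = set(truth.locus_positions)
    if multi != locus_set:
        problems.append(
            f"multi-copy SecA_DEAD genomes {sorted(multi)} != planted {sorted(locus_set)}"
        )
    return problems
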