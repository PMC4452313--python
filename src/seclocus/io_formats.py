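"""Readers and writers for the tabular and sequence formats the pipeline consumes.

Every reader is a pure function of the file bytes and normalizes into the
internal data model: gene positions become 0-based ranks per replicon,
amino-acid coordinates stay 1-based inclusive, and pairwise similarity
records are stored undirected with a canonical (a < b) endpoint order.

Supported dialects (deliberately narrow):

* protein FASTA (via :mod:`Bio.SeqIO`);
* HMMER3 ``--domtblout`` tables or a simplified 7-column TSV of domain hits;
* a GFF3 subset (CDS features with an ``ID`` attribute) or a 4-column TSV
  for gene order;
* plain TSVs for signal-peptide calls, phenotypes, neighbor scores,
  complex/pathway membership and protein-to-group maps;
* BLAST tabular (``-outfmt 6``) pairwise hits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "unknown"}
VALID_SP_CLASSES = {"SPI", "SPII", "TAT", "none"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One protein with optional sequence and optional gene-order metadata.

    ``index_on_replicon`` is the 0-based gene rank after sorting by start
    coordinate; it is ``None`` when only sequence data has been loaded.
    """

    protein_id: str
    genome_id: str = ""
    replicon_id: str | None = None
    index_on_replicon: int | None = None
    strand: str = "unknown"
    length: int = 0
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for {self.protein_id}")
        if self.sequence is not None:
            if self.length and self.length != len(self.sequence):
                raise ValueError(
                    f"length {self.length} != len(sequence) for {self.protein_id}"
                )
            object.__setattr__(self, "length", len(self.sequence))
        if self.length < 1:
            raise ValueError(f"protein {self.protein_id} has length < 1")
        if self.index_on_replicon is not None and self.index_on_replicon < 0:
            raise ValueError("index_on_replicon must be a 0-based rank")


@dataclass(frozen=True)
class DomainHit:
    """A single domain envelope on one protein (1-based inclusive coords)."""

    protein_id: str
    domain_name: str
    env_start: int
    env_end: int
    e_value: float
    bit_score: float
    above_trusted_cutoff: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.env_start <= self.env_end:
            raise ValueError(
                f"bad envelope [{self.env_start},{self.env_end}] on {self.protein_id}"
            )
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")

    @property
    def env_length(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass(frozen=True)
class SignalPeptideCall:
    """Predicted signal-peptide class for one protein from one predictor."""

    protein_id: str
    sp_class: str
    predictor_tag: str = "lipoP"

    def __post_init__(self) -> None:
        if self.sp_class not in VALID_SP_CLASSES:
            raise ValueError(f"invalid sp_class {self.sp_class!r}")


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected pairwise similarity record with per-side coverage.

    ``percent_identity`` is the percentage of aligned columns that are
    identical; ``coverage_a`` / ``coverage_b`` are the fraction of each
    sequence spanned by the alignment. Endpoints are stored canonically
    (``protein_a < protein_b``) so an unordered pair has one representation.
    """

    protein_a: str
    protein_b: str
    percent_identity: float
    coverage_a: float
    coverage_b: float

    def __post_init__(self) -> None:
        if self.protein_a > self.protein_b:
            a, b = self.protein_a, self.protein_b
            cov_a, cov_b = self.coverage_a, self.coverage_b
            object.__setattr__(self, "protein_a", b)
            object.__setattr__(self, "protein_b", a)
            object.__setattr__(self, "coverage_a", cov_b)
            object.__setattr__(self, "coverage_b", cov_a)
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity outside [0, 100]")
        for cov in (self.coverage_a, self.coverage_b):
            if not 0 <= cov <= 1:
                raise ValueError("coverage outside [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass
class GeneOrder:
    """Gene ranks per replicon plus per-replicon circularity flags."""

    records: list[ProteinRecord]
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for rec in self.records:
            if rec.replicon_id is None or rec.index_on_replicon is None:
                raise ValueError(f"{rec.protein_id} lacks gene-order metadata")
            key = (rec.replicon_id, rec.index_on_replicon)
            if key in seen:
                raise ValueError(
                    f"duplicate rank {key[1]} on {key[0]}: "
                    f"{seen[key]} vs {rec.protein_id}"
                )
            seen[key] = rec.protein_id

    def by_replicon(self) -> dict[str, list[ProteinRecord]]:
        out: dict[str, list[ProteinRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.replicon_id, []).append(rec)
        for members in out.values():
            members.sort(key=lambda r: r.index_on_replicon)
        return out

    def is_circular(self, replicon_id: str) -> bool:
        return self.circular.get(replicon_id, False)

    def find(self, protein_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.protein_id == protein_id:
                return rec
        raise KeyError(f"protein {protein_id!r} absent from gene-order table")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into records (sequences only, no order metadata).

    Headers up to the first whitespace become protein ids; a ``genome|rest``
    prefix, when present, also populates ``genome_id``. Sequences are
    uppercased and terminal ``*`` stop characters stripped.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate FASTA header {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper().strip("*")
        genome = pid.split("|", 1)[0] if "|" in pid else ""
        records.append(ProteinRecord(protein_id=pid, genome_id=genome, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = []
    for rec in records:
        if rec.sequence is None:
            raise ValueError(f"{rec.protein_id} has no sequence to write")
        seq_records.append(SeqRecord(Seq(rec.sequence), id=rec.protein_id, description=""))
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Domain annotations
# ---------------------------------------------------------------------------

_DOMAIN_TSV_COLUMNS = [
    "protein_id", "domain_name", "env_start", "env_end",
    "e_value", "bit_score", "trusted",
]

#: e-value used by ``trusted_cutoff`` mode when the table carries no
#: trusted-cutoff column (simplified TSV without curated bits).
TRUSTED_FALLBACK_EVALUE = 1e-5


def read_domain_annotations(
    path: str | Path,
    mode: str = "evalue_le_1",
    known_proteins: set[str] | None = None,
) -> list[DomainHit]:
    """Read per-protein domain hits and filter by the requested mode.

    ``mode='trusted_cutoff'`` keeps hits flagged above the model's trusted
    cutoff (the conservative filter used when drawing architectures);
    ``mode='evalue_le_1'`` keeps hits with e-value <= 1, the permissive
    filter meant to retain even weak domain similarity. The dialect
    (HMMER3 domtblout vs simplified TSV) is auto-detected.
    """
    if mode not in {"trusted_cutoff", "evalue_le_1"}:
        raise ValueError(f"unknown mode {mode!r}")
    path = Path(path)
    text = path.read_text()
    first_data = next(
        (ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")), ""
    )
    if first_data.split("\t")[0] == "protein_id" or "\t" in first_data:
        hits, has_trusted = _parse_domain_tsv(text, path)
    else:
        hits, has_trusted = _parse_domtblout(text)

    if mode == "trusted_cutoff" and not has_trusted:
        warnings.warn(
            f"{path.name}: no trusted-cutoff column; falling back to "
            f"e-value <= {TRUSTED_FALLBACK_EVALUE:g} as the conservative filter",
            stacklevel=2,
        )
        kept = [h for h in hits if h.e_value <= TRUSTED_FALLBACK_EVALUE]
    elif mode == "trusted_cutoff":
        kept = [h for h in hits if h.above_trusted_cutoff]
    else:
        kept = [h for h in hits if h.e_value <= 1.0]

    if known_proteins is not None:
        unknown = {h.protein_id for h in kept} - known_proteins
        if unknown:
            logger.info("domain hits reference %d unknown protein ids", len(unknown))
    kept.sort(key=lambda h: (h.protein_id, h.env_start, h.env_end, h.domain_name))
    return kept


def _parse_domain_tsv(text: str, path: Path) -> tuple[list[DomainHit], bool]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    if header[0] == "protein_id":
        body = lines[1:]
        has_trusted = "trusted" in header
        cols = {name: i for i, name in enumerate(header)}
    else:
        body = lines
        has_trusted = len(header) >= 7
        cols = {name: i for i, name in enumerate(_DOMAIN_TSV_COLUMNS)}
    hits: list[DomainHit] = []
    for ln in body:
        parts = ln.split("\t")
        start = int(parts[cols["env_start"]])
        end = int(parts[cols["env_end"]])
        if end < start:
            warnings.warn(f"{path.name}: rejecting row with env_end < env_start: {ln!r}")
            continue
        trusted = False
        if has_trusted:
            trusted = parts[cols["trusted"]].strip().lower() in {"1", "true", "yes"}
        hits.append(
            DomainHit(
                protein_id=parts[cols["protein_id"]],
                domain_name=parts[cols["domain_name"]],
                env_start=start,
                env_end=end,
                e_value=float(parts[cols["e_value"]]),
                bit_score=float(parts[cols["bit_score"]]),
                above_trusted_cutoff=trusted,
            )
        )
    return hits, has_trusted


def _parse_domtblout(text: str) -> tuple[list[DomainHit], bool]:
    # HMMER3 domtblout: whitespace-delimited; fields of interest are
    # target(0)=protein, query(3)=domain, i-Evalue(12), score(13), env(19,20).
    hits: list[DomainHit] = []
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split()
        start, end = int(parts[19]), int(parts[20])
        if end < start:
            warnings.warn(f"rejecting domtblout row with env_end < env_start: {ln!r}")
            continue
        hits.append(
            DomainHit(
                protein_id=parts[0],
                domain_name=parts[3],
                env_start=start,
                env_end=end,
                e_value=float(parts[12]),
                bit_score=float(parts[13]),
            )
        )
    return hits, False


def write_domain_annotations(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the simplified TSV dialect (with the trusted column)."""
    rows = [
        (h.protein_id, h.domain_name, h.env_start, h.env_end,
         f"{h.e_value:g}", f"{h.bit_score:g}", int(h.above_trusted_cutoff))
        for h in hits
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(_DOMAIN_TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Gene order
# ---------------------------------------------------------------------------

def read_gene_order(path: str | Path, genome_of: Mapping[str, str] | None = None) -> GeneOrder:
    """Read gene order from a GFF3 CDS subset or a 4-column TSV.

    GFF3 1-based start coordinates are converted to 0-based ranks per
    replicon; ties on start are broken by end coordinate then feature id
    (logged). Circularity is read from a ``region`` feature carrying a
    ``circular=true`` (or ``Is_circular=true``) attribute; the TSV dialect
    carries ranks directly and is always linear unless a ``#circular:``
    header comment lists replicons.
    """
    path = Path(path)
    text = path.read_text()
    if text.startswith("##gff-version") or "\tCDS\t" in text:
        return _parse_gff(text, genome_of)
    return _parse_gene_order_tsv(text, genome_of)


def _parse_gff(text: str, genome_of: Mapping[str, str] | None) -> GeneOrder:
    circular: dict[str, bool] = {}
    raw: dict[str, list[tuple[int, int, str, str]]] = {}
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 9:
            continue
        seqid, _source, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
        )
        if ftype == "region":
            flag = attr_map.get("circular", attr_map.get("Is_circular", "false"))
            circular[seqid] = flag.lower() == "true"
            continue
        if ftype != "CDS":
            continue
        pid = attr_map.get("ID")
        if pid is None:
            raise ValueError(f"CDS without ID attribute: {ln!r}")
        raw.setdefault(seqid, []).append(
            (int(start), int(end), pid, strand if strand in "+-" else "unknown")
        )
    records: list[ProteinRecord] = []
    for seqid, feats in raw.items():
        starts = [f[0] for f in feats]
        if len(set(starts)) != len(starts):
            logger.info("tied CDS starts on %s; breaking by end then id", seqid)
        feats.sort()  # (start, end, id) lexicographic = documented tie-break
        for rank, (_s, _e, pid, strand) in enumerate(feats):
            genome = genome_of.get(pid, pid.split("|", 1)[0]) if genome_of else pid.split("|", 1)[0]
            records.append(
                ProteinRecord(
                    protein_id=pid, genome_id=genome, replicon_id=seqid,
                    index_on_replicon=rank, strand=strand, length=1,
                )
            )
    return GeneOrder(records=records, circular=circular)


def _parse_gene_order_tsv(text: str, genome_of: Mapping[str, str] | None) -> GeneOrder:
    circular: dict[str, bool] = {}
    records: list[ProteinRecord] = []
    for ln in text.splitlines():
        if ln.startswith("#circular:"):
            for rep in ln.split(":", 1)[1].split(","):
                if rep.strip():
                    circular[rep.strip()] = True
            continue
        if not ln.strip() or ln.startswith("#") or ln.startswith("protein_id\t"):
            continue
        pid, replicon, index, strand = ln.split("\t")[:4]
        genome = genome_of.get(pid, pid.split("|", 1)[0]) if genome_of else pid.split("|", 1)[0]
        records.append(
            ProteinRecord(
                protein_id=pid, genome_id=genome, replicon_id=replicon,
                index_on_replicon=int(index),
                strand=strand if strand in "+-" else "unknown", length=1,
            )
        )
    return GeneOrder(records=records, circular=circular)


def write_gene_order_tsv(order: GeneOrder, path: str | Path) -> None:
    with open(path, "w") as fh:
        circ = sorted(r for r, flag in order.circular.items() if flag)
        if circ:
            fh.write("#circular:" + ",".join(circ) + "\n")
        fh.write("protein_id\treplicon_id\tindex\tstrand\n")
        for rec in sorted(order.records, key=lambda r: (r.replicon_id, r.index_on_replicon)):
            fh.write(f"{rec.protein_id}\t{rec.replicon_id}\t{rec.index_on_replicon}\t{rec.strand}\n")


def write_gene_order_gff(order: GeneOrder, path: str | Path, gene_span: int = 1000) -> None:
    """Write the rank table as a minimal GFF3 (one CDS per gene).

    Ranks are expanded to synthetic 1-based coordinates ``rank*gene_span+1``
    so that reading the file back recovers the same ranks.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        per_rep = order.by_replicon()
        for rep in sorted(per_rep):
            n = len(per_rep[rep])
            flag = "true" if order.is_circular(rep) else "false"
            fh.write(
                f"{rep}\tseclocus\tregion\t1\t{n * gene_span}\t.\t+\t.\t"
                f"ID={rep};circular={flag}\n"
            )
            for rec in per_rep[rep]:
                start = rec.index_on_replicon * gene_span + 1
                end = start + gene_span - 101
                strand = rec.strand if rec.strand in "+-" else "."
                fh.write(
                    f"{rep}\tseclocus\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
                    f"ID={rec.protein_id}\n"
                )


# ---------------------------------------------------------------------------
# Signal-peptide calls, phenotypes and other plain TSVs
# ---------------------------------------------------------------------------

def read_sp_calls(path: str | Path) -> list[SignalPeptideCall]:
    calls: list[SignalPeptideCall] = []
    seen: set[tuple[str, str]] = set()
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#") or ln.startswith("protein_id\t"):
            continue
        pid, sp_class, predictor = ln.split("\t")[:3]
        key = (pid, predictor)
        if key in seen:
            raise ValueError(f"duplicate signal-peptide call for {key}")
        seen.add(key)
        calls.append(SignalPeptideCall(pid, sp_class, predictor))
    return calls


def write_sp_calls(calls: Iterable[SignalPeptideCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tsp_class\tpredictor\n")
        for c in calls:
            fh.write(f"{c.protein_id}\t{c.sp_class}\t{c.predictor_tag}\n")


def read_phenotypes(path: str | Path) -> dict[str, int | None]:
    """Read a ``genome_id <tab> trait`` table; trait is 1, 0 or NA (None)."""
    out: dict[str, int | None] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#") or ln.startswith("genome_id\t"):
            continue
        genome, trait = ln.split("\t")[:2]
        out[genome] = None if trait.upper() == "NA" else int(trait)
    return out


def write_phenotypes(phenotypes: Mapping[str, int | None], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\ttrait\n")
        for genome in sorted(phenotypes):
            trait = phenotypes[genome]
            fh.write(f"{genome}\t{'NA' if trait is None else trait}\n")


def read_family_table(path: str | Path) -> pd.DataFrame:
    """Read ``family_id <tab> protein_id <tab> genome_id [<tab> trait_associated]``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"family_id", "protein_id", "genome_id"}
    if not required <= set(df.columns):
        raise ValueError(f"family table missing columns {required - set(df.columns)}")
    if "trait_associated" in df.columns:
        df["trait_associated"] = df["trait_associated"].astype(int).astype(bool)
    return df


def read_membership(path: str | Path) -> dict[str, set[str]]:
    """Read ``group_id <tab> protein_id`` membership (complexes or pathways)."""
    groups: dict[str, set[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#") or ln.split("\t")[0] in {"complex_id", "pathway_id", "group_id"}:
            continue
        gid, pid = ln.split("\t")[:2]
        groups.setdefault(gid, set()).add(pid)
    return groups


def read_score_table(path: str | Path) -> dict[tuple[str, str], float]:
    """Read ``group_a <tab> group_b <tab> neighbor_score`` with canonical pairs."""
    scores: dict[tuple[str, str], float] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#") or ln.startswith("group_a\t"):
            continue
        a, b, s = ln.split("\t")[:3]
        pair = (a, b) if a < b else (b, a)
        score = float(s)
        if pair in scores:
            scores[pair] = max(scores[pair], score)
        else:
            scores[pair] = score
    return scores


def read_protein_group_map(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#") or ln.startswith("protein_id\t"):
            continue
        pid, group = ln.split("\t")[:2]
        mapping[pid] = group
    return mapping


# ---------------------------------------------------------------------------
# Pairwise similarity tables
# ---------------------------------------------------------------------------

def read_blast_tabular(
    path: str | Path,
    lengths: Mapping[str, int],
) -> list[SimilarityEdge]:
    """Read BLAST ``-outfmt 6`` and convert each pair's best HSP to an edge.

    Coverage on each side is the HSP span divided by the sequence length
    (``lengths`` must provide both endpoints). When a pair has several
    HSPs only the highest-bit-score HSP is used; HSPs are never merged.
    Self hits are dropped.
    """
    best: dict[tuple[str, str], tuple[float, SimilarityEdge]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        q, s = parts[0], parts[1]
        if q == s:
            continue
        pident = float(parts[2])
        qstart, qend = int(parts[6]), int(parts[7])
        sstart, send = int(parts[8]), int(parts[9])
        bit = float(parts[11])
        cov_q = (abs(qend - qstart) + 1) / lengths[q]
        cov_s = (abs(send - sstart) + 1) / lengths[s]
        if q < s:
            edge = SimilarityEdge(q, s, pident, min(cov_q, 1.0), min(cov_s, 1.0))
        else:
            edge = SimilarityEdge(s, q, pident, min(cov_s, 1.0), min(cov_q, 1.0))
        key = edge.pair
        if key not in best or bit > best[key][0]:
            best[key] = (bit, edge)
    return [edge for _bit, edge in (best[k] for k in sorted(best))]


def read_similarity_tsv(path: str | Path) -> list[SimilarityEdge]:
    edges: list[SimilarityEdge] = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#") or ln.startswith("protein_a\t"):
            continue
        a, b, ident, cov_a, cov_b = ln.split("\t")[:5]
        edges.append(SimilarityEdge(a, b, float(ident), float(cov_a), float(cov_b)))
    return edges


def write_similarity_tsv(edges: Iterable[SimilarityEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tpercent_identity\tcoverage_a\tcoverage_b\n")
        for e in sorted(edges, key=lambda e: e.pair):
            fh.write(
                f"{e.protein_a}\t{e.protein_b}\t{e.percent_identity:.4f}\t"
                f"{e.coverage_a:.4f}\t{e.coverage_b:.4f}\n"
            )
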