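"""Signature-domain inference and paralog/rearrangement calls.

A pathway component's *signature* is the domain carried by that component
in every reference organism; when several domains are universal, the one
with the greatest mean envelope length wins (it is the most specific
marker). If no single domain is universal, the smallest co-occurring set
of domains that covers all references is used instead.

Homologs of a component are then simply the proteins carrying every
signature domain. Where a signature domain appears in more than one
protein of a genome, the copies are separated into *canonical* and
*secondary* by how much of a discriminator domain they retain: the
canonical SecA ATPase keeps its full wing/scaffold domain (SecA_SW) while
secondary copies lack it entirely or keep only a small fragment.
Rearrangement flags mark architectures whose watched domain is split into
distant fragments or whose shared-domain order differs from the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import DomainHit


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainArchitecture:
    """The ordered domain content of one protein."""

    protein_id: str
    ordered_domains: tuple[DomainHit, ...]

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.ordered_domains, key=lambda h: (h.env_start, h.env_end, h.domain_name))
        )
        object.__setattr__(self, "ordered_domains", ordered)

    @property
    def architecture_string(self) -> str:
        return "-".join(h.domain_name for h in self.ordered_domains)

    @property
    def domain_names(self) -> set[str]:
        return {h.domain_name for h in self.ordered_domains}

    @classmethod
    def from_hits(cls, protein_id: str, hits: Iterable[DomainHit]) -> "DomainArchitecture":
        own = tuple(h for h in hits if h.protein_id == protein_id)
        if not own:
            raise ValueError(f"no domain hits for {protein_id}")
        return cls(protein_id=protein_id, ordered_domains=own)


@dataclass(frozen=True)
class Signature:
    """Detection marker for one pathway component.

    ``required_domains`` is a single universal domain or a co-occurring
    set; a protein is a homolog iff it carries every required domain.
    """

    component_name: str
    required_domains: frozenset[str]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.required_domains:
            raise ValueError("signature must require at least one domain")


@dataclass(frozen=True)
class ParalogCall:
    """Per-genome copy-number call for one component."""

    genome_id: str
    component_name: str
    copies: tuple[tuple[str, str], ...]  # (protein_id, class)

    @property
    def copy_count(self) -> int:
        return len(self.copies)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(cls for _pid, cls in self.copies)


@dataclass(frozen=True)
class RearrangementCall:
    protein_id: str
    flag: bool
    description: str


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching 1-based inclusive intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _merged_envelope_length(arch: DomainArchitecture, domain: str) -> int:
    spans = [(h.env_start, h.env_end) for h in arch.ordered_domains if h.domain_name == domain]
    return sum(e - s + 1 for s, e in merge_intervals(spans))


def _best_bit_score(arch: DomainArchitecture, domain: str) -> float:
    return max(h.bit_score for h in arch.ordered_domains if h.domain_name == domain)


def architectures_from_hits(hits: Sequence[DomainHit]) -> dict[str, DomainArchitecture]:
    """Group a flat hit list into one architecture per protein."""
    per_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        per_protein.setdefault(h.protein_id, []).append(h)
    return {
        pid: DomainArchitecture(protein_id=pid, ordered_domains=tuple(own))
        for pid, own in per_protein.items()
    }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def infer_signature(
    component_name: str,
    reference_architectures: Sequence[DomainArchitecture],
    max_cover_size: int = 3,
) -> Signature:
    """Infer a signature from the component's reference architectures.

    The intersection of domain names across all references is computed
    first; if non-empty, the domain with the greatest mean (merged)
    envelope length across references is the signature, with ties broken
    by higher mean best-hit bit score and then lexicographically. If the
    intersection is empty, the smallest set of domains whose union covers
    every reference (greedy set cover, lexicographic tie-break) becomes a
    co-occurrence signature; failure to cover with <= ``max_cover_size``
    domains is an error.
    """
    if not reference_architectures:
        raise ValueError("need at least one reference architecture")
    provenance = tuple(sorted(a.protein_id for a in reference_architectures))
    shared = set.intersection(*(a.domain_names for a in reference_architectures))
    if shared:
        def rank(domain: str) -> tuple[float, float, str]:
            mean_len = sum(
                _merged_envelope_length(a, domain) for a in reference_architectures
            ) / len(reference_architectures)
            mean_bit = sum(
                _best_bit_score(a, domain) for a in reference_architectures
            ) / len(reference_architectures)
            # sort ascending: negate numeric keys, keep name for final tie
            return (-mean_len, -mean_bit, domain)

        best = min(shared, key=rank)
        return Signature(component_name, frozenset({best}), provenance)

    # Greedy set cover: each chosen domain must cover (appear in) as many
    # yet-uncovered references as possible.
    uncovered = set(range(len(reference_architectures)))
    all_domains = sorted(set.union(*(a.domain_names for a in reference_architectures)))
    chosen: set[str] = set()
    while uncovered:
        if len(chosen) >= max_cover_size:
            raise ValueError(
                f"no signature for {component_name}: no covering set of size <= {max_cover_size}"
            )
        best_domain = max(
            all_domains,
            key=lambda d: (
                sum(1 for i in uncovered if d in reference_architectures[i].domain_names),
                d,
            ),
        )
        covered = {
            i for i in uncovered if best_domain in reference_architectures[i].domain_names
        }
        if not covered:
            raise ValueError(f"no signature for {component_name}")
        chosen.add(best_domain)
        uncovered -= covered
    return Signature(component_name, frozenset(chosen), provenance)


def find_homologs(
    signature: Signature,
    hits: Sequence[DomainHit],
    genome_of: Mapping[str, str],
    genomes: Iterable[str] | None = None,
) -> dict[str, list[str]]:
    """Group proteins carrying every signature domain by genome.

    ``hits`` must already be filtered to the desired annotation mode.
    ``genomes`` optionally lists all genomes so that zero-hit genomes
    appear explicitly with an empty list.
    """
    domains_of: dict[str, set[str]] = {}
    for h in hits:
        domains_of.setdefault(h.protein_id, set()).add(h.domain_name)
    result: dict[str, list[str]] = {g: [] for g in (genomes or [])}
    for pid, names in sorted(domains_of.items()):
        if signature.required_domains <= names:
            genome = genome_of.get(pid)
            if genome is None:
                warnings.warn(f"homolog {pid} has no genome assignment; skipped")
                continue
            result.setdefault(genome, []).append(pid)
    return result


def classify_copies(
    component_name: str,
    homologs_by_genome: Mapping[str, Sequence[str]],
    hits: Sequence[DomainHit],
    discriminator_domain: str,
    fragment_fraction: float = 0.5,
    model_length: int | None = None,
) -> list[ParalogCall]:
    """Split each genome's component copies into canonical vs secondary.

    A copy is canonical iff its total (merged) discriminator-domain
    envelope covers at least ``fragment_fraction`` of the domain's model
    length — the boundary is inclusive on the canonical side. Copies below
    that, including copies lacking the domain entirely, are secondary.
    A genome with two or more canonical (or two or more secondary) copies
    has those copies re-marked ambiguous. When no model length is known,
    the longest observed envelope of the discriminator stands in for it.
    """
    archs = architectures_from_hits(list(hits))
    if model_length is None:
        observed = [
            h.env_length for h in hits if h.domain_name == discriminator_domain
        ]
        if not observed:
            raise ValueError(
                f"discriminator {discriminator_domain!r} absent from annotations "
                "and no model length given"
            )
        model_length = max(observed)
        warnings.warn(
            f"model length for {discriminator_domain} unknown; using longest "
            f"observed envelope ({model_length} aa)"
        )
    calls: list[ParalogCall] = []
    for genome in sorted(homologs_by_genome):
        copies: list[tuple[str, str]] = []
        for pid in sorted(homologs_by_genome[genome]):
            coverage = 0.0
            if pid in archs:
                coverage = _merged_envelope_length(archs[pid], discriminator_domain) / model_length
            cls = "canonical" if coverage >= fragment_fraction else "secondary"
            copies.append((pid, cls))
        n_canon = sum(1 for _p, c in copies if c == "canonical")
        n_sec = sum(1 for _p, c in copies if c == "secondary")
        if n_canon >= 2:
            copies = [(p, "ambiguous" if c == "canonical" else c) for p, c in copies]
        if n_sec >= 2:
            copies = [(p, "ambiguous" if c == "secondary" else c) for p, c in copies]
        if copies:
            calls.append(ParalogCall(genome, component_name, tuple(copies)))
    return calls


def detect_rearrangement(
    architecture: DomainArchitecture,
    reference_architecture: DomainArchitecture,
    watched_domain: str,
    gap_threshold: int = 30,
) -> RearrangementCall:
    """Flag architectures whose watched domain is fragmented or reordered.

    The flag is raised when (a) the watched domain's merged envelope
    fragments are separated by more than ``gap_threshold`` amino acids, or
    (b) the order of domain names shared with the reference differs from
    the reference's order.
    """
    if watched_domain not in reference_architecture.domain_names:
        raise ValueError(f"{watched_domain!r} absent from reference architecture")
    if watched_domain not in architecture.domain_names:
        raise ValueError(f"{watched_domain!r} absent from {architecture.protein_id}")

    spans = merge_intervals(
        (h.env_start, h.env_end)
        for h in architecture.ordered_domains
        if h.domain_name == watched_domain
    )
    for (s0, e0), (s1, _e1) in zip(spans, spans[1:]):
        if s1 - e0 - 1 > gap_threshold:
            return RearrangementCall(
                architecture.protein_id, True,
                f"{watched_domain} split into fragments with a {s1 - e0 - 1} aa gap",
            )

    shared = architecture.domain_names & reference_architecture.domain_names

    def shared_order(arch: DomainArchitecture) -> list[str]:
        # First occurrence order of each shared domain name.
        seen: list[str] = []
        for h in arch.ordered_domains:
            if h.domain_name in shared and h.domain_name not in seen:
                seen.append(h.domain_name)
        return seen

    if shared_order(architecture) != shared_order(reference_architecture):
        return RearrangementCall(
            architecture.protein_id, True,
            "shared-domain order differs from reference",
        )
    return RearrangementCall(architecture.protein_id, False, "consistent with reference")
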