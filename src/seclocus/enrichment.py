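"""Signal-peptide family classification, hypergeometric enrichment and phi.

A gene family is called signal-peptide positive when at least half of its
member proteins carry a predicted signal peptide of the requested classes
(the 50% rule is inclusive). Over-representation of signal-peptide
families among trait-associated families is tested with the hypergeometric
distribution: draw ``n`` trait-associated families from ``N`` total of
which ``K`` are signal-peptide positive and observe ``k`` in the overlap.

Two upper-tail conventions exist in the wild and both are computed here:

* ``inclusive`` — P(X >= k), the standard one-sided enrichment p-value;
* ``exclusive`` — P(X > k), the survival-function convention (e.g. R's
  ``phyper(k, ...)`` with ``lower.tail=FALSE``), which some published
  analyses report.

The tail is accumulated in log space from exact log-factorials
(``gammaln``), so extreme p-values far below float underflow of naive
products are still exact to full double precision.

The phi coefficient between two binary genome-level traits is the Pearson
correlation of the 0/1 indicator vectors, computed directly from the 2x2
contingency table; genomes with an unknown phenotype are excluded before
tabulation, never counted as absence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .io_formats import SignalPeptideCall

DEFAULT_SP_CLASSES = frozenset({"SPI", "SPII"})
TAT_CLASSES = frozenset({"TAT"})

#: Floor below which p-values are reported as a bound, never as zero.
P_FLOOR = 1e-300


@dataclass
class GeneFamily:
    """A gene family with its signal-peptide classification state."""

    family_id: str
    members: list[str]
    genomes: list[str] = field(default_factory=list)
    is_trait_associated: bool = False
    sp_fraction: float | None = None
    sp_positive: bool | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id} has no members")


@dataclass(frozen=True)
class EnrichmentInput:
    """2x2 overlap counts: N families, K positives, n drawn, k overlap."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid margins N={self.N} K={self.K} n={self.n}")
        lo = max(0, self.n + self.K - self.N)
        hi = min(self.K, self.n)
        if not lo <= self.k <= hi:
            raise ValueError(
                f"k={self.k} outside hypergeometric support [{lo},{hi}]"
            )


@dataclass(frozen=True)
class PhiResult:
    """Phi coefficient with its 2x2 table and the count of excluded genomes."""

    a: int
    b: int
    c: int
    d: int
    phi: float
    degenerate_marginal: bool = False
    n_excluded_unknown: int = 0


@dataclass
class EnrichmentResult:
    counts: EnrichmentInput
    p_exclusive: float
    p_inclusive: float
    primary_convention: str = "exclusive"

    @property
    def p_primary(self) -> float:
        return self.p_exclusive if self.primary_convention == "exclusive" else self.p_inclusive

    def format_p(self, value: float) -> str:
        return f"< {P_FLOOR:g}" if value < P_FLOOR else f"{value:.4g}"


def classify_family_sp(
    family: GeneFamily,
    sp_calls: Iterable[SignalPeptideCall] | Mapping[str, str],
    sp_classes: frozenset[str] | set[str] = DEFAULT_SP_CLASSES,
    threshold: float = 0.5,
) -> GeneFamily:
    """Set ``sp_fraction`` / ``sp_positive`` on a family (threshold inclusive).

    ``sp_calls`` maps protein ids to predicted classes (an iterable of calls
    is accepted and collapsed; a protein counts as positive if any of its
    calls is in ``sp_classes``).
    """
    if isinstance(sp_calls, Mapping):
        positive = {pid for pid, cls in sp_calls.items() if cls in sp_classes}
    else:
        positive = {c.protein_id for c in sp_calls if c.sp_class in sp_classes}
    n_pos = sum(1 for pid in family.members if pid in positive)
    family.sp_fraction = n_pos / len(family.members)
    family.sp_positive = family.sp_fraction >= threshold
    return family


def _log_pmf(N: int, K: int, n: int, k: np.ndarray) -> np.ndarray:
    """Exact log P(X = k) for X ~ Hypergeometric(N, K, n) via log-factorials."""
    k = np.asarray(k, dtype=np.int64)
    lg = lambda x: gammaln(np.asarray(x, dtype=np.float64) + 1.0)
    return (
        lg(K) - lg(k) - lg(K - k)
        + lg(N - K) - lg(n - k) - lg(N - K - (n - k))
        - (lg(N) - lg(n) - lg(N - n))
    )


def hypergeometric_tail(
    N: int, K: int, n: int, k: int, convention: str = "inclusive"
) -> float:
    """Upper-tail hypergeometric probability, exact in log space.

    ``inclusive`` returns P(X >= k); ``exclusive`` returns P(X > k). The
    sum runs over the actual support, so both conventions are exact for
    any valid counts (the result is clipped into [0, 1] only to absorb
    last-ulp rounding of the log-sum).
    """
    if convention not in {"inclusive", "exclusive"}:
        raise ValueError(f"unknown convention {convention!r}")
    EnrichmentInput(N, K, n, k)  # validates margins and support
    lo = k if convention == "inclusive" else k + 1
    hi = min(K, n)
    if lo > hi:
        return 0.0
    if lo <= max(0, n + K - N):  # whole support: exactly 1 by definition
        return 1.0
    support = np.arange(lo, hi + 1)
    return float(min(1.0, math.exp(logsumexp(_log_pmf(N, K, n, support)))))


def enrich(
    families: Sequence[GeneFamily],
    primary_convention: str = "exclusive",
) -> EnrichmentResult:
    """Assemble overlap counts from classified families and test enrichment.

    Families must already carry ``is_trait_associated`` and ``sp_positive``.
    Both tail conventions are always computed; ``primary_convention``
    selects which one headlines the result (the exclusive survival-function
    tail by default, with the inclusive tail reported alongside as the
    standard one-sided test).
    """
    if not families:
        raise ValueError("no families to test")
    unclassified = [f.family_id for f in families if f.sp_positive is None]
    if unclassified:
        raise ValueError(f"families not classified: {unclassified[:5]}")
    N = len(families)
    K = sum(1 for f in families if f.sp_positive)
    n = sum(1 for f in families if f.is_trait_associated)
    k = sum(1 for f in families if f.is_trait_associated and f.sp_positive)
    if n == 0:
        raise ValueError("no trait-associated families")
    counts = EnrichmentInput(N, K, n, k)
    return EnrichmentResult(
        counts=counts,
        p_exclusive=hypergeometric_tail(N, K, n, k, "exclusive"),
        p_inclusive=hypergeometric_tail(N, K, n, k, "inclusive"),
        primary_convention=primary_convention,
    )


def phi_coefficient(a: int, b: int, c: int, d: int, n_excluded_unknown: int = 0) -> PhiResult:
    """Phi coefficient from a 2x2 table ``[[a, b], [c, d]]``.

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)). A zero marginal makes
    the coefficient undefined; it is reported as 0.0 with the
    ``degenerate_marginal`` flag set.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("negative cell count")
    if a + b + c + d < 1:
        raise ValueError("empty table")
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return PhiResult(a, b, c, d, 0.0, degenerate_marginal=True,
                         n_excluded_unknown=n_excluded_unknown)
    phi = (a * d - b * c) / math.sqrt(denom)
    return PhiResult(a, b, c, d, phi, n_excluded_unknown=n_excluded_unknown)


def phi_from_phenotypes(
    trait1: Mapping[str, int | None],
    trait2: Mapping[str, int | None],
) -> PhiResult:
    """Phi between two genome-level binary traits, excluding unknowns.

    Genomes missing from either table or marked NA (None) in either are
    excluded and counted in ``n_excluded_unknown``. Cell ``a`` counts
    genomes positive for both traits, ``d`` negative for both.
    """
    genomes = set(trait1) | set(trait2)
    a = b = c = d = excluded = 0
    for g in genomes:
        t1, t2 = trait1.get(g), trait2.get(g)
        if t1 is None or t2 is None:
            excluded += 1
            continue
        if t1 and t2:
            a += 1
        elif t1 and not t2:
            b += 1
        elif not t1 and t2:
            c += 1
        else:
            d += 1
    return phi_coefficient(a, b, c, d, n_excluded_unknown=excluded)


def build_families(
    family_table,
    sp_calls: Iterable[SignalPeptideCall] | Mapping[str, str],
    sp_classes: frozenset[str] | set[str] = DEFAULT_SP_CLASSES,
    threshold: float = 0.5,
) -> list[GeneFamily]:
    """Build classified GeneFamily objects from a family membership table.

    ``family_table`` is a DataFrame with columns family_id, protein_id,
    genome_id and optionally trait_associated (see ``read_family_table``).
    """
    families: list[GeneFamily] = []
    for fid, grp in family_table.groupby("family_id", sort=True):
        fam = GeneFamily(
            family_id=str(fid),
            members=list(grp["protein_id"]),
            genomes=list(grp["genome_id"]),
            is_trait_associated=bool(grp["trait_associated"].iloc[0])
            if "trait_associated" in grp.columns else False,
        )
        families.append(classify_family_sp(fam, sp_calls, sp_classes, threshold))
    return families
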