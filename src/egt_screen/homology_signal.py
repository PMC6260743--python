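"""Hit-table level screens: domain classification, contamination flags,
top-hit taxonomy, composition-adjusted enrichment and paralog merging.

All published cutoffs used here (">60%" of top hits, ">50%" hit overlap,
E-value "lower than 1e-50", best hit "< 1e-10") are strict inequalities:
boundary cases fail their gates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from .io_taxa import HitRow, HitSet, TaxonScheme

__all__ = [
    "DomainCall",
    "GroupDistribution",
    "ParalogPartition",
    "classify_query_domain",
    "classify_contig",
    "flag_bacterial_contigs",
    "top_hit_distribution",
    "enrichment_ratio",
    "merge_paralogs",
    "select_marker_homolog",
]

AMBIGUOUS = "Ambiguous"


@dataclass(frozen=True)
class DomainCall:
    """Domain-of-life call for one protein (or one contig).

    ``value`` is a domain name or ``"Ambiguous"``; ``supporting_fraction``
    is the fraction of considered hits (or gene calls) behind the winning
    domain, and ``n_hits_considered`` the denominator used.
    """

    value: str
    supporting_fraction: float
    n_hits_considered: int


@dataclass(frozen=True)
class GroupDistribution:
    """Counts of queries per higher group, e.g. a top-hit taxonomic profile."""

    counts: Mapping[str, int]
    n_classified: int
    n_no_hit: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_classified:
            raise ValueError("counts must sum to n_classified")

    def fraction(self, group: str) -> float:
        if self.n_classified == 0:
            return 0.0
        return self.counts.get(group, 0) / self.n_classified


@dataclass(frozen=True)
class ParalogPartition:
    """Disjoint groups of query identifiers considered paralogous."""

    groups: tuple[frozenset[str], ...]
    overlap_threshold: float

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self, query: str) -> frozenset[str]:
        for grp in self.groups:
            if query in grp:
                return grp
        raise KeyError(query)


def classify_query_domain(
    hits: Sequence[HitRow],
    scheme: TaxonScheme,
    top_n: int = 10,
    threshold: float = 0.6,
) -> DomainCall:
    """Classify a protein's domain of life from its top homology hits.

    The first ``min(top_n, available)`` ranked hits are considered; the
    protein is assigned to a domain only if that domain's hit fraction
    strictly exceeds *threshold*, otherwise the call is ambiguous.  A
    protein with zero hits is ambiguous (not an error); a subject that the
    scheme cannot resolve is an error.
    """
    considered = sorted(hits, key=lambda h: h.rank)[:top_n]
    n = len(considered)
    if n == 0:
        return DomainCall(AMBIGUOUS, 0.0, 0)
    tallies: dict[str, int] = {}
    for hit in considered:
        domain = scheme.domain_of(hit.subject_id)
        tallies[domain] = tallies.get(domain, 0) + 1
    best_domain, best_count = max(tallies.items(), key=lambda kv: kv[1])
    fraction = best_count / n
    if fraction > threshold:
        return DomainCall(best_domain, fraction, n)
    return DomainCall(AMBIGUOUS, fraction, n)


def classify_contig(
    gene_calls: Sequence[DomainCall], threshold: float = 0.6
) -> DomainCall:
    """Rescue call for a contig from the domain calls of its gene models.

    The denominator is the number of non-ambiguous gene calls; a contig
    whose genes are all ambiguous is itself ambiguous.  As for proteins,
    the winning domain's fraction must strictly exceed *threshold*.
    """
    if not gene_calls:
        raise ValueError("classify_contig requires at least one gene call")
    informative = [c for c in gene_calls if c.value != AMBIGUOUS]
    n = len(informative)
    if n == 0:
        return DomainCall(AMBIGUOUS, 0.0, 0)
    tallies: dict[str, int] = {}
    for call in informative:
        tallies[call.value] = tallies.get(call.value, 0) + 1
    best_domain, best_count = max(tallies.items(), key=lambda kv: kv[1])
    fraction = best_count / n
    if fraction > threshold:
        return DomainCall(best_domain, fraction, n)
    return DomainCall(AMBIGUOUS, fraction, n)


def flag_bacterial_contigs(
    contig_hits: HitSet,
    scheme: TaxonScheme,
    evalue_cutoff: float = 1e-50,
) -> set[str]:
    """Contigs with at least one bacterial hit at E-value strictly below cutoff.

    Mirrors the assembly decontamination step: a nucleotide-level hit to a
    Bacteria-domain subject at E < 1e-50 marks the whole contig as
    bacterial.  A hit at exactly the cutoff does not flag.
    """
    flagged: set[str] = set()
    for contig, rows in contig_hits.items():
        for hit in rows:
            if (
                scheme.domain_of(hit.subject_id) == "Bacteria"
                and hit.evalue < evalue_cutoff
            ):
                flagged.add(contig)
                break
    return flagged


def top_hit_distribution(
    hitset: HitSet,
    scheme: TaxonScheme,
    exclude_taxa: Callable[[str], bool] | None = None,
    evalue_cutoff: float = 1e-10,
) -> GroupDistribution:
    """Taxonomic distribution of each query's best surviving hit.

    Hits whose subject taxon satisfies *exclude_taxa* (typically: same
    genus as the query organism) and hits at E-value >= *evalue_cutoff*
    are removed before taking the best remaining hit.  Queries with no
    surviving hit are counted separately in ``n_no_hit``.
    """
    counts: dict[str, int] = {}
    n_classified = 0
    n_no_hit = 0
    for _, rows in hitset.items():
        best: HitRow | None = None
        for hit in sorted(rows, key=lambda h: h.rank):
            if hit.evalue >= evalue_cutoff:
                continue
            if exclude_taxa is not None and exclude_taxa(
                scheme.taxon_of(hit.subject_id)
            ):
                continue
            best = hit
            break
        if best is None:
            n_no_hit += 1
            continue
        group = scheme.group_of(best.subject_id)
        counts[group] = counts.get(group, 0) + 1
        n_classified += 1
    return GroupDistribution(counts, n_classified, n_no_hit)


def enrichment_ratio(
    dist_query: GroupDistribution,
    dist_control: GroupDistribution,
    db_comp: Mapping[str, float],
    group: str,
) -> float:
    """Database-composition-adjusted enrichment of *group* in the query profile.

    Each profile's group fraction is normalised by the group's share of the
    search database before taking the ratio::

        [f_q(g) / db(g)] / [f_c(g) / db(g)]

    which collapses to ``f_q(g) / f_c(g)`` when both profiles were scored
    against the same database.  A zero control fraction yields ``inf`` with
    a warning; a zero query fraction yields 0.0.
    """
    if group not in db_comp or db_comp[group] <= 0:
        raise ValueError(f"group {group!r} missing from db composition or <= 0")
    if dist_query.n_classified == 0 or dist_control.n_classified == 0:
        raise ValueError("both distributions must classify at least one query")
    f_q = dist_query.fraction(group) / db_comp[group]
    f_c = dist_control.fraction(group) / db_comp[group]
    if f_c == 0:
        if f_q == 0:
            return 0.0
        warnings.warn(
            f"control fraction for {group!r} is zero; enrichment is infinite",
            stacklevel=2,
        )
        return math.inf
    return f_q / f_c


def _overlap(h_i: frozenset, h_j: frozenset, denominator: str) -> float:
    inter = len(h_i & h_j)
    if denominator == "min":
        denom = min(len(h_i), len(h_j))
    elif denominator == "union":
        denom = len(h_i | h_j)
    elif denominator == "mean":
        denom = (len(h_i) + len(h_j)) / 2
    else:
        raise ValueError(f"unknown overlap denominator {denominator!r}")
    return inter / denom


def merge_paralogs(
    hitsets: Mapping[str, Iterable[str]],
    overlap_threshold: float = 0.5,
    denominator: str = "min",
) -> ParalogPartition:
    """Merge queries whose homolog lists overlap above the threshold.

    Two queries are paralogous when ``|H_i & H_j| / min(|H_i|, |H_j|)``
    strictly exceeds *overlap_threshold*; merging is transitive, so the
    partition is the connected components of the over-threshold overlap
    graph.  The min denominator guarantees that a subset relationship
    (short fragment vs full-length paralog) always merges; ``union`` and
    ``mean`` denominators are available as alternatives.
    """
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must be in (0, 1]")
    sets: dict[str, frozenset[str]] = {}
    for query, subjects in hitsets.items():
        fs = frozenset(subjects)
        if not fs:
            raise ValueError(f"query {query!r} has an empty hit set")
        sets[query] = fs
    graph = nx.Graph()
    graph.add_nodes_from(sets)
    queries = list(sets)
    for i, q_i in enumerate(queries):
        for q_j in queries[i + 1 :]:
            if _overlap(sets[q_i], sets[q_j], denominator) > overlap_threshold:
                graph.add_edge(q_i, q_j)
    components = sorted(
        (frozenset(c) for c in nx.connected_components(graph)),
        key=lambda c: sorted(c),
    )
    return ParalogPartition(tuple(components), overlap_threshold)


def select_marker_homolog(
    hits: Sequence[HitRow], evalue_cutoff: float = 1e-10
) -> str | None:
    """Best hit for a marker gene, or None if it misses the strict E-value gate."""
    if not hits:
        return None
    best = min(hits, key=lambda h: h.rank)
    if best.evalue < evalue_cutoff:
        return best.subject_id
    return None
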