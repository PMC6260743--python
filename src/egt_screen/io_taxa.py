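"""Validated containers and readers for the three screen input formats.

Taxonomic screening of a predicted proteome runs on three kinds of files:

* 12-column tabular homology-search output (BLAST/DIAMOND ``outfmt 6``),
  of which the query, subject, E-value and bitscore columns are retained;
* a four-column TSV mapping sequence identifiers to a taxon name, a
  higher-level group (supergroup) and a domain of life;
* newick gene trees whose internal node labels carry bootstrap-style
  support values, normalised here to a 0-100 scale.

All identifiers are treated case-sensitively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "DOMAINS",
    "DEFAULT_GROUP_DOMAINS",
    "ARCHAEPLASTIDA_GROUPS",
    "SECONDARY_PLASTID_GROUPS",
    "TaxonEntry",
    "TaxonScheme",
    "HitRow",
    "HitSet",
    "SupportTree",
    "read_hit_table",
    "read_taxon_map",
    "read_newick",
    "iter_newick",
    "write_newick",
]

#: Controlled vocabulary of domains of cellular life.
DOMAINS = ("Eukaryota", "Bacteria", "Archaea")

#: Default controlled vocabulary of higher groups and the domain each
#: belongs to.  Additional groups may be declared in a taxon-map header
#: block or passed to :class:`TaxonScheme` directly.
DEFAULT_GROUP_DOMAINS: dict[str, str] = {
    "Viridiplantae": "Eukaryota",
    "Glaucophyta": "Eukaryota",
    "Rhodophyta": "Eukaryota",
    "Cryptista": "Eukaryota",
    "Cryptophyceae": "Eukaryota",
    "Goniomonadea": "Eukaryota",
    "Haptista": "Eukaryota",
    "Stramenopiles": "Eukaryota",
    "Alveolata": "Eukaryota",
    "Rhizaria": "Eukaryota",
    "Amoebozoa": "Eukaryota",
    "Opisthokonta": "Eukaryota",
    "Excavata": "Eukaryota",
    "Bacteria": "Bacteria",
    "Archaea": "Archaea",
}

#: The primary-plastid supergroup: hosts of the original cyanobacterial
#: endosymbiosis.
ARCHAEPLASTIDA_GROUPS = frozenset({"Viridiplantae", "Glaucophyta", "Rhodophyta"})

#: Lineages carrying (or ancestrally carrying) secondary plastids; these are
#: the "intervening" taxa that turn an exclusive algal affinity into an
#: inclusive one.
SECONDARY_PLASTID_GROUPS = frozenset(
    {"Cryptophyceae", "Haptista", "Stramenopiles", "Alveolata", "Rhizaria"}
)


@dataclass(frozen=True)
class TaxonEntry:
    """Taxonomic assignment of one sequence/leaf identifier."""

    taxon: str
    group: str
    domain: str


class TaxonScheme:
    """Mapping from sequence/leaf identifiers to (taxon, group, domain).

    Invariants enforced at construction: every identifier maps to exactly
    one group, every group maps to exactly one domain, and domains come
    from the controlled vocabulary :data:`DOMAINS`.
    """

    def __init__(
        self,
        entries: Mapping[str, TaxonEntry | tuple[str, str, str]],
        group_domains: Mapping[str, str] | None = None,
    ) -> None:
        self._entries: dict[str, TaxonEntry] = {}
        self._group_domains: dict[str, str] = dict(group_domains or {})
        for group, domain in self._group_domains.items():
            if domain not in DOMAINS:
                raise ValueError(
                    f"group {group!r}: domain {domain!r} not in {DOMAINS}"
                )
        for ident, entry in entries.items():
            if not isinstance(entry, TaxonEntry):
                entry = TaxonEntry(*entry)
            if entry.domain not in DOMAINS:
                raise ValueError(
                    f"identifier {ident!r}: domain {entry.domain!r} not in {DOMAINS}"
                )
            known = self._group_domains.get(entry.group)
            if known is not None and known != entry.domain:
                raise ValueError(
                    f"group {entry.group!r} maps to both {known!r} and "
                    f"{entry.domain!r}"
                )
            self._group_domains.setdefault(entry.group, entry.domain)
            self._entries[ident] = entry

    # -- lookup ----------------------------------------------------------
    def entry(self, identifier: str) -> TaxonEntry:
        try:
            return self._entries[identifier]
        except KeyError:
            raise KeyError(
                f"identifier {identifier!r} is not resolvable in the taxon scheme"
            ) from None

    def taxon_of(self, identifier: str) -> str:
        return self.entry(identifier).taxon

    def group_of(self, identifier: str) -> str:
        return self.entry(identifier).group

    def domain_of(self, identifier: str) -> str:
        return self.entry(identifier).domain

    def domain_of_group(self, group: str) -> str:
        try:
            return self._group_domains[group]
        except KeyError:
            raise KeyError(f"group {group!r} is not declared in the scheme") from None

    @property
    def groups(self) -> tuple[str, ...]:
        """Declared group labels, in declaration/first-seen order."""
        return tuple(self._group_domains)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()


@dataclass(frozen=True)
class HitRow:
    """One retained homology hit; ``rank`` 1 is the best hit for the query."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    rank: int


class HitSet:
    """Per-query ordered homology hits.

    Hits are stored ranked: within each query, ranks run 1..n, ordered by
    ascending E-value with ties broken by descending bitscore and then
    ascending subject identifier.
    """

    def __init__(self, hits: Mapping[str, Sequence[HitRow]]) -> None:
        self._hits: dict[str, tuple[HitRow, ...]] = {
            q: tuple(rows) for q, rows in hits.items()
        }

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float, float]]
    ) -> "HitSet":
        """Build a ranked hit set from (query, subject, evalue, bitscore) rows."""
        by_query: dict[str, list[tuple[str, str, float, float]]] = {}
        for rec in records:
            by_query.setdefault(rec[0], []).append(rec)
        ranked: dict[str, list[HitRow]] = {}
        for query, rows in by_query.items():
            rows.sort(key=lambda r: (r[2], -r[3], r[1]))
            ranked[query] = [
                HitRow(query, s, e, b, rank)
                for rank, (_, s, e, b) in enumerate(rows, start=1)
            ]
        return cls(ranked)

    @property
    def queries(self) -> tuple[str, ...]:
        return tuple(self._hits)

    def __getitem__(self, query: str) -> tuple[HitRow, ...]:
        return self._hits[query]

    def get(self, query: str, default=()) -> tuple[HitRow, ...]:
        return self._hits.get(query, default)

    def __contains__(self, query: str) -> bool:
        return query in self._hits

    def __len__(self) -> int:
        return len(self._hits)

    def items(self):
        return self._hits.items()


def read_hit_table(path: str | Path) -> HitSet:
    """Read a 12-column tabular homology-search file into a ranked :class:`HitSet`.

    Only query, subject, E-value and bitscore are retained (columns 1, 2,
    11, 12).  Lines starting with ``#`` and blank lines are skipped.  An
    empty file yields an empty hit set.
    """
    records: list[tuple[str, str, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=12 tab-separated "
                    f"fields, found {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric E-value/bitscore"
                ) from exc
            if evalue < 0:
                raise ValueError(
                    f"{path}: line {lineno}: negative E-value {evalue}"
                )
            records.append((fields[0], fields[1], evalue, bitscore))
    return HitSet.from_records(records)


_TAXON_MAP_COLUMNS = ("identifier", "taxon", "group", "domain")


def read_taxon_map(
    path: str | Path,
    extra_group_domains: Mapping[str, str] | None = None,
) -> TaxonScheme:
    """Read a four-column identifier/taxon/group/domain TSV.

    The first non-comment line must be the header naming the four columns.
    Groups outside the default vocabulary are rejected unless declared in a
    header block of lines of the form ``#group<TAB>NAME<TAB>DOMAIN`` (or
    supplied via *extra_group_domains*).
    """
    vocab = dict(DEFAULT_GROUP_DOMAINS)
    if extra_group_domains:
        vocab.update(extra_group_domains)
    entries: dict[str, TaxonEntry] = {}
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts and parts[0].strip().lower() == "group":
                    if len(parts) != 3:
                        raise ValueError(
                            f"{path}: line {lineno}: group declaration needs "
                            "'#group<TAB>NAME<TAB>DOMAIN'"
                        )
                    name, domain = parts[1].strip(), parts[2].strip()
                    if domain not in DOMAINS:
                        raise ValueError(
                            f"{path}: line {lineno}: domain {domain!r} not in "
                            f"{DOMAINS}"
                        )
                    vocab[name] = domain
                continue
            fields = [f.strip() for f in line.split("\t")]
            if not header_seen:
                if tuple(f.lower() for f in fields[:4]) != _TAXON_MAP_COLUMNS:
                    raise ValueError(
                        f"{path}: line {lineno}: header must name columns "
                        f"{_TAXON_MAP_COLUMNS}"
                    )
                header_seen = True
                continue
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 columns, found "
                    f"{len(fields)}"
                )
            ident, taxon, group, domain = fields[:4]
            if domain not in DOMAINS:
                raise ValueError(
                    f"{path}: line {lineno}: domain {domain!r} not in {DOMAINS}"
                )
            if group not in vocab:
                raise ValueError(
                    f"{path}: line {lineno}: group {group!r} is not in the "
                    "controlled vocabulary and was not declared in a header "
                    "block"
                )
            if vocab[group] != domain:
                raise ValueError(
                    f"{path}: line {lineno}: group {group!r} belongs to domain "
                    f"{vocab[group]!r}, row says {domain!r}"
                )
            new = TaxonEntry(taxon, group, domain)
            old = entries.get(ident)
            if old is not None and old != new:
                raise ValueError(
                    f"{path}: line {lineno}: identifier {ident!r} already "
                    f"mapped to group {old.group!r}, conflicting with "
                    f"{group!r}"
                )
            entries[ident] = new
    if not header_seen:
        raise ValueError(f"{path}: missing header line")
    return TaxonScheme(entries)


class SupportTree:
    """A phylogenetic tree with per-internal-node support values in [0, 100].

    Wraps a :class:`dendropy.Tree`.  On construction, numeric internal node
    labels are interpreted as supports; values in [0, 1] are rescaled by
    x100 (fractional bootstrap conventions), values above 100 are rejected,
    and non-numeric labels are ignored with a warning.  Supports live on
    each internal node's subtending edge (the edge to its parent).
    """

    def __init__(self, tree: dendropy.Tree, *, _normalized: bool = False) -> None:
        self._tree = tree
        labels = [
            (leaf.taxon.label if leaf.taxon is not None else leaf.label)
            for leaf in tree.leaf_node_iter()
        ]
        if any(lbl is None for lbl in labels):
            raise ValueError("tree contains an unlabeled leaf")
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")
        if not _normalized:
            self._normalize_supports()

    def _normalize_supports(self) -> None:
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            nd.support = None
            label = nd.label
            nd.label = None
            if label is None or not str(label).strip():
                continue
            if nd.parent_node is None:
                # a support on the root edge is meaningless; drop it
                continue
            try:
                value = float(label)
            except ValueError:
                warnings.warn(
                    f"ignoring non-numeric internal node label {label!r}",
                    stacklevel=2,
                )
                continue
            if value < 0:
                raise ValueError(f"negative support value {value}")
            if value > 100:
                raise ValueError(
                    f"support value {value} exceeds 100 (percent scale)"
                )
            if value <= 1.0:
                value *= 100.0
            nd.support = value

    # -- construction ----------------------------------------------------
    @classmethod
    def from_string(cls, newick: str) -> "SupportTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
                rooting="force-rooted",
            )
        except Exception as exc:  # dendropy raises several parser errors
            raise ValueError(f"newick parse error: {exc}") from exc
        return cls(tree)

    # -- basic structure -------------------------------------------------
    @property
    def tree(self) -> dendropy.Tree:
        """The underlying dendropy tree (supports stored on ``node.support``)."""
        return self._tree

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(
            leaf.taxon.label for leaf in self._tree.leaf_node_iter()
        )

    def __len__(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def supports(self) -> tuple[float, ...]:
        """All defined internal supports (root excluded), preorder."""
        return tuple(
            nd.support
            for nd in self._tree.preorder_internal_node_iter()
            if nd.parent_node is not None and getattr(nd, "support", None) is not None
        )

    # -- serialisation ---------------------------------------------------
    def as_newick(self) -> str:
        """Serialise to newick with supports as internal node labels."""
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            support = getattr(nd, "support", None)
            nd.label = None if support is None else f"{support:g}"
        text = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        for nd in self._tree.preorder_node_iter():
            if not nd.is_leaf():
                nd.label = None
        return text

    def clone(self) -> "SupportTree":
        return SupportTree.from_string(self.as_newick())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<SupportTree with {len(self)} leaves>"


def read_newick(path: str | Path) -> SupportTree:
    """Read the first tree from a newick file."""
    return SupportTree.from_string(Path(path).read_text())


def iter_newick(path: str | Path) -> Iterator[SupportTree]:
    """Iterate over all trees in a (possibly multi-tree) newick file.

    Each ``;``-terminated statement is parsed independently, so trees in a
    multi-tree file do not share a taxon namespace.
    """
    text = Path(path).read_text()
    for statement in text.split(";"):
        if statement.strip():
            yield SupportTree.from_string(statement + ";")


def write_newick(tree: SupportTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")
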