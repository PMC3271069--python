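"""Post-alignment classification and similarity-network modularization.

Sequence queries (e.g. 16S rRNA gene fragments cut from a DGGE gel, or
peptides screened for carbohydrate-binding modules) are compared against
a reference database with an external aligner; this module consumes the
resulting tabular hit list. Hits above the user's E-value threshold are
dropped, the best surviving hit per query is picked (lowest E-value,
ties by highest bit score, then lexicographic subject id), and the query
inherits its subject's annotation: the taxonomic lineage truncated at a
requested rank (phylum, class, order or family), or the subject's CBM
(carbohydrate-binding module, CAZy) family when ``rank="CBM"``. Queries
with no surviving hit are reported as "unassigned".

Database modularization builds an undirected sequence-similarity graph
from an all-vs-all hit table (edge when any HSP in either direction
passes the edge E-value threshold) and partitions it into modules =
connected components, singletons included. Each module is represented
by its member with the most within-module connections (maximum degree,
ties to the lexicographically smallest id); the representative list is
the reduced, "modularized" database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .io_formats import HitRecord, HitTable, TaxonomyTable

__all__ = [
    "RANKS",
    "ClassifiedQuery",
    "CompositionSummary",
    "ModuleSet",
    "best_hits",
    "assign_queries",
    "summarize_composition",
    "build_similarity_graph",
    "modularize",
]

RANKS = ("phylum", "class", "order", "family", "CBM")
UNASSIGNED = "unassigned"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassifiedQuery:
    """A query's best passing hit and the label(s) it inherits.

    ``labels`` is usually a single label; a CBM subject carrying several
    binding-domain families contributes one label per family (the query
    is then counted once per distinct family in compositions).
    """

    query_id: str
    best_subject_id: str | None
    best_e_value: float | None
    labels: tuple[str, ...]

    @property
    def label(self) -> str:
        return self.labels[0]

    @property
    def assigned(self) -> bool:
        return self.labels != (UNASSIGNED,)


@dataclass
class CompositionSummary:
    """Label counts and fractions over the full query set."""

    rank: str
    counts: dict[str, int]
    total_queries: int
    unassigned: int

    def fractions(self) -> dict[str, float]:
        return {k: v / self.total_queries for k, v in self.counts.items()}

    def ordered_labels(self) -> list[str]:
        """Deterministic rendering order: count descending, then name."""
        return sorted(self.counts, key=lambda k: (-self.counts[k], k))


@dataclass
class ModuleSet:
    """A partition of similarity-graph nodes with one representative each."""

    modules: list[frozenset[str]]
    representatives: list[str]

    def __post_init__(self) -> None:
        if len(self.modules) != len(self.representatives):
            raise ValueError("one representative per module is required")
        seen: set[str] = set()
        for mod, rep in zip(self.modules, self.representatives):
            if rep not in mod:
                raise ValueError(f"representative {rep!r} is not a member of its module")
            if seen & mod:
                raise ValueError("modules must be disjoint")
            seen |= mod

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def n_nodes(self) -> int:
        return sum(len(m) for m in self.modules)

    @property
    def reduction_ratio(self) -> float:
        """|representatives| / |nodes|: the size of the reduced database."""
        return self.n_modules / self.n_nodes if self.n_nodes else 0.0

    def canonical(self) -> list[tuple[str, tuple[str, ...]]]:
        """(representative, sorted members) sorted by representative."""
        out = [
            (rep, tuple(sorted(mod)))
            for rep, mod in zip(self.representatives, self.modules)
        ]
        return sorted(out)


def best_hits(hits: HitTable, e_threshold: float) -> dict[str, HitRecord]:
    """Best passing hit per query: lowest E, then highest bit score, then id."""
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    best: dict[str, HitRecord] = {}
    for rec in hits:
        if rec.e_value > e_threshold:
            continue
        cur = best.get(rec.query_id)
        if cur is None or (rec.e_value, -rec.bit_score, rec.subject_id) < (
            cur.e_value,
            -cur.bit_score,
            cur.subject_id,
        ):
            best[rec.query_id] = rec
    return best


def _subject_labels(subject_id: str, meta: TaxonomyTable, rank: str) -> tuple[str, ...]:
    if rank == "CBM":
        fams = meta.cbm_families.get(subject_id)
        if fams:
            return tuple(dict.fromkeys(fams))
        return (UNCLASSIFIED,)
    lineage = meta.lineages.get(subject_id)
    if lineage is None:
        return (UNCLASSIFIED,)
    return (lineage.get(rank, UNCLASSIFIED) or UNCLASSIFIED,)


def assign_queries(
    hits: HitTable,
    meta: TaxonomyTable,
    e_threshold: float,
    rank: str = "phylum",
    query_ids: Sequence[str] | None = None,
) -> list[ClassifiedQuery]:
    """Classify each query by its best hit under the E-value threshold.

    ``query_ids`` may enumerate the full query set (e.g. from the input
    FASTA) so that queries with zero passing hits are reported as
    "unassigned"; by default the queries observed in the hit table are
    used. Subjects missing from the metadata produce a warning and the
    label "unclassified".
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    best = best_hits(hits, e_threshold)
    if query_ids is None:
        query_ids = hits.query_ids()
    out: list[ClassifiedQuery] = []
    for qid in query_ids:
        rec = best.get(qid)
        if rec is None:
            out.append(ClassifiedQuery(qid, None, None, (UNASSIGNED,)))
            continue
        if rec.subject_id not in meta:
            warnings.warn(
                f"subject {rec.subject_id!r} (best hit of {qid!r}) missing from metadata; "
                f"labelled '{UNCLASSIFIED}'",
                stacklevel=2,
            )
        labels = _subject_labels(rec.subject_id, meta, rank)
        out.append(ClassifiedQuery(qid, rec.subject_id, rec.e_value, labels))
    return out


def summarize_composition(assigned: list[ClassifiedQuery], rank: str = "phylum") -> CompositionSummary:
    """Count queries per label (one count per distinct label per query)."""
    if not assigned:
        raise ValueError("cannot summarize an empty query list")
    counts: dict[str, int] = {}
    unassigned = 0
    for q in assigned:
        if not q.assigned:
            unassigned += 1
        for label in dict.fromkeys(q.labels):
            counts[label] = counts.get(label, 0) + 1
    return CompositionSummary(
        rank=rank, counts=counts, total_queries=len(assigned), unassigned=unassigned
    )


def build_similarity_graph(
    pairwise_hits: HitTable,
    edge_e_threshold: float,
    exclude_self: bool = True,
    nodes: Iterable[str] | None = None,
) -> nx.Graph:
    """Similarity graph from an all-vs-all hit table.

    An undirected edge (a, b) exists when some HSP a->b or b->a has
    e_value <= edge_e_threshold and a != b; duplicates collapse.
    ``nodes`` may pre-register the full sequence set so sequences with
    no passing hit appear as isolated nodes (singleton modules).
    """
    g: nx.Graph = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for rec in pairwise_hits:
        g.add_node(rec.query_id)
        g.add_node(rec.subject_id)
        if rec.e_value > edge_e_threshold:
            continue
        if exclude_self and rec.query_id == rec.subject_id:
            continue
        if rec.query_id != rec.subject_id:
            g.add_edge(rec.query_id, rec.subject_id)
    return g


def modularize(graph: nx.Graph) -> ModuleSet:
    """Partition a similarity graph into modules with representatives.

    Modules are the connected components (singletons included); each
    module's representative is the member connected to the most module
    members (maximum degree), ties resolved to the lexicographically
    smallest id. Output order is deterministic (sorted by representative).
    """
    modules: list[frozenset[str]] = []
    reps: list[str] = []
    for comp in nx.connected_components(graph):
        members = frozenset(comp)
        rep = min(members, key=lambda v: (-graph.degree(v), v))
        modules.append(members)
        reps.append(rep)
    order = sorted(range(len(reps)), key=lambda i: reps[i])
    return ModuleSet([modules[i] for i in order], [reps[i] for i in order])
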