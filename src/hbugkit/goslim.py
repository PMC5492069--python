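"""Pfam-based GO annotation and penultimate-ancestor GO-Slim resolution.

Transcripts annotated with Pfam domains acquire Gene Ontology terms through
a pfam2go mapping table. Fine-grained terms are then projected onto a
"GO-Slim" view defined structurally: a term resolves to every *penultimate*
ancestor — each direct is_a child of its aspect root that lies on some is_a
path from the term up to that root. Only ``is_a`` edges are traversed;
``part_of`` and other relations are ignored (a documented limitation).

The ontology is held as a rooted DAG per aspect (biological_process,
cellular_component, molecular_function), parsed from OBO text via
``obonet``/``networkx``; obsolete terms are dropped at parse time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "ASPECTS",
    "OntologyGraph",
    "strip_version",
    "map_pfam_to_go",
    "resolve_goslim",
    "slim_assignments",
    "count_distinct_terms",
    "tabulate_pfam",
]

log = logging.getLogger(__name__)

ASPECTS = ("biological_process", "cellular_component", "molecular_function")

_PFAM_RE = re.compile(r"^PF\d{5}(\.\d+)?$")


@dataclass
class OntologyGraph:
    """Rooted is_a DAG over GO-style terms, one root per aspect.

    ``graph`` holds directed edges child -> parent (is_a only). ``aspect``
    maps every term to its namespace; ``roots`` maps each namespace to its
    single root term.
    """

    graph: nx.DiGraph
    aspect: dict[str, str]
    roots: dict[str, str]

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology is_a graph contains a cycle")
        for u, v in self.graph.edges:
            if self.aspect[u] != self.aspect[v]:
                raise ValueError(f"is_a edge {u} -> {v} crosses aspects")
        for term, asp in self.aspect.items():
            root = self.roots.get(asp)
            if root is None:
                raise ValueError(f"no root recorded for aspect {asp!r}")
            if term != root and not nx.has_path(self.graph, term, root):
                raise ValueError(f"term {term} cannot reach its aspect root {root}")

    @classmethod
    def from_obo(cls, path) -> "OntologyGraph":
        """Parse an OBO file, keeping is_a edges of non-obsolete terms."""
        raw = obonet.read_obo(path)  # drops obsolete stanzas by default
        g = nx.DiGraph()
        aspect: dict[str, str] = {}
        for term, data in raw.nodes(data=True):
            ns = data.get("namespace")
            if ns not in ASPECTS:
                log.warning("dropping term %s with unknown namespace %r", term, ns)
                continue
            g.add_node(term)
            aspect[term] = ns
        for child, parent, key in raw.edges(keys=True):
            if key != "is_a":
                continue
            if child in aspect and parent in aspect:
                g.add_edge(child, parent)
        roots = {}
        for asp in sorted(set(aspect.values())):
            cands = [t for t, a in aspect.items() if a == asp and g.out_degree(t) == 0]
            if len(cands) != 1:
                raise ValueError(f"aspect {asp!r} has {len(cands)} roots, expected 1")
            roots[asp] = cands[0]
        return cls(graph=g, aspect=aspect, roots=roots)

    def root_of(self, term: str) -> str:
        return self.roots[self.aspect[term]]

    def slim_terms(self, aspect: str) -> set[str]:
        """Direct is_a children of an aspect's root (the slim vocabulary)."""
        root = self.roots[aspect]
        return {u for u, v in self.graph.in_edges(root)}

    def __contains__(self, term: str) -> bool:
        return term in self.aspect


def strip_version(accession: str) -> str:
    """Drop a Pfam accession's version suffix (PF00067.20 -> PF00067)."""
    return accession.split(".", 1)[0]


def map_pfam_to_go(
    assignments: pd.DataFrame, pfam2go: pd.DataFrame
) -> pd.DataFrame:
    """Join transcript Pfam assignments to GO terms via a pfam2go table.

    ``assignments`` needs columns ``transcript_id``, ``pfam``; ``pfam2go``
    needs ``pfam``, ``go_term``. Version suffixes on accessions are ignored
    for matching. Returns distinct (transcript_id, go_term) pairs; Pfams
    absent from the map contribute nothing.
    """
    for col in ("transcript_id", "pfam"):
        if col not in assignments.columns:
            raise ValueError(f"assignments table missing column {col!r}")
    for i, acc in enumerate(pfam2go.get("pfam", pd.Series(dtype=str)), start=1):
        if not _PFAM_RE.match(str(acc)):
            raise ValueError(f"pfam2go row {i}: malformed accession {acc!r}")
    if "go_term" not in pfam2go.columns:
        raise ValueError("pfam2go table missing column 'go_term'")
    left = assignments.assign(_key=assignments["pfam"].map(strip_version))
    right = pfam2go.assign(_key=pfam2go["pfam"].map(strip_version))[["_key", "go_term"]]
    merged = left.merge(right, on="_key")[["transcript_id", "go_term"]]
    return merged.drop_duplicates(ignore_index=True)


def resolve_goslim(term: str, g: OntologyGraph) -> set[str]:
    """Resolve a term to its penultimate ancestors.

    Returns every direct is_a child of the term's aspect root lying on some
    is_a path from ``term`` to the root; a term that is itself a child of
    the root resolves to itself. The aspect root has no penultimate ancestor
    and is rejected, as are unknown terms.
    """
    if term not in g:
        raise KeyError(f"unknown term {term!r}")
    root = g.root_of(term)
    if term == root:
        raise ValueError(f"{term} is an aspect root; no penultimate ancestor exists")
    # Edges run child -> parent, so graph-descendants of `term` are its
    # ontology ancestors. Any ancestor with an is_a edge into the root lies
    # on a term -> ... -> ancestor -> root path by construction.
    upward = {term} | nx.descendants(g.graph, term)
    slim = {u for u in upward if g.graph.has_edge(u, root)}
    if not slim:
        raise ValueError(f"{term} has no is_a path to its aspect root")
    return slim


def slim_assignments(
    pairs: pd.DataFrame, g: OntologyGraph
) -> pd.DataFrame:
    """Project (transcript_id, go_term) pairs onto slim terms.

    Aspect roots appearing as annotations are skipped (they carry no slim
    meaning). Returns distinct (transcript_id, aspect, slim_term) rows.
    """
    rows = []
    for tid, term in pairs[["transcript_id", "go_term"]].itertuples(index=False):
        if term not in g or term == g.root_of(term):
            continue
        asp = g.aspect[term]
        for s in sorted(resolve_goslim(term, g)):
            rows.append((tid, asp, s))
    out = pd.DataFrame(rows, columns=["transcript_id", "aspect", "slim_term"])
    return out.drop_duplicates(ignore_index=True)


def count_distinct_terms(
    pairs: pd.DataFrame, g: OntologyGraph
) -> dict[str, dict[str, int]]:
    """Distinct annotated term counts per aspect, full and slim.

    Returns ``{aspect: {"full": n_distinct_terms, "slim": n_distinct_slim}}``
    over the three aspects; terms absent from the ontology are ignored.
    """
    full: dict[str, set] = {a: set() for a in ASPECTS}
    slim: dict[str, set] = {a: set() for a in ASPECTS}
    for term in pairs["go_term"].unique():
        if term not in g:
            continue
        asp = g.aspect[term]
        full[asp].add(term)
        if term != g.root_of(term):
            slim[asp] |= resolve_goslim(term, g)
    return {a: {"full": len(full[a]), "slim": len(slim[a])} for a in ASPECTS}


def tabulate_pfam(assignments: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Rank Pfam accessions by the number of transcripts carrying them.

    Descending count, ties broken by accession; ``top_k`` limits the rows
    (None or k beyond the table returns everything).
    """
    if top_k is not None and top_k < 0:
        raise ValueError("top_k must be >= 0")
    counts = (
        assignments.drop_duplicates(["transcript_id", "pfam"])
        .groupby("pfam", sort=False)
        .size()
        .reset_index(name="count")
        .sort_values(["count", "pfam"], ascending=[False, True], ignore_index=True)
    )
    return counts if top_k is None else counts.head(top_k).reset_index(drop=True)
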