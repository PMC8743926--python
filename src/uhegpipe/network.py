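"""Term co-annotation counting and phenotype-tree export.

Two machine-readable network products mirror the study's visual analyses:

* a weighted co-annotation graph — for every gene, all unordered pairs of
  its terms passing a level filter (level-4 terms by default, the most
  specific retained level); an edge's weight is the number of genes
  sharing that pair;
* one hierarchical phenotype tree per top-level term — the term's is_a
  descendant closure truncated to the retained levels, each node carrying
  the number of genes annotated with exactly that term, pruned so that
  zero-count nodes are kept only when needed to connect an annotated
  descendant to the top-level term.

Exports target network viewers (Cytoscape and friends): SIF with a node
attribute sidecar, GraphML, and weighted edge-list TSV.  Layout and
rendering are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .annotation import GeneTermAnnotation
from .ontology import Ontology

__all__ = [
    "PairCount",
    "PhenotypeTree",
    "pair_counts",
    "build_phenotype_tree",
    "export_network",
    "EXPORT_FORMATS",
]

EXPORT_FORMATS = ("sif", "graphml", "edgelist")


@dataclass(frozen=True)
class PairCount:
    term_a: str  # term_a < term_b lexicographically
    term_b: str
    shared_genes: int


@dataclass
class PhenotypeTree:
    top_term: str
    nodes: dict[str, tuple[str, int, int]]  # term_id -> (name, level, gene_count)
    edges: list[tuple[str, str]]  # parent -> child


def pair_counts(
    annotation: GeneTermAnnotation,
    level_filter: Iterable[int] | None = None,
) -> list[PairCount]:
    """Count genes sharing each unordered pair of terms passing the filter.

    Default filter: the deepest retained level only.
    """
    levels = (
        {annotation.max_level} if level_filter is None else set(level_filter)
    )
    bad = levels - set(range(1, annotation.max_level + 1))
    if bad:
        raise ValueError(f"level filter outside 1..{annotation.max_level}: {sorted(bad)}")
    counts: dict[tuple[str, str], int] = {}
    for terms in annotation.genes.values():
        passing = sorted({t for t, lv in terms if lv in levels})
        for i, a in enumerate(passing):
            for b in passing[i + 1 :]:
                counts[(a, b)] = counts.get((a, b), 0) + 1
    return [
        PairCount(a, b, n) for (a, b), n in sorted(counts.items())
    ]


def build_phenotype_tree(
    ontology: Ontology,
    top_term: str,
    annotation: GeneTermAnnotation,
    max_level: int | None = None,
) -> PhenotypeTree:
    """Hierarchical tree under one top-level term with per-term gene counts.

    Nodes are the top term's descendants (itself included) with level at
    most ``max_level``; gene_count is the number of distinct genes whose
    annotation contains exactly that term.  Zero-count nodes survive only
    if some retained descendant is annotated (path preservation); edges are
    the is_a links induced on retained nodes, directed parent -> child.
    """
    if ontology.term_level(top_term) != 1:
        raise ValueError(
            f"top term {top_term!r} has level {ontology.term_level(top_term)}, expected 1"
        )
    max_level = annotation.max_level if max_level is None else max_level

    per_term: dict[str, set[str]] = {}
    for g, terms in annotation.genes.items():
        for tid, _ in terms:
            per_term.setdefault(tid, set()).add(g)

    members = {
        t
        for t in ontology.descendant_closure([top_term])
        if ontology.term_level(t) <= max_level
    }
    # keep nodes that are annotated or lie on a path to an annotated node
    annotated = {t for t in members if per_term.get(t)}
    keep = set()
    for t in annotated:
        keep.add(t)
        keep |= ontology.ancestors(t) & members
    nodes = {
        t: (ontology.name(t), ontology.term_level(t), len(per_term.get(t, set())))
        for t in sorted(keep)
    }
    edges = sorted(
        (parent, child)
        for child in keep
        for parent in ontology.parents(child)
        if parent in keep
    )
    return PhenotypeTree(top_term=top_term, nodes=nodes, edges=edges)


def _tree_graph(tree: PhenotypeTree) -> nx.DiGraph:
    g = nx.DiGraph()
    for tid, (name, level, count) in sorted(tree.nodes.items()):
        g.add_node(tid, name=name, level=level, gene_count=count)
    g.add_edges_from(tree.edges, interaction="is_a")
    return g


def _pair_graph(pairs: Sequence[PairCount]) -> nx.Graph:
    g = nx.Graph()
    for p in pairs:
        g.add_edge(p.term_a, p.term_b, weight=p.shared_genes, interaction="coannotated")
    return g


def export_network(
    obj: PhenotypeTree | Sequence[PairCount],
    fmt: str,
    path: str | Path,
) -> list[Path]:
    """Write a tree or pair list for a network viewer; deterministic output.

    ``fmt`` is one of ``sif`` (plus a ``.nodes.tsv`` attribute sidecar for
    trees), ``graphml`` or ``edgelist``.  Returns the written paths.
    """
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; choose from {EXPORT_FORMATS}")
    path = Path(path)
    is_tree = isinstance(obj, PhenotypeTree)
    written: list[Path] = []

    if fmt == "sif":
        lines = []
        if is_tree:
            connected = {n for e in obj.edges for n in e}
            for parent, child in obj.edges:
                lines.append(f"{parent}\tis_a\t{child}")
            for tid in sorted(set(obj.nodes) - connected):  # isolated nodes
                lines.append(tid)
        else:
            for p in obj:
                lines.append(f"{p.term_a}\tcoannotated\t{p.term_b}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        written.append(path)
        if is_tree:
            sidecar = path.with_suffix(".nodes.tsv")
            rows = ["term_id\tname\tlevel\tgene_count"]
            for tid, (name, level, count) in sorted(obj.nodes.items()):
                rows.append(f"{tid}\t{name}\t{level}\t{count}")
            sidecar.write_text("\n".join(rows) + "\n")
            written.append(sidecar)
    elif fmt == "graphml":
        g = _tree_graph(obj) if is_tree else _pair_graph(obj)
        nx.write_graphml(g, path)
        written.append(path)
    else:  # edgelist
        lines = ["source\ttarget\tinteraction\tweight"]
        if is_tree:
            for parent, child in obj.edges:
                lines.append(f"{parent}\t{child}\tis_a\t1")
        else:
            for p in obj:
                lines.append(f"{p.term_a}\t{p.term_b}\tcoannotated\t{p.shared_genes}")
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return written
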