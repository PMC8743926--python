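"""Phenotype-ontology handling: OBO parsing, is_a closures, term levels.

The Mammalian Phenotype Ontology is a single-rooted DAG of phenotype terms
linked by ``is_a`` relations; a term may have several parents.  This module
parses the OBO flat format (via :mod:`obonet`), validates the single-root /
acyclicity invariants, and exposes the three graph primitives the
annotation pipeline needs: ancestor sets, minimum-depth term levels
(root = 0, the 27 top-level phenotype classes = 1), and downward descendant
closures (used to excise the "normal phenotype" and "no phenotypic
analysis" subtrees).

Only ``is_a`` edges are honored; other OBO relationship types are counted
and ignored.  Obsolete terms are retained for bookkeeping but excluded
from every closure and level query.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = ["Term", "Ontology", "parse_obo", "read_obo", "write_obo", "OboFormatError"]


class OboFormatError(ValueError):
    """Structurally invalid ontology (cycle, zero or multiple roots, ...)."""


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    parent_ids: frozenset[str]
    obsolete: bool = False


class Ontology:
    """Rooted is_a DAG over phenotype terms.

    Levels follow the minimum-depth convention: the level of a multi-parent
    term is one plus the minimum of its parents' levels, so a term counts as
    a "level-N term" as soon as any path from the root reaches it in N
    steps.  Pass ``level_convention="max"`` for a maximum-depth sensitivity
    variant.
    """

    def __init__(self, terms: Mapping[str, Term], level_convention: str = "min"):
        if level_convention not in {"min", "max"}:
            raise ValueError("level_convention must be 'min' or 'max'")
        self.terms: dict[str, Term] = dict(terms)
        self._active = {t for t, term in self.terms.items() if not term.obsolete}

        # child -> parent graph over non-obsolete terms
        g = nx.DiGraph()
        g.add_nodes_from(self._active)
        for tid in self._active:
            for p in self.terms[tid].parent_ids:
                if p not in self.terms:
                    raise OboFormatError(f"term {tid} has unknown parent {p}")
                g.add_edge(tid, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OboFormatError(f"is_a cycle involving term {cycle[0][0]}")
        roots = [t for t in self._active if not self.terms[t].parent_ids]
        if len(roots) != 1:
            raise OboFormatError(
                f"ontology must have exactly one root, found {len(roots)}: "
                f"{sorted(roots)[:5]}"
            )
        self.root_id: str = roots[0]
        self._up = g  # edges child -> parent

        # terms reaching the root by walking child->parent edges
        unreachable = self._active - nx.ancestors(g, self.root_id) - {self.root_id}
        if unreachable:
            raise OboFormatError(
                f"terms not reachable from root: {sorted(unreachable)[:5]}"
            )

        # min- (or max-) depth levels via topological sweep
        levels: dict[str, int] = {self.root_id: 0}
        agg = min if level_convention == "min" else max
        for tid in reversed(list(nx.topological_sort(g))):
            if tid == self.root_id:
                continue
            levels[tid] = 1 + agg(levels[p] for p in self.terms[tid].parent_ids)
        self._levels = levels
        self.level_convention = level_convention

        self._by_name: dict[str, str] = {}
        for tid in self._active:
            self._by_name.setdefault(self.terms[tid].name, tid)

    # -- queries ---------------------------------------------------------

    def _check(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise KeyError(f"unknown term {term_id!r}")
        if term_id not in self._active:
            raise KeyError(f"term {term_id!r} is obsolete")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._active

    def __len__(self) -> int:
        return len(self._active)

    def name(self, term_id: str) -> str:
        self._check(term_id)
        return self.terms[term_id].name

    def id_of_name(self, name: str) -> str:
        if name not in self._by_name:
            raise KeyError(f"no term named {name!r}")
        return self._by_name[name]

    def children(self, term_id: str) -> set[str]:
        self._check(term_id)
        return set(self._up.predecessors(term_id))

    def parents(self, term_id: str) -> set[str]:
        self._check(term_id)
        return set(self.terms[term_id].parent_ids)

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable upward via is_a, root included, term excluded."""
        self._check(term_id)
        return set(nx.descendants(self._up, term_id))

    def term_level(self, term_id: str) -> int:
        """Depth from the root (root = 0, its children = 1)."""
        self._check(term_id)
        return self._levels[term_id]

    def descendant_closure(self, seed_ids: Iterable[str]) -> set[str]:
        """Seeds plus every is_a descendant of any seed."""
        out: set[str] = set()
        for s in seed_ids:
            self._check(s)
            out.add(s)
            out |= set(nx.ancestors(self._up, s))
        return out

    def top_level_terms(self) -> set[str]:
        return self.children(self.root_id)


def parse_obo(text: str, level_convention: str = "min") -> Ontology:
    """Parse OBO 1.2-style text into an :class:`Ontology`.

    Honors ``id``, ``name``, ``is_a`` and ``is_obsolete``; other
    relationship lines are ignored.
    """
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    terms: dict[str, Term] = {}
    for tid, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents = frozenset(data.get("is_a", [])) if not obsolete else frozenset()
        terms[tid] = Term(
            term_id=tid,
            name=data.get("name", tid),
            parent_ids=parents,
            obsolete=obsolete,
        )
    if not terms:
        raise OboFormatError("no [Term] stanzas found")
    return Ontology(terms, level_convention=level_convention)


def read_obo(path: str | Path, level_convention: str = "min") -> Ontology:
    return parse_obo(Path(path).read_text(), level_convention=level_convention)


def write_obo(ontology: Ontology, path: str | Path | None = None) -> str:
    """Serialize the id/name/is_a/is_obsolete subset of OBO; deterministic."""
    lines = ["format-version: 1.2", "ontology: phenotype", ""]
    for tid in sorted(ontology.terms):
        term = ontology.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {term.term_id}")
        lines.append(f"name: {term.name}")
        for p in sorted(term.parent_ids):
            lines.append(f"is_a: {p} ! {ontology.terms[p].name}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
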