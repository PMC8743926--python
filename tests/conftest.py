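"""Shared fixtures and independent brute-force oracles.

The oracle helpers deliberately avoid the package's graph machinery: they
re-parse OBO text with a minimal line scanner and compute reachability and
depths by plain recursion/BFS, so that graph-primitive tests compare two
independent routes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from uhegpipe.expression import ExpressionMatrix, SampleMeta
from uhegpipe.ontology import parse_obo


# --------------------------------------------------------------------------
# minimal independent OBO scanner (oracle side)
# --------------------------------------------------------------------------


def scan_obo(text: str) -> dict[str, dict]:
    """term_id -> {name, parents: set, obsolete: bool} by plain line scanning."""
    terms: dict[str, dict] = {}
    cur = None
    for line in text.splitlines():
        line = line.strip()
        if line == "[Term]":
            cur = {"name": "", "parents": set(), "obsolete": False}
        elif cur is not None and line.startswith("id: "):
            terms[line[4:].strip()] = cur
        elif cur is not None and line.startswith("name: "):
            cur["name"] = line[6:].strip()
        elif cur is not None and line.startswith("is_a: "):
            cur["parents"].add(line[6:].split("!")[0].strip())
        elif cur is not None and line.startswith("is_obsolete: true"):
            cur["obsolete"] = True
        elif line.startswith("["):
            cur = None
    return terms


def oracle_ancestors(terms: dict[str, dict], tid: str) -> set[str]:
    out: set[str] = set()

    def walk(t: str) -> None:
        for p in terms[t]["parents"]:
            if p not in out:
                out.add(p)
                walk(p)

    walk(tid)
    return out


def oracle_levels(terms: dict[str, dict]) -> dict[str, int]:
    active = {t for t, d in terms.items() if not d["obsolete"]}
    roots = [t for t in active if not terms[t]["parents"]]
    assert len(roots) == 1
    children: dict[str, list[str]] = {}
    for t in active:
        for p in terms[t]["parents"]:
            children.setdefault(p, []).append(t)
    levels = {roots[0]: 0}
    frontier = [roots[0]]
    while frontier:
        nxt = []
        for t in frontier:
            for c in children.get(t, []):
                if c not in levels:
                    levels[c] = levels[t] + 1
                    nxt.append(c)
        frontier = nxt
    return levels


def oracle_descendants(terms: dict[str, dict], seeds) -> set[str]:
    out = set(seeds)
    changed = True
    while changed:
        changed = False
        for t, d in terms.items():
            if d["obsolete"] or t in out:
                continue
            if d["parents"] & out:
                out.add(t)
                changed = True
    return out


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

DIAMOND_OBO = """\
format-version: 1.2
ontology: phenotype

[Term]
id: MP:0000001
name: root

[Term]
id: MP:0000002
name: branch a
is_a: MP:0000001

[Term]
id: MP:0000003
name: branch b
is_a: MP:0000001

[Term]
id: MP:0000004
name: deep under a
is_a: MP:0000002

[Term]
id: MP:0000005
name: deeper under a
is_a: MP:0000004

[Term]
id: MP:0000006
name: diamond child
is_a: MP:0000003
is_a: MP:0000005

[Term]
id: MP:0000007
name: leaf
is_a: MP:0000006

[Term]
id: MP:0000008
name: normal phenotype
is_a: MP:0000001

[Term]
id: MP:0000009
name: normal child
is_a: MP:0000008

[Term]
id: MP:0000010
name: no phenotypic analysis
is_a: MP:0000001

[Term]
id: MP:0000011
name: retired
is_obsolete: true
"""


@pytest.fixture
def diamond_ontology():
    """Small hand-written DAG with a multi-parent diamond, excluded
    subtrees and one obsolete term."""
    return parse_obo(DIAMOND_OBO)


def make_matrix(values: np.ndarray, probe_ids=None, days=None) -> ExpressionMatrix:
    """Matrix helper: values (P x S), samples from one experiment."""
    P, S = values.shape
    probe_ids = probe_ids or [f"p{i:03d}" for i in range(P)]
    days = days or [10] * S
    samples = [SampleMeta(f"s{j}", "EXP", days[j], j + 1) for j in range(S)]
    df = pd.DataFrame(values, index=probe_ids, columns=[s.sample_id for s in samples])
    return ExpressionMatrix(df, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
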