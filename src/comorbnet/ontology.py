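"""Rooted-ontology helpers (HPO-style parent-child term tables)."""

from __future__ import annotations

import pandas as pd

from .containers import ROOT_MARKER


def validate_ontology(ontology: pd.DataFrame) -> str:
    """Check the (term_id, parent_id) table is a rooted DAG; return the root.

    Exactly one term must have the root marker as parent; every other
    parent must itself be a term; no cycles are allowed.
    """
    terms = set(ontology["term_id"])
    if len(terms) != len(ontology):
        raise ValueError("duplicate term_id rows")
    roots = ontology.loc[ontology["parent_id"] == ROOT_MARKER, "term_id"].tolist()
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root, found {len(roots)}")
    for parent in ontology["parent_id"]:
        if parent != ROOT_MARKER and parent not in terms:
            raise ValueError(f"parent {parent!r} is not a term")
    # cycle check by iterative parent-walk with memoized reachability
    parent_of = dict(zip(ontology["term_id"], ontology["parent_id"]))
    safe: set[str] = set()
    for start in parent_of:
        seen = []
        node = start
        while node != ROOT_MARKER and node not in safe:
            if node in seen:
                raise ValueError(f"cycle through term {node!r}")
            seen.append(node)
            node = parent_of[node]
        safe.update(seen)
    return roots[0]


def children_map(ontology: pd.DataFrame) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for term, parent in zip(ontology["term_id"], ontology["parent_id"]):
        if parent != ROOT_MARKER:
            out.setdefault(parent, []).append(term)
    return out


def subtree_terms(ontology: pd.DataFrame, root: str) -> frozenset[str]:
    """Return ``root`` plus all of its descendants."""
    if root not in set(ontology["term_id"]):
        raise KeyError(f"unknown ontology term {root!r}")
    kids = children_map(ontology)
    out = {root}
    stack = [root]
    while stack:
        node = stack.pop()
        for child in kids.get(node, ()):
            if child not in out:
                out.add(child)
                stack.append(child)
    return frozenset(out)
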