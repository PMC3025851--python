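"""Phylogenetic lability of a binary trait via small parsimony.

Teleost fishes carry duplicate glucocorticoid receptors (GR1, GR2) whose
mineralocorticoid (aldosterone/DOC) sensitivity varies between species in a
way that does not track the receptor phylogeny: sister receptors can differ
while distant receptors agree. This module quantifies that observation as
the minimum number of state changes a binary sensitivity character requires
on a user-supplied rooted tree.

The count is computed by unit-cost small parsimony (Sankoff dynamic
programming), which handles polytomies natively and lets tips with unknown
state contribute no constraint. A trait whose minimum change count exceeds 1
cannot be explained by a single origin on the tree — the operational meaning
of "not consistent with the phylogeny". Branch lengths are ignored; the
claim concerns topology only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping

import dendropy
import pandas as pd

from .errors import InputError, ParseError

__all__ = [
    "STATES",
    "UNKNOWN",
    "parse_newick",
    "read_tip_states",
    "fitch_min_changes",
    "lability_report",
]

#: The two observable character states.
STATES = ("sensitive", "insensitive")
UNKNOWN = "unknown"

_INF = float("inf")


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted newick string; polytomies allowed, tips must be unique."""
    if ";" not in text:
        raise ParseError("newick string must be terminated by ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"cannot parse newick: {exc}") from exc
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None]
    if len(tips) < 2:
        raise InputError("tree needs >= 2 tips")
    dupes = {t for t in tips if tips.count(t) > 1}
    if dupes:
        raise ParseError(f"duplicate tip labels: {sorted(dupes)}")
    return tree


def read_tip_states(source: str | Path | IO[str]) -> dict[str, str]:
    """Read a two-column ``tip,state`` CSV; states sensitive/insensitive/unknown."""
    df = pd.read_csv(source)
    if df.shape[1] < 2:
        raise ParseError("tip state CSV needs two columns (tip, state)")
    tipc, stc = df.columns[:2]
    states = {}
    for tip, st in zip(df[tipc], df[stc]):
        st = str(st).strip().lower()
        if st not in (*STATES, UNKNOWN):
            raise ParseError(f"tip {tip!r}: unknown state {st!r}")
        states[str(tip)] = st
    return states


def _validate_states(tree: dendropy.Tree, states: Mapping[str, str]) -> dict[str, str]:
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown_tips = sorted(set(states) - tips)
    if unknown_tips:
        raise InputError(f"states name tips absent from the tree: {unknown_tips}")
    full = {t: states.get(t, UNKNOWN) for t in tips}
    for t, s in full.items():
        if s not in (*STATES, UNKNOWN):
            raise InputError(f"tip {t!r}: state must be one of {STATES + (UNKNOWN,)}, got {s!r}")
    if all(s == UNKNOWN for s in full.values()):
        raise InputError("all tips have unknown state; minimum change count is undefined")
    return full


def fitch_min_changes(tree: dendropy.Tree, states: Mapping[str, str]) -> int:
    """Minimum number of state changes of a binary character on the tree.

    Unit-cost parsimony by postorder dynamic programming: each node carries
    the minimal cost of the subtree below it conditional on its own state;
    a child contributes ``min(cost[same], 1 + cost[other])``. Tips with
    unknown state (or absent from ``states``) are unconstrained. Exact for
    arbitrary (including multifurcating) rooted trees, and invariant to the
    root position because the cost is symmetric.
    """
    full = _validate_states(tree, states)
    cost: dict[int, tuple[float, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = full[node.taxon.label]
            if s == UNKNOWN:
                cost[id(node)] = (0.0, 0.0)
            else:
                cost[id(node)] = (0.0, _INF) if s == STATES[0] else (_INF, 0.0)
        else:
            c0 = c1 = 0.0
            for child in node.child_nodes():
                ch0, ch1 = cost[id(child)]
                c0 += min(ch0, ch1 + 1.0)
                c1 += min(ch1, ch0 + 1.0)
            cost[id(node)] = (c0, c1)
    root0, root1 = cost[id(tree.seed_node)]
    return int(min(root0, root1))


def lability_report(tree: dendropy.Tree, states: Mapping[str, str]) -> dict:
    """Summarize trait lability: minimum changes and single-origin consistency.

    The trait pattern is called consistent with the phylogeny iff at most one
    state change explains it (a single origin or loss).
    """
    full = _validate_states(tree, states)
    changes = fitch_min_changes(tree, states)
    known = {t: s for t, s in full.items() if s != UNKNOWN}
    return {
        "n_tips": len(full),
        "n_tips_known": len(known),
        "tip_states": dict(sorted(known.items())),
        "min_state_changes": changes,
        "single_origin_consistent": changes <= 1,
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
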