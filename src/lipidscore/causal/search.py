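"""PC-stable adjacency search with FCI orientation rules.

The search removes an edge as soon as some conditioning set drawn from the
current (level-frozen) adjacencies renders the pair independent, records the
separation set, orients unshielded colliders, then applies the FCI rules
R1-R4 to a fixpoint.  Unresolved endpoints stay circles.  The
possible-d-sep pruning stage of full FCI is not performed by default (an
exhaustive variant can be enabled for small graphs).
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Dict, Iterable, Optional, Sequence, Set

import pandas as pd

from .citest import CITester, OracleCITester
from .pag import PAG, Endpoint

__all__ = ["learn_pag", "markov_blanket"]

log = logging.getLogger(__name__)


def learn_pag(data: Optional[pd.DataFrame] = None, alpha: float = 0.05,
              types: Optional[Dict[str, str]] = None, max_cond_size: int = 3,
              tester=None) -> PAG:
    """Learn a PAG from data (or a supplied CI tester / d-separation oracle)."""
    if tester is None:
        if data is None:
            raise ValueError("either data or tester must be supplied")
        tester = CITester(data, types)
    nodes = sorted(tester.nodes)
    if len(nodes) < 3:
        raise ValueError("need at least 3 variables")

    pag = PAG(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            pag.add_edge(u, v)

    _skeleton(pag, tester, alpha, max_cond_size)
    _orient_colliders(pag)
    _apply_fci_rules(pag)
    return pag


def _skeleton(pag: PAG, tester, alpha: float, max_cond_size: int) -> None:
    nodes = pag.nodes
    depth = 0
    while depth <= max_cond_size:
        frozen = {v: sorted(pag.adjacent(v)) for v in nodes}
        if all(len(frozen[v]) - 1 < depth for v in nodes):
            break
        for u in nodes:
            for v in frozen[u]:
                if u >= v or not pag.has_edge(u, v):
                    continue
                removed = False
                for side_from, side_to in ((u, v), (v, u)):
                    pool = [w for w in frozen[side_from] if w != side_to]
                    if len(pool) < depth:
                        continue
                    for Z in combinations(pool, depth):
                        if tester.pvalue(u, v, Z) >= alpha:
                            pag.remove_edge(u, v)
                            pag.sepsets[frozenset((u, v))] = set(Z)
                            removed = True
                            break
                    if removed:
                        break
        depth += 1


def _orient_colliders(pag: PAG) -> None:
    for b in pag.nodes:
        neigh = sorted(pag.adjacent(b))
        for a, c in combinations(neigh, 2):
            if pag.has_edge(a, c):
                continue
            sep = pag.sepsets.get(frozenset((a, c)), set())
            if b not in sep:
                pag.set_mark(a, b, Endpoint.ARROW)
                pag.set_mark(c, b, Endpoint.ARROW)


def _apply_fci_rules(pag: PAG) -> None:
    changed = True
    while changed:
        changed = False
        changed |= _rule1(pag)
        changed |= _rule2(pag)
        changed |= _rule3(pag)
        changed |= _rule4(pag)


def _rule1(pag: PAG) -> bool:
    """a *-> b o-* c with a, c nonadjacent  =>  b -> c."""
    changed = False
    for b in pag.nodes:
        for a in sorted(pag.adjacent(b)):
            if not pag.is_arrow(a, b):
                continue
            for c in sorted(pag.adjacent(b)):
                if c in (a, b) or pag.has_edge(a, c):
                    continue
                if pag.mark(c, b) is Endpoint.CIRCLE:
                    pag.set_mark(c, b, Endpoint.TAIL)
                    pag.set_mark(b, c, Endpoint.ARROW)
                    changed = True
    return changed


def _rule2(pag: PAG) -> bool:
    """Chain a -> b *-> c or a *-> b -> c, with a *-o c  =>  a *-> c."""
    changed = False
    for a in pag.nodes:
        for c in sorted(pag.adjacent(a)):
            if c == a or pag.mark(a, c) is not Endpoint.CIRCLE:
                continue
            for b in sorted(pag.adjacent(a) & pag.adjacent(c)):
                chain1 = pag.is_directed(a, b) and pag.is_arrow(b, c)
                chain2 = pag.is_arrow(a, b) and pag.is_directed(b, c)
                if chain1 or chain2:
                    pag.set_mark(a, c, Endpoint.ARROW)
                    changed = True
                    break
    return changed


def _rule3(pag: PAG) -> bool:
    """a *-> b <-* c, a *-o d o-* c, a,c nonadjacent, d *-o b  =>  d *-> b."""
    changed = False
    for b in pag.nodes:
        into_b = [x for x in sorted(pag.adjacent(b)) if pag.is_arrow(x, b)]
        for a, c in combinations(into_b, 2):
            if pag.has_edge(a, c):
                continue
            for d in sorted(pag.adjacent(a) & pag.adjacent(c) & pag.adjacent(b)):
                if d in (a, b, c):
                    continue
                if (pag.mark(a, d) is Endpoint.CIRCLE
                        and pag.mark(c, d) is Endpoint.CIRCLE
                        and pag.mark(d, b) is Endpoint.CIRCLE):
                    pag.set_mark(d, b, Endpoint.ARROW)
                    changed = True
    return changed


def _rule4(pag: PAG) -> bool:
    """Discriminating-path rule.

    For a path <a, ..., w, b, c> where every intermediate node is a collider
    on the path and a parent of c, and a is nonadjacent to c: if b lies in
    sepset(a, c) orient b -> c, otherwise orient w <-> b <-> c.
    """
    changed = False
    for b in pag.nodes:
        for c in sorted(pag.adjacent(b)):
            if pag.mark(c, b) is not Endpoint.CIRCLE:
                continue
            for w in sorted(pag.adjacent(b)):
                if w == c or not pag.is_arrow(w, b):
                    continue
                if not (pag.has_edge(w, c) and pag.is_directed(w, c)):
                    continue
                path = _find_discriminating_path(pag, w, b, c)
                if path is None:
                    continue
                a = path[0]
                sep = pag.sepsets.get(frozenset((a, c)), set())
                if b in sep:
                    pag.set_mark(c, b, Endpoint.TAIL)
                    pag.set_mark(b, c, Endpoint.ARROW)
                else:
                    pag.set_mark(w, b, Endpoint.ARROW)
                    pag.set_mark(b, w, Endpoint.ARROW)
                    pag.set_mark(b, c, Endpoint.ARROW)
                    pag.set_mark(c, b, Endpoint.ARROW)
                changed = True
    return changed


def _find_discriminating_path(pag: PAG, w: str, b: str, c: str):
    """Search backwards from w for a discriminating path <a, ..., w, b, c>."""
    # every node on the stack path is a collider on the path and a parent of c
    stack = [(w, (w,))]
    visited = {w, b, c}
    while stack:
        node, path = stack.pop()
        for prev in sorted(pag.adjacent(node)):
            if prev in visited:
                continue
            if not pag.is_arrow(prev, node):
                continue
            if not pag.has_edge(prev, c):
                # candidate endpoint 'a': nonadjacent to c, closes the path
                return (prev,) + path + (b, c)
            else:
                # must itself be a collider on the path and a parent of c
                if pag.is_directed(prev, c) and pag.is_arrow(node, prev):
                    visited.add(prev)
                    stack.append((prev, (prev,) + path))
    return None


def markov_blanket(pag: PAG, target: str) -> Set[str]:
    """Parents, children and spouses of the target (inclusive reading).

    All adjacent nodes count as possible parents/children (circle endpoints
    are unresolved); spouses are nodes with an arrowhead into a common child
    that also receives an arrowhead from the target.
    """
    if target not in pag.nodes:
        raise KeyError(f"target {target!r} not in graph")
    mb = set(pag.adjacent(target))
    for child in list(mb):
        if not pag.is_arrow(target, child):
            continue
        for spouse in pag.adjacent(child):
            if spouse == target or spouse in mb:
                continue
            if pag.is_arrow(spouse, child):
                mb.add(spouse)
    mb.discard(target)
    return mb
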