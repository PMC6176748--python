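"""Minimal directed-graph primitives shared across modules.

Edges are (child, parent) pairs with the arrow read parent -> child.
"""

from __future__ import annotations

from collections import deque


def topological_order(edges, p: int):
    """Kahn's algorithm on the parent -> child digraph.

    Returns ``(True, order)`` with a topological order of all ``p`` nodes when
    the graph is acyclic, else ``(False, cycle)`` where ``cycle`` is a list of
    nodes forming one directed cycle (a certificate).
    """
    children: dict[int, list[int]] = {v: [] for v in range(p)}
    indeg = [0] * p
    for child, parent in edges:
        children[parent].append(child)
        indeg[child] += 1
    queue = deque(v for v in range(p) if indeg[v] == 0)
    order: list[int] = []
    indeg = list(indeg)
    while queue:
        v = queue.popleft()
        order.append(v)
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) == p:
        return True, order
    # residual graph = nodes with indeg > 0; walk parent links to find a cycle
    residual = {v for v in range(p) if indeg[v] > 0}
    parent_of: dict[int, list[int]] = {v: [] for v in residual}
    for child, parent in edges:
        if child in residual and parent in residual:
            parent_of[child].append(parent)
    v = next(iter(residual))
    seen: dict[int, int] = {}
    path: list[int] = []
    while v not in seen:
        seen[v] = len(path)
        path.append(v)
        v = parent_of[v][0]
    return False, path[seen[v]:]
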