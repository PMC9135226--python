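"""Dependency graph over datatype names, with depth-first cycle detection."""

from __future__ import annotations

from .errors import CircularReferenceError


class DependencyGraph:
    """Directed graph: an edge A -> B means definition A references B."""

    def __init__(self):
        self.nodes: set[str] = set()
        self.edges: dict[str, list[str]] = {}

    def add_node(self, name: str) -> None:
        self.nodes.add(name)
        self.edges.setdefault(name, [])

    def add_edge(self, src: str, dst: str) -> None:
        self.add_node(src)
        self.add_node(dst)
        if dst not in self.edges[src]:
            self.edges[src].append(dst)

    @classmethod
    def from_table(cls, table) -> "DependencyGraph":
        g = cls()
        for name, defn in table.items():
            g.add_node(name)
            for ref in defn.references():
                g.add_edge(name, ref)
        return g


def check_acyclic(graph: DependencyGraph) -> None:
    """Raise :class:`CircularReferenceError` carrying one witness cycle (in
    dependency order, first node repeated at the end) if the graph has a
    directed cycle; return silently otherwise.

    Iterative depth-first search with the classic white/grey/black colouring;
    the grey stack yields the witness when a back edge is found.
    """
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {n: WHITE for n in graph.nodes}
    for root in sorted(graph.nodes):
        if colour[root] != WHITE:
            continue
        stack = [(root, iter(sorted(graph.edges.get(root, ()))))]
        colour[root] = GREY
        path = [root]
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if colour[nxt] == GREY:
                    cycle = path[path.index(nxt):] + [nxt]
                    raise CircularReferenceError(cycle)
                if colour[nxt] == WHITE:
                    colour[nxt] = GREY
                    stack.append((nxt, iter(sorted(graph.edges.get(nxt, ())))))
                    path.append(nxt)
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                stack.pop()
                path.pop()
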