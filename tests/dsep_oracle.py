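"""Brute-force d-separation oracle: enumerate every undirected path and
apply the blocking rules directly. Independent of the package's
reachability implementation; used only as a test reference."""

import itertools

from reefscale import CausalGraph


def descendants(g: CausalGraph, node):
    out, stack = {node}, [node]
    while stack:
        for c in g.children(stack.pop()):
            if c not in out:
                out.add(c)
                stack.append(c)
    return out


def path_blocked(g: CausalGraph, path, z):
    for idx in range(1, len(path) - 1):
        prev, node, nxt = path[idx - 1], path[idx], path[idx + 1]
        into_prev = (prev, node) in g.directed
        into_next = (nxt, node) in g.directed
        if into_prev and into_next:  # collider
            if not (descendants(g, node) & z):
                return True
        else:
            if node in z:
                return True
    return False


def d_separated_bruteforce(g: CausalGraph, x, y, z=()):
    z = set([z]) if isinstance(z, str) else set(z)
    adj = {n: set() for n in g.nodes}
    for u, v in g.directed:
        adj[u].add(v)
        adj[v].add(u)

    def paths(node, target, seen):
        if node == target:
            yield list(seen) + [node]
            return
        for nb in adj[node]:
            if nb not in seen and nb != node:
                yield from paths(nb, target, seen + [node])

    for path in paths(x, y, []):
        if not path_blocked(g, path, z):
            return False
    return True


def all_dags(n):
    """Every labeled DAG on n nodes (directed graphs filtered for acyclicity)."""
    nodes = tuple(f"n{i}" for i in range(n))
    arcs = [(a, b) for a in nodes for b in nodes if a != b]
    for bits in range(2 ** len(arcs)):
        directed = {arcs[i] for i in range(len(arcs)) if bits >> i & 1}
        g = CausalGraph(nodes=nodes, directed=directed)
        if g.is_acyclic():
            yield g


def random_dag(n, p, rng):
    nodes = tuple(f"n{i}" for i in range(n))
    order = rng.permutation(n)
    directed = set()
    for i, j in itertools.combinations(range(n), 2):
        if rng.uniform() < p:
            a, b = order[i], order[j]
            directed.add((nodes[a], nodes[b]))
    return CausalGraph(nodes=nodes, directed=directed)
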