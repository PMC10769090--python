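"""Constraint-based causal inference for binary site variables.

Implements the stratified G² (log-likelihood ratio) test of conditional
independence, Inductive-Causation discovery (skeleton via exhaustive
conditional-independence search, collider orientation, and orientation
rule R1), d-separation on directed acyclic graphs, the do-calculus Rule 2
check that licenses replacing an interventional probability with an
observational one, the six-route "genuine cause" criterion, and the
average causal effect (ACE) of a binary treatment on a binary outcome.

All tests operate on a pandas DataFrame whose columns are 0/1 coded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IndependenceResult",
    "CausalGraph",
    "RouteReport",
    "validate_binary",
    "g2_test",
    "ic_skeleton",
    "orient_v_structures",
    "apply_meek_r1",
    "discover",
    "d_separated",
    "do_rule2_check",
    "genuine_cause_test",
    "ace",
]

DEFAULT_ALPHA = 0.05


def validate_binary(data: pd.DataFrame) -> pd.DataFrame:
    """Check that every column of ``data`` is 0/1 coded; return it unchanged."""
    if data.shape[0] < 1:
        raise ValueError("dataset must have at least one row")
    if len(set(data.columns)) != data.shape[1]:
        raise ValueError("variable names must be unique")
    for col in data.columns:
        vals = pd.unique(data[col])
        if not set(np.asarray(vals).tolist()) <= {0, 1}:
            raise ValueError(f"column {col!r} is not binary (values {vals[:5]})")
    return data


# ---------------------------------------------------------------------------
# G² test of (conditional) independence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndependenceResult:
    """Outcome of one G² (conditional) independence test."""

    x: str
    y: str
    s: tuple[str, ...]
    g2: float
    df: int
    p: float
    alpha: float

    @property
    def dependent(self) -> bool:
        """Independence is rejected when p < alpha."""
        return self.p < self.alpha

    @property
    def independent(self) -> bool:
        return not self.dependent

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "y": self.y,
            "given": list(self.s),
            "g2": self.g2,
            "df": self.df,
            "p": self.p,
            "alpha": self.alpha,
            "verdict": "dependent" if self.dependent else "independent",
        }


def g2_test(
    data: pd.DataFrame,
    x: str,
    y: str,
    s: Iterable[str] = (),
    alpha: float = DEFAULT_ALPHA,
) -> IndependenceResult:
    """Stratified G² test of ``x`` independent of ``y`` given ``s``.

    Within each configuration (stratum) of the conditioning variables,
    expected counts come from the stratum's margins and the statistic is
    ``G² = 2 * sum O * ln(O/E)`` over cells with O > 0; stratum
    contributions add. Degrees of freedom are 1 per nonempty stratum
    (binary x binary tables); empty strata are skipped. The p-value is
    the chi-square upper tail.
    """
    s = tuple(s)
    if x == y:
        raise ValueError("x and y must differ")
    if x in s or y in s:
        raise ValueError("conditioning set must exclude x and y")
    xv = data[x].to_numpy(np.int64)
    yv = data[y].to_numpy(np.int64)
    n = xv.size
    if n < 1:
        raise ValueError("no observations")
    if s:
        stratum = np.zeros(n, dtype=np.int64)
        for col in s:
            stratum = stratum * 2 + data[col].to_numpy(np.int64)
        n_strata = 2 ** len(s)
    else:
        stratum = np.zeros(n, dtype=np.int64)
        n_strata = 1
    cell = (stratum * 4 + xv * 2 + yv).astype(np.int64)
    counts = np.bincount(cell, minlength=n_strata * 4).reshape(n_strata, 2, 2)
    totals = counts.sum(axis=(1, 2))
    nonempty = totals > 0
    if not nonempty.any():
        raise ValueError("no nonempty stratum")
    g2 = 0.0
    for t in np.flatnonzero(nonempty):
        obs = counts[t].astype(float)
        nt = totals[t]
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        expected = row * col / nt
        mask = obs > 0
        g2 += 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    g2 = max(g2, 0.0)
    df = int(nonempty.sum())
    p = float(stats.chi2.sf(g2, df))
    return IndependenceResult(x=x, y=y, s=s, g2=g2, df=df, p=p, alpha=alpha)


# ---------------------------------------------------------------------------
# Causal graph container
# ---------------------------------------------------------------------------

@dataclass
class CausalGraph:
    """Partially directed acyclic graph with separating-set records.

    ``directed`` holds (a, b) meaning a -> b; ``undirected`` holds
    frozensets {a, b}. ``sepsets`` maps non-adjacent pairs (frozensets)
    to the first (smallest) separating set found during skeleton search.
    """

    nodes: tuple[str, ...]
    directed: set[tuple[str, str]] = field(default_factory=set)
    undirected: set[frozenset] = field(default_factory=set)
    sepsets: dict[frozenset, tuple[str, ...]] = field(default_factory=dict)
    conflicts: list[tuple[str, str]] = field(default_factory=list)

    def copy(self) -> "CausalGraph":
        return CausalGraph(
            nodes=self.nodes,
            directed=set(self.directed),
            undirected=set(self.undirected),
            sepsets=dict(self.sepsets),
            conflicts=list(self.conflicts),
        )

    def adjacent(self, a: str, b: str) -> bool:
        return (
            frozenset((a, b)) in self.undirected
            or (a, b) in self.directed
            or (b, a) in self.directed
        )

    def neighbors(self, a: str) -> list[str]:
        out = set()
        for e in self.undirected:
            if a in e:
                out |= set(e) - {a}
        for u, v in self.directed:
            if u == a:
                out.add(v)
            elif v == a:
                out.add(u)
        return sorted(out)

    def parents(self, a: str) -> list[str]:
        return sorted(u for u, v in self.directed if v == a)

    def children(self, a: str) -> list[str]:
        return sorted(v for u, v in self.directed if u == a)

    def has_directed_path(self, a: str, b: str) -> bool:
        """True when a directed path a -> ... -> b exists."""
        stack, seen = [a], set()
        while stack:
            node = stack.pop()
            if node == b:
                return True
            if node in seen:
                continue
            seen.add(node)
            stack.extend(self.children(node))
        return False

    def is_acyclic(self) -> bool:
        return not any(
            self.has_directed_path(v, u) for u, v in self.directed
        )

    def validate(self) -> None:
        for u, v in self.directed:
            if frozenset((u, v)) in self.undirected:
                raise ValueError(f"edge {u}-{v} is both directed and undirected")
        if not self.is_acyclic():
            raise ValueError("directed part contains a cycle")
        for pair in self.sepsets:
            a, b = tuple(pair)
            if self.adjacent(a, b):
                raise ValueError(f"sepset recorded for adjacent pair {a}, {b}")

    def edge_list(self) -> dict:
        return {
            "directed": sorted([list(e) for e in self.directed]),
            "undirected": sorted(sorted(e) for e in self.undirected),
        }

    def to_dot(self) -> str:
        lines = ["digraph causal {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in sorted(self.directed):
            lines.append(f'  "{u}" -> "{v}";')
        for e in sorted(self.undirected, key=sorted):
            u, v = sorted(e)
            lines.append(f'  "{u}" -> "{v}" [dir=none];')
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Inductive Causation: skeleton, colliders, R1
# ---------------------------------------------------------------------------

def ic_skeleton(data: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> CausalGraph:
    """Skeleton discovery by exhaustive conditional-independence search.

    An edge X--Y is absent iff some conditioning subset of the remaining
    variables renders them independent at level ``alpha``. Subsets are
    scanned in increasing cardinality and deterministic (column) order;
    the first separating set is recorded.
    """
    validate_binary(data)
    nodes = tuple(data.columns)
    g = CausalGraph(nodes=nodes)
    for x, y in itertools.combinations(nodes, 2):
        others = [v for v in nodes if v not in (x, y)]
        sep: tuple[str, ...] | None = None
        for size in range(len(others) + 1):
            for cand in itertools.combinations(others, size):
                if g2_test(data, x, y, cand, alpha).independent:
                    sep = cand
                    break
            if sep is not None:
                break
        if sep is None:
            g.undirected.add(frozenset((x, y)))
        else:
            g.sepsets[frozenset((x, y))] = sep
    return g


def orient_v_structures(skeleton: CausalGraph) -> CausalGraph:
    """Orient colliders X -> Z <- Y.

    For each pair of nonadjacent variables X, Y with a common neighbor Z,
    the edges are oriented into Z exactly when Z is not in the recorded
    separating set of (X, Y). Conflicting orientations (an edge already
    directed the opposite way by an earlier triple, in deterministic
    lexicographic order) are recorded on ``conflicts`` and skipped.
    """
    g = skeleton.copy()
    triples = []
    for x, y in itertools.combinations(sorted(g.nodes), 2):
        if g.adjacent(x, y):
            continue
        for z in g.nodes:
            if z in (x, y):
                continue
            if g.adjacent(x, z) and g.adjacent(y, z):
                triples.append((x, z, y))
    for x, z, y in sorted(triples):
        pair = frozenset((x, y))
        if z in g.sepsets.get(pair, ()):
            continue
        for a in (x, y):
            e = frozenset((a, z))
            if (z, a) in g.directed:
                g.conflicts.append((z, a))
                continue
            if e in g.undirected:
                g.undirected.discard(e)
            g.directed.add((a, z))
    return g


def apply_meek_r1(graph: CausalGraph) -> CausalGraph:
    """Orientation rule R1, applied to a fixpoint.

    Whenever a -> b exists, b -- c is undirected, and a and c are
    nonadjacent, orient b -> c (otherwise a new collider a -> b <- c
    would have been detected). Raises if an application would create a
    directed cycle.
    """
    g = graph.copy()
    changed = True
    while changed:
        changed = False
        for a, b in sorted(g.directed):
            for c in sorted(g.nodes):
                e = frozenset((b, c))
                if c in (a, b) or e not in g.undirected:
                    continue
                if g.adjacent(a, c):
                    continue
                if g.has_directed_path(c, b):
                    raise ValueError(
                        f"orienting {b} -> {c} would create a directed cycle"
                    )
                g.undirected.discard(e)
                g.directed.add((b, c))
                changed = True
    g.validate()
    return g


def discover(data: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> CausalGraph:
    """Full IC pipeline: skeleton, collider orientation, rule R1."""
    return apply_meek_r1(orient_v_structures(ic_skeleton(data, alpha)))


# ---------------------------------------------------------------------------
# d-separation and do-calculus Rule 2
# ---------------------------------------------------------------------------

def _as_set(x) -> set:
    if x is None:
        return set()
    if isinstance(x, str):
        return {x}
    return set(x)


def _ancestors_of(g: CausalGraph, targets: set) -> set:
    out = set(targets)
    frontier = list(targets)
    while frontier:
        node = frontier.pop()
        for p in g.parents(node):
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def d_separated(graph: CausalGraph, x, y, z=()) -> bool:
    """True when every path between ``x`` and ``y`` is blocked given ``z``.

    Reachability ("Bayes-ball") formulation: a ball bounces through
    chains and forks at unobserved nodes and through colliders whose
    node is in, or has a descendant in, the conditioning set. ``x`` and
    ``y`` may be names or sets of names. Only the directed part of the
    graph is used; undirected edges must already be resolved.
    """
    if graph.undirected:
        raise ValueError("d-separation requires a fully directed graph")
    X, Y, Z = _as_set(x), _as_set(y), _as_set(z)
    if X & Z or Y & Z:
        raise ValueError("query nodes must not be in the conditioning set")
    if X & Y:
        return False
    anc_z = _ancestors_of(graph, Z)
    # direction "up": arrived from a child (moving against edges is allowed);
    # direction "down": arrived from a parent.
    visited: set[tuple[str, str]] = set()
    frontier: list[tuple[str, str]] = [(s, "up") for s in X]
    while frontier:
        node, direction = frontier.pop()
        if (node, direction) in visited:
            continue
        visited.add((node, direction))
        if node not in Z and node in Y:
            return False
        if direction == "up" and node not in Z:
            frontier.extend((p, "up") for p in graph.parents(node))
            frontier.extend((c, "down") for c in graph.children(node))
        elif direction == "down":
            if node not in Z:
                frontier.extend((c, "down") for c in graph.children(node))
            if node in anc_z:
                frontier.extend((p, "up") for p in graph.parents(node))
    return True


def _mutilate(graph: CausalGraph, remove_into: set, remove_out_of: set) -> CausalGraph:
    g = graph.copy()
    g.directed = {
        (u, v)
        for u, v in g.directed
        if v not in remove_into and u not in remove_out_of
    }
    return g


def do_rule2_check(graph: CausalGraph, y, z, x=(), w=()) -> bool:
    """Do-calculus Rule 2 (action/observation exchange).

    ``P(y | do(x), do(z), w) = P(y | do(x), z, w)`` holds when Y and Z
    are d-separated given X union W in the graph with arrows into X and
    arrows out of Z removed. With X and W empty this licenses replacing
    ``P(y | do(z))`` by the observational ``P(y | z)``.
    """
    Y, Z, X, W = _as_set(y), _as_set(z), _as_set(x), _as_set(w)
    if (Y & Z) or (Y & X) or (Z & X):
        raise ValueError("y, z and x must be disjoint")
    mutilated = _mutilate(graph, remove_into=X, remove_out_of=Z)
    return d_separated(mutilated, Y, Z, X | W)


# ---------------------------------------------------------------------------
# Genuine-cause criterion and ACE
# ---------------------------------------------------------------------------

@dataclass
class Route:
    """One route through the three-step genuine-cause criterion."""

    index: int
    z: str
    w: str
    step_ii_zx: IndependenceResult
    step_ii_zw: IndependenceResult
    step_ii_wx: IndependenceResult
    step_iii_dep: IndependenceResult
    step_iii_indep: IndependenceResult

    @property
    def passed(self) -> bool:
        return (
            self.step_ii_zx.dependent
            and self.step_ii_zw.independent
            and self.step_ii_wx.dependent
            and self.step_iii_dep.dependent
            and self.step_iii_indep.independent
        )

    def to_dict(self) -> dict:
        return {
            "route": self.index,
            "z": self.z,
            "w": self.w,
            "tests": {
                "ii_z_dep_x": self.step_ii_zx.to_dict(),
                "ii_z_indep_w": self.step_ii_zw.to_dict(),
                "ii_w_dep_x": self.step_ii_wx.to_dict(),
                "iii_z_dep_y": self.step_iii_dep.to_dict(),
                "iii_z_indep_y_given_x": self.step_iii_indep.to_dict(),
            },
            "passed": self.passed,
        }


@dataclass
class RouteReport:
    """Full genuine-cause evaluation of treatment X on outcome Y."""

    x: str
    y: str
    context: tuple[str, ...]
    alpha: float
    step_i: IndependenceResult
    routes: list[Route]
    ace: float

    @property
    def n_routes_passed(self) -> int:
        if not self.step_i.dependent:
            return 0
        return sum(r.passed for r in self.routes)

    @property
    def genuine(self) -> bool:
        """At least one full route satisfied (more routes = stronger support)."""
        return self.step_i.dependent and self.n_routes_passed >= 1

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "y": self.y,
            "context": list(self.context),
            "alpha": self.alpha,
            "step_i": self.step_i.to_dict(),
            "routes": [r.to_dict() for r in self.routes],
            "n_routes_passed": self.n_routes_passed,
            "genuine": self.genuine,
            "ace": self.ace,
        }


def genuine_cause_test(
    data: pd.DataFrame,
    x: str,
    y: str,
    context: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> RouteReport:
    """Three-step criterion for a genuine causal effect of ``x`` on ``y``.

    Step (i): x and y are dependent given the full context C.
    Step (ii): some Z in C is a potential cause of x — Z is dependent on
    x conditioned on the remaining context plus y, and there is a witness
    W in C with Z independent of W (marginally) while W is dependent on x.
    Step (iii): Z is dependent on y given the remaining context, but
    independent once x is added to the conditioning set (x screens Z off
    from y).

    With a three-variable context this yields six routes (three choices
    of Z, two witnesses W each); every route is evaluated and reported.
    The ACE of x on y is attached for convenience.
    """
    validate_binary(data)
    context = tuple(context)
    if x in context or y in context:
        raise ValueError("context must exclude x and y")
    missing = [v for v in (x, y, *context) if v not in data.columns]
    if missing:
        raise ValueError(f"variables not in dataset: {missing}")
    step_i = g2_test(data, x, y, context, alpha)
    routes: list[Route] = []
    idx = 0
    for z in context:
        rest = tuple(v for v in context if v != z)
        cond_ii = rest + (y,)
        step_ii_zx = g2_test(data, z, x, cond_ii, alpha)
        step_iii_dep = g2_test(data, z, y, rest, alpha)
        step_iii_indep = g2_test(data, z, y, rest + (x,), alpha)
        for w in rest:
            idx += 1
            routes.append(
                Route(
                    index=idx,
                    z=z,
                    w=w,
                    step_ii_zx=step_ii_zx,
                    step_ii_zw=g2_test(data, z, w, (), alpha),
                    step_ii_wx=g2_test(data, w, x, (), alpha),
                    step_iii_dep=step_iii_dep,
                    step_iii_indep=step_iii_indep,
                )
            )
    # a context with < 2 variables yields no routes: reported, not an error
    return RouteReport(
        x=x,
        y=y,
        context=context,
        alpha=alpha,
        step_i=step_i,
        routes=routes,
        ace=ace(data, x, y) if data[x].nunique() == 2 else float("nan"),
    )


def ace(data: pd.DataFrame, treatment: str, outcome: str) -> float:
    """Average causal effect ``P(Y=1 | M=1) - P(Y=1 | M=0)``.

    Valid as a causal quantity when do-calculus Rule 2 licenses the
    action/observation exchange for the underlying graph (checked
    separately with :func:`do_rule2_check`).
    """
    t = data[treatment].to_numpy()
    yv = data[outcome].to_numpy()
    arm1 = yv[t == 1]
    arm0 = yv[t == 0]
    if arm1.size == 0:
        raise ValueError(f"empty treatment arm: {treatment}=1")
    if arm0.size == 0:
        raise ValueError(f"empty treatment arm: {treatment}=0")
    return float(arm1.mean() - arm0.mean())
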