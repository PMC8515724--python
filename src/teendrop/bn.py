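"""Discrete Bayesian networks with exact inference.

A network is a directed acyclic graph plus one conditional probability table
(CPT) per node; together they induce the joint distribution

    P(x_1, ..., x_n) = prod_k P(x_k | pa(X_k))

where ``pa`` denotes the graph parents.  Every variable here is discrete with
an explicit, ordered state tuple (binary ``(0, 1)`` throughout the teenage
pregnancy study).  Conditional queries use sum-product variable elimination;
MAP completions use max-product elimination with a canonical lexicographic
decode.  All arithmetic is in linear space: with the handful of binary nodes
this package targets, products of probabilities cannot underflow, so a zero
marginal genuinely means impossible evidence.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ATOL",
    "Dag",
    "Cpt",
    "BayesNet",
    "CyclicGraphError",
    "GraphValidationError",
    "CptEstimationError",
    "ZeroProbabilityError",
    "validate_dag",
    "fit_cpts",
    "joint_probability",
    "query",
    "map_assignment",
]

#: tolerance for probability normalisation checks
ATOL = 1e-9

#: relative tolerance used to declare two joint probabilities tied in MAP decoding
_TIE_RTOL = 1e-12


class GraphValidationError(ValueError):
    """A proposed graph is structurally invalid (dangling endpoint, self-loop...)."""


class CyclicGraphError(GraphValidationError):
    """A proposed graph contains a directed cycle."""

    def __init__(self, cycle: Sequence[str]):
        self.cycle = list(cycle)
        super().__init__(f"graph contains a directed cycle: {' -> '.join(self.cycle)}")


class CptEstimationError(ValueError):
    """CPT estimation failed (e.g. an unobserved parent configuration under MLE)."""


class ZeroProbabilityError(ValueError):
    """Evidence has probability exactly zero under the network.

    Raised only when the evidence marginal is identically zero; with linear-space
    products over a handful of binary nodes this cannot be confused with
    floating-point underflow.
    """


@dataclass(frozen=True)
class Dag:
    """An acyclic digraph over named variables.

    Construct through :func:`validate_dag` (or :meth:`from_edges`); the
    constructor itself trusts its inputs.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of *node*, in lexicographic order (the canonical CPT axis order)."""
        if node not in self.nodes:
            raise KeyError(node)
        return tuple(sorted(p for p, c in self.edges if c == node))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(c for p, c in self.edges if p == node))

    def topological_order(self) -> tuple[str, ...]:
        return tuple(nx.topological_sort(self.graph()))

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   nodes: Iterable[str] | None = None) -> "Dag":
        edges = list(edges)
        if nodes is None:
            nodes = sorted({v for e in edges for v in e})
        return validate_dag(nodes, edges)

    # -- plain-text edge-list interchange ("parent<TAB>child" per line) --

    @classmethod
    def from_edge_list(cls, path) -> "Dag":
        edges = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise GraphValidationError(
                        f"{path}:{lineno}: expected 'parent<TAB>child', got {line!r}")
                edges.append((parts[0], parts[1]))
        return cls.from_edges(edges)

    def to_edge_list(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for p, c in sorted(self.edges):
                fh.write(f"{p}\t{c}\n")


def validate_dag(nodes: Iterable[str], edges: Iterable[tuple[str, str]]) -> Dag:
    """Validate acyclicity and edge endpoints, returning an immutable :class:`Dag`.

    Raises :class:`CyclicGraphError` naming one offending cycle, or
    :class:`GraphValidationError` for dangling endpoints / self-loops.
    """
    nodes = tuple(dict.fromkeys(nodes))  # preserve order, drop duplicates
    node_set = set(nodes)
    edge_set = set()
    for p, c in edges:
        if p not in node_set or c not in node_set:
            raise GraphValidationError(f"edge ({p!r}, {c!r}) has an endpoint outside the node set")
        if p == c:
            raise GraphValidationError(f"self-loop on {p!r}")
        edge_set.add((p, c))
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edge_set)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return Dag(nodes=nodes, edges=frozenset(edge_set))
    raise CyclicGraphError([e[0] for e in cycle] + [cycle[-1][1]])


@dataclass(frozen=True)
class Cpt:
    """Conditional probability table P(node | parents).

    ``table`` has one axis per parent (in ``parents`` order) plus a trailing
    axis for the node's own states; ``table[i_1, ..., i_m, j]`` is
    P(node = states[j] | parent_k = parent_states[k][i_k]).
    """

    node: str
    parents: tuple[str, ...]
    table: np.ndarray
    states: tuple = (0, 1)
    parent_states: tuple[tuple, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.parent_states is None:
            object.__setattr__(self, "parent_states",
                               tuple((0, 1) for _ in self.parents))
        tab = np.asarray(self.table, dtype=float)
        expected = tuple(len(s) for s in self.parent_states) + (len(self.states),)
        if tab.shape != expected:
            raise ValueError(
                f"CPT for {self.node!r}: table shape {tab.shape} != expected {expected}")
        if np.any(tab < -ATOL) or np.any(tab > 1 + ATOL):
            raise ValueError(f"CPT for {self.node!r}: probabilities outside [0, 1]")
        sums = tab.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=ATOL, rtol=0):
            raise ValueError(
                f"CPT for {self.node!r}: rows do not sum to 1 (max dev "
                f"{np.abs(sums - 1).max():.3g})")
        tab.setflags(write=False)
        object.__setattr__(self, "table", tab)

    def prob(self, state, parent_assignment: Mapping[str, object]) -> float:
        idx = tuple(self.parent_states[k].index(parent_assignment[p])
                    for k, p in enumerate(self.parents))
        return float(self.table[idx + (self.states.index(state),)])

    @classmethod
    def point_mass(cls, node: str, state, states: tuple = (0, 1)) -> "Cpt":
        tab = np.zeros(len(states))
        tab[states.index(state)] = 1.0
        return cls(node=node, parents=(), table=tab, states=states)


@dataclass(frozen=True)
class BayesNet:
    """A :class:`Dag` plus one :class:`Cpt` per node."""

    dag: Dag
    cpts: Mapping[str, Cpt]

    def __post_init__(self):
        missing = set(self.dag.nodes) - set(self.cpts)
        if missing:
            raise ValueError(f"no CPT for nodes: {sorted(missing)}")
        for node in self.dag.nodes:
            cpt = self.cpts[node]
            if cpt.node != node:
                raise ValueError(f"CPT keyed {node!r} describes {cpt.node!r}")
            if tuple(cpt.parents) != self.dag.parents(node):
                raise ValueError(
                    f"CPT parents {cpt.parents} for {node!r} do not match graph "
                    f"parents {self.dag.parents(node)}")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    def states(self, node: str) -> tuple:
        return self.cpts[node].states

    def check_normalized(self) -> float:
        """Exhaustively sum the joint over all full assignments (<= 12 binary nodes)."""
        total_states = 1
        for n in self.nodes:
            total_states *= len(self.states(n))
        if total_states > 4096:
            raise ValueError("exhaustive normalisation check limited to 4096 joint states")
        total = 0.0
        for combo in itertools.product(*(self.states(n) for n in self.nodes)):
            total += joint_probability(self, dict(zip(self.nodes, combo)))
        return total

    # -- JSON serialization: nodes, edges, per-node parent order, CPT rows in
    #    row-major parent-state order (lossless round trip) --

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "edges": sorted(list(e) for e in self.dag.edges),
            "cpts": {
                n: {
                    "parents": list(self.cpts[n].parents),
                    "states": list(self.cpts[n].states),
                    "rows": np.asarray(self.cpts[n].table).reshape(
                        -1, len(self.cpts[n].states)).tolist(),
                }
                for n in self.nodes
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BayesNet":
        dag = validate_dag(d["nodes"], [tuple(e) for e in d["edges"]])
        cpts = {}
        for node, spec in d["cpts"].items():
            parents = tuple(spec["parents"])
            states = tuple(spec["states"])
            rows = np.asarray(spec["rows"], dtype=float)
            shape = tuple(2 for _ in parents) + (len(states),)
            cpts[node] = Cpt(node=node, parents=parents,
                             table=rows.reshape(shape), states=states)
        return cls(dag=dag, cpts=cpts)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "BayesNet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def fit_cpts(dag: Dag, data, pseudocount: float = 0.0) -> BayesNet:
    """Estimate one CPT per node from a complete 0/1 data table.

    Each entry is ``(count(child state, parent config) + pseudocount) /
    (count(parent config) + pseudocount * n_states)``; ``pseudocount == 0`` is
    plain maximum likelihood, in which case an unobserved parent configuration
    raises :class:`CptEstimationError` (a silent uniform row would hide data
    sparsity).

    Parameters
    ----------
    data : pandas.DataFrame
        Complete table whose columns cover ``dag.nodes`` with values in {0, 1}.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    missing_cols = set(dag.nodes) - set(data.columns)
    if missing_cols:
        raise ValueError(f"data lacks columns for nodes: {sorted(missing_cols)}")
    for node in dag.nodes:
        bad = set(np.unique(data[node])) - {0, 1}
        if bad:
            raise ValueError(f"column {node!r} has non-binary values {sorted(bad)}")

    cpts = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        shape = tuple(2 for _ in parents) + (2,)
        cols = data[list(parents) + [node]].to_numpy(dtype=int)
        flat = np.ravel_multi_index(tuple(cols.T), shape)
        counts = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape).astype(float)
        denom = counts.sum(axis=-1, keepdims=True)
        if pseudocount == 0 and np.any(denom == 0):
            cfg = np.argwhere(denom[..., 0] == 0)[0]
            named = ", ".join(f"{p}={v}" for p, v in zip(parents, cfg))
            raise CptEstimationError(
                f"parent configuration ({named}) of {node!r} never observed; "
                f"use a positive pseudocount or more data")
        table = (counts + pseudocount) / (denom + 2 * pseudocount)
        cpts[node] = Cpt(node=node, parents=parents, table=table)
    return BayesNet(dag=dag, cpts=cpts)


def joint_probability(bn: BayesNet, assignment: Mapping[str, object]) -> float:
    """The joint probability of a *full* assignment, as the CPT product."""
    missing = set(bn.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment must cover every node; missing {sorted(missing)}")
    p = 1.0
    for node in bn.nodes:
        p *= bn.cpts[node].prob(assignment[node], assignment)
    return p


# --------------------------------------------------------------------------
# factors and variable elimination


class _Factor:
    """A non-negative table over an ordered tuple of variables."""

    __slots__ = ("variables", "values")

    def __init__(self, variables: tuple[str, ...], values: np.ndarray):
        self.variables = variables
        self.values = values

    @classmethod
    def from_cpt(cls, cpt: Cpt) -> "_Factor":
        return cls(tuple(cpt.parents) + (cpt.node,), np.asarray(cpt.table))

    def reduce(self, var: str, state_index: int) -> "_Factor":
        ax = self.variables.index(var)
        vals = np.take(self.values, state_index, axis=ax)
        variables = self.variables[:ax] + self.variables[ax + 1:]
        return _Factor(variables, vals)

    def _expand_to(self, order: tuple[str, ...]) -> np.ndarray:
        """View of values broadcastable over *order* (a superset of variables)."""
        perm = sorted(range(len(self.variables)), key=lambda i: order.index(self.variables[i]))
        vals = np.transpose(self.values, perm)
        shape = []
        k = 0
        ordered_vars = [self.variables[i] for i in perm]
        for v in order:
            if k < len(ordered_vars) and ordered_vars[k] == v:
                shape.append(vals.shape[k])
                k += 1
            else:
                shape.append(1)
        return vals.reshape(shape)

    def __mul__(self, other: "_Factor") -> "_Factor":
        order = self.variables + tuple(v for v in other.variables if v not in self.variables)
        return _Factor(order, self._expand_to(order) * other._expand_to(order))

    def sum_out(self, var: str) -> "_Factor":
        ax = self.variables.index(var)
        return _Factor(self.variables[:ax] + self.variables[ax + 1:],
                       self.values.sum(axis=ax))

    def max_out(self, var: str) -> "_Factor":
        ax = self.variables.index(var)
        return _Factor(self.variables[:ax] + self.variables[ax + 1:],
                       self.values.max(axis=ax))

    def scalar(self) -> float:
        return float(self.values.reshape(()))


def _evidence_indices(bn: BayesNet, evidence: Mapping[str, object]) -> dict[str, int]:
    idx = {}
    for var, state in evidence.items():
        if var not in bn.nodes:
            raise KeyError(f"unknown variable {var!r}")
        states = bn.states(var)
        if state not in states:
            raise KeyError(f"unknown state {state!r} for variable {var!r}")
        idx[var] = states.index(state)
    return idx


def _reduced_factors(bn: BayesNet, evidence: Mapping[str, object]) -> list[_Factor]:
    ev = _evidence_indices(bn, evidence)
    factors = []
    for node in bn.nodes:
        f = _Factor.from_cpt(bn.cpts[node])
        for var, i in ev.items():
            if var in f.variables:
                f = f.reduce(var, i)
        factors.append(f)
    return factors


def _eliminate(factors: list[_Factor], variables: Iterable[str], op: str) -> list[_Factor]:
    """Eliminate *variables* by sum- or max-product, greedy min-width order."""
    factors = list(factors)
    remaining = set(variables)
    while remaining:
        # greedy: pick the variable whose elimination builds the smallest factor
        def width(v: str) -> int:
            scope = set()
            for f in factors:
                if v in f.variables:
                    scope.update(f.variables)
            return len(scope)

        var = min(sorted(remaining), key=width)
        remaining.discard(var)
        related = [f for f in factors if var in f.variables]
        factors = [f for f in factors if var not in f.variables]
        if not related:
            continue
        prod = related[0]
        for f in related[1:]:
            prod = prod * f
        factors.append(prod.sum_out(var) if op == "sum" else prod.max_out(var))
    return factors


def _contract(factors: list[_Factor]) -> _Factor:
    prod = factors[0]
    for f in factors[1:]:
        prod = prod * f
    return prod


def evidence_probability(bn: BayesNet, evidence: Mapping[str, object]) -> float:
    """Marginal probability of a (possibly partial) assignment, by sum-product."""
    factors = _reduced_factors(bn, evidence)
    hidden = [n for n in bn.nodes if n not in evidence]
    out = _contract(_eliminate(factors, hidden, "sum"))
    return out.scalar()


def query(bn: BayesNet, target: str, evidence: Mapping[str, object] | None = None
          ) -> dict:
    """Exact conditional distribution P(target | evidence) by variable elimination.

    Returns a dict mapping each target state to its probability (summing to 1).
    Raises :class:`ZeroProbabilityError` if the evidence is impossible.
    """
    evidence = dict(evidence or {})
    if target not in bn.nodes:
        raise KeyError(f"unknown variable {target!r}")
    p_ev = evidence_probability(bn, evidence)
    if p_ev == 0.0:
        raise ZeroProbabilityError(
            f"evidence {evidence} has probability exactly zero under the network")
    if target in evidence:
        return {s: (1.0 if s == evidence[target] else 0.0) for s in bn.states(target)}
    factors = _reduced_factors(bn, evidence)
    hidden = [n for n in bn.nodes if n not in evidence and n != target]
    out = _contract(_eliminate(factors, hidden, "sum"))
    if out.variables != (target,):
        out = _Factor((target,), out._expand_to((target,)).reshape(-1))
    vals = out.values / out.values.sum()
    return dict(zip(bn.states(target), (float(v) for v in vals)))


def _max_joint(bn: BayesNet, clamped: Mapping[str, object]) -> float:
    """max over completions of the joint probability, with *clamped* fixed."""
    factors = _reduced_factors(bn, clamped)
    free = [n for n in bn.nodes if n not in clamped]
    out = _contract(_eliminate(factors, free, "max")) if factors else None
    return out.scalar() if out is not None else 1.0


def map_assignment(bn: BayesNet, evidence: Mapping[str, object] | None = None
                   ) -> dict:
    """Most probable full completion of *evidence* (MAP), by max-product elimination.

    Decoding is canonical: variables are fixed in lexicographic name order and,
    within a variable, earlier states (0 before 1) win ties; a tie triggers a
    warning.  The result equals the argmax of the joint over all completions.
    """
    evidence = dict(evidence or {})
    if evidence_probability(bn, evidence) == 0.0:
        raise ZeroProbabilityError(
            f"evidence {evidence} has probability exactly zero under the network")
    assignment = dict(evidence)
    for var in sorted(n for n in bn.nodes if n not in evidence):
        branch = [(state, _max_joint(bn, {**assignment, var: state}))
                  for state in bn.states(var)]
        vmax = max(v for _, v in branch)
        winners = [s for s, v in branch if v >= vmax * (1 - _TIE_RTOL)]
        if len(winners) > 1:
            warnings.warn(
                f"MAP tie at variable {var!r}: states {winners} are equally "
                f"probable; keeping {winners[0]!r} (canonical order)", stacklevel=2)
        assignment[var] = winners[0]
    return assignment
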