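"""Interventions, backdoor adjustment, and average causal effects.

The do-operator ``do(X = x)`` is realised two equivalent ways:

* **graph surgery** (:func:`intervene`): delete every edge into the treatment
  and replace its CPT by a point mass, then query the mutilated network; and
* the **adjustment formula** (:func:`adjustment_probability`):

      P(Y = y | do(X = x)) = sum_z P(Y = y | X = x, Z = z) P(Z = z),

  computed term by term with exact inference on the *unmutilated* network.

When the adjustment set Z equals the treatment's parents the two agree, which
is exercised as a cross-check in the test suite.  The average causal effect
(ACE) contrasts two treatment states:

      ACE = P(Y = y | do(X = x_i)) - P(Y = y | do(X = x_j)).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .bn import BayesNet, Cpt, Dag, evidence_probability

__all__ = [
    "InterventionQuery",
    "AceResult",
    "PositivityError",
    "intervene",
    "adjustment_probability",
    "average_causal_effect",
    "is_backdoor_admissible",
]


class PositivityError(ValueError):
    """An adjustment stratum with positive probability never exhibits the
    treatment state, so the adjustment formula's conditional is undefined."""


@dataclass(frozen=True)
class InterventionQuery:
    """An ACE query: outcome Y = y, treatment X contrasted at (x_i, x_j),
    adjusting for the set Z."""

    outcome: str
    outcome_state: object
    treatment: str
    treatment_states: tuple
    adjustment_set: frozenset

    def __init__(self, outcome, outcome_state, treatment, treatment_states,
                 adjustment_set=()):
        if outcome == treatment:
            raise ValueError("outcome and treatment must differ")
        adj = frozenset(adjustment_set)
        if outcome in adj or treatment in adj:
            raise ValueError("adjustment set must exclude outcome and treatment")
        if len(tuple(treatment_states)) != 2:
            raise ValueError("treatment_states must be an ordered pair")
        object.__setattr__(self, "outcome", outcome)
        object.__setattr__(self, "outcome_state", outcome_state)
        object.__setattr__(self, "treatment", treatment)
        object.__setattr__(self, "treatment_states", tuple(treatment_states))
        object.__setattr__(self, "adjustment_set", adj)

    def to_dict(self) -> dict:
        return {
            "outcome": {"var": self.outcome, "state": self.outcome_state},
            "treatment": {"var": self.treatment,
                          "states": list(self.treatment_states)},
            "adjust": sorted(self.adjustment_set),
        }

    @classmethod
    def from_dict(cls, d) -> "InterventionQuery":
        return cls(outcome=d["outcome"]["var"], outcome_state=d["outcome"]["state"],
                   treatment=d["treatment"]["var"],
                   treatment_states=tuple(d["treatment"]["states"]),
                   adjustment_set=d.get("adjust", ()))


@dataclass(frozen=True)
class AceResult:
    """An intervention contrast: ``ace = p_do_i - p_do_j`` exactly."""

    query: InterventionQuery
    p_do_i: float
    p_do_j: float

    @property
    def ace(self) -> float:
        return self.p_do_i - self.p_do_j

    def to_dict(self) -> dict:
        return {**self.query.to_dict(), "p_do_i": self.p_do_i,
                "p_do_j": self.p_do_j, "ace": self.ace}


def intervene(bn: BayesNet, treatment: str, state) -> BayesNet:
    """Graph surgery for ``do(treatment = state)``.

    Returns the mutilated network: all edges into the treatment removed, its
    CPT replaced by a point mass on *state*, every other CPT unchanged.
    """
    if treatment not in bn.nodes:
        raise KeyError(f"unknown node {treatment!r}")
    states = bn.states(treatment)
    if state not in states:
        raise KeyError(f"unknown state {state!r} for node {treatment!r}")
    edges = {e for e in bn.dag.edges if e[1] != treatment}
    dag = Dag(nodes=bn.dag.nodes, edges=frozenset(edges))
    cpts = dict(bn.cpts)
    cpts[treatment] = Cpt.point_mass(treatment, state, states)
    return BayesNet(dag=dag, cpts=cpts)


def is_backdoor_admissible(dag: Dag, treatment: str, outcome: str,
                           adjustment_set: Iterable[str]) -> bool:
    """Whether Z d-separates treatment from outcome once the treatment's
    outgoing edges are removed (the backdoor criterion's blocking condition)."""
    z = set(adjustment_set)
    pruned = dag.graph()
    pruned.remove_edges_from([e for e in list(pruned.edges) if e[0] == treatment])
    return nx.is_d_separator(pruned, {treatment}, {outcome}, z)


def adjustment_probability(bn: BayesNet, outcome: str, outcome_state,
                           treatment: str, treatment_state,
                           adjustment_set: Iterable[str] = (),
                           check_backdoor: bool = False) -> float:
    """Backdoor estimate of P(outcome = y | do(treatment = x)).

    Each term P(Y=y | X=x, Z=z) P(Z=z) uses exact inference on the
    unmutilated network; the sum runs over adjustment-set configurations with
    positive probability.  A positive-probability stratum where the treatment
    state never occurs raises :class:`PositivityError` naming the stratum
    rather than silently dropping it.  An empty adjustment set degenerates to
    the plain conditional P(Y=y | X=x).
    """
    adj = sorted(set(adjustment_set))
    if outcome in adj or treatment in adj:
        raise ValueError("adjustment set must exclude outcome and treatment")
    if check_backdoor and not is_backdoor_admissible(bn.dag, treatment, outcome, adj):
        warnings.warn(
            f"adjustment set {adj} does not block every backdoor path from "
            f"{treatment!r} to {outcome!r}; the adjustment formula may not "
            f"identify the interventional probability", stacklevel=2)
    total = 0.0
    for combo in itertools.product(*(bn.states(v) for v in adj)):
        z = dict(zip(adj, combo))
        p_z = evidence_probability(bn, z)
        if p_z == 0.0:
            continue
        p_xz = evidence_probability(bn, {**z, treatment: treatment_state})
        if p_xz == 0.0:
            stratum = ", ".join(f"{k}={v}" for k, v in z.items()) or "(empty)"
            raise PositivityError(
                f"stratum {{{stratum}}} has positive probability but "
                f"{treatment}={treatment_state!r} never occurs there")
        p_yxz = evidence_probability(
            bn, {**z, treatment: treatment_state, outcome: outcome_state}) / p_xz
        total += p_yxz * p_z
    return total


def average_causal_effect(bn: BayesNet, q: InterventionQuery,
                          check_backdoor: bool = False) -> AceResult:
    """The ACE of the treatment contrast in *q* via the adjustment formula."""
    x_i, x_j = q.treatment_states
    p_i = adjustment_probability(bn, q.outcome, q.outcome_state, q.treatment,
                                 x_i, q.adjustment_set, check_backdoor)
    p_j = adjustment_probability(bn, q.outcome, q.outcome_state, q.treatment,
                                 x_j, q.adjustment_set)
    return AceResult(query=q, p_do_i=p_i, p_do_j=p_j)
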