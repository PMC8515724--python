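"""Brute-force enumeration oracles, independent of the package's inference engine.

Everything here works by exhaustively enumerating full assignments and
multiplying CPT entries with plain Python loops - no factors, no elimination -
so it can serve as the reference for variable elimination, MAP and the
adjustment formula on small networks.
"""

from __future__ import annotations

import itertools


def all_assignments(bn):
    nodes = list(bn.nodes)
    for combo in itertools.product(*(bn.states(n) for n in nodes)):
        yield dict(zip(nodes, combo))


def joint(bn, assignment) -> float:
    p = 1.0
    for node in bn.nodes:
        cpt = bn.cpts[node]
        p *= cpt.prob(assignment[node], {pa: assignment[pa] for pa in cpt.parents})
    return p


def _consistent(assignment, evidence) -> bool:
    return all(assignment[k] == v for k, v in evidence.items())


def enum_evidence_probability(bn, evidence) -> float:
    return sum(joint(bn, a) for a in all_assignments(bn) if _consistent(a, evidence))


def enum_query(bn, target, evidence) -> dict:
    mass = {s: 0.0 for s in bn.states(target)}
    for a in all_assignments(bn):
        if _consistent(a, evidence):
            mass[a[target]] += joint(bn, a)
    total = sum(mass.values())
    if total == 0:
        raise ZeroDivisionError("impossible evidence")
    return {s: m / total for s, m in mass.items()}


def enum_map(bn, evidence) -> dict:
    """Argmax completion; ties resolved toward the assignment that is
    lexicographically smallest over name-sorted variables (state order as in
    the variable's state tuple)."""
    free = sorted(n for n in bn.nodes if n not in evidence)
    best, best_p = None, -1.0
    for combo in itertools.product(*(bn.states(n) for n in free)):
        a = {**evidence, **dict(zip(free, combo))}
        p = joint(bn, a)
        if p > best_p * (1 + 1e-12):
            best, best_p = a, p
    return best


def enum_adjustment(bn, outcome, outcome_state, treatment, treatment_state,
                    adjustment_set) -> float:
    """sum_z P(Y=y | X=x, Z=z) P(Z=z) via enumeration."""
    adj = sorted(adjustment_set)
    total = 0.0
    for combo in itertools.product(*(bn.states(v) for v in adj)):
        z = dict(zip(adj, combo))
        p_z = enum_evidence_probability(bn, z)
        if p_z == 0:
            continue
        p_xz = enum_evidence_probability(bn, {**z, treatment: treatment_state})
        p_yxz = enum_evidence_probability(
            bn, {**z, treatment: treatment_state, outcome: outcome_state})
        total += p_yxz / p_xz * p_z
    return total
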