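"""Expert-elicited causal structure and the pairwise correlation table.

Domain experts (physicians, nurses, psychologists, teachers, pedagogues)
assert directed cause-effect edges over the seven study attributes; the
consensus DAG keeps an edge when at least a configurable fraction of experts
asserted it, resolving direction conflicts by vote and repairing any residual
cycle by dropping its weakest edge.  Alongside, the Pearson (phi) correlation
matrix of the binary table is computed and annotated: a pair with no directed
path between its members in the consensus DAG is flagged as a spurious
correlation (SC) - an association attributed to confounding or noise rather
than causation.  The SC rule is a replaceable policy and the raw coefficient
is always preserved next to the flag.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .bn import Dag, validate_dag
from .preprocess import BINARY_COLUMNS

__all__ = [
    "ExpertSurvey",
    "CorrelationTable",
    "load_surveys",
    "aggregate_consensus_dag",
    "correlation_table",
    "annotate_spurious",
    "write_correlation_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpertSurvey:
    """One expert's set of asserted directed causal edges."""

    expert_id: str
    profession: str = ""
    asserted_edges: frozenset = frozenset()

    def __post_init__(self):
        edges = frozenset(tuple(e) for e in self.asserted_edges)
        for s, t in edges:
            if s == t:
                raise ValueError(f"survey {self.expert_id}: self-loop on {s!r}")
        object.__setattr__(self, "asserted_edges", edges)


def load_surveys(path, attributes: Sequence[str] = BINARY_COLUMNS
                 ) -> list[ExpertSurvey]:
    """Read surveys from a CSV with columns expert_id, profession, source, target
    (one row per expert per asserted edge)."""
    allowed = set(attributes)
    by_expert: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"expert_id", "profession", "source", "target"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for rownum, row in enumerate(reader, start=2):
            src, tgt = row["source"].strip(), row["target"].strip()
            if src not in allowed or tgt not in allowed:
                raise ValueError(
                    f"{path}:{rownum}: edge ({src!r}, {tgt!r}) outside the "
                    f"attribute set {sorted(allowed)}")
            entry = by_expert.setdefault(
                row["expert_id"].strip(),
                {"profession": row["profession"].strip(), "edges": set()})
            entry["edges"].add((src, tgt))
    return [ExpertSurvey(expert_id=eid, profession=e["profession"],
                         asserted_edges=frozenset(e["edges"]))
            for eid, e in sorted(by_expert.items())]


def aggregate_consensus_dag(surveys: Sequence[ExpertSurvey],
                            vote_threshold: float = 0.5,
                            nodes: Sequence[str] = BINARY_COLUMNS,
                            ) -> tuple[Dag, dict]:
    """Majority-style vote over asserted edges, returning a repaired DAG.

    An edge enters when asserted by at least ``vote_threshold`` of the experts.
    If both directions qualify the higher-voted one survives (an exact tie
    drops both, with a warning).  Any remaining directed cycle is repaired by
    iteratively removing the lowest-voted edge on a detected cycle; every drop
    is recorded in the vote report.
    """
    if not surveys:
        raise ValueError("at least one survey is required")
    if not 0 < vote_threshold <= 1:
        raise ValueError("vote_threshold must be in (0, 1]")
    n = len(surveys)
    votes: dict[tuple[str, str], int] = {}
    for s in surveys:
        for e in s.asserted_edges:
            votes[e] = votes.get(e, 0) + 1
    passing = {e for e, v in votes.items() if v / n >= vote_threshold}

    dropped: list[dict] = []
    for a, b in sorted(passing):
        rev = (b, a)
        if rev in passing and (a, b) in passing:
            if votes[(a, b)] == votes[rev]:
                passing -= {(a, b), rev}
                dropped += [{"edge": [a, b], "votes": votes[(a, b)],
                             "reason": "direction tie"},
                            {"edge": [b, a], "votes": votes[rev],
                             "reason": "direction tie"}]
                warnings.warn(
                    f"edges {a}->{b} and {b}->{a} tie at {votes[(a, b)]} votes; "
                    f"excluding both", stacklevel=2)
            else:
                loser = (a, b) if votes[(a, b)] < votes[rev] else rev
                passing.discard(loser)
                dropped.append({"edge": list(loser), "votes": votes[loser],
                                "reason": "reverse direction won"})

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(passing)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(((u, v) for u, v, *_ in cycle),
                      key=lambda e: (votes[e], e))
        g.remove_edge(*weakest)
        passing.discard(weakest)
        dropped.append({"edge": list(weakest), "votes": votes[weakest],
                        "reason": "cycle repair"})
        logger.warning("cycle repair: dropped %s->%s (%d votes)",
                       weakest[0], weakest[1], votes[weakest])

    dag = validate_dag(nodes, passing)
    report = {
        "n_experts": n,
        "vote_threshold": vote_threshold,
        "votes": {f"{a}->{b}": v for (a, b), v in sorted(votes.items())},
        "kept_edges": sorted([a, b] for a, b in passing),
        "dropped_edges": dropped,
    }
    return dag, report


@dataclass(frozen=True)
class CorrelationTable:
    """Symmetric Pearson/phi coefficient matrix with optional SC flags."""

    coefficients: pd.DataFrame
    spurious: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self):
        coef = self.coefficients
        if not np.allclose(coef.to_numpy(), coef.to_numpy().T, atol=1e-12):
            raise ValueError("coefficient matrix must be symmetric")
        if not np.allclose(np.diag(coef.to_numpy()), 1.0):
            raise ValueError("diagonal must be 1")
        if (coef.to_numpy() < -1 - 1e-12).any() or (coef.to_numpy() > 1 + 1e-12).any():
            raise ValueError("coefficients must lie in [-1, 1]")
        if self.spurious is None:
            object.__setattr__(
                self, "spurious",
                pd.DataFrame(False, index=coef.index, columns=coef.columns))

    def is_spurious(self, a: str, b: str) -> bool:
        return bool(self.spurious.loc[a, b])


def correlation_table(data: pd.DataFrame) -> CorrelationTable:
    """Pearson product-moment coefficients of the 0/1 columns (phi coefficients).

    A constant column makes the coefficient undefined and is an error.
    """
    for col in data.columns:
        if data[col].nunique() < 2:
            raise ValueError(f"column {col!r} is constant; correlation undefined")
    return CorrelationTable(coefficients=data.corr(method="pearson"))


def annotate_spurious(table: CorrelationTable, dag: Dag) -> CorrelationTable:
    """Flag attribute pairs with no directed path in either direction as SC.

    Reachability (not mere adjacency) is the policy: a pair linked through a
    causal chain is never spurious, however long the chain.
    """
    cols = list(table.coefficients.columns)
    missing = set(cols) - set(dag.nodes)
    if missing:
        raise ValueError(f"DAG lacks attributes {sorted(missing)}")
    g = dag.graph()
    flags = pd.DataFrame(False, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sc = not (nx.has_path(g, a, b) or nx.has_path(g, b, a))
            flags.loc[a, b] = flags.loc[b, a] = sc
    return CorrelationTable(coefficients=table.coefficients, spurious=flags)


def write_correlation_csv(table: CorrelationTable, path,
                          decimals: int = 2) -> None:
    """Write the matrix as CSV, flagged cells holding the literal token ``SC``."""
    cols = list(table.coefficients.columns)
    out = table.coefficients.round(decimals).astype(object)
    for a in cols:
        for b in cols:
            if a != b and table.is_spurious(a, b):
                out.loc[a, b] = "SC"
    out.to_csv(path, index=True)
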