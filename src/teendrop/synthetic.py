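"""Synthetic interview-record generator.

Emulates raw interview-survey data so that every pipeline stage is testable
without access to real respondent records: binary attribute profiles are drawn by
ancestral sampling from a configurable ground-truth Bayesian network, then
"de-binarized" into raw survey answers (an age in years, a monthly income in
US$, an ethnicity self-declaration, ...) whose re-binarization provably
returns the sampled profile.  Sex is drawn independently (14.3% male, the
study's share) and missingness is injected completely at random.

The default ground-truth network is a *reconstruction*: the study's full
expert-consensus graph is published only as a figure, so the shipped DAG uses
the text-supported edges (MF->TP and TP->SS, with Age/EG/ES as shared parents
of TP and SS and ES->LS).  Its CPTs are fixed numbers, solved offline so that
exact single-node marginals match the study's descriptive statistics
(Age .70, EG .52, MF .57, ES .24, SS .66, LS .16, TP 130/294) and the key
effect sizes match the reported ones (balanced-network P(TP=1|MF=1) = 0.58,
balanced-data corr(TP, SS) = -0.5); remaining effect directions follow the
reported correlation signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .bn import BayesNet, Cpt, validate_dag
from .preprocess import BINARY_COLUMNS, RAW_COLUMNS, RawRecord, ThresholdConfig

__all__ = [
    "GeneratorConfig",
    "GROUND_TRUTH_EDGES",
    "ground_truth_network",
    "default_config",
    "sample_records",
    "sample_with_profiles",
    "roundtrip_check",
    "write_raw_csv",
]

#: reconstructed study DAG (the published consensus graph is figure-only)
GROUND_TRUTH_EDGES = (
    ("MF", "TP"), ("Age", "TP"), ("EG", "TP"), ("ES", "TP"),
    ("Age", "SS"), ("EG", "SS"), ("ES", "SS"), ("TP", "SS"),
    ("ES", "LS"),
)

# P(node = 1 | parent configuration); parents in lexicographic order, rows
# row-major over parent states.  Solved offline (logistic link; slopes signed
# per the reported correlation pattern, intercepts and the MF->TP / TP->SS
# slopes fitted to the marginal and effect targets quoted in the module
# docstring), then frozen here as plain numbers.
_GROUND_TRUTH_P1 = {
    "Age": [0.70],
    "EG": [0.52],
    "ES": [0.24],
    "MF": [0.57],
    # parents Age, EG, ES, MF
    "TP": [0.2203072986, 0.3915718919, 0.1342518554, 0.2610130937,
           0.2118388907, 0.3797264115, 0.1285459751, 0.2514846742,
           0.4344110219, 0.6362883299, 0.2965300734, 0.4898239981,
           0.4221688157, 0.6246401062, 0.2862072437, 0.4773381296],
    # parents Age, EG, ES, TP
    "SS": [0.8897289621, 0.4539620217, 0.9363133698, 0.6023640267,
           0.8945397809, 0.4663820492, 0.9392306517, 0.6142766541,
           0.8303310883, 0.3352186935, 0.8991645037, 0.4788438918,
           0.8372592837, 0.3464512554, 0.9036082731, 0.4913321213],
    # parent ES
    "LS": [0.1410526316, 0.22],
}

#: default raw-value samplers per attribute and binary state (declarative so
#: configs serialize; every rule maps back to its state under the default cuts)
DEFAULT_RAW_EMISSION = {
    "Age": {0: {"kind": "int_uniform", "low": 12, "high": 14},
            1: {"kind": "int_uniform", "low": 15, "high": 18}},
    "EG": {0: {"kind": "choice", "values": ["branca"]},
           1: {"kind": "choice", "values": ["parda", "preta", "amarela", "indigena"]}},
    "TP": {0: {"kind": "const", "value": 0},
           1: {"kind": "one_plus_poisson", "lam": 0.2}},
    "MF": {0: {"kind": "const", "value": 0}, 1: {"kind": "const", "value": 1}},
    "ES": {0: {"kind": "int_uniform", "low": 0, "high": 779},
           1: {"kind": "int_uniform", "low": 780, "high": 2600}},
    "SS": {0: {"kind": "const", "value": 0}, 1: {"kind": "const", "value": 1}},
    "LS": {0: {"kind": "const", "value": 0}, 1: {"kind": "const", "value": 1}},
}

#: maps each binary attribute to its raw CSV field
_RAW_FIELD_OF = {
    "Age": "age", "EG": "ethnicity", "TP": "pregnancy_count",
    "MF": "mother_teen_pregnancy", "ES": "family_income_usd_month",
    "SS": "enrolled", "LS": "has_job",
}


def ground_truth_network() -> BayesNet:
    """The calibrated default ground-truth network (see module docstring)."""
    dag = validate_dag(BINARY_COLUMNS, GROUND_TRUTH_EDGES)
    cpts = {}
    for node in BINARY_COLUMNS:
        parents = dag.parents(node)
        p1 = np.asarray(_GROUND_TRUTH_P1[node], dtype=float)
        shape = tuple(2 for _ in parents)
        table = np.stack([1 - p1.reshape(shape), p1.reshape(shape)], axis=-1)
        cpts[node] = Cpt(node=node, parents=parents, table=table)
    return BayesNet(dag=dag, cpts=cpts)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults mirror the interview campaign: 343 respondents, 14.3% of them
    male, a small completely-at-random per-cell nonresponse rate.
    """

    ground_truth: BayesNet
    n_records: int = 343
    male_fraction: float = 0.143
    missing_rate: float = 0.01
    seed: int = 0
    raw_emission: dict = field(default_factory=lambda: DEFAULT_RAW_EMISSION)

    def __post_init__(self):
        if self.n_records < 0:
            raise ValueError("n_records must be non-negative")
        for name, p in (("male_fraction", self.male_fraction),
                        ("missing_rate", self.missing_rate)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be a probability, got {p}")
        missing = set(BINARY_COLUMNS) - set(self.raw_emission)
        if missing:
            raise ValueError(f"raw_emission lacks rules for {sorted(missing)}")

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "male_fraction": self.male_fraction,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
            "raw_emission": self.raw_emission,
            "ground_truth": self.ground_truth.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        net = BayesNet.from_dict(d.pop("ground_truth"))
        emission = {
            attr: {int(s): rule for s, rule in rules.items()}
            for attr, rules in d.pop("raw_emission").items()
        }
        return cls(ground_truth=net, raw_emission=emission, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(n_records: int = 343, seed: int = 0,
                   missing_rate: float = 0.01) -> GeneratorConfig:
    """The calibrated study-scale configuration."""
    return GeneratorConfig(ground_truth=ground_truth_network(),
                           n_records=n_records, seed=seed,
                           missing_rate=missing_rate)


def _emit(rule: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = rule["kind"]
    if kind == "const":
        return np.full(n, rule["value"], dtype=object)
    if kind == "int_uniform":
        return rng.integers(rule["low"], rule["high"] + 1, size=n).astype(object)
    if kind == "choice":
        return rng.choice(np.asarray(rule["values"], dtype=object), size=n)
    if kind == "one_plus_poisson":
        return (1 + rng.poisson(rule["lam"], size=n)).astype(object)
    raise ValueError(f"unknown emission kind {kind!r}")


def sample_with_profiles(cfg: GeneratorConfig
                         ) -> tuple[list[RawRecord], "np.ndarray"]:
    """Sample raw records plus the underlying binary profiles.

    Returns ``(records, profiles)`` where ``profiles`` is an ``(n, 7)`` int
    array in :data:`BINARY_COLUMNS` order.  Missingness is injected *after*
    raw emission, so profiles always describe the complete latent answers.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_records
    net = cfg.ground_truth
    order = net.dag.topological_order()
    col_index = {a: i for i, a in enumerate(BINARY_COLUMNS)}

    profiles = np.zeros((n, len(BINARY_COLUMNS)), dtype=int)
    for node in order:
        parents = net.dag.parents(node)
        table = np.asarray(net.cpts[node].table)
        if parents:
            idx = tuple(profiles[:, col_index[p]] for p in parents)
            p1 = table[idx + (1,)]
        else:
            p1 = np.full(n, table[1])
        profiles[:, col_index[node]] = rng.random(n) < p1

    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female").astype(object)

    raw = {}
    for attr in BINARY_COLUMNS:
        states = profiles[:, col_index[attr]]
        vals = np.empty(n, dtype=object)
        for s in (0, 1):
            mask = states == s
            vals[mask] = _emit(cfg.raw_emission[attr][s], int(mask.sum()), rng)
        raw[_RAW_FIELD_OF[attr]] = vals

    missing = rng.random((n, len(RAW_COLUMNS))) < cfg.missing_rate

    flag_fields = {"mother_teen_pregnancy", "enrolled", "has_job"}
    records = []
    for i in range(n):
        cells: dict = {"sex": sex[i]}
        cells.update({f: raw[f][i] for f in raw})
        for j, fieldname in enumerate(RAW_COLUMNS):
            if missing[i, j]:
                cells[fieldname] = None
        for f in ("age", "pregnancy_count"):
            if cells[f] is not None:
                cells[f] = int(cells[f])
        for f in flag_fields:
            if cells[f] is not None:
                cells[f] = int(cells[f])
        if cells["family_income_usd_month"] is not None:
            cells["family_income_usd_month"] = float(cells["family_income_usd_month"])
        records.append(RawRecord(**cells))
    return records, profiles


def sample_records(cfg: GeneratorConfig) -> list[RawRecord]:
    """Sample ``cfg.n_records`` raw interview records (see module docstring)."""
    return sample_with_profiles(cfg)[0]


def roundtrip_check(cfg: GeneratorConfig,
                    thresholds: ThresholdConfig | None = None) -> dict:
    """Verify that emitted raw values binarize back to the sampled profiles.

    Requires ``missing_rate == 0``.  Mismatches (an emission rule inconsistent
    with the thresholds) are report content, not errors.
    """
    from .preprocess import binarize  # local import to avoid cycle at import time

    if cfg.missing_rate != 0:
        raise ValueError("roundtrip_check requires missing_rate == 0")
    thresholds = thresholds or ThresholdConfig()
    records, profiles = sample_with_profiles(cfg)
    table = binarize(records, thresholds).to_numpy()
    mismatch_idx = np.argwhere(table != profiles)
    mismatches = [
        {"row": int(r), "column": BINARY_COLUMNS[c],
         "sampled": int(profiles[r, c]), "binarized": int(table[r, c])}
        for r, c in mismatch_idx[:100]
    ]
    return {"n_records": cfg.n_records,
            "n_mismatches": int(len(mismatch_idx)),
            "mismatches": mismatches}


def write_raw_csv(records, path) -> None:
    """Write records in the raw schema; missing cells become empty, flags yes/no."""
    import csv

    flag_fields = {"mother_teen_pregnancy", "enrolled", "has_job"}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RAW_COLUMNS)
        for rec in records:
            row = []
            for name in RAW_COLUMNS:
                v = getattr(rec, name)
                if v is None:
                    row.append("")
                elif name in flag_fields:
                    row.append("yes" if v else "no")
                elif name == "family_income_usd_month":
                    row.append(f"{v:g}")
                else:
                    row.append(str(v))
            writer.writerow(row)
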