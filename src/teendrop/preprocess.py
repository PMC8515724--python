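"""Interview-record preprocessing: imputation, exclusion, balancing, binarization.

The study protocol transforms raw adolescent-interview records (ages 12-18)
into a balanced binary analysis table in a fixed order:

1. median imputation of missing cells,
2. exclusion of male respondents,
3. class balancing on teenage pregnancy by random undersampling of the
   majority class,
4. binarization of all seven attributes.

The binary encoding: Age (1 if >= 15 years), EG (0 white / 1 non-white),
TP (1 if at least one pregnancy, abortions included), MF (1 if the
respondent's mother experienced teenage pregnancy), ES (0 if family income
< US$780/month), SS (1 if enrolled in school), LS (1 if employed).
Thresholds follow a ">= cut goes to state 1" convention.
"""

from __future__ import annotations

import csv
import logging
import statistics
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BINARY_COLUMNS",
    "RAW_COLUMNS",
    "RawRecord",
    "ThresholdConfig",
    "PreprocessError",
    "RecordValidationError",
    "load_raw_records",
    "impute_missing",
    "exclude_males",
    "balance_on_attribute",
    "binarize",
    "run_preprocess",
    "write_binary_csv",
]

logger = logging.getLogger(__name__)

#: canonical column order of the binary analysis table
BINARY_COLUMNS = ("Age", "EG", "TP", "MF", "ES", "SS", "LS")

#: canonical raw CSV schema (one row per respondent)
RAW_COLUMNS = (
    "age", "sex", "ethnicity", "pregnancy_count", "mother_teen_pregnancy",
    "enrolled", "family_income_usd_month", "has_job",
)

#: adolescence window in years (Brazilian Child and Adolescent Statute)
AGE_WINDOW = (12, 18)

_DEFAULT_MISSING_TOKENS = frozenset({"", "na", "n/a", "nan", "null", "none", "?", "missing"})

_WHITE_TERMS = frozenset({"white", "branca", "branco", "caucasian"})
_NONWHITE_TERMS = frozenset({
    "non-white", "nonwhite", "parda", "pardo", "preta", "preto", "negra",
    "negro", "black", "brown", "mixed", "indigena", "indigenous", "amarela",
    "amarelo", "asian",
})


class PreprocessError(ValueError):
    """A preprocessing stage could not be carried out."""


class RecordValidationError(PreprocessError):
    """A raw value violates a record invariant (age window, negative count...)."""


@dataclass(frozen=True)
class RawRecord:
    """One respondent's untransformed answers; ``None`` marks a missing cell.

    Flags (``mother_teen_pregnancy``, ``enrolled``, ``has_job``) are stored as
    0/1 once parsed; ``sex`` is ``"female"``/``"male"``; ``ethnicity`` is the
    free self-declared string.
    """

    age: int | None = None
    sex: str | None = None
    ethnicity: str | None = None
    pregnancy_count: int | None = None
    mother_teen_pregnancy: int | None = None
    enrolled: int | None = None
    family_income_usd_month: float | None = None
    has_job: int | None = None

    def __post_init__(self):
        if self.age is not None and not (AGE_WINDOW[0] <= self.age <= AGE_WINDOW[1]):
            raise RecordValidationError(
                f"age {self.age} outside the adolescence window "
                f"[{AGE_WINDOW[0]}, {AGE_WINDOW[1]}]")
        if self.pregnancy_count is not None and self.pregnancy_count < 0:
            raise RecordValidationError("pregnancy_count must be non-negative")
        if (self.family_income_usd_month is not None
                and self.family_income_usd_month < 0):
            raise RecordValidationError("family_income_usd_month must be non-negative")


@dataclass(frozen=True)
class ThresholdConfig:
    """Binarization cut points; every field uses the '>= cut -> state 1' rule
    (for ES, income >= cut -> state 1; for TP, pregnancy_count >= cut -> 1)."""

    age_cut: int = 15
    income_cut: float = 780.0
    pregnancy_cut: int = 1

    def __post_init__(self):
        if self.age_cut <= 0 or self.income_cut <= 0 or self.pregnancy_cut <= 0:
            raise ValueError("all threshold cuts must be strictly positive")


def ethnicity_to_binary(value: str, extra_map: Mapping[str, int] | None = None) -> int:
    """Map a self-declared ethnicity string to the EG encoding (0 white, 1 non-white).

    Matching is case-insensitive on a built-in lookup, optionally extended by
    *extra_map*; an unmapped string is an error, never silently non-white.
    """
    key = value.strip().lower()
    if extra_map:
        lowered = {k.strip().lower(): v for k, v in extra_map.items()}
        if key in lowered:
            return int(lowered[key])
    if key in _WHITE_TERMS:
        return 0
    if key in _NONWHITE_TERMS:
        return 1
    raise PreprocessError(
        f"ethnicity {value!r} not in the white/non-white lookup; extend the "
        f"mapping explicitly rather than defaulting")


# --------------------------------------------------------------------------
# loading


def _parse_flag(text: str) -> int | None:
    t = text.strip().lower()
    if t in {"1", "yes", "y", "true", "t"}:
        return 1
    if t in {"0", "no", "n", "false", "f"}:
        return 0
    return None


def _parse_sex(text: str) -> str | None:
    t = text.strip().lower()
    if t in {"female", "f", "girl", "feminino"}:
        return "female"
    if t in {"male", "m", "boy", "masculino"}:
        return "male"
    return None


def load_raw_records(path, delimiter: str = ",",
                     missing_tokens: Iterable[str] = _DEFAULT_MISSING_TOKENS,
                     ) -> tuple[list[RawRecord], dict]:
    """Read raw interview records from a headed CSV.

    Returns ``(records, report)`` where the report counts missing cells per
    column.  Unparseable cells become explicit missing markers; a value that
    parses but violates a record invariant (age outside 12-18, negative count)
    raises :class:`RecordValidationError` naming the row.
    """
    missing_tokens = {t.lower() for t in missing_tokens}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise PreprocessError(f"{path}: empty file, header row required") from None
        header = [h.strip() for h in header]
        if set(header) != set(RAW_COLUMNS):
            raise PreprocessError(
                f"{path}: header {header} does not match the raw schema "
                f"{list(RAW_COLUMNS)}")
        col_of = {name: header.index(name) for name in RAW_COLUMNS}

        records: list[RawRecord] = []
        missing_counts = {name: 0 for name in RAW_COLUMNS}
        for rownum, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise PreprocessError(
                    f"{path}:{rownum}: expected {len(header)} cells, got {len(row)}")
            cells = {}
            for name in RAW_COLUMNS:
                raw = row[col_of[name]].strip()
                if raw.lower() in missing_tokens:
                    cells[name] = None
                    missing_counts[name] += 1
                    continue
                parsed: object | None
                try:
                    if name == "age":
                        parsed = int(float(raw))
                    elif name == "pregnancy_count":
                        parsed = int(float(raw))
                    elif name == "family_income_usd_month":
                        parsed = float(raw)
                    elif name == "sex":
                        parsed = _parse_sex(raw)
                    elif name in ("mother_teen_pregnancy", "enrolled", "has_job"):
                        parsed = _parse_flag(raw)
                    else:  # ethnicity: free string
                        parsed = raw
                except ValueError:
                    parsed = None
                if parsed is None:
                    missing_counts[name] += 1
                cells[name] = parsed
            try:
                records.append(RawRecord(**cells))
            except RecordValidationError as exc:
                raise RecordValidationError(f"{path}:{rownum}: {exc}") from None
    report = {"n_records": len(records), "missing_per_column": missing_counts}
    return records, report


# --------------------------------------------------------------------------
# pipeline stages


_NUMERIC_FIELDS = ("age", "pregnancy_count", "family_income_usd_month")
_FLAG_FIELDS = ("mother_teen_pregnancy", "enrolled", "has_job")


def _binary_median(values: Sequence[int], column: str) -> int:
    """Median of a 0/1 sample; an exact 0.5 tie rounds down to 0 with a warning."""
    med = float(np.median(values))
    if med == 0.5:
        logger.warning("imputation tie on column %r (median 0.5); rounding down to 0",
                       column)
        return 0
    return int(round(med))


def impute_missing(records: Sequence[RawRecord]) -> tuple[list[RawRecord], dict]:
    """Replace every missing value by its column's median of observed values.

    Integer-valued columns use the low median (an observed value), income the
    ordinary median.  Flags are 0/1-encoded before the median; an even-sample
    0.5 tie rounds down to 0 with a logged warning.  ``sex`` (the downstream
    exclusion key) and ``ethnicity`` are categorical and use the mode / the
    white-vs-non-white median respectively.  Observed values are never altered
    and record order is preserved.

    Returns ``(records, report)``; the report counts imputed cells per column.
    """
    fills: dict[str, object] = {}
    imputed = {name: 0 for name in RAW_COLUMNS}

    def observed(field: str) -> list:
        return [getattr(r, field) for r in records if getattr(r, field) is not None]

    for field in RAW_COLUMNS:
        obs = observed(field)
        if len(obs) == len(records):
            continue
        if not obs:
            raise PreprocessError(
                f"column {field!r} is entirely missing; imputation undefined")
        if field in ("age", "pregnancy_count"):
            fills[field] = statistics.median_low(obs)
        elif field == "family_income_usd_month":
            fills[field] = float(np.median(obs))
        elif field in _FLAG_FIELDS:
            fills[field] = _binary_median(obs, field)
        elif field == "sex":
            counts = {s: obs.count(s) for s in ("female", "male")}
            if counts["female"] == counts["male"]:
                logger.warning("sex imputation tie; filling with 'female'")
                fills[field] = "female"
            else:
                fills[field] = max(counts, key=counts.get)
            logger.info("imputing %d missing sex cells with mode %r",
                        len(records) - len(obs), fills[field])
        else:  # ethnicity
            enc = [ethnicity_to_binary(v) for v in obs]
            fills[field] = "non-white" if _binary_median(enc, field) == 1 else "white"

    out = []
    for rec in records:
        updates = {}
        for field, fill in fills.items():
            if getattr(rec, field) is None:
                updates[field] = fill
                imputed[field] += 1
        out.append(replace(rec, **updates) if updates else rec)
    return out, {"imputed_per_column": imputed}


def exclude_males(records: Sequence[RawRecord]) -> list[RawRecord]:
    """Keep exactly the female records, in their original order."""
    for i, rec in enumerate(records):
        if rec.sex is None:
            raise PreprocessError(
                f"record {i}: sex is missing; run imputation before exclusion")
    return [r for r in records if r.sex == "female"]


def balance_on_attribute(records: Sequence[RawRecord],
                         attribute: str = "pregnancy_count",
                         cut: float = 1,
                         seed: int = 0) -> list[RawRecord]:
    """Equalize the two classes (value < cut vs value >= cut) of *attribute*.

    The minority class is kept whole; the majority class is randomly
    undersampled without replacement using *seed*.  Original record order is
    preserved and the result has ``2 x minority count`` rows.
    """
    values = [getattr(r, attribute) for r in records]
    if any(v is None for v in values):
        raise PreprocessError(
            f"attribute {attribute!r} has missing values; impute before balancing")
    hi = [i for i, v in enumerate(values) if v >= cut]
    lo = [i for i, v in enumerate(values) if v < cut]
    if not hi or not lo:
        raise PreprocessError(
            f"balancing on {attribute!r} undefined: one class is empty "
            f"(>= {cut}: {len(hi)}, < {cut}: {len(lo)})")
    minority, majority = (hi, lo) if len(hi) <= len(lo) else (lo, hi)
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(len(majority), size=len(minority), replace=False)
    kept = set(minority) | {majority[i] for i in kept_majority}
    return [records[i] for i in sorted(kept)]


def binarize(records: Sequence[RawRecord],
             cfg: ThresholdConfig | None = None,
             ethnicity_map: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Encode records into the 7-column 0/1 analysis table.

    Deterministic and total on imputed data; any missing value is an error
    (binarization must follow imputation).
    """
    cfg = cfg or ThresholdConfig()
    rows = []
    for i, rec in enumerate(records):
        for field in RAW_COLUMNS:
            if field != "sex" and getattr(rec, field) is None:
                raise PreprocessError(
                    f"record {i}: missing {field!r}; binarize must follow imputation")
        rows.append({
            "Age": int(rec.age >= cfg.age_cut),
            "EG": ethnicity_to_binary(rec.ethnicity, ethnicity_map),
            "TP": int(rec.pregnancy_count >= cfg.pregnancy_cut),
            "MF": int(rec.mother_teen_pregnancy),
            "ES": int(rec.family_income_usd_month >= cfg.income_cut),
            "SS": int(rec.enrolled),
            "LS": int(rec.has_job),
        })
    return pd.DataFrame(rows, columns=list(BINARY_COLUMNS), dtype=int)


def run_preprocess(records: Sequence[RawRecord],
                   thresholds: ThresholdConfig | None = None,
                   seed: int = 0,
                   ethnicity_map: Mapping[str, int] | None = None,
                   ) -> tuple[pd.DataFrame, dict]:
    """Full protocol: impute -> exclude males -> balance on TP -> binarize.

    Returns the balanced binary table and a run report (row counts per stage,
    imputation counts, balancing seed).
    """
    thresholds = thresholds or ThresholdConfig()
    imputed, imp_report = impute_missing(records)
    females = exclude_males(imputed)
    balanced = balance_on_attribute(females, "pregnancy_count",
                                    thresholds.pregnancy_cut, seed=seed)
    table = binarize(balanced, thresholds, ethnicity_map)
    report = {
        "rows_loaded": len(records),
        "rows_after_imputation": len(imputed),
        "rows_after_exclusion": len(females),
        "rows_after_balancing": len(balanced),
        "males_excluded": len(imputed) - len(females),
        "balancing_seed": seed,
        "thresholds": {"age_cut": thresholds.age_cut,
                       "income_cut": thresholds.income_cut,
                       "pregnancy_cut": thresholds.pregnancy_cut},
        **imp_report,
    }
    return table, report


def write_binary_csv(table: pd.DataFrame, path) -> None:
    """Write the binary table with the canonical ``Age,EG,TP,MF,ES,SS,LS`` header."""
    table.loc[:, list(BINARY_COLUMNS)].to_csv(path, index=False)
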