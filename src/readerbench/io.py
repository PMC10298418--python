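"""Reading and writing the tabular study artifacts.

Four input schemas (``cases``, ``readers``, ``ratings``, ``model_scores``) and
one output schema (``report``) are supported.  Files are delimited text with a
header line; the delimiter (comma or tab) is sniffed from the header and files
are always written comma-separated.  Every field is validated against its
domain invariants on read: an invalid value raises :class:`ValidationError`
with the offending row number, a missing column raises :class:`SchemaError` —
malformed input is never silently dropped.

Conventions fixed here and used everywhere downstream:

* ``label`` is an integer, 1 = "with pathology", 0 = "without pathology";
  the string forms are accepted on read and mapped.
* higher score / probability always means "more likely pathological".
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

logger = logging.getLogger(__name__)

MODALITIES = ("XRAY", "FLG", "MMG")
EXPERIENCE_BANDS = ("E0_1", "E1_5", "E5_10", "E10P")
SEXES = ("M", "F", "unknown")

_LABEL_STRINGS = {
    "with pathology": 1,
    "without pathology": 0,
    "with (target) pathology": 1,
    "without (target) pathology": 0,
}

#: required columns per schema (optional columns listed separately)
SCHEMAS = {
    "cases": {"required": ["case_id", "modality", "label"],
              "optional": ["age", "sex"],
              "key": ["case_id"]},
    "readers": {"required": ["reader_id", "experience_band", "breast_specialist"],
                "optional": ["country"],
                "key": ["reader_id"]},
    "ratings": {"required": ["reader_id", "case_id", "score"],
                "optional": [],
                "key": ["reader_id", "case_id"]},
    "model_scores": {"required": ["model_id", "case_id", "prob"],
                     "optional": [],
                     "key": ["model_id", "case_id"]},
}

REPORT_COLUMNS = [
    "modality", "group", "n",
    "auroc", "auroc_lo", "auroc_hi",
    "threshold", "youden_j",
    "sens", "sens_lo", "sens_hi",
    "spec", "spec_lo", "spec_hi",
    "acc", "acc_lo", "acc_hi",
    "p_value",
]


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _coerce_label(value, row: int):
    if isinstance(value, str):
        key = value.strip().lower()
        if key in _LABEL_STRINGS:
            return _LABEL_STRINGS[key]
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: label {value!r} is not 0/1 or a "
                              "'with/without pathology' string") from None
    if f not in (0.0, 1.0):
        raise ValidationError(f"row {row}: label {value!r} not in {{0, 1}}")
    return int(f)


def _check_enum(frame: pd.DataFrame, column: str, allowed: tuple, schema: str) -> None:
    bad = ~frame[column].isin(allowed)
    if bad.any():
        row = int(frame.index[bad][0]) + 2  # 1-based + header line
        raise ValidationError(
            f"{schema}: row {row}: {column}={frame.loc[frame.index[bad][0], column]!r} "
            f"not one of {allowed}")


def _check_duplicates(frame: pd.DataFrame, key: list[str], schema: str) -> None:
    dup = frame.duplicated(subset=key, keep=False)
    if dup.any():
        keys = frame.loc[dup, key].astype(str).agg("/".join, axis=1).unique()
        raise ValidationError(
            f"{schema}: duplicate key(s) on ({', '.join(key)}): "
            + ", ".join(keys[:10]))


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate one study table.

    Parameters
    ----------
    path : str or Path
        Delimited text file (comma or tab, sniffed from the header line).
    schema : {"cases", "readers", "ratings", "model_scores"}

    Returns
    -------
    pandas.DataFrame
        Typed, validated records in file order.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of "
                          f"{sorted(SCHEMAS)}")
    path = Path(path)
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                        na_values=[""])
    spec = SCHEMAS[schema]
    missing = [c for c in spec["required"] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{schema}: missing required column(s) "
                          f"{', '.join(missing)} in {path}")
    frame = frame.reset_index(drop=True)

    if schema == "cases":
        frame["label"] = [_coerce_label(v, i + 2)
                          for i, v in enumerate(frame["label"])]
        _check_enum(frame, "modality", MODALITIES, schema)
        if "age" in frame.columns:
            frame["age"] = pd.to_numeric(frame["age"], errors="raise")
        if "sex" in frame.columns:
            frame["sex"] = frame["sex"].fillna("unknown")
            _check_enum(frame, "sex", SEXES, schema)
    elif schema == "readers":
        _check_enum(frame, "experience_band", EXPERIENCE_BANDS, schema)
        truthy = {"true": True, "1": True, "false": False, "0": False}
        vals = frame["breast_specialist"].astype(str).str.strip().str.lower()
        bad = ~vals.isin(truthy)
        if bad.any():
            row = int(frame.index[bad][0]) + 2
            raise ValidationError(f"readers: row {row}: breast_specialist must "
                                  "be true/false")
        frame["breast_specialist"] = vals.map(truthy)
    elif schema == "ratings":
        scores = pd.to_numeric(frame["score"], errors="coerce")
        bad = scores.isna() | ~scores.isin([1, 2, 3, 4, 5])
        if bad.any():
            row = int(frame.index[bad][0]) + 2
            raise ValidationError(
                f"ratings: row {row}: score {frame.loc[frame.index[bad][0], 'score']!r}"
                " outside the 1..5 ordinal scale")
        frame["score"] = scores.astype(int)
    elif schema == "model_scores":
        probs = pd.to_numeric(frame["prob"], errors="coerce")
        bad = probs.isna() | (probs < 0) | (probs > 1)
        if bad.any():
            row = int(frame.index[bad][0]) + 2
            raise ValidationError(
                f"model_scores: row {row}: prob {frame.loc[frame.index[bad][0], 'prob']!r}"
                " outside [0, 1]")
        frame["prob"] = probs.astype(float)

    _check_duplicates(frame, spec["key"], schema)
    return frame


def write_table(frame: pd.DataFrame, path) -> None:
    """Write a study table as comma-separated text (the package's one dialect)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def _round_half_up(x, ndigits: int = 2):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return np.nan
    factor = 10 ** ndigits
    return np.floor(abs(x) * factor + 0.5) / factor * np.sign(x)


def write_report(report: pd.DataFrame, path) -> None:
    """Write a benchmark report table (one row per modality/group).

    Numeric performance columns are rounded to 2 decimals (half-up), p-values
    to 4, so re-reading the file reproduces the printed numbers exactly.
    An empty report writes the header only and logs a warning.
    """
    if report.empty:
        logger.warning("writing empty benchmark report to %s", path)
        out = pd.DataFrame(columns=REPORT_COLUMNS)
        write_table(out, path)
        return
    out = report.copy()
    for col in REPORT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    two_dp = [c for c in REPORT_COLUMNS
              if c not in ("modality", "group", "n", "p_value", "threshold")]
    for col in two_dp:
        out[col] = [_round_half_up(v, 2) for v in out[col]]
    out["threshold"] = [_round_half_up(v, 4) for v in out["threshold"]]
    out["p_value"] = [_round_half_up(v, 4) for v in out["p_value"]]
    write_table(out[REPORT_COLUMNS], path)


def read_report(path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    sep = _sniff_delimiter(Path(path))
    return pd.read_csv(path, sep=sep)
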