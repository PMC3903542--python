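"""Trial-table round trip: delimited text, one row per 2AFC trial.

Format: a comment line carrying the schema version, then a CSV header and
rows.  Floats are written with 17 significant digits so the round trip is
lossless.  ``staircase_id`` is empty for MOCS trials; distractor hues are
empty when no distractors were shown.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import TrialTableError
from .experiment import TRIAL_COLUMNS

__all__ = ["SCHEMA_VERSION", "write_trials", "read_trials"]

SCHEMA_VERSION = 1
_HEADER_COMMENT = f"# huemem trial table v{SCHEMA_VERSION}"

_FLOAT_COLS = ["reference_hue", "test_hue", "distractor1_hue", "distractor2_hue"]
_INT_COLS = ["trial_index", "seed"]
_STR_COLS = ["condition", "phase", "block_background", "reference_background", "reference_side"]


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table to ``path`` (CSV with a schema-version comment)."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialTableError(f"trial table is missing columns {missing}")
    out = trials.loc[:, TRIAL_COLUMNS].copy()
    out["response_test_bluer"] = out["response_test_bluer"].astype(int)
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(_HEADER_COMMENT + "\n")
        out.to_csv(fh, index=False, float_format="%.17g")


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`.

    Raises :class:`TrialTableError` naming the offending line for missing
    columns, non-numeric values, or out-of-range responses.
    """
    path = Path(path)
    with path.open("r") as fh:
        first = fh.readline()
        has_comment = first.startswith("#")
        if has_comment and "huemem trial table" not in first:
            raise TrialTableError(f"unrecognized schema header {first.strip()!r}", line=1)
        rest = first * (not has_comment) + fh.read()

    try:
        raw = pd.read_csv(_io.StringIO(rest), dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise TrialTableError(f"unparseable trial table: {exc}") from exc

    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns]
    if missing:
        raise TrialTableError(f"trial table is missing columns {missing}")

    # data rows start after the comment + header lines
    offset = 2 + int(has_comment)

    def _numeric(col: str, required: bool) -> pd.Series:
        text = raw[col].str.strip()
        probe = pd.to_numeric(text, errors="coerce")
        bad = probe.isna() & (text != "")
        if required:
            bad |= text == ""
        if bad.any():
            line = int(bad.idxmax()) + offset
            raise TrialTableError(f"bad value {text[bad.idxmax()]!r} in column {col!r}", line=line)
        # numpy's parser round-trips "%.17g" output exactly; pd.to_numeric does not
        return text.where(text != "", "nan").astype(float)

    out = pd.DataFrame(index=raw.index)
    for col in _INT_COLS:
        out[col] = _numeric(col, required=True).astype(np.int64)
    for col in _STR_COLS:
        out[col] = raw[col]
    for col in _FLOAT_COLS:
        out[col] = _numeric(col, required=col in ("reference_hue", "test_hue")).astype(float)
    out["staircase_id"] = _numeric("staircase_id", required=False).astype("Int64")

    resp = _numeric("response_test_bluer", required=True)
    if not resp.isin([0, 1]).all():
        bad = ~resp.isin([0, 1])
        raise TrialTableError(
            f"response_test_bluer must be 0 or 1, got {resp[bad].iloc[0]!r}",
            line=int(bad.idxmax()) + offset,
        )
    out["response_test_bluer"] = resp.astype(bool)
    return out.loc[:, TRIAL_COLUMNS]
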