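"""Long-format cohort CSV input/output.

Header-keyed, comma-delimited, UTF-8.  Enum values are serialized exactly as
the vocabulary strings in :mod:`teamdx.data_model`; structurally absent
fields are empty strings.  Reading validates the cohort and reports every
violation with row numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

from .data_model import COHORT_COLUMNS, Cohort, CohortValidationError, validate_cohort

__all__ = ["read_cohort_csv", "write_cohort_csv"]


def read_cohort_csv(path: Union[str, Path]) -> Cohort:
    """Read and validate a cohort CSV.  Column order is irrelevant."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(
            [f"{path}: missing column(s): {', '.join(missing)}"]
        )
    return validate_cohort(df)


def write_cohort_csv(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write a cohort in the canonical column order; byte-stable for a given cohort."""
    cohort.df[list(COHORT_COLUMNS)].to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
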