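"""Skin-conductance learning index.

Raw per-trial SCR amplitudes (maximum phasic response in the 1-5 s
post-stimulus window, scored upstream) are turned into the subject-level
learning index in three steps: amplitudes below 0.01 microsiemens are scored
as non-responses (exactly 0), responses are square-root transformed to reduce
skew, and each subject's transformed responses are range-corrected by
dividing by that subject's maximum so values span [0, 1].  The learning delta
is the mean corrected CS+ response minus the mean corrected CS- response;
habituation and general reactivity affect both cue types equally and cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NONRESPONSE_FLOOR_US",
    "LearningIndex",
    "floor_nonresponses",
    "transform_range_correct",
    "learning_delta",
    "process_scr_table",
]

#: Amplitudes below this (microsiemens) are scored as non-responses.
NONRESPONSE_FLOOR_US = 0.01


@dataclass(frozen=True)
class LearningIndex:
    """Per-subject conditioned-discrimination index on the corrected scale."""

    delta: float
    mean_csp: float
    mean_csm: float
    subject_id: str = ""


def floor_nonresponses(raw: np.ndarray) -> np.ndarray:
    """Score amplitudes below 0.01 microsiemens as 0 (non-response)."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("SCR amplitudes must be nonnegative")
    return np.where(raw < NONRESPONSE_FLOOR_US, 0.0, raw)


def transform_range_correct(floored: np.ndarray) -> np.ndarray:
    """Square-root transform then divide by the subject's maximum.

    Operates on one subject's complete trial set.  A subject whose every
    response is zero maps to all zeros (guard against division by zero); this
    situation is also surfaced by ``process_scr_table`` as a flag.
    """
    x = np.sqrt(np.asarray(floored, dtype=float))
    m = x.max() if x.size else 0.0
    if m == 0.0:
        return np.zeros_like(x)
    return x / m


def learning_delta(table: pd.DataFrame, value_col: str = "transformed",
                   subject_id: str = "",
                   exclude_reinforced: bool = False) -> LearningIndex:
    """Mean corrected CS+ minus mean corrected CS- response.

    All trials enter the means by default (reinforced trials are not
    excluded); set ``exclude_reinforced`` to drop shock-contaminated CS+
    trials instead.
    """
    if not {"cs_type", value_col} <= set(table.columns):
        raise ValueError(f"table must contain 'cs_type' and '{value_col}'")
    t = table
    if exclude_reinforced and "reinforced" in t.columns:
        t = t[(t["cs_type"] != "+") | (t["reinforced"] == 0)]
    csp = t.loc[t["cs_type"] == "+", value_col]
    csm = t.loc[t["cs_type"] == "-", value_col]
    if csp.empty or csm.empty:
        raise ValueError("both CS+ and CS- trials are required")
    return LearningIndex(delta=float(csp.mean() - csm.mean()),
                         mean_csp=float(csp.mean()),
                         mean_csm=float(csm.mean()),
                         subject_id=subject_id)


def process_scr_table(table: pd.DataFrame, subject_id: str = "",
                      exclude_reinforced: bool = False
                      ) -> tuple[pd.DataFrame, LearningIndex]:
    """Run the full pipeline on a raw trial table.

    Returns a copy of the table with a ``transformed`` column in [0, 1] plus
    the subject's :class:`LearningIndex`.  If the subject's maximum response
    is zero (no scoreable responses at all) the transformed values are all
    zero and the index carries ``delta = 0``.
    """
    out = table.copy()
    floored = floor_nonresponses(out["amplitude_uS"].to_numpy())
    out["transformed"] = transform_range_correct(floored)
    idx = learning_delta(out, subject_id=subject_id,
                         exclude_reinforced=exclude_reinforced)
    return out, idx
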