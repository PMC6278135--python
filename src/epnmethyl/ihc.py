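"""H3K27me3 immunohistochemistry rule.

A tumor shows *intact* H3K27me3 expression when strictly more than 80% of
tumor cells are labeled, *reduced* expression at 0–80% (the boundary belongs
to reduced), and is *not evaluable* when endothelial cells — the internal
positive control — fail to stain. Intact expression predicts PFB, reduced
predicts PFA. Staining intensity is not part of the rule.
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError

INTACT, REDUCED, NOT_EVALUABLE = "intact", "reduced", "not_evaluable"
_CATEGORY_TO_SUBGROUP = {INTACT: "PFB", REDUCED: "PFA",
                         NOT_EVALUABLE: NOT_EVALUABLE}


def categorize(percent_labeled: float, endothelial_control_intact: bool = True,
               cutoff: float = 80.0) -> str:
    if not 0.0 <= percent_labeled <= 100.0:
        raise ValidationError(
            f"percent_labeled must be in [0, 100], got {percent_labeled!r}")
    if not endothelial_control_intact:
        return NOT_EVALUABLE
    return INTACT if percent_labeled > cutoff else REDUCED


def categorize_frame(records: pd.DataFrame, cutoff: float = 80.0) -> pd.DataFrame:
    """Add a ``category`` column to an IHC frame (sample_id, percent_labeled,
    control_ok)."""
    out = records.copy()
    control = out["control_ok"] if "control_ok" in out.columns else pd.Series(
        True, index=out.index)
    out["category"] = [
        categorize(p, bool(c), cutoff=cutoff)
        for p, c in zip(out["percent_labeled"], control)
    ]
    return out


def ihc_predict_subgroup(categories: pd.Series) -> pd.Series:
    """intact -> PFB, reduced -> PFA; not_evaluable propagates."""
    bad = set(categories) - set(_CATEGORY_TO_SUBGROUP)
    if bad:
        raise ValidationError(f"unknown IHC categories: {sorted(bad)}")
    return categories.map(_CATEGORY_TO_SUBGROUP).rename("prediction")
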