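"""Compute the headline screening statistics from a source-data directory.

Expected layout (plain CSV):
  activity.csv    well-level assay readings (see assay.ASSAY_COLUMNS)
  expression.csv  enzyme_id, yield_ug, concentration_mg_ml
  tm.csv          enzyme_id, tm  (tm empty/NaN when no transition was seen)

These are the per-candidate tables a screening campaign publishes as
supplementary source data; all statistics are recomputed from the well-level
rules (activity call, purification threshold, round prefix, co-tested
exclusion), never copied from a summary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .assay import (
    PURIFIED_MIN_CONC,
    condition_contingency,
    hit_rate,
    per_condition_table,
)
from .groups import split_groups


def load_source_data(directory: str | Path) -> dict[str, pd.DataFrame]:
    d = Path(directory)
    required = {"activity": "activity.csv", "expression": "expression.csv", "tm": "tm.csv"}
    out = {}
    for key, fname in required.items():
        path = d / fname
        if not path.exists():
            raise FileNotFoundError(f"source data file missing: {path}")
        out[key] = pd.read_csv(path)
    return out


def compute_targets(directory: str | Path) -> dict[str, dict]:
    """Screening statistics keyed by acceptance-target id."""
    data = load_source_data(directory)
    activity, expression, tm = data["activity"], data["expression"], data["tm"]
    per_cond = per_condition_table(activity)
    n_assayed = per_cond["enzyme_id"].nunique()

    out: dict[str, dict] = {}
    n_active = per_cond.loc[per_cond["active"], "enzyme_id"].nunique()
    out["t1"] = {"value": int(n_active), "n": int(n_assayed)}

    purified = expression["concentration_mg_ml"] >= PURIFIED_MIN_CONC
    out["t2"] = {"value": int(purified.sum()), "n": int(len(expression))}

    has_tm = tm["tm"].notna()
    out["t3"] = {"value": int(has_tm.sum()), "n": int(len(tm))}

    mean_yield = expression.loc[purified, "yield_ug"].mean()
    out["t4"] = {"value": float(round(mean_yield)), "n": int(purified.sum())}

    only_cry, both_sub, only_film = condition_contingency(
        per_cond, "substrate", "cryPow", "aFilm"
    )
    out["t6"] = {"value": int(only_cry), "n": int(only_cry + both_sub + only_film)}

    only_40, both_t, only_60 = condition_contingency(per_cond, "temperature", 40.0, 60.0)
    out["t7"] = {"value": int(only_40), "n": int(only_40 + both_t + only_60)}

    split = split_groups(per_cond, low_ph=4.5)
    out["t8"] = {
        "value": int(len(split.acid_group)),
        "n": int(len(split.acid_group) + len(split.neutral_group)),
    }

    esm = per_cond[per_cond["round"] == "ESM"]
    hr_any = hit_rate(esm)
    if hr_any is not None:
        out["t9"] = {"value": float(round(100.0 * hr_any)), "n": int(esm["enzyme_id"].nunique())}
    cond = {"substrate": "cryPow", "pH": 5.5, "temperature": 40.0}
    hr_fixed = hit_rate(esm, condition=cond)
    if hr_fixed is not None:
        tested = esm.copy()
        for key, val in cond.items():
            tested = tested[tested[key] == val]
        out["t10"] = {
            "value": float(round(100.0 * hr_fixed)),
            "n": int(tested["enzyme_id"].nunique()),
        }

    esm_tm = tm[tm["enzyme_id"].astype(str).str.startswith("ESM")]
    vals = esm_tm["tm"].dropna()
    if len(vals):
        out["t11"] = {"value": float(np.round(vals.mean(), 1)), "n": int(len(vals))}
    return out
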