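"""Plate-assay processing: product quantification, activity calls, enzyme
summaries, Tm extraction, contingency tables and hit rates."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

ASSAY_COLUMNS = [
    "enzyme_id",
    "round",
    "substrate",
    "pH",
    "temperature",
    "replicate",
    "A260",
    "A280",
    "blank_A260",
]
CONDITION_KEYS = ["substrate", "pH", "temperature"]

#: activity call: A260 at least this much above the matched blank
ACTIVITY_DELTA = 0.05
#: enzyme loading per well, mg (5 ug)
ENZYME_MG = 0.005
#: purification success threshold, mg/mL
PURIFIED_MIN_CONC = 0.1


def validate_assay_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assay table missing columns {missing}")
    if (df["A260"] < 0).any() or (df["blank_A260"] < 0).any():
        raise ValueError("absorbances must be nonnegative")
    dup = df.duplicated(subset=["enzyme_id", *CONDITION_KEYS, "replicate"])
    if dup.any():
        raise ValueError("duplicate (enzyme, condition, replicate) rows")
    return df


def quantify_product(
    A260: float,
    blank_A260: float,
    epsilon: float = 17.0,
    path_length: float = 1.0,
    reaction_volume: float = 0.5,
    dilution: float = 1.0,
) -> float:
    """Aromatic product in umol from blank-corrected absorbance.

    epsilon in mM^-1 cm^-1, path_length in cm, reaction_volume in mL.
    """
    if epsilon <= 0 or path_length <= 0 or reaction_volume <= 0:
        raise ValueError("epsilon, path_length and reaction_volume must be positive")
    dA = max(0.0, A260 - blank_A260)
    return dA * dilution / (epsilon * path_length) * reaction_volume


def call_activity(A260: float, blank_A260: float, delta: float = ACTIVITY_DELTA) -> bool:
    """Per-condition activity call: A260 >= blank + delta (inclusive boundary).

    A tiny tolerance keeps the inclusive boundary robust to float round-off.
    """
    return bool(A260 - blank_A260 >= delta - 1e-12)


def specific_activity(umol: float, enzyme_mg: float = ENZYME_MG) -> float:
    """umol product per mg enzyme at the standard 5 ug loading."""
    if enzyme_mg <= 0:
        raise ValueError("enzyme mass must be positive")
    return umol / enzyme_mg


def per_condition_table(
    assay: pd.DataFrame,
    replicate_rule: str = "mean",
    delta: float = ACTIVITY_DELTA,
    epsilon: float = 17.0,
    path_length: float = 1.0,
    reaction_volume: float = 0.5,
    dilution: float = 1.0,
    enzyme_mg: float = ENZYME_MG,
) -> pd.DataFrame:
    """Collapse replicates and derive per-(enzyme, condition) activity.

    replicate_rule "mean" (default) averages duplicate A260 readings before the
    call; "either" calls active if any single replicate passes.
    """
    validate_assay_table(assay)
    grouped = assay.groupby(["enzyme_id", "round", *CONDITION_KEYS], sort=True)
    rows = []
    for (eid, rnd, sub, ph, temp), g in grouped:
        mean_a = g["A260"].mean()
        blank = g["blank_A260"].mean()
        if replicate_rule == "mean":
            active = call_activity(mean_a, blank, delta)
        elif replicate_rule == "either":
            active = bool(
                any(call_activity(a, b, delta) for a, b in zip(g["A260"], g["blank_A260"]))
            )
        else:
            raise ValueError(f"unknown replicate rule {replicate_rule!r}")
        umol = quantify_product(mean_a, blank, epsilon, path_length, reaction_volume, dilution)
        rows.append(
            {
                "enzyme_id": eid,
                "round": rnd,
                "substrate": sub,
                "pH": ph,
                "temperature": temp,
                "n_replicates": len(g),
                "A260": mean_a,
                "blank_A260": blank,
                "active": active,
                "umol_product": umol,
                "specific_activity": specific_activity(umol, enzyme_mg),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MeltCurve:
    """A DSF melt curve; temperatures must be strictly increasing."""

    enzyme_id: str
    temperature: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, float)
        self.fluorescence = np.asarray(self.fluorescence, float)
        if self.temperature.size != self.fluorescence.size:
            raise ValueError("temperature/fluorescence length mismatch")
        if not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperatures must be strictly increasing")


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    yp = np.pad(y, pad, mode="edge")
    return np.convolve(yp, kernel, mode="valid")[: y.size]


def extract_tm(
    curve: MeltCurve,
    smooth_window: int = 7,
    prominence_fraction: float = 0.25,
    min_height_fraction: float = 0.5,
) -> float | None:
    """Melting temperature from a melt curve.

    Smooths the curve and its derivative with a moving window, finds dF/dT
    maxima above a prominence threshold (fraction of the derivative range) and
    at least min_height_fraction of the tallest maximum, and returns the
    highest-temperature qualifying transition. Returns None when no transition
    is found (e.g. a flat curve).
    """
    t, f = curve.temperature, curve.fluorescence
    if t.size < 10 or t[-1] - t[0] < 10.0:
        raise ValueError("melt curve must have >=10 points spanning >=10 degrees")
    f = _moving_average(f, smooth_window)
    dfdt = _moving_average(np.gradient(f, t), smooth_window)
    rng = dfdt.max() - dfdt.min()
    if rng <= 0:
        return None
    # noise floor: most of a melt curve is flat, so the derivative MAD tracks noise
    med = np.median(dfdt)
    mad = 1.4826 * np.median(np.abs(dfdt - med))
    floor = med + 6.0 * mad
    peaks, _props = find_peaks(dfdt, prominence=prominence_fraction * rng)
    peaks = [p for p in peaks if dfdt[p] > 0 and dfdt[p] > floor]
    if not peaks:
        return None
    tallest = max(dfdt[p] for p in peaks)
    peaks = [p for p in peaks if dfdt[p] >= min_height_fraction * tallest]
    return float(t[max(peaks, key=lambda p: t[p])])


def extract_tm_table(melt: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Tm per enzyme from a long-form melt-curve table
    (enzyme_id, temperature, fluorescence)."""
    rows = []
    for eid, g in melt.groupby("enzyme_id", sort=True):
        g = g.sort_values("temperature")
        tm = extract_tm(MeltCurve(eid, g["temperature"].to_numpy(), g["fluorescence"].to_numpy()), **kwargs)
        rows.append({"enzyme_id": eid, "tm": tm})
    return pd.DataFrame(rows)


def summarize_enzymes(
    per_condition: pd.DataFrame,
    tm_table: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-enzyme summary: tested conditions, overall activity, pH optimum,
    Tm, purification status.

    pH optimum is the pH of the maximum specific activity over all tested
    conditions, ties broken toward lower pH; NaN for inactive enzymes.
    """
    rows = []
    for eid, g in per_condition.groupby("enzyme_id", sort=True):
        active = bool(g["active"].any())
        ph_opt = np.nan
        if active:
            best = g.loc[g["specific_activity"].idxmax(), "specific_activity"]
            ph_opt = float(g.loc[np.isclose(g["specific_activity"], best), "pH"].min())
        rows.append(
            {
                "enzyme_id": eid,
                "round": g["round"].iloc[0],
                "n_conditions": len(g),
                "active": active,
                "max_specific_activity": float(g["specific_activity"].max()),
                "pH_optimum": ph_opt,
            }
        )
    out = pd.DataFrame(rows)
    if tm_table is not None:
        out = out.merge(tm_table, on="enzyme_id", how="left")
    if expression is not None:
        exp = expression.copy()
        exp["purified"] = exp["concentration_mg_ml"] >= PURIFIED_MIN_CONC
        out = out.merge(
            exp[["enzyme_id", "yield_ug", "concentration_mg_ml", "purified"]],
            on="enzyme_id",
            how="left",
        )
    return out


def condition_contingency(
    per_condition: pd.DataFrame, axis: str, value1, value2
) -> tuple[int, int, int]:
    """(only value1, both, only value2) active counts over enzymes tested at
    both axis values; enzymes not tested at both are excluded. Activity at a
    value is marginalized over the other condition axes."""
    if axis not in CONDITION_KEYS:
        raise ValueError(f"axis must be one of {CONDITION_KEYS}")
    only1 = both = only2 = 0
    for _eid, g in per_condition.groupby("enzyme_id", sort=True):
        tested1 = (g[axis] == value1).any()
        tested2 = (g[axis] == value2).any()
        if not (tested1 and tested2):
            continue
        a1 = bool(g.loc[g[axis] == value1, "active"].any())
        a2 = bool(g.loc[g[axis] == value2, "active"].any())
        if a1 and a2:
            both += 1
        elif a1:
            only1 += 1
        elif a2:
            only2 += 1
    return only1, both, only2


def hit_rate(
    per_condition: pd.DataFrame,
    round_label: str | None = None,
    condition: dict | None = None,
) -> float | None:
    """Fraction of tested enzymes with a positive activity call.

    condition=None ("any condition" mode): each enzyme's own tested set is the
    denominator. Otherwise only enzymes tested at the exact condition count,
    and activity is evaluated there. Returns None when nothing was tested.
    """
    df = per_condition
    if round_label is not None:
        df = df[df["round"] == round_label]
    if condition:
        mask = np.ones(len(df), dtype=bool)
        for key, val in condition.items():
            mask &= df[key] == val
        df = df[mask]
        tested = df["enzyme_id"].nunique()
        if tested == 0:
            return None
        actives = df.loc[df["active"], "enzyme_id"].nunique()
        return actives / tested
    tested = df["enzyme_id"].nunique()
    if tested == 0:
        return None
    actives = df.loc[df["active"], "enzyme_id"].nunique()
    return actives / tested
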