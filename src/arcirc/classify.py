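"""Threshold-based classification of ADAR-regulated circRNAs.

A junction is called for a regulator when the read-sum gates hold
(EV+OE >= 10 and Scr+KD >= 10) and the reciprocal fold-change criteria are
met: promoted means OE/EV >= 2 together with KD/Scr <= 0.5; repressed means
OE/EV <= 0.5 together with KD/Scr >= 2 (closed thresholds).  Dependence on
editing uses the deaminase-dead (DeAD) overexpression: a call is
editing-dependent when DeAD/EV shows no or minor change (0.8 < fc < 1.25)
or moves opposite to the wildtype direction, editing-independent when it
moves the same way by at least 1.25-fold, and undetermined when EV+DeAD
reads fall under the gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circquant import CircCountMatrix

REGULATORS = ("ADAR1", "ADAR2")


@dataclass(frozen=True)
class ClassifyThresholds:
    fc_up: float = 2.0
    fc_down: float = 0.5
    read_gate: int = 10
    dead_low: float = 0.8
    dead_high: float = 1.25
    gate_mode: str = "sum"  # "sum" (default reading) or "each"


def fold_change(count_num: float, count_den: float, *, gated: bool = False) -> float:
    """Ratio of counts; 0 denominator with positive numerator gives +inf.

    0/0 is undefined: inside a gated context it is returned as NaN (the gate
    upstream guarantees it is never interpreted), otherwise it is an error.
    """
    if count_num < 0 or count_den < 0:
        raise ValueError("counts must be non-negative")
    if count_den == 0:
        if count_num == 0:
            if gated:
                return float("nan")
            raise ValueError("0/0 fold change is undefined outside a gated context")
        return float("inf")
    return count_num / count_den


def call_arcircs(matrix: CircCountMatrix, regulator: str,
                 thresholds: ClassifyThresholds | None = None,
                 depth_factors: dict[str, float] | None = None) -> pd.DataFrame:
    """Call promoted/repressed circRNAs for one regulator.

    Returns one row per junction with the gates, fold changes and the call
    (direction in {promoted, repressed} or None when uncalled).
    """
    th = thresholds or ClassifyThresholds()
    counts = matrix.counts
    if depth_factors:
        counts = counts.div(pd.Series(depth_factors).reindex(counts.columns, fill_value=1.0),
                            axis=1)
    totals = {}
    for cond in ("EV", "OE", "Scr", "KD"):
        samples = matrix.samples_for(regulator, cond)
        if not samples:
            raise ValueError(f"design lacks condition {cond} for {regulator}")
        totals[cond] = counts[samples].sum(axis=1)

    if th.gate_mode == "sum":
        gate_oe = (totals["EV"] + totals["OE"]) >= th.read_gate
        gate_kd = (totals["Scr"] + totals["KD"]) >= th.read_gate
    elif th.gate_mode == "each":
        gate_oe = (totals["EV"] >= th.read_gate) & (totals["OE"] >= th.read_gate)
        gate_kd = (totals["Scr"] >= th.read_gate) & (totals["KD"] >= th.read_gate)
    else:
        raise ValueError(f"unknown gate_mode {th.gate_mode!r}")

    fc_oe = np.array([fold_change(o, e, gated=True)
                      for o, e in zip(totals["OE"], totals["EV"])])
    fc_kd = np.array([fold_change(k, s, gated=True)
                      for k, s in zip(totals["KD"], totals["Scr"])])
    gated = (gate_oe & gate_kd).to_numpy()

    promoted = gated & (fc_oe >= th.fc_up) & (fc_kd <= th.fc_down)
    repressed = gated & (fc_oe <= th.fc_down) & (fc_kd >= th.fc_up)
    direction = np.where(promoted, "promoted",
                         np.where(repressed, "repressed", None))

    out = matrix.junctions.copy()
    out["regulator"] = regulator
    out["ev"] = totals["EV"].to_numpy()
    out["oe"] = totals["OE"].to_numpy()
    out["scr"] = totals["Scr"].to_numpy()
    out["kd"] = totals["KD"].to_numpy()
    out["gate_passed"] = gated
    out["fc_oe"] = fc_oe
    out["fc_kd"] = fc_kd
    out["direction"] = direction
    out["called"] = pd.notna(out["direction"])
    return out


def classify_dependence(calls: pd.DataFrame, matrix: CircCountMatrix,
                        regulator: str,
                        thresholds: ClassifyThresholds | None = None) -> pd.DataFrame:
    """Fill the dependence column of an ARcirc call table from DeAD counts."""
    th = thresholds or ClassifyThresholds()
    dead_samples = matrix.samples_for(regulator, "DeAD")
    out = calls.copy()
    if not dead_samples:
        out["fc_dead"] = float("nan")
        out["dependence"] = np.where(out["called"], "undetermined", None)
        return out
    dead = matrix.counts[dead_samples].sum(axis=1)
    ev = matrix.counts[matrix.samples_for(regulator, "EV")].sum(axis=1)

    fc_dead, dependence = [], []
    for r in out.itertuples():
        if not r.called:
            fc_dead.append(float("nan"))
            dependence.append(None)
            continue
        e, d = ev.at[r.key], dead.at[r.key]
        if e + d < th.read_gate:
            fc_dead.append(float("nan"))
            dependence.append("undetermined")
            continue
        fc = fold_change(d, e, gated=True)
        fc_dead.append(fc)
        if th.dead_low < fc < th.dead_high:
            dependence.append("dependent")
        elif _same_log_sign(fc, r.fc_oe):
            # shifted >= 1.25x (or <= 0.8x) in the wildtype direction
            dependence.append("independent")
        else:
            dependence.append("dependent")  # opposite to the wildtype pattern
    out["fc_dead"] = fc_dead
    out["dependence"] = dependence
    return out


def _log_sign(fc: float) -> int | None:
    """Sign of log fold change: +1 above 1, -1 below 1, 0 at exactly 1."""
    if math.isnan(fc):
        return None
    return 1 if fc > 1 else (-1 if fc < 1 else 0)


def _same_log_sign(fc_a: float, fc_b: float) -> bool:
    sa, sb = _log_sign(fc_a), _log_sign(fc_b)
    return sa is not None and sa == sb and sa != 0


def concordance(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> dict:
    """Direction agreement between two regulators' call tables.

    Reports the common called junctions, same/opposite direction counts and
    per-regulator promoted/repressed percentages.
    """
    a = calls_a[calls_a["called"]].set_index("key")
    b = calls_b[calls_b["called"]].set_index("key")
    common = a.index.intersection(b.index)
    same = int((a.loc[common, "direction"] == b.loc[common, "direction"]).sum())

    def pct(calls):
        n = len(calls)
        if n == 0:
            return {"promoted_pct": float("nan"), "repressed_pct": float("nan")}
        return {
            "promoted_pct": 100.0 * (calls["direction"] == "promoted").sum() / n,
            "repressed_pct": 100.0 * (calls["direction"] == "repressed").sum() / n,
        }

    return {
        "n_common": int(len(common)),
        "n_same_direction": same,
        "n_opposite_direction": int(len(common)) - same,
        "regulator_a": pct(a),
        "regulator_b": pct(b),
        "common_keys": sorted(common),
    }
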