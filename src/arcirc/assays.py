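"""Wet-lab assay arithmetic: qPCR fold change, RIP %input, TA-clone editing
frequency, native-gel migration, xenograft tumor volume and patient
stratification.

Relative quantification uses the standard 2^-ddCt scheme with dCt =
Ct_target - Ct_reference and ddCt taken against the mean control dCt.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats


def ddct_fold_change(records: pd.DataFrame) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold change against the mean control dCt.

    ``records`` needs columns sample / group / ct_target / ct_ref with at
    least one control-group row.
    """
    ctl = records[records["group"] == "control"]
    if ctl.empty:
        raise ValueError("no control samples: ddCt undefined")
    dct = records["ct_target"] - records["ct_ref"]
    ref = (ctl["ct_target"] - ctl["ct_ref"]).mean()
    out = records.copy()
    out["dct"] = dct
    out["ddct"] = dct - ref
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out


def rip_percent_input(ct_rip: float, ct_input: float, dilution_factor: float) -> float:
    """%input = 2^-dCt x 100 with dCt = Ct_RIP - (Ct_input - dilution factor).

    The dilution factor is the log2 correction for the input fraction used
    (e.g. log2(100) for a 1% input) and must be supplied by the caller.
    """
    if not (math.isfinite(ct_rip) and math.isfinite(ct_input)):
        raise ValueError("Ct values must be finite")
    dct = ct_rip - (ct_input - dilution_factor)
    return 100.0 * 2.0 ** (-dct)


def clone_editing_frequency(n_a: int, n_g: int,
                            ci_level: float = 0.95) -> dict[str, float]:
    """Edited-clone frequency G/(A+G) with an exact binomial CI.

    This ratio is the maximum-likelihood estimate of the per-transcript
    editing probability under Bernoulli sampling of clones.
    """
    n = n_a + n_g
    if n < 1:
        raise ValueError("need at least one clone")
    freq = n_g / n
    alpha = 1 - ci_level
    lo = 0.0 if n_g == 0 else stats.beta.ppf(alpha / 2, n_g, n_a + 1)
    hi = 1.0 if n_a == 0 else stats.beta.ppf(1 - alpha / 2, n_g + 1, n_a)
    return {"frequency": freq, "ci_low": float(lo), "ci_high": float(hi),
            "n_clones": n}


def relative_migration(distances, d_slowest: float, d_fastest: float) -> np.ndarray:
    """Map gel migration distances linearly onto [0, 1] (slowest 0, fastest 1)."""
    if d_fastest == d_slowest:
        raise ValueError("degenerate migration range")
    return (np.asarray(distances, dtype=float) - d_slowest) / (d_fastest - d_slowest)


def tumor_volume(length: float, width: float) -> float:
    """Xenograft volume 0.5 x length x width^2 (length >= width > 0)."""
    if not 0 < width <= length:
        raise ValueError("need length >= width > 0")
    return 0.5 * length * width**2


def stratify_patients(pairs: pd.DataFrame, fold_threshold: float = 2.0) -> dict:
    """Stratify patients by tumor-vs-normal ADAR1 change and tally concordant
    circRNA expression changes.

    ADAR1-up means tumor > NT (a ratio of exactly 1 is assigned ADAR1-down
    and flagged ambiguous).  Within ADAR1-up the count is of patients with a
    circRNA tumor/NT ratio >= fold_threshold; within ADAR1-down, <= 1/fold.
    Patients with a missing pair member are excluded with a warning.
    """
    import logging

    log = logging.getLogger(__name__)
    cols = ["adar1_tumor", "adar1_nt", "circ_tumor", "circ_nt"]
    ok = pairs[cols].notna().all(axis=1) & (pairs[cols] > 0).all(axis=1)
    if (~ok).any():
        log.warning("excluding %d patients with incomplete pairs", int((~ok).sum()))
    df = pairs[ok].copy()
    df["adar1_ratio"] = df["adar1_tumor"] / df["adar1_nt"]
    df["circ_ratio"] = df["circ_tumor"] / df["circ_nt"]
    df["group"] = np.where(df["adar1_ratio"] > 1, "ADAR1-up", "ADAR1-down")
    df["ambiguous_tie"] = df["adar1_ratio"] == 1

    up = df[df["group"] == "ADAR1-up"]
    down = df[df["group"] == "ADAR1-down"]
    n_up_conc = int((up["circ_ratio"] >= fold_threshold).sum())
    n_down_conc = int((down["circ_ratio"] <= 1 / fold_threshold).sum())
    return {
        "patients": df,
        "n_up": len(up), "n_down": len(down),
        "n_up_concordant": n_up_conc, "n_down_concordant": n_down_conc,
        "frac_up_concordant": n_up_conc / len(up) if len(up) else float("nan"),
        "frac_down_concordant": n_down_conc / len(down) if len(down) else float("nan"),
    }
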