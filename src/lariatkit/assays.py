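"""Bespoke statistics for the co-IP spectral-count screen and the
ADAR-fusion RNA-timestamp editing assay."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .analytics import pearson_chi2_2x2

CTRL_COLS = ["ctrl1", "ctrl2", "ctrl3"]
IP_COLS = ["ip1", "ip2", "ip3"]

ZERO_PSEUDOCOUNT = 0.1  # substituted for zero spectral-count means


def coip_hits(
    table: pd.DataFrame,
    ctrl_cols: list[str] | None = None,
    ip_cols: list[str] | None = None,
    ctrl_max: float = 3.0,
    ip_min: float = 10.0,
) -> pd.DataFrame:
    """Spectral-count hit filter over 3 control and 3 IP replicates.

    A protein is a hit when mean(control) < 3 and mean(IP) > 10 (strict
    inequalities).  The fold change substitutes a 0.1 pseudocount for
    zero-count means; p-values come from a two-sided t-test on the two
    triplets.
    """
    ctrl_cols = ctrl_cols or CTRL_COLS
    ip_cols = ip_cols or IP_COLS
    missing = [c for c in ctrl_cols + ip_cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing replicate columns: {missing}")
    if table[ctrl_cols + ip_cols].isna().any().any():
        raise ValueError("missing replicate values in the spectral-count table")
    ctrl = table[ctrl_cols].to_numpy(dtype=float)
    ip = table[ip_cols].to_numpy(dtype=float)
    ctrl_mean = ctrl.mean(axis=1)
    ip_mean = ip.mean(axis=1)
    fc = np.where(ip_mean == 0, ZERO_PSEUDOCOUNT, ip_mean) / np.where(
        ctrl_mean == 0, ZERO_PSEUDOCOUNT, ctrl_mean
    )
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # identical triplets give a degenerate t statistic; p is set to 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(ip, ctrl, axis=1)
    out = table.copy()
    out["ctrl_mean"] = ctrl_mean
    out["ip_mean"] = ip_mean
    out["fold_change"] = fc
    out["p"] = np.where(np.isnan(p), 1.0, p)
    out["hit"] = (ctrl_mean < ctrl_max) & (ip_mean > ip_min)
    return out


def editing_rate(edited: int, total: int) -> float:
    """Fraction of edited adenosines."""
    if total <= 0:
        raise ValueError("total A bases must be > 0")
    if edited > total:
        raise ValueError("edited count exceeds total")
    return edited / total


def corrected_rate(rate: float, nt_rate: float, mode: str = "subtract") -> float:
    """Editing rate corrected by the non-transfected background.

    Default correction subtracts the matched non-transfected rate and floors
    at zero; ``mode='ratio'`` divides instead (labelled alternative)."""
    if mode == "subtract":
        return max(0.0, rate - nt_rate)
    if mode == "ratio":
        if nt_rate <= 0:
            raise ValueError("ratio correction needs a positive background rate")
        return rate / nt_rate
    raise ValueError("mode must be 'subtract' or 'ratio'")


def editing_contrast(
    a: tuple[int, int], b: tuple[int, int], correction: bool = False
) -> dict[str, float]:
    """Pearson chi-square on the 2x2 edited/unedited x condition table of
    raw (uncorrected) base counts."""
    ea, ta = a
    eb, tb = b
    if ta <= 0 or tb <= 0:
        raise ValueError("both conditions need counted bases")
    stat, p = pearson_chi2_2x2(
        np.array([[ea, ta - ea], [eb, tb - eb]]), correction=correction
    )
    return {"statistic": stat, "p": p, "rate_a": ea / ta, "rate_b": eb / tb}
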