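"""Damage scoring, stress-score regression, and risk classification.

The in vitro study scores each specimen by the failures it develops: large
annulus fibrosus failures (AFF) and endplate-junction failures (EPJF) count
1.0, small ones 0.5,

    S = LargeEPJF + 0.5 SmallEPJF + LargeAFF + 0.5 SmallAFF.

Ordinary least squares then relates each regional stress predictor to the
per-specimen scores; predictors with p < 0.05 are flagged as significant.
Finally, stress levels are classified against the empirically identified
thresholds (axial 10/6 MPa, circumferential 9/6 MPa high/low risk; 3.5 MPa
at the annulus-endplate interface).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FailureCounts",
    "RegressionResult",
    "RiskThresholds",
    "damage_score",
    "regress_stress_vs_score",
    "classify_risk",
    "load_failure_counts",
    "specimen_scores",
]

WEIGHT_LARGE = 1.0
WEIGHT_SMALL = 0.5


@dataclass(frozen=True)
class FailureCounts:
    """Failure counts for a specimen (0/1 indicators) or a group (counts)."""

    scenario: int
    large_aff: float = 0
    small_aff: float = 0
    large_epjf: float = 0
    small_epjf: float = 0
    specimen: Optional[int] = None

    def __post_init__(self) -> None:
        for nm in ("large_aff", "small_aff", "large_epjf", "small_epjf"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")


def damage_score(counts: FailureCounts) -> float:
    """Weighted damage score: large failures count 1.0, small ones 0.5."""
    return (WEIGHT_LARGE * (counts.large_aff + counts.large_epjf)
            + WEIGHT_SMALL * (counts.small_aff + counts.small_epjf))


def load_failure_counts() -> pd.DataFrame:
    """Experimental group failure counts shipped with the package
    (five loading scenarios, six specimens each)."""
    with resources.files("discfem.data").joinpath(
            "failure_counts.csv").open() as fh:
        return pd.read_csv(fh)


def specimen_scores(group_counts: pd.DataFrame,
                    n_per_group: int = 6) -> pd.DataFrame:
    """Expand group failure counts into deterministic per-specimen rows.

    Within a group the j-th specimen receives a large failure of a type if
    j < (count of large failures), then small failures fill the next
    specimens. The per-specimen scores sum to the group total by
    construction.
    """
    rows = []
    for _, g in group_counts.iterrows():
        for j in range(n_per_group):
            rec = {"scenario": int(g["scenario"]), "specimen": j}
            for kind in ("aff", "epjf"):
                nl, ns = int(g[f"large_{kind}"]), int(g[f"small_{kind}"])
                rec[f"large_{kind}"] = 1 if j < nl else 0
                rec[f"small_{kind}"] = 1 if nl <= j < nl + ns else 0
            rec["score"] = damage_score(FailureCounts(
                scenario=rec["scenario"], large_aff=rec["large_aff"],
                small_aff=rec["small_aff"], large_epjf=rec["large_epjf"],
                small_epjf=rec["small_epjf"], specimen=j))
            rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    """Per-predictor OLS slope, intercept, and two-sided p-value with a
    significance flag at alpha (optionally Benjamini-Hochberg adjusted)."""

    table: pd.DataFrame
    alpha: float = 0.05

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def regress_stress_vs_score(stresses: pd.DataFrame, scores: np.ndarray,
                            alpha: float = 0.05, joint: bool = False,
                            fdr: bool = False) -> RegressionResult:
    """OLS of damage score on regional stress predictors.

    ``stresses``: one row per specimen, one column per predictor. Default is
    one simple regression per predictor with a two-sided t-test on the slope
    (matching per-cell significance reporting); ``joint=True`` fits a single
    multiple regression instead; ``fdr=True`` applies Benjamini-Hochberg
    across predictors. Zero-variance predictors are flagged non-estimable.
    """
    y = np.asarray(scores, dtype=float)
    if len(stresses) != len(y):
        raise ValueError("predictor rows and scores differ in length")
    if len(y) < 3:
        raise ValueError("need at least 3 specimens")
    if np.std(y) <= 1e-12:
        # constant response: slopes are exactly zero and no predictor can be
        # significant; numerical residual noise must not drive the t-tests
        df = pd.DataFrame({"predictor": stresses.columns,
                           "slope": 0.0, "intercept": float(y.mean()),
                           "pvalue": math.nan, "estimable": False,
                           "significant": False})
        return RegressionResult(table=df, alpha=alpha)
    rows = []
    if joint:
        X = stresses.to_numpy(dtype=float)
        keep = X.std(axis=0) > 1e-12
        Xk = sm.add_constant(X[:, keep])
        fit = sm.OLS(y, Xk).fit()
        ki = 1
        for col, used in zip(stresses.columns, keep):
            if used:
                rows.append((col, fit.params[ki], fit.params[0],
                             fit.pvalues[ki], True))
                ki += 1
            else:
                rows.append((col, 0.0, math.nan, math.nan, False))
    else:
        for col in stresses.columns:
            x = stresses[col].to_numpy(dtype=float)
            if np.std(x) <= 1e-12 or np.any(~np.isfinite(x)):
                rows.append((col, 0.0, math.nan, math.nan, False))
                continue
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            rows.append((col, fit.params[1], fit.params[0],
                         fit.pvalues[1], True))
    df = pd.DataFrame(rows, columns=["predictor", "slope", "intercept",
                                     "pvalue", "estimable"])
    pv = df["pvalue"].to_numpy()
    flag = np.zeros(len(df), dtype=bool)
    ok = np.isfinite(pv)
    if fdr and ok.any():
        flag[ok] = multipletests(pv[ok], alpha=alpha, method="fdr_bh")[0]
    else:
        flag[ok] = pv[ok] < alpha
    df["significant"] = flag & df["estimable"]
    return RegressionResult(table=df, alpha=alpha)


@dataclass(frozen=True)
class RiskThresholds:
    """Empirical failure-risk thresholds (MPa)."""

    axial_high: float = 10.0
    axial_low: float = 6.0
    circumferential_high: float = 9.0
    circumferential_low: float = 6.0
    interface_high: float = 3.5

    def __post_init__(self) -> None:
        for hi, lo in ((self.axial_high, self.axial_low),
                       (self.circumferential_high, self.circumferential_low)):
            if not hi > lo > 0:
                raise ValueError("thresholds must satisfy high > low > 0")
        if self.interface_high <= 0:
            raise ValueError("interface threshold must be positive")


def classify_risk(values: Dict[str, float],
                  thresholds: Optional[RiskThresholds] = None,
                  ) -> Dict[str, str]:
    """Classify stress levels as high / moderate / low failure risk.

    ``values`` maps entries to MPa; keys containing "axial",
    "circumferential" or "interface" select the threshold pair. Interface
    entries use the single high threshold (at or above -> high, else low).
    """
    th = thresholds or RiskThresholds()
    out = {}
    for key, v in values.items():
        k = key.lower()
        if "interface" in k or k.endswith("ep"):
            out[key] = "high" if v >= th.interface_high else "low"
            continue
        if "circum" in k:
            hi, lo = th.circumferential_high, th.circumferential_low
        else:
            hi, lo = th.axial_high, th.axial_low
        if v >= hi:
            out[key] = "high"
        elif v <= lo:
            out[key] = "low"
        else:
            out[key] = "moderate"
    return out
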