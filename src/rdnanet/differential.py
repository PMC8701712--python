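"""Position-wise differential occupancy between two strains.

At every template position a two-sample t-test compares the normalized
per-replicate occupancies of strain A and strain B and the position is
called ``up`` (higher in B), ``down`` or ``ns``.  Positions with zero
pooled variance carry no information for the test and are ``untestable``.
The default is the classic pooled-variance (Student) test on raw p-values
at alpha = 0.05; Welch's variant and Benjamini-Hochberg adjustment are
available for reuse beyond the original design.

A centred moving average (default 300 nt, truncated at the template edges)
summarises broad occupancy trends on top of the single-nucleotide track.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .occupancy import OccupancyProfile

__all__ = [
    "DifferentialTrack",
    "positionwise_test",
    "moving_average",
    "adjust_pvalues",
]

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "ns"
CALL_UNTESTABLE = "untestable"


@dataclass
class DifferentialTrack:
    """Per-position two-sample test results (A = reference, B = comparison).

    ``table`` columns: position, mean_a, mean_b, t_statistic, p_value,
    call.  ``up`` means occupancy is significantly higher in B than in A.
    """

    table: pd.DataFrame
    alpha: float
    n_a: int
    n_b: int
    strain_a: str = "A"
    strain_b: str = "B"
    adjust_method: str = "none"

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def positions_called(self, call: str) -> np.ndarray:
        return self.table.loc[self.table["call"] == call, "position"].to_numpy()

    def significant_fraction(self) -> float:
        """Fraction of testable positions called up or down."""
        testable = self.table["call"] != CALL_UNTESTABLE
        if not testable.any():
            return float("nan")
        sig = self.table["call"].isin([CALL_UP, CALL_DOWN])
        return float(sig.sum() / testable.sum())


def _make_calls(
    mean_a: np.ndarray, mean_b: np.ndarray, p: np.ndarray, alpha: float
) -> np.ndarray:
    calls = np.full(p.shape, CALL_NS, dtype=object)
    calls[~np.isfinite(p)] = CALL_UNTESTABLE
    sig = np.isfinite(p) & (p < alpha)
    calls[sig & (mean_b > mean_a)] = CALL_UP
    calls[sig & (mean_b < mean_a)] = CALL_DOWN
    return calls


def positionwise_test(
    reps_a: Sequence[OccupancyProfile],
    reps_b: Sequence[OccupancyProfile],
    alpha: float = 0.05,
    variant: str = "student",
    region: tuple[int, int] | None = None,
) -> DifferentialTrack:
    """Two-sided t-test at every position of the analysis region.

    ``variant`` is ``student`` (pooled variance, the default) or ``welch``.
    Replicate tracks must be normalized so that library depth cancels.
    """
    if len(reps_a) < 2 or len(reps_b) < 2:
        raise ValueError("need at least two replicates per group")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown test variant {variant!r}")
    for p in list(reps_a) + list(reps_b):
        if not p.normalized:
            raise ValueError("positionwise_test expects normalized profiles")
    length = len(reps_a[0])
    if any(len(p) != length for p in list(reps_a) + list(reps_b)):
        raise ValueError("profiles have mixed lengths")
    if region is None:
        region = (1, length)
    A = np.vstack([p.slice(region) for p in reps_a])
    B = np.vstack([p.slice(region) for p in reps_b])
    mean_a = A.mean(axis=0)
    mean_b = B.mean(axis=0)
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant positions trip scipy's precision warning; they are
        # marked untestable below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(A, B, axis=0, equal_var=(variant == "student"))
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    # Zero pooled variance leaves the statistic undefined even when the
    # group means differ; mark those positions untestable.
    zero_var = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    t[zero_var] = np.nan
    p[zero_var] = np.nan
    table = pd.DataFrame(
        {
            "position": np.arange(region[0], region[1] + 1),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t_statistic": t,
            "p_value": p,
            "call": _make_calls(mean_a, mean_b, p, alpha),
        }
    )
    return DifferentialTrack(
        table=table,
        alpha=alpha,
        n_a=len(reps_a),
        n_b=len(reps_b),
        strain_a=reps_a[0].strain or "A",
        strain_b=reps_b[0].strain or "B",
    )


def moving_average(profile: OccupancyProfile, window: int = 300) -> OccupancyProfile:
    """Centred moving average; edge windows are truncated, not padded.

    For even windows the extra position goes downstream of the centre.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return profile.copy_with(replicate=f"{profile.replicate}|ma1")
    v = profile.values
    n = v.size
    half_left = (window - 1) // 2
    half_right = window // 2
    csum = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_left, 0)
    hi = np.minimum(idx + half_right, n - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return profile.copy_with(values=out, replicate=f"{profile.replicate}|ma{window}")


def adjust_pvalues(track: DifferentialTrack, method: str = "none") -> DifferentialTrack:
    """Recompute calls after multiple-testing adjustment.

    ``none`` reproduces the raw-p procedure unchanged;
    ``benjamini_hochberg`` applies the BH step-up over testable positions.
    """
    if method == "none":
        return track
    if method != "benjamini_hochberg":
        raise ValueError(f"unknown adjustment method {method!r}")
    table = track.table.copy()
    p = table["p_value"].to_numpy(dtype=float)
    ok = np.isfinite(p)
    adjusted = np.full_like(p, np.nan)
    if ok.any():
        adjusted[ok] = multipletests(p[ok], method="fdr_bh")[1]
    table["p_value"] = adjusted
    table["call"] = _make_calls(
        table["mean_a"].to_numpy(),
        table["mean_b"].to_numpy(),
        adjusted,
        track.alpha,
    )
    return replace(track, table=table, adjust_method=method)
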