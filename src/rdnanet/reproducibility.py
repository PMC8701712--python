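"""Replicate agreement via Spearman rank correlation.

Occupancy tracks span several orders of magnitude, so rank correlation is
the natural reproducibility measure: it asks whether two replicates rank
positions the same way, regardless of scale, which also makes it
indifferent to whether tracks were normalized first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import RdnaAnnotation
from .occupancy import OccupancyProfile

__all__ = ["CorrelationMatrix", "spearman_matrix"]


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman coefficients between replicate tracks.

    ``rho`` is symmetric with a unit diagonal; a pair where either track is
    constant over the region has no defined ranking and is reported NaN.
    """

    labels: list[str]
    rho: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def min_offdiagonal(self) -> float:
        mask = ~np.eye(len(self.labels), dtype=bool)
        return float(np.nanmin(self.rho[mask]))


def spearman_matrix(
    profiles: Sequence[OccupancyProfile],
    region: tuple[int, int] | None = None,
    ann: RdnaAnnotation | None = None,
) -> CorrelationMatrix:
    """Pairwise Spearman rho over a region (default: the 35S body).

    Ties get average ranks.  Positions where both tracks are zero are kept;
    they contribute tied ranks rather than being masked out.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    if region is None:
        if ann is None:
            raise ValueError("provide a region or an annotation")
        region = (1, ann.feature("T1").start)
    mat = np.vstack([p.slice(region) for p in profiles])
    n = len(profiles)
    rho = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if np.ptp(mat[i]) == 0 or np.ptp(mat[j]) == 0:
                r = np.nan  # constant track: ranking undefined
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = stats.spearmanr(mat[i], mat[j]).statistic
            rho[i, j] = rho[j, i] = r
    labels = [p.label for p in profiles]
    return CorrelationMatrix(labels=labels, rho=rho)
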