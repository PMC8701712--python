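"""Terminator read-through and pause-cluster detection.

Under steady-state transcription with a locally constant elongation rate,
occupancy is proportional to polymerase flux, so the ratio of mean
occupancy downstream vs upstream of a terminator estimates the fraction of
polymerases reading through it (the read-through index); termination
efficiency is one minus that index.  The flanking windows are separated
from the terminator by a small gap so the pause peak that precedes
termination does not inflate the upstream mean.

Pause/arrest clusters are called as positions whose occupancy stands out
from a robust local background (rolling median and MAD) by both a z-score
and a minimum fold change; nearby outlier positions are merged into one
cluster.  The fold floor keeps deep libraries from calling tiny relative
fluctuations that are nevertheless many MADs above background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import DOWNSTREAM_TSS, Feature, RdnaAnnotation
from .occupancy import OccupancyProfile

__all__ = [
    "TerminatorMetrics",
    "PauseCluster",
    "TerminationReport",
    "terminator_metrics",
    "detect_pause_clusters",
]

_MAD_SCALE = 1.4826  # MAD -> sigma for a normal distribution


@dataclass
class TerminatorMetrics:
    """Read-through at one terminator.

    ``readthrough_index`` is downstream_mean / upstream_mean (NaN when the
    upstream mean is zero, flagged ``undefined``); ``efficiency`` is
    1 - index clipped to [0, 1].
    """

    name: str
    upstream_mean: float
    downstream_mean: float
    readthrough_index: float
    efficiency: float
    undefined: bool
    upstream_window: tuple[int, int]
    downstream_window: tuple[int, int]


@dataclass
class PauseCluster:
    """A run of positions sharply above the local background."""

    start: int
    end: int
    peak_position: int
    peak_value: float
    extent: int
    enrichment_score: float
    distance_upstream_of_downstream_tss: int


@dataclass
class TerminationReport:
    terminators: list[TerminatorMetrics] = field(default_factory=list)
    pause_clusters: list[PauseCluster] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "terminator": [t.name for t in self.terminators],
                "upstream_mean": [t.upstream_mean for t in self.terminators],
                "downstream_mean": [t.downstream_mean for t in self.terminators],
                "readthrough_index": [t.readthrough_index for t in self.terminators],
                "efficiency": [t.efficiency for t in self.terminators],
                "undefined": [t.undefined for t in self.terminators],
            }
        )

    def clusters_to_bed(self, path, chrom: str = "rDNA") -> None:
        with open(path, "w") as fh:
            for c in self.pause_clusters:
                fh.write(
                    f"{chrom}\t{c.start - 1}\t{c.end}\tpause_{c.peak_position}\t"
                    f"{c.enrichment_score:.3f}\t+\n"
                )


def terminator_metrics(
    profile: OccupancyProfile,
    ann: RdnaAnnotation,
    terminator: Feature | str,
    up_window: int = 100,
    down_window: int = 100,
    gap: int = 10,
) -> TerminatorMetrics:
    """Estimate read-through of one terminator from flanking occupancy.

    Upstream window: [t.start - gap - up_window, t.start - gap - 1];
    downstream window: [t.end + gap + 1, t.end + gap + down_window].
    The index is scale-invariant, so raw and normalized tracks agree.
    """
    feat = ann.feature(terminator) if isinstance(terminator, str) else terminator
    up_region = (feat.start - gap - up_window, feat.start - gap - 1)
    down_region = (feat.end + gap + 1, feat.end + gap + down_window)
    if up_region[0] < 1 or down_region[1] > len(profile):
        raise ValueError(
            f"flanking windows of {feat.name} fall outside the template"
        )
    up_mean = float(profile.slice(up_region).mean())
    down_mean = float(profile.slice(down_region).mean())
    if up_mean == 0:
        return TerminatorMetrics(
            name=feat.name,
            upstream_mean=up_mean,
            downstream_mean=down_mean,
            readthrough_index=float("nan"),
            efficiency=float("nan"),
            undefined=True,
            upstream_window=up_region,
            downstream_window=down_region,
        )
    index = down_mean / up_mean
    return TerminatorMetrics(
        name=feat.name,
        upstream_mean=up_mean,
        downstream_mean=down_mean,
        readthrough_index=index,
        efficiency=float(np.clip(1.0 - index, 0.0, 1.0)),
        undefined=False,
        upstream_window=up_region,
        downstream_window=down_region,
    )


def _rolling_median_mad(
    values: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray]:
    s = pd.Series(values)
    med = s.rolling(window, center=True, min_periods=1).median().to_numpy()
    absdev = pd.Series(np.abs(values - med))
    mad = absdev.rolling(window, center=True, min_periods=1).median().to_numpy()
    return med, mad


def detect_pause_clusters(
    profile: OccupancyProfile,
    region: tuple[int, int] | str,
    ann: RdnaAnnotation | None = None,
    z_threshold: float = 4.0,
    min_extent: int = 1,
    background_window: int = 500,
    merge_distance: int = 5,
    min_fold: float = 1.5,
) -> list[PauseCluster]:
    """Call clusters of sharply increased occupancy within a region.

    A position is an outlier when its occupancy exceeds the rolling-median
    background by ``z_threshold`` robust (MAD-scaled) deviations *and* by
    ``min_fold`` times the background median.  Outliers within
    ``merge_distance`` nt are merged; clusters shorter than ``min_extent``
    are dropped.  ``region`` may be a feature name (e.g. ``"IGS2"``) when
    an annotation is supplied.  Each cluster reports its maximal position
    as the peak together with the peak's distance upstream of the
    downstream 35S TSS.  Clusters are returned sorted by descending
    enrichment score.
    """
    if isinstance(region, str):
        if ann is None:
            raise ValueError("a feature-name region requires an annotation")
        region = ann.region(region)
    start, end = region
    values = profile.slice(region)
    if background_window > values.size:
        warnings.warn(
            "background window exceeds the region; using whole-region background",
            stacklevel=2,
        )
        med = np.full(values.size, np.median(values))
        mad = np.full(values.size, np.median(np.abs(values - med)))
    else:
        med, mad = _rolling_median_mad(values, background_window)
    scale = np.maximum(_MAD_SCALE * mad, 1e-12)
    z = (values - med) / scale
    fold_ok = np.where(med > 0, values >= min_fold * med, values > 0)
    outliers = np.flatnonzero((z > z_threshold) & fold_ok)
    clusters: list[PauseCluster] = []
    if outliers.size:
        downstream_tss = None
        if ann is not None:
            downstream_tss = ann.anchors.get(DOWNSTREAM_TSS)
        run_start = outliers[0]
        prev = outliers[0]
        runs: list[tuple[int, int]] = []
        for idx in outliers[1:]:
            if idx - prev > merge_distance:
                runs.append((run_start, prev))
                run_start = idx
            prev = idx
        runs.append((run_start, prev))
        for lo, hi in runs:
            extent = hi - lo + 1
            if extent < min_extent:
                continue
            peak_rel = lo + int(np.argmax(values[lo : hi + 1]))
            peak_pos = start + peak_rel
            dist = downstream_tss - peak_pos if downstream_tss is not None else -1
            clusters.append(
                PauseCluster(
                    start=start + lo,
                    end=start + hi,
                    peak_position=peak_pos,
                    peak_value=float(values[peak_rel]),
                    extent=extent,
                    enrichment_score=float(z[peak_rel]),
                    distance_upstream_of_downstream_tss=dist,
                )
            )
    clusters.sort(key=lambda c: -c.enrichment_score)
    return clusters
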