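"""Single-nucleotide polymerase occupancy profiles.

A NET-seq read reports the polymerase active site through the position of
its 5' end, so a profile is simply the per-position tally of retained 5'
read ends over one rDNA repeat.  In the standard Pol I NET-seq chemistry
the sequenced cDNA aligns antisense to the 35S direction, hence the default
strand policy keeps reverse-strand alignments and places their 5' end at
the rightmost aligned base.

Profiles are normalized to the total 35S-body signal (canonical positions
1 .. T1), which makes tracks comparable between replicates and strains of
very different sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import RdnaAnnotation

__all__ = [
    "OccupancyProfile",
    "count_five_prime_ends",
    "load_bedgraph",
    "write_bedgraph",
    "normalize_35S",
    "median_profile",
    "aggregate",
    "NormalizationError",
]

NORM_TOL = 1e-9


class NormalizationError(ValueError):
    """Raised when a profile cannot be (re)normalized."""


@dataclass
class OccupancyProfile:
    """Per-position occupancy over one rDNA repeat (canonical + strand).

    ``values[i]`` is the signal at canonical position ``i + 1``.
    ``total_35S`` records the pre-normalization 35S-body sum once the
    profile has been normalized (None until then, unless set by a reader).
    """

    strain: str
    replicate: str
    values: np.ndarray
    strand: str = "+"
    normalized: bool = False
    total_35S: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def label(self) -> str:
        return f"{self.strain}/{self.replicate}"

    def value_at(self, position: int) -> float:
        """Signal at a 1-based canonical position."""
        return float(self.values[position - 1])

    def slice(self, region: tuple[int, int]) -> np.ndarray:
        """Values over a 1-based closed interval."""
        start, end = region
        if start < 1 or end > len(self) or start > end:
            raise ValueError(f"region {region} outside [1, {len(self)}]")
        return self.values[start - 1 : end]

    def copy_with(self, **kwargs) -> "OccupancyProfile":
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": np.arange(1, len(self) + 1), "value": self.values}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def count_five_prime_ends(
    alignments,
    ann: RdnaAnnotation,
    strand_policy: str = "antisense",
    strain: str = "",
    replicate: str = "",
) -> OccupancyProfile:
    """Tally 5' read-end positions from SAM/BAM alignments.

    ``alignments`` is a path or an open :class:`pysam.AlignmentFile` whose
    single reference matches ``ann.repeat_length``.  Unmapped, secondary
    and supplementary records are dropped.  ``strand_policy``:

    - ``antisense`` (default): keep reverse-strand alignments — nascent
      transcripts sequenced antisense to the 35S direction; the read 5' end
      is the rightmost aligned reference base.
    - ``sense``: keep forward-strand alignments; 5' end is the leftmost
      aligned base.
    - ``both``: keep all mapped primary records, 5' end per alignment
      strand as above.

    The returned profile is always expressed on the canonical + strand.
    """
    if strand_policy not in ("antisense", "sense", "both"):
        raise ValueError(f"unknown strand_policy {strand_policy!r}")
    own = isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__")
    af = pysam.AlignmentFile(str(alignments)) if own else alignments
    try:
        if af.header.nreferences != 1:
            raise ValueError("expected a single-reference alignment file")
        ref_len = af.header.lengths[0]
        if ref_len != ann.repeat_length:
            raise ValueError(
                f"reference length {ref_len} != repeat_length {ann.repeat_length}"
            )
        values = np.zeros(ann.repeat_length, dtype=float)
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if strand_policy == "antisense" and not rec.is_reverse:
                continue
            if strand_policy == "sense" and rec.is_reverse:
                continue
            if rec.is_reverse:
                pos = rec.reference_end  # 1-based rightmost aligned base
            else:
                pos = rec.reference_start + 1
            values[pos - 1] += 1
    finally:
        if own:
            af.close()
    return OccupancyProfile(strain=strain, replicate=replicate, values=values)


# -- bedGraph I/O ------------------------------------------------------------
# bedGraph intervals are 0-based half-open on disk; a disk interval [s, e)
# covers canonical positions s+1 .. e.


def load_bedgraph(
    path, ann: RdnaAnnotation, strain: str = "", replicate: str = ""
) -> OccupancyProfile:
    import io

    with open(path) as fh:
        body = "".join(
            line
            for line in fh
            if line.strip() and not line.startswith(("track", "browser", "#"))
        )
    if not body:
        return OccupancyProfile(
            strain=strain,
            replicate=replicate,
            values=np.zeros(ann.repeat_length, dtype=float),
        )
    df = pd.read_csv(
        io.StringIO(body),
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"start": int, "end": int, "value": float},
    )
    df = df.sort_values("start", kind="stable").reset_index(drop=True)
    values = np.zeros(ann.repeat_length, dtype=float)
    prev_end = 0
    first = True
    for start, end, value in zip(df["start"], df["end"], df["value"]):
        if start < 0 or end > ann.repeat_length or start >= end:
            raise ValueError(
                f"interval [{start}, {end}) outside [0, {ann.repeat_length})"
            )
        if not first and start < prev_end:
            raise ValueError(f"overlapping bedGraph intervals at start {start}")
        values[start:end] = value
        prev_end = end
        first = False
    return OccupancyProfile(strain=strain, replicate=replicate, values=values)


def write_bedgraph(
    profile: OccupancyProfile, path, chrom: str = "rDNA"
) -> None:
    """Write a profile as bedGraph; zero-valued runs are omitted."""
    v = profile.values
    with open(path, "w") as fh:
        if v.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [v.size]))
        for s, e in zip(starts, ends):
            if v[s] != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.10g}\n")


def normalize_35S(profile: OccupancyProfile, ann: RdnaAnnotation) -> OccupancyProfile:
    """Scale a profile by its total 35S-body signal.

    Every position (including ETS 2 and the IGS beyond T1) is divided by
    the sum over canonical positions [1, T1], so the 35S body integrates to
    one while downstream signal stays on the same relative scale.
    """
    if profile.normalized:
        raise NormalizationError("profile is already normalized")
    t1 = ann.feature("T1").start
    total = float(profile.values[:t1].sum())
    if total <= 0:
        raise NormalizationError("35S-body signal sums to zero; cannot normalize")
    return profile.copy_with(
        values=profile.values / total, normalized=True, total_35S=total
    )


def _check_uniform(profiles: Sequence[OccupancyProfile]) -> None:
    if not profiles:
        raise ValueError("need at least one profile")
    strains = {p.strain for p in profiles}
    if len(strains) != 1:
        raise ValueError(f"profiles mix strains: {sorted(strains)}")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"profiles have mixed lengths: {sorted(lengths)}")
    if not all(p.normalized for p in profiles):
        raise ValueError("aggregate profiles must all be normalized")


def median_profile(profiles: Sequence[OccupancyProfile]) -> OccupancyProfile:
    """Per-position median across normalized replicates of one strain.

    The result is on the normalized scale but its own 35S-body sum is the
    median track's, not exactly one.
    """
    _check_uniform(profiles)
    stack = np.vstack([p.values for p in profiles])
    return OccupancyProfile(
        strain=profiles[0].strain,
        replicate="median",
        values=np.median(stack, axis=0),
        normalized=True,
    )


def aggregate(
    profiles: Sequence[OccupancyProfile], method: str = "median"
) -> OccupancyProfile:
    """Aggregate replicates by ``median`` (default) or ``sum``."""
    if method == "median":
        return median_profile(profiles)
    if method == "sum":
        _check_uniform(profiles)
        stack = np.vstack([p.values for p in profiles])
        return OccupancyProfile(
            strain=profiles[0].strain,
            replicate="sum",
            values=stack.sum(axis=0),
            normalized=True,
        )
    raise ValueError(f"unknown aggregation method {method!r}")
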