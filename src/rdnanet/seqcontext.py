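"""Sequence context of highly occupied template positions.

The top-occupied positions of a strain are interpreted as the positions of
the last incorporated nucleotide (LNT) of stalled/paused polymerases.  For
each such position the surrounding template sequence is extracted in
RNA-sense (non-template strand, 35S direction) over a fixed offset window:
offset 0 is the LNT itself, negative offsets lie inside the RNA:DNA hybrid
(already transcribed), positive offsets are still untranscribed.

Two strains' context matrices are compared column by column with a
difference-logo statistic: the Jensen-Shannon divergence (base 2, so at
most 1 bit) between the per-column symbol distributions, split into signed
per-symbol contributions.  Column significance comes from a permutation
test that shuffles strain labels over the pooled context sequences, which
preserves the within-sequence dependence between offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import RdnaAnnotation
from .occupancy import OccupancyProfile

__all__ = [
    "ContextMatrix",
    "DiffLogoResult",
    "select_top_positions",
    "extract_context_matrix",
    "difference_logo",
]

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}


def select_top_positions(
    profile: OccupancyProfile,
    q: float = 0.025,
    region: tuple[int, int] | None = None,
    ann: RdnaAnnotation | None = None,
) -> np.ndarray:
    """The floor(q * |region|) highest-occupancy positions of a region.

    Default region is the 35S body (requires ``ann``).  Ties at the
    selection threshold are broken by ascending position, so the output is
    deterministic and invariant to any strictly increasing transform of
    the profile values.  Returned positions are sorted ascending.
    """
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    if region is None:
        if ann is None:
            raise ValueError("provide a region or an annotation")
        region = (1, ann.feature("T1").start)
    values = profile.slice(region)
    if values.size == 0:
        raise ValueError("empty region")
    k = int(np.floor(q * values.size))
    positions = np.arange(region[0], region[1] + 1)
    order = np.lexsort((positions, -values))  # by value desc, then position asc
    return np.sort(positions[order[:k]])


@dataclass
class ContextMatrix:
    """Symbol counts around a set of LNT positions.

    ``counts[s, w]`` is the number of contexts whose symbol at offset
    ``offsets[w]`` is ``ALPHABET[s]``; every column sums to
    ``n_sequences``.  The raw context strings are retained so that two
    matrices can be compared by label permutation.
    """

    counts: np.ndarray
    offsets: np.ndarray
    n_sequences: int
    sequences: list[str]
    n_skipped_bounds: int = 0
    n_skipped_symbols: int = 0

    def column_probabilities(self, pseudocount: float = 1.0) -> np.ndarray:
        denom = self.n_sequences + pseudocount * len(ALPHABET)
        return (self.counts + pseudocount) / denom

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(ALPHABET), columns=self.offsets)


def extract_context_matrix(
    positions: Sequence[int],
    template: str,
    window: tuple[int, int] = (-8, 4),
    ann: RdnaAnnotation | None = None,
) -> ContextMatrix:
    """Tally RNA-sense symbols at fixed offsets around each LNT position.

    ``template`` is the repeat sequence written 5'->3' in the 35S
    direction (the RNA-sense strand), so symbols are read off directly.
    Positions whose window would run off the template are skipped and
    counted in ``n_skipped_bounds``; contexts containing non-ACGT symbols
    are skipped and counted in ``n_skipped_symbols``.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("window must satisfy lo <= hi")
    template = str(template).upper()
    if ann is not None and len(template) != ann.repeat_length:
        raise ValueError(
            f"template length {len(template)} != repeat_length {ann.repeat_length}"
        )
    width = hi - lo + 1
    counts = np.zeros((len(ALPHABET), width), dtype=int)
    kept: list[str] = []
    skipped_bounds = 0
    skipped_symbols = 0
    for p in positions:
        start = p + lo
        end = p + hi
        if start < 1 or end > len(template):
            skipped_bounds += 1
            continue
        ctx = template[start - 1 : end]
        if any(c not in _CODE for c in ctx):
            skipped_symbols += 1
            continue
        for w, c in enumerate(ctx):
            counts[_CODE[c], w] += 1
        kept.append(ctx)
    return ContextMatrix(
        counts=counts,
        offsets=np.arange(lo, hi + 1),
        n_sequences=len(kept),
        sequences=kept,
        n_skipped_bounds=skipped_bounds,
        n_skipped_symbols=skipped_symbols,
    )


def _js_divergence(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Column-wise Jensen-Shannon divergence in bits (inputs: 4 x W)."""
    m = 0.5 * (pa + pb)
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = np.where(pa > 0, pa * np.log2(np.where(pa > 0, pa, 1) / m), 0.0)
        tb = np.where(pb > 0, pb * np.log2(np.where(pb > 0, pb, 1) / m), 0.0)
    return 0.5 * ta.sum(axis=0) + 0.5 * tb.sum(axis=0)


def _column_counts(seq_codes: np.ndarray) -> np.ndarray:
    """Counts (4 x W) from an integer-coded sequence matrix (N x W)."""
    n, width = seq_codes.shape
    counts = np.zeros((len(ALPHABET), width), dtype=int)
    for w in range(width):
        counts[:, w] = np.bincount(seq_codes[:, w], minlength=len(ALPHABET))
    return counts


@dataclass
class DiffLogoResult:
    """Per-column divergence between two context matrices.

    ``contributions[s, w]`` is the signed share of column ``w``'s
    divergence attributed to symbol ``s``; positive means the symbol is
    enriched in matrix B relative to A.  The absolute contributions of a
    column sum to its divergence height.
    """

    offsets: np.ndarray
    heights: np.ndarray
    contributions: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    alpha: float
    pseudocount: float

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "offset": self.offsets,
                "divergence_bits": self.heights,
                "p_value": self.p_values,
            }
        )
        for i, sym in enumerate(ALPHABET):
            df[f"contrib_{sym}"] = self.contributions[i]
        df["holm_p"] = self.holm_adjusted()
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def holm_adjusted(self) -> np.ndarray:
        from statsmodels.stats.multitest import multipletests

        return multipletests(self.p_values, method="holm")[1]

    def significant_offsets(self, alpha: float | None = None) -> np.ndarray:
        """Offsets significant after Holm correction across columns.

        Holm's step-down keeps the family-wise error at ``alpha`` over the
        window's columns, which is what calling out individual offsets of
        a logo implicitly requires.
        """
        a = self.alpha if alpha is None else alpha
        return self.offsets[self.holm_adjusted() < a]


def difference_logo(
    cm_a: ContextMatrix,
    cm_b: ContextMatrix,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    pseudocount: float = 1.0,
) -> DiffLogoResult:
    """Column-wise JS divergence between two context matrices.

    Per column, symbol probabilities are estimated with ``pseudocount``
    added to each symbol count; the divergence height (bits, <= 1) is
    split into per-symbol contributions proportional to |p_b - p_a| and
    signed by the direction of enrichment.  P-values come from
    ``n_permutations`` random reassignments of the pooled context
    sequences to the two strain labels, scoring each column by the same
    divergence statistic (one-sided: larger divergence is more extreme),
    with the +1 finite-sample correction.
    """
    if cm_a.offsets.shape != cm_b.offsets.shape or np.any(cm_a.offsets != cm_b.offsets):
        raise ValueError("context matrices have different offset windows")
    if cm_a.n_sequences < 1 or cm_b.n_sequences < 1:
        raise ValueError("both context matrices need at least one sequence")
    pa = cm_a.column_probabilities(pseudocount)
    pb = cm_b.column_probabilities(pseudocount)
    heights = _js_divergence(pa, pb)
    delta = pb - pa
    denom = np.abs(delta).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(denom > 0, np.abs(delta) / np.where(denom > 0, denom, 1), 0.0)
    contributions = np.sign(delta) * share * heights

    rng = np.random.default_rng(seed)
    # sort the pool so p-values do not depend on input or group order
    pooled = sorted(cm_a.sequences + cm_b.sequences)
    codes = np.array([[_CODE[c] for c in s] for s in pooled], dtype=np.int64)
    n_a = cm_a.n_sequences
    n_total = len(pooled)
    exceed = np.zeros(heights.size, dtype=int)
    for _ in range(n_permutations):
        perm = rng.permutation(n_total)
        ca = _column_counts(codes[perm[:n_a]])
        cb = _column_counts(codes[perm[n_a:]])
        qa = (ca + pseudocount) / (n_a + pseudocount * len(ALPHABET))
        qb = (cb + pseudocount) / (n_total - n_a + pseudocount * len(ALPHABET))
        exceed += _js_divergence(qa, qb) >= heights - 1e-12
    p_values = (1 + exceed) / (1 + n_permutations)
    return DiffLogoResult(
        offsets=cm_a.offsets.copy(),
        heights=heights,
        contributions=contributions,
        p_values=p_values,
        n_permutations=n_permutations,
        alpha=alpha,
        pseudocount=pseudocount,
    )
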