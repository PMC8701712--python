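"""Synthetic NET-seq data with the statistical structure the analyses assume.

The generator produces per-position polymerase dwell counts over one rDNA
repeat under a simple steady-state flux model: the expected weight at
position ``i`` is

    w_i = exp(sum of per-symbol dwell coefficients over the hybrid window)
          * pause_fold(i) * survival(i)

where ``survival(i)`` multiplies ``1 - e_T`` for every terminator the
polymerase must read through to reach ``i`` (memoryless terminator
action), and pause folds model sequence-specific stalling.  Replicate
counts are drawn from a negative-binomial (gamma-Poisson) distribution
around ``depth * library_factor * w_i / sum(w)`` so that biological
overdispersion and library-size variation are both representable; the
Poisson limit is recovered at dispersion zero.  Everything is
bit-reproducible under a fixed seed.

A companion emitter writes toy single-end SAM alignments whose 5' ends
reproduce the simulated counts exactly, closing the loop with the
alignment-counting stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pysam

from .annotation import RdnaAnnotation
from .occupancy import OccupancyProfile

__all__ = [
    "Pause",
    "StrainEffects",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_template",
    "place_motif",
    "simulate_occupancy",
    "emit_toy_alignments",
    "example_truth",
    "DEFAULT_SEQUENCE_COEFFICIENTS",
]

ALPHABET = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

#: Mild A/T dwell preference: summed over an 8-9 nt hybrid window these
#: weights give the heavy-tailed, sequence-driven dynamic range real
#: occupancy tracks show (roughly e^{+/-2} around the mean).
DEFAULT_SEQUENCE_COEFFICIENTS = {"A": 0.3, "C": -0.3, "G": -0.2, "T": 0.2}


@dataclass(frozen=True)
class Pause:
    """A sequence- or factor-driven stall site.

    ``fold`` multiplies the dwell weight at ``position``.  An optional
    ``motif`` is written into the template so that its last base sits at
    the pause position (offsets ``-len(motif)+1 .. 0`` relative to the
    LNT), letting context analyses recover it.
    """

    position: int
    fold: float
    motif: str | None = None

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("pause fold-strength must be >= 1")


@dataclass
class StrainEffects:
    pauses: list[Pause] = field(default_factory=list)
    terminator_efficiencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, e in self.terminator_efficiencies.items():
            if not (0.0 <= e <= 1.0):
                raise ValueError(f"efficiency of {name} must be in [0, 1], got {e}")


@dataclass
class SimulationTruth:
    """Generative parameters for one simulated experiment.

    ``library_size_factors`` maps a strain to per-replicate depth
    multipliers (default: all ones).  ``hybrid_window`` is the LNT-anchored
    offset range over which sequence coefficients are summed.
    """

    template: str
    strains: dict[str, StrainEffects]
    sequence_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEQUENCE_COEFFICIENTS)
    )
    hybrid_window: tuple[int, int] = (-8, 0)
    depth: float = 1e6
    dispersion: float = 0.01
    n_replicates: int = 3
    library_size_factors: dict[str, list[float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for strain, effects in self.strains.items():
            for pause in effects.pauses:
                if not (1 <= pause.position <= len(self.template)):
                    raise ValueError(
                        f"{strain}: pause at {pause.position} outside template"
                    )

    def factors(self, strain: str) -> list[float]:
        return self.library_size_factors.get(strain, [1.0] * self.n_replicates)


@dataclass
class SimulatedDataset:
    truth: SimulationTruth
    profiles: dict[tuple[str, str], OccupancyProfile]

    def replicates(self, strain: str) -> list[OccupancyProfile]:
        return [
            p for (s, _), p in sorted(self.profiles.items()) if s == strain
        ]

    @property
    def strains(self) -> list[str]:
        return sorted({s for s, _ in self.profiles})


def simulate_template(length: int, gc_fraction: float = 0.4, seed: int = 0) -> str:
    """An i.i.d. random repeat sequence at the requested GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2
    gc = gc_fraction / 2
    symbols = rng.choice(list(ALPHABET), size=length, p=[at, gc, gc, at])
    return "".join(symbols)


def place_motif(template: str, position: int, motif: str) -> str:
    """Write ``motif`` into the template ending at ``position`` (the LNT)."""
    start = position - len(motif)
    if start < 0:
        raise ValueError("motif does not fit upstream of the position")
    return template[:start] + motif.upper() + template[position:]


def _dwell_weights(truth: SimulationTruth) -> np.ndarray:
    """exp(sum of symbol coefficients over the hybrid window), per position."""
    coefs = np.array(
        [truth.sequence_coefficients.get(c, 0.0) for c in truth.template]
    )
    lo, hi = truth.hybrid_window
    n = coefs.size
    # position i sums coefficients at template positions i+lo .. i+hi,
    # truncated at the template boundaries
    csum = np.concatenate(([0.0], np.cumsum(coefs)))
    idx = np.arange(n)
    a = np.clip(idx + lo, 0, n)
    b = np.clip(idx + hi + 1, 0, n)
    return np.exp(csum[b] - csum[a])


def _apply_motifs(truth: SimulationTruth) -> SimulationTruth:
    template = truth.template
    for effects in truth.strains.values():
        for pause in effects.pauses:
            if pause.motif:
                template = place_motif(template, pause.position, pause.motif)
    if template is truth.template:
        return truth
    from dataclasses import replace

    return replace(truth, template=template)


def simulate_occupancy(truth: SimulationTruth, ann: RdnaAnnotation) -> SimulatedDataset:
    """Draw raw-count replicate profiles for every strain of a truth.

    Pause motifs are first written into the shared template.  Terminator
    efficiencies are resolved against ``ann`` feature positions (a strain
    reads through each terminator independently with probability
    ``1 - e_T``).  Replicates are drawn strain by strain in sorted order
    from a single seeded generator, so outputs are reproducible.
    """
    if len(truth.template) != ann.repeat_length:
        raise ValueError("template length does not match the annotation")
    truth = _apply_motifs(truth)
    base = _dwell_weights(truth)
    rng = np.random.default_rng(truth.seed)
    profiles: dict[tuple[str, str], OccupancyProfile] = {}
    positions = np.arange(1, ann.repeat_length + 1)
    for strain in sorted(truth.strains):
        effects = truth.strains[strain]
        w = base.copy()
        for pause in effects.pauses:
            w[pause.position - 1] *= pause.fold
        survival = np.ones(ann.repeat_length)
        for name, e in sorted(effects.terminator_efficiencies.items()):
            t_end = ann.feature(name).end
            survival[positions > t_end] *= 1.0 - e
        w *= survival
        p = w / w.sum()
        factors = truth.factors(strain)
        if len(factors) != truth.n_replicates:
            raise ValueError(
                f"{strain}: {len(factors)} library factors for "
                f"{truth.n_replicates} replicates"
            )
        for r, factor in enumerate(factors, start=1):
            mean = truth.depth * factor * p
            if truth.dispersion > 0:
                lam = rng.gamma(
                    shape=1.0 / truth.dispersion,
                    scale=truth.dispersion * mean,
                )
                counts = rng.poisson(lam)
            else:
                counts = rng.poisson(mean)
            profiles[(strain, f"rep{r}")] = OccupancyProfile(
                strain=strain,
                replicate=f"rep{r}",
                values=counts.astype(float),
            )
    return SimulatedDataset(truth=truth, profiles=profiles)


def expected_weights(
    truth: SimulationTruth, ann: RdnaAnnotation, strain: str
) -> np.ndarray:
    """Normalized expected per-position weights for one strain (sums to 1)."""
    truth = _apply_motifs(truth)
    w = _dwell_weights(truth)
    effects = truth.strains[strain]
    for pause in effects.pauses:
        w[pause.position - 1] *= pause.fold
    positions = np.arange(1, ann.repeat_length + 1)
    for name, e in sorted(effects.terminator_efficiencies.items()):
        t_end = ann.feature(name).end
        w[positions > t_end] *= 1.0 - e
    return w / w.sum()


def emit_toy_alignments(
    profile: OccupancyProfile,
    path,
    template: str,
    read_length: int = 30,
    chrom: str = "rDNA",
) -> None:
    """Write one minus-strand SAM record per counted read.

    Each record's 5' end (the rightmost aligned base of a reverse-strand
    alignment) sits at the counted position, matching the ``antisense``
    counting policy, so counting the emitted file reproduces the profile
    exactly.  Reads near the template start are shortened to fit.
    """
    counts = np.rint(profile.values).astype(int)
    if np.any(np.abs(profile.values - counts) > 1e-6):
        raise ValueError("can only emit alignments for integer count profiles")
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": chrom, "LN": len(template)}],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        serial = 0
        for pos in np.flatnonzero(counts) + 1:
            length = min(read_length, pos)
            start = pos - length + 1
            ref_seq = template[start - 1 : pos].upper()
            read_seq = ref_seq.translate(_COMP)[::-1]
            for _ in range(int(counts[pos - 1])):
                rec = pysam.AlignedSegment(header)
                rec.query_name = (
                    f"{profile.strain or 'sim'}_{profile.replicate or 'r'}_{serial}"
                )
                rec.flag = 16  # reverse strand, mapped, primary
                rec.reference_id = 0
                rec.reference_start = start - 1
                rec.mapping_quality = 60
                rec.cigarstring = f"{length}M"
                rec.query_sequence = read_seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * length)
                out.write(rec)
                serial += 1


def example_truth(
    ann: RdnaAnnotation,
    seed: int = 0,
    depth: float = 1e6,
    n_replicates: int = 3,
) -> SimulationTruth:
    """A two-strain scenario shaped like the WT vs termination-deficient
    mutant comparison: the wild type terminates efficiently at T1 (with a
    T2 failsafe), the mutant reads through both terminators and stalls
    10-fold at the promoter-proximal Tp site.
    """
    template = simulate_template(ann.repeat_length, gc_fraction=0.4, seed=seed)
    tp = ann.feature("Tp").start
    return SimulationTruth(
        template=template,
        strains={
            "WT": StrainEffects(
                terminator_efficiencies={"T1": 0.9, "T2": 0.9, "FIVE_S": 0.95}
            ),
            "mutant": StrainEffects(
                pauses=[Pause(position=tp, fold=10.0)],
                terminator_efficiencies={"T1": 0.2, "T2": 0.2},
            ),
        },
        depth=depth,
        n_replicates=n_replicates,
        seed=seed,
    )
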