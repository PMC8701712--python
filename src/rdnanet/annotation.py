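"""Coordinate frames and features of a single yeast rDNA repeat.

The canonical frame is 1-based with closed intervals; position 1 is the 35S
transcription start site (TSS) and the ``+`` strand is the 35S transcription
direction.  Besides the canonical frame, two anchored offset frames are
supported: offsets relative to the mature 3' end of the 25S rRNA (the frame
used for the terminator region, where the primary terminator T1 sits at +91)
and offsets relative to the TSS of the *downstream* 35S repeat (the frame
used for the promoter-proximal region of IGS 2, where the putative third
terminator Tp sits at -215).

Well-characterised coordinates are fixed defaults: T1 at canonical 6739,
91 nt downstream of the mature 25S end (6648); the Rnt1 stem-loop cleavage
sites at +14/+15 and +49/+50 relative to the 25S end; the 20-bp A/T tract
ending at T1; Tp 215 bp upstream of the downstream TSS.  Everything else
(repeat length, T2, 5S boundaries, Reb1/Nsi1 sites, spacer boundaries) is a
plausible editable default flagged ``approximate`` — override it with a BED
file when analysing a specific reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

__all__ = [
    "Feature",
    "RdnaAnnotation",
    "AnnotationError",
    "default_annotation",
    "transform",
    "load_annotation_bed",
    "write_annotation_bed",
]

#: Anchor names of the supported coordinate frames.
TSS_35S = "TSS_35S"
MATURE_25S_END = "MATURE_25S_END"
DOWNSTREAM_TSS = "DOWNSTREAM_TSS"

#: Features that occupy a single nucleotide.
POINT_FEATURES = frozenset({"T1", "T2", "Tp"})
#: Rnt1 cleaves between two nucleotides; its sites span the flanking pair.
DINUCLEOTIDE_FEATURES = frozenset({"RNT1_SITE_PROX", "RNT1_SITE_DIST"})


class AnnotationError(ValueError):
    """Raised when an annotation violates its structural invariants."""


@dataclass(frozen=True)
class Feature:
    """A named interval on the rDNA repeat (1-based, closed).

    ``approximate`` marks coordinates that are editable placeholders rather
    than well-established positions; they are serialised but not relied on
    for any fixed arithmetic.
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    approximate: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"feature {self.name}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"feature {self.name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RdnaAnnotation:
    """One rDNA repeat: its length, features, and coordinate-frame anchors.

    ``anchors`` maps each frame name to the canonical position of its
    origin.  The canonical (``TSS_35S``) frame is 1-based, so its anchor
    position (1) carries frame coordinate 1; the other frames are signed
    offsets, so their anchor position carries frame coordinate 0.
    """

    repeat_length: int
    features: tuple[Feature, ...]
    anchors: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        problems: list[str] = []
        if self.repeat_length <= 0:
            problems.append(f"repeat_length must be positive, got {self.repeat_length}")
        if self.anchors.get(TSS_35S) != 1:
            problems.append("anchor TSS_35S must be canonical position 1")
        by_name = {f.name: f for f in self.features}
        for f in self.features:
            if f.start < 1 or f.end > self.repeat_length:
                problems.append(
                    f"feature {f.name} [{f.start}, {f.end}] outside "
                    f"[1, {self.repeat_length}]"
                )
            if f.name in POINT_FEATURES and f.start != f.end:
                problems.append(f"point feature {f.name} must have start == end")
            if f.name in DINUCLEOTIDE_FEATURES and f.length != 2:
                problems.append(f"{f.name} must span exactly two nucleotides")
        if "T1" in by_name and MATURE_25S_END in self.anchors:
            if by_name["T1"].start - self.anchors[MATURE_25S_END] != 91:
                problems.append(
                    "T1 must lie 91 nt downstream of the mature 25S end"
                )
        if "FIVE_S" in by_name and "35S" in by_name:
            if by_name["FIVE_S"].strand == by_name["35S"].strand:
                problems.append("5S must be on the strand opposite to 35S")
        if problems:
            raise AnnotationError("; ".join(problems))

    # -- lookups ------------------------------------------------------------

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r}")

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def position(self, name: str, frame: str = TSS_35S) -> int:
        """Canonical-frame start of a feature, expressed in ``frame``."""
        return transform(self.feature(name).start, TSS_35S, frame, self)

    def region(self, name: str) -> tuple[int, int]:
        f = self.feature(name)
        return f.start, f.end

    def with_feature(self, feat: Feature) -> "RdnaAnnotation":
        """Return a copy with ``feat`` replacing any same-named feature."""
        kept = tuple(f for f in self.features if f.name != feat.name)
        return replace(self, features=kept + (feat,))

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "repeat_length": self.repeat_length,
                "anchors": self.anchors,
                "features": [
                    {
                        "name": f.name,
                        "start": f.start,
                        "end": f.end,
                        "strand": f.strand,
                        "approximate": f.approximate,
                    }
                    for f in self.features
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RdnaAnnotation":
        obj = json.loads(text)
        return cls(
            repeat_length=obj["repeat_length"],
            features=tuple(Feature(**f) for f in obj["features"]),
            anchors=dict(obj["anchors"]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RdnaAnnotation):
            return NotImplemented
        return (
            self.repeat_length == other.repeat_length
            and self.anchors == other.anchors
            and sorted(self.features, key=lambda f: (f.start, f.name))
            == sorted(other.features, key=lambda f: (f.start, f.name))
        )


def _to_canonical(pos: int, frame: str, ann: RdnaAnnotation) -> int:
    if frame not in ann.anchors:
        raise KeyError(f"unknown frame {frame!r}; known: {sorted(ann.anchors)}")
    if frame == TSS_35S:
        return pos  # 1-based positions, anchor at 1
    return ann.anchors[frame] + pos  # signed offsets, anchor at 0


def _from_canonical(pos: int, frame: str, ann: RdnaAnnotation) -> int:
    if frame not in ann.anchors:
        raise KeyError(f"unknown frame {frame!r}; known: {sorted(ann.anchors)}")
    if frame == TSS_35S:
        return pos
    return pos - ann.anchors[frame]


def transform(pos: int, from_frame: str, to_frame: str, ann: RdnaAnnotation) -> int:
    """Re-express ``pos`` from one coordinate frame in another.

    The transform is an affine shift by the anchor difference, so composing
    transforms is associative and each transform is inverted by swapping the
    frames.  Examples: T1 (canonical 6739) is +91 in the 25S-end frame; Tp
    is -215 in the downstream-TSS frame.
    """
    return _from_canonical(_to_canonical(pos, from_frame, ann), to_frame, ann)


# Default layout of one repeat.  The 35S transcribed unit runs from the TSS
# (position 1) to T1 (6739); the mature 25S 3' end sits at 6648.  Only the
# offsets 6739, 91, +14/+15, +49/+50, the 20-bp A/T tract, and Tp at -215
# are well established; intervals flagged approximate are editable defaults
# sized after the S. cerevisiae repeat (~9.1 kb).
_DEFAULT_REPEAT_LENGTH = 9100
_DEFAULT_FEATURES: tuple[Feature, ...] = (
    Feature("35S", 1, 6739, "+"),
    Feature("ETS1", 1, 700, "+", approximate=True),
    Feature("18S", 701, 2500, "+", approximate=True),
    Feature("ITS1", 2501, 2860, "+", approximate=True),
    Feature("5_8S", 2861, 3018, "+", approximate=True),
    Feature("ITS2", 3019, 3250, "+", approximate=True),
    Feature("25S", 3251, 6648, "+", approximate=True),
    Feature("ETS2", 6649, 6739, "+"),
    Feature("RNT1_SITE_PROX", 6662, 6663, "+"),   # +14/+15 from 25S end
    Feature("RNT1_SITE_DIST", 6697, 6698, "+"),   # +49/+50 from 25S end
    Feature("AT_TRACT", 6720, 6739, "+"),          # 20 bp ending at T1
    Feature("T1", 6739, 6739, "+"),
    Feature("NSI1_SITE", 6742, 6752, "+", approximate=True),
    Feature("IGS1", 6740, 7699, "+", approximate=True),
    Feature("T2", 6989, 6989, "+", approximate=True),
    Feature("RFB", 6990, 7200, "+", approximate=True),
    Feature("FIVE_S", 7700, 7820, "-", approximate=True),
    Feature("IGS2", 7821, 9100, "+", approximate=True),
    Feature("Tp", 8886, 8886, "+"),                # -215 from downstream TSS
    Feature("REB1_PROMOTER_PROXIMAL", 8891, 8900, "+", approximate=True),
)


def default_annotation(repeat_length: int = _DEFAULT_REPEAT_LENGTH) -> RdnaAnnotation:
    """The packaged single-repeat annotation.

    With a non-default ``repeat_length`` the downstream-TSS anchor, Tp and
    the IGS 2 right edge shift accordingly; everything upstream keeps its
    canonical coordinate.
    """
    feats = list(_DEFAULT_FEATURES)
    if repeat_length != _DEFAULT_REPEAT_LENGTH:
        if repeat_length < 8901:
            raise AnnotationError(
                "repeat_length too short for the default feature layout"
            )
        for i, f in enumerate(feats):
            if f.name == "IGS2":
                feats[i] = replace(f, end=repeat_length)
            elif f.name == "Tp":
                feats[i] = replace(f, start=repeat_length + 1 - 215,
                                   end=repeat_length + 1 - 215)
            elif f.name == "REB1_PROMOTER_PROXIMAL":
                shift = repeat_length - _DEFAULT_REPEAT_LENGTH
                feats[i] = replace(f, start=f.start + shift, end=f.end + shift)
    return RdnaAnnotation(
        repeat_length=repeat_length,
        features=tuple(feats),
        anchors={
            TSS_35S: 1,
            MATURE_25S_END: 6648,
            DOWNSTREAM_TSS: repeat_length + 1,
        },
    )


# -- BED6 I/O ----------------------------------------------------------------
# On disk BED is 0-based half-open; internally everything is 1-based closed.
# Repeat length and anchors ride along as '#' header comments so that a
# write/load round trip reproduces the annotation exactly; the BED score
# column stores the `approximate` flag (0 fixed, 1 approximate).

_BED_CHROM = "rDNA"


def write_annotation_bed(ann: RdnaAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# repeat_length={ann.repeat_length}\n")
        for name, pos in ann.anchors.items():
            fh.write(f"# anchor {name}={pos}\n")
        for f in sorted(ann.features, key=lambda f: (f.start, f.name)):
            fh.write(
                f"{_BED_CHROM}\t{f.start - 1}\t{f.end}\t{f.name}\t"
                f"{int(f.approximate)}\t{f.strand}\n"
            )


def load_annotation_bed(path) -> RdnaAnnotation:
    """Load an annotation from BED6 (plus optional header comments).

    Without header comments the repeat length is taken as the largest
    feature end and the frame anchors are derived from the features
    (25S end = T1 - 91 when T1 is present).
    """
    repeat_length = None
    anchors: dict[str, int] = {}
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser")):
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("repeat_length="):
                    repeat_length = int(body.split("=", 1)[1])
                elif body.startswith("anchor "):
                    name, pos = body[len("anchor "):].split("=", 1)
                    anchors[name.strip()] = int(pos)
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise AnnotationError(f"expected BED6, got {len(cols)} columns")
            _, start0, end0, name, score, strand = cols[:6]
            feats.append(
                Feature(
                    name=name,
                    start=int(start0) + 1,
                    end=int(end0),
                    strand=strand,
                    approximate=bool(int(float(score))),
                )
            )
    if repeat_length is None:
        repeat_length = max((f.end for f in feats), default=0)
    if not anchors:
        anchors[TSS_35S] = 1
        for f in feats:
            if f.name == "T1":
                anchors[MATURE_25S_END] = f.start - 91
        anchors.setdefault(DOWNSTREAM_TSS, repeat_length + 1)
    return RdnaAnnotation(
        repeat_length=repeat_length, features=tuple(feats), anchors=anchors
    )
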