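"""End-to-end orchestration: inputs -> tracks -> QC -> comparisons -> reports.

``run`` executes the full analysis deterministically from a single
:class:`RunConfig`: build (or simulate) replicate occupancy profiles,
normalize each replicate to its 35S-body signal, check replicate agreement
by Spearman correlation, compare the first two strains position by
position, characterise the sequence context of the top-occupied positions,
and quantify terminator read-through plus IGS 2 pause clusters.  All
outputs land in one results directory together with a machine-readable
manifest that echoes the configuration actually used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotation import RdnaAnnotation, default_annotation, load_annotation_bed
from .differential import moving_average, positionwise_test
from .occupancy import (
    OccupancyProfile,
    count_five_prime_ends,
    load_bedgraph,
    median_profile,
    normalize_35S,
    write_bedgraph,
)
from .reproducibility import spearman_matrix
from .seqcontext import difference_logo, extract_context_matrix, select_top_positions
from .simulate import example_truth, simulate_occupancy
from .termination import TerminationReport, detect_pause_clusters, terminator_metrics

__all__ = ["RunConfig", "PipelineError", "run"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` selects the input source: ``simulate`` (synthetic dataset),
    ``alignments`` (SAM/BAM per replicate) or ``bedgraph`` (count tracks).
    ``manifest`` lists ``{"strain": ..., "replicate": ..., "path": ...}``
    entries in the real-input modes.  The defaults mirror the analysis
    design this pipeline implements: alpha 0.05, three replicates
    expected, a 300-nt moving average, and the top 2.5% of occupied
    positions for sequence-context analysis.
    """

    outdir: str
    mode: str = "simulate"
    manifest: list[dict] = field(default_factory=list)
    annotation_bed: str | None = None
    template_fasta: str | None = None
    strain_a: str | None = None
    strain_b: str | None = None
    alpha: float = 0.05
    ma_window: int = 300
    top_q: float = 0.025
    context_window: tuple[int, int] = (-8, 4)
    n_permutations: int = 1000
    terminators: tuple[str, ...] = ("T1", "T2")
    up_window: int = 100
    down_window: int = 100
    gap: int = 10
    strand_policy: str = "antisense"
    depth: float = 1e6
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.top_q <= 1):
            raise ValueError("top_q must be in (0, 1]")
        if self.mode not in ("simulate", "alignments", "bedgraph"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != "simulate":
            if not self.manifest:
                raise ValueError("manifest must be non-empty in real-input modes")
            for entry in self.manifest:
                if not Path(entry["path"]).exists():
                    raise FileNotFoundError(
                        f"manifest file missing: {entry['path']}"
                    )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            obj = yaml.safe_load(fh)
        if "context_window" in obj:
            obj["context_window"] = tuple(obj["context_window"])
        if "terminators" in obj:
            obj["terminators"] = tuple(obj["terminators"])
        return cls(**obj)


def _load_profiles(
    config: RunConfig, ann: RdnaAnnotation
) -> tuple[dict[str, list[OccupancyProfile]], str | None]:
    """Return raw replicate profiles per strain plus a template sequence."""
    if config.mode == "simulate":
        truth = example_truth(
            ann,
            seed=config.seed,
            depth=config.depth,
            n_replicates=config.n_replicates,
        )
        dataset = simulate_occupancy(truth, ann)
        by_strain: dict[str, list[OccupancyProfile]] = {
            s: dataset.replicates(s) for s in dataset.strains
        }
        return by_strain, dataset.truth.template
    by_strain = {}
    for entry in config.manifest:
        strain, rep, path = entry["strain"], entry["replicate"], entry["path"]
        if config.mode == "alignments":
            prof = count_five_prime_ends(
                path, ann, config.strand_policy, strain=strain, replicate=rep
            )
        else:
            prof = load_bedgraph(path, ann, strain=strain, replicate=rep)
        by_strain.setdefault(strain, []).append(prof)
    template = None
    if config.template_fasta:
        from Bio import SeqIO

        template = str(next(SeqIO.parse(config.template_fasta, "fasta")).seq)
    return by_strain, template


def run(config: RunConfig) -> Path:
    """Execute the pipeline; returns the results directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "outputs": [],
        "stages_completed": [],
    }

    def _emit(name: str) -> Path:
        path = outdir / name
        manifest["outputs"].append(name)
        return path

    try:
        stage = "annotation"
        ann = (
            load_annotation_bed(config.annotation_bed)
            if config.annotation_bed
            else default_annotation()
        )

        stage = "input"
        raw, template = _load_profiles(config, ann)
        strains = sorted(raw)
        strain_a = config.strain_a or strains[0]
        strain_b = config.strain_b or (strains[1] if len(strains) > 1 else None)

        stage = "normalize"
        norm = {
            s: [normalize_35S(p, ann) for p in reps] for s, reps in raw.items()
        }
        for s, reps in norm.items():
            for p in reps:
                write_bedgraph(p, _emit(f"{s}_{p.replicate}.normalized.bedgraph"))

        stage = "reproducibility"
        for s, reps in norm.items():
            if len(reps) >= 2:
                spearman_matrix(reps, ann=ann).to_tsv(_emit(f"{s}.spearman.tsv"))

        stage = "aggregate"
        medians = {s: median_profile(reps) for s, reps in norm.items()}
        for s, med in medians.items():
            med.to_tsv(_emit(f"{s}.median.tsv"))
            moving_average(med, config.ma_window).to_tsv(
                _emit(f"{s}.median.ma{config.ma_window}.tsv")
            )

        if strain_b is not None:
            stage = "differential"
            track = positionwise_test(
                norm[strain_a],
                norm[strain_b],
                alpha=config.alpha,
                region=(1, ann.feature("T1").start),
            )
            track.to_tsv(_emit(f"{strain_a}_vs_{strain_b}.differential.tsv"))

            if template is not None:
                stage = "seqcontext"
                cms = {}
                for s in (strain_a, strain_b):
                    top = select_top_positions(
                        medians[s], q=config.top_q, ann=ann
                    )
                    cms[s] = extract_context_matrix(
                        top, template, window=config.context_window, ann=ann
                    )
                    cms[s].to_dataframe().to_csv(
                        _emit(f"{s}.context_counts.tsv"), sep="\t"
                    )
                logo = difference_logo(
                    cms[strain_a],
                    cms[strain_b],
                    n_permutations=config.n_permutations,
                    alpha=config.alpha,
                    seed=config.seed,
                )
                logo.to_tsv(_emit(f"{strain_a}_vs_{strain_b}.difflogo.tsv"))

        stage = "termination"
        report = TerminationReport()
        focus = strain_b or strain_a
        for term in config.terminators:
            if ann.has_feature(term):
                report.terminators.append(
                    terminator_metrics(
                        medians[focus],
                        ann,
                        term,
                        up_window=config.up_window,
                        down_window=config.down_window,
                        gap=config.gap,
                    )
                )
        report.pause_clusters = detect_pause_clusters(
            medians[focus], "IGS2", ann=ann
        )
        report.to_dataframe().to_csv(
            _emit(f"{focus}.termination.tsv"), sep="\t", index=False
        )
        report.clusters_to_bed(_emit(f"{focus}.pause_clusters.bed"))

        manifest["stages_completed"] = [
            "annotation",
            "input",
            "normalize",
            "reproducibility",
            "aggregate",
            "differential",
            "seqcontext",
            "termination",
        ]
    except Exception as exc:  # annotate and re-raise with the failing stage
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
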