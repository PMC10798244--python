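"""Pipeline orchestration: start generation and stepwise extension.

Start generation: sketch a pool of conformations for the initial 2D
structure, cluster them, refine each cluster representative in n_run
short constrained samplings, and keep from each the best frame that
exactly realises the initial structure.  Each surviving frame seeds an
independent extension lineage.

Stepwise extension: for every step of the 2D path, n_sim constrained
samplings run from the current conformation; the pooled frames are
ranked hierarchically; a checkpoint then asks whether the realised
interaction actually grew.  Runs stop when it did not (stalled), or
succeed when the annotated interaction covers the target.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .duplex2d import (
    BasePair,
    ComplexStructure,
    ConstraintStructure,
    InteractionMetrics,
    bp_distance,
    interaction_metrics,
)
from .model3d import (
    Conformation3D,
    DEFAULT_GEOMETRY,
    GeometryParams,
    SketchError,
    annotate_pairs,
    sketch_structure,
    write_trajectory_pdb,
)
from .pathgen import InteractionPath
from .sampler import SamplerConfig, TrajectoryFrame, derive_seed, sample
from .selection import NoValidStartError, cluster_starts, select_start, select_step

logger = logging.getLogger("stepfold")

TERM_REACHED = "reached_target"
TERM_STALLED = "stalled_at_checkpoint"
TERM_NO_START = "no_valid_start"
TERM_EXHAUSTED = "path_exhausted"


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level knobs; the counts mirror the stage structure.

    n_cluster start clusters x n_run refinements give the lineages;
    each extension step runs n_sim samplings of n_step iterations.
    Stop setting I demands perfect-helix growth at the checkpoint;
    setting II also accepts growth with bulges/interior loops.
    """

    n_cluster: int = 10
    n_run: int = 5
    n_sim: int = 5
    n_step: int = 10000
    stop_setting: str = "I"
    spacer: int = 2
    gap_limit: int = 4
    master_seed: int = 0
    start_mode: str = "sketch"  # or "pdb_file"
    n_sketch: Optional[int] = None  # sketch pool size; default 3 * n_cluster
    lookahead_steps: int = 0
    #: pipeline sampling runs colder and with stronger constraint springs
    #: than the bare sampler defaults: each extension step only needs the
    #: local neighbourhood around the previous selected frame, and the
    #: constraint must dominate the chain terms for the zipper to advance
    sampler: SamplerConfig = field(
        default_factory=lambda: SamplerConfig(
            temperature=0.2, constraint_weight=3.0, max_rotate=40.0
        )
    )
    geometry: GeometryParams = field(default_factory=GeometryParams)
    #: pairing window used for the *sampling* constraint wells only.  It is
    #: a slice near the bottom of the annotation window: pulling constrained
    #: pairs toward the shortest in-window distances makes them the nearest
    #: candidates of their own residues, so geometric annotation reads the
    #: realised interaction in the intended register; its floor sits half an
    #: Angstrom above the annotation floor so thermal excursions rarely drop
    #: a pair out of the annotation window.
    pull_window: tuple[float, float] = (13.5, 14.5)

    @property
    def sampling_geometry(self) -> GeometryParams:
        return dataclasses.replace(self.geometry, pair_window=self.pull_window)

    def __post_init__(self) -> None:
        for name in ("n_cluster", "n_run", "n_sim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.stop_setting not in ("I", "II"):
            raise ValueError("stop_setting must be 'I' or 'II'")
        if self.start_mode not in ("sketch", "pdb_file"):
            raise ValueError("start_mode must be 'sketch' or 'pdb_file'")


@dataclass
class StepRecord:
    step: int
    constraint_n_inter: int
    metrics: InteractionMetrics
    n_inter: int
    bp_dist_interaction: int
    bp_dist_full: int
    base_energy: float
    constraint_penalty: float
    frame: TrajectoryFrame


@dataclass
class RunRecord:
    run_id: str
    steps: list[StepRecord]
    termination: str

    @property
    def n_executed(self) -> int:
        return len(self.steps)


@dataclass
class Report:
    """Per-extension-step interaction-length histograms and attrition."""

    runs: list[RunRecord]
    per_run: pd.DataFrame
    summary: pd.DataFrame
    n_initial: int


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# checkpoint (e3)


def checkpoint(prev: InteractionMetrics, new: InteractionMetrics, setting: str) -> str:
    """'continue' iff the realised interaction grew between two steps.

    Setting I requires the perfect helix to lengthen; setting II also
    continues when the with-loops interaction site grew (bulges and small
    interior loops tolerated).  Pure function of the two metric records.
    """
    if setting == "I":
        go = new.longest_perfect > prev.longest_perfect
    elif setting == "II":
        go = (new.with_loops > prev.with_loops) or (
            new.longest_perfect > prev.longest_perfect
        )
    else:
        raise ValueError("setting must be 'I' or 'II'")
    return "continue" if go else "stop"


# ---------------------------------------------------------------------------
# start generation (s1-s4)


def generate_starts(
    config: PipelineConfig,
    system,
    initial: ComplexStructure,
    start_conf: Optional[Conformation3D] = None,
) -> list[tuple[str, TrajectoryFrame]]:
    """Produce up to n_cluster x n_run start frames matching *initial*.

    sketch mode: a seeded pool of ideal-geometry sketches is clustered to
    n_cluster representatives; each is refined by n_run short constrained
    samplings; from each refinement the best exactly-matching frame is
    kept.  pdb_file mode: the provided conformation is the single cluster
    representative (n_cluster = 1).
    """
    params = config.geometry
    init_constraint = ConstraintStructure(system, initial.pairs)
    if config.start_mode == "pdb_file":
        if start_conf is None:
            raise PipelineError("pdb_file start mode requires a conformation")
        reps = [TrajectoryFrame(start_conf, 0.0, 0.0, 0)]
    else:
        n_pool = config.n_sketch or 3 * config.n_cluster
        pool = []
        for i in range(n_pool):
            seed = derive_seed(config.master_seed, 1000 + i)
            try:
                conf = sketch_structure(system, initial, params, seed=seed, require="exact")
            except SketchError:
                logger.warning("sketch %d failed; skipped", i)
                continue
            pool.append(TrajectoryFrame(conf, 0.0, 0.0, 0))
        if not pool:
            raise PipelineError("no valid start structures: all sketches failed")
        assignment = cluster_starts(pool, config.n_cluster)
        reps = list(assignment.representatives)

    starts: list[tuple[str, TrajectoryFrame]] = []
    refine_cfg = dataclasses.replace(
        config.sampler, n_step=max(1, config.n_step // 2)
    )
    for ci, rep in enumerate(reps):
        for ri in range(config.n_run):
            seed = derive_seed(config.master_seed, 2000 + ci * 100 + ri)
            cfg = dataclasses.replace(refine_cfg, seed=seed)
            traj = sample(rep.conf, init_constraint, cfg, config.sampling_geometry)
            try:
                frame = select_start(traj.frames, initial, params)
            except NoValidStartError:
                logger.info("cluster %d run %d: no exactly matching frame", ci, ri)
                continue
            starts.append((f"c{ci}r{ri}", frame))
    if not starts:
        raise PipelineError("no valid start structures")
    return starts


# ---------------------------------------------------------------------------
# stepwise extension (e1-e3)


def run_extension(
    start: TrajectoryFrame,
    path: InteractionPath,
    config: PipelineConfig,
    run_id: str = "run0",
    run_index: int = 0,
) -> RunRecord:
    """One lineage: extend along *path* until success or stall."""
    params = config.geometry
    target = frozenset(path.target)
    setting = config.stop_setting

    def record(step_k: int, frame: TrajectoryFrame, constraint: ConstraintStructure) -> StepRecord:
        annotated = annotate_pairs(frame.conf, params)
        canon = annotated.replace_pairs(annotated.canonical_pairs())
        m = interaction_metrics(canon, gap_limit=config.gap_limit)
        reference = constraint.as_structure()
        region = {pos for bp in constraint.intermolecular_pairs for pos in bp.positions()}
        return StepRecord(
            step=step_k,
            constraint_n_inter=len(constraint.intermolecular_pairs),
            metrics=m,
            n_inter=m.n_inter,
            bp_dist_interaction=bp_distance(annotated, reference, region=region),
            bp_dist_full=bp_distance(annotated, reference),
            base_energy=frame.base_energy,
            constraint_penalty=frame.constraint_penalty,
            frame=frame,
        )

    steps: list[StepRecord] = [record(0, start, path.steps[0])]
    prev_metrics = steps[0].metrics

    def reached(rec: StepRecord) -> bool:
        annotated = annotate_pairs(rec.frame.conf, params)
        canon = annotated.canonical_pairs()
        inter = frozenset(bp for bp in canon if bp.intermolecular)
        return target <= inter

    if reached(steps[0]):
        return RunRecord(run_id, steps, TERM_REACHED)

    current = start.conf
    for k in range(1, len(path.steps)):
        constraint = path.steps[k]
        pool: list[TrajectoryFrame] = []
        failures = 0
        for s in range(config.n_sim):
            seed = derive_seed(
                config.master_seed, 30000 + run_index * 1000 + k * 50 + s
            )
            cfg = dataclasses.replace(config.sampler, n_step=config.n_step, seed=seed)
            try:
                traj = sample(current, constraint, cfg, config.sampling_geometry)
            except Exception as exc:  # sampler failure: omit, log
                logger.warning("%s step %d sim %d failed: %s", run_id, k, s, exc)
                failures += 1
                continue
            pool.extend(traj.frames)
        if failures == config.n_sim:
            raise PipelineError(f"{run_id}: all {config.n_sim} samplings failed at step {k}")
        chosen = select_step(pool, constraint, params)
        rec = record(k, chosen, constraint)
        steps.append(rec)
        if reached(rec):
            return RunRecord(run_id, steps, TERM_REACHED)
        verdict = checkpoint(prev_metrics, rec.metrics, setting)
        logger.debug("%s step %d: %s (%s)", run_id, k, verdict, rec.metrics)
        if verdict == "stop":
            return RunRecord(run_id, steps, TERM_STALLED)
        prev_metrics = rec.metrics
        current = chosen.conf
    return RunRecord(run_id, steps, TERM_EXHAUSTED)


def run_pipeline(
    system,
    initial: ComplexStructure,
    path: InteractionPath,
    config: PipelineConfig,
    start_conf: Optional[Conformation3D] = None,
) -> Report:
    """Full pipeline: start generation, per-start extension, aggregation."""
    starts = generate_starts(config, system, initial, start_conf=start_conf)
    runs = []
    for idx, (sid, frame) in enumerate(starts):
        runs.append(run_extension(frame, path, config, run_id=sid, run_index=idx))
    return aggregate(runs)


# ---------------------------------------------------------------------------
# aggregation and reports


def aggregate(runs: Sequence[RunRecord]) -> Report:
    """Per-step histograms and attrition statistics over the runs.

    A run is *active* at step k when it executed that step.  The active
    fraction is rendered against the initial number of runs, so it is
    non-increasing along the path by construction.
    """
    if not runs:
        raise PipelineError("aggregate requires at least one run")
    rows = []
    for run in runs:
        for rec in run.steps:
            rows.append(
                {
                    "run_id": run.run_id,
                    "step": rec.step,
                    "constraint_n_inter": rec.constraint_n_inter,
                    "longest_perfect": rec.metrics.longest_perfect,
                    "with_loops": rec.metrics.with_loops,
                    "n_inter": rec.n_inter,
                    "bp_dist_interaction": rec.bp_dist_interaction,
                    "bp_dist_full": rec.bp_dist_full,
                    "base_energy": round(rec.base_energy, 6),
                    "constraint_penalty": round(rec.constraint_penalty, 6),
                    "active": 1,
                    "termination": run.termination,
                }
            )
    per_run = pd.DataFrame(rows).sort_values(["run_id", "step"]).reset_index(drop=True)
    n_initial = len(runs)
    summary_rows = []
    for step in sorted(per_run["step"].unique()):
        sub = per_run[per_run["step"] == step]
        hist_perfect = sub["longest_perfect"].value_counts().sort_index()
        hist_loops = sub["with_loops"].value_counts().sort_index()
        frac = len(sub) / n_initial
        summary_rows.append(
            {
                "step": step,
                "constraint_n_inter": int(sub["constraint_n_inter"].iloc[0]),
                "n_active": len(sub),
                "active_fraction": f"{round(100 * frac):d}%",
                "hist_longest_perfect": ";".join(
                    f"{k}:{v}" for k, v in hist_perfect.items()
                ),
                "hist_with_loops": ";".join(f"{k}:{v}" for k, v in hist_loops.items()),
            }
        )
    summary = pd.DataFrame(summary_rows)
    return Report(runs=list(runs), per_run=per_run, summary=summary, n_initial=n_initial)


def write_report(report: Report, outdir) -> None:
    """runs.tsv (per run per step) and summary.tsv (per constraint size)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.per_run.to_csv(outdir / "runs.tsv", sep="\t", index=False)
    report.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    frames = [run.steps[-1].frame.conf for run in report.runs]
    write_trajectory_pdb(frames, outdir / "selected_final.pdb")
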