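"""Constrained Metropolis Monte-Carlo sampling of bead chains.

This is the built-in sampler behind the pipeline's sampling contract.  It
works in reduced units and makes no claim of thermodynamic realism: the
question it answers is steric/kinetic reachability.  Soft base-pair
constraints enter as a flat-bottom quadratic penalty on the pairing
window, biasing -- never forcing -- the chains toward the constrained
pairs.  Moves preserve bond lengths exactly; proposals that create a
clash are rejected outright, so excluded volume is a hard wall.

External 3D tools can stand behind the same contract through the adapter
interfaces at the bottom of this module.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .duplex2d import ConstraintStructure, Position
from .model3d import (
    Conformation3D,
    DEFAULT_GEOMETRY,
    GeometryParams,
    clash_count,
)


@dataclass(frozen=True)
class SamplerConfig:
    """Monte-Carlo settings (reduced units)."""

    n_step: int = 10000
    temperature: float = 1.0
    constraint_weight: float = 1.0
    move_weights: tuple[float, float, float] = (0.6, 0.2, 0.2)
    max_rotate: float = 60.0  # degrees per crankshaft / pivot proposal
    max_translate: float = 3.0  # Angstrom per rigid-move proposal
    record_every: Optional[int] = None  # default: max(1, n_step // 200)
    seed: int = 0
    ev_radius: float = 6.0  # soft excluded-volume onset
    ev_weight: float = 0.25
    #: worm-like-chain bending stiffness per joint (reduced units); gives
    #: the chains a persistence of a few beads, as single-stranded RNA
    #: has, and keeps unconstrained segments from crumpling into the
    #: pairing shell of the duplex
    bend_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_step < 0:
            raise ValueError("n_step must be >= 0")
        if any(w < 0 for w in self.move_weights) or sum(self.move_weights) <= 0:
            raise ValueError("move weights must be non-negative with positive sum")

    @property
    def effective_record_every(self) -> int:
        if self.record_every is not None:
            return max(1, self.record_every)
        return max(1, self.n_step // 200)


@dataclass(frozen=True)
class TrajectoryFrame:
    """One recorded state: conformation plus its energy bookkeeping."""

    conf: Conformation3D
    base_energy: float
    constraint_penalty: float
    step_index: int

    @property
    def total_energy(self) -> float:
        return self.base_energy + self.constraint_penalty


@dataclass(frozen=True)
class Trajectory:
    frames: tuple[TrajectoryFrame, ...]
    config: SamplerConfig

    def __post_init__(self) -> None:
        steps = [f.step_index for f in self.frames]
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("frame step_index must be strictly increasing")

    @property
    def final(self) -> TrajectoryFrame:
        return self.frames[-1]


# ---------------------------------------------------------------------------
# energies


def base_energy(
    conf: Conformation3D,
    config: SamplerConfig,
    params: GeometryParams = DEFAULT_GEOMETRY,
) -> float:
    """Chain energy: soft excluded volume plus worm-like-chain bending.

    Excluded volume is a quadratic onset below ``ev_radius`` over
    non-bonded bead pairs (hard clashes below clash_dist never occur in
    accepted states -- they are rejected outright).  Bending is
    ``bend_weight * (1 - cos phi)`` per joint, phi the angle between
    successive bond vectors.
    """
    coords = conf.all_coords
    na = len(conf.system.chain_a)
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=2))
    iu = np.triu_indices(n, k=1)
    di = d[iu]
    # mask bonded neighbours
    idx_i, idx_j = iu
    same_chain = (idx_i < na) == (idx_j < na)
    bonded = same_chain & (idx_j - idx_i == 1)
    overlap = np.clip(config.ev_radius - di, 0.0, None)
    overlap[bonded] = 0.0
    e = float(config.ev_weight * np.sum(overlap**2))
    for arr in (conf.coords_a, conf.coords_b):
        if len(arr) > 2:
            u = np.diff(arr, axis=0)
            u = u / np.linalg.norm(u, axis=1, keepdims=True)
            cosphi = np.sum(u[:-1] * u[1:], axis=1)
            e += float(config.bend_weight * np.sum(1.0 - cosphi))
    return e


def constraint_penalty(
    conf: Conformation3D,
    constraint: ConstraintStructure,
    params: GeometryParams = DEFAULT_GEOMETRY,
    k: float = 1.0,
) -> float:
    """Flat-bottom quadratic penalty on the pairing window.

    Each required pair contributes ``k*max(0, d-d_hi)^2 + k*max(0, d_lo-d)^2``.
    A forced-unpaired position contributes ``k*max(0, d_hi - d_nearest)^2``
    when any pairing candidate currently sits within the window.  Zero iff
    every constraint is geometrically satisfied.
    """
    if (
        constraint.system.chain_a != conf.system.chain_a
        or constraint.system.chain_b != conf.system.chain_b
    ):
        raise ValueError("constraint and conformation are over different systems")
    d_lo, d_hi = params.pair_window
    total = 0.0
    for bp in constraint.required_pairs:
        d = float(np.linalg.norm(conf.coord(bp.p) - conf.coord(bp.q)))
        total += k * max(0.0, d - d_hi) ** 2 + k * max(0.0, d_lo - d) ** 2
    if constraint.forced_unpaired:
        coords = conf.all_coords
        na = len(conf.system.chain_a)
        for pos in constraint.forced_unpaired:
            x = conf.coord(pos)
            flat = pos.index - 1 if pos.chain == "A" else na + pos.index - 1
            d_all = np.linalg.norm(coords - x, axis=1)
            # pairing candidates: other chain, or same chain with |i-j| >= 4
            idx = np.arange(len(coords))
            same = (idx < na) == (flat < na)
            sep = np.abs(idx - flat)
            cand = (~same) | (sep >= 4)
            cand[flat] = False
            dc = d_all[cand]
            in_window = dc[(dc >= d_lo) & (dc <= d_hi)]
            if in_window.size:
                total += k * max(0.0, d_hi - float(dc.min())) ** 2
    return total


def total_energy(
    conf: Conformation3D,
    constraint: ConstraintStructure,
    config: SamplerConfig,
    params: GeometryParams = DEFAULT_GEOMETRY,
) -> tuple[float, float]:
    return (
        base_energy(conf, config, params),
        constraint_penalty(conf, constraint, params, config.constraint_weight),
    )


# ---------------------------------------------------------------------------
# moves (all preserve bond lengths exactly)


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    return np.array(
        [
            [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
            [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
            [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
        ]
    )


def _propose(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    rng: np.random.Generator,
    config: SamplerConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """One move proposal: crankshaft, end pivot, or rigid chain-B move."""
    weights = np.asarray(config.move_weights, dtype=float)
    kind = rng.choice(3, p=weights / weights.sum())
    arrs = [coords_a.copy(), coords_b.copy()]
    max_angle = np.radians(config.max_rotate)
    if kind == 0:  # crankshaft: rotate interior segment about its endpoint axis
        which = int(rng.integers(2))
        arr = arrs[which]
        n = len(arr)
        if n < 3:
            kind = 1
        else:
            # short segments dominate: local register adjustments are the
            # moves that still get accepted in a nearly-zipped duplex
            i = int(rng.integers(0, n - 2))
            span = 2 + int(rng.geometric(0.45)) - 1
            j = min(i + max(2, span), n - 1)
            axis = arr[j] - arr[i]
            if np.linalg.norm(axis) < 1e-9:
                return arrs[0], arrs[1]
            rot = _rotation_about_axis(axis, rng.uniform(-max_angle, max_angle))
            seg = arr[i + 1 : j] - arr[i]
            arr[i + 1 : j] = seg @ rot.T + arr[i]
            return arrs[0], arrs[1]
    if kind == 1:  # end pivot: rotate a terminal segment about a pivot bead
        which = int(rng.integers(2))
        arr = arrs[which]
        n = len(arr)
        if n < 2:
            kind = 2
        else:
            p = int(rng.integers(0, n))
            axis = rng.normal(size=3)
            if rng.random() < 0.5 and p > 0:
                seg_len = p
                damp = 1.0 / np.sqrt(seg_len)
                rot = _rotation_about_axis(
                    axis, rng.uniform(-max_angle, max_angle) * damp
                )
                seg = arr[:p] - arr[p]
                arr[:p] = seg @ rot.T + arr[p]
            elif p < n - 1:
                seg_len = n - 1 - p
                damp = 1.0 / np.sqrt(seg_len)
                rot = _rotation_about_axis(
                    axis, rng.uniform(-max_angle, max_angle) * damp
                )
                seg = arr[p + 1 :] - arr[p]
                arr[p + 1 :] = seg @ rot.T + arr[p]
            return arrs[0], arrs[1]
    # rigid move of chain B relative to chain A
    arr = arrs[1]
    center = arr.mean(axis=0)
    rot = _rotation_about_axis(rng.normal(size=3), rng.uniform(-max_angle, max_angle))
    shift = rng.uniform(-config.max_translate, config.max_translate, size=3)
    arrs[1] = (arr - center) @ rot.T + center + shift
    return arrs[0], arrs[1]


def _make_evaluator(
    start: Conformation3D,
    constraint: ConstraintStructure,
    config: SamplerConfig,
    params: GeometryParams,
) -> Callable[[np.ndarray, np.ndarray], tuple[bool, float, float]]:
    """Vectorised (clash?, base_energy, constraint_penalty) evaluator.

    Agrees with :func:`base_energy` / :func:`constraint_penalty` to
    floating-point accuracy; exists because the sampler evaluates every
    proposal.
    """
    na = len(start.system.chain_a)
    nb = len(start.system.chain_b)
    n = na + nb
    idx = np.arange(n)
    on_b = idx >= na
    resi = np.where(on_b, idx - na, idx)
    same_chain = on_b[:, None] == on_b[None, :]
    bonded = same_chain & (np.abs(resi[:, None] - resi[None, :]) == 1)
    iu = np.triu_indices(n, k=1)
    nonbond = ~bonded[iu]
    d_lo, d_hi = params.pair_window
    k = config.constraint_weight

    def flat(pos: Position) -> int:
        return pos.index - 1 if pos.chain == "A" else na + pos.index - 1

    req = np.array(
        [[flat(bp.p), flat(bp.q)] for bp in sorted(
            constraint.required_pairs, key=lambda b: (b.p, b.q)
        )],
        dtype=int,
    ).reshape(-1, 2)
    forced = sorted(constraint.forced_unpaired)
    forced_rows = []
    for pos in forced:
        f = flat(pos)
        cand = (~same_chain[f]) | (np.abs(resi - resi[f]) >= 4)
        cand[f] = False
        forced_rows.append((f, cand))

    def evaluate(ca: np.ndarray, cb: np.ndarray) -> tuple[bool, float, float]:
        coords = np.vstack([ca, cb])
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=2))
        di = d[iu][nonbond]
        if np.any(di < params.clash_dist):
            return True, 0.0, 0.0
        overlap = np.clip(config.ev_radius - di, 0.0, None)
        be = float(config.ev_weight * np.sum(overlap**2))
        for arr in (ca, cb):
            if len(arr) > 2:
                u = np.diff(arr, axis=0)
                u = u / np.linalg.norm(u, axis=1, keepdims=True)
                cosphi = np.sum(u[:-1] * u[1:], axis=1)
                be += float(config.bend_weight * np.sum(1.0 - cosphi))
        cp = 0.0
        if len(req):
            dr = d[req[:, 0], req[:, 1]]
            cp += float(
                k * np.sum(np.clip(dr - d_hi, 0.0, None) ** 2)
                + k * np.sum(np.clip(d_lo - dr, 0.0, None) ** 2)
            )
        for f, cand in forced_rows:
            dc = d[f][cand]
            in_window = dc[(dc >= d_lo) & (dc <= d_hi)]
            if in_window.size:
                cp += k * max(0.0, d_hi - float(dc.min())) ** 2
        return False, be, cp

    return evaluate


def sample(
    start: Conformation3D,
    constraint: ConstraintStructure,
    config: SamplerConfig,
    params: GeometryParams = DEFAULT_GEOMETRY,
) -> Trajectory:
    """Run the constrained Metropolis sampler from *start*.

    Acceptance is ``exp(-dE / temperature)`` on the total energy; any
    proposal with a clash (closer than ``clash_dist``) is rejected before
    energy evaluation.  Identical inputs and seed give an identical
    trajectory.  Frames are recorded every ``record_every`` iterations
    plus the final frame; with ``n_step == 0`` only the start frame is
    returned.
    """
    start.validate(params)
    if clash_count(start, params.clash_dist) > 0:
        raise ValueError("start conformation contains clashes")
    rng = np.random.default_rng(config.seed)
    ca, cb = start.coords_a.copy(), start.coords_b.copy()
    evaluate = _make_evaluator(start, constraint, config, params)

    clash0, cur_be, cur_cp = evaluate(ca, cb)

    def snapshot(step: int) -> TrajectoryFrame:
        conf = Conformation3D(
            start.system, ca.copy(), cb.copy(), provenance=f"toy_mc:step={step}"
        )
        return TrajectoryFrame(conf, cur_be, cur_cp, step)

    frames = [snapshot(0)]
    record_every = config.effective_record_every
    temp = max(config.temperature, 1e-12)
    for step in range(1, config.n_step + 1):
        pa, pb = _propose(ca, cb, rng, config)
        clash, be, cp = evaluate(pa, pb)
        if clash:
            accept = False
        else:
            de = (be + cp) - (cur_be + cur_cp)
            accept = de <= 0 or rng.random() < np.exp(-de / temp)
        if accept:
            ca, cb = pa, pb
            cur_be, cur_cp = be, cp
        if step % record_every == 0:
            frames.append(snapshot(step))
    if frames[-1].step_index != config.n_step and config.n_step > 0:
        frames.append(snapshot(config.n_step))
    return Trajectory(tuple(frames), config)


def dump_trajectory_tsv(traj: Trajectory, path) -> None:
    """TSV dump: step_index, base_energy, constraint_penalty."""
    lines = ["step_index\tbase_energy\tconstraint_penalty"]
    for f in traj.frames:
        lines.append(f"{f.step_index}\t{f.base_energy:.6f}\t{f.constraint_penalty:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# external-tool adapters (optional plug-ins)


class ExternalSamplerUnavailable(RuntimeError):
    """The configured external sampler binary cannot be found."""


@dataclass
class ExternalAdapter:
    """Adapter contract for external 3D samplers.

    ``tool`` selects the restraint dialect: ``simrna-like`` writes one
    distance-restraint line per required pair; ``fragment-assembly-like``
    writes a dot-bracket constraint block.  The executable is invoked as
    ``exe restraints_file n_step seed`` and must print one frame per line
    as ``step energy restraint_energy``.  The adapter maps tool energy to
    ``base_energy`` and restraint-violation energy to
    ``constraint_penalty``.  There is never a silent fallback: a missing
    binary raises :class:`ExternalSamplerUnavailable`.
    """

    tool: str
    executable: str

    def __post_init__(self) -> None:
        if self.tool not in ("simrna-like", "fragment-assembly-like"):
            raise ValueError(f"unknown external tool kind: {self.tool!r}")

    def check_available(self) -> str:
        exe = shutil.which(self.executable) or (
            self.executable if Path(self.executable).is_file() else None
        )
        if exe is None:
            raise ExternalSamplerUnavailable(
                f"external sampler binary not found: {self.executable!r}"
            )
        return exe

    def write_restraints(self, constraint: ConstraintStructure, path) -> None:
        lines = []
        if self.tool == "simrna-like":
            d_lo, d_hi = DEFAULT_GEOMETRY.pair_window
            for bp in sorted(constraint.required_pairs, key=lambda b: (b.p, b.q)):
                lines.append(
                    f"SLOPE {bp.p.chain}/{bp.p.index} {bp.q.chain}/{bp.q.index} "
                    f"{d_lo:.1f} {d_hi:.1f} 1.0"
                )
        else:
            from .duplex2d import write_constraint

            lines.append(write_constraint(constraint))
        Path(path).write_text("\n".join(lines) + "\n")

    def sample(
        self,
        start: Conformation3D,
        constraint: ConstraintStructure,
        config: SamplerConfig,
        workdir,
    ) -> Trajectory:
        exe = self.check_available()
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
        restraints = workdir / "restraints.txt"
        self.write_restraints(constraint, restraints)
        out = subprocess.run(
            [exe, str(restraints), str(config.n_step), str(config.seed)],
            capture_output=True,
            text=True,
            check=True,
        )
        frames = []
        for line in out.stdout.splitlines():
            parts = line.split()
            if len(parts) != 3:
                continue
            step, energy, restraint_e = int(parts[0]), float(parts[1]), float(parts[2])
            frames.append(
                TrajectoryFrame(
                    conf=start.copy(provenance=f"{self.tool}:step={step}"),
                    base_energy=energy,
                    constraint_penalty=restraint_e,
                    step_index=step,
                )
            )
        if not frames:
            raise RuntimeError(f"external sampler produced no frames: {self.executable}")
        return Trajectory(tuple(frames), config)


def derive_seed(master_seed: int, run_index: int) -> int:
    """Per-run seed: ``master + run_index * 10007``, kept below 2^31."""
    return (master_seed + run_index * 10007) % (2**31)
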