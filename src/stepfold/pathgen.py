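"""2D interaction-path generation.

An interaction path is an ordered list of constraint structures that grow
a seed intermolecular helix by 1-2 bp per step toward a target (the
maximal bulge-free extension by default).  Each step's constraint keeps
the monomer (intramolecular) structure, except that intramolecular pairs
consumed by, or within a spacer of, the growing interaction are dropped
so the stems can open as the duplex zips up.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .duplex2d import (
    CANONICAL_PAIRS,
    BasePair,
    ComplexStructure,
    ConstraintStructure,
    DuplexSystem,
    Position,
    StructureError,
    parse_constraint,
    write_constraint,
)


class ExtensionScheme(enum.Enum):
    """How new target pairs are picked at each step.

    The *left* end is the side with the smaller chain-A index.
    ALTERNATING adds to one end per step, switching sides; SYMMETRIC adds
    one pair at each end simultaneously; the DIRECTIONAL schemes exhaust
    one end before extending the other.
    """

    ALTERNATING = "alternating"
    SYMMETRIC = "symmetric"
    DIRECTIONAL_LEFT = "left"
    DIRECTIONAL_RIGHT = "right"


AUTO = "AUTO"


@dataclass(frozen=True)
class InteractionPath:
    """Ordered constraint structures from seed (step 0) to target."""

    system: DuplexSystem
    steps: tuple[ConstraintStructure, ...]
    scheme: Optional[ExtensionScheme]
    spacer: int
    seed: frozenset[BasePair]
    target: frozenset[BasePair]

    def __len__(self) -> int:
        return len(self.steps)

    def validate_nesting(self) -> list[str]:
        """Return warnings for steps whose interaction sets are not nested."""
        problems = []
        prev: frozenset[BasePair] = frozenset()
        for k, step in enumerate(self.steps):
            cur = step.intermolecular_pairs
            if not prev <= cur:
                problems.append(
                    f"step {k}: intermolecular constraints not a superset of step {k - 1}"
                )
            prev = cur
        return problems


def _as_ab(bp: BasePair) -> tuple[int, int]:
    a = bp.p if bp.p.chain == "A" else bp.q
    b = bp.q if bp.p.chain == "A" else bp.p
    return a.index, b.index


def _canonical(system: DuplexSystem, i: int, j: int, allow_gu: bool) -> bool:
    ident = (system.chain_a[i - 1], system.chain_b[j - 1])
    if ident not in CANONICAL_PAIRS:
        return False
    if not allow_gu and ident in (("G", "U"), ("U", "G")):
        return False
    return True


def _check_contiguous_inter_seed(seed: Iterable[BasePair]) -> list[tuple[int, int]]:
    seed = list(seed)
    if not seed:
        raise StructureError("seed must contain at least one base pair")
    if any(not bp.intermolecular for bp in seed):
        raise StructureError("seed must consist of intermolecular pairs only")
    ab = sorted(_as_ab(bp) for bp in seed)
    for (i0, j0), (i1, j1) in zip(ab, ab[1:]):
        if i1 != i0 + 1 or j1 != j0 - 1:
            raise StructureError("seed must be a contiguous antiparallel helix")
    return ab


def max_bulge_free_extension(
    system: DuplexSystem,
    seed: Iterable[BasePair],
    allow_gu: bool = True,
) -> frozenset[BasePair]:
    """Extend a contiguous helix outward while facing residues pair.

    Extension proceeds one antiparallel position at a time on each side
    (left: smaller A index / larger B index) for as long as the facing
    residues form a canonical pair (GU wobble included iff *allow_gu*)
    and both indices stay within chain bounds.
    """
    ab = _check_contiguous_inter_seed(seed)
    (ai, bj) = ab[0]
    # left extension: A index down, B index up
    left = []
    i, j = ai - 1, bj + 1
    while i >= 1 and j <= len(system.chain_b) and _canonical(system, i, j, allow_gu):
        left.append((i, j))
        i, j = i - 1, j + 1
    (ai, bj) = ab[-1]
    right = []
    i, j = ai + 1, bj - 1
    while i <= len(system.chain_a) and j >= 1 and _canonical(system, i, j, allow_gu):
        right.append((i, j))
        i, j = i + 1, j - 1
    full = ab + left + right
    return frozenset(BasePair(Position("A", i), Position("B", j)) for i, j in full)


def _order_additions(
    seed_ab: list[tuple[int, int]],
    target_ab: list[tuple[int, int]],
    scheme: ExtensionScheme,
    step_pairs: int,
) -> list[list[tuple[int, int]]]:
    """Group the target pairs outside the seed into per-step additions.

    Target pairs are ordered by chain-A position; pairs left of the seed
    form the left queue (nearest first, i.e. descending A index), pairs
    right of it the right queue (ascending A index).  Bulged targets are
    handled naturally: a skipped residue just never appears in a queue.
    """
    seed_set = set(seed_ab)
    seed_min = min(i for i, _ in seed_ab)
    seed_max = max(i for i, _ in seed_ab)
    left_q = sorted(
        [p for p in target_ab if p not in seed_set and p[0] < seed_min], reverse=True
    )
    right_q = sorted([p for p in target_ab if p not in seed_set and p[0] > seed_max])
    inner = [p for p in target_ab if p not in seed_set and seed_min <= p[0] <= seed_max]
    if inner:
        raise StructureError("target contains pairs interleaved with the seed helix")

    additions: list[list[tuple[int, int]]] = []
    side = 0  # 0 = left, 1 = right, for ALTERNATING
    if scheme is ExtensionScheme.DIRECTIONAL_LEFT:
        order = [left_q, right_q]
    elif scheme is ExtensionScheme.DIRECTIONAL_RIGHT:
        order = [right_q, left_q]
    else:
        order = None

    while left_q or right_q:
        step: list[tuple[int, int]] = []
        if scheme is ExtensionScheme.SYMMETRIC:
            for q in (left_q, right_q):
                for _ in range(step_pairs):
                    if q:
                        step.append(q.pop(0))
        elif scheme is ExtensionScheme.ALTERNATING:
            q = left_q if (side == 0 and left_q) or not right_q else right_q
            side ^= 1
            for _ in range(step_pairs):
                if q:
                    step.append(q.pop(0))
        else:  # directional
            q = order[0] if order[0] else order[1]
            for _ in range(step_pairs):
                if q:
                    step.append(q.pop(0))
        additions.append(step)
    return additions


def _prune_intramolecular(
    intrapairs: Iterable[BasePair],
    inter_ab: list[tuple[int, int]],
    spacer: int,
) -> frozenset[BasePair]:
    """Drop intramolecular constraint pairs conflicting with the interaction.

    A pair is dropped when either of its residues is consumed by an
    interaction pair, or lies within *spacer* residues of the current
    interaction span on its chain (the spacer keeps room around the
    growing site so stems can open ahead of the zipper).
    """
    if not inter_ab:
        return frozenset(intrapairs)
    a_lo = min(i for i, _ in inter_ab) - spacer
    a_hi = max(i for i, _ in inter_ab) + spacer
    b_lo = min(j for _, j in inter_ab) - spacer
    b_hi = max(j for _, j in inter_ab) + spacer

    def blocked(pos: Position) -> bool:
        lo, hi = (a_lo, a_hi) if pos.chain == "A" else (b_lo, b_hi)
        return lo <= pos.index <= hi

    return frozenset(
        bp for bp in intrapairs if not (blocked(bp.p) or blocked(bp.q))
    )


def generate_path(
    system: DuplexSystem,
    seed: Iterable[BasePair],
    target=AUTO,
    scheme: ExtensionScheme = ExtensionScheme.SYMMETRIC,
    step_pairs: int = 1,
    spacer: int = 2,
    intramolecular: Optional[ComplexStructure] = None,
    allow_gu: bool = True,
) -> InteractionPath:
    """Generate the constraint path from *seed* to *target*.

    ``target=AUTO`` resolves the target via :func:`max_bulge_free_extension`.
    Step 0 constrains exactly the seed; each later step adds *step_pairs*
    target pairs per extended end according to *scheme*.  At every step
    intramolecular constraints that conflict with (or sit within *spacer*
    residues of) the current interaction span are dropped.
    """
    seed = frozenset(seed)
    seed_ab = _check_contiguous_inter_seed(seed)
    if target == AUTO:
        target = max_bulge_free_extension(system, seed, allow_gu=allow_gu)
    target = frozenset(target)
    if not seed <= target:
        raise StructureError("seed must be a subset of the target interaction")
    if any(not bp.intermolecular for bp in target):
        raise StructureError("target must consist of intermolecular pairs")
    # validate target consistency (one partner per position)
    ComplexStructure(system, target)
    target_ab = sorted(_as_ab(bp) for bp in target)
    if step_pairs not in (1, 2):
        raise StructureError("step_pairs must be 1 or 2")

    intrapairs = frozenset(intramolecular.pairs) if intramolecular is not None else frozenset()
    if any(bp.intermolecular for bp in intrapairs):
        raise StructureError("intramolecular structure must not contain intermolecular pairs")

    additions = _order_additions(seed_ab, target_ab, scheme, step_pairs)
    steps = []
    current = list(seed_ab)
    for add in [[]] + additions:
        current = sorted(current + add)
        inter_pairs = frozenset(
            BasePair(Position("A", i), Position("B", j)) for i, j in current
        )
        intra = _prune_intramolecular(intrapairs, current, spacer)
        steps.append(ConstraintStructure(system, inter_pairs | intra))
    return InteractionPath(
        system=system,
        steps=tuple(steps),
        scheme=scheme,
        spacer=spacer,
        seed=seed,
        target=target,
    )


# ---------------------------------------------------------------------------
# path files: header lines then one TSV row (step_index, constraint) per step


def write_path_file(path_obj: InteractionPath, path) -> None:
    lines = [
        f"# system\t{path_obj.system.name}\t{path_obj.system.chain_a}\t{path_obj.system.chain_b}",
        f"# scheme\t{path_obj.scheme.value if path_obj.scheme else 'explicit'}",
        f"# spacer\t{path_obj.spacer}",
    ]
    for k, step in enumerate(path_obj.steps):
        lines.append(f"{k}\t{write_constraint(step)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_path_file(path) -> InteractionPath:
    """Load an explicit path file (user hypothesis: nesting only warned)."""
    name, chain_a, chain_b = "duplex", None, None
    scheme: Optional[ExtensionScheme] = None
    spacer = 0
    rows: list[tuple[int, str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            fields = line[1:].strip().split("\t")
            key = fields[0]
            if key == "system":
                name, chain_a, chain_b = fields[1], fields[2], fields[3]
            elif key == "scheme":
                scheme = None if fields[1] == "explicit" else ExtensionScheme(fields[1])
            elif key == "spacer":
                spacer = int(fields[1])
            continue
        idx_s, db = line.split("\t")
        rows.append((int(idx_s), db))
    if chain_a is None:
        raise StructureError("path file missing '# system' header")
    system = DuplexSystem(name, chain_a, chain_b)
    rows.sort(key=lambda r: r[0])
    steps = []
    for _, db in rows:
        steps.append(parse_constraint(db, system=system))
    if not steps:
        raise StructureError("path file contains no steps")
    path_obj = InteractionPath(
        system=system,
        steps=tuple(steps),
        scheme=scheme,
        spacer=spacer,
        seed=steps[0].intermolecular_pairs,
        target=steps[-1].intermolecular_pairs,
    )
    for msg in path_obj.validate_nesting():
        warnings.warn(f"path file {path}: {msg}", stacklevel=2)
    return path_obj
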