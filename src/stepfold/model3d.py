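"""Coarse-grained 3D representation: one bead per nucleotide.

The bead sits at a C3'-like position.  This resolution preserves what the
feasibility question needs -- connectivity, reach, and excluded volume --
while keeping sampling cheap.  Geometric defaults (6 A bonds, a 14-20 A
pairing window, 4 A clash distance, A-form-like helix constants) are
package choices recorded in :class:`GeometryParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .duplex2d import (
    BasePair,
    ComplexStructure,
    DuplexSystem,
    Position,
    StructureError,
)


@dataclass(frozen=True)
class GeometryParams:
    """Geometric constants of the one-bead model (Angstrom / degrees)."""

    bond_len: float = 6.0
    bond_tol: float = 0.75
    clash_dist: float = 4.0
    pair_window: tuple[float, float] = (13.0, 16.0)
    helix_rise: float = 2.8
    helix_twist: float = 32.7
    helix_radius: float = 9.0
    #: angular offset of the partner strand; 92.6 deg ~ 2*asin(d_lo/2R)
    #: puts the partner just above d_lo (13.01 A).  In an ideal helix no
    #: other bead is then an in-window candidate at all: the near
    #: cross-strand diagonal falls below the window and the far diagonal
    #: and the 4-apart same-strand contact fall beyond d_hi, so mutual-best
    #: annotation recovers ideal helices essentially always (a stray bead
    #: could only steal a partner from the sliver [13.0, 13.01)).
    pair_phase: float = 92.6

    def __post_init__(self) -> None:
        d_lo, d_hi = self.pair_window
        if not (0 < d_lo < d_hi):
            raise ValueError("pair_window must satisfy 0 < d_lo < d_hi")
        for name in ("bond_len", "clash_dist", "helix_rise", "helix_twist", "helix_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_GEOMETRY = GeometryParams()


class ConformationError(ValueError):
    """Invalid 3D conformation or PDB content."""


@dataclass
class Conformation3D:
    """Bead coordinates for the two chains, 5'->3', in Angstrom."""

    system: DuplexSystem
    coords_a: np.ndarray
    coords_b: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coords_a = np.asarray(self.coords_a, dtype=float)
        self.coords_b = np.asarray(self.coords_b, dtype=float)
        if self.coords_a.shape != (len(self.system.chain_a), 3):
            raise ConformationError(
                f"chain A bead count {self.coords_a.shape} != chain length "
                f"{len(self.system.chain_a)}"
            )
        if self.coords_b.shape != (len(self.system.chain_b), 3):
            raise ConformationError(
                f"chain B bead count {self.coords_b.shape} != chain length "
                f"{len(self.system.chain_b)}"
            )

    @property
    def all_coords(self) -> np.ndarray:
        return np.vstack([self.coords_a, self.coords_b])

    def coord(self, pos: Position) -> np.ndarray:
        arr = self.coords_a if pos.chain == "A" else self.coords_b
        return arr[pos.index - 1]

    def copy(self, provenance: Optional[str] = None) -> "Conformation3D":
        return Conformation3D(
            self.system,
            self.coords_a.copy(),
            self.coords_b.copy(),
            self.provenance if provenance is None else provenance,
        )

    def bond_violations(self, params: GeometryParams = DEFAULT_GEOMETRY) -> int:
        n = 0
        for arr in (self.coords_a, self.coords_b):
            if len(arr) > 1:
                d = np.linalg.norm(np.diff(arr, axis=0), axis=1)
                n += int(np.sum(np.abs(d - params.bond_len) > params.bond_tol))
        return n

    def validate(self, params: GeometryParams = DEFAULT_GEOMETRY) -> None:
        nb = self.bond_violations(params)
        if nb:
            raise ConformationError(f"{nb} bond lengths outside tolerance")


# ---------------------------------------------------------------------------
# PDB I/O (one pseudo-atom per residue)

_REPRESENTATIVE_PRIORITY = ("C3'", "P", "C1'")
_NUCLEIC_RESNAMES = {
    "A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU",
    "RA", "RC", "RG", "RU", "ADE", "CYT", "GUA", "URA", "URI", "THY",
}


def read_pdb(path, system: Optional[DuplexSystem] = None) -> Conformation3D:
    """Read a (possibly full-atom) PDB into a one-bead conformation.

    For every residue the first available representative atom is taken,
    priority C3' > P > C1'.  Exactly two nucleic-acid chains are required;
    they map to chains A and B in file order.  When *system* is given the
    residue counts must match; otherwise the sequence is taken from the
    residue names.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains = []
    for chain in model:
        beads, seq = [], []
        for res in chain:
            if res.name.strip() not in _NUCLEIC_RESNAMES:
                continue
            atom = None
            for name in _REPRESENTATIVE_PRIORITY:
                atom = res.find_atom(name, "*")
                if atom is not None:
                    break
            if atom is None:
                raise ConformationError(
                    f"residue {chain.name}/{res.seqid.num} {res.name} has no "
                    f"representative atom ({'/'.join(_REPRESENTATIVE_PRIORITY)})"
                )
            beads.append([atom.pos.x, atom.pos.y, atom.pos.z])
            one = res.name.strip()[-1].upper().replace("T", "U")
            seq.append(one if one in "ACGU" else "A")
        if beads:
            chains.append((np.array(beads), "".join(seq)))
    if len(chains) != 2:
        raise ConformationError(f"expected 2 nucleic-acid chains in PDB, found {len(chains)}")
    (ca, sa), (cb, sb) = chains
    if system is None:
        system = DuplexSystem("pdb", sa, sb)
    elif len(system.chain_a) != len(ca) or len(system.chain_b) != len(cb):
        raise ConformationError(
            "PDB chain lengths do not match the bound duplex system"
        )
    return Conformation3D(system, ca, cb, provenance=f"file:{path}")


def write_pdb(conf: Conformation3D, path) -> None:
    """Write one C3' pseudo-atom per residue; chain IDs A and B."""
    st = gemmi.Structure()
    st.name = conf.system.name
    model = gemmi.Model("1")
    for cid, seq, coords in (
        ("A", conf.system.chain_a, conf.coords_a),
        ("B", conf.system.chain_b, conf.coords_b),
    ):
        chain = gemmi.Chain(cid)
        for i, (res_name, xyz) in enumerate(zip(seq, coords), start=1):
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "C3'"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def write_trajectory_pdb(confs: Iterable[Conformation3D], path) -> None:
    """Multi-model PDB of recorded frames."""
    st = gemmi.Structure()
    for m, conf in enumerate(confs, start=1):
        model = gemmi.Model(str(m))
        for cid, seq, coords in (
            ("A", conf.system.chain_a, conf.coords_a),
            ("B", conf.system.chain_b, conf.coords_b),
        ):
            chain = gemmi.Chain(cid)
            for i, (res_name, xyz) in enumerate(zip(seq, coords), start=1):
                res = gemmi.Residue()
                res.name = res_name
                res.seqid = gemmi.SeqId(i, " ")
                atom = gemmi.Atom()
                atom.name = "C3'"
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*xyz)
                res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# annotation, superposition, clashes


def _candidate_mask(conf: Conformation3D) -> tuple[np.ndarray, np.ndarray]:
    """Flat bead indexing helpers: chain labels and residue indices."""
    na, nb = len(conf.system.chain_a), len(conf.system.chain_b)
    chains = np.array([0] * na + [1] * nb)
    indices = np.concatenate([np.arange(1, na + 1), np.arange(1, nb + 1)])
    return chains, indices


def annotate_pairs(
    conf: Conformation3D, params: GeometryParams = DEFAULT_GEOMETRY
) -> ComplexStructure:
    """Translate a 3D conformation back into a set of base pairs.

    Candidates are residue pairs i, j (|i-j| >= 4 when on the same
    chain) whose bead distance lies in the pairing window.  Candidates
    are accepted greedily by ascending distance, skipping any that would
    give a residue a second partner -- each accepted pair is therefore
    the nearest remaining candidate of both its residues.  Deterministic;
    ties break toward the smaller (chain, index).
    """
    d_lo, d_hi = params.pair_window
    coords = conf.all_coords
    chains, indices = _candidate_mask(conf)
    tree = cKDTree(coords)
    sparse = tree.query_pairs(d_hi, output_type="ndarray")
    cands = []
    for i, j in sparse:
        if chains[i] == chains[j] and abs(int(indices[i]) - int(indices[j])) < 4:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < d_lo:
            continue
        cands.append((d, int(i), int(j)))
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    taken: set[int] = set()
    pairs = []
    na = len(conf.system.chain_a)

    def to_pos(k: int) -> Position:
        return Position("A", k + 1) if k < na else Position("B", k - na + 1)

    for _, i, j in cands:
        if i in taken or j in taken:
            continue
        taken.update((i, j))
        pairs.append(BasePair(to_pos(i), to_pos(j)))
    return ComplexStructure(conf.system, frozenset(pairs), enforce_hairpin=False)


def kabsch_rotation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centred *x* onto centred *y*."""
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose_rmsd(a: Conformation3D, b: Conformation3D) -> float:
    """Least-squares RMSD after optimal rigid superposition (no reflection)."""
    xa, xb = a.all_coords, b.all_coords
    if xa.shape != xb.shape:
        raise ConformationError("superpose_rmsd requires equal bead counts")
    ca, cb = xa - xa.mean(axis=0), xb - xb.mean(axis=0)
    rot = kabsch_rotation(ca, cb)
    diff = ca @ rot.T - cb
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def clash_count(conf: Conformation3D, clash_dist: Optional[float] = None) -> int:
    """Number of non-bonded bead pairs closer than *clash_dist*."""
    if clash_dist is None:
        clash_dist = DEFAULT_GEOMETRY.clash_dist
    coords = conf.all_coords
    chains, indices = _candidate_mask(conf)
    tree = cKDTree(coords)
    close = tree.query_pairs(clash_dist, output_type="ndarray")
    n = 0
    for i, j in close:
        if chains[i] == chains[j] and abs(int(indices[i]) - int(indices[j])) == 1:
            continue  # bonded neighbours
        n += 1
    return int(n)


# ---------------------------------------------------------------------------
# ideal-geometry sketching


@dataclass
class _Helix:
    """A maximal stack of consecutive pairs.

    strand1: positions along the first strand in ascending traversal
    order; strand2[k] pairs strand1[k].
    """

    strand1: list[Position]
    strand2: list[Position]

    def __len__(self) -> int:
        return len(self.strand1)


def find_helices(structure: ComplexStructure) -> list[_Helix]:
    """Maximal stacks (i,j),(i+1,j-1),... over intra- and intermolecular pairs."""
    remaining = {(bp.p, bp.q) for bp in structure.pairs}
    by_p = {p: q for p, q in remaining}
    helices = []
    for p, q in sorted(remaining):
        if (p, q) not in remaining:
            continue
        prev = (Position(p.chain, p.index - 1) if p.index > 1 else None)
        nxt_q = Position(q.chain, q.index + 1) if q.index < structure.system.length(q.chain) else None
        if prev is not None and nxt_q is not None and by_p.get(prev) == nxt_q and (prev, nxt_q) in remaining:
            continue  # not a helix start; will be reached from its outermost pair
        s1, s2 = [p], [q]
        while True:
            np_ = Position(p.chain, p.index + 1)
            if q.index <= 1:
                break
            nq = Position(q.chain, q.index - 1)
            if np_.index > structure.system.length(p.chain):
                break
            if by_p.get(np_) == nq and (np_, nq) in remaining:
                p, q = np_, nq
                s1.append(p)
                s2.append(q)
            else:
                break
        for pp, qq in zip(s1, s2):
            remaining.discard((pp, qq))
        helices.append(_Helix(s1, s2))
    return helices


def ideal_helix_coords(n: int, params: GeometryParams) -> tuple[np.ndarray, np.ndarray]:
    """Local coordinates of an ideal two-start helix of *n* pairs.

    Returns (strand1, strand2) arrays; strand2[k] pairs strand1[k] at the
    same z, offset by ``pair_phase`` around the axis.
    """
    t = math.radians(params.helix_twist)
    phase = math.radians(params.pair_phase)
    r = params.helix_radius
    ks = np.arange(n)
    s1 = np.stack(
        [r * np.cos(ks * t), r * np.sin(ks * t), ks * params.helix_rise], axis=1
    )
    s2 = np.stack(
        [r * np.cos(ks * t + phase), r * np.sin(ks * t + phase), ks * params.helix_rise],
        axis=1,
    )
    return s1, s2


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _arc_guess(
    start: np.ndarray,
    end: np.ndarray,
    n: int,
    bond_len: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Initial guess for a bridge: beads on a circular arc in a random plane.

    The arc has the segment's contour length, so slack bulges outward (as
    loops do) instead of crumpling onto the chord.
    """
    chord_vec = end - start
    gap = float(np.linalg.norm(chord_vec))
    contour = (n + 1) * bond_len
    ratio = min(gap / contour, 0.999)
    # solve sin(t/2)/(t/2) = ratio for the arc's central angle t in (0, 2pi)
    from scipy.optimize import brentq

    f = lambda t: np.sin(t / 2.0) / (t / 2.0) - ratio
    theta = brentq(f, 1e-6, 2.0 * np.pi - 1e-6)
    radius = contour / theta
    u = chord_vec / max(gap, 1e-9)
    w = rng.normal(size=3)
    w -= u * (w @ u)
    norm = np.linalg.norm(w)
    if norm < 1e-9:
        w = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        w -= u * (w @ u)
        norm = np.linalg.norm(w)
    w /= norm
    mid = 0.5 * (start + end)
    center = mid - w * radius * np.cos(theta / 2.0)
    # angles of start/end around the center in the (u, w) plane
    phis = np.linspace(-theta / 2.0, theta / 2.0, n + 2)[1:-1]
    pts = center[None, :] + radius * (
        np.sin(phis)[:, None] * u[None, :] + np.cos(phis)[:, None] * w[None, :]
    )
    return pts


def _bridge_once(
    start: np.ndarray,
    end: np.ndarray,
    n: int,
    params: GeometryParams,
    rng: np.random.Generator,
) -> Optional[np.ndarray]:
    pts = _arc_guess(start, end, n, params.bond_len, rng)
    pts = pts + rng.normal(scale=0.3, size=pts.shape)
    chain = np.vstack([start, pts, end])
    for _ in range(200):
        vec = np.diff(chain, axis=0)
        dist = np.linalg.norm(vec, axis=1)
        if np.all(np.abs(dist - params.bond_len) <= params.bond_tol * 0.9):
            return chain[1:-1]
        for k in range(len(vec)):
            d = dist[k]
            if d < 1e-9:
                chain[k + 1] += rng.normal(scale=0.1, size=3)
                continue
            err = (d - params.bond_len) / d
            corr = 0.5 * err * vec[k]
            if k > 0:
                chain[k] += corr
            if k + 1 < len(chain) - 1:
                chain[k + 1] -= corr
        vec = np.diff(chain, axis=0)
        dist = np.linalg.norm(vec, axis=1)
    return None


def _bridge(
    start: np.ndarray,
    end: np.ndarray,
    n: int,
    params: GeometryParams,
    rng: np.random.Generator,
    existing: Optional[np.ndarray] = None,
) -> Optional[np.ndarray]:
    """Place *n* beads between two fixed endpoints with ~bond_len bonds.

    Beads start on the straight line with a random perpendicular
    perturbation, then bond lengths are relaxed by iterative projection;
    candidates clashing with *existing* beads are re-drawn a few times.
    Returns None when the gap is unreachable with n+1 bonds or no
    clash-light candidate is found.
    """
    gap = float(np.linalg.norm(end - start))
    max_reach = (n + 1) * (params.bond_len + params.bond_tol * 0.5)
    if gap > max_reach:
        return None
    best = None
    for _ in range(12):
        pts = _bridge_once(start, end, n, params, rng)
        if pts is None:
            continue
        if existing is not None and len(existing):
            dmin = np.min(
                np.linalg.norm(existing[None, :, :] - pts[:, None, :], axis=2)
            )
            if dmin < params.clash_dist:
                best = pts if best is None else best
                continue
        return pts
    return best


def _saw_tail(
    anchor: np.ndarray,
    n: int,
    params: GeometryParams,
    rng: np.random.Generator,
    direction: int = 1,
) -> np.ndarray:
    """Self-avoiding random-walk tail of *n* beads from *anchor*.

    Direction persistence keeps tails locally extended; global clash
    rejection enforces self-avoidance against the rest of the structure.
    """
    pts = np.empty((n, 3))
    prev = anchor
    step_dir = rng.normal(size=3)
    step_dir /= np.linalg.norm(step_dir)
    for k in range(n):
        step_dir = step_dir + 0.8 * rng.normal(size=3)
        step_dir /= np.linalg.norm(step_dir)
        prev = prev + params.bond_len * step_dir
        pts[k] = prev
    return pts if direction == 1 else pts[::-1]


class SketchError(RuntimeError):
    """Clash-free ideal-geometry placement not found within the attempt budget."""


def sketch_structure(
    system: DuplexSystem,
    structure: ComplexStructure,
    params: GeometryParams = DEFAULT_GEOMETRY,
    seed: int = 0,
    max_attempts: int = 1000,
    require: str = "helices",
) -> Conformation3D:
    """Build a clash-free conformation realising *structure*.

    Helices are placed on ideal two-start geometry with seeded random
    orientations; loops and junction strands bridge between fixed
    endpoints; free tails are self-avoiding walks.  The whole sketch is
    rejection-resampled until it is clash-free and, per *require*, until
    geometric annotation recovers every helix of >= 2 pairs ("helices",
    the default) or equals the structure's canonical pairs exactly
    ("exact"); "none" skips the annotation check.
    """
    rng = np.random.default_rng(seed)
    helices = find_helices(structure)
    na, nb = len(system.chain_a), len(system.chain_b)
    stats = {"helix": 0, "bridge": 0, "bond": 0, "clash": 0, "recovery": 0}
    sketch_structure.last_stats = stats

    for attempt in range(max_attempts):
        coords: dict[Position, np.ndarray] = {}
        ok = True
        # --- place helices in traversal order of their first residue
        for hx in sorted(helices, key=lambda h: (h.strand1[0].chain, h.strand1[0].index)):
            s1_local, s2_local = ideal_helix_coords(len(hx), params)
            # helix end beads and their local coordinates
            end_list = [
                (hx.strand1[0], 0, "s1"),
                (hx.strand1[-1], len(hx) - 1, "s1"),
                (hx.strand2[0], 0, "s2"),
                (hx.strand2[-1], len(hx) - 1, "s2"),
            ]

            def nearest_placed(pos: Position) -> Optional[tuple[Position, int]]:
                found = None
                for away in range(1, system.length(pos.chain)):
                    for delta in (-1, 1):
                        idx = pos.index + delta * away
                        if 1 <= idx <= system.length(pos.chain):
                            cand = Position(pos.chain, idx)
                            if cand in coords:
                                return (cand, away)
                return found

            # anchor through the end whose placed neighbour is closest in sequence
            anchor = None
            for pos, k, strand in end_list:
                hit = nearest_placed(pos)
                if hit is not None and (anchor is None or hit[1] < anchor[3]):
                    anchor = (pos, k, strand, hit[1], hit[0])
            placed = False
            for _ in range(40):
                rot = _random_rotation(rng)
                g1 = s1_local @ rot.T
                g2 = s2_local @ rot.T

                # direct bonds (adjacent placed residues) pin the translation
                direct = []
                for pos, k, strand in end_list:
                    hit = nearest_placed(pos)
                    if hit is not None and hit[1] == 1:
                        g_end = (g1 if strand == "s1" else g2)[k]
                        direct.append(coords[hit[0]] - g_end)
                if len(direct) >= 2:
                    # translation on the intersection of two bond spheres
                    c1, c2 = direct[0], direct[1]
                    dd = float(np.linalg.norm(c2 - c1))
                    if dd > 2 * params.bond_len - 1e-6 or dd < 1e-9:
                        continue
                    nrm = (c2 - c1) / dd
                    rho = math.sqrt(params.bond_len**2 - (dd / 2.0) ** 2)
                    e1 = np.cross(nrm, [1.0, 0.0, 0.0])
                    if np.linalg.norm(e1) < 1e-6:
                        e1 = np.cross(nrm, [0.0, 1.0, 0.0])
                    e1 /= np.linalg.norm(e1)
                    e2 = np.cross(nrm, e1)
                    phi = rng.uniform(0, 2 * np.pi)
                    trans = 0.5 * (c1 + c2) + rho * (
                        np.cos(phi) * e1 + np.sin(phi) * e2
                    )
                elif len(direct) == 1:
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    trans = direct[0] + params.bond_len * u
                elif anchor is None:
                    if not coords:
                        offset = np.zeros(3)
                    else:
                        base = coords[next(iter(coords))]
                        offset = base + rng.normal(scale=12.0, size=3) + 15.0
                    trans = offset - g1[0]
                else:
                    _, k, strand, away, cand = anchor
                    local_end = (s1_local if strand == "s1" else s2_local)[k] @ rot.T
                    reach = away * params.bond_len
                    r = rng.uniform(params.bond_len, 0.85 * reach)
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    trans = coords[cand] + r * u - local_end
                g1t, g2t = g1 + trans, g2 + trans
                # feasibility of every other fixed connection around this helix
                feasible = True
                ends = list(zip(hx.strand1, g1t)) + list(zip(hx.strand2, g2t))
                for pos, xyz in (
                    (hx.strand1[0], g1t[0]),
                    (hx.strand1[-1], g1t[-1]),
                    (hx.strand2[0], g2t[0]),
                    (hx.strand2[-1], g2t[-1]),
                ):
                    # nearest placed residue after/before on same chain must stay reachable
                    for delta in (-1, 1):
                        steps_away = None
                        for away in range(1, 60):
                            idx = pos.index + delta * away
                            if idx < 1 or idx > system.length(pos.chain):
                                break
                            cand = Position(pos.chain, idx)
                            if cand in coords:
                                steps_away = (cand, away)
                                break
                        if steps_away is not None:
                            cand, away = steps_away
                            d = np.linalg.norm(coords[cand] - xyz)
                            if away == 1:
                                # direct bond: must already sit at bond length
                                if abs(d - params.bond_len) > params.bond_tol * 0.9:
                                    feasible = False
                                    break
                            elif d > away * params.bond_len * 0.95:
                                feasible = False
                                break
                    if not feasible:
                        break
                if feasible and coords:
                    # no interpenetration with already-placed beads
                    placed_xyz = np.array(list(coords.values()))
                    new_xyz = np.vstack([g1t, g2t])
                    dmin = np.min(
                        np.linalg.norm(
                            placed_xyz[None, :, :] - new_xyz[:, None, :], axis=2
                        )
                    )
                    if dmin < params.clash_dist * 1.2:
                        feasible = False
                if feasible:
                    for pos, xyz in ends:
                        coords[pos] = xyz
                    placed = True
                    break
            if not placed:
                ok = False
                stats["helix"] += 1
                break
        if not ok:
            continue
        # --- fill unpaired segments per chain
        for chain, n in (("A", na), ("B", nb)):
            i = 1
            while i <= n and ok:
                if Position(chain, i) in coords:
                    i += 1
                    continue
                j = i
                while j <= n and Position(chain, j) not in coords:
                    j += 1
                seg = j - i  # beads i..j-1 unplaced
                left = coords.get(Position(chain, i - 1)) if i > 1 else None
                right = coords.get(Position(chain, j)) if j <= n else None
                if left is not None and right is not None:
                    pts = _bridge(
                        left,
                        right,
                        seg,
                        params,
                        rng,
                        existing=np.array(list(coords.values())),
                    )
                    if pts is None:
                        ok = False
                        stats["bridge"] += 1
                        break
                elif left is not None:
                    pts = _saw_tail(left, seg, params, rng)
                elif right is not None:
                    pts = _saw_tail(right, seg, params, rng)[::-1]
                else:
                    # fully unpaired chain: walk from a seeded origin
                    origin = (
                        np.zeros(3)
                        if not coords
                        else rng.normal(scale=10.0, size=3) + 18.0
                    )
                    pts = np.vstack([origin, _saw_tail(origin, seg - 1, params, rng)]) if seg > 1 else origin[None, :]
                for k in range(seg):
                    coords[Position(chain, i + k)] = pts[k]
                i = j
            if not ok:
                break
        if not ok:
            continue
        conf = Conformation3D(
            system,
            np.array([coords[Position("A", i)] for i in range(1, na + 1)]),
            np.array([coords[Position("B", i)] for i in range(1, nb + 1)]),
            provenance=f"sketch:seed={seed}:attempt={attempt}",
        )
        if conf.bond_violations(params):
            stats["bond"] += 1
            continue
        if clash_count(conf, params.clash_dist) > 0:
            stats["clash"] += 1
            continue
        if require != "none":
            annotated = annotate_pairs(conf, params)
            if require == "exact":
                got_c = annotated.canonical_pairs()
                want_c = structure.canonical_pairs()
                if got_c != want_c:
                    stats["recovery"] += 1
                    continue
            else:
                wanted = {
                    (p, q)
                    for hx in helices
                    if len(hx) >= 2
                    for p, q in zip(hx.strand1, hx.strand2)
                }
                got = {(bp.p, bp.q) for bp in annotated.pairs}
                if not wanted <= got:
                    stats["recovery"] += 1
                    continue
        return conf
    raise SketchError(
        f"no clash-free placement found in {max_attempts} attempts; "
        "consider a smaller clash_dist or a less entangled structure"
    )
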