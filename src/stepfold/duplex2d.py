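"""Two-chain RNA secondary structures.

A *complex structure* is the set of intra- and intermolecular base pairs
over a two-chain system (an RNA duplex).  It is the universal 2D currency
of the package: constraint paths are written in it, sampled 3D
conformations are annotated back into it, and selection compares
structures through the base-pair distance defined on it.

Structures are serialised as extended dot-bracket strings with a ``&``
chain separator.  Crossing pair sets (kissing hairpins) use additional
bracket layers ``[]``, ``{}``, ``<>``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

#: Canonical pair identities: Watson-Crick plus GU wobble.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: Bracket layers for extended dot-bracket, in assignment priority order.
BRACKET_LAYERS: tuple[tuple[str, str], ...] = (("(", ")"), ("[", "]"), ("{", "}"), ("<", ">"))

MIN_HAIRPIN_LOOP = 3


class StructureError(ValueError):
    """Invalid secondary structure or dot-bracket text."""


def _normalize_seq(seq: str, what: str) -> str:
    s = seq.strip().upper().replace("T", "U")
    if not s:
        raise StructureError(f"{what}: empty sequence")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise StructureError(f"{what}: invalid residues {sorted(bad)}")
    return s


@dataclass(frozen=True)
class DuplexSystem:
    """The two RNA chains under study.

    Chains are labelled ``A`` and ``B`` in input order; residue indices are
    1-based throughout.
    """

    name: str
    chain_a: str
    chain_b: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chain_a", _normalize_seq(self.chain_a, "chain A"))
        object.__setattr__(self, "chain_b", _normalize_seq(self.chain_b, "chain B"))

    def length(self, chain: str) -> int:
        return len(self.chain_a) if chain == "A" else len(self.chain_b)

    def residue(self, pos: "Position") -> str:
        seq = self.chain_a if pos.chain == "A" else self.chain_b
        return seq[pos.index - 1]

    @property
    def n_total(self) -> int:
        return len(self.chain_a) + len(self.chain_b)

    def positions(self) -> Iterable["Position"]:
        for i in range(1, len(self.chain_a) + 1):
            yield Position("A", i)
        for i in range(1, len(self.chain_b) + 1):
            yield Position("B", i)


@dataclass(frozen=True, order=True)
class Position:
    """1-based residue address: chain 'A' or 'B' plus index."""

    chain: str
    index: int

    def __post_init__(self) -> None:
        if self.chain not in ("A", "B"):
            raise StructureError(f"chain must be 'A' or 'B', got {self.chain!r}")
        if self.index < 1:
            raise StructureError(f"index must be >= 1, got {self.index}")

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.chain}{self.index}"


@dataclass(frozen=True)
class BasePair:
    """An unordered residue pair, stored with p < q lexicographically."""

    p: Position
    q: Position

    def __post_init__(self) -> None:
        if self.p == self.q:
            raise StructureError("a residue cannot pair with itself")
        if self.q < self.p:
            p, q = self.q, self.p
            object.__setattr__(self, "p", p)
            object.__setattr__(self, "q", q)

    @property
    def intermolecular(self) -> bool:
        return self.p.chain != self.q.chain

    def positions(self) -> tuple[Position, Position]:
        return (self.p, self.q)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.p}-{self.q}"


def pair(chain_p: str, i: int, chain_q: str, j: int) -> BasePair:
    """Convenience constructor: ``pair('A', 1, 'B', 3)``."""
    return BasePair(Position(chain_p, i), Position(chain_q, j))


def _validate_pairs(
    system: DuplexSystem,
    pairs: Iterable[BasePair],
    enforce_hairpin: bool = True,
) -> frozenset[BasePair]:
    pairs = frozenset(pairs)
    seen: dict[Position, BasePair] = {}
    for bp in pairs:
        for pos in bp.positions():
            if pos.index > system.length(pos.chain):
                raise StructureError(f"position {pos} outside chain bounds")
            if pos in seen:
                raise StructureError(f"position {pos} participates in two pairs")
            seen[pos] = bp
        if not bp.intermolecular and enforce_hairpin:
            if bp.q.index - bp.p.index < MIN_HAIRPIN_LOOP + 1:
                raise StructureError(
                    f"intramolecular pair {bp} encloses a loop shorter than "
                    f"{MIN_HAIRPIN_LOOP} nt"
                )
    return pairs


@dataclass(frozen=True)
class ComplexStructure:
    """A set of base pairs over a :class:`DuplexSystem`.

    Each position participates in at most one pair.  Intramolecular pairs
    must enclose at least a 3 nt hairpin loop unless ``enforce_hairpin``
    is disabled (geometric annotation of 3D models may violate it).
    """

    system: DuplexSystem
    pairs: frozenset[BasePair]
    enforce_hairpin: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pairs", _validate_pairs(self.system, self.pairs, self.enforce_hairpin)
        )

    @property
    def intermolecular_pairs(self) -> frozenset[BasePair]:
        return frozenset(bp for bp in self.pairs if bp.intermolecular)

    @property
    def intramolecular_pairs(self) -> frozenset[BasePair]:
        return frozenset(bp for bp in self.pairs if not bp.intermolecular)

    def is_canonical(self, bp: BasePair) -> bool:
        return (self.system.residue(bp.p), self.system.residue(bp.q)) in CANONICAL_PAIRS

    def canonical_pairs(self) -> frozenset[BasePair]:
        return frozenset(bp for bp in self.pairs if self.is_canonical(bp))

    def partner(self, pos: Position) -> Optional[Position]:
        for bp in self.pairs:
            if bp.p == pos:
                return bp.q
            if bp.q == pos:
                return bp.p
        return None

    def replace_pairs(self, pairs: Iterable[BasePair]) -> "ComplexStructure":
        return ComplexStructure(self.system, frozenset(pairs), self.enforce_hairpin)


@dataclass(frozen=True)
class ConstraintStructure:
    """Soft constraint: pairs that must form plus positions forced unpaired.

    All other positions are unconstrained.  In constraint dot-bracket,
    ``.`` is unconstrained and ``x`` is forced unpaired.
    """

    system: DuplexSystem
    required_pairs: frozenset[BasePair]
    forced_unpaired: frozenset[Position] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "required_pairs", _validate_pairs(self.system, self.required_pairs)
        )
        object.__setattr__(self, "forced_unpaired", frozenset(self.forced_unpaired))
        occupied = {pos for bp in self.required_pairs for pos in bp.positions()}
        overlap = occupied & self.forced_unpaired
        if overlap:
            raise StructureError(f"positions both paired and forced unpaired: {sorted(overlap)}")
        for pos in self.forced_unpaired:
            if pos.index > self.system.length(pos.chain):
                raise StructureError(f"forced-unpaired position {pos} outside chain bounds")

    @property
    def intermolecular_pairs(self) -> frozenset[BasePair]:
        return frozenset(bp for bp in self.required_pairs if bp.intermolecular)

    def as_structure(self) -> ComplexStructure:
        return ComplexStructure(self.system, self.required_pairs)


@dataclass(frozen=True)
class InteractionMetrics:
    """Interaction-length summary of one complex structure.

    n_inter
        total number of intermolecular pairs.
    longest_perfect
        longest contiguous intermolecular helix: a run of pairs
        (i,j), (i+1,j-1), ... with no interruptions.
    with_loops
        number of intermolecular pairs in the largest interaction *site*,
        where consecutive pairs may be separated by up to ``gap_limit``
        unpaired residues on each strand (bulges / small interior loops).
    """

    n_inter: int
    longest_perfect: int
    with_loops: int

    def __post_init__(self) -> None:
        if not (self.longest_perfect <= self.with_loops <= self.n_inter):
            raise ValueError("metrics must satisfy longest_perfect <= with_loops <= n_inter")


# ---------------------------------------------------------------------------
# dot-bracket I/O


def _positions_of(text_len_a: int, flat_index: int) -> Position:
    if flat_index < text_len_a:
        return Position("A", flat_index + 1)
    return Position("B", flat_index - text_len_a + 1)


def parse_dotbracket(
    text: str,
    system: Optional[DuplexSystem] = None,
    name: str = "duplex",
) -> ComplexStructure:
    """Parse an extended two-chain dot-bracket string into a structure.

    The string must contain exactly one ``&`` separating chain A from
    chain B.  Bracket layers ``() [] {} <>`` may cross each other, which
    is how kissing-hairpin complexes are written.  ``.`` ``x`` ``,`` are
    treated as unpaired.  If *system* is omitted, a placeholder system of
    ``N``-free 'A' residues is created (structure-only parsing is enough
    for topology metrics but canonical filters then see all-'A' chains).
    """
    if text.count("&") != 1:
        raise StructureError("dot-bracket must contain exactly one '&' chain separator")
    a_part, b_part = text.split("&")
    len_a, len_b = len(a_part), len(b_part)
    if system is None:
        system = DuplexSystem(name, "A" * len_a or "A", "A" * len_b or "A")
    if len_a != len(system.chain_a) or len_b != len(system.chain_b):
        raise StructureError(
            f"dot-bracket lengths {len_a}&{len_b} do not match system "
            f"{len(system.chain_a)}&{len(system.chain_b)}"
        )
    flat = a_part + b_part
    stacks: dict[str, list[int]] = {op: [] for op, _ in BRACKET_LAYERS}
    closer_of = {cl: op for op, cl in BRACKET_LAYERS}
    pairs: list[BasePair] = []
    for k, ch in enumerate(flat):
        if ch in stacks:
            stacks[ch].append(k)
        elif ch in closer_of:
            op = closer_of[ch]
            if not stacks[op]:
                raise StructureError(
                    f"unbalanced bracket layer '{op}{ch}': unmatched '{ch}' at offset {k}"
                )
            i = stacks[op].pop()
            pairs.append(BasePair(_positions_of(len_a, i), _positions_of(len_a, k)))
        elif ch in ".x,~":
            continue
        else:
            raise StructureError(f"unexpected character {ch!r} at offset {k}")
    for op, stack in stacks.items():
        if stack:
            raise StructureError(
                f"unbalanced bracket layer '{op}': unmatched '{op}' at offset {stack[-1]}"
            )
    return ComplexStructure(system, frozenset(pairs))


def parse_constraint(
    text: str, system: Optional[DuplexSystem] = None, name: str = "duplex"
) -> ConstraintStructure:
    """Parse constraint dot-bracket: brackets = required pairs, 'x' = forced unpaired."""
    structure = parse_dotbracket(text, system=system, name=name)
    a_part, b_part = text.split("&")
    forced = set()
    for chain, part in (("A", a_part), ("B", b_part)):
        for i, ch in enumerate(part):
            if ch == "x":
                forced.add(Position(chain, i + 1))
    return ConstraintStructure(structure.system, structure.pairs, frozenset(forced))


def _flat_index(system: DuplexSystem, pos: Position) -> int:
    return pos.index - 1 if pos.chain == "A" else len(system.chain_a) + pos.index - 1


def write_dotbracket(
    structure: ComplexStructure,
    forced_unpaired: Iterable[Position] = (),
) -> str:
    """Serialise a structure to extended dot-bracket.

    Bracket layers are assigned greedily: pairs sorted by opening index
    take the first layer in which they cross no already-assigned pair.
    """
    system = structure.system
    spans = sorted(
        (_flat_index(system, bp.p), _flat_index(system, bp.q)) for bp in structure.pairs
    )
    layers: list[list[tuple[int, int]]] = []
    assignment: dict[tuple[int, int], int] = {}

    def crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
        (i, j), (k, l) = a, b
        return (i < k < j < l) or (k < i < l < j)

    for span in spans:
        for li, members in enumerate(layers):
            if not any(crosses(span, m) for m in members):
                members.append(span)
                assignment[span] = li
                break
        else:
            if len(layers) >= len(BRACKET_LAYERS):
                raise StructureError(
                    f"structure needs more than {len(BRACKET_LAYERS)} bracket layers"
                )
            layers.append([span])
            assignment[span] = len(layers) - 1
    chars = ["."] * system.n_total
    for span, li in assignment.items():
        op, cl = BRACKET_LAYERS[li]
        chars[span[0]] = op
        chars[span[1]] = cl
    for pos in forced_unpaired:
        chars[_flat_index(system, pos)] = "x"
    na = len(system.chain_a)
    return "".join(chars[:na]) + "&" + "".join(chars[na:])


def write_constraint(constraint: ConstraintStructure) -> str:
    return write_dotbracket(constraint.as_structure(), constraint.forced_unpaired)


# ---------------------------------------------------------------------------
# metrics and comparisons


def bp_distance(
    a: ComplexStructure,
    b: ComplexStructure,
    region: Optional[Iterable[Position]] = None,
) -> int:
    """Base-pair distance: |symmetric difference| of the two pair sets.

    With *region* given, only pairs having at least one position in the
    region are counted on either side.
    """
    if a.system is not b.system and (
        a.system.chain_a != b.system.chain_a or a.system.chain_b != b.system.chain_b
    ):
        raise StructureError("bp_distance requires structures over the same system")
    pa, pb = a.pairs, b.pairs
    if region is not None:
        reg = frozenset(region)
        pa = frozenset(bp for bp in pa if bp.p in reg or bp.q in reg)
        pb = frozenset(bp for bp in pb if bp.p in reg or bp.q in reg)
    return len(pa ^ pb)


def _inter_sorted(structure: ComplexStructure) -> list[tuple[int, int]]:
    """Intermolecular pairs as (a_index, b_index), sorted along chain A."""
    out = []
    for bp in structure.intermolecular_pairs:
        a_pos = bp.p if bp.p.chain == "A" else bp.q
        b_pos = bp.q if bp.p.chain == "A" else bp.p
        out.append((a_pos.index, b_pos.index))
    return sorted(out)


def interaction_metrics(structure: ComplexStructure, gap_limit: int = 4) -> InteractionMetrics:
    """Compute interaction-length metrics of one complex structure.

    Sites group intermolecular pairs whose neighbours (along chain A) are
    separated by at most *gap_limit* unpaired residues on each strand.
    """
    inter = _inter_sorted(structure)
    n_inter = len(inter)
    if n_inter == 0:
        return InteractionMetrics(0, 0, 0)
    # longest perfect helix: consecutive (i, j), (i+1, j-1)
    longest = 1
    run = 1
    for (i0, j0), (i1, j1) in zip(inter, inter[1:]):
        if i1 == i0 + 1 and j1 == j0 - 1:
            run += 1
        else:
            run = 1
        longest = max(longest, run)
    # sites: split where the gap on either strand exceeds gap_limit
    site_sizes = []
    size = 1
    for (i0, j0), (i1, j1) in zip(inter, inter[1:]):
        gap_a = i1 - i0 - 1
        gap_b = abs(j1 - j0) - 1
        if gap_a <= gap_limit and gap_b <= gap_limit:
            size += 1
        else:
            site_sizes.append(size)
            size = 1
    site_sizes.append(size)
    return InteractionMetrics(n_inter, longest, max(site_sizes))


def longest_intramolecular_helix(structure: ComplexStructure, chain: str) -> int:
    """Longest run of stacked intramolecular pairs within one chain."""
    pairs = sorted(
        (bp.p.index, bp.q.index)
        for bp in structure.intramolecular_pairs
        if bp.p.chain == chain
    )
    best = 0
    run = 0
    prev = None
    for i, j in pairs:
        if prev is not None and i == prev[0] + 1 and j == prev[1] - 1:
            run += 1
        else:
            run = 1
        best = max(best, run)
        prev = (i, j)
    return best


def hairpin_loop_size(structure: ComplexStructure, chain: str) -> int:
    """Residues enclosed by the innermost intramolecular pair of *chain*.

    The innermost pair is the one with the smallest enclosed span; returns
    0 when the chain has no intramolecular pair.
    """
    spans = [
        bp.q.index - bp.p.index - 1
        for bp in structure.intramolecular_pairs
        if bp.p.chain == chain
    ]
    return min(spans) if spans else 0


def is_exact_match(
    structure: ComplexStructure,
    reference: ComplexStructure,
    canonical_only: bool = False,
) -> bool:
    """True iff the (optionally canonical-filtered) pair sets are equal."""
    sa = structure.canonical_pairs() if canonical_only else structure.pairs
    sb = reference.canonical_pairs() if canonical_only else reference.pairs
    return sa == sb


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_duplex(path, name: Optional[str] = None) -> DuplexSystem:
    """Read the two chains (exactly two records; order = chain A, chain B)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise StructureError(f"expected exactly 2 FASTA records, found {len(records)}")
    sys_name = name or f"{records[0].id}-{records[1].id}"
    return DuplexSystem(sys_name, str(records[0].seq), str(records[1].seq))
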