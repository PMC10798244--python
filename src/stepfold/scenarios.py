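"""Packaged study systems and synthetic system generators.

Two generator families emulate the two steric regimes the pipeline
contrasts: *exterior-loop* duplexes (two unstructured chains, free ends,
extension sterically easy) and *kissing hairpins* (loop-loop contact
between two closed stems, extension sterically frustrated).

The named systems reproduce the architecture of the studied complexes:
the CopA/CopT antisense pair (54 and 47 nt hairpins, nearly perfectly
complementary, 3 bp CCG/GGC loop-loop seed), the HIV-1 DIS homodimer
(23 nt chains: 7 bp stem, 9 nt loop, 6 bp palindromic GUGCAC kiss), and
DsrA variants against an unstructured 41 nt rpoS model.  CopA/CopT and
DsrA/rpoS sequences are synthetic stand-ins built to those published
architectural facts (lengths, stems, seed identity, complementarity),
not experimental transcripts; each Scenario carries a provenance note
saying so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .duplex2d import (
    BasePair,
    ComplexStructure,
    DuplexSystem,
    Position,
    StructureError,
    parse_dotbracket,
)
from .pathgen import AUTO, max_bulge_free_extension
from .pipeline import PipelineConfig

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU")) for _ in range(n))


@dataclass(frozen=True)
class Scenario:
    """A ready-to-run system: sequences, initial structure, seed, target."""

    name: str
    system: DuplexSystem
    initial: ComplexStructure
    seed: frozenset[BasePair]
    target: Union[frozenset, str]
    config: PipelineConfig = field(default_factory=PipelineConfig)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.target != AUTO:
            if not self.seed <= frozenset(self.target):
                raise StructureError("scenario seed must be a subset of its target")
        for bp in self.seed:
            if bp not in self.initial.pairs:
                raise StructureError("scenario seed pairs must appear in the initial structure")

    @property
    def intramolecular(self) -> ComplexStructure:
        return self.initial.replace_pairs(self.initial.intramolecular_pairs)

    def resolved_target(self, allow_gu: bool = True) -> frozenset[BasePair]:
        if self.target == AUTO:
            return max_bulge_free_extension(self.system, self.seed, allow_gu=allow_gu)
        return frozenset(self.target)


def _hairpin_pairs(chain: str, start: int, stem: int, loop: int) -> frozenset[BasePair]:
    """Stem pairs of a hairpin whose 5' stem begins at *start*."""
    return frozenset(
        BasePair(
            Position(chain, start + k),
            Position(chain, start + 2 * stem + loop - 1 - k),
        )
        for k in range(stem)
    )


def make_kissing_system(
    stem_len: int, loop_len: int, seed_len: int, rng_seed: int = 0
) -> Scenario:
    """Two hairpins whose loops are reverse-complementary: a kissing system.

    Each chain is ``stem + loop + stem`` with the loops complementary over
    their full length, so the automatic target spans the loops; the seed
    is the central *seed_len* loop-loop pairs.  Stem boundary residues are
    fixed so the bulge-free extension cannot run past the loops.
    """
    if loop_len < seed_len + 2:
        raise StructureError("loop_len must be >= seed_len + 2")
    if stem_len < 2:
        raise StructureError("stem_len must be >= 2")
    rng = np.random.default_rng(rng_seed)
    stem_a = _random_seq(rng, stem_len - 1) + "A"
    stem_b = _random_seq(rng, stem_len - 1) + "C"
    loop_a = _random_seq(rng, loop_len)
    loop_b = revcomp(loop_a)
    chain_a = stem_a + loop_a + revcomp(stem_a)
    chain_b = stem_b + loop_b + revcomp(stem_b)
    system = DuplexSystem(f"kissing-s{stem_len}l{loop_len}", chain_a, chain_b)
    s, L = stem_len, loop_len
    kiss = [
        BasePair(Position("A", s + 1 + k), Position("B", s + L - k)) for k in range(L)
    ]
    k0 = (L - seed_len) // 2
    seed = frozenset(kiss[k0 : k0 + seed_len])
    initial = ComplexStructure(
        system,
        _hairpin_pairs("A", 1, s, L) | _hairpin_pairs("B", 1, s, L) | seed,
    )
    return Scenario(
        name=system.name,
        system=system,
        initial=initial,
        seed=seed,
        target=AUTO,
        provenance=f"synthetic kissing-hairpin generator, rng_seed={rng_seed}",
    )


def make_exterior_system(
    len_a: int, len_b: int, duplex_len: int, seed_len: int, rng_seed: int = 0
) -> Scenario:
    """Two unstructured chains complementary over a central window.

    The initial structure carries only the central *seed_len* pairs; the
    automatic target is the *duplex_len* window (residues flanking the
    window are fixed non-complementary so extension stops there).
    """
    if duplex_len > min(len_a, len_b):
        raise StructureError("duplex_len must fit in both chains")
    if seed_len > duplex_len:
        raise StructureError("seed_len must be <= duplex_len")
    rng = np.random.default_rng(rng_seed)
    wa = (len_a - duplex_len) // 2  # 0-based window start on A
    wb = (len_b - duplex_len) // 2
    window = _random_seq(rng, duplex_len)
    a = list(_random_seq(rng, len_a))
    b = list(_random_seq(rng, len_b))
    a[wa : wa + duplex_len] = list(window)
    b[wb : wb + duplex_len] = list(revcomp(window))
    # block extension past the window on both sides (non-canonical facings)
    if wa > 0:
        a[wa - 1] = "A"
    if wb + duplex_len < len_b:
        b[wb + duplex_len] = "G"
    if wa + duplex_len < len_a:
        a[wa + duplex_len] = "C"
    if wb > 0:
        b[wb - 1] = "A"
    system = DuplexSystem(f"exterior-{len_a}x{len_b}d{duplex_len}", "".join(a), "".join(b))
    duplex = [
        BasePair(Position("A", wa + 1 + k), Position("B", wb + duplex_len - k))
        for k in range(duplex_len)
    ]
    k0 = (duplex_len - seed_len) // 2
    seed = frozenset(duplex[k0 : k0 + seed_len])
    initial = ComplexStructure(system, seed)
    return Scenario(
        name=system.name,
        system=system,
        initial=initial,
        seed=seed,
        target=AUTO,
        provenance=f"synthetic exterior-loop generator, rng_seed={rng_seed}",
    )


# ---------------------------------------------------------------------------
# named study systems

#: 23 nt HIV-1 DIS monomer: 7 bp stem, 9 nt loop whose central palindrome
#: GUGCAC forms the 6 bp kiss (subtype-F loop identity).
HIV_DIS_SEQ = "CUUGCUGAAGUGCACACAGCAAG"
HIV_DIS_DOTBRACKET = "(((((((..[[[[[[.)))))))&(((((((..]]]]]].)))))))"


def _copa_copt_sequences() -> tuple[str, str]:
    """Synthetic CopA (54 nt) / CopT (47 nt) stand-in pair.

    CopA: 3 nt 5' tail, 18 bp stem, 9 nt loop with central CCG, 6 nt 3'
    tail.  CopT is the reverse complement of CopA positions 4-50, so the
    two chains are perfectly complementary over that window (the studied
    pair is nearly perfectly complementary) and CopT folds the mirrored
    18 bp hairpin with a GGC-centred loop.
    """
    stem5 = "GCGAUCCAGGUCGACUAG"  # 18 nt
    loop = "GUACCGAAA"  # 9 nt, positions 25-27 of CopA = CCG
    copa = "GGA" + stem5 + loop + revcomp(stem5) + "AUCCAA"
    copt = revcomp(copa[3:50])
    return copa, copt


def _copa_scenario() -> Scenario:
    copa, copt = _copa_copt_sequences()
    system = DuplexSystem("copa_copt", copa, copt)
    seed = frozenset(
        BasePair(Position("A", i), Position("B", 51 - i)) for i in (25, 26, 27)
    )
    intra = _hairpin_pairs("A", 4, 18, 9) | _hairpin_pairs("B", 3, 18, 9)
    initial = ComplexStructure(system, intra | seed)
    return Scenario(
        name="copa_copt",
        system=system,
        initial=initial,
        seed=seed,
        target=AUTO,
        config=PipelineConfig(n_cluster=10, n_run=5, n_sim=5, n_step=5000),
        provenance=(
            "synthetic stand-in: published architecture (54/47 nt hairpins, "
            "3 bp CCG/GGC loop-loop seed, near-perfect complementarity), "
            "synthetic sequence"
        ),
    )


def _hiv_scenario() -> Scenario:
    system = DuplexSystem("hiv_dis", HIV_DIS_SEQ, HIV_DIS_SEQ)
    initial = parse_dotbracket(HIV_DIS_DOTBRACKET, system=system)
    seed = initial.intermolecular_pairs
    return Scenario(
        name="hiv_dis",
        system=system,
        initial=initial,
        seed=seed,
        target=AUTO,
        config=PipelineConfig(
            n_cluster=1, n_run=10, n_sim=10, n_step=10000, start_mode="pdb_file"
        ),
        provenance=(
            "homodimer transcribed from the published structural description "
            "(23 nt, 7 bp stem, 9 nt loop, 6 bp GUGCAC kiss); start "
            "conformation is a sketch standing in for the 1ZCI crystal"
        ),
    )


def _dsra_sequences() -> tuple[str, str]:
    """Synthetic DsrA-like 50 nt chain and its 41 nt unstructured rpoS model.

    DsrA layout: SL1 (6 bp stem, 4 nt loop, residues 1-16), linker region
    LR (17-24), SL2 (4 bp stem, 4 nt loop, 25-36), SL3 (5 bp stem, 4 nt
    loop, 37-50).  rpoS is the reverse complement of DsrA positions
    15-55-clipped window (15-50 plus padding), i.e. fully complementary
    to the LR/SL2 region it invades.
    """
    rng = np.random.default_rng(20240201)
    sl1_stem = _random_seq(rng, 6)
    sl1_loop = _random_seq(rng, 4)
    lr = _random_seq(rng, 8)
    sl2_stem = _random_seq(rng, 4)
    sl2_loop = _random_seq(rng, 4)
    sl3_stem = _random_seq(rng, 5)
    sl3_loop = _random_seq(rng, 4)
    dsra = (
        sl1_stem + sl1_loop + revcomp(sl1_stem)
        + lr
        + sl2_stem + sl2_loop + revcomp(sl2_stem)
        + sl3_stem + sl3_loop + revcomp(sl3_stem)
    )
    # rpoS: 41 nt complementary to DsrA 15..50 (36 nt) plus a 5 nt tail
    rpos = revcomp(dsra[14:50]) + _random_seq(rng, 5)
    return dsra, rpos


_DSRA_FOLDS = {
    # fold name -> intramolecular stems present
    "dsra_rpos_foldA": ("SL1", "SL2", "SL3"),
    "dsra_rpos_foldB": ("SL1", "SL3"),
    "dsra_rpos_rfam": ("SL1", "SL2w", "SL3"),
}


def _dsra_scenario(name: str) -> Scenario:
    dsra, rpos = _dsra_sequences()
    system = DuplexSystem(name, dsra, rpos)
    stems = {
        "SL1": _hairpin_pairs("A", 1, 6, 4),
        "SL2": _hairpin_pairs("A", 25, 4, 4),
        # weaker consensus-style SL2: only the outer 3 pairs
        "SL2w": frozenset(
            BasePair(Position("A", 25 + k), Position("A", 36 - k)) for k in range(3)
        ),
        "SL3": _hairpin_pairs("A", 37, 5, 4),
    }
    intra = frozenset().union(*(stems[s] for s in _DSRA_FOLDS[name]))
    # seed: 3 bp at the start of the linker region (A17-19); DsrA position i
    # pairs rpoS position 51 - i (rpoS_k = comp(dsra[51-k]) over the window)
    seed = frozenset(
        BasePair(Position("A", i), Position("B", 51 - i)) for i in (17, 18, 19)
    )
    initial = ComplexStructure(system, intra | seed)
    return Scenario(
        name=name,
        system=system,
        initial=initial,
        seed=seed,
        target=AUTO,
        config=PipelineConfig(n_cluster=10, n_run=5, n_sim=5, n_step=5000),
        provenance=(
            "synthetic stand-in: DsrA-like SL1/LR/SL2/SL3 architecture with "
            "fold variants; rpoS modelled as an unstructured 41 nt chain"
        ),
    )


SCENARIO_NAMES = (
    "copa_copt",
    "hiv_dis",
    "dsra_rpos_foldA",
    "dsra_rpos_foldB",
    "dsra_rpos_rfam",
)


def load_scenario(name: str) -> Scenario:
    """Return one of the packaged study scenarios by name."""
    if name == "copa_copt":
        return _copa_scenario()
    if name == "hiv_dis":
        return _hiv_scenario()
    if name in _DSRA_FOLDS:
        return _dsra_scenario(name)
    raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
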