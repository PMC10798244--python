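import numpy as np
import pytest

from stepfold.duplex2d import (
    BasePair,
    ComplexStructure,
    DuplexSystem,
    Position,
)

ALPHABET = "ACGU"


def random_system(rng: np.random.Generator, na: int, nb: int, name: str = "rnd") -> DuplexSystem:
    return DuplexSystem(
        name,
        "".join(rng.choice(list(ALPHABET)) for _ in range(na)),
        "".join(rng.choice(list(ALPHABET)) for _ in range(nb)),
    )


def random_structure(
    rng: np.random.Generator,
    system: DuplexSystem,
    n_pairs: int,
    p_inter: float = 0.5,
) -> ComplexStructure:
    """Random valid structure: each position once, hairpin rule respected.

    Crossing pairs arise naturally from random placement, so kissing-like
    layouts are covered.
    """
    taken: set[Position] = set()
    pairs: list[BasePair] = []
    for _ in range(n_pairs * 30):
        if len(pairs) >= n_pairs:
            break
        if rng.random() < p_inter:
            p = Position("A", int(rng.integers(1, len(system.chain_a) + 1)))
            q = Position("B", int(rng.integers(1, len(system.chain_b) + 1)))
        else:
            chain = "A" if rng.random() < 0.5 else "B"
            n = len(system.chain_a) if chain == "A" else len(system.chain_b)
            if n < 6:
                continue
            i = int(rng.integers(1, n - 4))
            j = int(rng.integers(i + 5, n + 1))
            p, q = Position(chain, i), Position(chain, j)
        if p in taken or q in taken or p == q:
            continue
        taken.update((p, q))
        pairs.append(BasePair(p, q))
    return ComplexStructure(system, frozenset(pairs))


def random_sketchable_structure(
    rng: np.random.Generator, system: DuplexSystem
) -> ComplexStructure:
    """Random stem/kissing layout that a coarse 3D embedding can realise.

    Up to two hairpins per chain in disjoint intervals, plus (half the
    time) an intermolecular helix between unpaired stretches -- the
    crossing kissing-hairpin case when those stretches are loops.
    """
    pairs: list[BasePair] = []
    taken_a: set[int] = set()
    taken_b: set[int] = set()

    def add_hairpin(chain: str, taken: set[int], n: int) -> None:
        for _ in range(20):
            stem = int(rng.integers(2, 5))
            loop = int(rng.integers(3, 7))
            need = 2 * stem + loop
            if need > n:
                continue
            start = int(rng.integers(1, n - need + 2))
            span = set(range(start, start + need))
            if span & taken:
                continue
            for k in range(stem):
                pairs.append(
                    BasePair(
                        Position(chain, start + k),
                        Position(chain, start + need - 1 - k),
                    )
                )
            taken.update(range(start, start + stem))
            taken.update(range(start + need - stem, start + need))
            return

    na, nb = len(system.chain_a), len(system.chain_b)
    for _ in range(int(rng.integers(0, 3))):
        add_hairpin("A", taken_a, na)
    for _ in range(int(rng.integers(0, 3))):
        add_hairpin("B", taken_b, nb)
    if rng.random() < 0.5:
        free_a = [i for i in range(1, na + 1) if i not in taken_a]
        free_b = [i for i in range(1, nb + 1) if i not in taken_b]
        # contiguous free runs
        def runs(free):
            out, cur = [], []
            for i in free:
                if cur and i != cur[-1] + 1:
                    out.append(cur)
                    cur = []
                cur.append(i)
            if cur:
                out.append(cur)
            return out

        ra = [r for r in runs(free_a) if len(r) >= 2]
        rb = [r for r in runs(free_b) if len(r) >= 2]
        if ra and rb:
            run_a = ra[int(rng.integers(len(ra)))]
            run_b = rb[int(rng.integers(len(rb)))]
            h = min(len(run_a), len(run_b), int(rng.integers(2, 6)))
            for k in range(h):
                pairs.append(
                    BasePair(Position("A", run_a[k]), Position("B", run_b[-1 - k]))
                )
    return ComplexStructure(system, frozenset(pairs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240215)


@pytest.fixture
def small_system():
    return DuplexSystem("small", "GGGGAAAACCCC", "GGGAAACCC")
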