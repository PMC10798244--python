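"""3D model: PDB I/O, annotation, superposition, clashes, sketching."""

import numpy as np
import pytest

from stepfold.duplex2d import (
    BasePair,
    ComplexStructure,
    DuplexSystem,
    Position,
    pair,
    parse_dotbracket,
)
from stepfold.model3d import (
    Conformation3D,
    ConformationError,
    DEFAULT_GEOMETRY,
    GeometryParams,
    annotate_pairs,
    clash_count,
    ideal_helix_coords,
    read_pdb,
    sketch_structure,
    superpose_rmsd,
    write_pdb,
)

from conftest import random_structure, random_system


def build_duplex(n: int, params: GeometryParams = DEFAULT_GEOMETRY) -> Conformation3D:
    """Ideal n-bp intermolecular duplex over complementary poly-G/poly-C."""
    s1, s2 = ideal_helix_coords(n, params)
    sys_ = DuplexSystem("duplex", "G" * n, "C" * n)
    return Conformation3D(sys_, s1, s2[::-1].copy())


class TestPdbIO:
    def test_roundtrip_coordinates_within_format_precision(self, tmp_path, rng):
        sys_ = random_system(rng, 10, 10)
        coords = rng.normal(scale=20, size=(20, 3))
        # enforce bondable geometry is not needed for pure I/O
        conf = Conformation3D(sys_, coords[:10], coords[10:])
        f = tmp_path / "c.pdb"
        write_pdb(conf, f)
        back = read_pdb(f, system=sys_)
        assert np.allclose(back.all_coords, conf.all_coords, atol=1.5e-3)
        assert back.system.chain_a == sys_.chain_a

    def test_p_only_backbone_fallback(self, tmp_path):
        lines = []
        serial = 1
        for cid in ("X", "Y"):
            for i in range(1, 4):
                x = serial * 10.0
                lines.append(
                    f"ATOM  {serial:5d}  P     G {cid}{i:4d}    "
                    f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           P"
                )
                serial += 1
        f = tmp_path / "p.pdb"
        f.write_text("\n".join(lines) + "\nEND\n")
        conf = read_pdb(f)
        assert conf.coords_a.shape == (3, 3)
        assert conf.coords_a[0, 0] == pytest.approx(10.0)

    def test_two_chain_requirement(self, tmp_path):
        f = tmp_path / "one.pdb"
        f.write_text(
            "ATOM      1  C3'   G A   1      1.000   0.000   0.000  1.00  0.00           C\nEND\n"
        )
        with pytest.raises(ConformationError, match="2 nucleic-acid chains"):
            read_pdb(f)

    def test_homodimer_sized_chains(self, tmp_path):
        """A coarse two-chain file with 23 residues per chain reads back as
        23 beads per chain (the packaged kissing-dimer start geometry)."""
        from stepfold.scenarios import load_scenario

        sc = load_scenario("hiv_dis")
        conf = sketch_structure(sc.system, sc.initial, seed=4, require="exact")
        f = tmp_path / "dimer.pdb"
        write_pdb(conf, f)
        back = read_pdb(f)
        assert back.coords_a.shape == (23, 3)
        assert back.coords_b.shape == (23, 3)


class TestAnnotatePairs:
    def test_extended_chain_is_unpaired(self):
        sys_ = DuplexSystem("t", "A" * 10, "A" * 10)
        a = np.column_stack([np.arange(10) * 6.0, np.zeros(10), np.zeros(10)])
        b = a + np.array([0.0, 500.0, 0.0])
        conf = Conformation3D(sys_, a, b)
        assert len(annotate_pairs(conf).pairs) == 0

    def test_built_duplex_recovered_exactly(self):
        conf = build_duplex(5)
        ann = annotate_pairs(conf)
        expect = {pair("A", i, "B", 6 - i) for i in range(1, 6)}
        assert ann.pairs == frozenset(expect)

    def test_displaced_terminal_pair_lost_inner_retained(self):
        conf = build_duplex(5)
        conf.coords_b[4] += np.array([10.0, 0, 0])  # B5 pairs A1
        ann = annotate_pairs(conf)
        assert pair("A", 1, "B", 5) not in ann.pairs
        for i in range(2, 6):
            assert pair("A", i, "B", 6 - i) in ann.pairs

    def test_same_chain_minimum_separation(self):
        # two beads 14 A apart but only 2 residues apart: no pair
        sys_ = DuplexSystem("t", "AAAA", "AAAA")
        a = np.array([[0, 0, 0], [6, 0, 0], [6, 6, 0], [0, 14.0, 0]])
        b = a + 500.0
        ann = annotate_pairs(Conformation3D(sys_, a, b))
        assert all(bp.intermolecular or bp.q.index - bp.p.index >= 4 for bp in ann.pairs)


class TestSuperposeRmsd:
    def test_identity_and_rigid_motion_invariance(self, rng):
        sys_ = random_system(rng, 10, 10)
        conf = Conformation3D(sys_, rng.normal(size=(10, 3)) * 10, rng.normal(size=(10, 3)) * 10)
        assert superpose_rmsd(conf, conf) == pytest.approx(0.0, abs=1e-9)
        # rotate 90 deg about z and translate
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        moved = Conformation3D(
            sys_, conf.coords_a @ rot.T + 5.0, conf.coords_b @ rot.T + 5.0
        )
        assert superpose_rmsd(conf, moved) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry_and_self_consistency(self, rng):
        """RMSD equals the naive RMSD after applying the computed optimal
        superposition explicitly (independent recomputation)."""
        from stepfold.model3d import kabsch_rotation

        sys_ = random_system(rng, 10, 10)
        c1 = Conformation3D(sys_, rng.normal(size=(10, 3)) * 8, rng.normal(size=(10, 3)) * 8)
        c2 = Conformation3D(sys_, rng.normal(size=(10, 3)) * 8, rng.normal(size=(10, 3)) * 8)
        assert superpose_rmsd(c1, c2) == pytest.approx(superpose_rmsd(c2, c1), abs=1e-9)
        xa, xb = c1.all_coords, c2.all_coords
        ca, cb = xa - xa.mean(0), xb - xb.mean(0)
        rot = kabsch_rotation(ca, cb)
        naive = np.sqrt(np.mean(np.sum((ca @ rot.T - cb) ** 2, axis=1)))
        assert superpose_rmsd(c1, c2) == pytest.approx(naive, abs=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_biotite_superimpose(self, rng):
        """Independent cross-check against biotite's superimposition."""
        import biotite.structure as struc

        sys_ = random_system(rng, 8, 8)
        c1 = Conformation3D(sys_, rng.normal(size=(8, 3)) * 9, rng.normal(size=(8, 3)) * 9)
        c2 = Conformation3D(sys_, rng.normal(size=(8, 3)) * 9, rng.normal(size=(8, 3)) * 9)
        fixed, mobile = c1.all_coords, c2.all_coords
        fitted, _ = struc.superimpose(fixed, mobile)
        ref_rmsd = np.sqrt(np.mean(np.sum((fitted - fixed) ** 2, axis=1)))
        assert superpose_rmsd(c2, c1) == pytest.approx(ref_rmsd, abs=1e-6)

    def test_size_mismatch(self, rng):
        s1 = random_system(rng, 5, 5)
        s2 = random_system(rng, 6, 5)
        c1 = Conformation3D(s1, np.zeros((5, 3)), np.zeros((5, 3)))
        c2 = Conformation3D(s2, np.zeros((6, 3)), np.zeros((5, 3)))
        with pytest.raises(ConformationError):
            superpose_rmsd(c1, c2)


class TestClashCount:
    def test_ideal_duplex_clash_free(self):
        assert clash_count(build_duplex(6)) == 0

    def test_coincident_beads_clash(self):
        sys_ = DuplexSystem("t", "AAA", "AAA")
        a = np.array([[0, 0, 0], [6, 0, 0], [12, 0, 0.0]])
        b = a.copy() + np.array([0.0, 0.001, 0.0])
        assert clash_count(Conformation3D(sys_, a, b)) >= 1

    def test_matches_brute_force_enumeration(self, rng):
        """Spatial-query result equals the O(n^2) double loop."""
        sys_ = random_system(rng, 25, 25)
        for _ in range(10):
            coords = rng.normal(scale=8.0, size=(50, 3))
            conf = Conformation3D(sys_, coords[:25], coords[25:])
            na = 25
            brute = 0
            for i in range(50):
                for j in range(i + 1, 50):
                    same = (i < na) == (j < na)
                    if same and abs((i % na) - (j % na)) == 1:
                        continue
                    if np.linalg.norm(coords[i] - coords[j]) < 4.0:
                        brute += 1
            assert clash_count(conf, 4.0) == brute


class TestSketchStructure:
    def test_unstructured_chain_geometry(self):
        sys_ = DuplexSystem("t", "A" * 10, "A" * 4)
        st = ComplexStructure(sys_, frozenset())
        conf = sketch_structure(sys_, st, seed=1)
        assert conf.coords_a.shape == (10, 3)
        d = np.linalg.norm(np.diff(conf.coords_a, axis=0), axis=1)
        assert np.allclose(d, DEFAULT_GEOMETRY.bond_len, atol=DEFAULT_GEOMETRY.bond_tol)
        assert clash_count(conf) == 0

    def test_hairpin_stem_recovered(self):
        sys_ = DuplexSystem("t", "GGGGAAAACCCC", "AAAA")
        st = parse_dotbracket("((((....))))&....", system=sys_)
        conf = sketch_structure(sys_, st, seed=2)
        ann = annotate_pairs(conf)
        for bp in st.pairs:
            assert bp in ann.pairs

    def test_seed_diversity(self):
        sys_ = DuplexSystem("t", "GGGGAAAACCCC", "AAAA")
        st = parse_dotbracket("((((....))))&....", system=sys_)
        c1 = sketch_structure(sys_, st, seed=10)
        c2 = sketch_structure(sys_, st, seed=11)
        assert not np.allclose(c1.all_coords, c2.all_coords)
        assert clash_count(c1) == 0 and clash_count(c2) == 0

    def test_determinism_given_seed(self):
        sys_ = DuplexSystem("t", "GGGGAAAACCCC", "AAAA")
        st = parse_dotbracket("((((....))))&....", system=sys_)
        c1 = sketch_structure(sys_, st, seed=7)
        c2 = sketch_structure(sys_, st, seed=7)
        assert np.array_equal(c1.all_coords, c2.all_coords)

    def test_recovers_all_helices_on_random_structures(self, rng):
        """annotate o sketch recovers every helix of >= 2 pairs (50 random
        structures up to 40 nt per chain)."""
        from stepfold.model3d import find_helices

        from conftest import random_sketchable_structure

        n_done = 0
        while n_done < 50:
            system = random_system(rng, int(rng.integers(12, 41)), int(rng.integers(12, 41)))
            st = random_sketchable_structure(rng, system)
            conf = sketch_structure(system, st, seed=int(rng.integers(2**31)))
            ann = annotate_pairs(conf)
            got = {(bp.p, bp.q) for bp in ann.pairs}
            for hx in find_helices(st):
                if len(hx) >= 2:
                    for p, q in zip(hx.strand1, hx.strand2):
                        assert (p, q) in got
            n_done += 1
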