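"""Constrained Monte-Carlo sampler: penalties, moves, determinism, adapters."""

import os
import stat

import numpy as np
import pytest

from stepfold.duplex2d import (
    ComplexStructure,
    ConstraintStructure,
    DuplexSystem,
    Position,
    pair,
    parse_dotbracket,
)
from stepfold.model3d import (
    Conformation3D,
    DEFAULT_GEOMETRY,
    clash_count,
    ideal_helix_coords,
    sketch_structure,
)
from stepfold.sampler import (
    ExternalAdapter,
    ExternalSamplerUnavailable,
    SamplerConfig,
    Trajectory,
    base_energy,
    constraint_penalty,
    derive_seed,
    sample,
)


@pytest.fixture
def two_chain_start():
    sys_ = DuplexSystem("two", "ACGUA", "UACGU")
    empty = parse_dotbracket(".....&.....", system=sys_)
    return sketch_structure(sys_, empty, seed=11, require="none")


class TestConstraintPenalty:
    def test_satisfied_duplex_is_zero(self):
        s1, s2 = ideal_helix_coords(4, DEFAULT_GEOMETRY)
        sys_ = DuplexSystem("d", "GGGG", "CCCC")
        conf = Conformation3D(sys_, s1, s2[::-1].copy())
        con = ConstraintStructure(
            sys_, frozenset(pair("A", i, "B", 5 - i) for i in range(1, 5))
        )
        assert constraint_penalty(conf, con) == 0.0

    def test_closed_form_single_pair(self):
        """Two 1-bead-relevant chains 30 A apart: k*(30-d_hi)^2."""
        sys_ = DuplexSystem("d", "G", "C")
        conf = Conformation3D(sys_, np.zeros((1, 3)), np.array([[30.0, 0, 0]]))
        con = ConstraintStructure(sys_, frozenset({pair("A", 1, "B", 1)}))
        d_hi = DEFAULT_GEOMETRY.pair_window[1]
        assert constraint_penalty(conf, con, k=1.0) == pytest.approx((30 - d_hi) ** 2)

    def test_matches_term_by_term_oracle(self, rng):
        """Independent loop over pairs with the flat-bottom formula."""
        sys_ = DuplexSystem("d", "G" * 8, "C" * 8)
        con = ConstraintStructure(
            sys_, frozenset(pair("A", i, "B", 9 - i) for i in range(1, 6))
        )
        d_lo, d_hi = DEFAULT_GEOMETRY.pair_window
        for _ in range(20):
            conf = Conformation3D(
                sys_, rng.normal(scale=15, size=(8, 3)), rng.normal(scale=15, size=(8, 3))
            )
            expected = 0.0
            for bp in con.required_pairs:
                d = np.linalg.norm(conf.coord(bp.p) - conf.coord(bp.q))
                expected += max(0, d - d_hi) ** 2 + max(0, d_lo - d) ** 2
            assert constraint_penalty(conf, con, k=1.0) == pytest.approx(
                expected, abs=1e-9
            )

    def test_forced_unpaired_penalised_only_in_window(self):
        sys_ = DuplexSystem("d", "G", "CAAAG")
        d_lo, d_hi = DEFAULT_GEOMETRY.pair_window
        mid = (d_lo + d_hi) / 2
        con = ConstraintStructure(sys_, frozenset(), frozenset({Position("A", 1)}))
        near = Conformation3D(
            sys_, np.zeros((1, 3)),
            np.array([[mid, 0, 0], [mid + 6, 0, 0], [mid + 12, 0, 0], [mid + 18, 0, 0], [mid + 24, 0, 0]]),
        )
        far = Conformation3D(
            sys_, np.zeros((1, 3)),
            np.array([[50.0, 0, 0], [56, 0, 0], [62, 0, 0], [68, 0, 0], [74, 0, 0]]),
        )
        assert constraint_penalty(near, con) > 0
        assert constraint_penalty(far, con) == 0.0

    def test_mismatched_systems_raise(self, two_chain_start):
        other = ConstraintStructure(
            DuplexSystem("x", "GGGG", "CCCC"), frozenset({pair("A", 1, "B", 4)})
        )
        with pytest.raises(ValueError, match="different systems"):
            constraint_penalty(two_chain_start, other)


class TestSample:
    def test_zero_steps_returns_start_frame_only(self, two_chain_start):
        con = ConstraintStructure(two_chain_start.system, frozenset())
        traj = sample(two_chain_start, con, SamplerConfig(n_step=0, seed=1))
        assert len(traj.frames) == 1
        assert np.array_equal(traj.frames[0].conf.all_coords, two_chain_start.all_coords)

    def test_required_pair_closes(self, two_chain_start):
        """A single required pair between two free chains closes (penalty
        reaches zero) in a modest cold run."""
        con = ConstraintStructure(
            two_chain_start.system, frozenset({pair("A", 3, "B", 3)})
        )
        traj = sample(
            two_chain_start, con, SamplerConfig(n_step=20000, temperature=0.1, seed=7)
        )
        assert traj.final.constraint_penalty == 0.0

    def test_downhill_limit(self, two_chain_start):
        con = ConstraintStructure(
            two_chain_start.system, frozenset({pair("A", 3, "B", 3)})
        )
        traj = sample(
            two_chain_start, con, SamplerConfig(n_step=2000, temperature=1e-12, seed=3)
        )
        assert traj.final.total_energy <= traj.frames[0].total_energy + 1e-9

    def test_bitwise_determinism(self, two_chain_start):
        con = ConstraintStructure(
            two_chain_start.system, frozenset({pair("A", 2, "B", 4)})
        )
        cfg = SamplerConfig(n_step=3000, seed=42)
        t1 = sample(two_chain_start, con, cfg)
        t2 = sample(two_chain_start, con, cfg)
        assert len(t1.frames) == len(t2.frames)
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.array_equal(f1.conf.all_coords, f2.conf.all_coords)
            assert f1.base_energy == f2.base_energy
            assert f1.constraint_penalty == f2.constraint_penalty

    def test_every_frame_respects_hard_invariants(self, two_chain_start):
        """No clash and no bond violation in any recorded frame."""
        con = ConstraintStructure(
            two_chain_start.system, frozenset({pair("A", 1, "B", 5)})
        )
        traj = sample(two_chain_start, con, SamplerConfig(n_step=4000, seed=9))
        for f in traj.frames:
            assert clash_count(f.conf) == 0
            assert f.conf.bond_violations() == 0

    def test_energy_bookkeeping_rederivable(self, two_chain_start):
        """Frame energies equal fresh recomputation from coordinates."""
        con = ConstraintStructure(
            two_chain_start.system, frozenset({pair("A", 2, "B", 2)})
        )
        cfg = SamplerConfig(n_step=2000, seed=5)
        traj = sample(two_chain_start, con, cfg)
        for f in traj.frames[:: max(1, len(traj.frames) // 10)]:
            assert f.base_energy == pytest.approx(base_energy(f.conf, cfg), abs=1e-9)
            assert f.constraint_penalty == pytest.approx(
                constraint_penalty(f.conf, con, k=cfg.constraint_weight), abs=1e-9
            )

    def test_constraint_pull_beats_unconstrained(self, two_chain_start):
        """Across seeds, the mean final penalty with the spring on is below
        the mean penalty value of unconstrained runs measured on the same
        required pair."""
        req = frozenset({pair("A", 3, "B", 3)})
        con_on = ConstraintStructure(two_chain_start.system, req)
        con_off = ConstraintStructure(two_chain_start.system, frozenset())
        on, off = [], []
        for s in range(20):
            cfg_on = SamplerConfig(n_step=2500, temperature=0.3, seed=s)
            t_on = sample(two_chain_start, con_on, cfg_on)
            on.append(t_on.final.constraint_penalty)
            t_off = sample(two_chain_start, con_off, cfg_on)
            off.append(constraint_penalty(t_off.final.conf, con_on))
        assert np.mean(on) < np.mean(off)

    def test_monotone_step_index(self, two_chain_start):
        con = ConstraintStructure(two_chain_start.system, frozenset())
        traj = sample(two_chain_start, con, SamplerConfig(n_step=1000, seed=2))
        steps = [f.step_index for f in traj.frames]
        assert steps == sorted(set(steps))
        assert steps[-1] == 1000


class TestDerivedSeeds:
    def test_formula_and_range(self):
        assert derive_seed(5, 0) == 5
        assert derive_seed(5, 3) == 5 + 3 * 10007
        assert 0 <= derive_seed(2**30, 10**6) < 2**31


class TestExternalAdapters:
    def test_missing_binary_is_explicit_error(self):
        ad = ExternalAdapter("simrna-like", "definitely-not-a-real-sampler-xyz")
        with pytest.raises(ExternalSamplerUnavailable, match="not found"):
            ad.check_available()

    def test_restraint_file_lists_every_pair(self, tmp_path):
        sys_ = DuplexSystem("d", "GGGG", "CCCC")
        con = ConstraintStructure(
            sys_, frozenset(pair("A", i, "B", 5 - i) for i in range(1, 4))
        )
        ad = ExternalAdapter("simrna-like", "unused")
        f = tmp_path / "restraints.txt"
        ad.write_restraints(con, f)
        lines = [l for l in f.read_text().splitlines() if l.strip()]
        assert len(lines) == 3
        assert all(l.startswith("SLOPE") for l in lines)

    def test_stub_executable_roundtrip(self, tmp_path, two_chain_start):
        """A stub tool echoing fixed frames is parsed into a Trajectory."""
        stub = tmp_path / "stub_sampler.sh"
        stub.write_text(
            "#!/bin/sh\n"
            'echo "0 -1.5 2.0"\n'
            'echo "10 -2.5 1.0"\n'
            'echo "20 -3.5 0.0"\n'
        )
        stub.chmod(stub.stat().st_mode | stat.S_IEXEC)
        con = ConstraintStructure(
            two_chain_start.system, frozenset({pair("A", 1, "B", 1)})
        )
        ad = ExternalAdapter("simrna-like", str(stub))
        traj = ad.sample(two_chain_start, con, SamplerConfig(n_step=20, seed=1), tmp_path)
        assert isinstance(traj, Trajectory)
        assert [f.step_index for f in traj.frames] == [0, 10, 20]
        assert traj.final.base_energy == -3.5
        assert traj.final.constraint_penalty == 0.0

    def test_unknown_tool_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown external tool"):
            ExternalAdapter("molecular-dynamics", "x")
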