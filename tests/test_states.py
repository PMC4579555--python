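"""State-class enumeration, canonical forms and rigid tilt machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pentastate as ps
from pentastate._geometry import rotate_about_line
from pentastate.states import StateString, count_state_classes
from pentastate.synthdata import INTENDED_AXIS

PAPER_ORDER = ["ttttt", "ttttr", "tttrr", "ttrtr", "ttrrr", "trtrr", "trrrr", "rrrrr"]


def brute_force_class_count(n: int, k: int = 2) -> int:
    """Independent oracle: count cyclic orbits by explicit enumeration."""
    seen = set()
    for word in itertools.product(range(k), repeat=n):
        orbit = min(tuple(word[i:] + word[:i]) for i in range(n))
        seen.add(orbit)
    return len(seen)


class TestEnumeration:
    def test_pentamer_classes(self):
        assert [str(s) for s in ps.enumerate_state_classes(5)] == PAPER_ORDER

    @pytest.mark.parametrize("n,expected", [(1, ["t", "r"]), (3, ["ttt", "ttr", "trr", "rrr"])])
    def test_small_n(self, n, expected):
        assert [str(s) for s in ps.enumerate_state_classes(n)] == expected

    @pytest.mark.parametrize("n", range(1, 9))
    def test_counts_match_brute_force_and_burnside(self, n):
        classes = ps.enumerate_state_classes(n)
        assert len(classes) == brute_force_class_count(n)
        assert len(classes) == count_state_classes(n, 2)
        assert len({str(c) for c in classes}) == len(classes)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            ps.enumerate_state_classes(0)


class TestCanonicalForm:
    @pytest.mark.parametrize("raw,canon", [("rtttt", "ttttr"), ("ttttt", "ttttt")])
    def test_examples(self, raw, canon):
        assert str(ps.canonical_form(raw)) == canon

    def test_matches_brute_force_over_rotations(self):
        word = "rrtrt"
        key = lambda w: tuple("tr".index(c) for c in w)
        expected = min((word[i:] + word[:i] for i in range(5)), key=key)
        assert expected == "trtrr"
        assert str(ps.canonical_form(word)) == expected

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            ps.canonical_form("ttxtt")

    @given(st.text(alphabet="tr", min_size=1, max_size=8), st.integers(0, 7))
    def test_rotation_invariance(self, word, k):
        s = StateString(word)
        assert str(s.canonical()) == str(s.rotated(k).canonical())
        # the canonical form is itself a rotation of the input
        assert str(s.canonical()) in {str(s.rotated(i)) for i in range(len(word))}


class TestTiltProtomer:
    def test_zero_angle_is_identity(self, phantom_protomer, axis):
        tilted = ps.tilt_protomer(phantom_protomer, axis, 0.0)
        assert np.abs(tilted.positions - phantom_protomer.positions).max() < 1e-12

    def test_inverse_composition(self, phantom_protomer, axis):
        there = ps.tilt_protomer(phantom_protomer, axis, 20.0)
        back = ps.tilt_protomer(there, axis, -20.0)
        assert np.abs(back.positions - phantom_protomer.positions).max() < 1e-9

    def test_pivot_fixed_point(self, phantom_protomer, axis):
        tilted = ps.tilt_protomer(phantom_protomer, axis, 20.0)
        assert np.linalg.norm(tilted.atom(250).position
                              - phantom_protomer.atom(250).position) < 1e-12

    def test_isometry(self, phantom_protomer, axis):
        rng = np.random.default_rng(7)
        tilted = ps.tilt_protomer(phantom_protomer, axis, -10.0)
        n = len(phantom_protomer)
        i, j = rng.integers(0, n, 1000), rng.integers(0, n, 1000)
        d0 = np.linalg.norm(phantom_protomer.positions[i] - phantom_protomer.positions[j], axis=1)
        d1 = np.linalg.norm(tilted.positions[i] - tilted.positions[j], axis=1)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_chord_length_closed_form(self, axis):
        # marker at L = 40 Å from the pivot, perpendicular to the (radial) tilt line
        pivot = np.array([12.0, 0.0, 10.0])
        marker = pivot + np.array([0.0, 0.0, 40.0])
        atoms = [ps.AtomRecord("CA", 250, "A", pivot),
                 ps.AtomRecord("CA", 278, "A", marker)]
        prot = ps.ProtomerCoords(atoms, pivot_residue=250, motif_residues=(278,))
        angle = 20.0
        tilted = ps.tilt_protomer(prot, axis, angle)
        moved = np.linalg.norm(tilted.atom(278).position - marker)
        expected = 2 * 40.0 * np.sin(np.deg2rad(angle) / 2)
        assert abs(moved - expected) < 1e-9

    def test_positive_angle_moves_motif_outward(self, phantom_protomer, axis):
        r0 = np.hypot(*phantom_protomer.atom(278).position[:2])
        r_plus = np.hypot(*ps.tilt_protomer(phantom_protomer, axis, 20.0).atom(278).position[:2])
        r_minus = np.hypot(*ps.tilt_protomer(phantom_protomer, axis, -10.0).atom(278).position[:2])
        assert r_minus < r0 < r_plus

    def test_pivot_on_axis_error(self, axis):
        atoms = [ps.AtomRecord("CA", 250, "A", np.array([0.0, 0.0, 5.0])),
                 ps.AtomRecord("CA", 278, "A", np.array([8.0, 0.0, 0.0]))]
        prot = ps.ProtomerCoords(atoms, pivot_residue=250, motif_residues=(278,))
        with pytest.raises(ValueError, match="axis"):
            ps.tilt_protomer(prot, axis, 10.0)


def _model_rmsd_to_rotated_copy(model, angle):
    rot = rotate_about_line(model.positions, model.axis.point, model.axis.direction, angle)
    # chain k maps onto chain k+1: compare against the relabelled original
    n = len(model.protomers[0])
    perm = np.concatenate([np.arange(n) + ((k + 1) % 5) * n for k in range(5)])
    return float(np.sqrt(np.mean(np.sum((rot - model.positions[perm]) ** 2, axis=1))))


class TestBuildStateModel:
    def test_ttttt_with_zero_t_angle_equals_symmetrize(self, phantom_protomer, axis):
        tilts = ps.TiltSpec(250, 0.0, 20.0)
        model = ps.build_state_model(phantom_protomer, axis, "ttttt", tilts)
        ref = ps.symmetrize(phantom_protomer, axis)
        assert np.abs(model.positions - ref.positions).max() < 1e-12

    def test_uniform_state_keeps_c5(self, phantom_protomer, axis):
        model = ps.build_state_model(phantom_protomer, axis, "rrrrr")
        assert _model_rmsd_to_rotated_copy(model, 72.0) < 1e-9

    def test_mixed_state_breaks_c5(self, phantom_protomer, axis):
        model = ps.build_state_model(phantom_protomer, axis, "tttrr")
        assert _model_rmsd_to_rotated_copy(model, 72.0) > 1.0

    def test_commutes_with_cyclic_relabelling(self, phantom_protomer, axis):
        state = ps.StateString("ttrrr")
        m1 = ps.build_state_model(phantom_protomer, axis, state.rotated(1))
        m0 = ps.build_state_model(phantom_protomer, axis, state)
        rot = rotate_about_line(m1.positions, axis.point, axis.direction, 72.0)
        n = len(phantom_protomer)
        perm = np.concatenate([np.arange(n) + ((k + 1) % 5) * n for k in range(5)])
        # chain k of the rotated-state model, after a +72° turn, is chain k+1
        assert np.abs(rot - m0.positions[perm]).max() < 1e-6

    def test_tilt_before_or_after_replication_equivalent(self, phantom_protomer, axis):
        # tilting the replicated chain about its own pivot-to-axis line
        # equals replicating the tilted protomer
        model = ps.build_state_model(phantom_protomer, axis, "rtttt")
        chain0_direct = ps.tilt_protomer(phantom_protomer, axis, 20.0).positions
        assert np.abs(model.protomers[0].positions - chain0_direct).max() < 1e-12


class TestConsensusOverlay:
    def test_single_model_identity(self, phantom_protomer, axis):
        model = ps.build_state_model(phantom_protomer, axis, "tttrr")
        ens = ps.consensus_overlay([model], [1.0])
        assert np.abs(ens.positions - model.positions).max() == 0.0
        np.testing.assert_allclose(ens.point_weights, model.weights)

    def test_paper_weights(self, phantom_protomer, axis):
        models = [ps.build_state_model(phantom_protomer, axis, s)
                  for s in ("ttttr", "tttrr", "ttrrr")]
        ens = ps.consensus_overlay(models, [0.38, 0.32, 0.30])
        assert ens.positions.shape[0] == 3 * 5 * len(phantom_protomer)
        assert abs(ens.weights.sum() - 1.0) < 1e-12

    def test_all_zero_weights_error(self, phantom_protomer, axis):
        model = ps.build_state_model(phantom_protomer, axis, "tttrr")
        with pytest.raises(ValueError):
            ps.consensus_overlay([model], [0.0])
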