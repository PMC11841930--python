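import numpy as np
import pytest
from oracles import kabsch_rmsd_oracle

from motifshift import structure as st
from motifshift.seq_io import ProteinRecord, Residue, StructureModel


def model(plddts, coords=None):
    coords = coords if coords is not None else [(float(i), 0.0, 0.0) for i in range(len(plddts))]
    return StructureModel(
        residues=[
            Residue("A", i + 1, "ALA", float(p), tuple(map(float, c)))
            for i, (p, c) in enumerate(zip(plddts, coords))
        ]
    )


class TestFilterPlddt:
    def test_threshold_at_50(self):
        filtered = st.filter_plddt(model([90.0, 45.0, 72.0]))
        assert [r.residue_index for r in filtered.residues] == [1, 3]

    def test_all_confident_is_identity(self):
        m = model([90.0, 55.0, 50.0])
        assert st.filter_plddt(m).plddt == m.plddt  # 50 itself is kept

    def test_all_low_flags_excluded_entirely(self):
        filtered = st.filter_plddt(model([10.0, 49.9]))
        assert filtered.excluded_entirely and len(filtered) == 0

    def test_idempotent(self):
        m = model([90.0, 45.0, 72.0, 30.0])
        once = st.filter_plddt(m)
        twice = st.filter_plddt(once)
        assert [r.residue_index for r in twice.residues] == [
            r.residue_index for r in once.residues
        ]


def rigid(coords, angle_deg=90.0, translation=(5.0, -2.0, 1.0)):
    th = np.deg2rad(angle_deg)
    R = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
    )
    return coords @ R.T + np.asarray(translation)


class TestKabsch:
    def test_identical_sets_zero_rmsd(self, rng):
        a = rng.normal(size=(12, 3))
        res = st.kabsch(a, a.copy())
        assert res.rmsd < 1e-8 and res.similar
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_rigid_motion_zero_rmsd(self, rng):
        a = rng.normal(size=(10, 3))
        res = st.kabsch(a, rigid(a))
        assert res.rmsd < 1e-8
        # recovered transform maps B back onto A
        b = rigid(a)
        mapped = b @ res.rotation.T + res.translation
        assert np.abs(mapped - a).max() < 1e-8

    def test_rotation_is_orthonormal(self, rng):
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        R = st.kabsch(a, b).rotation
        assert np.abs(R @ R.T - np.eye(3)).max() < 1e-8
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(9, 3)), rng.normal(size=(9, 3))
        assert st.kabsch(a, b).rmsd == pytest.approx(st.kabsch(b, a).rmsd, abs=1e-9)

    def test_rigid_motion_invariance_of_rmsd(self, rng):
        a, b = rng.normal(size=(9, 3)), rng.normal(size=(9, 3))
        base = st.kabsch(a, b).rmsd
        moved = st.kabsch(a, rigid(b, angle_deg=37.0, translation=(1, 2, 3))).rmsd
        assert abs(base - moved) < 1e-8

    def test_two_point_closed_form_via_collinear_triplet(self):
        # pair separations d1, d2 around a shared midpoint: optimal RMSD of
        # the two outer points is |d1-d2|/2; a shared center point keeps
        # n >= 3 without adding deviation
        d1, d2 = 4.0, 1.0
        a = np.array([[-d1 / 2, 0, 0], [0, 0, 0], [d1 / 2, 0, 0]])
        b = np.array([[-d2 / 2, 0, 0], [0, 0, 0], [d2 / 2, 0, 0]])
        res = st.kabsch(a, b)
        expected = np.sqrt((2 * ((d1 - d2) / 2) ** 2) / 3)
        assert res.rmsd == pytest.approx(expected, abs=1e-9)

    def test_reflection_not_allowed_matches_numeric_oracle(self, rng):
        a = rng.normal(size=(6, 3))
        mirrored = a * np.array([1.0, 1.0, -1.0])
        res = st.kabsch(a, mirrored)
        assert res.rmsd > 1e-3  # a proper rotation cannot undo a reflection
        assert res.rmsd == pytest.approx(kabsch_rmsd_oracle(a, mirrored), abs=1e-6)

    def test_general_case_matches_numeric_oracle(self, rng):
        a, b = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
        assert st.kabsch(a, b).rmsd == pytest.approx(
            kabsch_rmsd_oracle(a, b), abs=1e-6
        )

    def test_too_few_or_mismatched_pairs_rejected(self, rng):
        a = rng.normal(size=(2, 3))
        with pytest.raises(ValueError):
            st.kabsch(a, a)
        with pytest.raises(ValueError):
            st.kabsch(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestSuperposeModels:
    def test_low_confidence_residues_excluded_from_pairing(self, rng):
        coords = rng.normal(size=(10, 3))
        a = model([90.0] * 10, coords)
        noisy = coords.copy()
        noisy[3] += 50.0  # a wildly wrong low-confidence residue
        b = model([90.0] * 3 + [20.0] + [90.0] * 6, rigid(noisy))
        res = st.superpose_models(a, b)
        assert res.n_atoms == 9 and res.rmsd < 1e-6 and res.similar

    def test_entirely_excluded_model_rejected(self):
        a = model([90.0, 90.0, 90.0])
        b = model([10.0, 10.0, 10.0])
        with pytest.raises(ValueError, match="excluded"):
            st.superpose_models(a, b)


class TestInterface:
    def test_self_check_is_five_of_five(self, interface_panel):
        refs = interface_panel["mouse"]
        imap = st.default_interface_map(refs["STAT2"].id, refs["IRF9"].id)
        report = st.check_interface(refs, refs, imap)
        assert (report.conserved_count, report.total) == (5, 5)

    def test_substitution_detected_and_reported(self, interface_panel):
        refs = interface_panel["mouse"]
        stat2 = refs["STAT2"]
        mutated_seq = stat2.sequence[:173] + "A" + stat2.sequence[174:]
        queries = {
            "STAT2": ProteinRecord(id="mut", sequence=mutated_seq),
            "IRF9": refs["IRF9"],
        }
        imap = st.default_interface_map(stat2.id, refs["IRF9"].id)
        report = st.check_interface(refs, queries, imap)
        assert report.conserved_count == 4
        (bad,) = [e for e in report.entries if not e.conserved]
        assert (bad.role, bad.ref_position, bad.observed) == ("STAT2", 174, "A")

    def test_divergent_orthologs_keep_interface(self, interface_panel):
        """All five contact residues survive in every query pair despite
        sequence divergence and indels elsewhere."""
        refs = interface_panel["mouse"]
        imap = st.default_interface_map(refs["STAT2"].id, refs["IRF9"].id)
        for species in ("human", "stingray", "shark"):
            report = st.check_interface(refs, interface_panel[species], imap)
            assert report.conserved_count == 5, species

    def test_deleted_position_counts_against_conservation(self, interface_panel):
        refs = interface_panel["mouse"]
        stat2 = refs["STAT2"]
        deleted = stat2.sequence[:170] + stat2.sequence[178:]
        queries = {
            "STAT2": ProteinRecord(id="del", sequence=deleted),
            "IRF9": refs["IRF9"],
        }
        imap = st.default_interface_map(stat2.id, refs["IRF9"].id)
        report = st.check_interface(refs, queries, imap)
        entry = next(e for e in report.entries if e.role == "STAT2")
        assert not entry.liftable and not entry.conserved
        assert report.conserved_count == 4


class TestSanitizeUnknown:
    def test_x_replaced_by_companion_consensus(self, interface_panel):
        shark = interface_panel["shark"]["IRF9"]
        idx = shark.sequence.find("X")
        assert idx >= 0
        fixed = st.sanitize_unknown(
            shark,
            [interface_panel["stingray"]["IRF9"], interface_panel["mouse"]["IRF9"]],
        )
        assert fixed.sequence[idx] == "S"
        assert "X" not in fixed.sequence

    def test_no_x_is_a_no_op(self, interface_panel):
        rec = interface_panel["mouse"]["IRF9"]
        assert st.sanitize_unknown(rec, []) is rec
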