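"""Structure triage: classification rules, checks and summary arithmetic."""

import numpy as np
import pytest

from abfekit import fixtures, qc
from abfekit.qc import (TriageCategory, TriageReport, check_sequence_consistency,
                        check_site_completeness, classify_complex,
                        compare_disulfides, detect_chain_gaps,
                        detect_disulfides, summarize_triage, triage)
from abfekit.structio import Atom, MolecularSystem


def _mini_system(residues, ligand_xyz=(0.0, 0.0, 0.0)):
    """Build a hand-specified system: residues as (resname, resid, atoms)."""
    atoms, serial = [], 0
    for resname, resid, atom_list in residues:
        for name, xyz in atom_list:
            serial += 1
            atoms.append(Atom(serial, name, name[0], resname, "A", resid,
                              np.array(xyz), "standard-residue"))
    serial += 1
    atoms.append(Atom(serial, "C1", "C", "LIG", "L", 1,
                      np.array(ligand_xyz), "hetero"))
    return MolecularSystem(atoms,
                           receptor_selection=np.arange(serial - 1),
                           ligand_selection=np.array([serial - 1]))


class TestClassify:
    def test_membrane_flag_rejects(self):
        system, _ = fixtures.make_toy_complex(
            fixtures.FixtureSpec(seed=1, defects=("membrane-flag",)))
        category, evidence = classify_complex(system)
        assert (category.outcome, category.reason) == (
            "rejected-scientific", "membrane-protein")
        assert evidence

    def test_nonstandard_residue_rule_fires(self):
        system = _mini_system(
            [("SEP", 1, [("N", (5, 0, 0)), ("CA", (6, 0, 0)), ("C", (7, 0, 0))])])
        category, _ = classify_complex(system)
        assert category.reason == "nonstandard-amino-acid"

    def test_clean_fixture_converted(self, toy_complex):
        system, _ = toy_complex
        category, _ = classify_complex(system)
        assert category.outcome == "converted"

    def test_supported_ion_is_not_a_metal_rejection(self):
        system, _ = fixtures.make_toy_complex(
            fixtures.FixtureSpec(seed=1, include_ion=True))
        category, _ = classify_complex(system)
        assert category.outcome == "converted"


class TestSiteCompleteness:
    GLU_COMPLETE = [("N", (2.0, 0, 0)), ("CA", (2.5, 1, 0)), ("C", (3.5, 1, 0)),
                    ("O", (4.0, 2, 0)), ("CB", (2.5, 2, 0)), ("CG", (3.0, 3, 0)),
                    ("CD", (3.0, 4, 0)), ("OE1", (2.5, 5, 0)), ("OE2", (4.0, 4.5, 0))]

    def test_truncated_side_chain_near_ligand_violates(self):
        truncated = [a for a in self.GLU_COMPLETE if a[0] != "OE1"]
        system = _mini_system([("GLU", 1, truncated)])
        violations, _ = check_site_completeness(system)
        assert [(key[2], name) for key, name in violations] == [("GLU", "OE1")]

    def test_same_truncation_outside_radius_passes(self):
        far = [(n, (x + 8.0, y, z)) for n, (x, y, z) in self.GLU_COMPLETE
               if n != "OE1"]
        system = _mini_system([("GLU", 1, far)])
        violations, _ = check_site_completeness(system)
        assert violations == []

    def test_complete_residue_passes(self):
        system = _mini_system([("GLU", 1, self.GLU_COMPLETE)])
        violations, _ = check_site_completeness(system)
        assert violations == []

    def test_unknown_template_skipped_with_note(self):
        system = _mini_system([("XYZ", 1, [("C1", (2.0, 0, 0))])])
        violations, notes = check_site_completeness(system)
        assert violations == []
        assert any("XYZ" in n for n in notes)


class TestSequenceConsistency:
    def _system(self, resnames):
        residues = [(rn, i + 1, [("CA", (float(i), 0, 0))])
                    for i, rn in enumerate(resnames)]
        return _mini_system(residues, ligand_xyz=(50.0, 0, 0))

    def test_exact_match_ok(self):
        system = self._system(["ALA", "CYS", "ASP"])
        assert check_sequence_consistency(system, {"A": "ACD"})[0] == "ok"

    def test_point_mismatch_located(self):
        system = self._system(["ALA", "CYS", "ASP"])
        status, details = check_sequence_consistency(system, {"A": "AVD"})
        assert status == "mismatch"
        assert "residue 2" in details[0]

    def test_unknown_x_at_resolved_position(self):
        system = self._system(["ALA", "CYS", "ASP"])
        status, _ = check_sequence_consistency(system, {"A": "AXD"})
        assert status == "unknown-sequence"

    def test_missing_chain_record(self):
        system = self._system(["ALA"])
        status, _ = check_sequence_consistency(system, {"B": "A"})
        assert status == "unknown-sequence"


class TestGaps:
    def _dipeptide(self, second_offset=0.0, second_resid=2):
        res1 = [("N", (0, 0, 0)), ("CA", (1.0, 0.5, 0)), ("C", (2.0, 0, 0))]
        res2 = [("N", (3.33 + second_offset, 0, 0)),
                ("CA", (4.3 + second_offset, 0.5, 0)),
                ("C", (5.3 + second_offset, 0, 0))]
        return _mini_system([("ALA", 1, res1), ("ALA", second_resid, res2)],
                            ligand_xyz=(50, 0, 0))

    def test_continuous_dipeptide_no_gap(self):
        assert detect_chain_gaps(self._dipeptide()) == []

    def test_translated_residue_is_a_gap(self):
        assert detect_chain_gaps(self._dipeptide(second_offset=10.0)) == [
            ("A", 1, 2)]

    def test_numbering_jump_flagged_despite_geometry(self):
        assert detect_chain_gaps(self._dipeptide(second_resid=3)) == [
            ("A", 1, 3)]


class TestDisulfides:
    def _two_cys(self, sep):
        res1 = [("N", (0, 0, 0)), ("CA", (1, 1, 0)), ("C", (2, 0, 0)),
                ("SG", (0, 3, 0))]
        res2 = [("N", (6, 0, 0)), ("CA", (7, 1, 0)), ("C", (8, 0, 0)),
                ("SG", (0, 3 + sep, 0))]
        return _mini_system([("CYS", 1, res1), ("CYS", 2, res2)],
                            ligand_xyz=(50, 0, 0))

    def test_pair_inside_cutoff(self):
        assert detect_disulfides(self._two_cys(2.05)) == [(("A", 1), ("A", 2))]

    def test_pair_outside_cutoff(self):
        assert detect_disulfides(self._two_cys(2.5)) == []

    def test_changed_count_is_note_not_rejection(self):
        system, params = fixtures.make_toy_complex(
            fixtures.FixtureSpec(seed=1, defects=("disulfide-loss",)))
        report = triage(system, params)
        assert report.category.outcome == "converted"
        assert any("disulfide" in n for n in report.notes)

    def test_compare_detects_loss(self):
        status, changed = compare_disulfides([(("A", 1), ("A", 2))], [])
        assert status == "changed" and len(changed) == 1


class TestTriage:
    def test_defect_free_fixture_converted(self, toy_complex):
        system, params = toy_complex
        report = triage(system, params, fixtures.make_sequences(system))
        assert report.category.outcome == "converted"

    def test_priority_membrane_beats_later_defects(self):
        system, params = fixtures.make_toy_complex(fixtures.FixtureSpec(
            seed=1, defects=("membrane-flag", "missing-site-atom")))
        report = triage(system, params)
        assert report.category.reason == "membrane-protein"

    def test_gap_detection_crash_is_technical_failure(self):
        system, params = fixtures.make_toy_complex(
            fixtures.FixtureSpec(seed=1, defects=("gap-detection-failure",)))
        report = triage(system, params)
        assert (report.category.outcome, report.category.reason) == (
            "failed-technical", "gap-detection-failure")

    def test_parameter_mismatch_is_parameterization_failure(self, toy_complex):
        system, params = toy_complex
        report = triage(system, params.subset(np.arange(3)))
        assert report.category.reason == "ligand-parameterization-failure"

    def test_deterministic_reports(self, toy_complex):
        system, params = toy_complex
        seqs = fixtures.make_sequences(system)
        r1 = triage(system, params, seqs)
        r2 = triage(system, params, seqs)
        assert r1.as_dict() == r2.as_dict()


def _bulk_reports(count, outcome, reason):
    if outcome == "converted":
        return [TriageReport(f"c{i}", TriageCategory("converted"))
                for i in range(count)]
    return [TriageReport(f"{reason}{i}", TriageCategory(outcome, reason),
                         evidence=["injected"]) for i in range(count)]


class TestSummary:
    def test_outcome_percentages_sum_to_100(self):
        reports = (_bulk_reports(7, "converted", "none")
                   + _bulk_reports(2, "rejected-scientific", "membrane-protein")
                   + _bulk_reports(1, "failed-technical", "other-technical"))
        table = summarize_triage(reports)
        outcome_rows = table[table.group == "outcome"]
        assert abs(outcome_rows.percent.sum() - 100.0) <= 0.1

    def test_single_report_is_100_percent(self):
        table = summarize_triage(_bulk_reports(1, "converted", "none"))
        row = table[(table.group == "outcome") & (table.key == "converted")]
        assert float(row.percent.iloc[0]) == 100.0

    def test_reason_percentages_relative_to_group(self):
        reports = (_bulk_reports(6, "converted", "none")
                   + _bulk_reports(3, "rejected-scientific", "membrane-protein")
                   + _bulk_reports(1, "rejected-scientific",
                                   "unsupported-metal"))
        table = summarize_triage(reports)
        row = table[(table.group == "rejected-scientific")
                    & (table.key == "membrane-protein")]
        assert float(row.percent.iloc[0]) == 75.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            summarize_triage([])


def test_category_invariant_reason_none_iff_converted():
    with pytest.raises(ValueError):
        TriageCategory("rejected-scientific", "none")
    with pytest.raises(ValueError):
        TriageCategory("converted", "membrane-protein")
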