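"""Domain-type invariants and table/ensemble round trips."""

import numpy as np
import pytest

from chexfit.datamodel import (
    CESTProfile,
    ConformerEnsemble,
    RelaxationSeries,
    ResidueID,
    ShiftTable,
)
from chexfit.io import (
    CPMGIntensities,
    FormatError,
    ParseError,
    SchemaError,
    read_ensemble,
    read_intensity_table,
    read_shift_table,
    write_ensemble,
    write_intensity_table,
    write_shift_table,
)
from chexfit.synthetic import gen_ensemble, toy_backbone


class TestResidueID:
    def test_label(self):
        assert str(ResidueID("A", 122, "VAL")) == "VAL122"

    def test_rejects_unknown_code(self):
        with pytest.raises(ValueError, match="unknown residue name"):
            ResidueID("A", 1, "XYZ")


class TestRelaxationSeriesInvariants:
    def test_rejects_nonpositive_delay(self):
        with pytest.raises(ValueError, match="positive"):
            RelaxationSeries(ResidueID("A", 1, "ALA"), [0.0, 0.1],
                             [1.0, 0.5], [0.01, 0.01])

    def test_hetnoe_single_point(self):
        with pytest.raises(ValueError, match="exactly one"):
            RelaxationSeries(ResidueID("A", 1, "ALA"), [1.0, 2.0],
                             [1.0, 0.5], [0.01, 0.01], kind="hetnoe-sat")


class TestIntensityTable:
    def _cpmg_records(self, n_res=3):
        nu = np.array([50., 100., 200., 350., 500., 750., 1000., 1500.,
                       2000., 750., 50.])
        return [CPMGIntensities(
            residue=ResidueID("A", 100 + i, "ALA"),
            nu_cpmg=nu,
            intensities=np.linspace(0.6, 0.2, len(nu)) + 0.01 * i,
            errors=np.full(len(nu), 0.01),
            reference=1.0 + 0.001 * i) for i in range(n_res)]

    def test_cpmg_round_trip_preserves_duplicates(self, tmp_path):
        path = tmp_path / "cpmg.tsv"
        write_intensity_table(self._cpmg_records(), path)
        back = read_intensity_table(path, "cpmg")
        assert len(back) == 3
        for orig, new in zip(self._cpmg_records(), back):
            assert len(new.nu_cpmg) == 11          # 9 freqs + 2 duplicates
            np.testing.assert_allclose(new.intensities, orig.intensities,
                                       rtol=1e-6)
            np.testing.assert_allclose(new.reference, orig.reference,
                                       rtol=1e-6)

    def test_relaxation_round_trip(self, tmp_path):
        series = RelaxationSeries(
            ResidueID("A", 110, "GLN"),
            delays=np.array([0.05, 0.2, 0.5, 1.1]),
            intensities=np.array([0.9, 0.6, 0.3, 0.08]),
            errors=np.full(4, 0.01), kind="T1")
        path = tmp_path / "t1.tsv"
        write_intensity_table([series], path)
        back = read_intensity_table(path, "T1")
        assert len(back) == 1
        np.testing.assert_allclose(back[0].delays, series.delays, rtol=1e-6)
        np.testing.assert_allclose(back[0].intensities, series.intensities,
                                   rtol=1e-6)

    def test_cest_round_trip_keeps_b1(self, tmp_path):
        prof = CESTProfile(
            ResidueID("A", 134, "ASN"),
            offsets=np.linspace(134, 99, 16),
            intensities=np.linspace(0.9, 0.8, 16),
            errors=np.full(16, 0.01), b1_hz=15.0)
        path = tmp_path / "cest.tsv"
        write_intensity_table([prof], path)
        back = read_intensity_table(path, "cest")
        assert len(back) == 1 and back[0].b1_hz == 15.0

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert read_intensity_table(path, "T1") == []

    def test_non_numeric_cell_names_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "residue_number\tresidue_name\texperiment\tparameter\tvalue"
            "\tintensity\terror\n"
            "110\tGLN\tT1\tdelay\t0.05\t0.9\t0.01\n"
            "110\tGLN\tT1\tdelay\t0.20\toops\t0.01\n")
        with pytest.raises(ParseError, match="row 3"):
            read_intensity_table(path, "T1")

    def test_missing_column_names_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("residue_number\tvalue\n1\t2\n")
        with pytest.raises(SchemaError, match="intensity"):
            read_intensity_table(path, "T1")

    def test_no_silent_row_drops(self, tmp_path):
        """Input row count equals parsed plus reported-skipped."""
        path = tmp_path / "mixed.tsv"
        rows = ["residue_number\tresidue_name\texperiment\tparameter\tvalue"
                "\tintensity\terror"]
        for d in (0.05, 0.2, 0.5):
            rows.append(f"110\tGLN\tT1\tdelay\t{d}\t0.5\t0.01")
        rows.append("110\tGLN\tT2\tdelay\t0.005\t0.9\t0.01")
        path.write_text("\n".join(rows) + "\n")
        records, report = read_intensity_table(path, "T1", with_report=True)
        assert report["total"] == report["parsed"] + report["skipped"] == 4
        assert report["parsed"] == 3 and len(records) == 1


STAR_MINIMAL = """\
data_synthetic_shifts

save_assigned_chemical_shifts
   loop_
      _Atom_chem_shift.ID
      _Atom_chem_shift.Comp_index_ID
      _Atom_chem_shift.Comp_ID
      _Atom_chem_shift.Atom_ID
      _Atom_chem_shift.Val

      1 111 ARG N 118.42
      2 111 ARG H 8.21
      3 134 ASN N 121.77
      4 134 ASN H 7.95
      5 134 ASN CA 53.10

   stop_
save_
"""


class TestShiftTable:
    def test_star_reader(self, tmp_path):
        path = tmp_path / "shifts.str"
        path.write_text(STAR_MINIMAL)
        table = read_shift_table(path)
        assert len(table) == 5
        assert table[(ResidueID("A", 111, "ARG"), "N")] == pytest.approx(118.42)

    def test_tsv_and_star_dialects_agree(self, tmp_path):
        star = tmp_path / "shifts.str"
        star.write_text(STAR_MINIMAL)
        table = read_shift_table(star)
        tsv = tmp_path / "shifts.tsv"
        write_shift_table(table, tsv)
        assert read_shift_table(tsv).entries == table.entries

    def test_star_without_shift_loop_errors(self, tmp_path):
        path = tmp_path / "bad.str"
        path.write_text("data_x\nloop_\n_Other.Tag\n1\nstop_\n")
        with pytest.raises(FormatError, match="shift loop"):
            read_shift_table(path)

    def test_out_of_range_shift_flagged_not_dropped(self, tmp_path):
        path = tmp_path / "odd.tsv"
        path.write_text("residue_number\tresidue_name\tatom\tshift_ppm\n"
                        "111\tARG\tN\t300.0\n")
        table = read_shift_table(path)
        assert len(table) == 1
        assert len(table.out_of_range()) == 1

    def test_duplicate_key_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("residue_number\tresidue_name\tatom\tshift_ppm\n"
                        "111\tARG\tN\t118.0\n111\tARG\tN\t119.0\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_shift_table(path)


class TestEnsembleIO:
    def test_multi_model_round_trip(self, tmp_path):
        base = toy_backbone(5)
        ens = gen_ensemble(base, 0.2, n_models=2, seed=1)
        path = tmp_path / "ens.pdb"
        write_ensemble(ens, path)
        back = read_ensemble(path)
        assert back.n_models == 2
        assert back.n_atoms == ens.n_atoms
        np.testing.assert_allclose(back.coords, ens.coords, atol=1e-3)

    def test_backbone_selection(self, tmp_path):
        ens = gen_ensemble(toy_backbone(5), 0.0, n_models=2, seed=1)
        path = tmp_path / "ens.pdb"
        write_ensemble(ens, path)
        sel = read_ensemble(path, atom_names={"N", "CA", "C", "O"})
        assert sel.n_models == 2 and sel.n_atoms == 20

    def test_single_model(self, tmp_path):
        path = tmp_path / "one.pdb"
        write_ensemble(toy_backbone(4), path)
        assert read_ensemble(path).n_models == 1

    def test_absent_residue_selection_errors(self, tmp_path):
        path = tmp_path / "ens.pdb"
        write_ensemble(toy_backbone(4, start=101), path)
        with pytest.raises(FormatError, match="selection matches no atoms"):
            read_ensemble(path, residues={999})

    def test_ensemble_rejects_nonfinite(self):
        atoms = [(ResidueID("A", 1, "ALA"), "CA")]
        with pytest.raises(ValueError, match="finite"):
            ConformerEnsemble(atoms, np.array([[[np.nan, 0, 0]]]))
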