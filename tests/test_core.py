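"""Domain types, thermodynamic conversions, and docking-table / PDB I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dibs.core import (
    ConformerEnsemble,
    DockingRun,
    EnsembleDockingTable,
    ProteinDefinition,
    StructureModel,
    delta_g_from_kd,
    kd_from_delta_g,
    read_docking_table,
    read_ensemble_pdb,
    read_fasta_protein,
    write_docking_table,
    write_ensemble_pdb,
)


class TestThermodynamics:
    @pytest.mark.parametrize(
        "kd_molar, expected",
        [
            (817.24e-9, 8.30),  # top-ranked IDP-ensemble run
            (766.47e-9, 8.34),  # top-ranked random-coil run
        ],
    )
    def test_reproduces_reported_binding_energies(self, kd_molar, expected):
        assert round(delta_g_from_kd(kd_molar, 298.0), 2) == expected

    def test_unit_kd_gives_zero_energy(self):
        assert delta_g_from_kd(1.0) == 0.0
        assert kd_from_delta_g(0.0) == 1.0

    def test_inverse_identity_at_micromolar(self):
        dg = delta_g_from_kd(1e-6)
        assert kd_from_delta_g(dg) == pytest.approx(1e-6, rel=1e-12)

    def test_2dp_energy_recovers_kd_within_rounding(self):
        # 8.30 kcal/mol is the 2-d.p. rounding of the 817.24 nM conversion
        kd = kd_from_delta_g(8.30, 298.0)
        assert kd == pytest.approx(8.19e-7, rel=2e-3)

    @given(st.floats(min_value=-12, max_value=0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_exact(self, log10_kd):
        kd = 10.0**log10_kd
        assert kd_from_delta_g(delta_g_from_kd(kd)) == pytest.approx(kd, rel=1e-12)

    def test_strictly_decreasing_in_kd(self):
        kds = np.logspace(-12, 0, 40)
        dgs = delta_g_from_kd(kds)
        assert np.all(np.diff(dgs) < 0)

    @pytest.mark.parametrize("bad", [0.0, -1e-9])
    def test_nonpositive_kd_rejected(self, bad):
        with pytest.raises(ValueError):
            delta_g_from_kd(bad)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            delta_g_from_kd(1e-6, temperature=0.0)

    def test_overflow_guard(self):
        with pytest.raises(ValueError):
            kd_from_delta_g(150.0)


class TestProteinDefinition:
    def test_default_numbering_is_one_based(self):
        p = ProteinDefinition("ACD")
        assert p.residue_numbers == (1, 2, 3)

    def test_rejects_unknown_letters(self):
        with pytest.raises(ValueError):
            ProteinDefinition("ACZ")

    def test_rejects_non_increasing_numbering(self):
        with pytest.raises(ValueError):
            ProteinDefinition("ACD", residue_numbers=(1, 3, 3))

    def test_rejects_empty_sequence(self):
        with pytest.raises(ValueError):
            ProteinDefinition("")

    def test_fasta_round_trip(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">toy description\nACDEF\nGHIKL\n")
        p = read_fasta_protein(fasta)
        assert p.sequence == "ACDEFGHIKL"
        assert p.name == "toy"


class TestDockingTable:
    def test_contact_residues_must_belong_to_protein(self, protein10):
        run = DockingRun(1, 1, 8.0, 1e-6, frozenset({99}))
        with pytest.raises(ValueError, match="99"):
            EnsembleDockingTable([run], "idp", 1, protein10)

    def test_duplicate_run_ids_rejected(self, protein10):
        runs = [DockingRun(1, 1, 8.0, 1e-6), DockingRun(1, 2, 7.0, 1e-5)]
        with pytest.raises(ValueError):
            EnsembleDockingTable(runs, "idp", 1, protein10)

    def test_rank_assignment_ties_broken_by_run_id(self, protein10, table_builder):
        table = table_builder(
            protein10, [{1}, {2}, {3}], [1e-6, 1e-5, 1e-6], energies=[8.3, 7.1, 8.3]
        )
        ranked = {r.run_id: r.rank for r in table.ranked().runs}
        assert ranked == {1: 1, 2: 3, 3: 2}

    def test_tsv_round_trip_identity(self, tmp_path, protein10, random_tables):
        table = random_tables(seed=3, n_runs=25)
        path = write_docking_table(table, tmp_path / "t.tsv")
        back = read_docking_table(path, protein10)
        assert back.ensemble_label == table.ensemble_label
        assert back.replicate_id == table.replicate_id
        for a, b in zip(table.ranked().runs, back.runs):
            assert (a.run_id, a.conformer_id, a.contact_residues) == (
                b.run_id,
                b.conformer_id,
                b.contact_residues,
            )
            assert b.binding_energy == a.binding_energy
            assert b.dissociation_constant == a.dissociation_constant

    def test_serialization_is_byte_stable(self, tmp_path, random_tables):
        table = random_tables(seed=5)
        p1 = write_docking_table(table, tmp_path / "a.tsv")
        p2 = write_docking_table(table, tmp_path / "b.tsv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_table_writes_header_only(self, tmp_path, protein10):
        table = EnsembleDockingTable([], "idp", 1, protein10)
        path = write_docking_table(table, tmp_path / "empty.tsv")
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 1 and lines[0].startswith("run_id\t")

    def test_out_of_range_contact_cites_row(self, tmp_path, protein10):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "run_id\tconformer_id\tbinding_energy\tdissociation_constant\tcontact_residues\n"
            "1\t1\t8.18\t1e-06\t1,2\n"
            "2\t1\t8.18\t1e-06\t99\n"
        )
        with pytest.raises(ValueError, match=r":3.*99"):
            read_docking_table(path, protein10, ensemble_label="idp")

    def test_malformed_numeric_cites_line(self, tmp_path, protein10):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "run_id\tconformer_id\tbinding_energy\tdissociation_constant\tcontact_residues\n"
            "1\t1\tnotanumber\t1e-06\t1\n"
        )
        with pytest.raises(ValueError, match=":2"):
            read_docking_table(path, protein10, ensemble_label="idp")

    def test_kd_units_column_converted(self, tmp_path, protein10):
        path = tmp_path / "units.tsv"
        path.write_text(
            "run_id\tconformer_id\tbinding_energy\tdissociation_constant\tkd_units\tcontact_residues\n"
            "1\t1\t8.30\t817.24\tnM\t1\n"
        )
        table = read_docking_table(path, protein10, ensemble_label="idp")
        assert table.runs[0].dissociation_constant == pytest.approx(817.24e-9)

    def test_inconsistent_energy_kd_pair_rejected(self, tmp_path, protein10):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "run_id\tconformer_id\tbinding_energy\tdissociation_constant\tcontact_residues\n"
            "1\t1\t5.00\t1e-06\t1\n"  # 1 uM implies ~8.18 kcal/mol
        )
        with pytest.raises(ValueError, match="inconsistent"):
            read_docking_table(path, protein10, ensemble_label="idp")

    def test_ranks_assigned_when_missing(self, tmp_path, protein10):
        path = tmp_path / "norank.tsv"
        path.write_text(
            "# ensemble_label=idp\n"
            "run_id\tconformer_id\tbinding_energy\tdissociation_constant\tcontact_residues\n"
            "1\t1\t8.3\t8.2372e-07\t1\n"
            "2\t1\t7.1\t6.2076e-06\t2\n"
            "3\t2\t8.3\t8.2372e-07\t3\n"
        )
        table = read_docking_table(path, protein10)
        assert {r.run_id: r.rank for r in table.runs} == {1: 1, 2: 3, 3: 2}


def _toy_ensemble(protein, n_models=3, seed=0):
    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n_models):
        resnums, names, elems, coords = [], [], [], []
        for r in protein.residue_numbers:
            for name in ("N", "CA", "C", "O"):
                resnums.append(r)
                names.append(name)
                elems.append(name[0])
                coords.append(rng.normal(scale=5.0, size=3))
        models.append(StructureModel(np.array(resnums), tuple(names), tuple(elems), np.array(coords)))
    return ConformerEnsemble(models, protein)


class TestEnsemblePDB:
    def test_multi_model_round_trip(self, tmp_path, protein10):
        ens = _toy_ensemble(protein10, n_models=5)
        path = write_ensemble_pdb(ens, tmp_path / "e.pdb")
        back = read_ensemble_pdb(path, protein10)
        assert len(back) == 5
        np.testing.assert_allclose(
            back.models[0].coordinates, ens.models[0].coordinates, atol=1e-3
        )

    def test_single_model_file_yields_one_model(self, tmp_path):
        protein2 = ProteinDefinition("AC")
        ens = _toy_ensemble(protein2, n_models=1)
        path = write_ensemble_pdb(ens, tmp_path / "one.pdb")
        assert len(read_ensemble_pdb(path, protein2)) == 1

    def test_residue_mismatch_reported(self, tmp_path):
        protein5 = ProteinDefinition("ACDEF")
        protein4 = ProteinDefinition("ACDE")
        path = write_ensemble_pdb(_toy_ensemble(protein4), tmp_path / "m.pdb")
        with pytest.raises(ValueError, match="missing"):
            read_ensemble_pdb(path, protein5)

    def test_all_models_share_residue_set(self, protein10):
        models = _toy_ensemble(protein10, 2).models
        smaller = ProteinDefinition("ACDEF")
        bad = _toy_ensemble(smaller, 1).models[0]
        with pytest.raises(ValueError):
            ConformerEnsemble([models[0], bad], protein10)
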