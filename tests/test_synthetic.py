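"""Generators: determinism, truth consistency, generative-formula agreement."""

import json

import numpy as np
import pytest
from rdkit import Chem

from dimerscreen import synthetic as syn
from dimerscreen.doseresponse import FourPLFit, four_pl
from dimerscreen.exceptions import DataError, PackingError, PatternError
from dimerscreen.library import CompoundLibrary
from dimerscreen.plates import SAMPLE


class TestSimulateScreen:
    def test_degenerate_spec_gives_exact_grand_mean(self):
        spec = syn.PlateEffectSpec(
            row_gradient=0, col_gradient=0, edge_depression=0, noise_cv=0, spike_rate=0
        )
        plates, _ = syn.simulate_screen(spec, n_plates=1)
        sample = plates[0].sample_mask
        assert np.allclose(plates[0].values[sample], spec.grand_mean)

    def test_seed_reproducibility_byte_for_byte(self):
        spec = syn.PlateEffectSpec(seed=42)
        p1, t1 = syn.simulate_screen(spec, n_plates=3)
        p2, t2 = syn.simulate_screen(spec, n_plates=3)
        for a, b in zip(p1, p2):
            assert a.values.tobytes() == b.values.tobytes()
        assert t1.wells.equals(t2.wells)

    def test_truth_has_exactly_one_row_per_sample_well(self, small_screen):
        _, plates, truth = small_screen
        n_sample = sum(p.sample_mask.sum() for p in plates)
        assert len(truth.wells) == n_sample
        assert not truth.wells.duplicated(["plate_id", "row", "col"]).any()

    def test_row_gradient_orders_row_means(self):
        spec = syn.PlateEffectSpec(
            row_gradient=0.3, col_gradient=0, edge_depression=0, noise_cv=0, spike_rate=0
        )
        layout = syn.PlateLayout()
        plates, _ = syn.simulate_screen(spec, n_plates=1, layout=layout)
        plate = plates[0]
        sample = plate.sample_mask
        row_means = [plate.values[i][sample[i]].mean() for i in range(layout.n_rows)]
        assert np.all(np.diff(row_means) > 0)
        # column means constant for interior sample columns
        interior = [j for j in range(1, layout.n_cols - 1)
                    if np.all(sample[1:-1, j])]
        col_means = [plate.values[1:-1, j].mean() for j in interior]
        assert np.allclose(col_means, col_means[0], rtol=1e-12)
        # and each well equals the generative formula exactly at zero noise
        for i, j in zip(*np.nonzero(sample)):
            assert plate.values[i, j] == pytest.approx(
                syn.expected_well_mean(spec, layout, i, j)
            )

    def test_simulated_means_agree_with_generative_formula(self):
        # over many seeds the per-well mean matches the formula within 3 SE
        layout = syn.PlateLayout()
        n_seeds = 100
        acc = np.zeros((layout.n_rows, layout.n_cols))
        spec0 = syn.PlateEffectSpec(spike_rate=0.0)
        for seed in range(n_seeds):
            spec = syn.PlateEffectSpec(spike_rate=0.0, seed=seed)
            plates, _ = syn.simulate_screen(spec, n_plates=1, layout=layout)
            acc += plates[0].values
        acc /= n_seeds
        sample = layout.roles() == SAMPLE
        z = []
        for i, j in zip(*np.nonzero(sample)):
            mu = syn.expected_well_mean(spec0, layout, i, j)
            se = mu * spec0.noise_cv / np.sqrt(n_seeds)
            z.append(abs(acc[i, j] - mu) / se)
        z = np.asarray(z)
        # per-well z-scores: allow the expected few 3-sigma exceedances
        assert np.mean(z < 3) >= 0.98
        assert np.all(z < 5)

    def test_invalid_spec_rejected(self):
        with pytest.raises(DataError):
            syn.PlateEffectSpec(grand_mean=0)
        with pytest.raises(DataError):
            syn.PlateEffectSpec(spike_rate=1.5)
        with pytest.raises(DataError):
            syn.PlateEffectSpec(noise_cv=-0.1)


class TestGenerateLibrary:
    def test_forced_composition_extremes(self):
        lib1, t1 = syn.generate_library(syn.LibrarySpec(n_compounds=50, active_fraction=1.0, seed=1))
        lib0, t0 = syn.generate_library(syn.LibrarySpec(n_compounds=50, active_fraction=0.0, seed=1))
        query = Chem.MolFromSmiles(syn.LibrarySpec().pharmacophore)
        for lib, expect in ((lib1, True), (lib0, False)):
            _, mols = lib.parsed()
            assert len(mols) == 50
            assert all(m.HasSubstructMatch(query) is expect for m in mols)

    def test_truth_active_count_equals_brute_force_match_count(self, planted_library):
        spec, lib, truth = planted_library
        query = Chem.MolFromSmiles(spec.pharmacophore)
        brute = sum(
            Chem.MolFromSmiles(s).HasSubstructMatch(query)
            for s in lib.records["smiles"]
        )
        assert brute == int(truth.compounds["is_carrier"].sum())
        # with zero label noise the labels equal carrier truth
        assert (truth.compounds["label"] == truth.compounds["is_carrier"].astype(int)).all()

    def test_label_noise_flips_recorded_fraction(self):
        spec = syn.LibrarySpec(n_compounds=1000, active_fraction=0.5, label_noise=0.2, seed=9)
        _, truth = syn.generate_library(spec)
        flipped = (truth.compounds["label"] != truth.compounds["is_carrier"].astype(int)).mean()
        assert 0.14 < flipped < 0.26

    def test_smi_round_trip(self, tmp_path, planted_library):
        _, lib, _ = planted_library
        path = tmp_path / "lib.smi"
        lib.to_smi(path)
        back = CompoundLibrary.from_smi(path)
        assert back.ids == lib.ids
        assert back.records["smiles"].tolist() == lib.records["smiles"].tolist()

    def test_unparsable_pharmacophore_rejected(self):
        with pytest.raises(PatternError):
            syn.LibrarySpec(pharmacophore="not-a-smiles((")


class TestSimulateDrc:
    TRUE = FourPLFit(bottom=0.0, top=100.0, ec50=1e-6, hill=1.0)

    def test_zero_noise_lies_exactly_on_curve(self):
        table, _ = syn.simulate_drc(self.TRUE, noise_cv=0.0, pos_level=1e6, neg_level=0.0)
        samples = table[table["role"] == "sample"]
        for row in samples.itertuples(index=False):
            y = four_pl(row.conc_molar, 0.0, 100.0, 1e-6, 1.0)
            assert row.value == pytest.approx(1e6 * y / 100.0)

    def test_midpoint_identity_at_ec50(self):
        table, _ = syn.simulate_drc(
            self.TRUE, concentrations=[1e-7, 1e-6, 1e-5, 1e-4], noise_cv=0.0,
            pos_level=1e6, neg_level=0.0,
        )
        at_ec50 = table[(table["role"] == "sample") & (table["conc_molar"] == 1e-6)]
        assert np.allclose(at_ec50["value"], 1e6 * 50.0 / 100.0)

    def test_noise_cv_monte_carlo_envelope(self):
        # per-concentration sample CV stays within [0.01, 0.12] for >=95% of seeds
        inside = total = 0
        for seed in range(400):
            table, _ = syn.simulate_drc(self.TRUE, n_reps=4, noise_cv=0.05, seed=seed)
            samples = table[table["role"] == "sample"]
            for _, grp in samples.groupby("conc_molar"):
                cv = grp["value"].std(ddof=1) / grp["value"].mean()
                inside += 0.01 <= cv <= 0.12
                total += 1
        assert inside / total >= 0.95

    def test_negative_concentration_rejected(self):
        with pytest.raises(DataError):
            syn.simulate_drc(self.TRUE, concentrations=[-1e-6, 1e-6, 1e-5, 1e-4])


class TestRenderCellImage:
    def test_empty_image_is_pure_background_noise(self):
        spec = syn.CellImageSpec(n_cells=0, noise_sd=10.0, seed=0)
        image, truth = syn.render_cell_image(spec)
        assert truth.cells.empty
        assert image.shape == (2, *spec.image_shape)
        assert abs(image.astype(float).mean() - spec.background_intensity) < 5

    def test_disk_cell_truth_area_matches_rasterized_disk(self):
        # a single near-circular cell of ~pi * 50^2 px
        spec = syn.CellImageSpec(
            n_cells=1, cell_area_range=(np.pi * 2500, np.pi * 2500), seed=3,
        )
        _, truth = syn.render_cell_image(spec)
        assert truth.cells["area_px"].iloc[0] == pytest.approx(np.pi * 2500, rel=0.01)

    def test_seed_reproducibility(self):
        spec = syn.CellImageSpec(seed=7)
        i1, t1 = syn.render_cell_image(spec)
        i2, t2 = syn.render_cell_image(spec)
        assert np.array_equal(i1, i2)
        assert t1.cells.equals(t2.cells)

    def test_border_cells_flagged_in_truth(self):
        spec = syn.CellImageSpec(n_cells=6, n_border_cells=2, seed=8)
        _, truth = syn.render_cell_image(spec)
        assert truth.cells["touches_border"].sum() == 2

    def test_impossible_packing_raises(self):
        with pytest.raises(PackingError):
            syn.render_cell_image(
                syn.CellImageSpec(image_shape=(64, 64), n_cells=5,
                                  cell_area_range=(3000.0, 3000.0), seed=0)
            )

    def test_each_cell_has_one_nucleus_truth_entry(self, cell_image):
        _, _, truth = cell_image
        assert (truth.cells["nucleus_area_px"] > 0).all()
        labels = truth.cell_labels
        for rec in truth.cells.itertuples(index=False):
            nuc = truth.nucleus_labels == rec.cell_id
            assert nuc.sum() == rec.nucleus_area_px
            assert (labels[nuc] == rec.cell_id).all()


class TestWriteFixtures:
    def test_manifest_covers_all_input_kinds_and_recounts(self, tmp_path):
        manifest = syn.write_fixtures(tmp_path, seed=0, n_plates=1, n_images=1)
        names = list(manifest["files"])
        assert any(n.endswith(".csv") and "plate" in n for n in names)
        assert any(n.endswith(".smi") for n in names)
        assert any(n == "drc.csv" for n in names)
        assert any(n.endswith(".tif") for n in names)
        # truth recount: manifest rows equal generated record counts
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert len(truth["truth"]["compounds"]) == 200
        n_wells = len(truth["truth"]["wells"])
        assert n_wells == 16 * 24 - 2 * 16  # one plate minus control columns

    def test_rerun_with_same_seed_gives_identical_checksums(self, tmp_path):
        m1 = syn.write_fixtures(tmp_path / "a", seed=3, n_plates=1, n_images=1)
        m2 = syn.write_fixtures(tmp_path / "b", seed=3, n_plates=1, n_images=1)
        assert m1["files"] == m2["files"]
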