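import numpy as np
import pandas as pd
import pytest

from nirleaf.data_model import (
    DESIGNS,
    ReferenceTable,
    SpectraSet,
    align_reference,
    build_dataset,
    get_design,
    load_spectra,
    merge_spectra,
    read_jcamp,
    save_spectra,
    summarize_counts,
    write_jcamp,
)


class TestSpectraIO:
    def test_csv_round_trip(self, small_dataset, tmp_path):
        _, spectra, _ = small_dataset
        save_spectra(spectra, tmp_path / "s.csv", tmp_path / "m.csv")
        loaded = load_spectra(tmp_path / "s.csv", meta_path=tmp_path / "m.csv")
        np.testing.assert_allclose(loaded.wavenumbers, spectra.wavenumbers, atol=1e-12)
        np.testing.assert_allclose(loaded.intensities, spectra.intensities, atol=1e-12)
        assert list(loaded.meta["sample_id"]) == list(spectra.meta["sample_id"])
        assert list(loaded.meta["season"]) == list(spectra.meta["season"])

    def test_single_spectrum_csv(self, tmp_path):
        wn = np.arange(10000.0, 3999.0, -8.0)
        df = pd.DataFrame({"wavenumber_cm-1": wn, "leaf__r1": np.ones(wn.size)})
        df.to_csv(tmp_path / "one.csv", index=False)
        s = load_spectra(tmp_path / "one.csv")
        assert s.n_spectra == 1 and s.n_points == 751

    def test_ascending_grid_reordered_to_descending(self, tmp_path):
        wn = np.arange(400.0, 801.0, 8.0)  # ascending on disk
        df = pd.DataFrame({"wavenumber_cm-1": wn, "x__r1": wn * 0.001})
        df.to_csv(tmp_path / "asc.csv", index=False)
        s = load_spectra(tmp_path / "asc.csv")
        assert s.wavenumbers[0] == 800.0
        np.testing.assert_allclose(s.intensities[0], s.wavenumbers * 0.001)

    def test_non_numeric_cell_reported(self, tmp_path):
        (tmp_path / "bad.csv").write_text(
            "wavenumber_cm-1,x__r1\n100,0.5\n92,oops\n84,0.7\n"
        )
        with pytest.raises(ValueError, match="non-numeric"):
            load_spectra(tmp_path / "bad.csv")

    def test_grid_mismatch_names_offender(self, small_dataset):
        _, spectra, _ = small_dataset
        other = SpectraSet(
            spectra.wavenumbers[:-1],
            spectra.intensities[:1, :-1],
            spectra.meta.iloc[:1],
        )
        with pytest.raises(ValueError, match="grid mismatch"):
            merge_spectra([spectra, other])

    def test_jcamp_round_trip(self, tmp_path):
        wn = np.arange(10000.0, 3999.0, -8.0)
        y = np.exp(-((wn - 5200.0) ** 2) / (2 * 80.0 ** 2))
        write_jcamp(tmp_path / "s.jdx", wn, y, title="leaf")
        x2, y2, title = read_jcamp(tmp_path / "s.jdx")
        np.testing.assert_allclose(x2, wn, atol=1e-4)
        np.testing.assert_allclose(y2, y, atol=1e-7)
        assert title == "leaf"
        s = load_spectra(tmp_path / "s.jdx", format="jcamp")
        assert s.n_spectra == 1 and s.wavenumbers[0] == 10000.0


class TestDesigns:
    def test_canonical_designs(self):
        assert DESIGNS[1].seasons == frozenset({"spring", "fall", "winter"})
        assert DESIGNS[1].regions == frozenset({"RA", "RB", "RC"})
        assert DESIGNS[2].regions == frozenset({"RA"})
        assert DESIGNS[3].seasons == frozenset({"spring"})
        assert DESIGNS[4] == get_design(4)
        assert DESIGNS[5].seasons == frozenset({"fall"})
        assert DESIGNS[6].seasons == frozenset({"winter"})

    def test_design_1_is_identity(self, small_dataset):
        _, spectra, ref = small_dataset
        sub, subref = build_dataset(spectra, ref, 1)
        assert sub.n_spectra == spectra.n_spectra
        assert len(subref) == len(ref)

    def test_design_4_subset_of_2_and_3(self, small_dataset):
        _, spectra, ref = small_dataset
        ids = {
            d: set(build_dataset(spectra, ref, d)[0].sample_ids) for d in (2, 3, 4)
        }
        assert ids[4] <= ids[2] and ids[4] <= ids[3]

    def test_union_of_seasonal_designs_recovers_single_region_set(
        self, small_dataset
    ):
        _, spectra, ref = small_dataset
        ids = {
            d: set(build_dataset(spectra, ref, d)[0].sample_ids)
            for d in (2, 4, 5, 6)
        }
        assert ids[4] | ids[5] | ids[6] == ids[2]

    def test_filtering_idempotent(self, small_dataset):
        _, spectra, ref = small_dataset
        once = build_dataset(spectra, ref, 5)
        twice = build_dataset(*once, 5)
        assert once[0].sample_ids == twice[0].sample_ids

    def test_design_6_on_fixture_tpc_retains_18_entries(self, fixtures):
        _, ref = build_dataset(None, fixtures.tpc, 6)
        assert len(ref) == 18

    def test_empty_result_rejected(self, small_dataset):
        # the small dataset has region RA only, so an RB-only design is empty
        _, spectra, ref = small_dataset
        design = get_design(3)
        rb_only = type(design)(None, frozenset({"spring"}), frozenset({"RB"}))
        with pytest.raises(ValueError):
            build_dataset(spectra, ref, rb_only)


class TestAlign:
    def test_replicate_expansion(self, small_dataset):
        _, spectra, ref = small_dataset
        X, y, groups = align_reference(spectra, ref, "TPC")
        assert X.shape[0] == y.size == groups.size == spectra.n_spectra
        # y repeats the sample mean across its replicates
        sid = groups[0]
        expected = ref.df.query("sample_id == @sid and parameter == 'TPC'")[
            "mean"
        ].iloc[0]
        np.testing.assert_allclose(y[groups == sid], expected)

    def test_average_replicates_collapses_rows(self, small_dataset):
        _, spectra, ref = small_dataset
        X, y, groups = align_reference(spectra, ref, "TPC", average_replicates=True)
        assert X.shape[0] == len(spectra.sample_ids)
        assert len(set(groups)) == len(groups)

    def test_unknown_parameter_rejected(self, small_dataset):
        _, spectra, ref = small_dataset
        with pytest.raises(ValueError):
            align_reference(spectra, ref, "sugar")


class TestCounts:
    def test_cultivar_and_plant_counts(self, fixtures):
        counts = summarize_counts(fixtures.plants)
        assert counts["n_cultivars"] == 27
        assert counts["n_plants"] == 35
        assert counts["cultivars_per_species"]["V. ashei"] == 3
        assert counts["cultivars_per_species"]["V. corymbosum"] == 24

    def test_counts_come_from_the_table(self, fixtures):
        trimmed = fixtures.plants.iloc[:-2]
        counts = summarize_counts(trimmed)
        assert counts["n_cultivars"] == 25


class TestReferenceTable:
    def test_fixture_cells(self, fixtures):
        assert fixtures.tpc.cell("TPC", "Titan", "RA", "winter") == (272.8, 4.0)
        assert fixtures.tac.cell("TAC", "Huron", "RA", "fall") == (22.6, 0.7)
        # dash cells in the printed table are absent, not zero
        assert fixtures.tpc.cell("TPC", "Elliott", "RA", "spring") is None

    def test_fixture_column_counts_match_printed_tables(self, fixtures):
        for table in (fixtures.tpc, fixtures.tfc, fixtures.tac):
            counts = table.df.groupby(["season", "region"]).size().to_dict()
            assert counts == {
                ("spring", "RA"): 18,
                ("spring", "RB"): 9,
                ("spring", "RC"): 5,
                ("fall", "RA"): 13,
                ("winter", "RA"): 18,
            }

    def test_invalid_tables_rejected(self):
        df = pd.DataFrame(
            {
                "cultivar": ["a"],
                "region": ["RA"],
                "season": ["spring"],
                "parameter": ["TPC"],
                "mean": [-1.0],
                "sd": [0.1],
                "units": ["u"],
            }
        )
        with pytest.raises(ValueError):
            ReferenceTable(df)
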