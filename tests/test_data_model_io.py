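import numpy as np
import pytest

from reintroipm.data_model_io import (
    BugsParseError,
    CaptureHistory,
    Dataset,
    FecundityRecord,
    Individual,
    ModelConfig,
    ParameterSet,
    UnbandedCount,
    ValidationError,
    parse_bugs_dump,
    read_dataset,
    write_bugs_dump,
    write_dataset,
)
from reintroipm.synthetic_data import simulate_population

from conftest import small_scenario


class TestIndividual:
    def test_translocated_banding_method_flagged_not_applicable(self):
        ind = Individual(id="a", sex="male", origin="translocated",
                         banding_method="nestling", first_occasion=0)
        assert ind.banding_method == "not-applicable"

    def test_unknown_sex_code_rejected(self):
        with pytest.raises(ValidationError, match="sex"):
            Individual(id="a", sex="X", origin="wild-born",
                       banding_method="nestling", first_occasion=0)

    def test_wild_born_needs_banding_method(self):
        with pytest.raises(ValidationError, match="banding"):
            Individual(id="a", sex="male", origin="wild-born",
                       banding_method="not-applicable", first_occasion=0)


class TestCaptureHistoryValidation:
    def test_detection_before_first_occasion_rejected(self, toy_history):
        det = toy_history.detections.copy()
        det[2, 0] = 1  # w1 first seen at occasion 1
        with pytest.raises(ValidationError, match="w1"):
            CaptureHistory(toy_history.individuals, det, toy_history.occasions)

    def test_missing_entry_detection_rejected(self, toy_history):
        det = toy_history.detections.copy()
        det[0, 0] = 0
        with pytest.raises(ValidationError, match="f1"):
            CaptureHistory(toy_history.individuals, det, toy_history.occasions)

    def test_non_binary_matrix_rejected(self, toy_history):
        det = toy_history.detections.copy()
        det[0, 1] = 2
        with pytest.raises(ValidationError, match="0 or 1"):
            CaptureHistory(toy_history.individuals, det, toy_history.occasions)

    def test_duplicate_ids_rejected(self, toy_history):
        inds = list(toy_history.individuals)
        inds[1] = Individual(id="f1", sex="male", origin="translocated",
                             banding_method="not-applicable", first_occasion=0)
        with pytest.raises(ValidationError, match="duplicate"):
            CaptureHistory(inds, toy_history.detections, toy_history.occasions)


class TestDatasetValidation:
    def test_fecundity_female_must_exist(self, toy_history):
        with pytest.raises(ValidationError, match="ghost"):
            Dataset(history=toy_history,
                    fecundity=[FecundityRecord("ghost", 1, 2, 3.0)],
                    unbanded=[])

    def test_fecundity_female_must_be_female(self, toy_history):
        with pytest.raises(ValidationError, match="m1"):
            Dataset(history=toy_history,
                    fecundity=[FecundityRecord("m1", 1, 2, 3.0)],
                    unbanded=[])

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            FecundityRecord("f1", 1, -1, 3.0)
        with pytest.raises(ValidationError):
            UnbandedCount(occasion=0, sex="male", count=-2)


class TestCsvBundle:
    def test_toy_round_trip(self, toy_dataset, tmp_path):
        write_dataset(toy_dataset, tmp_path / "bundle")
        back = read_dataset(tmp_path / "bundle")
        assert back == toy_dataset
        assert back.history.n_individuals == 3
        assert back.history.n_occasions == 4

    def test_empty_fecundity_round_trips(self, toy_history, tmp_path):
        ds = Dataset(history=toy_history, fecundity=[], unbanded=[])
        write_dataset(ds, tmp_path / "b")
        assert (tmp_path / "b" / "fecundity.csv").read_text().startswith("female_id")
        assert read_dataset(tmp_path / "b") == ds

    def test_simulated_hundred_individuals_row_count(self, tmp_path):
        spec = small_scenario(seed=5, n_years=6)
        spec.releases = {0: (30, 30)}
        data, _, _ = simulate_population(spec)
        write_dataset(data, tmp_path / "big")
        n = data.history.n_individuals
        lines = (tmp_path / "big" / "individuals.csv").read_text().strip().splitlines()
        assert len(lines) == n + 1  # header + one row per individual

    def test_missing_file_raises(self, tmp_path):
        (tmp_path / "partial").mkdir()
        with pytest.raises(FileNotFoundError):
            read_dataset(tmp_path / "partial")


class TestBugsDump:
    TOY = """
# toy capture data
list(y=structure(.Data=c(1,1,0,1,
                          1,0,1,1,
                          0,1,1,0), .Dim=c(3,4)),
     first=c(1,1,2), sex=c(2,1,3), trans=c(1,1,0), band_fl=c(0,0,0),
     frac1=0.5)
"""

    def test_matches_csv_equivalent(self, toy_history, tmp_path):
        f = tmp_path / "toy.txt"
        f.write_text(self.TOY)
        ds = read_dataset(f, format="bugs-dump")
        assert np.array_equal(ds.history.detections, toy_history.detections)
        assert ds.history.first_occasions.tolist() == [0, 0, 1]
        assert [i.sex for i in ds.history.individuals] == ["female", "male", "unknown"]
        assert ds.history.first_interval_fraction == 0.5

    def test_round_trip_via_writer(self, toy_dataset, tmp_path):
        f = write_bugs_dump(toy_dataset, tmp_path / "dump.txt")
        back = read_dataset(f, format="bugs-dump")
        assert np.array_equal(back.history.detections, toy_dataset.history.detections)
        assert back.history.first_occasions.tolist() == \
            toy_dataset.history.first_occasions.tolist()
        assert [r.fledglings for r in back.fecundity] == \
            [r.fledglings for r in toy_dataset.fecundity]
        assert [u.count for u in back.unbanded] == [u.count for u in toy_dataset.unbanded]

    def test_parse_error_carries_line_number(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("list(y=c(1,2),\n  z=@bad)\n")
        with pytest.raises(BugsParseError, match="line 2"):
            read_dataset(f, format="bugs-dump")

    def test_unsupported_construct_rejected(self):
        with pytest.raises(BugsParseError, match="matrix"):
            parse_bugs_dump("list(y=matrix(c(1,2,3,4), 2, 2))")

    def test_scalars_and_na(self):
        out = parse_bugs_dump("list(a=3.5, b=c(1, NA, 2))")
        assert out["a"] == 3.5
        assert np.isnan(out["b"][1])

    def test_unknown_sex_code_in_dump(self, tmp_path):
        f = tmp_path / "bad_sex.txt"
        f.write_text("list(y=structure(.Data=c(1,1), .Dim=c(1,2)), first=c(1), sex=c(9))")
        with pytest.raises(ValidationError, match="sex"):
            read_dataset(f, format="bugs-dump")


class TestRoundTripProperty:
    def test_hundred_random_datasets(self, tmp_path):
        for seed in range(100):
            data, _, _ = simulate_population(small_scenario(seed))
            out = tmp_path / f"d{seed}"
            write_dataset(data, out)
            assert read_dataset(out) == data

    def test_bugs_round_trip_structure(self, tmp_path):
        for seed in range(10):
            data, _, _ = simulate_population(small_scenario(seed))
            f = write_bugs_dump(data, tmp_path / f"b{seed}.txt")
            back = read_dataset(f, format="bugs-dump")
            assert np.array_equal(back.history.detections, data.history.detections)
            assert len(back.fecundity) == len(data.fecundity)


class TestTruncate:
    def test_full_length_is_identity(self, toy_dataset):
        assert toy_dataset.truncate(toy_dataset.history.n_occasions) == toy_dataset

    def test_drops_later_individuals_and_records(self, toy_dataset):
        sub = toy_dataset.truncate(1)
        assert sub.history.n_individuals == 2  # w1 enters at occasion 1
        assert sub.fecundity == []
        assert sub.unbanded == []

    def test_out_of_range(self, toy_dataset):
        with pytest.raises(ValueError):
            toy_dataset.truncate(0)


class TestModelConfig:
    def test_defaults_are_full_model(self):
        cfg = ModelConfig()
        assert set(cfg.enabled_effects()) == {
            "density_on_fecundity", "year_re_on_fecundity", "female_re_on_fecundity",
            "density_on_juvenile", "sex_on_adult", "translocation_effect",
            "banding_age_effect", "year_re_on_juvenile", "year_re_on_resighting",
        }

    def test_bad_prior_mode(self):
        with pytest.raises(ValidationError):
            ModelConfig(prior_mode="nope")

    def test_iterations_must_exceed_burn_in(self):
        with pytest.raises(ValidationError):
            ModelConfig(iterations=100, burn_in=100)


class TestParameterSet:
    def test_probability_bounds(self):
        with pytest.raises(ValidationError):
            ParameterSet(phi_a=1.0)
        with pytest.raises(ValidationError):
            ParameterSet(p=0.0)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            ParameterSet(sigma_female=-0.1)

    def test_dict_round_trip(self):
        ps = ParameterSet(phi_a=0.7, eps_year_j=np.array([0.1, -0.2]),
                          eps_female={"f1": 0.3})
        back = ParameterSet.from_dict(ps.to_dict())
        assert back.phi_a == ps.phi_a
        assert np.allclose(back.eps_year_j, ps.eps_year_j)
        assert back.eps_female == ps.eps_female
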