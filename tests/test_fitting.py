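import numpy as np
import pytest

from morphospheroid import (
    Controls,
    FitSpec,
    GrowthDataset,
    fit,
    objective,
    read_growth_csv,
    synthesize_growth_data,
)
from morphospheroid.fitting import FitFailureError, ParseError

SHARED = {"L": 1.0, "T": 1.0, "chat": 0.5, "sigmahat_mu": 0.0, "beta": 1.0}
FAST = Controls(n=60, dt=0.05, steady_tol=0.0)


def make_dataset(times=(0.0, 1.0, 2.0), radii=(0.5, 0.6, 0.7), **kw):
    return GrowthDataset(
        label=kw.pop("label", "d"),
        times=np.asarray(times),
        radii=np.asarray(radii),
        **kw,
    )


class TestReadCsv:
    def test_radius_rows(self, tmp_path):
        f = tmp_path / "a.csv"
        f.write_text("time,radius\n0,100\n5,150\n")
        ds = read_growth_csv(f)
        assert ds.times.tolist() == [0.0, 5.0]
        assert ds.radii.tolist() == [100.0, 150.0]
        assert ds.label == "a"

    def test_diameter_halved(self, tmp_path):
        f = tmp_path / "a.csv"
        f.write_text("time,diameter\n0,100\n5,150\n")
        ds = read_growth_csv(f, value="diameter")
        assert ds.radii.tolist() == [50.0, 75.0]

    def test_unit_scaling(self, tmp_path):
        f = tmp_path / "a.csv"
        f.write_text("t,r\n0,100\n5,150\n")
        ds = read_growth_csv(f, time_scale=24.0, length_scale=1e-3)
        assert ds.times.tolist() == [0.0, 120.0]
        assert ds.radii.tolist() == [0.1, 0.15]

    def test_empty_file(self, tmp_path):
        f = tmp_path / "a.csv"
        f.write_text("")
        with pytest.raises(ParseError):
            read_growth_csv(f)

    def test_header_only(self, tmp_path):
        f = tmp_path / "a.csv"
        f.write_text("time,radius\n")
        with pytest.raises(ParseError):
            read_growth_csv(f)

    def test_malformed_row_reports_line(self, tmp_path):
        f = tmp_path / "a.csv"
        f.write_text("time,radius\n0,100\nbad,value\n")
        with pytest.raises(ParseError, match="3"):
            read_growth_csv(f)

    def test_non_monotone_times(self, tmp_path):
        f = tmp_path / "a.csv"
        f.write_text("time,radius\n5,100\n0,150\n")
        with pytest.raises(ParseError):
            read_growth_csv(f)

    def test_non_positive_radius(self, tmp_path):
        f = tmp_path / "a.csv"
        f.write_text("time,radius\n0,-3\n")
        with pytest.raises(ParseError):
            read_growth_csv(f)


class TestObjective:
    def test_noiseless_self_consistency(self):
        times = np.linspace(0.0, 4.0, 9)
        data = synthesize_growth_data(
            SHARED, [{"B": 0.8, "kappa_mu": 0.0}], "M1", times, seed=0, controls=FAST
        )
        spec = FitSpec(law_id="M1", fixed=SHARED, controls=FAST)
        val = objective(spec, SHARED, [{"B": 0.8, "kappa_mu": 0.0}], data)
        assert val == pytest.approx(0.0, abs=1e-16)

    def test_perturbed_B_increases_objective(self):
        times = np.linspace(0.0, 4.0, 9)
        data = synthesize_growth_data(
            SHARED, [{"B": 0.8, "kappa_mu": 0.0}], "M1", times, seed=0, controls=FAST
        )
        spec = FitSpec(law_id="M1", fixed=SHARED, controls=FAST)
        at_truth = objective(spec, SHARED, [{"B": 0.8, "kappa_mu": 0.0}], data)
        perturbed = objective(spec, SHARED, [{"B": 0.9, "kappa_mu": 0.0}], data)
        assert perturbed > at_truth

    def test_single_point_at_t0(self):
        ds = make_dataset(times=[0.0], radii=[0.8])
        spec = FitSpec(law_id="M1", fixed=SHARED, controls=FAST)
        assert objective(spec, SHARED, [{"B": 0.8, "kappa_mu": 0.0}], [ds]) == 0.0

    def test_dataset_order_invariance(self):
        times = np.linspace(0.0, 3.0, 7)
        data = synthesize_growth_data(
            SHARED,
            [{"B": 0.6, "kappa_mu": 0.0}, {"B": 0.9, "kappa_mu": 0.0}],
            "M1",
            times,
            seed=0,
            controls=FAST,
        )
        spec = FitSpec(law_id="M1", fixed=SHARED, controls=FAST)
        pers = [{"B": 0.7, "kappa_mu": 0.0}, {"B": 0.85, "kappa_mu": 0.0}]
        fwd = objective(spec, SHARED, pers, data)
        rev = objective(spec, SHARED, pers[::-1], data[::-1])
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_failure_penalised_not_raised(self):
        ds = make_dataset()
        spec = FitSpec(law_id="M1", fixed=SHARED, controls=FAST)
        bad = dict(SHARED, chat=5.0)  # invalid: simulation cannot be built
        val = objective(spec, bad, [{"B": 0.5, "kappa_mu": 0.0}], [ds])
        assert np.isfinite(val) and val >= 1e12


class TestFit:
    def test_zero_free_parameters_no_search(self):
        times = np.linspace(0.0, 3.0, 7)
        data = synthesize_growth_data(
            SHARED, [{"B": 0.8, "kappa_mu": 0.0}], "M1", times, seed=0, controls=FAST
        )
        spec = FitSpec(
            law_id="M1", fixed=SHARED, per_dataset_fixed=({"B": 0.8, "kappa_mu": 0.0},),
            controls=FAST,
        )
        res = fit(spec, data, seed=0)
        assert res.total_objective == pytest.approx(0.0, abs=1e-16)
        assert res.converged
        assert res.manifest["starts"] == []

    def test_recovers_initial_radius(self):
        times = np.linspace(0.0, 5.0, 11)
        data = synthesize_growth_data(
            SHARED, [{"B": 0.8, "kappa_mu": 0.0}], "M1", times, seed=0, controls=FAST
        )
        spec = FitSpec(
            law_id="M1",
            fixed=SHARED,
            per_dataset_bounds={"B": (0.2, 1.5)},
            controls=FAST,
            n_starts=3,
        )
        res = fit(spec, data, seed=1)
        assert res.per_dataset[0]["B"] == pytest.approx(0.8, rel=1e-3)

    def test_free_suspension_forces_zero_stiffness(self):
        times = np.linspace(0.0, 3.0, 7)
        data = synthesize_growth_data(
            SHARED,
            [{"B": 0.8, "kappa_mu": 0.0, "condition": "free"}],
            "M1",
            times,
            seed=0,
            controls=FAST,
        )
        spec = FitSpec(
            law_id="M1",
            fixed=SHARED,
            per_dataset_bounds={"B": (0.2, 1.5), "kappa_mu": (0.0, 5.0)},
            controls=FAST,
            n_starts=2,
        )
        res = fit(spec, data, seed=1)
        assert res.per_dataset[0]["kappa_mu"] == 0.0
        free_names = [f["name"] for f in res.manifest["free_parameters"]]
        assert "kappa_mu" not in free_names

    def test_no_datasets(self):
        spec = FitSpec(law_id="M1", fixed=SHARED, controls=FAST)
        with pytest.raises(FitFailureError):
            fit(spec, [], seed=0)

    def test_rss_sums_to_total(self):
        times = np.linspace(0.0, 3.0, 7)
        data = synthesize_growth_data(
            SHARED,
            [{"B": 0.6, "kappa_mu": 0.0}, {"B": 0.9, "kappa_mu": 0.0}],
            "M1",
            times,
            seed=0,
            controls=FAST,
        )
        spec = FitSpec(
            law_id="M1",
            fixed=SHARED,
            per_dataset_fixed=({"B": 0.65, "kappa_mu": 0.0}, {"B": 0.8, "kappa_mu": 0.0}),
            controls=FAST,
        )
        res = fit(spec, data, seed=0)
        assert res.total_objective == pytest.approx(sum(res.per_dataset_rss), rel=1e-12)


class TestSynthesize:
    def test_noiseless_is_exact_model(self):
        times = np.linspace(0.0, 4.0, 9)
        d1 = synthesize_growth_data(SHARED, [{"B": 0.8}], "M1", times, noise_sd=0.0, seed=1)
        d2 = synthesize_growth_data(SHARED, [{"B": 0.8}], "M1", times, noise_sd=0.0, seed=99)
        np.testing.assert_array_equal(d1[0].radii, d2[0].radii)  # seed-independent

    def test_same_seed_identical(self):
        times = np.linspace(0.0, 4.0, 9)
        d1 = synthesize_growth_data(SHARED, [{"B": 0.8}], "M1", times, noise_sd=0.05, seed=7)
        d2 = synthesize_growth_data(SHARED, [{"B": 0.8}], "M1", times, noise_sd=0.05, seed=7)
        np.testing.assert_array_equal(d1[0].radii, d2[0].radii)

    def test_different_seed_differs(self):
        times = np.linspace(0.0, 4.0, 9)
        d1 = synthesize_growth_data(SHARED, [{"B": 0.8}], "M1", times, noise_sd=0.05, seed=7)
        d2 = synthesize_growth_data(SHARED, [{"B": 0.8}], "M1", times, noise_sd=0.05, seed=8)
        assert not np.array_equal(d1[0].radii, d2[0].radii)

    def test_stiffer_media_grow_less(self):
        shared = dict(SHARED, sigmahat_mu=-0.5, beta=2.0)
        conds = [
            {"B": 0.5, "kappa_mu": 0.0, "condition": "free"},
            {"B": 0.5, "kappa_mu": 0.5},
            {"B": 0.5, "kappa_mu": 2.0},
        ]
        times = np.linspace(0.0, 12.0, 13)
        data = synthesize_growth_data(shared, conds, "M5", times, noise_sd=0.0, seed=0, controls=FAST)
        finals = [ds.radii[-1] for ds in data]
        assert finals[0] > finals[1] > finals[2]

    def test_condition_labels(self):
        times = np.linspace(0.0, 1.0, 3)
        data = synthesize_growth_data(
            SHARED, [{"B": 0.5, "kappa_mu": 0.0}, {"B": 0.5, "kappa_mu": 1.0}], "M1", times, seed=0,
            controls=FAST,
        )
        assert data[0].condition == "free"
        assert data[1].condition == "embedded"
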