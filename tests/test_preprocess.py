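import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

import droughtmet as dm
from droughtmet.datamodel import meta_to_frame


def _toy(rng, n_m=20, n_s=12):
    mets = [f"m{i}" for i in range(n_m)]
    samples = [f"s{j}" for j in range(n_s)]
    vals = pd.DataFrame(rng.uniform(10, 1000, size=(n_m + 1, n_s)),
                        index=["Std"] + mets, columns=samples)
    meta = [dm.SampleMeta(s, "WT", "root", "basal", 0, j + 1,
                          float(rng.uniform(25, 35)))
            for j, s in enumerate(samples)]
    return dm.AbundanceMatrix(vals, internal_standard_id="Std"), meta


class TestNormalize:
    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(1)
        abund, meta = _toy(rng)
        out = dm.normalize(abund, meta, "Std")
        fw = {m.sample_id: m.fresh_weight_mg for m in meta}
        for met in out.values.index:
            for s in out.values.columns:
                expect = abund.values.loc[met, s] / abund.values.loc["Std", s] / fw[s]
                assert out.values.loc[met, s] == expect

    def test_standard_row_removed(self):
        rng = np.random.default_rng(2)
        abund, meta = _toy(rng)
        out = dm.normalize(abund, meta, "Std")
        assert "Std" not in out.values.index
        assert out.state == "normalized"

    def test_per_sample_gain_cancels_exactly(self):
        rng = np.random.default_rng(3)
        abund, meta = _toy(rng)
        a = dm.normalize(abund, meta, "Std").values
        gained = abund.copy()
        gained.values["s3"] *= 4.0  # power-of-two gain: bit-identical result
        b = dm.normalize(gained, meta, "Std").values
        pd.testing.assert_frame_equal(a, b, check_exact=True)
        gained = abund.copy()
        gained.values["s3"] *= 7.0  # arbitrary gain: exact up to rounding
        c = dm.normalize(gained, meta, "Std").values
        assert np.allclose(a.to_numpy(), c.to_numpy(), rtol=1e-14, atol=0)

    def test_bad_standard_named_in_error(self):
        rng = np.random.default_rng(4)
        abund, meta = _toy(rng)
        abund.values.loc["Std", "s5"] = 0.0
        with pytest.raises(ValueError, match="s5"):
            dm.normalize(abund, meta, "Std")

    def test_missing_stays_missing(self):
        rng = np.random.default_rng(5)
        abund, meta = _toy(rng)
        abund.values.iloc[3, 2] = np.nan
        out = dm.normalize(abund, meta, "Std")
        assert np.isnan(out.values.iloc[2, 2])  # std row removed shifts index


class TestLogTransform:
    @pytest.mark.parametrize("base, value, expected", [
        ("10", 1000.0, 3.0), ("2", 8.0, 3.0), ("e", math.e, 1.0),
    ])
    def test_closed_forms(self, base, value, expected):
        am = dm.AbundanceMatrix(pd.DataFrame([[value]], index=["m"], columns=["s"]),
                                state="normalized")
        out = dm.log_transform(am, base=base)
        assert out.values.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_base_change_identity(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.uniform(0.1, 50, (4, 5)))
        am = dm.AbundanceMatrix(df, state="normalized")
        e = dm.log_transform(am, base="e").values
        ten = dm.log_transform(am, base="10").values
        assert np.allclose(e / math.log(10), ten, atol=1e-12)

    def test_all_ones_maps_to_zeros(self):
        am = dm.AbundanceMatrix(pd.DataFrame(np.ones((3, 3))), state="normalized")
        assert (dm.log_transform(am).values == 0).all().all()

    def test_nonpositive_cells_listed(self):
        df = pd.DataFrame([[1.0, 0.0]], index=["m1"], columns=["s1", "s2"])
        am = dm.AbundanceMatrix(df, state="normalized")
        with pytest.raises(ValueError, match="m1.*s2"):
            dm.log_transform(am)


class TestOutlierRule:
    def test_printed_quartiles_classify_printed_medians(self):
        # a log-median of -8.35 falls below Q1 = -8.01; 0.57 above Q3 = -4.13
        assert dm.flag_direction(-8.35, -8.01, -4.13) == "below_q1"
        assert dm.flag_direction(0.57, -8.01, -4.13) == "above_q3"
        assert dm.flag_direction(-6.30, -8.01, -4.13) is None

    def test_median_exactly_at_quartile_kept(self):
        assert dm.flag_direction(-8.01, -8.01, -4.13) is None
        assert dm.flag_direction(-4.13, -8.01, -4.13) is None

    def test_constant_matrix_flags_nothing(self):
        am = dm.AbundanceMatrix(pd.DataFrame(np.full((4, 6), 2.5)), state="log")
        report = dm.flag_outlier_samples(am)
        assert report.dataset_q1 == report.dataset_q3 == report.dataset_median
        assert report.flagged == {}

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(7)
        am = dm.AbundanceMatrix(pd.DataFrame(rng.normal(size=(30, 20))), state="log")
        report = dm.flag_outlier_samples(am)
        assert report.dataset_q1 <= report.dataset_median <= report.dataset_q3
        for sid, direction in report.flagged.items():
            m = report.per_sample_median[sid]
            assert (m > report.dataset_q3) if direction == "above_q3" \
                else (m < report.dataset_q1)

    def test_recovers_planted_outliers_exactly(self, full_sim, logged_full):
        _, _, _, truth = full_sim
        logged, _ = logged_full
        report = dm.flag_outlier_samples(logged)
        assert set(report.flagged) == set(truth.outlier_sample_ids)
        for sid, shift in truth.outlier_log10_shifts.items():
            assert report.flagged[sid] == ("above_q3" if shift > 0 else "below_q1")

    def test_no_flags_without_planted_outliers(self):
        cfg = dm.SimulationConfig(seed=13, n_metabolites=20, outliers=None)
        abund, meta, _ = dm.simulate_dataset(cfg)
        logged = dm.log_transform(dm.normalize(abund, meta, "Ribitol"))
        assert dm.flag_outlier_samples(logged).flagged == {}

    def test_empty_sample_rejected(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, np.nan]], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            dm.flag_outlier_samples(dm.AbundanceMatrix(df, state="log"))


class TestDropSamples:
    def test_not_identified_report_recomputed_after_filtering(self):
        vals = pd.DataFrame(
            [[1.0, np.nan, 5.0], [2.0, 3.0, 6.0]],
            index=["m1", "m2"], columns=["sh1", "sh2", "rt1"],
        )
        meta = [dm.SampleMeta("sh1", "WT", "shoot", "basal", 0, 1, 55.0),
                dm.SampleMeta("sh2", "WT", "shoot", "basal", 0, 2, 55.0),
                dm.SampleMeta("rt1", "WT", "root", "basal", 0, 1, 30.0)]
        am = dm.AbundanceMatrix(vals, state="normalized")
        # dropping sh1 removes m1's only shoot observation
        _, _, report = dm.drop_samples(am, meta, ["sh1"])
        assert report["shoot"] == ["m1"]


class TestPCA:
    def test_rank_one_data_has_unit_first_fraction(self):
        rng = np.random.default_rng(8)
        t = rng.normal(size=10)
        direction = rng.normal(size=6)
        vals = pd.DataFrame(np.outer(direction, t) + 5.0)
        am = dm.AbundanceMatrix(vals, state="log")
        _, fractions = dm.pca_scores(am, n_components=3)
        assert fractions[0] == pytest.approx(1.0, abs=1e-10)

    def test_fractions_match_correlation_eigendecomposition(self):
        rng = np.random.default_rng(9)
        vals = pd.DataFrame(rng.normal(size=(6, 10)))  # 6 metabolites x 10 samples
        am = dm.AbundanceMatrix(vals, state="log")
        _, fractions = dm.pca_scores(am, n_components=6)
        corr = np.corrcoef(vals.to_numpy())
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert np.allclose(fractions, eig / eig.sum(), atol=1e-8)

    def test_fractions_non_increasing_and_sum_below_one(self, logged_full):
        logged, _ = logged_full
        _, fractions = dm.pca_scores(logged, n_components=4)
        assert all(a >= b - 1e-12 for a, b in zip(fractions, fractions[1:]))
        assert fractions.sum() <= 1 + 1e-9

    def test_tissues_separate_in_score_space(self):
        """Shoot and root samples with tissue-specific offsets form separated
        groups in the first two components (positive silhouette)."""
        rng = np.random.default_rng(10)
        cfg = dm.SimulationConfig(seed=17, n_metabolites=20, outliers=None, dnb=None)
        abund, meta, _ = dm.simulate_dataset(cfg)
        # impose a tissue offset on half the metabolites
        shoot_ids = [m.sample_id for m in meta if m.tissue == "shoot"]
        abund.values.loc[abund.values.index[1:11], shoot_ids] *= 8.0
        logged = dm.log_transform(dm.normalize(abund, meta, "Ribitol"))
        scores, _ = dm.pca_scores(logged, n_components=2)
        labels = [m.tissue for m in meta]
        assert silhouette_score(scores.to_numpy(), labels) > 0

    def test_zero_variance_metabolite_excluded_with_warning(self):
        rng = np.random.default_rng(11)
        vals = pd.DataFrame(rng.normal(size=(5, 8)))
        vals.iloc[2] = 3.14
        am = dm.AbundanceMatrix(vals, state="log")
        with pytest.warns(UserWarning, match="zero-variance"):
            scores, _ = dm.pca_scores(am, n_components=2)
        assert scores.shape == (8, 2)
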