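"""Feature-construction tests: anchors, leakage guards, labs, PRS, sub-cohorts."""

import numpy as np
import pandas as pd
import pytest

from gravida.features import (
    CohortSpec,
    FeatureMatrix,
    RiskFactorProfile,
    additive_prs,
    aggregate_labs,
    build_code_count_matrix,
    build_gestational_cohort,
    build_predelivery_cohort,
    build_recurrent_cohort,
    check_leakage,
    classify_delivery_mode,
    downsample_to_match,
    encode_risk_factors,
    encode_risk_factors_cohort,
    identify_spontaneous,
    total_code_count_feature,
)
from gravida.phenotype import AscertainmentCodeSets


def _episodes(rows):
    defaults = dict(
        episode_index=1, label="term", label_source="consensus", code_label="term",
        ega_label="term", conception_day=pd.NA, multiple_gestation=False,
        is_earliest=True, n_delivery_dx=1, n_delivery_px=1, n_ega=1,
    )
    df = pd.DataFrame([{**defaults, **r} for r in rows])
    df["conception_day"] = df["conception_day"].astype("Float64")
    return df


def _events(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "code", "day"])
    df["system"] = "DX"
    return df[["patient_id", "system", "code", "day"]]


class TestCohorts:
    def test_delivered_before_anchor_excluded(self):
        eps = _episodes(
            [
                dict(patient_id="a", delivery_day=190, conception_day=0),
                dict(patient_id="b", delivery_day=200, conception_day=0),
            ]
        )
        cohort = build_gestational_cohort(eps, 28)  # anchor day 196
        assert cohort["patient_id"].tolist() == ["b"]
        assert cohort["anchor_day"].item() == 196

    def test_missing_conception_excluded_from_gestational_anchor(self):
        eps = _episodes([dict(patient_id="a", delivery_day=280)])
        assert len(build_gestational_cohort(eps, 0)) == 0

    def test_negative_weeks_rejected(self):
        with pytest.raises(ValueError):
            build_gestational_cohort(
                _episodes([dict(patient_id="a", delivery_day=280, conception_day=0)]), -1
            )

    def test_predelivery_anchor_arithmetic(self):
        eps = _episodes([dict(patient_id="a", delivery_day=300)])
        assert build_predelivery_cohort(eps, 60)["anchor_day"].item() == 240
        assert build_predelivery_cohort(eps, 0)["anchor_day"].item() == 300

    def test_cohort_monotonicity_in_gestational_weeks(self, episodes):
        c0 = build_gestational_cohort(episodes, 0)
        c28 = build_gestational_cohort(episodes, 28)
        assert set(c28["patient_id"]) <= set(c0["patient_id"])

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="require_conception"):
            CohortSpec("conception_plus_weeks", 13, require_conception=False)


class TestDownsampling:
    def test_matched_sizes_and_determinism(self):
        rng = np.random.default_rng(0)
        cohorts = [
            pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)],
                          "label": rng.choice(["preterm", "term"], size=n, p=[0.2, 0.8])})
            for n in (100, 80, 90)
        ]
        out1 = downsample_to_match(cohorts, seed=4)
        out2 = downsample_to_match(cohorts, seed=4)
        assert [len(c) for c in out1] == [80, 80, 80]
        for a, b in zip(out1, out2):
            pd.testing.assert_frame_equal(a, b)

    def test_subsample_prevalence_tracks_source(self):
        # hypergeometric oracle: sub-cohort case count concentrates around
        # n_sub * K / N with variance n_sub * K/N * (1-K/N) * (N-n_sub)/(N-1)
        N, K, n_sub = 400, 80, 100
        src = pd.DataFrame(
            {"patient_id": range(N), "label": ["preterm"] * K + ["term"] * (N - K)}
        )
        small = pd.DataFrame({"patient_id": range(n_sub), "label": ["term"] * n_sub})
        mean = n_sub * K / N
        var = n_sub * (K / N) * (1 - K / N) * (N - n_sub) / (N - 1)
        for seed in range(20):
            sub = downsample_to_match([src, small], seed=seed)[0]
            k = (sub["label"] == "preterm").sum()
            assert abs(k - mean) < 3 * np.sqrt(var)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            downsample_to_match([pd.DataFrame({"a": [1]}), pd.DataFrame({"a": []})], 0)


class TestCodeCountMatrix:
    def test_counting_and_boundary(self, code_sets):
        eps = _episodes([dict(patient_id="a", delivery_day=280, conception_day=0)])
        cohort = build_gestational_cohort(eps, 2)  # anchor 14... use events near it
        cohort.loc[:, "anchor_day"] = 15
        events = _events(
            [("a", "C1", 10), ("a", "C1", 20), ("a", "C2", 15), ("a", "C3", 14)]
        )
        fm = build_code_count_matrix(events, cohort, code_sets)
        row = fm.X.iloc[0]
        assert row["C1"] == 1  # day 20 is post-anchor
        assert "C2" not in fm.X.columns or row.get("C2", 0) == 0  # at-anchor excluded
        assert row["C3"] == 1

    def test_ascertainment_codes_never_columns(self, code_sets):
        eps = _episodes([dict(patient_id="a", delivery_day=280, conception_day=0)])
        cohort = build_gestational_cohort(eps, 28)
        events = _events([("a", "DDX.PRE.1", 100), ("a", "C9", 100)])
        fm = build_code_count_matrix(events, cohort, code_sets)
        assert "DDX.PRE.1" not in fm.X.columns
        assert fm.X.iloc[0]["C9"] == 1

    def test_no_history_row_is_all_zero(self, code_sets):
        eps = _episodes(
            [
                dict(patient_id="a", delivery_day=280, conception_day=0),
                dict(patient_id="b", delivery_day=285, conception_day=5),
            ]
        )
        cohort = build_gestational_cohort(eps, 13)
        events = _events([("a", "C1", 10)])
        fm = build_code_count_matrix(events, cohort, code_sets)
        assert len(fm) == 2
        assert fm.X.loc[("b", 1)].sum() == 0

    def test_total_count_collapses_columns(self, code_sets):
        eps = _episodes([dict(patient_id="a", delivery_day=280, conception_day=0)])
        cohort = build_gestational_cohort(eps, 28)
        events = _events([("a", "C1", 5), ("a", "C2", 6), ("a", "C2", 7), ("a", "C2", 500)])
        fm = total_code_count_feature(events, cohort, code_sets)
        assert fm.X["total_code_count"].item() == 3

    def test_leakage_guard_on_synthetic_cohort(self, sim, cohort28, fm28, code_sets):
        check_leakage(fm28, sim.code_events)
        # guard trips when a post-anchor event is smuggled into a cell
        broken = FeatureMatrix(
            fm28.X.copy(), fm28.y, fm28.anchors, fm28.excluded_codes
        )
        col = broken.X.columns[0]
        broken.X.iloc[0, 0] = broken.X.iloc[0, 0] + 999
        with pytest.raises(AssertionError):
            check_leakage(broken, sim.code_events)

    def test_excluded_code_as_column_rejected_at_construction(self):
        X = pd.DataFrame(
            {"DDX.PRE.1": [1]},
            index=pd.MultiIndex.from_tuples([("a", 1)], names=["patient_id", "episode_index"]),
        )
        y = pd.Series([1], index=X.index)
        anchors = pd.Series([100], index=X.index)
        with pytest.raises(ValueError, match="excluded"):
            FeatureMatrix(X, y, anchors, frozenset({"DDX.PRE.1"}))

    def test_triplet_round_trip(self, fm28, tmp_path):
        sub = fm28.subset(fm28.X.index[:40])
        sub.write_csv(tmp_path)
        back = FeatureMatrix.read_csv(tmp_path)
        expected = sub.X.loc[:, sorted(sub.X.columns)]
        expected.columns.name = None
        back_X = back.X.copy()
        back_X.columns.name = None
        pd.testing.assert_frame_equal(back_X, expected, check_dtype=False)
        assert (back.y == sub.y).all()
        assert back.excluded_codes == sub.excluded_codes


class TestRiskFactors:
    def _demo(self, **kw):
        base = dict(
            patient_id="a", age_at_first_delivery=25.0, race="White",
            prepregnancy_bmi=22.0, prepregnancy_sbp=110.0, prepregnancy_dbp=70.0,
        )
        base.update(kw)
        return pd.DataFrame([base])

    def _episode(self):
        return pd.Series(dict(patient_id="a", episode_index=1, delivery_day=500))

    def test_age_seventeen_is_extreme(self):
        prof = encode_risk_factors(
            self._demo(age_at_first_delivery=17.0),
            _events([]), self._episode(),
        )
        assert prof.flags["age_extreme"] == 1

    def test_bmi_measurement_before_prepregnancy_window(self):
        meas = pd.DataFrame(
            {"patient_id": ["a"], "kind": ["bmi"], "day": [200], "value": [36.0]}
        )  # 300 days before delivery at 500
        prof = encode_risk_factors(
            self._demo(), _events([]), self._episode(), measurements=meas
        )
        assert prof.flags["prepregnancy_bmi_ge_35"] == 1

    def test_recent_bmi_measurement_ignored(self):
        meas = pd.DataFrame(
            {"patient_id": ["a"], "kind": ["bmi"], "day": [400], "value": [36.0]}
        )  # only 100 days before delivery: in-pregnancy, not pre-pregnancy
        prof = encode_risk_factors(
            self._demo(), _events([]), self._episode(), measurements=meas
        )
        assert prof.flags["prepregnancy_bmi_ge_35"] == 0

    def test_low_risk_everything_gives_zero_profile(self):
        prof = encode_risk_factors(self._demo(), _events([]), self._episode())
        assert prof.count == 0

    def test_code_based_factor_requires_pre_delivery_code(self):
        fc = {"sickle_cell": frozenset({"SC1"})}
        before = encode_risk_factors(
            self._demo(), _events([("a", "SC1", 499)]), self._episode(), factor_codes=fc
        )
        after = encode_risk_factors(
            self._demo(), _events([("a", "SC1", 500)]), self._episode(), factor_codes=fc
        )
        assert before.flags["sickle_cell"] == 1
        assert after.flags["sickle_cell"] == 0

    def test_profile_requires_all_twelve(self):
        with pytest.raises(ValueError, match="missing"):
            RiskFactorProfile({"age_extreme": 1})

    def test_count_distribution_matches_poisson_binomial(self):
        # plant independent code-based factors; profile sums should match the
        # Poisson-binomial mean/variance oracle within sampling error
        rng = np.random.default_rng(5)
        n = 3000
        pats = [f"p{i}" for i in range(n)]
        prevs = {"sickle_cell": 0.3, "preeclampsia": 0.15, "eclampsia": 0.45}
        fc = {k: frozenset({f"{k}_code"}) for k in prevs}
        rows = []
        for p in pats:
            for k, pr in prevs.items():
                if rng.random() < pr:
                    rows.append((p, f"{k}_code", 10))
        events = _events(rows)
        demo = pd.DataFrame(
            {
                "patient_id": pats, "age_at_first_delivery": 25.0, "race": "White",
                "prepregnancy_bmi": 22.0, "prepregnancy_sbp": 110.0,
                "prepregnancy_dbp": 70.0,
            }
        )
        cohort = pd.DataFrame(
            {"patient_id": pats, "episode_index": 1, "delivery_day": 500}
        )
        profile = encode_risk_factors_cohort(demo, events, cohort, factor_codes=fc)
        counts = profile.sum(axis=1)
        mean = sum(prevs.values())
        var = sum(p * (1 - p) for p in prevs.values())
        assert abs(counts.mean() - mean) < 3 * np.sqrt(var / n)


class TestLabs:
    def _cohort(self):
        return pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(100)],
                "episode_index": 1,
                "conception_day": 0,
                "delivery_day": 280,
            }
        )

    def test_single_value_summary(self):
        labs = pd.DataFrame(
            {"patient_id": ["p0"], "lab": ["hb"], "day": [100], "value": [11.5]}
        )
        out = aggregate_labs(labs, self._cohort())
        row = out.iloc[0]
        assert row["mean"] == row["median"] == row["min"] == row["max"] == 11.5
        assert row["n_used"] == 1 and row["n_excluded"] == 0

    def test_four_sd_outlier_excluded(self):
        # 99 values of 10.0 and one 1000.0: brute-force cohort stats put the
        # outlier at z ~ 9.9, far beyond 4 SD
        values = [10.0] * 99 + [1000.0]
        labs = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(100)],
                "lab": "glu",
                "day": 100,
                "value": values,
            }
        )
        arr = np.array(values)
        z = abs(1000.0 - arr.mean()) / arr.std(ddof=1)
        assert z > 4
        out = aggregate_labs(labs, self._cohort()).set_index("patient_id")
        assert "p99" not in out.index  # its only measurement was excluded
        assert (out["n_excluded"] == 0).all()
        assert out.loc["p0", "mean"] == 10.0

    def test_zero_sd_excludes_nothing(self):
        labs = pd.DataFrame(
            {"patient_id": ["p0"] * 5, "lab": "glu", "day": range(5), "value": 7.0}
        )
        out = aggregate_labs(labs, self._cohort())
        assert out["n_used"].item() == 5 and out["n_excluded"].item() == 0

    def test_ordering_invariant_on_random_data(self):
        rng = np.random.default_rng(3)
        labs = pd.DataFrame(
            {
                "patient_id": rng.choice([f"p{i}" for i in range(30)], size=400),
                "lab": rng.choice(["a", "b"], size=400),
                "day": rng.integers(0, 281, size=400),
                "value": rng.normal(50, 10, size=400),
            }
        )
        out = aggregate_labs(labs, self._cohort())
        assert (out["min"] <= out["median"]).all()
        assert (out["median"] <= out["max"]).all()

    def test_out_of_window_measurements_ignored(self):
        labs = pd.DataFrame(
            {"patient_id": ["p0", "p0"], "lab": "glu", "day": [-5, 300], "value": [9.0, 9.0]}
        )
        assert len(aggregate_labs(labs, self._cohort())) == 0


class TestPRS:
    def _weights(self):
        return pd.DataFrame(
            {
                "variant": ["v1", "v2"],
                "effect_size": [0.5, -0.2],
                "p_value": [1e-8, 1e-6],
            }
        )

    def test_arithmetic(self):
        geno = pd.DataFrame({"patient_id": ["a"], "v1": [1], "v2": [2]})
        score = additive_prs(geno, self._weights(), p_threshold=0.05)
        assert score.loc["a"] == pytest.approx(1 * 0.5 + 2 * -0.2)

    def test_zero_dosage_zero_score(self):
        geno = pd.DataFrame({"patient_id": ["a"], "v1": [0], "v2": [0]})
        assert additive_prs(geno, self._weights(), 0.05).loc["a"] == 0.0

    def test_threshold_excludes_all(self):
        geno = pd.DataFrame({"patient_id": ["a"], "v1": [2], "v2": [2]})
        assert (additive_prs(geno, self._weights(), 1e-12) == 0).all()

    def test_missing_variant_skipped_with_log(self, caplog):
        geno = pd.DataFrame({"patient_id": ["a"], "v1": [2]})
        with caplog.at_level("WARNING"):
            score = additive_prs(geno, self._weights(), 0.05)
        assert score.loc["a"] == pytest.approx(1.0)
        assert "missing" in caplog.text


class TestSubCohorts:
    def test_spontaneous_exclusions(self, code_sets):
        eps = _episodes(
            [
                dict(patient_id="a", delivery_day=200, label="preterm"),
                dict(patient_id="b", delivery_day=200, label="preterm"),
            ]
        )
        events = _events([("a", "DPX.CSEC.1", 200)])
        flags = identify_spontaneous(eps, events, code_sets)
        assert flags.tolist() == [False, True]

    def test_non_preterm_rows_rejected(self, code_sets):
        eps = _episodes([dict(patient_id="a", delivery_day=200, label="term")])
        with pytest.raises(ValueError, match="preterm"):
            identify_spontaneous(eps, _events([]), code_sets)

    def test_recurrent_cohort_membership(self):
        eps = _episodes(
            [
                dict(patient_id="a", episode_index=1, label="preterm", delivery_day=200),
                dict(patient_id="a", episode_index=2, label="term", delivery_day=600,
                     is_earliest=False),
                dict(patient_id="b", episode_index=1, label="term", delivery_day=200),
                dict(patient_id="b", episode_index=2, label="preterm", delivery_day=600,
                     is_earliest=False),
                dict(patient_id="c", episode_index=1, label="preterm", delivery_day=200),
            ]
        )
        rec = build_recurrent_cohort(eps)
        assert rec["patient_id"].tolist() == ["a"]  # b's first was term; c has one delivery
        assert rec["label"].item() == "term"

    def test_delivery_mode_rules(self, code_sets):
        eps = _episodes(
            [
                dict(patient_id="a", delivery_day=200),
                dict(patient_id="b", delivery_day=200),
                dict(patient_id="c", delivery_day=200),
            ]
        )
        events = _events(
            [
                ("a", "DPX.CSEC.1", 205),
                ("b", "DPX.CSEC.1", 200), ("b", "DPX.VAG.1", 201),
                ("c", "DPX.VAG.1", 211),
            ]
        )
        modes = classify_delivery_mode(eps, events, code_sets)
        assert modes.tolist() == ["cesarean", "excluded", "unclassified"]
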