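"""Screen statistics: QC filtering, control normalization, Welch/Bonferroni
hit calling, and effect classification."""

import numpy as np
import pandas as pd
import pytest

from clockscreen import (
    EmptyControlError,
    ScreenBatch,
    call_hits,
    classify_effect,
    normalize,
    qc_filter,
)


def make_batch(control_periods, decoy_periods=None, experiment_id="E1", rae=0.1):
    rows = []
    for i, p in enumerate(control_periods):
        rows.append(
            dict(plant_id=f"c{i}", population_id="control", is_control=True,
                 period_h=p, phase_h=1.0, rae=rae)
        )
    for pop, periods in (decoy_periods or {}).items():
        for i, p in enumerate(periods):
            rows.append(
                dict(plant_id=f"{pop}_{i}", population_id=pop, is_control=False,
                     period_h=p, phase_h=1.0, rae=rae)
            )
    return ScreenBatch(experiment_id=experiment_id, plants=pd.DataFrame(rows))


def normalized_frame(pop_values, control_values, metric="period"):
    rows = []
    for i, v in enumerate(control_values):
        rows.append(dict(plant_id=f"c{i}", population_id="control",
                         experiment_id="E1", metric=metric, diff=v, is_control=True))
    for pop, values in pop_values.items():
        for i, v in enumerate(values):
            rows.append(dict(plant_id=f"{pop}_{i}", population_id=pop,
                             experiment_id="E1", metric=metric, diff=v, is_control=False))
    return pd.DataFrame(rows)


class TestQcFilter:
    def test_sd_below_cutoff_passes(self):
        # periods with sample SD just under 0.75 h
        periods = np.array([24.0 - 0.74, 24.0, 24.0 + 0.74]) / np.sqrt(2) * np.sqrt(2)
        sd = np.std([23.26, 24.0, 24.74], ddof=1)
        assert sd < 0.75
        batch = qc_filter(make_batch([23.26, 24.0, 24.74]))
        assert batch.qc_pass

    def test_sd_exactly_at_cutoff_fails(self):
        # construct controls whose sample SD is exactly 0.75
        vals = [24.0 - 0.75, 24.0 + 0.75]
        assert np.std(vals, ddof=1) == pytest.approx(0.75 * np.sqrt(2))
        scaled = [24.0 - 0.75 / np.sqrt(2), 24.0 + 0.75 / np.sqrt(2)]
        assert np.std(scaled, ddof=1) == pytest.approx(0.75)
        assert not qc_filter(make_batch(scaled)).qc_pass

    def test_identical_controls_pass(self):
        assert qc_filter(make_batch([24.0] * 5)).qc_pass

    def test_empty_controls_raise(self):
        batch = make_batch([], {"P1": [24.0, 25.0]})
        with pytest.raises(EmptyControlError):
            qc_filter(batch)


class TestNormalize:
    def test_diff_against_control_mean(self):
        batch = qc_filter(make_batch([23.5, 24.0, 24.5], {"P1": [25.0]}))
        out = normalize(batch, "period")
        decoy = out.loc[~out["is_control"], "diff"].to_numpy()
        np.testing.assert_allclose(decoy, [1.0])
        ctrl = out.loc[out["is_control"], "diff"].to_numpy()
        np.testing.assert_allclose(sorted(ctrl), [-0.5, 0.0, 0.5])
        assert ctrl.mean() == pytest.approx(0.0, abs=1e-12)

    def test_control_equal_to_mean_has_zero_diff(self):
        batch = qc_filter(make_batch([24.0, 24.0]))
        out = normalize(batch, "period")
        np.testing.assert_allclose(out["diff"], 0.0)

    def test_requires_qc(self):
        batch = make_batch([24.0, 24.5])
        with pytest.raises(ValueError, match="QC"):
            normalize(batch, "period")

    def test_idempotent_on_normalized_values(self):
        batch = qc_filter(make_batch([23.5, 24.0, 24.5], {"P1": [25.0, 26.0]}))
        once = normalize(batch, "period")
        renorm_plants = batch.plants.copy()
        renorm_plants["period_h"] = once.set_index("plant_id").loc[
            renorm_plants["plant_id"], "diff"
        ].to_numpy()
        twice = normalize(
            qc_filter(ScreenBatch("E1", renorm_plants)), "period"
        )
        merged = once.merge(twice, on="plant_id", suffixes=("_1", "_2"))
        np.testing.assert_allclose(merged["diff_1"], merged["diff_2"], atol=1e-12)

    def test_arrhythmic_plants_excluded(self):
        plants = pd.DataFrame(
            [
                dict(plant_id="c0", population_id="control", is_control=True,
                     period_h=24.0, phase_h=1.0, rae=0.1),
                dict(plant_id="c1", population_id="control", is_control=True,
                     period_h=24.5, phase_h=1.0, rae=0.1),
                dict(plant_id="a0", population_id="P1", is_control=False,
                     period_h=30.0, phase_h=1.0, rae=0.9),
                dict(plant_id="r0", population_id="P1", is_control=False,
                     period_h=25.0, phase_h=1.0, rae=0.2),
            ]
        )
        batch = qc_filter(ScreenBatch("E1", plants))
        out = normalize(batch, "period")
        assert set(out["plant_id"]) == {"c0", "c1", "r0"}


class TestCallHits:
    def test_corrected_alpha_matches_family_size(self):
        # 46 populations at family alpha 0.05 reproduces the U-box period
        # threshold of ~1.09e-3
        rng = np.random.default_rng(1)
        pops = {f"P{i:02d}": rng.normal(0, 0.4, 20) for i in range(46)}
        records = normalized_frame(pops, rng.normal(0, 0.4, 40))
        hits = call_hits(records, "period", "wildtype", alpha_family=0.05)
        assert hits["alpha_corrected"].iloc[0] == pytest.approx(0.05 / 46)
        assert hits["alpha_corrected"].iloc[0] == pytest.approx(1.09e-3, rel=0.01)

    def test_null_population_not_significant(self):
        rng = np.random.default_rng(7)
        records = normalized_frame(
            {"P1": rng.normal(0, 0.4, 20)}, rng.normal(0, 0.4, 40)
        )
        hits = call_hits(records, "period", "wildtype")
        assert not hits["significant"].any()

    def test_bonferroni_set_nested_in_uncorrected(self):
        rng = np.random.default_rng(3)
        pops = {
            f"P{i}": rng.normal(0.5 if i < 3 else 0.0, 0.4, 20) for i in range(12)
        }
        records = normalized_frame(pops, rng.normal(0, 0.4, 40))
        corrected = call_hits(records, "period", "wildtype", alpha_family=0.05)
        uncorrected = call_hits(
            records, "period", "wildtype", alpha_family=0.05, m_tests=1
        )
        sig_c = set(corrected.loc[corrected["significant"], "population_id"])
        sig_u = set(uncorrected.loc[uncorrected["significant"], "population_id"])
        assert sig_c <= sig_u

    def test_all_decoys_control_mode_pools_decoys(self):
        rng = np.random.default_rng(5)
        # every decoy population shifted +1 h: against the all-decoys pool
        # none stands out, against wildtype all would
        pops = {f"P{i}": rng.normal(1.0, 0.3, 20) for i in range(6)}
        records = normalized_frame(pops, rng.normal(0, 0.3, 40), metric="phase")
        vs_decoys = call_hits(records, "phase", "all_decoys")
        assert not vs_decoys["significant"].any()
        vs_wildtype = call_hits(records, "phase", "wildtype")
        assert vs_wildtype["significant"].all()

    def test_tiny_population_untestable(self):
        rng = np.random.default_rng(2)
        records = normalized_frame({"P1": [2.0]}, rng.normal(0, 0.4, 30))
        hits = call_hits(records, "period", "wildtype")
        row = hits.iloc[0]
        assert not row["significant"]
        assert "untestable" in row["reason"]

    def test_detection_power_monotone_in_effect_and_n(self):
        def detection_rate(effect, n, n_trials=60):
            det = 0
            for s in range(n_trials):
                rng = np.random.default_rng(10_000 + s)
                records = normalized_frame(
                    {"P1": rng.normal(effect, 0.4, n)}, rng.normal(0, 0.4, 40)
                )
                hits = call_hits(records, "period", "wildtype", m_tests=20)
                det += bool(hits["significant"].iloc[0])
            return det / n_trials

        small_effect = detection_rate(0.25, 10)
        bigger_effect = detection_rate(0.6, 10)
        bigger_n = detection_rate(0.6, 30)
        assert small_effect <= bigger_effect + 0.05
        assert bigger_effect <= bigger_n + 0.05


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "mean_diff, significant, metric, expected",
        [
            (-2.36, True, "phase", "major"),  # strongest phase-delay hit
            (1.02, True, "period", "major"),  # the one major period decoy
            (0.57, True, "period", "minor"),  # long-period-overall example
            (2.16, True, "phase", "major"),
            (1.5, False, "phase", "none"),
            (0.99, True, "period", "minor"),
        ],
    )
    def test_thresholds(self, mean_diff, significant, metric, expected):
        assert classify_effect(mean_diff, significant, metric) == expected
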