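"""Model/Results interface, pipeline bundles, exports, stratified comparison."""

import json

import numpy as np
import pandas as pd
import pytest

import ctmcohort as cc
from ctmcohort.pipeline import export_matrix_tables

from conftest import make_generator


class TestCTMCModel:
    def test_preprocessing_and_fit(self, demo_table):
        model = cc.CTMCModel(demo_table)
        assert model.n_patients == 2
        assert model.n_transitions == 5
        results = model.fit()
        assert results.mode == "paper"
        assert results.counts.N.sum() == 5
        results.generator.check()

    def test_from_dataframe_column_mapping(self):
        df = pd.DataFrame(
            {"pid": ["p1", "p1"], "evt": ["MI", "Death"], "t": [0, 50], "sex": ["F", "F"]}
        )
        model = cc.CTMCModel.from_dataframe(
            df, patient_col="pid", episode_col="evt", day_col="t", covariate_cols=("sex",)
        )
        assert model.trajectories[0].covariates == {"sex": "F"}
        assert model.state_space.absorbing == frozenset({"Death"})

    def test_summary_mentions_key_quantities(self, demo_table):
        text = cc.CTMCModel(demo_table).fit().summary()
        assert "No. patients:" in text and "2" in text
        assert "Generator estimator:" in text and "paper" in text
        assert "CHMI" in text

    def test_results_predictions_consistent(self, demo_table):
        results = cc.CTMCModel(demo_table).fit(mode="mle")
        tpm = results.transition_probability(90.0)
        tpm.check()
        mix = results.forecast_state_mix([1, 0, 0, 0], 90.0)
        np.testing.assert_allclose(mix.to_numpy(), tpm.P[0], atol=1e-12)


def run_config(tmp_path, table, **overrides):
    path = tmp_path / "episodes.csv"
    cc.write_episodes(table, path)
    kwargs = dict(input_path=str(path), out_dir=None, min_state_count=0)
    kwargs.update(overrides)
    return cc.AnalysisConfig(**kwargs)


class TestRunPipeline:
    def test_demo_bundle_counts(self, demo_table, tmp_path):
        bundle = cc.run_pipeline(run_config(tmp_path, demo_table))
        assert bundle.transition_counts.N.sum() == 5
        assert len(bundle.results.model.trajectories) == 2
        assert set(bundle.progression_patterns) == {"MI", "CHF", "CHMI", "CHANMI"}

    def test_deterministic_bundle_and_exports(self, demo_table, tmp_path):
        cfg_a = run_config(tmp_path, demo_table, out_dir=str(tmp_path / "out_a"))
        cfg_b = run_config(tmp_path, demo_table, out_dir=str(tmp_path / "out_b"))
        cc.run_pipeline(cfg_a)
        cc.run_pipeline(cfg_b)
        for name in ("jump_frequencies.csv", "generator_paper.csv", "progression_long.csv"):
            assert (tmp_path / "out_a" / name).read_text() == (
                tmp_path / "out_b" / name
            ).read_text()

    def test_stage_named_on_error_and_outputs_removed(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("patient_id,episode,day\np1,A,-3\n")
        out = tmp_path / "out"
        config = cc.AnalysisConfig(input_path=str(bad), out_dir=str(out))
        with pytest.raises(Exception, match=r"\[stage: input\]"):
            cc.run_pipeline(config)
        assert not out.exists()

    def test_provenance_written(self, demo_table, tmp_path):
        out = tmp_path / "out"
        cc.run_pipeline(run_config(tmp_path, demo_table, out_dir=str(out)))
        prov = json.loads((out / "provenance.json").read_text())
        assert prov["config"]["estimator_mode"] == "paper"
        assert len(prov["input_digest"]) == 64


class TestConfigFile:
    def test_missing_min_count_names_key(self, tmp_path):
        path = tmp_path / "run.cfg"
        path.write_text("[input]\npath = x.csv\n[states]\nabsorbing = Death\n")
        with pytest.raises(ValueError, match="states.min_count"):
            cc.load_config(path)

    def test_full_config_round_trip(self, tmp_path):
        path = tmp_path / "run.cfg"
        path.write_text(
            "[input]\npath = eps.csv\ndelimiter = ,\n"
            "[states]\nabsorbing = Death\nmin_count = 2\n"
            "[estimator]\nmode = mle\n"
            "[prediction]\ninterval_days = 30\nhorizon_days = 360\nstart_states = MI, CHF\n"
            "[output]\ndir = out\nscale = percent\nseed = 5\n"
        )
        cfg = cc.load_config(path)
        assert cfg.min_state_count == 2
        assert cfg.estimator_mode == "mle"
        assert cfg.start_states == ("MI", "CHF")
        assert cfg.interval_days == 30 and cfg.seed == 5


class TestExports:
    @pytest.fixture()
    def bundle(self, demo_table, tmp_path):
        return cc.run_pipeline(run_config(tmp_path, demo_table))

    def test_percent_scale_matches_report_rounding(self, cvd_counts, tmp_path, demo_table):
        bundle = cc.run_pipeline(run_config(tmp_path, demo_table))
        # replace the demo's probabilities by the packaged cohort fixture
        jump = cc.jump_probability_matrix(cvd_counts)
        bundle.jump_probabilities = pd.DataFrame(
            jump,
            index=list(cvd_counts.state_space.states),
            columns=list(cvd_counts.state_space.states),
        )
        out = tmp_path / "pc"
        export_matrix_tables(bundle, out, scale="percent")
        written = pd.read_csv(out / "jump_probabilities.csv", index_col=0)
        assert written.loc["MI", "Death"] == 51.2
        assert written.loc["Angina", "CHF"] == 38.6
        assert written.loc["CHST", "Stroke"] == 42.9

    def test_fraction_rows_sum_to_one(self, bundle, tmp_path):
        out = tmp_path / "fr"
        export_matrix_tables(bundle, out, scale="fraction")
        jump = pd.read_csv(out / "jump_probabilities.csv", index_col=0)
        sums = jump.sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_long_layout_row_count(self, bundle, tmp_path):
        out = tmp_path / "lg"
        export_matrix_tables(bundle, out, layout="long")
        long = pd.read_csv(out / "progression_long.csv")
        n_states = len(bundle.state_space)
        per_start = 20 * n_states
        assert len(long) == per_start * len(bundle.progression_patterns)

    def test_unknown_scale_layout_rejected(self, bundle, tmp_path):
        with pytest.raises(ValueError, match="scale"):
            export_matrix_tables(bundle, tmp_path / "x", scale="permille")
        with pytest.raises(ValueError, match="layout"):
            export_matrix_tables(bundle, tmp_path / "y", layout="diagonal")


def two_stratum_table(seed=31, n=150):
    """Two cohorts with different known generators, tagged by a sex covariate."""
    fast = make_generator(("A", "Death"), [[0, 0.02], [0, 0]])
    slow = make_generator(("A", "Death"), [[0, 0.005], [0, 0]])
    frames = []
    for value, Q, prefix in (("M", fast, "M"), ("F", slow, "F")):
        config = cc.SimulationConfig(
            Q_true=Q, initial_distribution=[1, 0], n_patients=n,
            seed=seed, id_prefix=prefix,
        )
        table = cc.simulate_cohort(config)
        table.df["sex"] = value
        frames.append(table.df)
    df = pd.concat(frames, ignore_index=True)
    return cc.EpisodeTable(df, covariate_labels=("sex",)).sort()


class TestStratifiedCompare:
    def test_pooled_counts_equal_unstratified(self):
        table = two_stratum_table()
        comparison = cc.stratified_compare(table, "sex")
        model = cc.CTMCModel(table, state_order=("A", "Death"))
        pooled = sum(b.transition_counts.N for b in comparison.bundles.values())
        full = cc.count_transitions(model.trajectories, next(iter(comparison.bundles.values())).state_space)
        assert (pooled == full.N).all()

    def test_difference_sign_matches_known_rate_ordering(self):
        table = two_stratum_table()
        comparison = cc.stratified_compare(table, "sex", start_states=("A",))
        diff = comparison.differences
        death = diff[(diff.to_state == "Death") & (diff.start_state == "A")]
        # stratum F (slow) minus stratum M (fast): death probability lower for F
        assert (death.difference < 0).all()

    def test_single_stratum_empty_difference(self):
        table = two_stratum_table()
        df = table.df[table.df.sex == "F"].reset_index(drop=True)
        single = cc.EpisodeTable(df, covariate_labels=("sex",))
        comparison = cc.stratified_compare(single, "sex")
        assert list(comparison.bundles) == ["F"]
        assert comparison.differences.empty

    def test_missing_or_nonconstant_covariate_rejected(self, demo_table):
        with pytest.raises(ValueError, match="not present"):
            cc.stratified_compare(demo_table, "sex")
        table = two_stratum_table()
        df = table.df.copy()
        pid = df.patient_id.iloc[0]
        df.loc[df.patient_id == pid, "sex"] = ["M"] + ["F"] * (
            (df.patient_id == pid).sum() - 1
        )
        broken = cc.EpisodeTable(df, covariate_labels=("sex",))
        with pytest.raises(ValueError, match="not constant"):
            cc.stratified_compare(broken, "sex")
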