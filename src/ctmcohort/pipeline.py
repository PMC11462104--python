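"""End-to-end cohort analysis: configuration, bundles, exports, strata.

A run reads (or simulates) an episode table, builds the Markov model,
estimates the generator, computes every output table — jump frequencies and
probabilities, the generator, per-start-state progression patterns,
transition-time statistics, first-episode distribution and death
attribution — and writes them as delimited text with full provenance.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import estimation, prediction
from .datasets import synthetic_cvd_generator
from .episodes import EpisodeTable, read_episodes, validate_episodes, write_episodes
from .estimation import DeathAttribution, GeneratorMatrix, TransitionCounts, as_percent
from .model import CTMCModel, CTMCResults
from .simulate import SimulationConfig, simulate_cohort
from .states import StateSpace, cvd_naming_scheme

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce a run bit-for-bit."""

    input_path: str | None = None
    delimiter: str = ","
    absorbing: tuple[str, ...] = ("Death",)
    min_state_count: int = 0
    prune_policy: str = "drop_records"
    estimator_mode: str = "paper"
    interval_days: float = 90.0
    horizon_days: float = 1800.0
    start_states: tuple[str, ...] | None = None
    out_dir: str | None = None
    scale: str = "fraction"
    layout: str = "wide"
    seed: int = 0
    simulate_n_patients: int | None = None
    simulate_mean_hold_days: float = 400.0
    simulate_max_followup_days: float = 5800.0

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> AnalysisConfig:
    """Parse a sectioned key-value (INI-style) configuration file.

    Sections: ``[input]`` (path, delimiter), ``[states]`` (absorbing,
    min_count — required, prune_policy), ``[estimator]`` (mode),
    ``[prediction]`` (interval_days, horizon_days, start_states),
    ``[simulation]`` (n_patients, mean_hold_days, max_followup_days) and
    ``[output]`` (dir, scale, layout, seed).
    """
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise ValueError(f"cannot read config file {path!r}")
    cfg = AnalysisConfig()
    if parser.has_section("input"):
        cfg.input_path = parser.get("input", "path", fallback=None)
        cfg.delimiter = parser.get("input", "delimiter", fallback=",")
        if cfg.delimiter == "tab":
            cfg.delimiter = "\t"
    if not parser.has_option("states", "min_count"):
        raise ValueError("missing required config key 'states.min_count'")
    cfg.min_state_count = parser.getint("states", "min_count")
    absorbing = parser.get("states", "absorbing", fallback="Death")
    cfg.absorbing = tuple(s.strip() for s in absorbing.split(",") if s.strip())
    cfg.prune_policy = parser.get("states", "prune_policy", fallback="drop_records")
    if parser.has_section("estimator"):
        cfg.estimator_mode = parser.get("estimator", "mode", fallback="paper")
    if parser.has_section("prediction"):
        cfg.interval_days = parser.getfloat("prediction", "interval_days", fallback=90.0)
        cfg.horizon_days = parser.getfloat("prediction", "horizon_days", fallback=1800.0)
        raw = parser.get("prediction", "start_states", fallback="")
        states = tuple(s.strip() for s in raw.split(",") if s.strip())
        cfg.start_states = states or None
    if parser.has_section("simulation"):
        cfg.simulate_n_patients = parser.getint("simulation", "n_patients", fallback=None)
        cfg.simulate_mean_hold_days = parser.getfloat(
            "simulation", "mean_hold_days", fallback=400.0
        )
        cfg.simulate_max_followup_days = parser.getfloat(
            "simulation", "max_followup_days", fallback=5800.0
        )
    if parser.has_section("output"):
        cfg.out_dir = parser.get("output", "dir", fallback=None)
        cfg.scale = parser.get("output", "scale", fallback="fraction")
        cfg.layout = parser.get("output", "layout", fallback="wide")
        cfg.seed = parser.getint("output", "seed", fallback=0)
    return cfg


@dataclass
class AnalysisBundle:
    """The complete output set of one pipeline run on one cohort."""

    state_space: StateSpace
    transition_counts: TransitionCounts
    jump_probabilities: pd.DataFrame
    generator: GeneratorMatrix
    transition_time_stats: pd.DataFrame
    first_episode_distribution: pd.DataFrame
    death_attribution: DeathAttribution | None
    progression_patterns: Mapping[str, prediction.ProgressionPattern]
    provenance: dict = field(default_factory=dict)
    results: CTMCResults | None = None


def _input_table(config: AnalysisConfig) -> EpisodeTable:
    if config.input_path:
        return read_episodes(config.input_path, delimiter=config.delimiter)
    if config.simulate_n_patients:
        Q = synthetic_cvd_generator(config.simulate_mean_hold_days)
        init = np.zeros(len(Q.state_space))
        # start patients in the four single-morbidity states, uniformly
        for s in ("MI", "Stroke", "CHF", "Angina"):
            init[Q.state_space.index(s)] = 0.25
        sim = SimulationConfig(
            Q_true=Q,
            initial_distribution=init,
            n_patients=config.simulate_n_patients,
            max_followup_days=config.simulate_max_followup_days,
            seed=config.seed,
        )
        return simulate_cohort(sim)
    raise ValueError("config must name an input episode file or a simulation size")


def _bundle_from_results(
    results: CTMCResults, config: AnalysisConfig, digest: str
) -> AnalysisBundle:
    space = results.state_space
    starts = config.start_states or tuple(
        s for s in space.states if not space.is_absorbing(s)
    )
    patterns = {
        s: results.progression(s, config.interval_days, config.horizon_days)
        for s in starts
    }
    attribution = None
    if space.absorbing:
        try:
            attribution = results.death_attribution()
        except ValueError:
            logger.warning("no transitions into the absorbing state; attribution skipped")
    provenance = {"config": config.to_dict(), "input_digest": digest, "seed": config.seed}
    return AnalysisBundle(
        state_space=space,
        transition_counts=results.counts,
        jump_probabilities=results.jump_probability_matrix(),
        generator=results.generator,
        transition_time_stats=results.transition_time_stats(),
        first_episode_distribution=results.first_episode_distribution(),
        death_attribution=attribution,
        progression_patterns=patterns,
        provenance=provenance,
        results=results,
    )


def run_pipeline(config: AnalysisConfig) -> AnalysisBundle:
    """Execute read → state construction → estimation → prediction → export.

    Stage failures propagate with the stage named; any files already written
    to the output directory by the failed run are removed.
    """
    stage = "input"
    out_dir = Path(config.out_dir) if config.out_dir else None
    created = out_dir is not None and not out_dir.exists()
    try:
        table = _input_table(config)
        report = validate_episodes(table, absorbing_labels=config.absorbing)
        logger.info(
            "input: %d records, %d patients, %d warnings",
            report.n_records, report.n_patients, len(report.warnings),
        )
        if not report.accepted:
            raise ValueError(f"input rejected: {report.errors[:5]}")
        stage = "state construction"
        model = CTMCModel(
            table,
            absorbing=config.absorbing,
            min_state_count=config.min_state_count,
            prune_policy=config.prune_policy,
        )
        logger.info(
            "states: %d states (%d pruned), %d trajectories",
            len(model.state_space), len(model.state_space.dropped_states),
            model.n_patients,
        )
        stage = "estimation"
        results = model.fit(mode=config.estimator_mode)
        logger.info("estimation: %d transitions, mode=%s", model.n_transitions, results.mode)
        stage = "prediction"
        digest = ""
        if config.input_path:
            digest = hashlib.sha256(Path(config.input_path).read_bytes()).hexdigest()
        bundle = _bundle_from_results(results, config, digest)
        if out_dir is not None:
            stage = "export"
            export_matrix_tables(bundle, out_dir, scale=config.scale, layout=config.layout)
            write_episodes(table, out_dir / "episodes_used.csv")
        return bundle
    except Exception as exc:
        if out_dir is not None and out_dir.exists() and created:
            shutil.rmtree(out_dir, ignore_errors=True)
        try:
            wrapped = type(exc)(f"[stage: {stage}] {exc}")
        except Exception:
            wrapped = RuntimeError(f"[stage: {stage}] {exc}")
        raise wrapped from exc


def _matrix_frame(df: pd.DataFrame, scale: str) -> pd.DataFrame:
    if scale == "percent":
        return pd.DataFrame(as_percent(df.to_numpy()), index=df.index, columns=df.columns)
    if scale == "fraction":
        return df
    raise ValueError(f"unknown scale {scale!r}")


def export_matrix_tables(
    bundle: AnalysisBundle, out_dir, scale: str = "fraction", layout: str = "wide"
) -> list[Path]:
    """Write every bundle table as delimited text; returns the paths written.

    Percent scale rounds half-up to one decimal (report formatting); wide
    layout writes states x states matrices per grid time, long layout one
    (start_state, time_days, to_state, probability) table.
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"unknown layout {layout!r}")
    if scale not in ("fraction", "percent"):
        raise ValueError(f"unknown scale {scale!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out / name
        df.to_csv(path, index=index)
        written.append(path)

    save(bundle.transition_counts.to_frame("N"), "jump_frequencies.csv")
    save(_matrix_frame(bundle.jump_probabilities, scale), "jump_probabilities.csv")
    save(bundle.generator.to_frame(), f"generator_{bundle.generator.mode}.csv")
    save(bundle.transition_time_stats, "transition_time_stats.csv", index=False)
    save(bundle.first_episode_distribution, "first_episodes.csv", index=False)
    if bundle.death_attribution is not None:
        save(bundle.death_attribution.table, "death_attribution.csv", index=False)
    long_parts = []
    for start, pattern in bundle.progression_patterns.items():
        if layout == "wide":
            save(_matrix_frame(pattern.to_wide(), scale), f"progression_wide_{start}.csv")
        long_parts.append(pattern.to_frame())
    if long_parts:
        long_df = pd.concat(long_parts, ignore_index=True)
        if scale == "percent":
            long_df["probability"] = as_percent(long_df["probability"])
        save(long_df, "progression_long.csv", index=False)
    # full P(t) matrices on the grid of the first pattern
    if bundle.progression_patterns:
        first = next(iter(bundle.progression_patterns.values()))
        pt_dir = out / "transition_probabilities"
        pt_dir.mkdir(exist_ok=True)
        for t in first.grid:
            P = prediction.transition_probability(bundle.generator, float(t))
            frame = _matrix_frame(P.to_frame(), scale)
            path = pt_dir / f"P_t{int(t) if float(t).is_integer() else t}.csv"
            frame.to_csv(path)
            written.append(path)
    if bundle.provenance:
        path = out / "provenance.json"
        path.write_text(json.dumps(bundle.provenance, indent=2, default=str))
        written.append(path)
    return written


def export_workbook(bundle: AnalysisBundle, path, scale: str = "percent") -> None:
    """Collate the bundle into one multi-sheet spreadsheet (needs openpyxl)."""
    try:
        import openpyxl  # noqa: F401
    except ImportError as exc:
        raise ImportError("workbook export requires the optional 'xlsx' extra") from exc
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        bundle.transition_counts.to_frame("N").to_excel(writer, sheet_name="jump_frequencies")
        _matrix_frame(bundle.jump_probabilities, scale).to_excel(
            writer, sheet_name="jump_probabilities"
        )
        bundle.generator.to_frame().to_excel(writer, sheet_name="generator")
        bundle.transition_time_stats.to_excel(
            writer, sheet_name="transition_times", index=False
        )
        bundle.first_episode_distribution.to_excel(
            writer, sheet_name="first_episodes", index=False
        )
        for start, pattern in bundle.progression_patterns.items():
            _matrix_frame(pattern.to_wide(), scale).to_excel(
                writer, sheet_name=f"progression_{start}"[:31]
            )


@dataclass
class StratifiedComparison:
    """Per-stratum bundles plus probability difference tables."""

    covariate: str
    bundles: Mapping[str, AnalysisBundle]
    differences: pd.DataFrame  # (stratum_a, stratum_b, start_state, time_days, to_state, difference)


def stratified_compare(
    table: EpisodeTable,
    stratum_covariate: str,
    absorbing: Sequence[str] = ("Death",),
    min_state_count: int = 0,
    estimator_mode: str = "paper",
    interval_days: float = 90.0,
    horizon_days: float = 1800.0,
    start_states: Sequence[str] | None = None,
) -> StratifiedComparison:
    """Partition the cohort by a covariate and compare progression patterns.

    All strata share one state space (built from the pooled cohort, so the
    strata's transition counts pool back to the unstratified counts), and
    the difference table reports stratumA − stratumB transition
    probabilities per grid time and target state for each stratum pair.
    """
    if stratum_covariate not in table.covariate_labels:
        raise ValueError(f"covariate {stratum_covariate!r} not present on the table")
    per_patient = table.df.groupby("patient_id")[stratum_covariate].nunique()
    if (per_patient > 1).any():
        bad = per_patient[per_patient > 1].index.tolist()
        raise ValueError(
            f"covariate {stratum_covariate!r} not constant within patients: {bad[:5]}"
        )
    model = CTMCModel(table, absorbing=absorbing, min_state_count=min_state_count)
    space = model.state_space
    strata: dict[str, list] = {}
    for traj in model.trajectories:
        strata.setdefault(str(traj.covariates[stratum_covariate]), []).append(traj)
    starts = tuple(start_states or (s for s in space.states if not space.is_absorbing(s)))
    bundles: dict[str, AnalysisBundle] = {}
    for value in sorted(strata):
        trajectories = strata[value]
        counts = estimation.count_transitions(trajectories, space)
        generator = estimation.estimate_generator(counts, mode=estimator_mode)
        patterns = {
            s: prediction.progression_series(generator, s, interval_days, horizon_days)
            for s in starts
        }
        attribution = None
        if space.absorbing:
            try:
                (absorbing_state,) = space.absorbing
                attribution = estimation.death_attribution(counts, absorbing_state)
            except ValueError:
                attribution = None
        bundles[value] = AnalysisBundle(
            state_space=space,
            transition_counts=counts,
            jump_probabilities=pd.DataFrame(
                estimation.jump_probability_matrix(counts),
                index=list(space.states), columns=list(space.states),
            ),
            generator=generator,
            transition_time_stats=estimation.transition_time_stats(counts),
            first_episode_distribution=estimation.first_episode_distribution(trajectories),
            death_attribution=attribution,
            progression_patterns=patterns,
            provenance={"stratum": {stratum_covariate: value}},
        )
    diff_rows = []
    values = sorted(bundles)
    for a_idx in range(len(values)):
        for b_idx in range(a_idx + 1, len(values)):
            a, b = values[a_idx], values[b_idx]
            for s in starts:
                pa, pb = bundles[a].progression_patterns[s], bundles[b].progression_patterns[s]
                for k, t in enumerate(pa.grid):
                    for j, to_state in enumerate(space.states):
                        diff_rows.append(
                            {
                                "stratum_a": a,
                                "stratum_b": b,
                                "start_state": s,
                                "time_days": float(t),
                                "to_state": to_state,
                                "difference": float(pa.probs[k, j] - pb.probs[k, j]),
                            }
                        )
    differences = pd.DataFrame(
        diff_rows,
        columns=["stratum_a", "stratum_b", "start_state", "time_days", "to_state", "difference"],
    )
    return StratifiedComparison(
        covariate=stratum_covariate, bundles=bundles, differences=differences
    )
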