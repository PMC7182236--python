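"""End-to-end orchestration: plan -> simulate -> screen -> filter -> CS -> fit.

The unit of work is one simulated participant: a randomized session plan
is generated from an experiment preset, epochs are forward-simulated,
screened for artifacts, truncated and detrended, and then — per
condition, as in the reference analysis — a RESS filter is derived at
the regularity frequency, trials are projected, spectra computed, and
the CS index taken from the phases at the target bin.  Stacking
participants yields the CS table that the multilevel model consumes.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import yaml

from . import design, simulate as sim
from .design import ExperimentSpec
from .epochs import EpochSet
from .inference import CSModel, CSResults, ModelSpec
from .phase_stats import cs_index_closed, itc
from .preprocess import ScreeningParams, rereference, screen_epochs
from .simulate import ForwardModel, SimulationConfig
from .spectral import (AnalysisWindow, FilterParams, phase_at, ress_fit,
                       ress_project, spectrum, truncate_detrend)

logger = logging.getLogger("fpvs")

__all__ = [
    "RunConfig",
    "load_config",
    "default_window",
    "compute_cs_table",
    "simulate_participant",
    "run_study",
    "StudyResult",
]


@dataclasses.dataclass
class RunConfig:
    """Everything needed for a reproducible multi-participant run."""

    experiment: str = "pilot1"
    n_participants: int = 16
    trials_per_condition: int | None = None  # None -> preset value
    preprocess: bool = True
    # between-participant spread of phase concentration (log-normal SD)
    participant_kappa_sd: float = 0.3
    tukey_alpha: float = 0.25
    pad_to: float = 10.0
    sim_overrides: dict = dataclasses.field(default_factory=dict)
    model: ModelSpec = dataclasses.field(default_factory=ModelSpec)

    def spec(self) -> ExperimentSpec:
        spec = design.preset(self.experiment)
        if self.trials_per_condition is not None:
            spec = design.scaled(spec, self.trials_per_condition)
        return spec


def load_config(path) -> RunConfig:
    """Read a YAML run configuration (one mapping, keys as in RunConfig)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model_kw = raw.pop("model", {})
    cfg = RunConfig(**raw)
    if model_kw:
        cfg.model = ModelSpec(**model_kw)
    return cfg


def default_window(spec: ExperimentSpec) -> AnalysisWindow:
    """3 s window for 15 Hz sessions, 6.5 s for 6 Hz sessions, 0.5 s offset."""
    length = 3.0 if spec.trial_duration <= 4.0 else 6.5
    return AnalysisWindow(start_offset=0.5, length=length)


def compute_cs_table(epochs: EpochSet, f_target: float,
                     window: AnalysisWindow | None = None,
                     params: FilterParams = FilterParams(),
                     tukey_alpha: float = 0.25, pad_to: float = 10.0,
                     frequency_label: str = "regularity") -> pd.DataFrame:
    """Per-condition RESS -> projection -> spectrum -> phase -> CS.

    Spatial filters are derived separately for each experimental
    condition; a single common filter can be emulated by passing a
    one-condition EpochSet.
    """
    if window is not None:
        epochs = truncate_detrend(epochs, window)
    rows = []
    for label in sorted(epochs.conditions.unique()):
        sub = epochs.select_condition(label)
        filt = ress_fit(sub, f_target, params, condition=label)
        proj = ress_project(sub, filt)
        spec = spectrum(proj, sub.sfreq, tukey_alpha=tukey_alpha, pad_to=pad_to)
        phases = phase_at(spec, f_target)
        cond = design.Condition.from_label(label)
        rows.append(
            {
                "condition": label,
                "orientation": cond.orientation,
                "regularity": cond.regularity,
                "variability": cond.variability,
                "frequency": frequency_label,
                "n_trials": phases.n,
                "cs": cs_index_closed(phases).value,
                "itc": itc(phases),
            }
        )
    return pd.DataFrame(rows)


def _participant_config(base: SimulationConfig, kappa_sd: float,
                        rng: np.random.Generator) -> SimulationConfig:
    """Per-participant draw of phase concentration (log-normal factor)."""
    if kappa_sd <= 0:
        return base
    factor = float(np.exp(rng.normal(0.0, kappa_sd)))
    kappa = {k: v * factor for k, v in base.kappa.items()}
    return dataclasses.replace(base, kappa=kappa)


def simulate_participant(spec: ExperimentSpec, model: ForwardModel,
                         config: SimulationConfig,
                         rng: np.random.Generator) -> EpochSet:
    """Plan and simulate one participant's session (target trials dropped,
    as trials with behavioral responses are discarded before analysis)."""
    plan = design.build_session_plan(spec, rng)
    plan = [s for s in plan if not s.target_onsets_ms]
    epochs = sim.simulate_experiment(plan, model, config, rng)
    return epochs


@dataclasses.dataclass
class StudyResult:
    """CS table, fitted model results, and per-participant rejection rates."""

    cs_table: pd.DataFrame
    results: CSResults | None
    rejection: pd.DataFrame

    def table1(self) -> pd.DataFrame:
        """Rejection percentages aggregated across simulated participants
        (condition, mean %, SD, min, max)."""
        if self.rejection.empty:
            return pd.DataFrame(
                columns=["condition", "mean", "st.dev.", "min.", "max."]
            )
        g = self.rejection.groupby("condition")["pct"]
        out = g.agg(["mean", "std", "min", "max"]).reset_index()
        out.columns = ["condition", "mean", "st.dev.", "min.", "max."]
        return out

    def table2(self) -> pd.DataFrame:
        """Condition-level CS mean with a 95% t-interval across participants."""
        from scipy import stats as st

        rows = []
        for label, grp in self.cs_table.groupby("condition"):
            v = grp["cs"].to_numpy()
            m = v.mean()
            if len(v) > 1 and v.std(ddof=1) > 0:
                half = st.t.ppf(0.975, len(v) - 1) * v.std(ddof=1) / np.sqrt(len(v))
            else:
                half = 0.0
            rows.append((label, m, m - half, m + half, len(v)))
        return pd.DataFrame(
            rows, columns=["condition", "cs_mean", "ci_low", "ci_high", "n"]
        )


def run_study(cfg: RunConfig, seed: int | None = None,
              fit: bool = True) -> StudyResult:
    """Simulate ``n_participants`` sessions and fit the multilevel model."""
    spec = cfg.spec()
    fwd = ForwardModel.default()
    base = SimulationConfig.for_spec(spec, **cfg.sim_overrides)
    window = default_window(spec)
    root = np.random.SeedSequence(seed)
    tables = []
    rej_rows = []
    for p, ss in enumerate(root.spawn(cfg.n_participants)):
        rng = np.random.default_rng(ss)
        config = _participant_config(base, cfg.participant_kappa_sd, rng)
        epochs = simulate_participant(spec, fwd, config, rng)
        epochs = rereference(epochs, "average")
        if cfg.preprocess:
            epochs, report = screen_epochs(epochs, ScreeningParams())
            pct = report.percentages()
            pct.insert(0, "participant", p)
            rej_rows.append(pct)
        table = compute_cs_table(
            epochs, spec.regularity_rate, window,
            tukey_alpha=cfg.tukey_alpha, pad_to=cfg.pad_to,
        )
        table.insert(0, "participant", p)
        table.insert(1, "experiment", spec.name)
        tables.append(table)
        logger.info("participant %d/%d done", p + 1, cfg.n_participants)
    cs_table = pd.concat(tables, ignore_index=True)
    rejection = (
        pd.concat(rej_rows, ignore_index=True) if rej_rows else pd.DataFrame()
    )
    results = None
    if fit:
        results = CSModel(cs_table, spec=cfg.model).fit(
            seed=int(root.generate_state(1)[0] % (2**31))
        )
    return StudyResult(cs_table=cs_table, results=results, rejection=rejection)
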