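"""RSVP session planning for fast periodic visual stimulation (FPVS) designs.

An FPVS oddball session presents a rapid serial stream of face images at a
fixed *stimulation rate*, with one expression category recurring on every
third cycle in the *regular* conditions.  This module builds frame-accurate
session plans: per-trial cycle sequences (identity, expression), condition
assignment, and target-dot scheduling for the orthogonal detection task.

Four presets reproduce the designs of the reference experiments: a 15 Hz
pilot with nine identities, a 15 Hz pilot with two identities (low/high
within-identity expression variability), and two 6 Hz experiments (the
second a passive-viewing session without targets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "TargetPolicy",
    "ExperimentSpec",
    "StimulusSequence",
    "ConfigurationError",
    "SchedulingError",
    "build_sequence",
    "build_session_plan",
    "schedule_targets",
    "rgb_to_luminance",
    "pilot1",
    "pilot2",
    "experiment1",
    "experiment2",
    "preset",
    "PRESET_NAMES",
    "plan_to_frame",
    "plan_to_json",
    "plan_from_json",
]


class ConfigurationError(ValueError):
    """Raised when an experiment specification is internally inconsistent."""


class SchedulingError(RuntimeError):
    """Raised when target-interval constraints cannot be satisfied."""


REGULAR_CATEGORIES = ("angry", "neutral")
#: expressions that only ever serve as fillers, never as the regular category
FILLER_ONLY = ("happy", "disgusted")

ORIENTATIONS = ("upright", "inverted")


@dataclass(frozen=True)
class Condition:
    """One factorial cell: orientation x regularity (x variability)."""

    orientation: str
    regularity: str  # "angry" | "neutral" | "irregular"
    variability: str = "none"  # "high" | "low" | "none"

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")
        if self.regularity not in REGULAR_CATEGORIES + ("irregular",):
            raise ConfigurationError(f"unknown regularity {self.regularity!r}")

    @property
    def label(self) -> str:
        return f"{self.orientation}/{self.regularity}/{self.variability}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        return cls(*label.split("/"))


@dataclass(frozen=True)
class TargetPolicy:
    """Parameters of the orthogonal dot-detection task."""

    target_trials_per_condition: int
    max_targets_per_trial: int = 3
    min_target_interval_ms: float = 600.0
    target_duration_frames: int = 2


@dataclass(frozen=True)
class ExperimentSpec:
    """Complete description of one RSVP experiment.

    ``identities`` is the pool used when no variability factor is active
    (a fresh identity drawn each cycle); when conditions carry a
    variability level, ``identity_by_variability`` maps each level to the
    single identity shown for the whole trial.
    """

    name: str
    stimulation_rate: float  # Hz, faces per second
    trial_duration: float  # s of RSVP stream
    trials_per_condition: int
    conditions: tuple[Condition, ...]
    expressions: tuple[str, ...]
    identities: tuple[str, ...] = ()
    identity_by_variability: dict[str, str] | None = None
    regularity_divisor: int = 3
    refresh_rate: float = 60.0  # display frames per second
    target_policy: TargetPolicy | None = None

    def __post_init__(self):
        if not self.conditions:
            raise ConfigurationError("spec lists no conditions")
        n_cyc = self.stimulation_rate * self.trial_duration
        if abs(n_cyc - round(n_cyc)) > 1e-9:
            raise ConfigurationError(
                f"trial_duration {self.trial_duration} s is not a whole number of "
                f"{self.stimulation_rate} Hz cycles"
            )
        if round(n_cyc) % self.regularity_divisor:
            raise ConfigurationError(
                f"{round(n_cyc)} cycles is not a whole number of "
                f"{self.regularity_divisor}-cycle triplets"
            )
        frames_per_cycle = self.refresh_rate / self.stimulation_rate
        if abs(frames_per_cycle - round(frames_per_cycle)) > 1e-9:
            raise ConfigurationError(
                f"refresh rate {self.refresh_rate} not divisible by "
                f"stimulation rate {self.stimulation_rate}"
            )
        for cond in self.conditions:
            if cond.variability != "none":
                if not self.identity_by_variability or cond.variability not in self.identity_by_variability:
                    raise ConfigurationError(
                        f"no identity mapped to variability level {cond.variability!r}"
                    )
            elif not self.identities:
                raise ConfigurationError("identity pool empty")

    @property
    def n_cycles(self) -> int:
        return round(self.stimulation_rate * self.trial_duration)

    @property
    def regularity_rate(self) -> float:
        return self.stimulation_rate / self.regularity_divisor

    @property
    def n_trials(self) -> int:
        return self.trials_per_condition * len(self.conditions)


@dataclass
class StimulusSequence:
    """One trial's ordered cycle entries plus condition and target onsets."""

    cycles: list[tuple[str, str]]  # (identity, expression) per cycle
    condition: Condition
    orientation: str
    target_onsets_ms: list[float] = field(default_factory=list)

    @property
    def expressions(self) -> list[str]:
        return [e for _, e in self.cycles]

    @property
    def n_triplets(self) -> int:
        return len(self.cycles) // 3


def rgb_to_luminance(red, green, blue):
    """Effective pixel luminance by the NTSC grayscale conversion.

    intensity = 0.2989*R + 0.5870*G + 0.1140*B, channels in [0, 255];
    the weighted sum is returned unrounded.
    """
    r, g, b = (np.asarray(c, dtype=float) for c in (red, green, blue))
    for name, c in (("red", r), ("green", g), ("blue", b)):
        if np.any(c < 0) or np.any(c > 255):
            raise ValueError(f"{name} channel outside [0, 255]")
    out = 0.2989 * r + 0.5870 * g + 0.1140 * b
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# presets

def pilot1() -> ExperimentSpec:
    """15 Hz RSVP, nine male identities, 3.8 s trials, 96 trials/condition."""
    ids = tuple(f"id{n:02d}" for n in (21, 22, 23, 25, 26, 33, 34, 36, 37))
    conds = tuple(
        Condition(o, r) for o in ORIENTATIONS for r in ("angry", "neutral", "irregular")
    )
    return ExperimentSpec(
        name="pilot1",
        stimulation_rate=15.0,
        trial_duration=3.8,
        trials_per_condition=96,
        conditions=conds,
        expressions=("neutral", "angry", "happy"),
        identities=ids,
        target_policy=TargetPolicy(target_trials_per_condition=36),
    )


def _two_identity_conditions() -> tuple[Condition, ...]:
    return tuple(
        Condition(o, r, v)
        for o in ORIENTATIONS
        for r in ("angry", "neutral", "irregular")
        for v in ("high", "low")
    )


def pilot2() -> ExperimentSpec:
    """15 Hz RSVP, one identity per trial (low/high expression variability)."""
    return ExperimentSpec(
        name="pilot2",
        stimulation_rate=15.0,
        trial_duration=3.8,
        trials_per_condition=48,
        conditions=_two_identity_conditions(),
        expressions=("neutral", "angry", "happy", "disgusted"),
        identity_by_variability={"low": "id06", "high": "id37"},
        target_policy=TargetPolicy(target_trials_per_condition=18),
    )


def experiment1() -> ExperimentSpec:
    """6 Hz RSVP, 7 s trials, 800 ms minimum target interval."""
    return ExperimentSpec(
        name="exp1",
        stimulation_rate=6.0,
        trial_duration=7.0,
        trials_per_condition=48,
        conditions=_two_identity_conditions(),
        expressions=("neutral", "angry", "happy", "disgusted"),
        identity_by_variability={"low": "id06", "high": "id37"},
        target_policy=TargetPolicy(
            target_trials_per_condition=18, min_target_interval_ms=800.0
        ),
    )


def experiment2() -> ExperimentSpec:
    """6 Hz RSVP, passive viewing: 360 trials, no targets."""
    return ExperimentSpec(
        name="exp2",
        stimulation_rate=6.0,
        trial_duration=7.0,
        trials_per_condition=30,
        conditions=_two_identity_conditions(),
        expressions=("neutral", "angry", "happy", "disgusted"),
        identity_by_variability={"low": "id06", "high": "id37"},
        target_policy=None,
    )


PRESET_NAMES = ("pilot1", "pilot2", "exp1", "exp2")


def preset(name: str) -> ExperimentSpec:
    try:
        return {
            "pilot1": pilot1,
            "pilot2": pilot2,
            "exp1": experiment1,
            "exp2": experiment2,
        }[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {PRESET_NAMES}"
        ) from None


def scaled(spec: ExperimentSpec, trials_per_condition: int) -> ExperimentSpec:
    """Copy of a preset with fewer trials per condition (target count scaled)."""
    policy = spec.target_policy
    if policy is not None:
        frac = policy.target_trials_per_condition / spec.trials_per_condition
        policy = replace(
            policy,
            target_trials_per_condition=max(1, round(frac * trials_per_condition)),
        )
    return replace(spec, trials_per_condition=trials_per_condition, target_policy=policy)


# ---------------------------------------------------------------------------
# sequence construction


def _balanced_draw(counts: dict[str, int], k: int, rng: np.random.Generator,
                   avoid: set[str] = frozenset()) -> list[str]:
    """Draw k distinct categories preferring the least-used ones.

    Ties broken at random; categories in ``avoid`` are skipped when enough
    alternatives remain (keeps session-level balance while honoring the
    no-short-term-repeat preference).
    """
    cats = list(counts)
    usable = [c for c in cats if c not in avoid]
    if len(usable) < k:
        usable = cats
    order = sorted(usable, key=lambda c: (counts[c], rng.random()))
    picked = order[:k]
    for c in picked:
        counts[c] += 1
    return picked


def _pick_identity(pool: tuple[str, ...], expression: str,
                   prev_tokens: set[tuple[str, str]],
                   rng: np.random.Generator) -> str:
    ok = [i for i in pool if (i, expression) not in prev_tokens]
    if not ok:  # single-identity designs: constraint infeasible, fall back
        ok = list(pool)
    return ok[rng.integers(len(ok))]


def build_sequence(condition: Condition, spec: ExperimentSpec,
                   rng: np.random.Generator) -> StimulusSequence:
    """Build the ordered (identity, expression) cycles for one trial.

    Regular conditions place the regular category on every first triplet
    position (cycles 0, 3, 6, ...) and draw the two fillers from the
    remaining categories, balanced over the trial; irregular conditions
    fill each triplet with distinct categories in random order.  Tokens
    (identity + expression) of one triplet are kept out of the next
    triplet where the identity pool permits.
    """
    if condition not in spec.conditions:
        raise ConfigurationError(f"condition {condition.label} not in spec {spec.name}")
    n_triplets = spec.n_cycles // spec.regularity_divisor

    if condition.variability == "none":
        id_pool = spec.identities
    else:
        id_pool = (spec.identity_by_variability[condition.variability],)

    regular = condition.regularity if condition.regularity != "irregular" else None
    fillers = [e for e in spec.expressions if e != regular]
    filler_counts = {e: 0 for e in fillers}

    cycles: list[tuple[str, str]] = []
    prev_tokens: set[tuple[str, str]] = set()
    for _ in range(n_triplets):
        prev_exprs = {e for _, e in prev_tokens} if len(id_pool) == 1 else set()
        if regular is not None:
            two = _balanced_draw(filler_counts, 2, rng, avoid=prev_exprs)
            rng.shuffle(two)
            exprs = [regular] + two
        else:
            k = spec.regularity_divisor  # all-distinct triplet
            exprs = _balanced_draw(filler_counts, k, rng, avoid=prev_exprs)
            rng.shuffle(exprs)
        triplet: list[tuple[str, str]] = []
        for pos, e in enumerate(exprs):
            exempt = regular is not None and pos == 0 and len(id_pool) == 1
            ident = (
                id_pool[0]
                if exempt
                else _pick_identity(id_pool, e, prev_tokens, rng)
            )
            triplet.append((ident, e))
        cycles.extend(triplet)
        prev_tokens = set(triplet)

    return StimulusSequence(
        cycles=cycles, condition=condition, orientation=condition.orientation
    )


def build_session_plan(spec: ExperimentSpec,
                       rng: np.random.Generator) -> list[StimulusSequence]:
    """All trials of a session in randomized order, targets scheduled."""
    plan = [
        build_sequence(cond, spec, rng)
        for cond in spec.conditions
        for _ in range(spec.trials_per_condition)
    ]
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]
    if spec.target_policy is not None:
        plan = schedule_targets(plan, spec, rng)
    return plan


def schedule_targets(plan: list[StimulusSequence], spec: ExperimentSpec,
                     rng: np.random.Generator) -> list[StimulusSequence]:
    """Assign target-dot onsets to a fixed number of trials per condition.

    Onsets are quantized to the display frame grid, lie fully inside the
    RSVP window, and consecutive onsets within a trial are separated by at
    least the configured minimum interval.
    """
    policy = spec.target_policy
    if policy is None:
        return plan
    frames_total = round(spec.trial_duration * spec.refresh_rate)
    gap_frames = int(np.ceil(policy.min_target_interval_ms / 1000.0 * spec.refresh_rate))
    latest = frames_total - policy.target_duration_frames
    if latest < 0:
        raise SchedulingError(
            f"trial of {frames_total} frames cannot contain a "
            f"{policy.target_duration_frames}-frame target"
        )

    by_cond: dict[str, list[int]] = {}
    for i, seq in enumerate(plan):
        by_cond.setdefault(seq.condition.label, []).append(i)

    for label, idxs in by_cond.items():
        n_tt = policy.target_trials_per_condition
        if n_tt > len(idxs):
            raise SchedulingError(
                f"{n_tt} target trials requested but condition {label} has "
                f"only {len(idxs)} trials"
            )
        chosen = rng.choice(idxs, size=n_tt, replace=False)
        for i in chosen:
            k = int(rng.integers(1, policy.max_targets_per_trial + 1))
            # reduce k until the interval constraint is feasible
            while k > 1 and latest - (k - 1) * gap_frames < 0:
                k -= 1
            if latest - (k - 1) * gap_frames < 0:
                raise SchedulingError(
                    f"minimum interval {policy.min_target_interval_ms} ms "
                    f"infeasible within a {spec.trial_duration} s trial"
                )
            # uniform draw of k onsets with pairwise gaps >= gap_frames
            slack = latest - (k - 1) * gap_frames
            base = np.sort(rng.integers(0, slack + 1, size=k))
            frames = base + gap_frames * np.arange(k)
            plan[i].target_onsets_ms = [
                1000.0 * f / spec.refresh_rate for f in frames
            ]
    return plan


# ---------------------------------------------------------------------------
# serialization


def plan_to_frame(plan: list[StimulusSequence]) -> pd.DataFrame:
    """Flat table: one row per cycle (trial, condition, cycle, identity, ...)."""
    rows = []
    for t, seq in enumerate(plan):
        onsets = ";".join(f"{o:g}" for o in seq.target_onsets_ms)
        for c, (ident, expr) in enumerate(seq.cycles):
            rows.append(
                (t, seq.condition.label, c, ident, expr, seq.orientation, onsets)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "trial", "condition", "cycle", "identity",
            "expression", "orientation", "target_onsets_ms",
        ],
    )


def plan_to_json(plan: list[StimulusSequence], path) -> None:
    payload = [
        {
            "condition": seq.condition.label,
            "orientation": seq.orientation,
            "cycles": [list(c) for c in seq.cycles],
            "target_onsets_ms": seq.target_onsets_ms,
        }
        for seq in plan
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def plan_from_json(path) -> list[StimulusSequence]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        StimulusSequence(
            cycles=[tuple(c) for c in item["cycles"]],
            condition=Condition.from_label(item["condition"]),
            orientation=item["orientation"],
            target_onsets_ms=list(item["target_onsets_ms"]),
        )
        for item in payload
    ]
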