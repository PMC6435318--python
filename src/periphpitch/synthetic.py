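"""Synthetic 2AFC observers.

Generates trial tables with the structural statistics of the behavioural
task — sessions of roughly 94 +/- 24 trials, an 80/20 standard/probe mix with
the four probe classes equally likely, forced error-correction trials after
incorrect standard responses (ferret task only), per-condition Bernoulli
accuracy plus lapse and side-bias nuisance parameters — so that the analysis
pipeline can be validated end-to-end without any behavioural data download.
Observer accuracies are free parameters of the generator, not derived from
the periphery model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stimuli import ProbeCondition
from .behavior import REQUIRED_COLUMNS, percent_correct

PROBE_CONDITIONS = (
    ProbeCondition.LOW_HARMONICS,
    ProbeCondition.HIGH_HARMONICS,
    ProbeCondition.ALL_RANDOM_PHASE,
    ProbeCondition.HIGH_RANDOM_PHASE,
)


@dataclass(frozen=True)
class ObserverParams:
    """One simulated subject.

    ``accuracy`` maps condition labels to the probability of a correct
    response before lapses and bias are applied.  ``lapse_rate`` is the
    probability of responding at random regardless of the stimulus;
    ``side_bias`` shifts the probability of a 'high' response.
    """

    subject_id: str
    species: str
    accuracy: Mapping[str, float]
    lapse_rate: float = 0.0
    side_bias: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for cond, p in self.accuracy.items():
            if not 0.0 <= float(p) <= 1.0:
                raise ValueError(f"accuracy for {cond!r} outside [0, 1]")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate outside [0, 1]")
        if not -0.5 <= self.side_bias <= 0.5:
            raise ValueError("side_bias outside [-0.5, 0.5]")


@dataclass(frozen=True)
class SessionDesign:
    """Trial-schedule statistics of the task."""

    n_sessions: int = 20
    trials_per_session_mean: float = 94.0
    trials_per_session_sd: float = 24.0
    probe_fraction: float = 0.2
    probe_conditions: Sequence[ProbeCondition] = PROBE_CONDITIONS
    error_correction: bool = True
    reference_hz: float = 707.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probe_fraction <= 1.0:
            raise ValueError("probe_fraction outside [0, 1]")
        if self.n_sessions < 1:
            raise ValueError("need at least one session")


def _condition_key(cond) -> str:
    return cond.value if isinstance(cond, ProbeCondition) else str(cond)


def generate_trials(obs: ObserverParams, design: SessionDesign) -> pd.DataFrame:
    """Simulate every trial of one observer.

    Per session the trial count is drawn from a normal distribution
    (truncated at 1).  Each trial is a standard trial with probability
    ``1 - probe_fraction``, otherwise one of the probe classes chosen
    uniformly.  The F0 class (low/high) is equiprobable.  The response is
    correct with the condition's accuracy, degraded by lapses and side bias.
    When ``design.error_correction`` is set, each incorrect standard response
    forces the next trial to repeat the same F0 class, flagged
    ``is_error_correction`` (itself eligible to trigger another repeat).
    Fully reproducible from ``obs.rng_seed``.
    """
    rng = np.random.default_rng(obs.rng_seed)
    acc = {_condition_key(k): float(v) for k, v in obs.accuracy.items()}
    std_key = ProbeCondition.STANDARD.value
    if std_key not in acc:
        raise ValueError("accuracy must include the 'standard' condition")
    probe_keys = [_condition_key(c) for c in design.probe_conditions]
    for k in probe_keys:
        if k not in acc:
            raise ValueError(f"accuracy missing probe condition {k!r}")

    rows = []
    for session in range(design.n_sessions):
        n_trials = max(1, int(round(rng.normal(design.trials_per_session_mean,
                                               design.trials_per_session_sd))))
        pending_ec: str | None = None  # f0_class to repeat
        for i in range(n_trials):
            if pending_ec is not None:
                cond, f0_class, is_ec = std_key, pending_ec, True
            else:
                if rng.random() < design.probe_fraction:
                    cond = probe_keys[rng.integers(len(probe_keys))]
                else:
                    cond = std_key
                f0_class = "high" if rng.random() < 0.5 else "low"
                is_ec = False
            p_correct = (1.0 - obs.lapse_rate) * acc[cond] + 0.5 * obs.lapse_rate
            p_high = p_correct if f0_class == "high" else 1.0 - p_correct
            p_high = min(1.0, max(0.0, p_high + obs.side_bias))
            response = "high" if rng.random() < p_high else "low"
            correct = response == f0_class
            rows.append((obs.subject_id, obs.species, session, i,
                         design.reference_hz, cond, f0_class, response,
                         correct, cond != std_key, is_ec))
            is_standard = cond == std_key
            pending_ec = (f0_class if design.error_correction and is_standard
                          and not correct else None)
    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS)


def recover_params(trials: pd.DataFrame) -> dict[str, float]:
    """Per-condition accuracy estimates from a (filtered) trial table.

    The generator/analyzer consistency loop: percent correct per condition
    divided by 100.  Conditions with no trials are omitted.
    """
    perf = percent_correct(trials, ["condition"])
    return {row.condition: row.percent_correct / 100.0
            for row in perf.itertuples()}
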