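"""End-to-end convenience layer: preprocess -> fragment -> select ->
features -> train/classify, plus a synthetic benchmark runner.

This module wires the per-stage operations into the canonical flow so that
scripts, the CLI and the evaluation suite all exercise the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classifier import MetricsReport, VADModel, classify_vad, evaluate, train_vad_model
from .exceptions import PreconditionError
from .features import (
    ChannelSelection,
    compute_band_powers,
    feature_matrix,
    reference_power,
    select_channels,
)
from .fragmentation import FragmentConfig, fragment_trialset
from .io import Trial, TrialSet
from .preprocessing import DEFAULT_BANDS, Band, car_array, highpass_array
from .rnn import LMConfig
from .synthetic import SyntheticConfig, default_effect_map, simulate_subject

__all__ = [
    "preprocess_trialset",
    "SubjectModel",
    "fit_subject",
    "predict_subject",
    "split_trials",
    "run_synthetic_benchmark",
]


def preprocess_trialset(
    ts: TrialSet, highpass_cutoff: float = 1.0
) -> TrialSet:
    """High-pass filter then common-average-reference every trial."""
    trials = []
    for t in ts.trials:
        data = highpass_array(t.data, ts.fs, highpass_cutoff)
        data = car_array(data)
        trials.append(replace(t, data=data))
    return TrialSet(trials, ts.fs, ts.channel_labels)


@dataclass
class SubjectModel:
    """Everything learned for one subject: electrode selection, reference
    powers and the six trained classifiers."""

    selection: ChannelSelection
    reference: np.ndarray  # (n_channels, n_bands)
    model: VADModel
    bands: tuple[Band, ...] = DEFAULT_BANDS


def split_trials(ts: TrialSet, test_fraction: float = 0.25, seed: int = 0):
    """Per-state trial-level train/test split (fragments of one trial never
    straddle the split)."""
    rng = np.random.default_rng(seed)
    train_trials: list[Trial] = []
    test_trials: list[Trial] = []
    for state, trials in sorted(ts.by_state().items(), key=lambda kv: str(kv[0])):
        idx = rng.permutation(len(trials))
        n_test = max(1, int(round(test_fraction * len(trials))))
        test_idx = set(idx[:n_test].tolist())
        for i, t in enumerate(trials):
            (test_trials if i in test_idx else train_trials).append(t)
    return (
        TrialSet(train_trials, ts.fs, ts.channel_labels),
        TrialSet(test_trials, ts.fs, ts.channel_labels),
    )


def fit_subject(
    train_fragments: TrialSet,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    alpha: float = 0.05,
    n_hidden: int = 80,
    lm_config: LMConfig = LMConfig(),
    seed: int = 0,
    subject_id: str = "",
) -> SubjectModel:
    """Select electrodes, derive reference powers and train the classifiers
    on (already preprocessed and fragmented) training fragments."""
    table = compute_band_powers(train_fragments, bands)
    selection = select_channels(
        train_fragments, bands, alpha=alpha, subject_id=subject_id, table=table
    )
    reference = reference_power(table)
    F = feature_matrix(train_fragments, selection, reference, bands)
    states = [t.state for t in train_fragments.trials]
    model, _ = train_vad_model(
        F, states, n_hidden=n_hidden, config=lm_config, seed=seed
    )
    return SubjectModel(selection, reference, model, bands)


def predict_subject(sm: SubjectModel, fragments: TrialSet):
    """Classify fragments with a fitted subject model -> list[VADDecision]."""
    F = feature_matrix(fragments, sm.selection, sm.reference, sm.bands)
    return classify_vad(F, sm.model)


def run_synthetic_benchmark(
    effect: float = 0.6,
    seed: int = 0,
    n_trials_per_state: int = 80,
    n_reference_trials: int = 96,
    trial_length_s: float = 12.0,
    n_hidden: int = 80,
    alpha: float = 0.05,
    fragment_cfg: FragmentConfig = FragmentConfig(),
    lm_config: LMConfig = LMConfig(),
    test_fraction: float = 0.25,
) -> tuple[MetricsReport, SubjectModel]:
    """Full pipeline on one synthetic subject; returns held-out metrics.

    Generates a subject with the default signature effect map at ratio
    ``effect``, splits trials per state, preprocesses and fragments both
    halves, fits selection + classifiers on the training half and evaluates
    on the held-out half.
    """
    if n_trials_per_state < 2:
        raise PreconditionError("need at least 2 trials per state to split")
    cfg = SyntheticConfig(
        effect_map=default_effect_map(effect),
        n_trials_per_state=n_trials_per_state,
        n_reference_trials=n_reference_trials,
        trial_length_s=trial_length_s,
        seed=seed,
    )
    ts, _ = simulate_subject(cfg)
    train_ts, test_ts = split_trials(ts, test_fraction=test_fraction, seed=seed)
    train_fr = fragment_trialset(preprocess_trialset(train_ts), fragment_cfg)
    test_fr = fragment_trialset(preprocess_trialset(test_ts), fragment_cfg)
    sm = fit_subject(
        train_fr, alpha=alpha, n_hidden=n_hidden, lm_config=lm_config,
        seed=seed, subject_id=cfg.subject_id,
    )
    preds = predict_subject(sm, test_fr)
    truth = [t.state for t in test_fr.trials]
    report = evaluate(preds, truth)
    return report, sm
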