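"""Synthetic EEG subjects and sessions with planted, emotion-dependent
band-power effects.

Each trial is a sum of one band-limited oscillation per frequency band plus
white Gaussian noise, per channel::

    x_c(t) = sum_b A_b * sin(2*pi*f_b,c * t + phi_b,c) + noise

with ``f_b,c`` drawn uniformly inside band ``b`` and phase drawn fresh for
every (trial, band, channel) — independent draws per channel keep the
oscillations from cancelling under common average referencing.  Amplitudes
carry log-normal trial-to-trial jitter (normalized so the expected squared
gain is 1), emulating the band-power variability of real EEG.  For a trial
of emotional state ``s``, every designated (channel, band) pair of the
effect map has its oscillation amplitude scaled by ``sqrt(1 + e)``, so the
expected band-power ratio against the (unscaled) neutral reference trials
is ``1 + e`` — the ground-truth ERD/ERS is analytic.  Reference trials are
neutral and unscaled.

The montage defaults to the 32-electrode 10-20 layout of the DEAP benchmark
at 128 Hz.  Generation is deterministic given the seed: every trial draws
from its own counter-derived substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .exceptions import RangeError, SchemaError
from .io import (
    EmotionalState,
    Event,
    EventLog,
    NEUTRAL_STATE,
    Recording,
    Trial,
    TrialSet,
    corner_states,
)
from .preprocessing import Band, DEFAULT_BANDS

__all__ = [
    "DEAP_CHANNELS",
    "SyntheticConfig",
    "default_effect_map",
    "simulate_subject",
    "simulate_session",
]

# 32-electrode montage in DEAP order
DEAP_CHANNELS = [
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
]

# per-band oscillation amplitudes, µV (roughly EEG-like: alpha dominant)
_DEFAULT_AMPLITUDES = {"theta": 8.0, "alpha": 10.0, "beta": 6.0, "gamma": 4.0}

# signature electrode pairs marking each (dimension, level); a corner state
# carries the union of its three signatures
_SIGNATURES: dict[tuple[str, str], list[tuple[str, str]]] = {
    ("valence", "upper"): [("F3", "alpha"), ("F4", "alpha")],
    ("valence", "lower"): [("F7", "beta"), ("F8", "beta")],
    ("arousal", "upper"): [("C3", "beta"), ("C4", "beta")],
    ("arousal", "lower"): [("P3", "alpha"), ("P4", "alpha")],
    ("dominance", "upper"): [("T7", "gamma"), ("T8", "gamma")],
    ("dominance", "lower"): [("O1", "theta"), ("O2", "theta")],
}


def default_effect_map(
    e: float,
    dimensions: Sequence[str] = ("valence", "arousal", "dominance"),
) -> dict[tuple[EmotionalState, str, str], float]:
    """Effect map planting ratio ``e`` on the signature electrodes.

    Every (dimension, level) combination owns two homologous electrodes in
    one band; each of the 8 corner states raises the band power of the
    union of its levels' signatures by the factor ``1 + e``.  Restricting
    ``dimensions`` shrinks the designated set (e.g. valence + arousal only:
    8 designated pairs).

    Returns a map (state, band_name, channel) -> e.
    """
    out: dict[tuple[EmotionalState, str, str], float] = {}
    for state in corner_states():
        for dim in dimensions:
            for chan, band in _SIGNATURES[(dim, state.level(dim))]:
                out[(state, band, chan)] = e
    return out


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic subject generator."""

    n_channels: int = 32
    fs: float = 128.0
    trial_length_s: float = 60.0
    n_trials_per_state: int = 40
    n_reference_trials: int = 40
    effect_map: Mapping[tuple[EmotionalState, str, str], float] = field(default_factory=dict)
    noise_sd: float = 1.0  # µV, white
    pink_noise_sd: float = 0.0  # µV, optional 1/f background (off by default)
    amplitude_jitter_sd: float = 0.1  # log-normal sigma of per-trial amplitude gain
    amplitudes: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_AMPLITUDES))
    bands: tuple[Band, ...] = DEFAULT_BANDS
    seed: int = 0
    subject_id: str = "synthetic"

    def __post_init__(self):
        if self.n_reference_trials < 5:
            raise RangeError("need at least 5 reference trials")
        for (state, band, chan), e in self.effect_map.items():
            if e <= -1:
                raise RangeError(f"effect {e} on ({state}, {band}, {chan}) must be > -1")
        if self.n_channels > len(DEAP_CHANNELS):
            raise SchemaError(f"at most {len(DEAP_CHANNELS)} channels available")

    @property
    def channel_labels(self) -> list[str]:
        return DEAP_CHANNELS[: self.n_channels]

    @property
    def states(self) -> list[EmotionalState]:
        planted = {s for (s, _, _) in self.effect_map}
        return sorted(planted, key=str) if planted else corner_states()


def _pink_noise(rng: np.random.Generator, shape, fs: float) -> np.ndarray:
    """1/f-amplitude noise, unit variance, via spectral shaping."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _one_trial(
    cfg: SyntheticConfig, state: EmotionalState, trial_counter: int
) -> np.ndarray:
    rng = np.random.default_rng([cfg.seed % (2 ** 31), trial_counter])
    n = int(round(cfg.trial_length_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    labels = cfg.channel_labels
    data = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_channels, n))
    if cfg.pink_noise_sd > 0:
        data += cfg.pink_noise_sd * _pink_noise(rng, (cfg.n_channels, n), cfg.fs)
    for band in cfg.bands:
        amp = cfg.amplitudes.get(band.name, 0.0)
        if amp == 0.0:
            continue
        freqs = rng.uniform(band.f_lo, band.f_hi, size=cfg.n_channels)
        phases = rng.uniform(0.0, 2 * np.pi, size=cfg.n_channels)
        # trial-to-trial band-power variability: log-normal amplitude gain
        # normalized so E[gain²] == 1 (planted power ratios stay exact)
        sj = cfg.amplitude_jitter_sd
        if sj > 0:
            gains = np.exp(sj * rng.standard_normal(cfg.n_channels) - sj ** 2)
        else:
            gains = np.ones(cfg.n_channels)
        for c, chan in enumerate(labels):
            e = cfg.effect_map.get((state, band.name, chan))
            if e is not None:
                gains[c] *= np.sqrt(1.0 + e)
        data += (amp * gains)[:, None] * np.sin(
            2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
        )
    return data


def simulate_subject(cfg: SyntheticConfig) -> tuple[TrialSet, dict]:
    """Generate one subject's labelled trials plus the ground truth.

    Emits ``n_trials_per_state`` trials for every state appearing in the
    effect map (all eight corner states when the map is empty) and
    ``n_reference_trials`` neutral reference trials, in a fixed order that
    is bit-reproducible given ``cfg.seed``.

    Returns
    -------
    (TrialSet, dict)
        The trials, and ground truth with keys ``effect_map`` and
        ``designated`` (the set of planted (channel, band_name) pairs).
    """
    trials: list[Trial] = []
    counter = 0
    for _ in range(cfg.n_reference_trials):
        trials.append(
            Trial(_one_trial(cfg, NEUTRAL_STATE, counter), NEUTRAL_STATE, is_reference=True)
        )
        counter += 1
    for state in cfg.states:
        for _ in range(cfg.n_trials_per_state):
            trials.append(Trial(_one_trial(cfg, state, counter), state))
            counter += 1
    ground_truth = {
        "effect_map": dict(cfg.effect_map),
        "designated": {(chan, band) for (_, band, chan) in cfg.effect_map},
    }
    return TrialSet(trials, cfg.fs, cfg.channel_labels), ground_truth


_LETTERS = "ABCDEFGHJKLMNPQRSTUVWYZ"  # X handled separately


def simulate_session(
    cfg: SyntheticConfig,
    tasks: Sequence[tuple[str, float]],
    cpt: tuple[int, float, Callable[[np.random.Generator], float] | float],
    task_states: Mapping[str, EmotionalState] | None = None,
    cpt_isi_s: float = 1.5,
) -> tuple[Recording, EventLog]:
    """Generate a continuous usability-session recording with its event log.

    The session opens with a continuous-performance-test (CPT) prologue of
    ``n_stimuli`` characters at ``cpt_isi_s`` spacing — each is 'X' with
    probability ``p_X``; every non-X stimulus gets a keypress at stimulus
    time plus a sampled reaction time, X stimuli get none — followed by the
    tasks back to back, each emitting ``task_start``/``task_end`` markers.
    EEG during the CPT prologue is neutral; each task's segment carries the
    state assigned by ``task_states`` (neutral by default).

    ``cpt = (n_stimuli, p_X, rt)`` where ``rt`` is a constant reaction time
    in seconds or a callable drawing one from an rng.
    """
    n_stimuli, p_x, rt_dist = cpt
    for _, dur in tasks:
        if dur <= 0:
            raise RangeError("task durations must be positive")
    rng = np.random.default_rng([cfg.seed % (2 ** 31), 999_983])
    draw_rt = rt_dist if callable(rt_dist) else (lambda _rng: float(rt_dist))

    events: list[Event] = []
    cpt_len = n_stimuli * cpt_isi_s
    for i in range(n_stimuli):
        t0 = i * cpt_isi_s
        is_x = rng.uniform() < p_x
        char = "X" if is_x else _LETTERS[int(rng.integers(len(_LETTERS)))]
        events.append(Event(t0, "cpt_stimulus", char))
        if not is_x:
            rt = draw_rt(rng)
            if rt <= 0 or rt >= cpt_isi_s:
                raise RangeError("reaction time must fall before the next stimulus")
            events.append(Event(t0 + rt, "cpt_keypress", "space"))

    seg_cfg = SyntheticConfig(**{**cfg.__dict__, "trial_length_s": cpt_len})
    pieces = [_one_trial(seg_cfg, NEUTRAL_STATE, 0)]
    t_cursor = cpt_len
    for k, (task_id, dur) in enumerate(tasks):
        state = (task_states or {}).get(task_id, NEUTRAL_STATE)
        seg_cfg = SyntheticConfig(**{**cfg.__dict__, "trial_length_s": dur})
        pieces.append(_one_trial(seg_cfg, state, k + 1))
        events.append(Event(t_cursor, "task_start", task_id))
        t_cursor += dur
        events.append(Event(t_cursor, "task_end", task_id))

    data = np.concatenate(pieces, axis=1)
    rec = Recording(data, cfg.fs, cfg.channel_labels, subject_id=cfg.subject_id)
    events.sort(key=lambda e: e.timestamp_s)
    return rec, EventLog(events)
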