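"""Overlapping-window trial fragmentation.

A trial of duration ``T`` seconds is split into ``N`` equal fragments of
window ``W`` seconds with overlap ratio ``O``::

    shift = (1 - O) * W
    N     = floor((T - W) / shift) + 1

A trailing partial window is discarded so all fragments are equal-sized.
Fragments inherit their trial's state label and reference flag.  The default
configuration is W = 12 s with 50% overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .exceptions import RangeError
from .io import Trial, TrialSet

__all__ = ["FragmentConfig", "count_fragments", "fragment_trial", "fragment_trialset"]


@dataclass(frozen=True)
class FragmentConfig:
    W: float = 12.0  # window length, seconds
    O: float = 0.5   # overlap ratio in [0, 1)

    def __post_init__(self):
        if self.W <= 0:
            raise RangeError("window length must be positive")
        if not (0 <= self.O < 1):
            raise RangeError("overlap ratio must lie in [0, 1)")

    @property
    def shift(self) -> float:
        """Hop between consecutive fragment starts, seconds."""
        return (1.0 - self.O) * self.W


def count_fragments(T: float, cfg: FragmentConfig = FragmentConfig()) -> int:
    """Number of full fragments in a trial of ``T`` seconds."""
    if T < cfg.W:
        raise RangeError(f"trial of {T} s shorter than window {cfg.W} s")
    # small epsilon absorbs float fuzz when (T - W) is an exact multiple of shift
    return int(math.floor((T - cfg.W) / cfg.shift + 1e-9)) + 1


def fragment_trial(trial: Trial, fs: float, cfg: FragmentConfig = FragmentConfig()) -> list[Trial]:
    """Cut one trial into overlapping fragments.

    Fragment ``i`` covers ``[i*shift, i*shift + W)`` seconds.  Sample indices
    are laid out so that consecutive fragments share exactly
    ``round(O * W * fs)`` samples.
    """
    n = trial.data.shape[-1]
    n_w = int(round(cfg.W * fs))
    if n < n_w:
        raise RangeError(f"trial of {n / fs} s shorter than window {cfg.W} s")
    n_shared = int(round(cfg.O * cfg.W * fs))
    n_shift = n_w - n_shared
    if n_shift <= 0:
        raise RangeError("overlap leaves a non-positive hop")
    out = []
    start = 0
    while start + n_w <= n:
        out.append(replace(trial, data=trial.data[..., start:start + n_w].copy()))
        start += n_shift
    return out


def fragment_trialset(ts: TrialSet, cfg: FragmentConfig = FragmentConfig()) -> TrialSet:
    """Fragment every trial of a set, concatenating in trial order."""
    frags: list[Trial] = []
    for t in ts.trials:
        frags.extend(fragment_trial(t, ts.fs, cfg))
    return TrialSet(frags, ts.fs, ts.channel_labels)
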