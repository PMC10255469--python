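"""ERD/ERS features and adaptive per-subject channel selection.

Event-related desynchronization/synchronization quantifies the relative band
power change of an active state against a neutral reference::

    ERD/ERS = (A - R) / R

where ``A`` is the active average band power of a fragment and ``R`` the
reference average power of the same channel and band, taken as the mean band
power over all reference (neutral) fragments of the subject.  Negative
values are desynchronization (power drop), positive values synchronization;
the ratio is bounded below by -1.

Channel selection is adaptive per subject: for each of the eight emotional
corner states, each band and each channel, the per-fragment active band
powers are compared against the subject's reference (neutral) fragment
powers with a two-sided Mann-Whitney rank-sum test, which holds its nominal
level exactly under the null.  (A Wilcoxon signed-rank variant testing
active powers against the reference mean is available as
``method='signed_rank'``; note its level degrades when the reference mean
is estimated from few fragments, since that estimation error shifts all of
a channel's tests coherently.)  A (channel, band) pair is selected if it is
significant (p < alpha) for at least one state — every chosen electrode has
activity in at least one emotional state.  No multiplicity correction is
applied; alpha defaults to 0.05.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import PreconditionError, RangeError, SchemaError, SelectionError
from .io import EmotionalState, Trial, TrialSet
from .preprocessing import Band, DEFAULT_BANDS, bandpass_fft

__all__ = [
    "band_power",
    "erd_ers",
    "BandPowerTable",
    "compute_band_powers",
    "reference_power",
    "ChannelSelection",
    "select_channels",
    "build_features",
    "feature_matrix",
    "asymmetry_pairs",
    "asymmetry_features",
]


def band_power(
    data: np.ndarray,
    fs: float,
    band: Band,
    *,
    band_limited: bool = False,
) -> np.ndarray:
    """Mean squared amplitude per channel within a band, in µV².

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Fragment signal.  Band extraction is applied internally unless the
        input is already band-limited (``band_limited=True``).
    fs : float
        Sampling rate in Hz.
    band : Band
        Frequency band of interest.

    Returns
    -------
    ndarray, shape (n_channels,)
        For a pure in-band sine of amplitude ``A`` this is ``A**2 / 2``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[-1] == 0:
        raise RangeError("empty fragment")
    if not band_limited:
        data = bandpass_fft(data, fs, band)
    return np.mean(data ** 2, axis=-1)


def erd_ers(A, R):
    """Relative band-power change ``(A - R) / R`` of active vs reference.

    ``A`` and ``R`` may be scalars or broadcastable arrays; every reference
    power must be strictly positive.
    """
    A = np.asarray(A, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise RangeError("reference power must be strictly positive")
    out = (A - R) / R
    return float(out) if out.ndim == 0 else out


@dataclass
class BandPowerTable:
    """Band power per fragment, channel and band, with axis labels."""

    values: np.ndarray  # (n_fragments, n_channels, n_bands), µV²
    states: list[EmotionalState]
    is_reference: np.ndarray  # (n_fragments,) bool
    channel_labels: list[str]
    bands: tuple[Band, ...]

    def __post_init__(self):
        if np.any(self.values < 0):
            raise SchemaError("band powers must be non-negative")


def compute_band_powers(
    fragments: TrialSet, bands: tuple[Band, ...] = DEFAULT_BANDS
) -> BandPowerTable:
    """Tabulate band power for every fragment of a set."""
    n_f = len(fragments)
    n_ch = fragments.n_channels
    values = np.empty((n_f, n_ch, len(bands)))
    for i, trial in enumerate(fragments.trials):
        for j, band in enumerate(bands):
            values[i, :, j] = band_power(trial.data, fragments.fs, band)
    return BandPowerTable(
        values=values,
        states=[t.state for t in fragments.trials],
        is_reference=np.array([t.is_reference for t in fragments.trials]),
        channel_labels=list(fragments.channel_labels),
        bands=bands,
    )


def reference_power(table: BandPowerTable) -> np.ndarray:
    """Reference average power R per (channel, band): the mean band power
    over all reference fragments."""
    if not table.is_reference.any():
        raise PreconditionError("no reference fragments available")
    return table.values[table.is_reference].mean(axis=0)


@dataclass
class ChannelSelection:
    """Per-subject map of significant electrodes.

    ``selected`` maps each band name to the set of channel labels significant
    in that band for at least one emotional state.  ``tests`` holds every
    (state, band, channel) Wilcoxon decision with its statistic and p-value.
    ``index`` fixes the feature-vector ordering: selected (channel, band)
    pairs sorted by band position then channel position.
    """

    subject_id: str
    selected: dict[str, set[str]]
    tests: pd.DataFrame
    alpha: float
    channel_labels: list[str] = field(default_factory=list)
    band_names: list[str] = field(default_factory=list)

    @property
    def index(self) -> list[tuple[str, str]]:
        pairs = []
        for b in self.band_names:
            chans = self.selected.get(b, set())
            for c in self.channel_labels:
                if c in chans:
                    pairs.append((c, b))
        return pairs

    def __len__(self) -> int:
        return sum(len(v) for v in self.selected.values())

    def to_json(self, path=None) -> str:
        obj = {
            "subject_id": self.subject_id,
            "alpha": self.alpha,
            "channel_labels": self.channel_labels,
            "band_names": self.band_names,
            "selected": {b: sorted(v) for b, v in self.selected.items()},
            "tests": self.tests.to_dict(orient="list"),
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ChannelSelection":
        if hasattr(source, "read"):
            obj = json.load(source)
        else:
            try:
                obj = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    obj = json.load(fh)
        return cls(
            subject_id=obj["subject_id"],
            selected={b: set(v) for b, v in obj["selected"].items()},
            tests=pd.DataFrame(obj["tests"]),
            alpha=obj["alpha"],
            channel_labels=obj["channel_labels"],
            band_names=obj["band_names"],
        )


_MIN_FRAGMENTS = 5


def select_channels(
    fragments: TrialSet,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    alpha: float = 0.05,
    subject_id: str = "",
    table: BandPowerTable | None = None,
    method: str = "ranksum",
) -> ChannelSelection:
    """Adaptively select significant electrodes for one subject.

    For every (state, band, channel) triple the per-fragment active band
    powers are tested against the subject's reference fragment powers; the
    pair is selected if significant for at least one state.

    Parameters
    ----------
    fragments : TrialSet
        All fragments of one subject, including at least 5 reference
        fragments and at least 5 fragments per tested state.
    alpha : float
        Per-test significance level (no multiplicity correction).
    table : BandPowerTable, optional
        Precomputed band powers for ``fragments`` (avoids recomputation).
    method : {'ranksum', 'signed_rank'}
        ``ranksum``: Mann-Whitney between active and reference fragment
        powers (default, exact level).  ``signed_rank``: Wilcoxon
        signed-rank of active powers minus the reference mean power.

    Raises
    ------
    PreconditionError
        If reference or per-state fragment counts fall below 5.
    SelectionError
        If no (channel, band) pair reaches significance; the caller may
        relax ``alpha``.
    """
    if method not in ("ranksum", "signed_rank"):
        raise SchemaError("method must be 'ranksum' or 'signed_rank'")
    if table is None:
        table = compute_band_powers(fragments, bands)
    ref_mask = table.is_reference
    if ref_mask.sum() < _MIN_FRAGMENTS:
        raise PreconditionError(
            f"need >= {_MIN_FRAGMENTS} reference fragments, got {int(ref_mask.sum())}"
        )
    R = table.values[ref_mask].mean(axis=0)  # (n_ch, n_band)

    states = sorted(
        {s for s, r in zip(table.states, ref_mask) if not r}, key=str
    )
    rows = []
    state_arr = np.array([str(s) for s in table.states])
    for state in states:
        mask = (state_arr == str(state)) & ~ref_mask
        n_active = int(mask.sum())
        if n_active < _MIN_FRAGMENTS:
            raise PreconditionError(
                f"state {state} has {n_active} fragments; need >= {_MIN_FRAGMENTS}"
            )
        active = table.values[mask]  # (n_active, n_ch, n_band)
        ref_vals = table.values[ref_mask]
        for j, band in enumerate(bands):
            for c, chan in enumerate(table.channel_labels):
                if method == "ranksum":
                    res = stats.mannwhitneyu(
                        active[:, c, j], ref_vals[:, c, j], alternative="two-sided"
                    )
                    stat, p = float(res.statistic), float(res.pvalue)
                else:
                    diffs = active[:, c, j] - R[c, j]
                    if np.allclose(diffs, 0):
                        stat, p = 0.0, 1.0
                    else:
                        res = stats.wilcoxon(diffs, alternative="two-sided")
                        stat, p = float(res.statistic), float(res.pvalue)
                rows.append(
                    {
                        "state": str(state),
                        "band": band.name,
                        "channel": chan,
                        "statistic": stat,
                        "pvalue": p,
                        "significant": bool(p < alpha or alpha >= 1.0),
                    }
                )
    tests = pd.DataFrame(rows)
    selected: dict[str, set[str]] = {b.name: set() for b in bands}
    for _, row in tests[tests["significant"]].iterrows():
        selected[row["band"]].add(row["channel"])

    sel = ChannelSelection(
        subject_id=subject_id,
        selected=selected,
        tests=tests,
        alpha=alpha,
        channel_labels=list(table.channel_labels),
        band_names=[b.name for b in bands],
    )
    if len(sel) == 0:
        raise SelectionError(
            "no channel reached significance; consider relaxing alpha"
        )
    return sel


def build_features(
    fragment: Trial | np.ndarray,
    selection: ChannelSelection,
    reference: np.ndarray | Mapping[tuple[str, str], float],
    fs: float,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
) -> np.ndarray:
    """ERD/ERS feature vector of one fragment, in ``selection.index`` order.

    ``reference`` is either the (n_channels, n_bands) array returned by
    :func:`reference_power` or a mapping (channel, band_name) -> R.
    """
    data = fragment.data if isinstance(fragment, Trial) else np.asarray(fragment)
    index = selection.index
    if not index:
        raise PreconditionError("empty channel selection")
    band_map = {b.name: b for b in bands}
    ch_pos = {c: i for i, c in enumerate(selection.channel_labels)}
    band_pos = {b: j for j, b in enumerate(selection.band_names)}

    # one band extraction per band actually used
    powers: dict[str, np.ndarray] = {}
    for _, bname in index:
        if bname not in powers:
            if bname not in band_map:
                raise SchemaError(f"band {bname!r} not configured")
            powers[bname] = band_power(data, fs, band_map[bname])

    out = np.empty(len(index))
    for k, (chan, bname) in enumerate(index):
        if chan not in ch_pos:
            raise SchemaError(f"fragment lacks channel {chan!r}")
        A = powers[bname][ch_pos[chan]]
        if isinstance(reference, Mapping):
            R = reference[(chan, bname)]
        else:
            R = reference[ch_pos[chan], band_pos[bname]]
        out[k] = erd_ers(A, R)
    return out


def feature_matrix(
    fragments: TrialSet,
    selection: ChannelSelection,
    reference: np.ndarray,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
) -> np.ndarray:
    """Stack :func:`build_features` over a fragment set -> (n_fragments, n_features)."""
    return np.stack(
        [build_features(t, selection, reference, fragments.fs, bands) for t in fragments.trials]
    )


# -- optional asymmetry feature mode ----------------------------------------

_HOMOLOGOUS = [
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F3", "F4"), ("F7", "F8"),
    ("FC1", "FC2"), ("FC5", "FC6"), ("C3", "C4"), ("T7", "T8"),
    ("CP1", "CP2"), ("CP5", "CP6"), ("P3", "P4"), ("P7", "P8"),
    ("PO3", "PO4"), ("O1", "O2"),
]


def asymmetry_pairs(channel_labels: Sequence[str]) -> list[tuple[str, str]]:
    """Left-right homologous electrode pairs present in a montage."""
    present = set(channel_labels)
    return [(l, r) for l, r in _HOMOLOGOUS if l in present and r in present]


def asymmetry_features(
    fragment: Trial | np.ndarray,
    channel_labels: Sequence[str],
    fs: float,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
) -> np.ndarray:
    """Alternative feature mode: per-band power difference (left - right)
    between homologous electrode pairs, flattened pair-major."""
    data = fragment.data if isinstance(fragment, Trial) else np.asarray(fragment)
    pos = {c: i for i, c in enumerate(channel_labels)}
    pairs = asymmetry_pairs(channel_labels)
    if not pairs:
        raise PreconditionError("montage has no homologous pairs")
    powers = [band_power(data, fs, band) for band in bands]
    out = np.empty(len(pairs) * len(bands))
    k = 0
    for l, r in pairs:
        for p in powers:
            out[k] = p[pos[l]] - p[pos[r]]
            k += 1
    return out
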