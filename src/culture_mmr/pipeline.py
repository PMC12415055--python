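"""From raw traces or spike tables to stimulus-aligned rasters and PSTHs.

Preprocessing follows the conventions of extracellular MEA work: a
zero-phase 300–3,000 Hz bandpass, negative threshold crossings at
``k`` times the robust (MAD-based) noise SD with a refractory period,
exclusion of the 1 ms post-stimulus artifact window, and 1 ms-binned
peri-stimulus time histograms.  Channels (electrode threshold crossings)
are the unit of analysis throughout; no spike sorting is attempted.

PSTH rates are normalised per trial per millisecond, so window means are
directly comparable across conditions with different trial counts and read
as "spikes per ms".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .grid import ElectrodeId
from .paradigms import StimulusSequence
from .simulate import SPIKE_COLUMNS, RawRecording


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass specification for the action-potential band."""

    low_hz: float = 300.0
    high_hz: float = 3000.0
    order: int = 2

    def validate(self, sample_rate_hz: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= sample_rate_hz / 2:
            raise ValueError(
                f"high_hz={self.high_hz} at or above Nyquist "
                f"({sample_rate_hz / 2})"
            )


@dataclass(frozen=True)
class DetectionParams:
    """Threshold-crossing detector settings.

    ``threshold_k`` multiplies the robust per-channel noise SD
    (median absolute deviation / 0.6745); detection is on *negative*
    crossings.  ``artifact_blank_ms`` is the post-stimulus exclusion
    window.
    """

    threshold_k: float = 5.0
    refractory_ms: float = 1.0
    artifact_blank_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be > 0")
        if self.artifact_blank_ms < 0 or self.refractory_ms < 0:
            raise ValueError("durations must be >= 0")


@dataclass
class PSTH:
    """Binned firing rate aligned to stimulus onset.

    ``rate`` holds spikes per ms per trial (per channel if
    ``n_channels == 1``, channel-averaged otherwise) for bins of width
    ``bin_ms`` covering ``window_ms = (start, end)``.
    """

    rate: np.ndarray
    bin_ms: float
    window_ms: Tuple[float, float]
    n_trials: int
    condition: str
    n_channels: int = 1

    def __post_init__(self) -> None:
        span = self.window_ms[1] - self.window_ms[0]
        n = span / self.bin_ms
        if abs(n - round(n)) > 1e-9:
            raise ValueError("bin_ms must divide the window length")
        if len(self.rate) != int(round(n)):
            raise ValueError("rate length does not match window/bin_ms")

    @property
    def bin_starts(self) -> np.ndarray:
        return self.window_ms[0] + np.arange(len(self.rate)) * self.bin_ms


@dataclass
class Raster:
    """Per-trial, per-channel spike times relative to stimulus onset.

    ``spikes`` columns: ``condition, trial, col, row, t_ms``; ``trial`` is
    the 0-based within-condition event index.  ``n_trials`` maps each
    condition to its event count (zero-spike trials still count).
    """

    spikes: pd.DataFrame
    n_trials: Dict[str, int]
    window_ms: Tuple[float, float]
    channels: list


def bandpass_filter(raw: RawRecording, spec: FilterSpec = FilterSpec()) -> RawRecording:
    """Zero-phase (forward–backward) Butterworth bandpass; removes DC."""
    spec.validate(raw.sample_rate_hz)
    sos = signal.butter(
        spec.order,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=raw.sample_rate_hz,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, raw.traces, axis=1)
    return RawRecording(
        traces=filtered.astype(np.float32),
        channels=list(raw.channels),
        sample_rate_hz=raw.sample_rate_hz,
        onsets_s=raw.onsets_s,
    )


def robust_noise_sd(trace: np.ndarray) -> float:
    """MAD-based noise SD estimate (Gaussian-consistent)."""
    return float(np.median(np.abs(trace - np.median(trace))) / 0.6745)


def detect_spikes(
    filtered: RawRecording, params: DetectionParams = DetectionParams()
) -> pd.DataFrame:
    """Negative threshold-crossing detection with refractory suppression.

    A spike is logged at each downward crossing of ``-k * sigma_robust``;
    crossings within the refractory period of the last accepted spike are
    suppressed.  Timestamps are crossing sample / sample rate.
    """
    fs = filtered.sample_rate_hz
    refr = params.refractory_ms / 1000.0
    cols, rows, times = [], [], []
    for (c, r), trace in zip(filtered.channels, filtered.traces):
        thr = -params.threshold_k * robust_noise_sd(trace)
        below = trace < thr
        crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
        t = crossings / fs
        if refr > 0 and len(t) > 1:
            keep = [0]
            for i in range(1, len(t)):
                if t[i] - t[keep[-1]] >= refr:
                    keep.append(i)
            t = t[keep]
        cols.append(np.full(len(t), c))
        rows.append(np.full(len(t), r))
        times.append(t)
    return pd.DataFrame(
        {
            "col": np.concatenate(cols).astype(int) if cols else [],
            "row": np.concatenate(rows).astype(int) if rows else [],
            "time_s": np.concatenate(times) if times else [],
        }
    )


def blank_artifact(
    spikes: pd.DataFrame, sequence: StimulusSequence, blank_ms: float = 1.0
) -> pd.DataFrame:
    """Drop spikes in the ``(onset, onset + blank_ms]`` window of every
    physical event.  Omitted events blank nothing, so omission responses
    remain measurable at their nominal onsets."""
    if blank_ms < 0:
        raise ValueError("blank_ms must be >= 0")
    if blank_ms == 0 or len(spikes) == 0:
        return spikes.reset_index(drop=True)
    ev = sequence.events
    onsets = np.sort(ev.loc[ev["physical"], "onset_s"].to_numpy())
    if len(onsets) == 0:
        return spikes.reset_index(drop=True)
    t = spikes["time_s"].to_numpy()
    idx = np.searchsorted(onsets, t, side="left") - 1
    idx = np.clip(idx, 0, len(onsets) - 1)
    rel = t - onsets[idx]
    drop = (rel > 0) & (rel <= blank_ms / 1000.0)
    return spikes.loc[~drop].reset_index(drop=True)


def build_raster(
    spikes: pd.DataFrame,
    sequence: StimulusSequence,
    window_ms: Tuple[float, float] = (-50.0, 150.0),
    channels: Optional[Sequence[ElectrodeId]] = None,
) -> Raster:
    """Re-reference spike times to stimulus onsets, grouped by role.

    ``channels`` should list every recorded channel (including silent
    ones); if omitted it is inferred from the spike table, which loses
    channels that never fired.
    """
    if window_ms[1] - window_ms[0] > sequence.isi_s * 1000.0:
        warnings.warn("analysis window longer than the ISI: trials overlap")
    if channels is None:
        channels = sorted(
            {(int(c), int(r)) for c, r in zip(spikes["col"], spikes["row"])}
        )
    ev = sequence.events.sort_values("onset_s")
    t = spikes["time_s"].to_numpy()
    order = np.argsort(t, kind="mergesort")
    t_sorted = t[order]
    col_s = spikes["col"].to_numpy()[order]
    row_s = spikes["row"].to_numpy()[order]

    out_cond, out_trial, out_col, out_row, out_t = [], [], [], [], []
    trial_idx: Dict[str, int] = {}
    n_trials: Dict[str, int] = {}
    w0, w1 = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    for onset, role in zip(ev["onset_s"], ev["role"]):
        k = trial_idx.get(role, 0)
        trial_idx[role] = k + 1
        n_trials[role] = k + 1
        a = np.searchsorted(t_sorted, onset + w0, side="left")
        b = np.searchsorted(t_sorted, onset + w1, side="right")
        if b > a:
            out_cond.append(np.full(b - a, role))
            out_trial.append(np.full(b - a, k))
            out_col.append(col_s[a:b])
            out_row.append(row_s[a:b])
            out_t.append((t_sorted[a:b] - onset) * 1000.0)
    df = pd.DataFrame(
        {
            "condition": np.concatenate(out_cond) if out_cond else [],
            "trial": np.concatenate(out_trial).astype(int) if out_trial else [],
            "col": np.concatenate(out_col).astype(int) if out_col else [],
            "row": np.concatenate(out_row).astype(int) if out_row else [],
            "t_ms": np.concatenate(out_t) if out_t else [],
        }
    )
    return Raster(
        spikes=df,
        n_trials=n_trials,
        window_ms=window_ms,
        channels=[tuple(c) for c in channels],
    )


def compute_psth(
    raster: Raster,
    condition: str,
    bin_ms: float = 1.0,
    channel: Optional[ElectrodeId] = None,
) -> PSTH:
    """Single-channel (or pooled) PSTH: count / (n_trials * bin_ms).

    With ``channel=None`` all spikes in the raster are pooled without
    channel normalisation — use :func:`population_psth_from_raster` for the
    channel-averaged population PSTH.
    """
    n_trials = raster.n_trials.get(condition, 0)
    if n_trials == 0:
        raise ValueError(f"no trials for condition {condition!r}")
    df = raster.spikes
    sel = df["condition"] == condition
    if channel is not None:
        sel &= (df["col"] == channel[0]) & (df["row"] == channel[1])
    t = df.loc[sel, "t_ms"].to_numpy()
    w0, w1 = raster.window_ms
    edges = np.arange(w0, w1 + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(t, bins=edges)
    rate = counts / (n_trials * bin_ms)
    return PSTH(
        rate=rate,
        bin_ms=bin_ms,
        window_ms=raster.window_ms,
        n_trials=n_trials,
        condition=condition,
    )


def population_psth(psths: Sequence[PSTH]) -> PSTH:
    """Unweighted mean across channel PSTHs with identical windows/bins."""
    if not psths:
        raise ValueError("empty PSTH list")
    first = psths[0]
    for p in psths[1:]:
        if p.window_ms != first.window_ms or p.bin_ms != first.bin_ms:
            raise ValueError("PSTHs have mismatched windows or bins")
    rate = np.mean([p.rate for p in psths], axis=0)
    return PSTH(
        rate=rate,
        bin_ms=first.bin_ms,
        window_ms=first.window_ms,
        n_trials=first.n_trials,
        condition=first.condition,
        n_channels=sum(p.n_channels for p in psths),
    )


def population_psth_from_raster(
    raster: Raster, condition: str, bin_ms: float = 1.0
) -> PSTH:
    """Channel-averaged population PSTH (spikes per ms per trial per
    channel).  Equals the mean of the per-channel PSTHs over
    ``raster.channels``."""
    pooled = compute_psth(raster, condition, bin_ms=bin_ms, channel=None)
    n_ch = len(raster.channels)
    if n_ch == 0:
        raise ValueError("raster has no channels")
    return PSTH(
        rate=pooled.rate / n_ch,
        bin_ms=bin_ms,
        window_ms=raster.window_ms,
        n_trials=pooled.n_trials,
        condition=condition,
        n_channels=n_ch,
    )
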