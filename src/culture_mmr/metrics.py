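"""Response metrics and adaptation/deviance indices.

Quantities computed here mirror standard oddball-paradigm analysis:

* windowed response amplitudes — the mean PSTH rate (spikes per ms) over
  the early (0–10 ms), late (11–150 ms) or any custom post-stimulus
  window;
* the SSA index ``SI(R) = (R - R_std) / (R + R_std)``, contrasting a test
  response (deviant or MSC) against the standard response — positive when
  the rare stimulus evokes more than the frequent one;
* the deviance-detection index
  ``DDI = (R_dev - R_MSC) / (R_dev + R_MSC)`` — positive values indicate
  deviance detection beyond rarity-driven adaptation, since the MSC
  matches the deviant's presentation rate without contextual deviance;
* peak latency and the 3-SD response-duration rule;
* latency-resolved index time courses in 10 ms bins;
* per-culture z-scoring, repetition dynamics and the best-group selection
  rule.

Window conventions: windows are half-open ``[start, end)`` over PSTH bin
*starts*, so with 1 ms bins the early window 0–10 ms covers bins 0..9 and
the late window 11–150 ms covers bins 11..149 (139 bins); the 10 ms bin
belongs to neither, avoiding double counting at the early/late boundary.
Indices with a zero denominator are undefined and returned as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .paradigms import StimulusSequence
from .pipeline import PSTH, Raster


@dataclass(frozen=True)
class ResponseWindows:
    """Early/late/baseline analysis windows in ms relative to onset."""

    early: Tuple[float, float] = (0.0, 10.0)
    late: Tuple[float, float] = (11.0, 150.0)
    baseline: Tuple[float, float] = (-50.0, 0.0)


DEFAULT_WINDOWS = ResponseWindows()


def window_amplitude(psth: PSTH, window: Tuple[float, float]) -> float:
    """Mean PSTH rate over bins whose start lies in ``[start, end)``."""
    starts = psth.bin_starts
    sel = (starts >= window[0] - 1e-9) & (starts < window[1] - 1e-9)
    if not sel.any():
        raise ValueError(f"window {window} contains no PSTH bins")
    return float(psth.rate[sel].mean())


def ssa_index(r: float, r_std: float) -> float:
    """SSA index (R - R_std) / (R + R_std); NaN when the denominator is 0."""
    denom = r + r_std
    if denom <= 0:
        return float("nan")
    return (r - r_std) / denom


def deviance_detection_index(r_dev: float, r_msc: float) -> float:
    """DDI (R_dev - R_MSC) / (R_dev + R_MSC); NaN when the denominator is 0."""
    denom = r_dev + r_msc
    if denom <= 0:
        return float("nan")
    return (r_dev - r_msc) / denom


@dataclass
class IndexResult:
    """SI and DDI with the amplitudes they derive from."""

    r_std: float
    r_dev: float
    r_msc: float
    si_dev: float
    si_msc: float
    ddi: float


def compute_indices(r_std: float, r_dev: float, r_msc: float) -> IndexResult:
    return IndexResult(
        r_std=r_std,
        r_dev=r_dev,
        r_msc=r_msc,
        si_dev=ssa_index(r_dev, r_std),
        si_msc=ssa_index(r_msc, r_std),
        ddi=deviance_detection_index(r_dev, r_msc),
    )


def peak_latency(psth: PSTH, window: Tuple[float, float]) -> float:
    """Start time (ms) of the maximal-rate bin in the window.

    Ties break to the earliest bin; an all-zero window is undefined (NaN).
    """
    starts = psth.bin_starts
    sel = (starts >= window[0] - 1e-9) & (starts < window[1] - 1e-9)
    if not sel.any():
        raise ValueError(f"window {window} contains no PSTH bins")
    rates = psth.rate[sel]
    if np.all(rates == 0):
        return float("nan")
    return float(starts[sel][int(np.argmax(rates))])


def response_duration(
    psth: PSTH,
    baseline_window: Tuple[float, float] = (-50.0, 0.0),
    mode: str = "total",
) -> float:
    """Post-stimulus time (ms) above baseline mean + 3 baseline SD.

    The threshold comes from the 50 ms pre-stimulus baseline (sample SD,
    n-1 denominator).  ``mode='total'`` counts every super-threshold
    post-stimulus bin; ``mode='contiguous'`` counts only the first
    contiguous super-threshold run.
    """
    starts = psth.bin_starts
    base = (starts >= baseline_window[0] - 1e-9) & (starts < baseline_window[1] - 1e-9)
    if not base.any():
        raise ValueError("PSTH does not include the baseline window")
    b = psth.rate[base]
    thr = b.mean() + 3.0 * (b.std(ddof=1) if len(b) > 1 else 0.0)
    post = starts >= -1e-9
    above = psth.rate[post] > thr
    if mode == "total":
        return float(above.sum() * psth.bin_ms)
    if mode == "contiguous":
        n = 0
        started = False
        for a in above:
            if a:
                n += 1
                started = True
            elif started:
                break
        return float(n * psth.bin_ms)
    raise ValueError(f"unknown mode {mode!r}")


def index_time_course(
    psths: Dict[str, PSTH],
    bin_width_ms: float = 10.0,
    span: Tuple[float, float] = (0.0, 150.0),
) -> pd.DataFrame:
    """SI and DDI per consecutive post-stimulus latency bin.

    ``psths`` maps condition names (``standard``, ``deviant``, ``msc``) to
    aligned PSTHs.  Returns one row per latency bin with columns
    ``bin_start_ms, bin_end_ms, si_dev, si_msc, ddi`` (NaN where
    undefined).
    """
    if len({(psths[c].bin_ms, psths[c].window_ms) for c in psths}) != 1:
        raise ValueError("condition PSTHs are not aligned")
    rows = []
    t0 = span[0]
    while t0 < span[1] - 1e-9:
        t1 = min(t0 + bin_width_ms, span[1])
        amp = {c: window_amplitude(psths[c], (t0, t1)) for c in psths}
        rows.append(
            {
                "bin_start_ms": t0,
                "bin_end_ms": t1,
                "si_dev": ssa_index(amp["deviant"], amp["standard"])
                if {"deviant", "standard"} <= set(amp)
                else float("nan"),
                "si_msc": ssa_index(amp["msc"], amp["standard"])
                if {"msc", "standard"} <= set(amp)
                else float("nan"),
                "ddi": deviance_detection_index(amp["deviant"], amp["msc"])
                if {"deviant", "msc"} <= set(amp)
                else float("nan"),
            }
        )
        t0 = t1
    return pd.DataFrame(rows)


def zscore_by_culture(
    table: pd.DataFrame,
    value_col: str = "value",
    culture_col: str = "culture",
) -> pd.DataFrame:
    """Normalise response values to z-scores within each culture.

    Pooling is joint across all of a culture's site-condition values
    (sample SD, n-1), which removes baseline firing differences between
    cultures while preserving within-culture condition contrasts.
    """
    out = table.copy()
    z = np.empty(len(out))
    for cid, idx in out.groupby(culture_col).groups.items():
        v = out.loc[idx, value_col].to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"culture {cid!r} has fewer than 2 values")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"culture {cid!r} has zero spread")
        z[out.index.get_indexer(idx)] = (v - v.mean()) / sd
    out["z"] = z
    return out


def trial_amplitudes(
    raster: Raster,
    condition: str,
    window: Tuple[float, float] = DEFAULT_WINDOWS.late,
) -> np.ndarray:
    """Per-trial channel-averaged window rate (spikes/ms) for a condition.

    Trials with no spikes contribute zeros; the divisor is the window
    length times the raster's channel count.
    """
    n_trials = raster.n_trials.get(condition, 0)
    if n_trials == 0:
        raise ValueError(f"no trials for condition {condition!r}")
    n_ch = max(len(raster.channels), 1)
    df = raster.spikes
    sel = (
        (df["condition"] == condition)
        & (df["t_ms"] >= window[0] - 1e-9)
        & (df["t_ms"] < window[1] - 1e-9)
    )
    counts = np.bincount(df.loc[sel, "trial"].to_numpy(), minlength=n_trials)
    return counts / ((window[1] - window[0]) * n_ch)


def repetition_dynamics(
    raster: Raster,
    sequence: StimulusSequence,
    window: Tuple[float, float] = DEFAULT_WINDOWS.late,
) -> pd.DataFrame:
    """First/first-half/second-half/last response amplitudes per condition.

    Halves split by within-condition event order; an odd trial count gives
    the extra trial to the first half.  Conditions with a single trial are
    flagged (halves NaN).
    """
    rows = []
    conditions = [c for c in sequence.events["role"].unique() if c in raster.n_trials]
    for cond in conditions:
        amps = trial_amplitudes(raster, cond, window)
        n = len(amps)
        half = (n + 1) // 2
        flagged = n < 2
        rows.append(
            {
                "condition": cond,
                "n_trials": n,
                "first": amps[0],
                "first_half": amps[:half].mean() if not flagged else float("nan"),
                "second_half": amps[half:].mean() if not flagged else float("nan"),
                "last": amps[-1],
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def select_best_group(group_amplitudes: Dict) -> object:
    """Pick the stimulation group with the largest mean response amplitude.

    Values may be scalars or per-condition sequences (averaged).  Ties
    break to the lowest group id under sorted order.
    """
    if not group_amplitudes:
        raise ValueError("no groups to select from")
    best = None
    best_val = -np.inf
    for gid in sorted(group_amplitudes, key=str):
        v = group_amplitudes[gid]
        val = float(np.mean(v))
        if val > best_val:
            best, best_val = gid, val
    return best
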