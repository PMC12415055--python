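"""Spatial analyses, the predictability contrast, and the test machinery.

Statistics follow the study design exactly: paired Wilcoxon signed-rank
tests (exact small-sample null, tie-aware normal approximation otherwise)
with Bonferroni correction across simultaneous contrasts.  The spatial
analyses classify recording channels by distance from the stimulation
sites — a 15-electrode proximity radius, concentric 15/30/45/60-electrode
rings, and small/medium/large stimulation-site separation categories
(18–40 / 41–68 / 69–175 um).  The predictability analysis classifies each
recording site as preferring random or periodic sequences from per-site
paired tests at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grid import ElectrodeGrid, ElectrodeId
from .metrics import DEFAULT_WINDOWS, ResponseWindows, trial_amplitudes
from .paradigms import StimulusSequence
from .pipeline import Raster, build_raster


@dataclass
class TestResult:
    """Outcome of a paired signed-rank test.

    ``statistic`` is W+, the sum of ranks of positive differences;
    ``n_effective`` counts non-zero differences; ``method`` is ``exact``,
    ``normal-approx`` or ``undefined`` (all differences zero).
    """

    statistic: float
    p_value: float
    n_effective: int
    method: str


def _exact_signed_rank_tails(ranks2: np.ndarray, w2: float) -> Tuple[float, float]:
    """(P[W+ <= w], P[W+ >= w]) under the exact null, for doubled ranks.

    Doubling the midranks makes them integers, so the null distribution of
    2*W+ is computed by the standard generating-polynomial recursion: each
    difference contributes rank 0 or 2r with equal probability.  Counts
    stay below 2^n <= 2^25, exactly representable in doubles.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n = len(ranks2)
    denom = 2.0**n
    w2i = int(round(w2))
    p_le = counts[: w2i + 1].sum() / denom
    p_ge = counts[w2i:].sum() / denom
    return p_le, p_ge


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Optional[Sequence[float]] = None,
    alternative: str = "two-sided",
    exact_cutoff: int = 25,
) -> TestResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped (classic convention); absolute
    differences are ranked with midranks for ties.  The null tail is
    enumerated exactly when the effective sample size is at most
    ``exact_cutoff``, and approximated by a tie-corrected normal with
    continuity correction above it.  ``alternative='greater'`` tests for
    x > y.  When every difference is zero the result is flagged
    undefined (NaN p-value).
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(float("nan"), float("nan"), 0, "undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_cutoff:
        ranks2 = np.round(ranks * 2).astype(int)
        p_le, p_ge = _exact_signed_rank_tails(ranks2, round(2 * w_plus))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, t_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (t_counts**3 - t_counts).sum() / 48.0
        sd = np.sqrt(var)
        # continuity correction of 0.5 toward the mean
        p_ge = float(sps.norm.sf((w_plus - 0.5 - mean) / sd))
        p_le = float(sps.norm.cdf((w_plus + 0.5 - mean) / sd))
        method = "normal-approx"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return TestResult(w_plus, float(p), n, method)


def bonferroni_adjust(
    p_values: Sequence[float], m: Optional[int] = None
) -> list[float]:
    """Bonferroni adjustment: ``min(1, p * m)`` elementwise."""
    ps = list(p_values)
    for p in ps:
        if not 0 < p <= 1:
            raise ValueError(f"p-value {p} outside (0, 1]")
    mm = m if m is not None else len(ps)
    return [min(1.0, p * mm) for p in ps]


# Spatial analyses --------------------------------------------------------


def _channel_window_amplitudes(
    raster: Raster, condition: str, window: Tuple[float, float]
) -> Dict[ElectrodeId, float]:
    """Mean per-trial window rate (spikes/ms) for every raster channel."""
    n_trials = raster.n_trials.get(condition, 0)
    if n_trials == 0:
        raise ValueError(f"no trials for condition {condition!r}")
    df = raster.spikes
    sel = (
        (df["condition"] == condition)
        & (df["t_ms"] >= window[0] - 1e-9)
        & (df["t_ms"] < window[1] - 1e-9)
    )
    sub = df.loc[sel]
    counts = sub.groupby(["col", "row"]).size()
    span = window[1] - window[0]
    out = {}
    for ch in raster.channels:
        out[ch] = counts.get(ch, 0) / (n_trials * span)
    return out


def _role_site(sequence: StimulusSequence, role: str) -> ElectrodeId:
    ev = sequence.events
    sites = {
        (int(c), int(r))
        for c, r in zip(ev.loc[ev["role"] == role, "col"], ev.loc[ev["role"] == role, "row"])
    }
    if len(sites) != 1:
        raise ValueError(f"role {role!r} is not delivered at a unique site")
    return next(iter(sites))


def proximity_analysis(
    spikes: pd.DataFrame,
    sequence: StimulusSequence,
    grid: ElectrodeGrid,
    channels: Sequence[ElectrodeId],
    radius_electrodes: float = 15.0,
    windows: ResponseWindows = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Early/late amplitudes by proximity to the stimulation electrodes.

    Channels within ``radius_electrodes`` electrode lengths of the
    standard (resp. deviant) site form the standard- (resp.
    deviant-)proximal area; channels inside both balls go to the nearer
    site (ties to standard); everything else is ``other``.  Returns one
    row per area x condition x window with the mean channel amplitude;
    empty areas are flagged with NaN amplitude and ``n_channels = 0``.
    """
    std_site = _role_site(sequence, "standard")
    dev_site = _role_site(sequence, "deviant")
    r_um = radius_electrodes * grid.pitch_um
    areas: Dict[str, list] = {"standard_proximal": [], "deviant_proximal": [], "other": []}
    for ch in channels:
        ds = grid.distance_um(ch, std_site)
        dd = grid.distance_um(ch, dev_site)
        if ds <= r_um and dd <= r_um:
            areas["standard_proximal" if ds <= dd else "deviant_proximal"].append(ch)
        elif ds <= r_um:
            areas["standard_proximal"].append(ch)
        elif dd <= r_um:
            areas["deviant_proximal"].append(ch)
        else:
            areas["other"].append(ch)

    raster = build_raster(spikes, sequence, channels=channels)
    rows = []
    for cond in ("standard", "deviant"):
        amps = _channel_window_amplitudes(raster, cond, windows.early)
        amps_late = _channel_window_amplitudes(raster, cond, windows.late)
        for area, chs in areas.items():
            for wname, a in (("early", amps), ("late", amps_late)):
                vals = [a[c] for c in chs]
                rows.append(
                    {
                        "area": area,
                        "condition": cond,
                        "window": wname,
                        "amplitude": float(np.mean(vals)) if vals else float("nan"),
                        "n_channels": len(chs),
                        "flagged_empty": not vals,
                    }
                )
    return pd.DataFrame(rows)


def ring_analysis(
    spikes: pd.DataFrame,
    sequence: StimulusSequence,
    grid: ElectrodeGrid,
    channels: Sequence[ElectrodeId],
    radii_electrodes: Sequence[float] = (15.0, 30.0, 45.0, 60.0),
    windows: ResponseWindows = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Early/late amplitudes in concentric distance rings.

    Channels are binned by annulus ``[0, r1], (r1, r2], ...`` of distance
    (in electrode lengths) from the stimulated site of each condition;
    channels beyond the last radius land in an ``overflow`` ring, which is
    reported.  The rings partition the channel set per condition.
    """
    radii = list(radii_electrodes)
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing")
    raster = build_raster(spikes, sequence, channels=channels)
    labels = [f"<= {r:g}" for r in radii] + ["overflow"]
    rows = []
    for cond in ("standard", "deviant"):
        site = _role_site(sequence, cond)
        dists = {
            ch: grid.distance_um(ch, site) / grid.pitch_um for ch in channels
        }
        ring_of = {}
        for ch, d in dists.items():
            for lab, r in zip(labels, radii):
                if d <= r:
                    ring_of[ch] = lab
                    break
            else:
                ring_of[ch] = "overflow"
        for wname, window in (("early", windows.early), ("late", windows.late)):
            amps = _channel_window_amplitudes(raster, cond, window)
            for lab in labels:
                chs = [c for c in channels if ring_of[tuple(c)] == lab]
                vals = [amps[tuple(c)] for c in chs]
                rows.append(
                    {
                        "ring": lab,
                        "condition": cond,
                        "window": wname,
                        "amplitude": float(np.mean(vals)) if vals else float("nan"),
                        "n_channels": len(chs),
                    }
                )
    return pd.DataFrame(rows)


# Separation categories ---------------------------------------------------


@dataclass(frozen=True)
class SeparationCategory:
    """Stimulation-site separation bands in um (inclusive endpoints)."""

    small: Tuple[float, float] = (18.0, 40.0)
    medium: Tuple[float, float] = (41.0, 68.0)
    large: Tuple[float, float] = (69.0, 175.0)

    def classify(self, separation_um: float) -> str:
        """Band of a separation; upper edges split adjacent bands."""
        if separation_um < self.small[0] or separation_um > self.large[1]:
            return "out_of_range"
        if separation_um <= self.small[1]:
            return "small"
        if separation_um <= self.medium[1]:
            return "medium"
        return "large"


def separation_analysis(
    results: pd.DataFrame,
    categories: SeparationCategory = SeparationCategory(),
) -> pd.DataFrame:
    """Deviant-vs-standard contrast by stimulation-site separation band.

    ``results`` needs columns ``separation_um, r_dev, r_std`` with one row
    per experiment.  Within each band a paired signed-rank test compares
    the deviant against the standard late amplitudes; empty bands are
    flagged.
    """
    req = {"separation_um", "r_dev", "r_std"}
    if not req <= set(results.columns):
        raise ValueError(f"results must have columns {sorted(req)}")
    band = results["separation_um"].map(categories.classify)
    rows = []
    for cat in ("small", "medium", "large", "out_of_range"):
        sub = results.loc[band == cat]
        if len(sub) == 0:
            if cat != "out_of_range":
                rows.append(
                    {"category": cat, "n": 0, "statistic": float("nan"),
                     "p_value": float("nan"), "flagged_empty": True}
                )
            continue
        res = wilcoxon_signed_rank(sub["r_dev"], sub["r_std"])
        rows.append(
            {
                "category": cat,
                "n": len(sub),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "flagged_empty": False,
            }
        )
    return pd.DataFrame(rows)


# Predictability preference ----------------------------------------------


@dataclass
class PreferenceClassification:
    """Per-site random-vs-periodic preference labels and their fractions."""

    labels: list
    n_sites: int
    counts: Dict[str, int]
    fractions: Dict[str, float]


def classify_site_preference(
    values_random: np.ndarray,
    values_periodic: np.ndarray,
    alpha: float = 0.05,
) -> PreferenceClassification:
    """Label each site by its random-vs-periodic response preference.

    ``values_random`` and ``values_periodic`` are (n_sites, n_trials)
    arrays of paired trial-level responses (raw or z-scored — the
    signed-rank test is invariant to any monotone per-culture rescaling).
    A site is ``prefers_random`` when its two-sided signed-rank p-value
    falls below *alpha* and the median paired difference is positive,
    ``prefers_periodic`` for negative, else ``nonsignificant``; sites
    whose test is undefined (all ties) count as nonsignificant.
    """
    vr = np.asarray(values_random, dtype=float)
    vp = np.asarray(values_periodic, dtype=float)
    if vr.shape != vp.shape:
        raise ValueError("paired arrays must have identical shapes")
    labels = []
    for i in range(vr.shape[0]):
        res = wilcoxon_signed_rank(vr[i], vp[i])
        if res.method == "undefined" or not res.p_value < alpha:
            labels.append("nonsignificant")
            continue
        d = vr[i] - vp[i]
        med = float(np.median(d[d != 0])) if np.any(d != 0) else 0.0
        if med == 0.0:
            med = float(np.mean(d))
        labels.append("prefers_random" if med > 0 else "prefers_periodic")
    n = len(labels)
    counts = {
        k: labels.count(k)
        for k in ("prefers_random", "prefers_periodic", "nonsignificant")
    }
    fractions = {k: v / n for k, v in counts.items()}
    return PreferenceClassification(labels, n, counts, fractions)


def preference_trial_values(
    raster: Raster,
    condition: str,
    window: Tuple[float, float] = DEFAULT_WINDOWS.late,
) -> np.ndarray:
    """(n_sites, n_trials) late-window spike counts per raster channel.

    Trial-level inputs for :func:`classify_site_preference`: one row per
    recording site, one column per within-condition trial.
    """
    n_trials = raster.n_trials.get(condition, 0)
    if n_trials == 0:
        raise ValueError(f"no trials for condition {condition!r}")
    df = raster.spikes
    sel = (
        (df["condition"] == condition)
        & (df["t_ms"] >= window[0] - 1e-9)
        & (df["t_ms"] < window[1] - 1e-9)
    )
    sub = df.loc[sel]
    idx = {tuple(c): i for i, c in enumerate(raster.channels)}
    out = np.zeros((len(raster.channels), n_trials))
    ch_i = [idx[(int(c), int(r))] for c, r in zip(sub["col"], sub["row"])]
    np.add.at(out, (ch_i, sub["trial"].to_numpy()), 1.0)
    return out
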