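"""Replica experiments on synthetic cultures.

Each function runs one of the study's analyses end-to-end on the synthetic
generator — oddball + MSC indices, NMDA-gain ablation, distance rings,
periodic-vs-random preference, detection fidelity, and the steady-state
adaptation check — and returns plain numbers.  They are the building
blocks of the acceptance script and of simulation-based tests.

Problem sizes default to the protocol's values (600 events at 500 ms ISI)
with channel counts in the dozens, which keeps a multi-culture replica in
the seconds-to-minutes range on one core while leaving Monte-Carlo errors
well below the effect sizes being measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import ElectrodeGrid, ElectrodeId
from .metrics import (
    DEFAULT_WINDOWS,
    IndexResult,
    compute_indices,
    trial_amplitudes,
    window_amplitude,
)
from .paradigms import (
    StimulusSequence,
    make_msc,
    make_oddball,
    make_predictable,
)
from .pipeline import (
    DetectionParams,
    bandpass_filter,
    blank_artifact,
    build_raster,
    detect_spikes,
    population_psth_from_raster,
)
from .simulate import (
    CultureParams,
    simulate_spikes,
    synthesize_raw,
)
from .stats import classify_site_preference, preference_trial_values

DEFAULT_STIM = ((110, 60), (113, 60))
DEFAULT_MSC_SITES = tuple((104 + 3 * i, 62) for i in range(10))


def _default_channels(n: int = 16) -> list:
    # a loose cluster 6-30 electrodes from the stimulation block, so early
    # responses are present but do not dominate the late window
    out = []
    for i in range(n):
        out.append((100 + 2 * (i % 8), 50 + 3 * (i // 8)))
    return out


def _msc_site_relabel(seq: StimulusSequence, test_site: ElectrodeId) -> StimulusSequence:
    """Restrict the MSC condition to the oddball test site.

    The MSC response entering the DDI is the response to the *same physical
    site* as the deviant, presented inside the many-standards sequence;
    events at the other nine sites are relabeled ``msc_other``.
    """
    ev = seq.events.copy()
    at_site = (ev["col"] == test_site[0]) & (ev["row"] == test_site[1])
    ev.loc[~at_site, "role"] = "msc_other"
    return StimulusSequence(events=ev, isi_s=seq.isi_s, mode=seq.mode)


def culture_indices(
    seed: int,
    params: Optional[CultureParams] = None,
    n_events: int = 600,
    channels: Optional[Sequence[ElectrodeId]] = None,
    grid: Optional[ElectrodeGrid] = None,
    window: Tuple[float, float] = DEFAULT_WINDOWS.late,
) -> IndexResult:
    """Late-window SI/DDI for one simulated culture (oddball + MSC runs).

    The oddball deviant site also appears in the MSC site set, and the MSC
    amplitude is measured at that shared site only.
    """
    grid = grid or ElectrodeGrid()
    channels = list(channels) if channels is not None else _default_channels()
    params = (params or CultureParams()).replace(seed=seed)
    std_site, dev_site = DEFAULT_STIM
    msc_sites = (dev_site,) + DEFAULT_MSC_SITES[:9]

    odd = make_oddball((std_site, dev_site), n_events, 0.1, 0.5, seed=seed)
    msc = make_msc(list(msc_sites), n_events, 0.5, seed=seed + 1000)

    sp_odd = simulate_spikes(grid, odd, params, channels)
    sp_msc = simulate_spikes(grid, msc, params.replace(seed=seed + 2000), channels)
    sp_odd = blank_artifact(sp_odd, odd, 1.0)
    sp_msc = blank_artifact(sp_msc, msc, 1.0)

    r_odd = build_raster(sp_odd, odd, channels=channels)
    msc_rel = _msc_site_relabel(msc, dev_site)
    r_msc = build_raster(sp_msc, msc_rel, channels=channels)

    amp = {}
    for raster, cond in ((r_odd, "standard"), (r_odd, "deviant"), (r_msc, "msc")):
        psth = population_psth_from_raster(raster, cond, 1.0)
        amp[cond] = window_amplitude(psth, window)
    return compute_indices(amp["standard"], amp["deviant"], amp["msc"])


def nmda_ablation(
    seed: int,
    params: Optional[CultureParams] = None,
    n_events: int = 600,
    channels: Optional[Sequence[ElectrodeId]] = None,
) -> dict:
    """Early/late population amplitudes at baseline vs. full NMDA blockade.

    Returns per-condition amplitudes plus the trial-level standard error of
    the blocked late amplitude and the baseline-rate expectation, so the
    "late collapses to baseline" contrast can be judged on the Monte-Carlo
    scale.
    """
    grid = ElectrodeGrid()
    channels = list(channels) if channels is not None else _default_channels()
    base = (params or CultureParams()).replace(seed=seed)
    blocked = base.replace(nmda_gain=0.0)
    seq = make_oddball(DEFAULT_STIM, n_events, 0.1, 0.5, seed=seed)

    out = {}
    for label, p in (("baseline", base), ("blocked", blocked)):
        spikes = blank_artifact(simulate_spikes(grid, seq, p, channels), seq, 1.0)
        raster = build_raster(spikes, seq, channels=channels)
        psth = population_psth_from_raster(raster, "standard", 1.0)
        out[f"early_{label}"] = window_amplitude(psth, DEFAULT_WINDOWS.early)
        out[f"late_{label}"] = window_amplitude(psth, DEFAULT_WINDOWS.late)
        amps = trial_amplitudes(raster, "standard", DEFAULT_WINDOWS.late)
        out[f"late_{label}_sem"] = float(
            amps.std(ddof=1) / np.sqrt(len(amps))
        )
    out["late_baseline_expectation"] = base.baseline_rate_hz / 1000.0
    return out


def ring_profile(
    seed: int,
    params: Optional[CultureParams] = None,
    n_events: int = 600,
    radii: Sequence[float] = (15.0, 30.0, 45.0, 60.0),
) -> pd.DataFrame:
    """Early/late standard-response amplitudes per distance ring.

    Channels form a strip out to beyond the last ring radius from the
    standard site, so every annulus is populated.
    """
    from .stats import ring_analysis

    grid = ElectrodeGrid()
    std_site, dev_site = (60, 60), (63, 60)
    seq = make_oddball((std_site, dev_site), n_events, 0.1, 0.5, seed=seed)
    # strip of channels out to ~60 electrode lengths from both sites
    channels = [(60 + dc, 60) for dc in range(0, 64, 2)]
    channels += [(60 + dc, 61) for dc in range(1, 64, 2)]
    p = (params or CultureParams()).replace(seed=seed)
    spikes = blank_artifact(simulate_spikes(grid, seq, p, channels), seq, 1.0)
    return ring_analysis(spikes, seq, grid, channels, radii)


def preference_experiment(
    seed: int,
    regularity_gain: float,
    n_sites: int = 500,
    n_events: int = 600,
    alpha: float = 0.05,
    condition: str = "standard",
):
    """Random-vs-periodic preference classification over simulated sites.

    Simulates matched periodic and random predictable-deviant runs (same
    deviant probability), extracts paired per-trial late-window counts for
    every recording site, and classifies each site's preference.  The
    depletion is switched off here so the paired trials differ only through
    the imposed regularity effect, not through sequence-specific adaptation
    histories (see the methods note).
    """
    grid = ElectrodeGrid()
    p = (params_for_preference(regularity_gain)).replace(seed=seed)
    rng = np.random.Generator(np.random.Philox(seed + 5000))
    cols = rng.integers(0, grid.n_cols, size=n_sites * 2)
    rows = rng.integers(0, grid.n_rows, size=n_sites * 2)
    channels = sorted({(int(c), int(r)) for c, r in zip(cols, rows)})[:n_sites]

    per = make_predictable(DEFAULT_STIM, n_events, 0.1, "periodic", 0.5, seed=seed)
    ran = make_predictable(DEFAULT_STIM, n_events, 0.1, "random", 0.5, seed=seed)
    vals = {}
    for label, seq, s_off in (("periodic", per, 0), ("random", ran, 1)):
        spikes = blank_artifact(
            simulate_spikes(grid, seq, p.replace(seed=seed * 2 + s_off), channels),
            seq,
            1.0,
        )
        raster = build_raster(spikes, seq, channels=channels)
        vals[label] = preference_trial_values(raster, condition)
    return classify_site_preference(vals["random"], vals["periodic"], alpha=alpha)


def params_for_preference(regularity_gain: float) -> CultureParams:
    """Generator settings for the predictability contrast (no depletion)."""
    return CultureParams(depletion_d=0.0, regularity_gain=regularity_gain)


def detection_fidelity(
    seed: int,
    n_spikes_per_channel: int = 100,
    n_channels: int = 4,
    snr: float = 10.0,
    match_tol_ms: float = 0.5,
) -> dict:
    """Recall/precision of the detector on templated synthetic raw traces.

    Ground-truth spikes are placed >= 3 ms apart, outside the 2 ms
    post-stimulus window of a 500 ms-ISI stimulus train; the spike template
    peak is ``snr`` times the noise SD.  Also reports whether blanking
    removed every detected event in the 1 ms post-stimulus windows.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    channels = [(10 + i, 10) for i in range(n_channels)]
    n_events = 20
    seq = make_oddball(
        ((10, 10), (12, 10)), n_events, 0.1, 0.5, seed=seed
    )
    duration = n_events * 0.5 + 0.2
    onsets = seq.events["onset_s"].to_numpy()

    truth = {}
    rows = []
    for ch in channels:
        times = []
        while len(times) < n_spikes_per_channel:
            t = rng.uniform(0.01, duration - 0.01)
            rel = t - onsets[np.searchsorted(onsets, t) - 1] if t >= onsets[0] else 1.0
            if 0 <= rel <= 0.002:
                continue
            if times and np.min(np.abs(np.asarray(times) - t)) < 0.003:
                continue
            times.append(t)
        times = np.sort(times)
        truth[ch] = times
        rows.extend((ch[0], ch[1], t) for t in times)
    spikes = pd.DataFrame(rows, columns=["col", "row", "time_s"])

    from .simulate import default_spike_template

    rec = synthesize_raw(
        spikes,
        seq,
        channels,
        noise_sd_uV=1.0,
        spike_template=default_spike_template(20_000.0, amplitude_uV=snr),
        sample_rate_hz=20_000.0,
        duration_s=duration,
        seed=seed + 1,
    )
    filtered = bandpass_filter(rec)
    detected = detect_spikes(filtered, DetectionParams())
    blanked = blank_artifact(detected, seq, 1.0)

    tol = match_tol_ms / 1000.0
    tp = 0
    n_det = len(blanked)
    for ch in channels:
        det_t = blanked.loc[
            (blanked["col"] == ch[0]) & (blanked["row"] == ch[1]), "time_s"
        ].to_numpy()
        used = np.zeros(len(det_t), dtype=bool)
        for t in truth[ch]:
            if len(det_t) == 0:
                continue
            j = int(np.argmin(np.abs(det_t - t)))
            if not used[j] and abs(det_t[j] - t) <= tol:
                used[j] = True
                tp += 1
    n_true = n_channels * n_spikes_per_channel

    # every surviving spike must fall outside the 1 ms blank windows
    t_all = blanked["time_s"].to_numpy()
    idx = np.clip(np.searchsorted(onsets, t_all) - 1, 0, len(onsets) - 1)
    rel = t_all - onsets[idx]
    in_blank = int(np.sum((rel > 0) & (rel <= 0.001)))
    return {
        "recall": tp / n_true,
        "precision": tp / n_det if n_det else 0.0,
        "spikes_in_blank_window": in_blank,
    }


def steady_state_check(
    seed: int,
    isi_s: float = 0.5,
    depletion_d: float = 0.2,
    recovery_tau_s: float = 5.0,
    n_events: int = 600,
    n_channels: int = 40,
) -> dict:
    """Simulated steady-state standard late response vs. the closed form.

    Channels sit far from the stimulation site so the late window holds
    only the network component; the first 100 stimuli are discarded as
    burn-in.  Returns the simulated mean late count per stimulus per
    channel, the prediction ``late_amp * g_nmda * r*`` and the Monte-Carlo
    SEM of the simulated mean.
    """
    from .simulate import resource_steady_state

    grid = ElectrodeGrid()
    p = CultureParams(
        seed=seed,
        baseline_rate_hz=0.0,
        early_amp=0.0,
        depletion_d=depletion_d,
        recovery_tau_s=recovery_tau_s,
    )
    site = (110, 60)
    from .paradigms import _events_frame

    ev = _events_frame(
        np.arange(n_events) * isi_s, [site] * n_events, ["standard"] * n_events,
        1, "train",
    )
    seq = StimulusSequence(events=ev, isi_s=isi_s)
    channels = [(5 + i % 20, 5 + i // 20) for i in range(n_channels)]
    spikes = simulate_spikes(grid, seq, p, channels)
    raster = build_raster(spikes, seq, channels=channels)
    amps = trial_amplitudes(raster, "standard", DEFAULT_WINDOWS.late)
    counts = amps[100:] * 139.0  # channel-averaged count per stimulus
    r_star = resource_steady_state(depletion_d, recovery_tau_s, isi_s)
    predicted = p.late_amp * p.nmda_gain * r_star
    sem = float(counts.std(ddof=1) / np.sqrt(len(counts)))
    return {
        "simulated": float(counts.mean()),
        "predicted": float(predicted),
        "sem": sem,
    }
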