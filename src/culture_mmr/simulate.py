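"""Synthetic neuronal-culture generator.

Produces spike tables (and optionally raw 20 kHz voltage traces) with the
statistical structure the downstream analysis assumes, so that every stage
of the pipeline is testable without recordings:

* a biphasic evoked response — an **early** component (direct electrical
  activation) whose amplitude decays exponentially with distance from the
  stimulation site, and a **late** component (synaptically mediated,
  network-wide) that is distance-independent;
* per-site **adaptation**: each stimulation site owns a synaptic resource
  ``r`` that is depleted multiplicatively at every physical stimulus at
  that site and relaxes back toward 1 between stimuli with a recovery time
  constant, producing stimulus-specific adaptation of the standard;
* a **deviance gain** that boosts the late response to contextual deviants
  (rare events inside an oddball/predictable sequence) beyond what rarity
  alone produces — MSC events never receive it;
* a **regularity gain** that attenuates late responses in periodic
  (predictable) sequences relative to random ones;
* an **NMDA gain** in [0, 1] scaling the late component (0 = receptor
  blockade, abolishing the late response while leaving the early one
  untouched).

Spiking is an inhomogeneous Poisson process: the rate is a constant
spontaneous baseline plus, for every physical stimulus, an early and a late
unit-area alpha-shaped kernel weighted as above.  Draws come from the
counter-based Philox generator, seeded once, with independent child streams
for the baseline, early and late components (so e.g. changing the NMDA gain
leaves the simulated early spikes bit-identical).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import ElectrodeGrid, ElectrodeId
from .paradigms import ROLE_DEVIANT, StimulusSequence

SPIKE_COLUMNS = ["col", "row", "time_s"]


@dataclass
class CultureParams:
    """Generative parameters of the synthetic culture.

    Amplitudes are expected spike counts per channel per stimulus (at full
    synaptic resource, distance 0 for the early term); rates are in Hz;
    times in the stated units.
    """

    baseline_rate_hz: float = 2.0       #: spontaneous rate per channel
    early_amp: float = 2.0              #: early spikes/stimulus at distance 0
    early_decay_um: float = 150.0       #: spatial length constant of the early term
    early_latency_ms: float = 2.5       #: dead time before the early kernel
    early_width_ms: float = 0.9         #: alpha-kernel time constant (early)
    late_amp: float = 3.0               #: late spikes/stimulus at full resource
    late_latency_ms: float = 11.0       #: dead time before the late kernel
    late_width_ms: float = 14.0         #: alpha-kernel time constant (late)
    depletion_d: float = 0.2            #: per-stimulus resource depletion in [0,1)
    recovery_tau_s: float = 5.0         #: resource recovery time constant
    deviance_gain: float = 0.5          #: late boost for contextual deviants (>= 0)
    regularity_gain: float = 0.3        #: late attenuation in periodic mode, [0,1)
    nmda_gain: float = 1.0              #: late-component scale, [0,1]; 0 = blockade
    cross_site_depletion: float = 0.0   #: fraction of depletion shared across sites
    cross_site_decay_um: float = 50.0   #: spatial decay of cross-site depletion
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` listing every violated bound."""
        bad = []
        for name in (
            "baseline_rate_hz", "early_amp", "late_amp", "deviance_gain",
            "early_decay_um", "early_width_ms", "late_width_ms",
            "early_latency_ms", "late_latency_ms", "cross_site_decay_um",
        ):
            if getattr(self, name) < 0:
                bad.append(f"{name} must be >= 0")
        if not 0 <= self.depletion_d < 1:
            bad.append("depletion_d must be in [0, 1)")
        if not 0 <= self.regularity_gain < 1:
            bad.append("regularity_gain must be in [0, 1)")
        if not 0 <= self.nmda_gain <= 1:
            bad.append("nmda_gain must be in [0, 1]")
        if not 0 <= self.cross_site_depletion <= 1:
            bad.append("cross_site_depletion must be in [0, 1]")
        if not self.recovery_tau_s > 0:
            bad.append("recovery_tau_s must be > 0")
        if bad:
            raise ValueError("invalid CultureParams: " + "; ".join(bad))

    def replace(self, **kw) -> "CultureParams":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return CultureParams(**d)


@dataclass
class RawRecording:
    """Multichannel sampled voltage with stimulation markers."""

    traces: np.ndarray                 # (n_channels, n_samples), uV
    channels: list                     # ElectrodeId per trace row
    sample_rate_hz: float
    onsets_s: np.ndarray               # physical stimulation onsets

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (channels x samples)")

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


def resource_steady_state(d: float, tau_s: float, isi_s: float) -> float:
    """Pre-stimulus resource fixed point under regular stimulation.

    For depletion ``r -> (1-d) r`` at every stimulus and exponential
    relaxation toward 1 between stimuli at interval ``isi_s``::

        r* = (1 - exp(-isi/tau)) / (1 - (1-d) exp(-isi/tau))
    """
    e = math.exp(-isi_s / tau_s)
    return (1.0 - e) / (1.0 - (1.0 - d) * e)


def event_response_means(
    grid: ElectrodeGrid,
    sequence: StimulusSequence,
    params: CultureParams,
    channels: Sequence[ElectrodeId],
) -> Tuple[np.ndarray, np.ndarray]:
    """Expected evoked spike counts per event.

    Returns ``(early, late)`` where ``early`` has shape
    ``(n_events, n_channels)`` — the distance-dependent direct component —
    and ``late`` has shape ``(n_events,)`` — the network-wide component,
    identical across channels.  Non-physical (omitted) events contribute
    zeros.  The late vector already includes the synaptic-resource state,
    the contextual-deviance boost, the periodicity attenuation and the NMDA
    gain.
    """
    params.validate()
    ev = sequence.events
    n_ev = len(ev)
    ch = [tuple(c) for c in channels]
    for c in ch:
        grid.validate_electrode(c)
    onsets = ev["onset_s"].to_numpy()
    sites = list(zip(ev["col"].astype(int), ev["row"].astype(int)))
    physical = ev["physical"].to_numpy(dtype=bool)
    is_dev = (ev["role"] == ROLE_DEVIANT).to_numpy()
    periodic = sequence.mode == "periodic"

    # Synaptic resource per stimulation site, tracked through the run.
    uniq = sorted(set(s for s, p in zip(sites, physical) if p))
    r = {s: 1.0 for s in uniq}
    t_last = {s: None for s in uniq}
    if params.cross_site_depletion > 0 and len(uniq) > 1:
        xdist = {
            (a, b): grid.distance_um(a, b) for a in uniq for b in uniq if a != b
        }
    resource = np.zeros(n_ev)
    tau = params.recovery_tau_s
    for i in range(n_ev):
        if not physical[i]:
            continue
        s = sites[i]
        t = onsets[i]
        for q in uniq:
            if t_last[q] is not None:
                r[q] = 1.0 - (1.0 - r[q]) * math.exp(-(t - t_last[q]) / tau)
            t_last[q] = t
        resource[i] = r[s]
        r[s] *= 1.0 - params.depletion_d
        if params.cross_site_depletion > 0:
            for q in uniq:
                if q != s:
                    w = params.cross_site_depletion * math.exp(
                        -xdist[(s, q)] / params.cross_site_decay_um
                    )
                    r[q] *= 1.0 - params.depletion_d * w

    late = (
        params.nmda_gain
        * params.late_amp
        * resource
        * (1.0 + params.deviance_gain * is_dev)
        * (1.0 - (params.regularity_gain if periodic else 0.0))
    )
    late = np.where(physical, late, 0.0)

    early = np.zeros((n_ev, len(ch)))
    ch_arr = np.asarray(ch, dtype=float)
    site_arr = np.asarray(sites, dtype=float)
    for i in range(n_ev):
        if not physical[i]:
            continue
        d_um = grid.pitch_um * np.hypot(
            ch_arr[:, 0] - site_arr[i, 0], ch_arr[:, 1] - site_arr[i, 1]
        )
        early[i] = params.early_amp * np.exp(-d_um / params.early_decay_um)
    return early, late


def _alpha_delays_s(
    rng: np.random.Generator, n: int, latency_ms: float, width_ms: float
) -> np.ndarray:
    # Unit-area alpha kernel t exp(-t/w)/w**2 == Gamma(shape=2, scale=w),
    # shifted by the latency.
    return (latency_ms + rng.gamma(2.0, width_ms, size=n)) / 1000.0


def simulate_spikes(
    grid: ElectrodeGrid,
    sequence: StimulusSequence,
    params: CultureParams,
    channels: Sequence[ElectrodeId],
    duration_s: Optional[float] = None,
) -> pd.DataFrame:
    """Draw a spike table from the inhomogeneous-Poisson culture model.

    Returns a DataFrame with columns ``col, row, time_s``, sorted by
    channel then time.  ``duration_s`` defaults to one ISI plus 200 ms past
    the last onset, so the last trial's analysis window is fully covered.
    """
    params.validate()
    ch = [tuple(c) for c in channels]
    early_mean, late_mean = event_response_means(grid, sequence, params, ch)
    onsets = sequence.events["onset_s"].to_numpy()
    if duration_s is None:
        duration_s = float(onsets[-1]) + sequence.isi_s + 0.2

    ss = np.random.SeedSequence(params.seed)
    k_base, k_early, k_late = ss.spawn(3)
    rng_b = np.random.Generator(np.random.Philox(k_base))
    rng_e = np.random.Generator(np.random.Philox(k_early))
    rng_l = np.random.Generator(np.random.Philox(k_late))

    cols, rows, times = [], [], []

    # Spontaneous baseline: homogeneous Poisson per channel.
    n_base = rng_b.poisson(params.baseline_rate_hz * duration_s, size=len(ch))
    for j, (c, r) in enumerate(ch):
        t = rng_b.uniform(0.0, duration_s, size=n_base[j])
        cols.append(np.full(n_base[j], c))
        rows.append(np.full(n_base[j], r))
        times.append(t)

    # Early (direct) component: counts per event x channel.
    cnt = rng_e.poisson(early_mean)
    ev_idx, ch_idx = np.nonzero(cnt)
    reps = cnt[ev_idx, ch_idx]
    ev_rep = np.repeat(ev_idx, reps)
    ch_rep = np.repeat(ch_idx, reps)
    n_early = len(ev_rep)
    t_early = onsets[ev_rep] + _alpha_delays_s(
        rng_e, n_early, params.early_latency_ms, params.early_width_ms
    )
    ch_np = np.asarray(ch, dtype=int)
    cols.append(ch_np[ch_rep, 0])
    rows.append(ch_np[ch_rep, 1])
    times.append(t_early)

    # Late (network) component: same expected count on every channel.
    cnt_l = rng_l.poisson(np.repeat(late_mean[:, None], len(ch), axis=1))
    ev_idx, ch_idx = np.nonzero(cnt_l)
    reps = cnt_l[ev_idx, ch_idx]
    ev_rep = np.repeat(ev_idx, reps)
    ch_rep = np.repeat(ch_idx, reps)
    t_late = onsets[ev_rep] + _alpha_delays_s(
        rng_l, len(ev_rep), params.late_latency_ms, params.late_width_ms
    )
    cols.append(ch_np[ch_rep, 0])
    rows.append(ch_np[ch_rep, 1])
    times.append(t_late)

    df = pd.DataFrame(
        {
            "col": np.concatenate(cols).astype(int),
            "row": np.concatenate(rows).astype(int),
            "time_s": np.concatenate(times),
        }
    )
    df = df[df["time_s"] < duration_s]
    df = df.sort_values(["col", "row", "time_s"], kind="mergesort").reset_index(
        drop=True
    )
    return df


# Raw-trace synthesis -----------------------------------------------------


def default_spike_template(
    sample_rate_hz: float = 20_000.0, amplitude_uV: float = 10.0
) -> np.ndarray:
    """Biphasic extracellular spike waveform, ~1.2 ms, negative-leading.

    The negative peak has magnitude ``amplitude_uV``; templates are aligned
    on that peak when inserted.
    """
    n = int(round(1.2e-3 * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz * 1000.0  # ms
    w = -amplitude_uV * np.exp(-(((t - 0.3) / 0.10) ** 2)) + 0.3 * amplitude_uV * np.exp(
        -(((t - 0.7) / 0.25) ** 2)
    )
    return w


def default_artifact_template(
    sample_rate_hz: float = 20_000.0, amplitude_uV: float = 40.0
) -> np.ndarray:
    """Stimulation artifact: smooth, large, confined to <1 ms post-onset.

    A raised-cosine-windowed decaying transient; smooth edges keep the
    zero-phase bandpass from ringing far outside the blanking window.
    """
    n = int(round(0.9e-3 * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz * 1000.0  # ms
    env = 0.5 * (1 - np.cos(2 * np.pi * np.minimum(t / 0.9, 1.0)))
    return amplitude_uV * env * np.exp(-t / 0.25) * np.sign(np.sin(2 * np.pi * t / 0.9))


def synthesize_raw(
    spikes: pd.DataFrame,
    sequence: StimulusSequence,
    channels: Sequence[ElectrodeId],
    noise_sd_uV: float = 1.0,
    spike_template: Optional[np.ndarray] = None,
    artifact_template: Optional[np.ndarray] = None,
    sample_rate_hz: float = 20_000.0,
    duration_s: Optional[float] = None,
    seed: int = 0,
) -> RawRecording:
    """Render a spike table as raw voltage traces.

    White Gaussian noise, plus the spike template at every spike time
    (negative peak aligned to ``round(time * rate)``), plus the artifact
    template starting at every *physical* stimulus onset.  Omitted events
    leave no artifact.  Templates longer than one ISI are rejected.
    """
    ch = [tuple(c) for c in channels]
    if spike_template is None:
        spike_template = default_spike_template(sample_rate_hz)
    if artifact_template is None:
        artifact_template = default_artifact_template(sample_rate_hz)
    isi_samples = sequence.isi_s * sample_rate_hz
    for name, tpl in (("spike", spike_template), ("artifact", artifact_template)):
        if len(tpl) >= isi_samples:
            raise ValueError(f"{name} template ({len(tpl)} samples) overruns the ISI")
    ev = sequence.events
    onsets = ev.loc[ev["physical"], "onset_s"].to_numpy()
    if duration_s is None:
        duration_s = float(ev["onset_s"].iloc[-1]) + sequence.isi_s + 0.2
    n_samp = int(round(duration_s * sample_rate_hz))

    rng = np.random.Generator(np.random.Philox(seed))
    if noise_sd_uV > 0:
        traces = rng.normal(0.0, noise_sd_uV, size=(len(ch), n_samp))
    else:
        traces = np.zeros((len(ch), n_samp))

    peak = int(np.argmin(spike_template))

    def _insert(row: np.ndarray, tpl: np.ndarray, start: int) -> None:
        a = max(start, 0)
        b = min(start + len(tpl), n_samp)
        if b > a:
            row[a:b] += tpl[a - start : b - start]

    by_channel = {c: i for i, c in enumerate(ch)}
    for c, r, t in zip(spikes["col"], spikes["row"], spikes["time_s"]):
        i = by_channel.get((int(c), int(r)))
        if i is None:
            continue
        _insert(traces[i], spike_template, int(round(t * sample_rate_hz)) - peak)
    for t in onsets:
        start = int(round(t * sample_rate_hz))
        for i in range(len(ch)):
            _insert(traces[i], artifact_template, start)

    return RawRecording(
        traces=traces.astype(np.float32),
        channels=ch,
        sample_rate_hz=sample_rate_hz,
        onsets_s=onsets,
    )


# Spike-table I/O ---------------------------------------------------------


def write_spikes(spikes: pd.DataFrame, path) -> None:
    df = spikes.copy()
    df["time_s"] = df["time_s"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_spikes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["time_s"] = df["time_s"].astype(float)
    return df[SPIKE_COLUMNS]


def write_raw_h5(rec: RawRecording, path) -> None:
    """Store a raw recording in HDF5 (/traces, /onsets, /meta attrs)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=rec.traces, compression="gzip")
        f.create_dataset("onsets", data=rec.onsets_s)
        f.create_dataset("channels", data=np.asarray(rec.channels, dtype=int))
        f.attrs["sample_rate_hz"] = rec.sample_rate_hz


def read_raw_h5(path) -> RawRecording:
    import h5py

    with h5py.File(path, "r") as f:
        return RawRecording(
            traces=f["traces"][...],
            channels=[tuple(c) for c in f["channels"][...]],
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            onsets_s=f["onsets"][...],
        )
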