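# Methods

## Scope and model of the data

`culture_mmr` analyses evoked responses of dissociated cortical cultures
grown on a high-density CMOS microelectrode array (220 × 120 electrodes at
17.5 µm pitch, 20 kHz sampling) under electrical oddball-type stimulation.
The unit of analysis is the electrode channel (threshold crossings); no
spike sorting is performed. Responses to a stimulus have two phases:

* an **early** phase, 0–10 ms post-stimulus, dominated by direct electrical
  activation of nearby somata and axons, whose amplitude decays with
  distance from the stimulation electrode;
* a **late** phase, 11–150 ms, carried by synaptic, network-wide
  recruitment. Deviance detection and regularity sensitivity are late-phase
  phenomena, so all indices are computed there by default.

Amplitudes are mean PSTH rates over a window, in spikes per ms per trial
(per channel for population PSTHs), built from 1 ms bins over a −50 to
+150 ms peri-stimulus window. Windows are half-open over bin starts: with
1 ms bins, "0–10 ms" covers bins 0–9 and "11–150 ms" covers bins 11–149
(139 bins). The 10 ms bin belongs to neither window; the printed labels
leave its assignment ambiguous and excluding it avoids double counting at
the early/late boundary.

The two indices are

    SI(R)  = (R − R_std) / (R + R_std)        for R in {R_dev, R_MSC}
    DDI    = (R_dev − R_MSC) / (R_dev + R_MSC)

`R_std`, `R_dev` are the standard/deviant amplitudes from the oddball run
and `R_MSC` is the amplitude of the *same physical site* presented inside
the many-standards control, so a positive DDI indicates responses beyond
what rarity-driven adaptation produces. Both indices are antisymmetric,
scale-invariant, bounded in [−1, 1], and undefined (returned as NaN) when
their denominator is zero.

Other response descriptors: peak latency is the bin start of the maximal
rate in a window (ties to the earliest bin); response duration is the
total post-stimulus time in bins exceeding the baseline mean + 3 baseline
SD, with the baseline taken over the 50 ms preceding onset (sample SD,
n−1). Because "the period in which the amplitude exceeded" the threshold
is ambiguous between a total count and the first contiguous run, the
total count is the default and a `contiguous` mode is provided.

## Stimulation paradigms

All generators use **exact-count allocation**: a 600-event oddball at
p = 0.1 contains exactly 540 standards and 60 deviants, in a uniformly
random order fixed by the seed (counter-based Philox, so sequences are
byte-reproducible across platforms). The ISI (500 ms by default) is
onset-to-onset. Specifics:

* **Oddball / flip-flop** — 9:1 standard:deviant at two sites; flip-flop
  pairs swap the roles in run 2, with a 5 min rest recorded between runs;
  a site triplet yields all 6 ordered assignments.
* **Omission** — the rare events are silent slots on the same onset grid
  (`physical = false`): the simulator evokes nothing, artifact blanking
  skips them, but rasters still align to their nominal onsets so omission
  responses can be measured.
* **MSC** — 10 distinct sites, each exactly 10% of events, every event
  labeled `msc`.
* **Predictable deviant** — deviant probability 5/10/20%. Periodic mode
  places the deviant at every (1/p)-th position starting at position 1/p
  (1-based), so every deviant is preceded by 1/p − 1 standards; random
  mode draws the same number of positions uniformly. Adjacent deviants in
  random mode are allowed by default (`min_gap` can forbid them).
* **Recovery** — n conditioning stimuli at one site, then a probe at the
  same site (the (n+1)-th stimulus there) after a recovery interval of
  0.5–10.5 s; an optional interposed site fills the gap on the
  conditioning ISI grid, starting one ISI after the last conditioning
  stimulus and ending strictly before the probe. The fill schedule is a
  documented convention, not an observed protocol detail.
* **Repetition count** — blocks of k standards followed by one deviant,
  block order randomised, boundaries recorded.

## Synthetic-culture generator

No public recordings exist for this preparation, so a generative model
reproduces the statistical structure the analysis relies on. Spiking is
an inhomogeneous Poisson process with rate

    baseline + Σ_events [ early(t, d) + late(t) ]

* **Early term**: expected count `early_amp · exp(−d/early_decay_um)` per
  stimulus at channel distance d, spread over a unit-area alpha kernel
  (Gamma(2, early_width_ms) delayed by early_latency_ms).
* **Late term**: distance-independent expected count
  `g_nmda · late_amp · r(site, t) · (1 + γ_dev·[contextual deviant]) ·
  (1 − γ_reg·[periodic sequence])`, spread over an alpha kernel delayed by
  late_latency_ms.
* **Adaptation**: each stimulation site owns a synaptic resource r that is
  multiplied by (1 − d) at every physical stimulus there and relaxes
  toward 1 with time constant τ between stimuli ("local fatigue, global
  recovery"). Under regular stimulation at interval Δ the pre-stimulus
  resource converges to the fixed point

      r* = (1 − e^(−Δ/τ)) / (1 − (1−d) e^(−Δ/τ)),

  which the simulation is verified against. Cross-site depletion (a
  distance-decaying fraction of the local depletion) is available but off
  by default, keeping the deviant/MSC contrast clean.
* An event is a **contextual deviant** iff its role is `deviant` inside an
  oddball/predictable sequence; MSC events never receive the γ_dev boost.
  Periodicity attenuation is a sequence-level flag rather than an online
  predictor: the experiments establish the phenomenon, not its mechanism,
  and the pipeline only needs to detect the imposed difference.

Default parameters (all configurable): baseline 2 Hz per channel; early
amplitude 2 spikes/stimulus at distance 0 with 150 µm decay length,
latency 2.5 ms, width 0.9 ms (kernel peak ≈ 3.4 ms, > 99.9% of mass inside
0–10 ms); late amplitude 3 spikes/stimulus at full resource, latency
11 ms, width 14 ms (kernel peak 25 ms, matching the later deviant peak
latencies seen experimentally, ≈ 99.9% of mass inside 11–150 ms);
depletion 0.2 per stimulus with τ = 5 s; γ_dev = 0.5; γ_reg = 0.3;
g_nmda = 1 (0 models full NMDA-receptor blockade, which abolishes the
late component and leaves the early one untouched). The deviance boost
and regularity attenuation have no experimentally reported effect sizes
and are free choices of this package, sized so the standard→deviant and
periodic→random contrasts are comfortably larger than Monte-Carlo noise
at protocol scale (600 events, tens of channels). The early decay length
is set so the direct response, while concentrated inside the
15-electrode proximity radius (262 µm), remains measurable across the
full 15/30/45/60-electrode ring span, as observed in the recordings this
generator emulates.

The generator deliberately omits network bursts/avalanches, biophysical
membrane dynamics, connectivity structure, electrode impedance variation
and spike-waveform diversity. Passing tests therefore demonstrate that
the *pipeline* recovers imposed effects of realistic size under Poisson
variability — not that real cultures obey this generative model.

Randomness: one top-level seed feeds a `SeedSequence` that spawns
independent Philox streams for the baseline, early and late components.
Changing a late-phase parameter (e.g. g_nmda) leaves the simulated
baseline and early spikes bit-identical, which makes ablation contrasts
exact rather than statistical where possible.

Raw-trace synthesis renders a spike table as white Gaussian noise plus a
biphasic spike template (negative peak aligned to the rounded sample
index) plus a smooth stimulation-artifact transient confined to < 1 ms
after each physical onset.

## Preprocessing

Zero-phase (forward–backward) Butterworth bandpass, 300–3,000 Hz, order 2
per pass — zero-phase so spike latencies are unbiased. Detection is
negative threshold crossings at k = 5 times the robust noise SD (median
absolute deviation / 0.6745) with a 1 ms refractory period; the detector
and threshold of the original recordings are unreported, so this standard
configuration is explicit and configurable, and exact replication of
recorded spike counts is not claimed. The 1 ms post-stimulus window after
every physical stimulus is excluded (artifact blanking); omissions blank
nothing.

## Statistics

Paired Wilcoxon signed-rank throughout. Zero differences are dropped;
absolute differences are midranked. For n ≤ 25 effective pairs the null
tail of W+ is enumerated exactly by a generating-polynomial recursion
over doubled (integer) midranks; above that a tie-corrected normal
approximation with continuity correction is used. Two-sided p doubles the
smaller tail, capped at 1. Bonferroni correction multiplies by the number
of simultaneous contrasts within one analysis; m is always explicit.

Spatial analyses classify channels by Euclidean distance in units of the
electrode pitch ("electrode lengths" is taken as Euclidean; the
alternative Chebyshev reading is rejected as a design decision):
proximity uses closed 15-electrode balls with overlap resolved to the
nearer site (ties to standard); rings are annuli [0, 15], (15, 30],
(30, 45], (45, 60] with an explicit overflow ring. Stimulation-site
separation bands are small 18–40 µm, medium 41–68 µm, large 69–175 µm
with inclusive printed endpoints (upper edges split adjacent bands);
separations outside 18–175 µm are flagged out of range.

Per-site predictability preference: trial-level late-window counts are
paired by within-condition trial order between the random and periodic
runs; each site gets a two-sided signed-rank test at α = 0.05 and, if
significant, is labeled by the sign of its median paired difference.
Per-culture z-scoring (joint pooling over sites and conditions, n−1 SD)
removes baseline-rate differences between cultures and, being monotone
within a culture, does not change the classification. The replica
experiment for this contrast runs the generator with depletion switched
off: with adaptation on, position-paired trials differ through
sequence-specific adaptation histories (e.g. the extra recovery a
standard site gets while a deviant is delivered elsewhere), which is a
confound of the paired test rather than part of the regularity
phenomenon being measured.

## Numerical conventions and degenerate inputs

* Indices, peak latency on an all-zero window, and tests with all-zero
  differences return NaN/flagged results rather than raising.
* Exact-count designs reject probabilities that do not divide the event
  count, instructing the caller to adjust n.
* A zero-SD baseline makes any positive post-stimulus bin count toward
  the response duration.
* Ties in peak latency and group selection break to the earliest bin /
  lowest group id.
* Event tables, spike tables and PSTHs are plain TSV; raw recordings are
  HDF5 (`/traces`, `/onsets`, `/channels`). Onsets and spike times are
  written at 6 decimals and round-trip losslessly at protocol time grids.

## Problem sizes

Replica experiments default to the protocol's 600 events at 500 ms ISI
with channel counts in the dozens (16–64 depending on the analysis), 20
simulated cultures for index recovery, 8 for the ring profile and 500
sites for the preference contrast. These sizes keep Monte-Carlo standard
errors several times smaller than the imposed effects while the whole
replica suite runs in well under a minute on one core.

## Known limitations

* The generator's late component is spatially uniform, so spatial "no
  ring effect in the late phase" checks are verifying an imposed
  property, not discovering one.
* Omission responses are absent by construction (omitted events evoke
  nothing), mirroring the experimental finding rather than testing it.
* The adaptation model is a single multiplicative resource per site;
  threshold adaptation, bursting and cross-frequency dynamics are out of
  scope.
* Channel-level analysis ignores that one electrode may see several
  neurons; all conclusions are about channel threshold crossings.
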