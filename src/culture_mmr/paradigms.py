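"""Stimulation paradigms as explicit, seeded event sequences.

Every protocol used in the analysis is generated here as an ordered table of
stimulation events: the oddball paradigm (frequent standard, rare deviant,
9:1 by default), its omission variant (the rare event is the *absence* of a
stimulus), the many-standards control (MSC: 10 sites each at 10%, matching
the deviant's rarity without contextual deviance), the predictable-deviant
paradigm (periodic vs. random deviant placement at 5/10/20%), and the
recovery- and repetition-count protocols used to probe adaptation dynamics.

All probability parameters use exact-count allocation rather than Bernoulli
draws: a 600-event oddball at p = 0.1 contains exactly 60 deviants in a
uniformly random order determined by the seed.  Role counts are therefore
identical across seeds, and the same seed reproduces the same event table
byte-for-byte.

Event tables are plain tab-separated text with columns
``onset_s  col  row  role  physical  run_id  paradigm`` and round-trip
losslessly through :func:`write_events` / :func:`read_events`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import ElectrodeId

ROLE_STANDARD = "standard"
ROLE_DEVIANT = "deviant"
ROLE_OMITTED = "omitted"
ROLE_MSC = "msc"
ROLES = (ROLE_STANDARD, ROLE_DEVIANT, ROLE_OMITTED, ROLE_MSC)

EVENT_COLUMNS = ["onset_s", "col", "row", "role", "physical", "run_id", "paradigm"]


@dataclass
class StimulusSequence:
    """An ordered run of stimulation events.

    ``events`` is a DataFrame with the :data:`EVENT_COLUMNS` schema, onsets
    strictly increasing.  ``mode`` is ``"periodic"`` or ``"random"`` for the
    predictable-deviant paradigm and ``None`` otherwise.  ``probe_index`` /
    ``blocks`` carry protocol structure for the recovery and
    repetition-count protocols.
    """

    events: pd.DataFrame
    isi_s: float
    mode: Optional[str] = None
    rest_between_runs_s: Optional[float] = None
    probe_index: Optional[int] = None
    blocks: Optional[list] = None  # list of (start_index, n_standards)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def duration_s(self) -> float:
        """Nominal run duration: one ISI per event."""
        return self.n_events * self.isi_s

    def role_counts(self) -> dict:
        return self.events["role"].value_counts().to_dict()

    def sites(self) -> list[ElectrodeId]:
        """Distinct stimulation sites in order of first appearance."""
        seen: dict[ElectrodeId, None] = {}
        for c, r in zip(self.events["col"], self.events["row"]):
            seen.setdefault((int(c), int(r)), None)
        return list(seen)


@dataclass(frozen=True)
class FlipFlopDesign:
    """Paired-run design in which standard and deviant roles are swapped.

    ``site_triplet`` holds the three candidate stimulation sites; the six
    ordered pairs of distinct sites enumerate every standard/deviant
    assignment.  Between the two runs of a pair the cultures rest for
    ``rest_between_runs_s`` (default 300 s = 5 min).
    """

    site_triplet: Tuple[ElectrodeId, ElectrodeId, ElectrodeId]
    rest_between_runs_s: float = 300.0

    def __post_init__(self) -> None:
        if len(set(self.site_triplet)) != 3:
            raise ValueError("site_triplet must contain 3 distinct sites")

    @property
    def assignments(self) -> list[Tuple[ElectrodeId, ElectrodeId]]:
        """All 6 ordered (standard_site, deviant_site) pairs."""
        return list(itertools.permutations(self.site_triplet, 2))


def _rng(seed: int) -> np.random.Generator:
    # Philox is counter-based, so identical seeds give identical sequences
    # across platforms and numpy versions.
    return np.random.Generator(np.random.Philox(seed))


def _exact_count(n_events: int, p: float, what: str) -> int:
    if not 0 < p < 1:
        raise ValueError(f"{what} probability must be in (0, 1), got {p}")
    c = n_events * p
    k = round(c)
    if abs(c - k) > 1e-9:
        raise ValueError(
            f"n_events * {what} probability = {c} is not an integer; "
            f"adjust n_events so the design allocates exact counts"
        )
    if k == 0:
        raise ValueError(f"{what} count is 0; increase n_events or probability")
    return int(k)


def _events_frame(
    onsets: np.ndarray,
    sites: Sequence[ElectrodeId],
    roles: Sequence[str],
    run_id: int,
    paradigm: str,
) -> pd.DataFrame:
    cols = [int(s[0]) for s in sites]
    rows = [int(s[1]) for s in sites]
    physical = [r != ROLE_OMITTED for r in roles]
    return pd.DataFrame(
        {
            "onset_s": np.asarray(onsets, dtype=float),
            "col": cols,
            "row": rows,
            "role": list(roles),
            "physical": physical,
            "run_id": run_id,
            "paradigm": paradigm,
        }
    )


def make_oddball(
    sites: Tuple[ElectrodeId, ElectrodeId],
    n_events: int = 600,
    p_deviant: float = 0.1,
    isi_s: float = 0.5,
    seed: int = 0,
    run_id: int = 1,
) -> StimulusSequence:
    """Oddball run: frequent standard at one site, rare deviant at another.

    Exactly ``round(n_events * p_deviant)`` deviants are placed in a
    uniformly random order determined by *seed*; onsets sit on a fixed
    ``isi_s`` grid starting at 0.
    """
    std_site, dev_site = sites
    if tuple(std_site) == tuple(dev_site):
        raise ValueError("standard and deviant sites must differ")
    n_dev = _exact_count(n_events, p_deviant, "deviant")
    roles = np.array([ROLE_STANDARD] * (n_events - n_dev) + [ROLE_DEVIANT] * n_dev)
    roles = _rng(seed).permutation(roles)
    site_list = [dev_site if r == ROLE_DEVIANT else std_site for r in roles]
    onsets = np.arange(n_events) * isi_s
    ev = _events_frame(onsets, site_list, roles, run_id, "oddball")
    return StimulusSequence(events=ev, isi_s=isi_s)


def make_omission(
    standard_site: ElectrodeId,
    n_events: int = 600,
    p_omitted: float = 0.1,
    isi_s: float = 0.5,
    seed: int = 0,
    run_id: int = 1,
) -> StimulusSequence:
    """Omission run: rare events are silent gaps on the same onset grid.

    Omitted events keep their nominal onset time but are flagged
    non-physical; downstream stages deliver no stimulus, no artifact and no
    evoked response at these slots, while omission responses can still be
    measured against the nominal onsets.
    """
    # The omitted "site" is recorded as the standard site: the omission is
    # the absence of that stimulus.
    n_om = _exact_count(n_events, p_omitted, "omitted")
    roles = np.array([ROLE_STANDARD] * (n_events - n_om) + [ROLE_OMITTED] * n_om)
    roles = _rng(seed).permutation(roles)
    site_list = [standard_site] * n_events
    onsets = np.arange(n_events) * isi_s
    ev = _events_frame(onsets, site_list, roles, run_id, "omission")
    return StimulusSequence(events=ev, isi_s=isi_s)


def make_flipflop_pair(
    design: FlipFlopDesign,
    sites: Tuple[ElectrodeId, ElectrodeId],
    n_events: int = 600,
    p_deviant: float = 0.1,
    isi_s: float = 0.5,
    seed: int = 0,
) -> Tuple[StimulusSequence, StimulusSequence]:
    """Two oddball runs with standard and deviant roles swapped.

    *sites* must be an ordered pair of distinct sites from the design's
    triplet; run 1 uses them as (standard, deviant), run 2 swaps them.
    """
    a, b = tuple(sites[0]), tuple(sites[1])
    triplet = {tuple(s) for s in design.site_triplet}
    if a == b:
        raise ValueError("flip-flop sites must be distinct")
    if not {a, b} <= triplet:
        raise ValueError("flip-flop sites must come from the design triplet")
    run1 = make_oddball((a, b), n_events, p_deviant, isi_s, seed=seed, run_id=1)
    run2 = make_oddball((b, a), n_events, p_deviant, isi_s, seed=seed + 1, run_id=2)
    run1.rest_between_runs_s = design.rest_between_runs_s
    run2.rest_between_runs_s = design.rest_between_runs_s
    return run1, run2


def make_msc(
    sites: Sequence[ElectrodeId],
    n_events: int = 600,
    isi_s: float = 0.5,
    seed: int = 0,
    run_id: int = 1,
) -> StimulusSequence:
    """Many-standards control: 10 sites, each at exactly 10% probability.

    Every event carries the ``msc`` role; each site appears exactly
    ``n_events / 10`` times in a uniformly random order.
    """
    sites = [tuple(s) for s in sites]
    if len(sites) != 10:
        raise ValueError(f"MSC paradigm requires exactly 10 sites, got {len(sites)}")
    if len(set(sites)) != 10:
        raise ValueError("MSC sites must be distinct")
    if n_events % 10 != 0:
        raise ValueError(f"n_events must be divisible by 10, got {n_events}")
    reps = n_events // 10
    site_list = [s for s in sites for _ in range(reps)]
    order = _rng(seed).permutation(n_events)
    site_list = [site_list[i] for i in order]
    onsets = np.arange(n_events) * isi_s
    ev = _events_frame(onsets, site_list, [ROLE_MSC] * n_events, run_id, "msc")
    return StimulusSequence(events=ev, isi_s=isi_s)


def make_predictable(
    sites: Tuple[ElectrodeId, ElectrodeId],
    n_events: int = 600,
    p_deviant: float = 0.1,
    mode: str = "random",
    isi_s: float = 0.5,
    seed: int = 0,
    run_id: int = 1,
    min_gap: int = 0,
) -> StimulusSequence:
    """Predictable-deviant run: periodic vs. random deviant placement.

    In ``periodic`` mode the deviant occupies every ``1/p_deviant``-th
    position (1-based), so every deviant is preceded by exactly
    ``1/p - 1`` standards.  In ``random`` mode the same number of deviants
    lands in uniformly random positions.  ``min_gap=1`` optionally forbids
    adjacent deviants in random mode (off by default).
    """
    if mode not in ("periodic", "random"):
        raise ValueError(f"mode must be 'periodic' or 'random', got {mode!r}")
    std_site, dev_site = tuple(sites[0]), tuple(sites[1])
    if std_site == dev_site:
        raise ValueError("standard and deviant sites must differ")
    period = 1.0 / p_deviant
    if abs(period - round(period)) > 1e-9:
        raise ValueError(f"1/p_deviant must be an integer, got 1/{p_deviant}")
    period = int(round(period))
    if n_events % period != 0:
        raise ValueError(f"n_events={n_events} not divisible by period {period}")
    n_dev = n_events // period
    roles = np.array([ROLE_STANDARD] * n_events, dtype=object)
    if mode == "periodic":
        roles[period - 1 :: period] = ROLE_DEVIANT
    else:
        rng = _rng(seed)
        while True:
            pos = rng.choice(n_events, size=n_dev, replace=False)
            pos.sort()
            if min_gap == 0 or np.all(np.diff(pos) > min_gap):
                break
        roles[pos] = ROLE_DEVIANT
    site_list = [dev_site if r == ROLE_DEVIANT else std_site for r in roles]
    onsets = np.arange(n_events) * isi_s
    ev = _events_frame(onsets, site_list, roles, run_id, f"predictable-{mode}")
    return StimulusSequence(events=ev, isi_s=isi_s, mode=mode)


def make_recovery_protocol(
    site: ElectrodeId,
    n_conditioning: int = 20,
    conditioning_isi_s: float = 0.5,
    recovery_times_s: Sequence[float] = (0.5, 1.5, 2.5, 4.5, 6.5, 8.5, 10.5),
    interposed: Optional[ElectrodeId] = None,
    seed: int = 0,
) -> list[StimulusSequence]:
    """Adaptation-recovery protocol.

    Each returned sequence delivers ``n_conditioning`` identical stimuli at
    ``conditioning_isi_s``, then a probe at the same site after the given
    recovery interval — the probe is the (n_conditioning+1)-th stimulus at
    that site.  If *interposed* names a different site, stimuli at that site
    fill the recovery gap on the conditioning ISI grid (starting one ISI
    after the last conditioning stimulus, ending strictly before the probe).
    """
    if n_conditioning < 1:
        raise ValueError("n_conditioning must be >= 1")
    site = tuple(site)
    if interposed is not None:
        interposed = tuple(interposed)
        if interposed == site:
            raise ValueError("interposed site must differ from the conditioning site")
    out = []
    for rec in recovery_times_s:
        if rec < conditioning_isi_s:
            raise ValueError(
                f"recovery time {rec} s shorter than conditioning ISI "
                f"{conditioning_isi_s} s"
            )
        onsets = list(np.arange(n_conditioning) * conditioning_isi_s)
        sites_l = [site] * n_conditioning
        roles = [ROLE_STANDARD] * n_conditioning
        last = onsets[-1]
        probe_onset = last + rec
        if interposed is not None:
            t = last + conditioning_isi_s
            while t < probe_onset - 1e-9:
                onsets.append(t)
                sites_l.append(interposed)
                roles.append(ROLE_STANDARD)
                t += conditioning_isi_s
        onsets.append(probe_onset)
        sites_l.append(site)
        roles.append(ROLE_STANDARD)
        ev = _events_frame(np.asarray(onsets), sites_l, roles, 1, "recovery")
        out.append(
            StimulusSequence(
                events=ev,
                isi_s=conditioning_isi_s,
                probe_index=len(onsets) - 1,
            )
        )
    return out


def make_repetition_protocol(
    sites: Tuple[ElectrodeId, ElectrodeId],
    counts_of_standards_before_deviant: Sequence[int],
    isi_s: float = 0.5,
    seed: int = 0,
) -> StimulusSequence:
    """Repetition-count protocol: blocks of k standards followed by a deviant.

    Block order is randomised by *seed*; block boundaries are recorded on
    the returned sequence as ``blocks = [(start_index, k), ...]``.
    """
    std_site, dev_site = tuple(sites[0]), tuple(sites[1])
    if std_site == dev_site:
        raise ValueError("standard and deviant sites must differ")
    counts = list(counts_of_standards_before_deviant)
    if any(k < 0 for k in counts):
        raise ValueError("standard counts must be >= 0")
    order = _rng(seed).permutation(len(counts))
    roles: list[str] = []
    sites_l: list[ElectrodeId] = []
    blocks: list[Tuple[int, int]] = []
    for i in order:
        k = counts[i]
        blocks.append((len(roles), k))
        roles.extend([ROLE_STANDARD] * k)
        sites_l.extend([std_site] * k)
        roles.append(ROLE_DEVIANT)
        sites_l.append(dev_site)
    onsets = np.arange(len(roles)) * isi_s
    ev = _events_frame(onsets, sites_l, roles, 1, "repetition")
    return StimulusSequence(events=ev, isi_s=isi_s, blocks=blocks)


# Event-table I/O ---------------------------------------------------------


def write_events(seq: StimulusSequence, path) -> None:
    """Write the event table as TSV (6-decimal onsets, stable formatting)."""
    df = seq.events.copy()
    df["onset_s"] = df["onset_s"].map(lambda v: f"{v:.6f}")
    df["physical"] = df["physical"].map(lambda v: "true" if v else "false")
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> StimulusSequence:
    """Read a TSV event table written by :func:`write_events`."""
    df = pd.read_csv(path, sep="\t", dtype={"role": str, "paradigm": str})
    df["onset_s"] = df["onset_s"].astype(float)
    df["physical"] = df["physical"].map(
        lambda v: str(v).strip().lower() in ("true", "1")
    )
    onsets = df["onset_s"].to_numpy()
    isi = float(np.median(np.diff(onsets))) if len(df) > 1 else 0.5
    mode = None
    paradigms = set(df["paradigm"])
    if paradigms and next(iter(paradigms)).startswith("predictable-"):
        mode = next(iter(paradigms)).split("-", 1)[1]
    return StimulusSequence(events=df[EVENT_COLUMNS], isi_s=isi, mode=mode)
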