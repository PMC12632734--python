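"""Synthetic spike-train sessions with the statistical structure the analyses assume.

Two families of generators live here.

*Surrogate Poisson populations* reproduce the validation design for the
population-ISI silence statistic: small populations (2-20 neurons, 10-20
trials of 3 s) of homogeneous Poisson trains with per-neuron rates drawn from
a discrete uniform 1-20 Hz, optionally with 1-3 coordinated 100 ms silent
windows deleted per trial.  Both variants (with / without silences) share the
same base spikes, so they form a paired construction.

*Tuned ODR sessions* emulate a recorded session: a population of neurons with
von Mises location tuning active from cue onset through the response epoch,
Poisson spiking, optional coordinated on/off gating of the tuned modulation
during the delay (the ground truth for state-detection recovery tests), and a
simple behavioral model linking reaction time and accuracy to the gating
state.

Everything is driven by numpy Generators; a fixed seed reproduces spike
tables exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CANONICAL_ANGLES_DEG, EpochSpec, SpikeDataset


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TuningSpec:
    """Von Mises tuning of the cue/delay firing rate.

    rate(theta) = baseline * (1 + (gain - 1) * exp(kappa * (cos(theta - pref) - 1)))
    so the peak multiplier at the preferred angle is exactly ``gain`` and the
    modulation decays to baseline for anti-preferred cues.
    """

    kappa: float = 2.0
    gain: float = 3.0
    pref_distribution: str = "uniform"  # uniform over [0, 360)


@dataclass
class SilenceSpec:
    n_min: int = 1
    n_max: int = 3
    duration_s: float = 0.1
    coordinated: bool = True  # shared across neurons within a trial


@dataclass
class OffGatingSpec:
    enabled: bool = False
    rate_hz: float = 0.5  # on+off alternation cycles per second
    off_duty: float = 0.3  # fraction of a cycle spent in the off state
    off_multiplier: float = 0.0  # scales tuned modulation during off states
    shared_across_areas: bool = True

    @property
    def mean_on_s(self) -> float:
        return (1.0 - self.off_duty) / self.rate_hz

    @property
    def mean_off_s(self) -> float:
        return self.off_duty / self.rate_hz


@dataclass
class RTModel:
    base_ms: float = 250.0
    beta_state_ms: float = 0.0  # RT_on - RT_off
    noise_sd_ms: float = 30.0
    p_error_base: float = 0.05
    p_error_off_slope: float = 0.4  # added error prob per unit off-fraction in last 0.5 s


@dataclass
class SimConfig:
    n_neurons: int = 100
    n_trials_per_location: int = 20
    baseline_rate_range: tuple[int, int] = (1, 20)  # discrete uniform, Hz
    tuning: TuningSpec = field(default_factory=TuningSpec)
    silences: SilenceSpec = field(default_factory=SilenceSpec)
    off_gating: OffGatingSpec = field(default_factory=OffGatingSpec)
    rt_model: RTModel = field(default_factory=RTModel)
    areas: dict | None = None  # e.g. {"PFC": 90, "PPC": 90}; None -> all PFC
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_neurons <= 0 or self.n_trials_per_location <= 0:
            raise ValueError("counts must be positive")
        if self.baseline_rate_range[0] <= 0:
            raise ValueError("rates must be positive")
        if self.tuning.kappa < 0 or self.tuning.gain < 1:
            raise ValueError("kappa must be >= 0 and gain >= 1")
        if not (0.0 <= self.off_gating.off_multiplier <= 1.0):
            raise ValueError("off multiplier must lie in [0, 1]")
        if self.silences.duration_s <= 0:
            raise ValueError("silence duration must be positive")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# surrogate Poisson populations (ISI validation design)


@dataclass
class PopulationTrains:
    """Ragged container of per-neuron, per-trial spike times in [0, duration)."""

    trains: list  # trains[neuron][trial] -> np.ndarray
    duration_s: float
    silences: list | None = None  # per trial: list of (start, end) windows

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    @property
    def n_trials(self) -> int:
        return len(self.trains[0]) if self.trains else 0

    def total_spikes(self) -> int:
        return int(sum(len(t) for row in self.trains for t in row))


def _poisson_times(rate_hz: float, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _delete_in_windows(times: np.ndarray, windows: Sequence[tuple[float, float]]) -> np.ndarray:
    if len(times) == 0 or not windows:
        return times
    keep = np.ones(len(times), dtype=bool)
    for a, b in windows:
        keep &= ~((times >= a) & (times < b))
    return times[keep]


def simulate_surrogate_population(
    rng: np.random.Generator,
    n_neurons: int | None = None,
    n_trials: int | None = None,
    duration_s: float = 3.0,
    rate_range: tuple[int, int] = (1, 20),
    silences: SilenceSpec | None = None,
) -> tuple[PopulationTrains, PopulationTrains]:
    """One surrogate population in both variants (without, with silences).

    Neuron and trial counts default to the validation design draws
    U{2..20} and U{10..20}.  The with-silence variant deletes the base
    variant's spikes inside each trial's silent windows; in coordinated mode
    the windows are shared by all neurons of the trial.
    """
    if silences is None:
        silences = SilenceSpec()
    if n_neurons is None:
        n_neurons = int(rng.integers(2, 21))
    if n_trials is None:
        n_trials = int(rng.integers(10, 21))
    rates = rng.integers(rate_range[0], rate_range[1] + 1, size=n_neurons)

    base = [
        [_poisson_times(float(rates[i]), duration_s, rng) for _ in range(n_trials)]
        for i in range(n_neurons)
    ]

    def draw_windows() -> list[tuple[float, float]]:
        k = int(rng.integers(silences.n_min, silences.n_max + 1))
        starts = rng.uniform(0.0, duration_s, size=k)
        return [(s, min(s + silences.duration_s, duration_s)) for s in starts]

    if silences.coordinated:
        trial_windows = [draw_windows() for _ in range(n_trials)]
        silenced = [
            [_delete_in_windows(base[i][t], trial_windows[t]) for t in range(n_trials)]
            for i in range(n_neurons)
        ]
    else:
        trial_windows = []
        silenced = []
        for i in range(n_neurons):
            row = []
            for t in range(n_trials):
                w = draw_windows()
                trial_windows.append(w)
                row.append(_delete_in_windows(base[i][t], w))
            silenced.append(row)

    without = PopulationTrains([list(r) for r in base], duration_s, silences=None)
    with_sil = PopulationTrains(silenced, duration_s, silences=trial_windows)
    return without, with_sil


def trains_to_dataset(pop: PopulationTrains, area: str = "PFC") -> SpikeDataset:
    """Embed a surrogate population into the ODR trial frame.

    The 3 s trains are mapped onto the delay period [0.5, 3.5) s; cue location
    is a placeholder 0 degrees for every trial.
    """
    delay0 = EpochSpec().delay[0]
    recs = []
    for i, row in enumerate(pop.trains):
        for t, times in enumerate(row):
            for s in times:
                recs.append((i, t, delay0 + s))
    spikes = pd.DataFrame(recs, columns=["unit_id", "trial_id", "time_s"])
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(pop.n_trials),
            "cue_location_deg": 0.0,
            "correct": True,
            "rt_ms": np.nan,
        }
    )
    units = pd.DataFrame(
        {
            "unit_id": np.arange(pop.n_neurons),
            "area": area,
            "depth_mm": 0.0,
            "kind": "single",
        }
    )
    return SpikeDataset(spikes, trials, units, meta={"generator": "surrogate"}).validate()


def simulate_poisson_population(
    cfg: SimConfig | None = None, rng: np.random.Generator | None = None
) -> tuple[SpikeDataset, SpikeDataset]:
    """Surrogate population as a pair of SpikeDatasets (without, with silences)."""
    cfg = (cfg or SimConfig()).validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    without, with_sil = simulate_surrogate_population(
        rng, rate_range=cfg.baseline_rate_range, silences=cfg.silences
    )
    ds_without = trains_to_dataset(without)
    ds_with = trains_to_dataset(with_sil)
    ds_with.meta["silent_windows"] = with_sil.silences
    return ds_without, ds_with


# ---------------------------------------------------------------------------
# tuned ODR sessions


def tuning_gain(theta_deg, pref_deg, kappa: float, gain: float, multiplier: float = 1.0):
    """Multiplicative rate modulation for a cue at ``theta_deg``."""
    d = np.deg2rad(np.asarray(theta_deg, dtype=float) - np.asarray(pref_deg, dtype=float))
    f = np.exp(kappa * (np.cos(d) - 1.0))
    return 1.0 + multiplier * (gain - 1.0) * f


def simulate_tuned_session(
    cfg: SimConfig | None = None, rng: np.random.Generator | None = None
) -> SpikeDataset:
    """A tuned ODR session: baseline Poisson in fixation, von Mises-tuned
    Poisson from cue onset through the response epoch.

    Ground-truth tuning parameters are stored in ``meta["truth"]`` so recovery
    tests can compare estimates with the generative values.
    """
    cfg = (cfg or SimConfig()).validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    epochs = EpochSpec()

    areas = cfg.areas or {"PFC": cfg.n_neurons}
    area_of = np.concatenate([[a] * n for a, n in areas.items()])
    n_units = len(area_of)

    baseline = rng.integers(
        cfg.baseline_rate_range[0], cfg.baseline_rate_range[1] + 1, size=n_units
    ).astype(float)
    if cfg.tuning.pref_distribution == "canonical":
        pref = rng.choice(CANONICAL_ANGLES_DEG, size=n_units)
    else:
        pref = rng.uniform(0.0, 360.0, size=n_units)
    depth = rng.uniform(0.0, 2.0, size=n_units)
    kind = np.where(rng.random(n_units) < 0.8, "single", "multi")

    locs = np.repeat(CANONICAL_ANGLES_DEG, cfg.n_trials_per_location)
    order = rng.permutation(len(locs))
    locs = locs[order]
    n_trials = len(locs)

    fix0, fix1 = epochs.fixation
    tune0, tune1 = epochs.cue[0], epochs.response[1]

    uid_col, tid_col, t_col = [], [], []
    for u in range(n_units):
        g = tuning_gain(locs, pref[u], cfg.tuning.kappa, cfg.tuning.gain)
        for t in range(n_trials):
            fix_sp = fix0 + _poisson_times(baseline[u], fix1 - fix0, rng)
            tuned_sp = tune0 + _poisson_times(baseline[u] * g[t], tune1 - tune0, rng)
            sp = np.concatenate([fix_sp, tuned_sp])
            uid_col.append(np.full(len(sp), u))
            tid_col.append(np.full(len(sp), t))
            t_col.append(sp)
    spikes = pd.DataFrame(
        {
            "unit_id": np.concatenate(uid_col).astype(int),
            "trial_id": np.concatenate(tid_col).astype(int),
            "time_s": np.concatenate(t_col),
        }
    ).sort_values(["unit_id", "trial_id", "time_s"], kind="stable").reset_index(drop=True)
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "cue_location_deg": locs,
            "correct": True,
            "rt_ms": np.nan,
        }
    )
    units = pd.DataFrame(
        {
            "unit_id": np.arange(n_units),
            "area": area_of,
            "depth_mm": depth,
            "kind": kind,
        }
    )
    truth = {
        "theta_pref_deg": pref.tolist(),
        "baseline_hz": baseline.tolist(),
        "kappa": cfg.tuning.kappa,
        "gain": cfg.tuning.gain,
    }
    ds = SpikeDataset(
        spikes, trials, units, epochs=epochs, meta={"generator": "tuned", "truth": truth}
    )
    return ds.validate()


def state_detection_session(
    seed: int = 0,
    gated: bool = True,
    shared_across_areas: bool = True,
    n_units_per_area: int = 15,
    n_trials_per_location: int = 50,
    gain: float = 8.0,
    kappa: float = 2.0,
    rate_hz: float = 0.25,
    off_duty: float = 0.3,
    off_multiplier: float = 0.0,
) -> tuple[SpikeDataset, dict | None]:
    """The canonical two-area session for on/off-state recovery studies.

    Two simultaneously recorded areas of strongly tuned units with many
    trials per location — the regime in which the label-shuffle null is
    tight enough for cluster-corrected state detection — optionally gated
    by a shared (or per-area independent) off-state train that flattens
    tuning (``off_multiplier`` 0) during off intervals of mean duration
    ``off_duty / rate_hz`` seconds.  Returns the session and the
    ground-truth off intervals (None when ungated).
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        n_neurons=2 * n_units_per_area,
        n_trials_per_location=n_trials_per_location,
        areas={"PFC": n_units_per_area, "PPC": n_units_per_area},
        tuning=TuningSpec(kappa=kappa, gain=gain),
        seed=seed,
    )
    ds = simulate_tuned_session(cfg, rng)
    if not gated:
        return ds, None
    gating = OffGatingSpec(
        enabled=True,
        rate_hz=rate_hz,
        off_duty=off_duty,
        off_multiplier=off_multiplier,
        shared_across_areas=shared_across_areas,
    )
    return impose_off_states(ds, gating, rng)


def gated_population_session(
    seed: int = 0,
    gated: bool = True,
    n_neurons: int = 200,
    n_trials_per_location: int = 18,
    gain: float = 2.5,
    kappa: float = 2.0,
    rate_hz: float = 0.25,
    off_duty: float = 0.4,
) -> SpikeDataset:
    """The canonical session for the simultaneous vs. pseudo-population
    contrast: many weakly tuned units (population-level accuracy near
    ceiling, per-unit signal small), with coordinated off-state gating
    shared by the whole population when ``gated``."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        n_neurons=n_neurons,
        n_trials_per_location=n_trials_per_location,
        tuning=TuningSpec(kappa=kappa, gain=gain),
        seed=seed,
    )
    ds = simulate_tuned_session(cfg, rng)
    if not gated:
        return ds
    gating = OffGatingSpec(enabled=True, rate_hz=rate_hz, off_duty=off_duty, off_multiplier=0.0)
    ds, truth = impose_off_states(ds, gating, rng)
    ds.meta["truth"]["off_intervals"] = truth
    return ds


def _alternating_states(
    rng: np.random.Generator,
    span: tuple[float, float],
    mean_on_s: float,
    mean_off_s: float,
) -> list[tuple[float, float]]:
    """Off intervals of an alternating on/off train with exponential dwell times."""
    t, t_end = span
    state_on = bool(rng.random() >= mean_off_s / (mean_on_s + mean_off_s))
    off: list[tuple[float, float]] = []
    while t < t_end:
        d = rng.exponential(mean_on_s if state_on else mean_off_s)
        seg_end = min(t + d, t_end)
        if not state_on and seg_end > t:
            off.append((t, seg_end))
        t = seg_end
        state_on = not state_on
    return off


def impose_off_states(
    ds: SpikeDataset,
    gating: OffGatingSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SpikeDataset, dict]:
    """Gate the tuned modulation during delay-period off states.

    Within each off interval the tuned part of the rate is scaled by
    ``off_multiplier`` (0 flattens tuning completely) while the baseline
    persists; spikes are thinned accordingly.  Off intervals alternate with on
    intervals (exponential dwell times, mean ``1/(2 rate_hz)``) and are shared
    by all neurons of an area; with ``shared_across_areas`` a single state
    train gates every area.

    Returns the gated dataset and the ground-truth off intervals per area:
    ``{area: {trial_id: [(start, end), ...]}}``.
    """
    gating = gating or OffGatingSpec(enabled=True)
    if not (0.0 <= gating.off_multiplier <= 1.0):
        raise ValueError("off multiplier must lie in [0, 1]")
    if "truth" not in ds.meta:
        raise ValueError("impose_off_states requires a tuned dataset with stored truth")
    if rng is None:
        rng = np.random.default_rng(0)
    truth = ds.meta["truth"]
    pref = np.asarray(truth["theta_pref_deg"])
    kappa, gain = truth["kappa"], truth["gain"]
    delay = ds.epochs.delay
    mean_on, mean_off = gating.mean_on_s, gating.mean_off_s

    areas = list(dict.fromkeys(ds.units["area"]))
    tids = ds.trial_ids
    truth_off: dict = {a: {} for a in areas}
    if gating.shared_across_areas:
        shared = {int(t): _alternating_states(rng, delay, mean_on, mean_off) for t in tids}
        for a in areas:
            truth_off[a] = {t: list(w) for t, w in shared.items()}
    else:
        for a in areas:
            truth_off[a] = {
                int(t): _alternating_states(rng, delay, mean_on, mean_off) for t in tids
            }

    loc_of = dict(
        zip(ds.trials["trial_id"], np.asarray(ds.trials["cue_location_deg"], dtype=float))
    )
    area_of = dict(zip(ds.units["unit_id"], ds.units["area"]))

    sp = ds.spikes
    u = sp["unit_id"].to_numpy()
    tr = sp["trial_id"].to_numpy()
    t = sp["time_s"].to_numpy()
    theta = np.array([loc_of[i] for i in tr])
    g_on = tuning_gain(theta, pref[u], kappa, gain)
    g_off = tuning_gain(theta, pref[u], kappa, gain, multiplier=gating.off_multiplier)
    p_keep = np.ones(len(sp))
    in_off = np.zeros(len(sp), dtype=bool)
    for a in areas:
        ua = np.array([area_of[i] == a for i in u])
        for tid, wins in truth_off[a].items():
            sel = ua & (tr == tid)
            if not sel.any():
                continue
            tt = t[sel]
            m = np.zeros(len(tt), dtype=bool)
            for w0, w1 in wins:
                m |= (tt >= w0) & (tt < w1)
            idx = np.where(sel)[0][m]
            in_off[idx] = True
    p_keep[in_off] = g_off[in_off] / g_on[in_off]
    keep = rng.random(len(sp)) < p_keep
    out = SpikeDataset(
        spikes=sp[keep].reset_index(drop=True),
        trials=ds.trials.copy(),
        units=ds.units.copy(),
        epochs=ds.epochs,
        meta={**ds.meta, "off_gating": asdict(gating)},
    )
    return out.validate(), truth_off


def off_fraction(windows: Sequence[tuple[float, float]], interval: tuple[float, float]) -> float:
    """Fraction of ``interval`` covered by the union of off windows."""
    a, b = interval
    if b <= a:
        return 0.0
    covered = 0.0
    cursor = a
    for w0, w1 in sorted(windows):
        lo, hi = max(w0, cursor), min(w1, b)
        if hi > lo:
            covered += hi - lo
            cursor = hi
    return min(1.0, covered / (b - a))


def simulate_behavior(
    ds: SpikeDataset,
    truth_off: dict | None,
    rt_model: RTModel | None = None,
    rng: np.random.Generator | None = None,
    area: str | None = None,
) -> SpikeDataset:
    """Attach reaction times and outcomes linked to the delay-end gating state.

    RT = base + beta_state * 1[state on at the go cue] + Gaussian noise.
    Error probability grows with the off-state fraction in the last 0.5 s of
    the delay.  With no gating truth, every trial counts as "on".
    """
    rt_model = rt_model or RTModel()
    if rng is None:
        rng = np.random.default_rng(0)
    delay_end = ds.epochs.delay[1]
    trials = ds.trials.copy()
    if truth_off:
        if area is None:
            area = next(iter(truth_off))
        wins_by_trial = truth_off[area]
    else:
        wins_by_trial = {}
    on_at_go = np.array(
        [
            not any(w0 <= delay_end - 1e-9 < w1 for w0, w1 in wins_by_trial.get(int(t), []))
            for t in trials["trial_id"]
        ]
    )
    off_frac = np.array(
        [
            off_fraction(wins_by_trial.get(int(t), []), (delay_end - 0.5, delay_end))
            for t in trials["trial_id"]
        ]
    )
    rt = (
        rt_model.base_ms
        + rt_model.beta_state_ms * on_at_go.astype(float)
        + rng.normal(0.0, rt_model.noise_sd_ms, size=len(trials))
    )
    p_err = np.clip(rt_model.p_error_base + rt_model.p_error_off_slope * off_frac, 0.0, 1.0)
    trials["rt_ms"] = rt
    trials["correct"] = rng.random(len(trials)) >= p_err
    trials["state_at_go"] = np.where(on_at_go, 1, 0)
    out = SpikeDataset(ds.spikes.copy(), trials, ds.units.copy(), ds.epochs, dict(ds.meta))
    return out.validate()
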