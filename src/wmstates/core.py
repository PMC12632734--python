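"""Trial-structured spike data and per-unit statistics.

The data model mirrors an oculomotor-delayed-response (ODR) session: a monkey
fixates for 1 s, a cue flashes for 0.5 s at one of eight locations spaced 45
degrees apart, a 3 s delay follows, and the animal saccades to the remembered
location.  Spike times are stored in seconds relative to cue onset, so the
fixation period is negative time and the delay period is [0.5, 3.5) s.

Three tables form a :class:`SpikeDataset`:

``spikes``  (unit_id, trial_id, time_s)
``trials``  (trial_id, cue_location_deg, correct, rt_ms)
``units``   (unit_id, area, depth_mm, kind)

On top of this the module provides the basic per-unit computations: sliding
binning, delay-period spatial selectivity (one-way ANOVA with a minimum-rate
gate), the spike-count-weighted circular mean that defines a neuron's
preferred location, laminar classification from recording depth, the
population rate conditioned on each neuron's preferred cue, and the
FDR-corrected test for delay-period rate elevation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CANONICAL_ANGLES_DEG = np.arange(0.0, 360.0, 45.0)
TRIAL_START_S = -1.0
TRIAL_END_S = 4.1


@dataclass(frozen=True)
class EpochSpec:
    """Half-open task epochs in seconds relative to cue onset."""

    fixation: tuple[float, float] = (-1.0, 0.0)
    cue: tuple[float, float] = (0.0, 0.5)
    delay: tuple[float, float] = (0.5, 3.5)
    response: tuple[float, float] = (3.5, 4.1)

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            "fixation": self.fixation,
            "cue": self.cue,
            "delay": self.delay,
            "response": self.response,
        }

    def validate(self) -> None:
        order = [self.fixation, self.cue, self.delay, self.response]
        for (a0, a1), (b0, b1) in zip(order, order[1:]):
            if not (a0 < a1 and a1 == b0):
                raise ValueError("epochs must be ordered, disjoint and contiguous")


def group_to_canonical(angles_deg: np.ndarray) -> np.ndarray:
    """Snap arbitrary cue angles to the nearest of the 8 canonical locations.

    Task variants present up to 120 equidistant cues; every analysis groups
    them into the 8 canonical 45-degree-spaced bins first.
    """
    a = np.asarray(angles_deg, dtype=float) % 360.0
    return (np.round(a / 45.0).astype(int) % 8) * 45.0


@dataclass
class SpikeDataset:
    """One session of trial-aligned extracellular spike data."""

    spikes: pd.DataFrame
    trials: pd.DataFrame
    units: pd.DataFrame
    epochs: EpochSpec = field(default_factory=EpochSpec)
    meta: dict = field(default_factory=dict)

    def validate(self) -> "SpikeDataset":
        for col in ("unit_id", "trial_id", "time_s"):
            if col not in self.spikes.columns:
                raise ValueError(f"spikes table missing column {col!r}")
        for col in ("trial_id", "cue_location_deg", "correct"):
            if col not in self.trials.columns:
                raise ValueError(f"trials table missing column {col!r}")
        for col in ("unit_id", "area", "depth_mm", "kind"):
            if col not in self.units.columns:
                raise ValueError(f"units table missing column {col!r}")
        if self.trials["trial_id"].duplicated().any():
            raise ValueError("duplicate trial_id in trials table")
        if self.units["unit_id"].duplicated().any():
            raise ValueError("duplicate unit_id in units table")
        if not set(self.spikes["unit_id"]).issubset(set(self.units["unit_id"])):
            orphan = set(self.spikes["unit_id"]) - set(self.units["unit_id"])
            raise ValueError(f"spikes reference unknown unit_id(s): {sorted(orphan)[:5]}")
        if not set(self.spikes["trial_id"]).issubset(set(self.trials["trial_id"])):
            orphan = set(self.spikes["trial_id"]) - set(self.trials["trial_id"])
            raise ValueError(f"spikes reference unknown trial_id(s): {sorted(orphan)[:5]}")
        t = self.spikes["time_s"].to_numpy()
        if len(t) and (t.min() < TRIAL_START_S or t.max() > TRIAL_END_S):
            raise ValueError(
                f"spike times outside trial bounds [{TRIAL_START_S}, {TRIAL_END_S}] s"
            )
        locs = np.asarray(self.trials["cue_location_deg"], dtype=float)
        if len(locs) and not np.isin(locs, CANONICAL_ANGLES_DEG).all():
            raise ValueError("cue locations must be grouped to the 8 canonical angles")
        if (np.asarray(self.units["depth_mm"], dtype=float) < 0).any():
            raise ValueError("unit depth_mm must be >= 0")
        self.epochs.validate()
        return self

    @property
    def unit_ids(self) -> np.ndarray:
        return self.units["unit_id"].to_numpy()

    @property
    def trial_ids(self) -> np.ndarray:
        return self.trials["trial_id"].to_numpy()

    def subset_units(self, unit_ids: Iterable) -> "SpikeDataset":
        keep = list(unit_ids)
        return SpikeDataset(
            spikes=self.spikes[self.spikes["unit_id"].isin(keep)].reset_index(drop=True),
            trials=self.trials.copy(),
            units=self.units[self.units["unit_id"].isin(keep)].reset_index(drop=True),
            epochs=self.epochs,
            meta=dict(self.meta),
        )

    def subset_trials(self, trial_ids: Iterable) -> "SpikeDataset":
        keep = list(trial_ids)
        return SpikeDataset(
            spikes=self.spikes[self.spikes["trial_id"].isin(keep)].reset_index(drop=True),
            trials=self.trials[self.trials["trial_id"].isin(keep)].reset_index(drop=True),
            units=self.units.copy(),
            epochs=self.epochs,
            meta=dict(self.meta),
        )


@dataclass
class BinnedRates:
    """Rate tensor (unit x trial x bin) in spikes/s on a sliding-bin grid."""

    rates: np.ndarray
    unit_ids: np.ndarray
    trial_ids: np.ndarray
    centers: np.ndarray
    width: float
    step: float

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]

    def bin_slice(self, interval: tuple[float, float]) -> np.ndarray:
        """Boolean mask of bins whose centers lie within the half-open interval."""
        return (self.centers >= interval[0]) & (self.centers < interval[1])


def n_bins_for(span: tuple[float, float], width: float, step: float) -> int:
    return int(math.floor((span[1] - span[0] - width) / step + 1e-9)) + 1


def bin_rates(
    ds: SpikeDataset,
    width: float = 0.05,
    step: float | None = None,
    span: tuple[float, float] = (TRIAL_START_S, TRIAL_END_S),
    unit_ids: Sequence | None = None,
    trial_ids: Sequence | None = None,
) -> BinnedRates:
    """Count spikes in (possibly overlapping) sliding bins and convert to rates.

    Bin ``b`` covers ``[span0 + b*step, span0 + b*step + width)``; the bin count
    is ``floor((span_length - width)/step) + 1``.
    """
    if step is None:
        step = width
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if span[0] < TRIAL_START_S - 1e-9 or span[1] > TRIAL_END_S + 1e-9:
        raise ValueError("span outside trial bounds")
    if len(ds.units) == 0 or len(ds.trials) == 0:
        raise ValueError("empty dataset")
    uids = np.asarray(unit_ids if unit_ids is not None else ds.unit_ids)
    tids = np.asarray(trial_ids if trial_ids is not None else ds.trial_ids)
    n_bins = n_bins_for(span, width, step)
    if n_bins < 1:
        raise ValueError("span shorter than one bin")
    starts = span[0] + step * np.arange(n_bins)
    counts = np.zeros((len(uids), len(tids), n_bins))

    uidx = pd.Series(np.arange(len(uids)), index=uids)
    tidx = pd.Series(np.arange(len(tids)), index=tids)
    sp = ds.spikes
    m = sp["unit_id"].isin(uidx.index) & sp["trial_id"].isin(tidx.index)
    sp = sp[m]
    ui = uidx[sp["unit_id"]].to_numpy()
    ti = tidx[sp["trial_id"]].to_numpy()
    t = sp["time_s"].to_numpy()

    # a spike can fall into ceil(width/step) overlapping bins
    n_sub = int(math.ceil(width / step - 1e-9))
    b_hi = np.floor((t - span[0]) / step + 1e-9).astype(int)
    for k in range(n_sub):
        b = b_hi - k
        ok = (b >= 0) & (b < n_bins) & (t >= starts[np.clip(b, 0, n_bins - 1)]) & (
            t < starts[np.clip(b, 0, n_bins - 1)] + width
        )
        np.add.at(counts, (ui[ok], ti[ok], b[ok]), 1.0)
    return BinnedRates(
        rates=counts / width,
        unit_ids=uids,
        trial_ids=tids,
        centers=starts + width / 2.0,
        width=width,
        step=step,
    )


def epoch_mean_rates(
    ds: SpikeDataset,
    epoch: tuple[float, float],
    unit_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Per-(unit, trial) mean firing rate (spikes/s) within an epoch.

    Returns a DataFrame indexed by unit_id with one column per trial_id.
    """
    uids = np.asarray(unit_ids if unit_ids is not None else ds.unit_ids)
    tids = ds.trial_ids
    dur = epoch[1] - epoch[0]
    if dur <= 0:
        raise ValueError("epoch must have positive duration")
    sp = ds.spikes
    m = (sp["time_s"] >= epoch[0]) & (sp["time_s"] < epoch[1]) & sp["unit_id"].isin(uids)
    sp = sp[m]
    counts = np.zeros((len(uids), len(tids)))
    uidx = pd.Series(np.arange(len(uids)), index=uids)
    tidx = pd.Series(np.arange(len(tids)), index=tids)
    np.add.at(counts, (uidx[sp["unit_id"]].to_numpy(), tidx[sp["trial_id"]].to_numpy()), 1.0)
    return pd.DataFrame(counts / dur, index=pd.Index(uids, name="unit_id"), columns=tids)


def classify_selectivity(
    ds: SpikeDataset,
    epoch: tuple[float, float] | None = None,
    alpha: float = 0.05,
    min_best_rate_hz: float = 2.0,
    kinds: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Flag spatially selective units: location ANOVA p < alpha and a best-location
    mean rate of at least ``min_best_rate_hz`` spikes/s.

    The ANOVA is a one-way test over the 8 cue-location groups of per-trial
    epoch-mean firing rates.  The rate gate guards against false positives in
    near-silent units.
    """
    if epoch is None:
        epoch = ds.epochs.delay
    units = ds.units
    if kinds is not None:
        units = units[units["kind"].isin(kinds)]
    uids = units["unit_id"].to_numpy()
    rates = epoch_mean_rates(ds, epoch, unit_ids=uids)  # unit x trial
    locs = group_to_canonical(ds.trials["cue_location_deg"].to_numpy())
    groups = []
    for ang in CANONICAL_ANGLES_DEG:
        idx = np.where(locs == ang)[0]
        if len(idx) < 2:
            raise ValueError(f"cue location {ang:.0f} deg has fewer than 2 trials")
        groups.append(idx)

    X = rates.to_numpy()
    k = len(groups)
    n = X.shape[1]
    gm = np.stack([X[:, g].mean(axis=1) for g in groups], axis=1)  # unit x k
    gn = np.array([len(g) for g in groups], dtype=float)
    grand = X.mean(axis=1)
    ss_between = ((gm - grand[:, None]) ** 2 * gn[None, :]).sum(axis=1)
    ss_total = ((X - grand[:, None]) ** 2).sum(axis=1)
    ss_within = ss_total - ss_between
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    p = np.where(np.isfinite(F), stats.f.sf(F, df_b, df_w), 1.0)
    p = np.where(ss_within <= 0, np.where(ss_between > 0, 0.0, 1.0), p)
    best = gm.max(axis=1)
    out = pd.DataFrame(
        {
            "unit_id": uids,
            "p_anova": p,
            "best_rate_hz": best,
            "selective": (p < alpha) & (best >= min_best_rate_hz),
        }
    )
    return out


@dataclass
class PreferredLocation:
    """Spike-count-weighted circular mean of the cue angles.

    ``theta_pref_deg`` is the angle of the complex resultant
    ``T = sum_j n_j exp(i theta_j) / sum_j n_j`` and ``modulus`` its length,
    a 0-1 index of tuning concentration.  ``defined`` is False when the
    resultant vanishes (perfectly symmetric counts).
    """

    theta_pref_deg: float
    modulus: float
    counts: np.ndarray
    angles_deg: np.ndarray
    defined: bool = True


def preferred_location(
    counts_by_location: Sequence[float],
    angles_deg: Sequence[float] | None = None,
) -> PreferredLocation:
    n = np.asarray(counts_by_location, dtype=float)
    ang = np.asarray(angles_deg if angles_deg is not None else CANONICAL_ANGLES_DEG, dtype=float)
    if n.shape != ang.shape:
        raise ValueError("counts and angles must have matching shape")
    if (n < 0).any():
        raise ValueError("spike counts must be non-negative")
    if n.sum() == 0:
        raise ValueError("no spikes; preferred location undefined")
    n = n / n.max()  # scale invariance; keeps subnormal counts finite
    z = np.sum(n * np.exp(1j * np.deg2rad(ang))) / n.sum()
    modulus = float(abs(z))
    if modulus < 1e-12:
        return PreferredLocation(float("nan"), 0.0, n, ang, defined=False)
    theta = float(np.rad2deg(np.angle(z)) % 360.0)
    return PreferredLocation(theta, modulus, n, ang)


def preferred_locations_table(
    ds: SpikeDataset, epoch: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Preferred location of every unit from mean delay spike counts per cue."""
    if epoch is None:
        epoch = ds.epochs.delay
    dur = epoch[1] - epoch[0]
    rates = epoch_mean_rates(ds, epoch)
    locs = group_to_canonical(ds.trials["cue_location_deg"].to_numpy())
    rows = []
    n_undefined = 0
    for uid, r in zip(rates.index, rates.to_numpy()):
        n_j = np.array(
            [
                r[locs == ang].mean() * dur if (locs == ang).any() else 0.0
                for ang in CANONICAL_ANGLES_DEG
            ]
        )
        if n_j.sum() == 0:
            rows.append((uid, np.nan, 0.0, np.nan, False))
            n_undefined += 1
            continue
        pref = preferred_location(n_j)
        canon = float(group_to_canonical(np.array([pref.theta_pref_deg]))[0]) if pref.defined else np.nan
        rows.append((uid, pref.theta_pref_deg, pref.modulus, canon, pref.defined))
        if not pref.defined:
            n_undefined += 1
    if n_undefined:
        logger.info("preferred location undefined for %d unit(s); excluded downstream", n_undefined)
    return pd.DataFrame(
        rows, columns=["unit_id", "theta_pref_deg", "modulus", "pref_canonical_deg", "defined"]
    )


def laminar_class(depth_mm):
    """Classify recording depth into cortical-layer bands.

    Depth is measured from the shallowest spiking contact.  Bands are
    half-open: superficial [0, 0.8), middle [0.8, 1.2), deep [1.2, inf).
    """
    d = np.asarray(depth_mm, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if (d < 0).any():
        raise ValueError("depth must be non-negative")
    out = np.where(d < 0.8, "superficial", np.where(d < 1.2, "middle", "deep"))
    return out.item() if scalar else out


def laminar_selectivity(ds: SpikeDataset, selectivity: pd.DataFrame) -> pd.DataFrame:
    """Proportion of selective units per laminar band."""
    merged = selectivity.merge(ds.units[["unit_id", "depth_mm"]], on="unit_id")
    merged["layer"] = laminar_class(merged["depth_mm"].to_numpy())
    g = merged.groupby("layer", observed=True)["selective"].agg(["sum", "count"])
    g["proportion"] = g["sum"] / g["count"]
    return g.reset_index().rename(columns={"sum": "n_selective", "count": "n_units"})


def population_rate_preferred(
    ds: SpikeDataset,
    width: float = 0.05,
    step: float | None = None,
    span: tuple[float, float] = (TRIAL_START_S, TRIAL_END_S),
    prefs: pd.DataFrame | None = None,
    state_masks: Mapping[str, np.ndarray] | None = None,
    state_trial_ids: Sequence | None = None,
    state_centers: np.ndarray | None = None,
) -> dict:
    """Population rate time course, each neuron contributing its preferred-cue trials.

    Returns bin centers and the across-(neuron, trial) mean rate.  When
    ``state_masks`` maps state names ("on"/"off") to boolean (trial x bin)
    arrays on the grid given by ``state_trial_ids``/``state_centers``, the
    returned dict additionally holds means restricted to bins carrying each
    label (computed on that grid).
    """
    if prefs is None:
        prefs = preferred_locations_table(ds)
    prefs = prefs[prefs["defined"]]
    if prefs.empty:
        raise ValueError("no unit with a defined preferred location")
    locs = group_to_canonical(ds.trials["cue_location_deg"].to_numpy())
    binned = bin_rates(ds, width=width, step=step, span=span)
    tpos = pd.Series(np.arange(len(binned.trial_ids)), index=binned.trial_ids)
    upos = pd.Series(np.arange(len(binned.unit_ids)), index=binned.unit_ids)

    traces = []
    skipped = 0
    per_unit_trials: list[tuple[int, np.ndarray]] = []
    for _, row in prefs.iterrows():
        tr = np.where(locs == row["pref_canonical_deg"])[0]
        if len(tr) == 0:
            skipped += 1
            continue
        ui = int(upos[row["unit_id"]])
        per_unit_trials.append((ui, tr))
        traces.append(binned.rates[ui][tr])
    if skipped:
        logger.warning("%d unit(s) had no trials at their preferred location; excluded", skipped)
    if not traces:
        raise ValueError("no (unit, preferred-trial) pairs available")
    stacked = np.concatenate(traces, axis=0)
    out = {"centers": binned.centers, "mean": stacked.mean(axis=0), "n_pairs": stacked.shape[0]}

    if state_masks is not None:
        if state_centers is None or state_trial_ids is None:
            raise ValueError("state grids require state_centers and state_trial_ids")
        stpos = pd.Series(np.arange(len(state_trial_ids)), index=state_trial_ids)
        sstep = state_centers[1] - state_centers[0] if len(state_centers) > 1 else 1.0
        # map each analysis bin center onto the state-grid bin containing it
        sbin = np.floor((binned.centers - state_centers[0]) / sstep + 0.5).astype(int)
        for name, mask in state_masks.items():
            num = np.zeros(binned.n_bins)
            den = np.zeros(binned.n_bins)
            valid_bin = (sbin >= 0) & (sbin < mask.shape[1])
            for ui, tr in per_unit_trials:
                for t in tr:
                    tid = binned.trial_ids[t]
                    if tid not in stpos.index:
                        continue
                    mrow = mask[int(stpos[tid])]
                    sel = valid_bin & mrow[np.clip(sbin, 0, mask.shape[1] - 1)]
                    num[sel] += binned.rates[ui, t, sel]
                    den[sel] += 1
            with np.errstate(invalid="ignore"):
                out[f"mean_{name}"] = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return out


def delay_elevation_test(
    ds: SpikeDataset,
    cue_location_deg: float,
    width: float = 0.05,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-bin test of delay-period population-rate elevation over fixation.

    For every 50 ms delay bin, a paired t-test across trials compares the
    population rate (mean over units) in that bin with the same trial's mean
    fixation rate; p-values are Benjamini-Hochberg corrected at level ``q``
    across the delay bins.
    """
    locs = group_to_canonical(ds.trials["cue_location_deg"].to_numpy())
    tids = ds.trial_ids[locs == group_to_canonical(np.array([cue_location_deg]))[0]]
    if len(tids) < 2:
        raise ValueError("need at least 2 trials at the requested cue location")
    delay = ds.epochs.delay
    binned = bin_rates(ds, width=width, step=width, span=delay, trial_ids=tids)
    pop = binned.rates.mean(axis=0)  # trial x bin
    fix = ds.epochs.fixation
    fix_rate = epoch_mean_rates(ds, fix)[tids].to_numpy().mean(axis=0)  # per trial
    tstat, p = stats.ttest_rel(pop, fix_rate[:, None], axis=0, alternative="greater")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame(
        {
            "bin_center_s": binned.centers,
            "t": tstat,
            "p": p,
            "p_fdr": p_adj,
            "significant": reject,
        }
    )
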