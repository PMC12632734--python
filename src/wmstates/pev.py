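"""Bias-corrected percentage of explained variance (omega squared).

omega^2 measures, per neuron and time bin, the share of firing-rate variance
attributable to the cue location in a one-way ANOVA decomposition:

    omega^2 = (SS_between - df * MSE) / (SS_total + MSE) * 100

with df = k - 1 (7 for the eight locations).  Unlike eta^2 it is unbiased
under the null, so its values may be negative; they are deliberately not
clipped, because downstream one-sample tests of "information > 0" rely on a
null centered at zero.  Trial counts are balanced across locations by
stratified downsampling to the smallest group before the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CANONICAL_ANGLES_DEG, BinnedRates, SpikeDataset, bin_rates, group_to_canonical


def omega_squared(groups: list[np.ndarray]) -> float:
    """Bias-corrected percent explained variance of a one-way layout.

    ``groups`` is a list of 1-D observation arrays, one per condition.
    Degenerate all-constant data returns 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 observations per group")
    x = np.concatenate(groups)
    n = len(x)
    k = len(groups)
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = ss_total - ss_between
    df = k - 1
    mse = ss_within / (n - k)
    denom = ss_total + mse
    if denom == 0.0:
        return 0.0
    return (ss_between - df * mse) / denom * 100.0


def _omega_squared_tensor(rates: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Vectorized omega^2 over a (unit, trial, bin) tensor with fixed groups."""
    n = rates.shape[1]
    k = len(group_idx)
    grand = rates.mean(axis=1)  # unit x bin
    ss_total = ((rates - grand[:, None, :]) ** 2).sum(axis=1)
    ss_between = np.zeros_like(ss_total)
    for idx in group_idx:
        gm = rates[:, idx, :].mean(axis=1)
        ss_between += len(idx) * (gm - grand) ** 2
    mse = (ss_total - ss_between) / (n - k)
    denom = ss_total + mse
    with np.errstate(invalid="ignore", divide="ignore"):
        w2 = (ss_between - (k - 1) * mse) / denom * 100.0
    return np.where(denom == 0.0, 0.0, w2)


def stratify_trials(
    trials: pd.DataFrame, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Balanced trial subset: every location downsampled (without replacement)
    to the smallest location count.  Returns the retained trial_ids.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    locs = group_to_canonical(trials["cue_location_deg"].to_numpy())
    tids = trials["trial_id"].to_numpy()
    sizes = {}
    for ang in CANONICAL_ANGLES_DEG:
        sizes[ang] = int((locs == ang).sum())
        if sizes[ang] == 0:
            raise ValueError(f"cue location {ang:.0f} deg has no trials")
    m = min(sizes.values())
    keep = []
    for ang in CANONICAL_ANGLES_DEG:
        idx = np.where(locs == ang)[0]
        keep.append(rng.choice(idx, size=m, replace=False))
    return np.sort(tids[np.concatenate(keep)])


@dataclass
class PEVResult:
    """Per-unit, per-bin omega^2 time courses on stratified trials."""

    omega2: np.ndarray  # unit x bin, percent
    unit_ids: np.ndarray
    centers: np.ndarray
    trial_ids: np.ndarray  # the stratified subset used for every bin

    def session_mean(self, unit_mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Across-unit mean and s.e.m. per bin."""
        w = self.omega2 if unit_mask is None else self.omega2[unit_mask]
        return w.mean(axis=0), w.std(axis=0, ddof=1) / np.sqrt(w.shape[0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, uid in enumerate(self.unit_ids):
            for b, c in enumerate(self.centers):
                rows.append((uid, c, self.omega2[i, b]))
        return pd.DataFrame(rows, columns=["unit_id", "bin_center_s", "omega2"])


def pev_timecourse(
    ds: SpikeDataset,
    width: float = 0.1,
    step: float = 0.05,
    span: tuple[float, float] | None = None,
    seed: int | np.random.Generator = 0,
    binned: BinnedRates | None = None,
) -> PEVResult:
    """omega^2 per unit in sliding bins (default 100 ms windows, 50 ms steps).

    Trials are stratified once per call, so the same balanced subset enters
    every bin.
    """
    keep = stratify_trials(ds.trials, seed)
    if binned is None:
        if span is None:
            span = (ds.epochs.fixation[0], ds.epochs.response[1])
        binned = bin_rates(ds, width=width, step=step, span=span, trial_ids=keep)
        rates = binned.rates
    else:
        pos = pd.Series(np.arange(len(binned.trial_ids)), index=binned.trial_ids)
        rates = binned.rates[:, pos[keep].to_numpy(), :]
    loc_of = dict(zip(ds.trials["trial_id"], group_to_canonical(ds.trials["cue_location_deg"].to_numpy())))
    locs = np.array([loc_of[t] for t in keep])
    group_idx = [np.where(locs == ang)[0] for ang in CANONICAL_ANGLES_DEG]
    w2 = _omega_squared_tensor(rates, group_idx)
    return PEVResult(omega2=w2, unit_ids=binned.unit_ids, centers=binned.centers, trial_ids=keep)
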