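"""On/off mnemonic-state labeling from decoder confidence.

The delay-period confidence trace of each trial is z-scored against a
label-shuffle null (per trial, across the 50 shuffled decodes).  Candidate
"on" states are maximal runs of z > 1.64; a run is accepted when its cluster
mass (the sum of z inside the run) exceeds the 95th percentile of the
max-cluster-mass distribution obtained by applying the identical clustering
to each shuffled trace — the standard cluster-based correction for multiple
comparisons over time.  "Off" states are maximal runs of z < 0.3 lasting at
least 3 consecutive bins.

Given state labels the module quantifies their firing-rate signature: 8-point
on- and off-state tuning curves aligned to each unit's preferred location and
debiased by subtracting the mean of label-shuffled curves (alignment alone
would manufacture a peak), cross-areal transfer of labels between
simultaneously recorded areas, and counts of states near the end of the delay
split by trial outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CANONICAL_ANGLES_DEG,
    SpikeDataset,
    bin_rates,
    group_to_canonical,
)
from .decoding import ConfidenceSeries, DecoderConfig, binary_diametric_decode, confidence_null, zscore_rates

logger = logging.getLogger(__name__)

Z_ON = 1.64
Z_OFF = 0.3
OFF_MIN_LEN = 3


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) index pairs."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _max_cluster_mass(z: np.ndarray, thresh: float) -> float:
    best = 0.0
    for a, b in _runs(z > thresh):
        best = max(best, float(z[a:b].sum()))
    return best


@dataclass
class StateLabels:
    """Per-trial on/off interval annotations on the delay-period bin grid."""

    trial_ids: np.ndarray
    centers: np.ndarray  # delay bin centers (s)
    z: np.ndarray  # trial x bin z-scored confidence
    on: list  # per trial: list of (start_bin, end_bin) half-open
    off: list
    crit_mass: np.ndarray  # per-trial cluster-mass criterion

    @property
    def on_mask(self) -> np.ndarray:
        m = np.zeros_like(self.z, dtype=bool)
        for i, ivs in enumerate(self.on):
            for a, b in ivs:
                m[i, a:b] = True
        return m

    @property
    def off_mask(self) -> np.ndarray:
        m = np.zeros_like(self.z, dtype=bool)
        for i, ivs in enumerate(self.off):
            for a, b in ivs:
                m[i, a:b] = True
        return m

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, tid in enumerate(self.trial_ids):
            for a, b in self.on[i]:
                rows.append((tid, "on", a, b))
            for a, b in self.off[i]:
                rows.append((tid, "off", a, b))
        return pd.DataFrame(rows, columns=["trial_id", "state", "start_bin", "end_bin"])


def label_states(
    series: ConfidenceSeries,
    delay: tuple[float, float] = (0.5, 3.5),
    z_on: float = Z_ON,
    z_off: float = Z_OFF,
    off_min_len: int = OFF_MIN_LEN,
    mass_percentile: float = 95.0,
) -> StateLabels:
    """Label on/off states on the delay portion of a confidence series.

    Requires ``series.null_conf`` (the 50 label-shuffled decodes) for both the
    z-scoring and the null max-cluster-mass criterion.
    """
    if series.null_conf is None:
        raise ValueError("confidence series has no shuffle null; run confidence_null first")
    sel = (series.centers >= delay[0]) & (series.centers < delay[1])
    centers = series.centers[sel]
    conf = series.conf[:, sel]
    null = series.null_conf[:, :, sel]  # shuffle x trial x bin
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=0)
    # pooled-sigma fallback for degenerate bins
    pooled = sd[sd > 0].mean() if (sd > 0).any() else 1.0
    n_zero = int((sd == 0).sum())
    if n_zero:
        logger.warning("%d (trial, bin) cells had zero null s.d.; pooled sigma used", n_zero)
    sd = np.where(sd > 0, sd, pooled)
    z = (conf - mu) / sd
    z_null = (null - mu[None]) / sd[None]

    n_trials, n_bins = z.shape
    on, off = [], []
    crit = np.zeros(n_trials)
    for i in range(n_trials):
        null_masses = np.array([_max_cluster_mass(z_null[s, i], z_on) for s in range(z_null.shape[0])])
        crit[i] = float(np.percentile(null_masses, mass_percentile))
        ivs_on = [
            (a, b) for a, b in _runs(z[i] > z_on) if float(z[i, a:b].sum()) > crit[i]
        ]
        on_bins = np.zeros(n_bins, dtype=bool)
        for a, b in ivs_on:
            on_bins[a:b] = True
        ivs_off = [
            (a, b)
            for a, b in _runs((z[i] < z_off) & ~on_bins)
            if b - a >= off_min_len
        ]
        on.append(ivs_on)
        off.append(ivs_off)
    return StateLabels(
        trial_ids=series.trial_ids, centers=centers, z=z, on=on, off=off, crit_mass=crit
    )


def label_states_all_pairs(
    ds: SpikeDataset,
    cfg: DecoderConfig | None = None,
    n_shuffles: int = 50,
    rng: np.random.Generator | int | None = None,
    span: tuple[float, float] | None = None,
    unit_ids=None,
    **label_kw,
) -> tuple[StateLabels, dict]:
    """Run binary diametric decoding + shuffle null for all four location
    pairs and merge the resulting labels over every trial of the session.

    Returns the merged labels and a dict of the per-pair confidence series.
    """
    cfg = cfg or DecoderConfig(scheme="binary-diametric")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sub = ds if unit_ids is None else ds.subset_units(unit_ids)
    series_by_pair = {}
    parts = []
    for ang in CANONICAL_ANGLES_DEG[:4]:
        pair = (float(ang), float((ang + 180.0) % 360.0))
        s = binary_diametric_decode(sub, cfg, pair=pair, span=span)
        s = confidence_null(sub, cfg, pair=pair, n_shuffles=n_shuffles, rng=rng, span=span, series=s)
        series_by_pair[pair] = s
        parts.append(label_states(s, delay=sub.epochs.delay, **label_kw))
    trial_ids = np.concatenate([p.trial_ids for p in parts])
    order = np.argsort(trial_ids)
    z = np.concatenate([p.z for p in parts], axis=0)[order]
    on = [iv for p in parts for iv in p.on]
    off = [iv for p in parts for iv in p.off]
    crit = np.concatenate([p.crit_mass for p in parts])[order]
    merged = StateLabels(
        trial_ids=trial_ids[order],
        centers=parts[0].centers,
        z=z,
        on=[on[i] for i in order],
        off=[off[i] for i in order],
        crit_mass=crit,
    )
    return merged, series_by_pair


# ---------------------------------------------------------------------------
# state tuning


@dataclass
class StateTuning:
    """Debiased on/off tuning curves aligned to each unit's preferred location.

    Curves are in z-scored rate units; index 0 is the preferred location and
    index 4 the diametric baseline.  ``depth = curve[0] - curve[4]``.
    """

    on_curve: np.ndarray  # population mean, 8 points
    off_curve: np.ndarray
    unit_ids: np.ndarray
    depth_on: np.ndarray  # per unit
    depth_off: np.ndarray
    n_excluded: int = 0
    rate_tests: dict = field(default_factory=dict)

    @property
    def mean_depth_on(self) -> float:
        return float(np.nanmean(self.depth_on))

    @property
    def mean_depth_off(self) -> float:
        return float(np.nanmean(self.depth_off))

    @property
    def depth_reduction_pct(self) -> float:
        """Percent reduction of tuning depth in off relative to on states."""
        d_on = self.mean_depth_on
        if d_on == 0:
            return float("nan")
        return (d_on - self.mean_depth_off) / d_on * 100.0


def _aligned_curves(
    num_on: np.ndarray, den_on: np.ndarray, num_off: np.ndarray, den_off: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Location curves -> preferred-aligned on/off curves per unit.

    Inputs are (unit, 8) numerators and (8,) denominators of masked rate
    means.  The preferred location is the argmax of the summed on+off curve;
    both curves are circularly rolled so it sits at index 0.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        von = np.where(den_on > 0, num_on / np.where(den_on > 0, den_on, 1.0), np.nan)
        voff = np.where(den_off > 0, num_off / np.where(den_off > 0, den_off, 1.0), np.nan)
    total = np.nan_to_num(von) + np.nan_to_num(voff)
    pref = np.argmax(total, axis=1)
    n_units = von.shape[0]
    out_on = np.empty_like(von)
    out_off = np.empty_like(voff)
    for u in range(n_units):
        out_on[u] = np.roll(von[u], -pref[u])
        out_off[u] = np.roll(voff[u], -pref[u])
    return out_on, out_off


def state_tuning(
    ds: SpikeDataset,
    labels: StateLabels,
    n_shuffles: int = 1000,
    rng: np.random.Generator | int | None = None,
    unit_ids=None,
    width: float = 0.1,
) -> StateTuning:
    """On/off-state tuning curves, shuffle-debiased.

    Per unit: average the z-scored delay rate over on-labeled (trial, bin)
    cells for each of the 8 cue locations, likewise for off; align both
    curves (circular rotation) to the location maximizing their sum.
    Alignment to a data-dependent argmax manufactures a peak, so the curves
    are debiased by subtracting the mean of ``n_shuffles`` curves
    recomputed with the state labels permuted across trials (each trial's
    rates paired with another trial's on/off masks), each shuffle
    re-picking its own preferred location and aligned the same way.  The
    shuffled curves estimate the state-independent (overall) tuning plus
    the alignment bias, so the debiased functions have expectation zero
    when the labels carry no information about the rates — genuine on/off
    structure survives as the excess over the state-independent curve.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    step = labels.centers[1] - labels.centers[0] if len(labels.centers) > 1 else width
    span = (labels.centers[0] - width / 2.0, labels.centers[-1] + width / 2.0)
    uids = np.asarray(unit_ids) if unit_ids is not None else ds.unit_ids
    binned = bin_rates(ds, width=width, step=step, span=span, unit_ids=uids, trial_ids=labels.trial_ids)
    z, _, _ = zscore_rates(binned.rates)  # unit x trial x bin

    m_on = labels.on_mask.astype(float)
    m_off = labels.off_mask.astype(float)
    # G[u, t, t'] = sum_b z[u, t, b] * mask[t', b]: trial t's rates under
    # trial t''s labels, so a label permutation is a (t, perm[t]) gather
    g_on = np.tensordot(z, m_on, axes=([2], [1]))
    g_off = np.tensordot(z, m_off, axes=([2], [1]))
    c_on = m_on.sum(axis=1)
    c_off = m_off.sum(axis=1)

    loc_of = dict(zip(ds.trials["trial_id"], group_to_canonical(ds.trials["cue_location_deg"].to_numpy())))
    locs = np.array([loc_of[t] for t in labels.trial_ids])
    loc_idx = [np.where(locs == ang)[0] for ang in CANONICAL_ANGLES_DEG]
    n_trials = len(labels.trial_ids)
    t_arange = np.arange(n_trials)

    def curves(perm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # s[u, t] = g[u, t, perm[t]]
        s_on = g_on[:, t_arange, perm]
        s_off = g_off[:, t_arange, perm]
        num_on = np.stack([s_on[:, idx].sum(axis=1) for idx in loc_idx], axis=1)
        num_off = np.stack([s_off[:, idx].sum(axis=1) for idx in loc_idx], axis=1)
        den_on = np.array([c_on[perm[idx]].sum() for idx in loc_idx])
        den_off = np.array([c_off[perm[idx]].sum() for idx in loc_idx])
        return _aligned_curves(num_on, den_on[None, :].repeat(z.shape[0], 0),
                               num_off, den_off[None, :].repeat(z.shape[0], 0))

    true_on, true_off = curves(np.arange(n_trials))
    acc_on = np.zeros_like(true_on)
    acc_off = np.zeros_like(true_off)
    for _ in range(n_shuffles):
        perm = rng.permutation(n_trials)
        so, sf = curves(perm)
        acc_on += np.nan_to_num(so)
        acc_off += np.nan_to_num(sf)
    deb_on = true_on - acc_on / n_shuffles
    deb_off = true_off - acc_off / n_shuffles

    no_off = np.isnan(true_off).all(axis=1)
    n_excl = int(no_off.sum())
    if n_excl:
        logger.info("%d unit(s) with no off-labeled time excluded from off curves", n_excl)
    depth_on = deb_on[:, 0] - deb_on[:, 4]
    depth_off = np.where(no_off, np.nan, deb_off[:, 0] - deb_off[:, 4])
    return StateTuning(
        on_curve=np.nanmean(deb_on, axis=0),
        off_curve=np.nanmean(deb_off[~no_off], axis=0) if (~no_off).any() else np.full(8, np.nan),
        unit_ids=binned.unit_ids,
        depth_on=depth_on,
        depth_off=depth_off,
        n_excluded=n_excl,
    )


def cross_areal_transfer(
    ds: SpikeDataset,
    labels: StateLabels,
    target_area: str,
    n_shuffles: int = 1000,
    rng: np.random.Generator | int | None = None,
    min_source_units: int = 80,
    n_source_units: int | None = None,
    width: float = 0.1,
) -> StateTuning:
    """Examine ``target_area`` tuning and rates within states labeled from
    another area's activity.

    ``n_source_units`` is the size of the population that produced ``labels``
    (checked against ``min_source_units``, the gate used for cross-areal
    analyses).  Adds paired t-tests on per-unit rates: on vs. off and on vs.
    the all-trial mean.
    """
    if n_source_units is not None and n_source_units < min_source_units:
        raise ValueError(
            f"source population has {n_source_units} units; "
            f"cross-areal transfer requires at least {min_source_units}"
        )
    units = ds.units[ds.units["area"] == target_area]
    if units.empty:
        raise ValueError(f"no units in area {target_area!r}")
    tuning = state_tuning(
        ds, labels, n_shuffles=n_shuffles, rng=rng, unit_ids=units["unit_id"].to_numpy(), width=width
    )

    step = labels.centers[1] - labels.centers[0] if len(labels.centers) > 1 else width
    span = (labels.centers[0] - width / 2.0, labels.centers[-1] + width / 2.0)
    binned = bin_rates(
        ds, width=width, step=step, span=span,
        unit_ids=units["unit_id"].to_numpy(), trial_ids=labels.trial_ids,
    )
    m_on, m_off = labels.on_mask, labels.off_mask
    r = binned.rates

    def masked_mean(mask: np.ndarray) -> np.ndarray:
        w = mask.astype(float)[None]
        den = w.sum(axis=(1, 2))
        return np.where(den > 0, (r * w).sum(axis=(1, 2)) / np.maximum(den, 1.0), np.nan)

    rate_on = masked_mean(m_on)
    rate_off = masked_mean(m_off)
    rate_all = r.mean(axis=(1, 2))
    ok = ~np.isnan(rate_on) & ~np.isnan(rate_off)
    tests = {}
    if ok.sum() >= 2:
        t1 = stats.ttest_rel(rate_on[ok], rate_off[ok])
        t2 = stats.ttest_rel(rate_on[ok], rate_all[ok])
        tests = {
            "on_vs_off": {"t": float(t1.statistic), "p": float(t1.pvalue)},
            "on_vs_mean": {"t": float(t2.statistic), "p": float(t2.pvalue)},
        }
    tuning.rate_tests = tests
    return tuning


def depth_reduction_test(tuning: StateTuning) -> dict:
    """One-sample t-test across units that on-state depth exceeds off-state depth."""
    d = tuning.depth_on - tuning.depth_off
    d = d[~np.isnan(d)]
    t = stats.ttest_1samp(d, 0.0, alternative="greater")
    return {"t": float(t.statistic), "p": float(t.pvalue), "n": int(len(d))}


# ---------------------------------------------------------------------------
# state counts by outcome


def site_preference_from_confidence(series_by_pair: dict, delay: tuple[float, float]) -> tuple[float, float]:
    """Site preferred / least-preferred cue = max / min mean delay confidence."""
    mean_conf = {}
    for (a, b), s in series_by_pair.items():
        sel = (s.centers >= delay[0]) & (s.centers < delay[1])
        for ang in (a, b):
            m = s.y == ang
            if m.any():
                mean_conf[ang] = float(s.conf[m][:, sel].mean())
    pref = max(mean_conf, key=mean_conf.get)
    least = min(mean_conf, key=mean_conf.get)
    return pref, least


def state_count_table(
    ds: SpikeDataset,
    labels: StateLabels,
    pref_cue: float,
    least_cue: float,
    window_s: float = 0.5,
) -> pd.DataFrame:
    """Mean number of on/off states per trial in the last ``window_s`` of the
    delay, for trials at the preferred and least-preferred cue, split by
    outcome.  A state counts if it overlaps the window at all.
    """
    delay_end = ds.epochs.delay[1]
    w0 = delay_end - window_s
    step = labels.centers[1] - labels.centers[0]
    width = step * 2  # decoder grid: windows are two steps wide
    starts = labels.centers - width / 2.0
    ends = labels.centers + width / 2.0
    loc_of = dict(zip(ds.trials["trial_id"], group_to_canonical(ds.trials["cue_location_deg"].to_numpy())))
    corr_of = dict(zip(ds.trials["trial_id"], ds.trials["correct"]))
    rows = []
    for i, tid in enumerate(labels.trial_ids):
        loc = loc_of[tid]
        if loc not in (pref_cue, least_cue):
            continue
        prefcat = "preferred" if loc == pref_cue else "least"
        for state, ivs in (("on", labels.on[i]), ("off", labels.off[i])):
            n = sum(1 for a, b in ivs if ends[b - 1] > w0 and starts[a] < delay_end)
            rows.append((tid, bool(corr_of[tid]), prefcat, state, n))
    df = pd.DataFrame(rows, columns=["trial_id", "correct", "preference", "state", "n_states"])
    return (
        df.groupby(["correct", "preference", "state"], observed=True)["n_states"]
        .mean()
        .reset_index()
    )


def state_counts_anova(tables: list[pd.DataFrame]) -> pd.DataFrame | None:
    """Three-way ANOVA (correct x preference x state, all interactions) on
    per-session cell means.  Returns None (with a warning) if any factor
    level is missing."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.concat(
        [t.assign(session=i) for i, t in enumerate(tables)], ignore_index=True
    )
    for col, levels in (("correct", 2), ("preference", 2), ("state", 2)):
        if df[col].nunique() < levels:
            logger.warning("factor %r has fewer than 2 levels; ANOVA skipped", col)
            return None
    model = smf.ols("n_states ~ C(correct) * C(preference) * C(state)", data=df).fit()
    return anova_lm(model, typ=2)
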