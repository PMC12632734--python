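"""Leave-one-out lasso-logistic decoding of cue location.

Two schemes are used throughout: an eight-way one-vs-all classifier for
cross-temporal accuracy matrices, and a binary classifier separating each cue
location from its diametric (180 degrees opposite) location, whose softmax
posterior is the "confidence" substrate for on/off-state labeling.

Features are firing rates in sliding 100 ms windows (50 ms steps), z-scored
per (unit, bin) across trials.  Decoding is strictly leave-one-trial-out: a
fresh model is fitted per training bin on n-1 trials and evaluated on the
held-out trial (at the same bin, or at every bin for the cross-temporal
matrix).  The lasso penalty is fixed at lambda = 0.01; the regularization
constant is C = 1/(n_train * lambda) so the penalty matches a mean-loss
formulation.

Two interchangeable engines solve the underlying L1-logistic problems: the
default batched coordinate-descent solver (``_lasso``), which fits every
(fold, bin, label-set) problem in one compiled pass, and a reference
``liblinear`` engine (scikit-learn) used for cross-checking and for the
fold-safe z-scoring variant.  Both optimize the identical objective and
agree on held-out margins to ~1e-4.

The module also implements the simultaneous vs. pseudo-population contrast:
pseudo-populations permute, independently per neuron, the trial identities
within each cue-location stratum, preserving single-neuron marginals while
destroying within-trial co-fluctuations across neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from ._lasso import loo_margins
from .core import (
    CANONICAL_ANGLES_DEG,
    BinnedRates,
    SpikeDataset,
    bin_rates,
    group_to_canonical,
)


@dataclass
class DecoderConfig:
    lam: float = 0.01
    width: float = 0.1
    step: float = 0.05
    scheme: str = "onevsall-8way"  # or "binary-diametric"
    zscore_full: bool = True  # z-score the full matrix; False = within training folds
    tol: float = 1e-6
    max_iter: int = 1000
    engine: str = "batch"  # or "liblinear" (reference; required for fold-safe z-scoring)

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.engine not in ("batch", "liblinear"):
            raise ValueError("engine must be 'batch' or 'liblinear'")


def zscore_rates(rates: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score a (unit, trial, bin) tensor across trials per (unit, bin).

    Zero-variance features become all-zero columns (rather than being
    dropped) so feature indices stay stable across folds.
    """
    if rates.shape[1] < 2:
        raise ValueError("need at least 2 trials to z-score")
    mu = rates.mean(axis=1, keepdims=True)
    sd = rates.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (rates - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z, mu, sd


def _lasso_kwargs() -> dict:
    """L1-penalty spelling compatible with sklearn before/after 1.8."""
    import sklearn

    major, minor = (int(v) for v in sklearn.__version__.split(".")[:2])
    if (major, minor) >= (1, 8):
        return {"l1_ratio": 1.0}
    return {"penalty": "l1"}


_LASSO_KW = _lasso_kwargs()


def _make_clf(cfg: DecoderConfig, n_train: int) -> LogisticRegression:
    return LogisticRegression(
        C=1.0 / (n_train * cfg.lam),
        solver="liblinear",
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        random_state=0,
        **_LASSO_KW,
    )


class OneVsAllLasso:
    """Eight one-vs-all lasso-logistic classifiers (liblinear engine);
    prediction is the class with the largest binary margin."""

    def __init__(self, cfg: DecoderConfig, n_train: int):
        self.cfg = cfg
        self.n_train = n_train

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneVsAllLasso":
        self.classes_ = np.unique(y)
        self._clfs = []
        for c in self.classes_:
            clf = _make_clf(self.cfg, self.n_train)
            clf.fit(X, (y == c).astype(int))
            self._clfs.append(clf)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.stack([clf.decision_function(X) for clf in self._clfs], axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def _fold_zscore(Xtr: np.ndarray, Xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (
        np.where(sd > 0, (Xtr - mu) / sd_safe, 0.0),
        np.where(sd > 0, (Xte - mu) / sd_safe, 0.0),
    )


@dataclass
class DecodeResult:
    accuracy: np.ndarray  # (train_bin, test_bin) or (bin,) when diagonal only
    centers: np.ndarray
    per_cue: dict = field(default_factory=dict)
    trial_ids: np.ndarray | None = None


def _ovr_sets(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """One-vs-all +/-1 label matrix (n_classes, n_trials)."""
    return np.where(y[None, :] == classes[:, None], 1.0, -1.0)


def decode_from_features(
    X: np.ndarray,
    y: np.ndarray,
    cfg: DecoderConfig,
    diagonal_only: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out decode of labels from a z-scored (trial, unit, bin) tensor.

    Returns per-(fold, train-bin[, test-bin]) correctness and the predicted
    labels on the diagonal.
    """
    n_trials, _, n_bins = X.shape
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 trials (absent from some training fold)")

    if cfg.engine == "batch" and cfg.zscore_full:
        C = 1.0 / ((n_trials - 1) * cfg.lam)
        if len(classes) == 2:
            Y = np.where(y == classes[1], 1.0, -1.0)[None]
            M = loo_margins(X, Y, C, tol=cfg.tol, cross_temporal=not diagonal_only)
            pred = classes[(M[0] > 0).astype(int)]
        else:
            Y = _ovr_sets(y, classes)
            M = loo_margins(X, Y, C, tol=cfg.tol, cross_temporal=not diagonal_only)
            pred = classes[np.argmax(M, axis=0)]
        if diagonal_only:
            correct = pred == y[:, None]
            diag_pred = pred
        else:
            correct = pred == y[:, None, None]
            diag_pred = np.einsum("ibb->ib", pred) if pred.ndim == 3 else pred
        return correct, diag_pred

    # reference engine: explicit per-fold fits (supports fold-safe z-scoring)
    if diagonal_only:
        correct = np.zeros((n_trials, n_bins), dtype=bool)
    else:
        correct = np.zeros((n_trials, n_bins, n_bins), dtype=bool)
    diag_pred = np.zeros((n_trials, n_bins), dtype=y.dtype)
    folds = np.arange(n_trials)
    binary = len(classes) == 2
    for b in range(n_bins):
        for i in folds:
            mask = folds != i
            Xtr = X[mask, :, b]
            if not cfg.zscore_full:
                Xtr, Xte_b = _fold_zscore(X[mask, :, b], X[i : i + 1, :, b])
            clf = _make_clf(cfg, n_trials - 1) if binary else OneVsAllLasso(cfg, n_trials - 1)
            clf.fit(Xtr, y[mask])
            if diagonal_only:
                xt = Xte_b if not cfg.zscore_full else X[i : i + 1, :, b]
                pred = clf.predict(xt)[0]
                diag_pred[i, b] = pred
                correct[i, b] = pred == y[i]
            else:
                if not cfg.zscore_full:
                    raise NotImplementedError(
                        "fold-safe z-scoring supports diagonal decoding only"
                    )
                preds = clf.predict(X[i].T)
                correct[i, b, :] = preds == y[i]
                diag_pred[i, b] = preds[b]
    return correct, diag_pred


def _features(
    ds: SpikeDataset,
    cfg: DecoderConfig,
    span: tuple[float, float],
    trial_ids: Sequence | None = None,
    binned: BinnedRates | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-scored feature tensor (trial, unit, bin) with trial ids and centers."""
    if binned is None:
        binned = bin_rates(ds, width=cfg.width, step=cfg.step, span=span, trial_ids=trial_ids)
    z, _, _ = zscore_rates(binned.rates)
    return np.transpose(z, (1, 0, 2)), binned.trial_ids, binned.centers


def crosstemporal_decode(
    ds: SpikeDataset,
    cfg: DecoderConfig | None = None,
    span: tuple[float, float] | None = None,
    diagonal_only: bool = False,
    binned: BinnedRates | None = None,
) -> DecodeResult:
    """Eight-way cross-temporal decoding accuracy (train bin x test bin),
    overall and restricted to trials of each cue."""
    cfg = cfg or DecoderConfig()
    if span is None:
        span = (ds.epochs.fixation[0], ds.epochs.response[1])
    X, trial_ids, centers = _features(ds, cfg, span, binned=binned)
    loc_of = dict(
        zip(ds.trials["trial_id"], group_to_canonical(ds.trials["cue_location_deg"].to_numpy()))
    )
    y = np.array([loc_of[t] for t in trial_ids])
    correct, _ = decode_from_features(X, y, cfg, diagonal_only=diagonal_only)
    per_cue = {float(ang): correct[y == ang].mean(axis=0) for ang in np.unique(y)}
    return DecodeResult(
        accuracy=correct.mean(axis=0), centers=centers, per_cue=per_cue, trial_ids=trial_ids
    )


# ---------------------------------------------------------------------------
# binary diametric decoding and confidence


@dataclass
class ConfidenceSeries:
    """Per-trial posterior-probability time course of the true cue class."""

    conf: np.ndarray  # trial x bin, posterior of the true class
    trial_ids: np.ndarray
    centers: np.ndarray
    y: np.ndarray  # true binary labels (cue angle)
    pair: tuple[float, float]
    null_conf: np.ndarray | None = None  # shuffle x trial x bin
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, tid in enumerate(self.trial_ids):
            for b, c in enumerate(self.centers):
                rows.append((tid, c, self.conf[i, b]))
        return pd.DataFrame(rows, columns=["trial_id", "bin_center_s", "posterior"])


def softmax_posterior(scores: np.ndarray) -> np.ndarray:
    """Two-class softmax: posterior_i = exp(score_i) / sum_j exp(score_j)."""
    s = np.asarray(scores, dtype=float)
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def _confidence_sets(
    X: np.ndarray, label_sets: np.ndarray, y_true: np.ndarray, cfg: DecoderConfig
) -> np.ndarray:
    """LOO posterior of each trial's true class for several training label
    sets at once (the empirical labels and/or shuffled copies).

    ``label_sets``: (S, n) cue angles; returns (S, n, bins).  The per-class
    scores are the symmetric halves of the binary margin, so the two-class
    softmax reduces to the logistic of the margin.
    """
    classes = np.unique(y_true)
    if len(classes) != 2:
        raise ValueError("binary decoding requires exactly 2 classes")
    n = X.shape[0]
    Ypm = np.where(label_sets == classes[1], 1.0, -1.0)
    if cfg.engine == "batch" and cfg.zscore_full:
        M = loo_margins(X, Ypm, 1.0 / ((n - 1) * cfg.lam), tol=cfg.tol)
    else:
        M = np.zeros((len(label_sets), n, X.shape[2]))
        folds = np.arange(n)
        for s in range(len(label_sets)):
            ys = Ypm[s]
            for b in range(X.shape[2]):
                for i in folds:
                    mask = folds != i
                    Xtr, Xte = X[mask, :, b], X[i : i + 1, :, b]
                    if not cfg.zscore_full:
                        Xtr, Xte = _fold_zscore(Xtr, Xte)
                    clf = _make_clf(cfg, n - 1)
                    clf.fit(Xtr, ys[mask])
                    M[s, i, b] = clf.decision_function(Xte)[0]
    post_pos = expit(M)  # softmax of scores (-m/2, +m/2)
    true_pos = (y_true == classes[1])[None, :, None]
    return np.where(true_pos, post_pos, 1.0 - post_pos)


def binary_diametric_decode(
    ds: SpikeDataset,
    cfg: DecoderConfig | None = None,
    pair: tuple[float, float] = (0.0, 180.0),
    span: tuple[float, float] | None = None,
    binned: BinnedRates | None = None,
) -> ConfidenceSeries:
    """Diametric binary decoding: posterior confidence of the true cue class,
    leave-one-trial-out, per time bin."""
    cfg = cfg or DecoderConfig(scheme="binary-diametric")
    if span is None:
        span = (ds.epochs.fixation[0], ds.epochs.response[1])
    a, b = group_to_canonical(np.asarray(pair))
    if (a - b) % 360.0 != 180.0:
        raise ValueError("pair must be diametric (180 degrees apart)")
    locs = group_to_canonical(ds.trials["cue_location_deg"].to_numpy())
    sel = np.isin(locs, [a, b])
    tids = ds.trial_ids[sel]
    for ang in (a, b):
        if (locs == ang).sum() < 2:
            raise ValueError(f"location {ang:.0f} deg has fewer than 2 trials")
    X, trial_ids, centers = _features(ds, cfg, span, trial_ids=tids, binned=binned)
    loc_of = dict(zip(ds.trial_ids, locs))
    y = np.array([loc_of[t] for t in trial_ids])
    conf = _confidence_sets(X, y[None], y, cfg)[0]
    return ConfidenceSeries(conf=conf, trial_ids=trial_ids, centers=centers, y=y, pair=(a, b))


def confidence_null(
    ds: SpikeDataset,
    cfg: DecoderConfig | None = None,
    pair: tuple[float, float] = (0.0, 180.0),
    n_shuffles: int = 50,
    rng: np.random.Generator | int | None = None,
    span: tuple[float, float] | None = None,
    series: ConfidenceSeries | None = None,
    binned: BinnedRates | None = None,
) -> ConfidenceSeries:
    """Label-shuffle null for the confidence series.

    Each shuffle permutes the training labels once and recomputes the full
    leave-one-out confidence of every trial's *true* class; the per-(trial,
    bin) mean and s.d. across shuffles form the null used for z-scoring.
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    cfg = cfg or DecoderConfig(scheme="binary-diametric")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if series is None:
        series = binary_diametric_decode(ds, cfg, pair=pair, span=span, binned=binned)
    if span is None:
        span = (ds.epochs.fixation[0], ds.epochs.response[1])
    X, trial_ids, _ = _features(ds, cfg, span, trial_ids=series.trial_ids, binned=binned)
    y = series.y
    shuffled = np.stack([y[rng.permutation(len(y))] for _ in range(n_shuffles)], axis=0)
    null = _confidence_sets(X, shuffled, y, cfg)
    series.null_conf = null
    series.null_mean = null.mean(axis=0)
    series.null_sd = null.std(axis=0, ddof=0)
    return series


# ---------------------------------------------------------------------------
# pseudo-populations


@dataclass
class PseudoPopulationSet:
    """Trial-permutation indices defining pseudo-populations of one session.

    ``perms[k, u]`` maps trial slots to source trials for neuron ``u`` in
    pseudo-population ``k``; permutations act within each cue-location
    stratum, so per-neuron per-location marginals are untouched.
    """

    perms: np.ndarray  # n_pseudo x n_units x n_trials
    binned: BinnedRates

    @property
    def n(self) -> int:
        return self.perms.shape[0]

    def rates(self, k: int) -> np.ndarray:
        """Rate tensor (unit, trial, bin) of pseudo-population ``k``."""
        r = self.binned.rates
        idx = self.perms[k]
        return np.take_along_axis(r, idx[:, :, None], axis=1)


def build_pseudopopulations(
    binned: BinnedRates,
    trial_locations: np.ndarray,
    n: int = 100,
    rng: np.random.Generator | int | None = None,
) -> PseudoPopulationSet:
    """Build ``n`` pseudo-populations by permuting, independently per neuron,
    trial identities within each cue-location stratum."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    locs = group_to_canonical(np.asarray(trial_locations))
    n_units, n_trials, _ = binned.rates.shape
    strata = [np.where(locs == ang)[0] for ang in np.unique(locs)]
    for s in strata:
        if len(s) < 2:
            raise ValueError("every location stratum needs at least 2 trials")
    perms = np.tile(np.arange(n_trials), (n, n_units, 1))
    for k in range(n):
        for u in range(n_units):
            for s in strata:
                perms[k, u, s] = s[rng.permutation(len(s))]
    return PseudoPopulationSet(perms=perms, binned=binned)


@dataclass
class SimulPseudoComparison:
    centers: np.ndarray
    simul_accuracy: np.ndarray
    pseudo_accuracy: np.ndarray  # n_pseudo x bin
    p_bin: np.ndarray  # normal-approximation two-sided p per bin
    significant_bonferroni: np.ndarray
    below_2p5: np.ndarray  # simultaneous below pseudo 2.5th percentile
    wilcoxon_p: float
    epoch_diff: dict  # epoch -> mean (simul - pseudo) accuracy difference


def compare_simul_vs_pseudo(
    simul_accuracy: np.ndarray,
    pseudo_accuracy: np.ndarray,
    centers: np.ndarray,
    epochs,
    alpha: float = 0.05,
) -> SimulPseudoComparison:
    """Compare simultaneous decoding accuracy against the pseudo-population
    distribution: per-bin z-tests (Bonferroni over bins), an across-bin
    Wilcoxon signed-rank test against the pseudo mean, and per-epoch mean
    accuracy differences."""
    simul = np.asarray(simul_accuracy, dtype=float)
    pseudo = np.asarray(pseudo_accuracy, dtype=float)
    mu = pseudo.mean(axis=0)
    sd = pseudo.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (simul - mu) / sd
    p_bin = np.where(sd > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    n_bins = len(simul)
    sig = p_bin < alpha / n_bins
    below = simul < np.percentile(pseudo, 2.5, axis=0)
    diff = simul - mu
    wp = 1.0 if np.allclose(diff, 0.0) else float(stats.wilcoxon(simul, mu).pvalue)
    epoch_diff = {}
    for name, (a, b) in epochs.as_dict().items():
        m = (centers >= a) & (centers < b)
        if m.any():
            epoch_diff[name] = float(diff[m].mean())
    return SimulPseudoComparison(
        centers=centers,
        simul_accuracy=simul,
        pseudo_accuracy=pseudo,
        p_bin=p_bin,
        significant_bonferroni=sig,
        below_2p5=below,
        wilcoxon_p=wp,
        epoch_diff=epoch_diff,
    )


def pseudo_population_decode(
    ds: SpikeDataset,
    cfg: DecoderConfig | None = None,
    n_pseudo: int = 100,
    span: tuple[float, float] | None = None,
    rng: np.random.Generator | int | None = None,
    width: float | None = None,
    step: float | None = None,
) -> SimulPseudoComparison:
    """End-to-end simultaneous vs. pseudo-population comparison (diagonal
    eight-way accuracy per bin)."""
    cfg = cfg or DecoderConfig()
    if span is None:
        span = (ds.epochs.fixation[0], ds.epochs.response[1])
    binned = bin_rates(ds, width=width or cfg.width, step=step or cfg.step, span=span)
    locs = group_to_canonical(ds.trials["cue_location_deg"].to_numpy())
    loc_of = dict(zip(ds.trial_ids, locs))
    y = np.array([loc_of[t] for t in binned.trial_ids])

    def diag_acc(rates: np.ndarray) -> np.ndarray:
        z, _, _ = zscore_rates(rates)
        X = np.transpose(z, (1, 0, 2))
        correct, _ = decode_from_features(X, y, cfg, diagonal_only=True)
        return correct.mean(axis=0)

    simul = diag_acc(binned.rates)
    pseudo_set = build_pseudopopulations(binned, locs, n=n_pseudo, rng=rng)
    pseudo = np.stack([diag_acc(pseudo_set.rates(k)) for k in range(n_pseudo)], axis=0)
    return compare_simul_vs_pseudo(simul, pseudo, binned.centers, ds.epochs)
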