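"""Beta-mixture modeling of confidence, state power spectra, and RT effects.

*Mixture modeling* asks whether delay-period decoder confidence is better
described by one beta distribution (a single mnemonic regime) or a
two-component beta mixture (discrete on/off regimes):

    p(c) = w Beta(c; a, b) + (1 - w) Beta(c; a', b')

fitted by EM with multiple restarts; model comparison uses
dAIC = AIC_2 - AIC_1 and dBIC = BIC_2 - BIC_1 (k = 5 vs. 2 parameters),
negative values favoring the two-state model.

*Spectra*: per-trial binary on/off series are mean-centered and analyzed
with Welch's method (2 s Hamming windows, 50% overlap, 1024-point FFT) to
test for rhythmicity in state alternation.

*Behavior*: per-session linear models RT ~ State (state at the go cue)
give a coefficient beta_state = RT_on - RT_off; inference on the
across-session mean uses a nonparametric bootstrap over sessions
(B = 10,000), with the one-sided p the proportion of bootstrap means >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal, special, stats

EPS = 1e-6


# ---------------------------------------------------------------------------
# beta mixture


def _beta_logpdf(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return stats.beta.logpdf(x, a, b)


def _weighted_beta_mle(x: np.ndarray, w: np.ndarray, a0: float, b0: float) -> tuple[float, float]:
    """Maximize sum_i w_i log Beta(x_i; a, b) over (a, b) > 0."""
    lx = np.log(x)
    l1x = np.log1p(-x)
    W = w.sum()
    s1 = (w * lx).sum()
    s2 = (w * l1x).sum()

    def nll(theta):
        a, b = np.exp(theta)
        return -((a - 1) * s1 + (b - 1) * s2 - W * special.betaln(a, b))

    def grad(theta):
        a, b = np.exp(theta)
        dig = special.digamma
        da = s1 - W * (dig(a) - dig(a + b))
        db = s2 - W * (dig(b) - dig(a + b))
        return -np.array([da * a, db * b])

    res = optimize.minimize(nll, np.log([a0, b0]), jac=grad, method="L-BFGS-B")
    a, b = np.exp(res.x)
    return float(a), float(b)


def _moments_init(x: np.ndarray) -> tuple[float, float]:
    m, v = x.mean(), max(x.var(), 1e-6)
    common = max(m * (1 - m) / v - 1.0, 1e-2)
    return max(m * common, 1e-2), max((1 - m) * common, 1e-2)


@dataclass
class BetaMixtureFit:
    a1: float
    b1: float
    loglik1: float
    w: float
    a2: tuple[float, float]
    b2: tuple[float, float]
    loglik2: float
    n: int

    @property
    def aic1(self) -> float:
        return 2 * 2 - 2 * self.loglik1

    @property
    def aic2(self) -> float:
        return 2 * 5 - 2 * self.loglik2

    @property
    def bic1(self) -> float:
        return 2 * np.log(self.n) - 2 * self.loglik1

    @property
    def bic2(self) -> float:
        return 5 * np.log(self.n) - 2 * self.loglik2

    @property
    def delta_aic(self) -> float:
        return self.aic2 - self.aic1

    @property
    def delta_bic(self) -> float:
        return self.bic2 - self.bic1

    def to_dict(self) -> dict:
        return {
            "one_state": {"a": self.a1, "b": self.b1, "loglik": self.loglik1},
            "two_state": {
                "w": self.w,
                "a": list(self.a2),
                "b": list(self.b2),
                "loglik": self.loglik2,
            },
            "delta_aic": self.delta_aic,
            "delta_bic": self.delta_bic,
            "n": self.n,
        }


def _em_two_beta(
    x: np.ndarray, w0: float, p1: tuple[float, float], p2: tuple[float, float],
    max_iter: int = 1000, tol: float = 1e-7,
) -> tuple[float, tuple, tuple, float, bool]:
    w = w0
    (a1, b1), (a2, b2) = p1, p2
    ll_prev = -np.inf
    for _ in range(max_iter):
        l1 = np.log(w) + _beta_logpdf(x, a1, b1)
        l2 = np.log1p(-w) + _beta_logpdf(x, a2, b2)
        m = np.maximum(l1, l2)
        ll = float((m + np.log(np.exp(l1 - m) + np.exp(l2 - m))).sum())
        with np.errstate(over="ignore"):
            r = 1.0 / (1.0 + np.exp(l2 - l1))  # responsibility of component 1
        w = float(np.clip(r.mean(), 1e-6, 1 - 1e-6))
        a1, b1 = _weighted_beta_mle(x, r, a1, b1)
        a2, b2 = _weighted_beta_mle(x, 1.0 - r, a2, b2)
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            return w, (a1, a2), (b1, b2), ll, True
        ll_prev = ll
    return w, (a1, a2), (b1, b2), ll, False


def fit_beta_mixture(
    confidences: np.ndarray,
    n_restarts: int = 10,
    rng: np.random.Generator | int | None = None,
) -> BetaMixtureFit:
    """Fit one-beta and two-component beta-mixture models to confidence values.

    Values are clamped to [eps, 1-eps] (saturated classifiers produce exact
    0/1).  The two-component fit runs EM from a quantile-split
    method-of-moments start plus random restarts, keeping the best
    likelihood.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.clip(np.asarray(confidences, dtype=float), EPS, 1 - EPS)
    if len(x) < 20:
        raise ValueError("need at least 20 confidence values")

    a1, b1 = _weighted_beta_mle(x, np.ones_like(x), *_moments_init(x))
    ll1 = float(_beta_logpdf(x, a1, b1).sum())

    best = None
    any_converged = False
    med = np.median(x)
    for k in range(n_restarts):
        if k == 0:
            lo, hi = x[x <= med], x[x > med]
            q = 0.5
        else:
            q = float(rng.uniform(0.2, 0.8))
            cut = np.quantile(x, q)
            lo, hi = x[x <= cut], x[x > cut]
        if len(lo) < 2 or len(hi) < 2:
            continue
        try:
            p_lo = _moments_init(lo)
            p_hi = _moments_init(hi)
            w, a2, b2, ll, conv = _em_two_beta(x, q, p_hi, p_lo)
        except (ValueError, FloatingPointError):
            continue
        any_converged = any_converged or conv
        if best is None or ll > best[3]:
            best = (w, a2, b2, ll)
    if best is None or not any_converged:
        raise RuntimeError("EM failed to converge in every restart (n=%d)" % len(x))
    w, a2, b2, ll2 = best
    ll2 = max(ll2, ll1)  # the mixture nests the single beta
    return BetaMixtureFit(a1=a1, b1=b1, loglik1=ll1, w=w, a2=a2, b2=b2, loglik2=ll2, n=len(x))


# ---------------------------------------------------------------------------
# power spectrum of states


def state_psd(
    series: list[np.ndarray] | np.ndarray,
    fs: float = 100.0,
    window_s: float = 2.0,
    nfft: int = 1024,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Welch PSD of binary state series, averaged across trials.

    Each trial's series is mean-centered; Welch uses Hamming windows of
    ``window_s`` seconds with 50% overlap and a ``nfft``-point FFT.  Trials
    shorter than one window are skipped.  Returns (freqs, mean PSD,
    n_skipped).
    """
    if isinstance(series, np.ndarray) and series.ndim == 1:
        series = [series]
    nperseg = int(round(window_s * fs))
    psds = []
    skipped = 0
    freqs = None
    for x in series:
        x = np.asarray(x, dtype=float)
        if len(x) < nperseg:
            skipped += 1
            continue
        x = x - x.mean()
        f, p = signal.welch(
            x,
            fs=fs,
            window="hamming",
            nperseg=nperseg,
            noverlap=nperseg // 2,
            nfft=max(nfft, nperseg),
            detrend=False,
        )
        freqs = f
        psds.append(p)
    if not psds:
        raise ValueError("every trial was shorter than one Welch window")
    return freqs, np.mean(psds, axis=0), skipped


def state_series_from_labels(labels, state: str = "off") -> list[np.ndarray]:
    """Per-trial binary series marking membership in the given state."""
    mask = labels.off_mask if state == "off" else labels.on_mask
    return [mask[i].astype(float) for i in range(mask.shape[0])]


# ---------------------------------------------------------------------------
# reaction time vs. state


@dataclass
class RTStateEffect:
    beta_per_session: np.ndarray  # ms, RT_on - RT_off
    bootstrap_means: np.ndarray
    p_ge_zero: float  # proportion of bootstrap means >= 0
    p_le_zero: float
    n_sessions: int
    n_dropped: int

    @property
    def mean_beta(self) -> float:
        return float(self.beta_per_session.mean())

    def to_dict(self) -> dict:
        return {
            "mean_beta_ms": self.mean_beta,
            "p_ge_zero": self.p_ge_zero,
            "p_le_zero": self.p_le_zero,
            "n_sessions": self.n_sessions,
            "n_dropped": self.n_dropped,
        }


def session_rt_beta(trials: pd.DataFrame) -> float | None:
    """OLS coefficient of RT (ms) on state (1 = on at go cue) for one session.

    Trials with a missing state label or RT are excluded; returns None when
    only one state is represented.
    """
    df = trials.dropna(subset=["rt_ms", "state_at_go"])
    s = df["state_at_go"].to_numpy(dtype=float)
    rt = df["rt_ms"].to_numpy(dtype=float)
    if len(np.unique(s)) < 2:
        return None
    return float(rt[s == 1].mean() - rt[s == 0].mean())


def rt_state_bootstrap(
    session_trials: list[pd.DataFrame],
    n_boot: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> RTStateEffect:
    """Session-bootstrapped inference on the RT-vs-state effect."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    betas = []
    dropped = 0
    for tr in session_trials:
        b = session_rt_beta(tr)
        if b is None:
            dropped += 1
        else:
            betas.append(b)
    if len(betas) < 2:
        raise ValueError("need at least 2 sessions with both states represented")
    betas = np.array(betas)
    idx = rng.integers(0, len(betas), size=(n_boot, len(betas)))
    boot = betas[idx].mean(axis=1)
    p_ge = float((boot >= 0).mean())
    return RTStateEffect(
        beta_per_session=betas,
        bootstrap_means=boot,
        p_ge_zero=max(p_ge, 1.0 / n_boot),
        p_le_zero=max(float((boot <= 0).mean()), 1.0 / n_boot),
        n_sessions=len(betas),
        n_dropped=dropped,
    )
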