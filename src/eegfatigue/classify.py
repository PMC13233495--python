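"""LDA on N-PLS latent scores and fatigue-trajectory summaries.

A shared-covariance Gaussian classifier turns latent scores into posterior
probabilities of the high-fatigue class; posteriors over a session are
smoothed with a 100-epoch moving average, summarized into an 11-point
trajectory (pre-session rest, three thirds of each of the three VR blocks,
post-session rest), and characterized by the slope of a linear trend
``y = p1 x + p2`` over the stage index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LDAParams",
    "FatigueTrajectory",
    "ERDTimecourse",
    "lda_fit",
    "lda_posterior",
    "decision_boundary",
    "smooth_trajectory",
    "summarize_blocks",
    "fit_trend",
    "fatigue_trajectory",
    "erd_timecourse",
]


@dataclass
class LDAParams:
    """Gaussian LDA: class means, pooled covariance, priors."""

    means: np.ndarray          # (2, d)
    cov: np.ndarray            # (d, d), pooled + shrinkage-regularized
    priors: np.ndarray         # (2,), sum to 1
    classes: np.ndarray        # (2,), sorted label values
    shrinkage: float = 1e-4

    @property
    def n_dim(self) -> int:
        return self.means.shape[1]


def lda_fit(T: np.ndarray, y: np.ndarray, shrinkage: float = 1e-4) -> LDAParams:
    """Fit a two-class shared-covariance LDA on latent scores.

    The pooled within-class covariance is shrunk toward its diagonal,
    ``(1 - lambda) S + lambda diag(S)``, to guarantee invertibility for
    near-collinear latent dimensions.  Raises if either class has fewer than
    two samples or if the regularized covariance is still singular.
    """
    y = np.asarray(y)
    T = np.asarray(T, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    if T.shape[0] != y.size:
        raise ValueError("T and y must have one row per epoch")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("LDA here is two-class; got %d classes" % classes.size)

    means, covs, ns = [], [], []
    for c in classes:
        Tc = T[y == c]
        if Tc.shape[0] < 2:
            raise ValueError("need >= 2 samples per class")
        means.append(Tc.mean(axis=0))
        covs.append(np.cov(Tc, rowvar=False, ddof=1))
        ns.append(Tc.shape[0])
    n = sum(ns)
    pooled = sum((nk - 1) * np.atleast_2d(ck) for nk, ck in zip(ns, covs)) / (n - 2)
    reg = (1.0 - shrinkage) * pooled + shrinkage * np.diag(np.diag(pooled))
    try:
        np.linalg.cholesky(reg)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("pooled covariance singular after shrinkage")
    priors = np.array(ns, dtype=float) / n
    return LDAParams(means=np.array(means), cov=reg, priors=priors,
                     classes=classes, shrinkage=shrinkage)


def lda_posterior(params: LDAParams, T_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior probability of the second (high-fatigue) class and decisions.

    Returns ``(posterior, decision)`` where ``posterior[i] = P(class 1 | t_i)``
    under the shared-covariance Gaussian model and ``decision`` is the
    argmax class label (posterior 0.5 boundary).
    """
    T_new = np.asarray(T_new, dtype=float)
    if T_new.ndim == 1:
        T_new = T_new[:, None] if params.n_dim == 1 else T_new[None, :]
    if T_new.shape[1] != params.n_dim:
        raise ValueError("latent dimension mismatch")
    cov_inv = np.linalg.inv(params.cov)
    # linear discriminant scores delta_k = x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + log pi_k
    deltas = np.empty((T_new.shape[0], 2))
    for k in range(2):
        mu = params.means[k]
        deltas[:, k] = (T_new @ cov_inv @ mu - 0.5 * mu @ cov_inv @ mu
                        + np.log(params.priors[k]))
    deltas -= deltas.max(axis=1, keepdims=True)
    expd = np.exp(deltas)
    post = expd / expd.sum(axis=1, keepdims=True)
    decision = params.classes[np.argmax(post, axis=1)]
    return post[:, 1], decision


def decision_boundary(params: LDAParams) -> tuple[np.ndarray, float]:
    """Hyperplane ``w . t + b = 0`` separating the two fatigue domains."""
    cov_inv = np.linalg.inv(params.cov)
    mu0, mu1 = params.means
    w = cov_inv @ (mu1 - mu0)
    b = -0.5 * (mu1 @ cov_inv @ mu1 - mu0 @ cov_inv @ mu0) \
        + np.log(params.priors[1] / params.priors[0])
    return w, float(b)


def smooth_trajectory(series: np.ndarray, window: int = 100) -> np.ndarray:
    """Centered moving average with edge windows truncated to the data.

    Index ``i`` averages ``series[i - (window-1)//2 : i + window//2 + 1]``
    clipped to the series; output length equals input length.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot smooth an empty series")
    if window < 1:
        raise ValueError("window must be >= 1")
    n = series.size
    csum = np.concatenate([[0.0], np.cumsum(series)])
    idx = np.arange(n)
    lo = np.maximum(idx - (window - 1) // 2, 0)
    hi = np.minimum(idx + window // 2 + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def summarize_blocks(posteriors: np.ndarray, epoch_labels: np.ndarray,
                     block_count: int = 3) -> np.ndarray:
    """11-point trajectory: pre-rest, three thirds per VR block, post-rest.

    Each block's epochs are split into three contiguous equal-count thirds
    (remainders go to the earlier thirds) and averaged; the pre-session and
    post-session resting means are prepended and appended.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    labels = np.asarray(epoch_labels).astype(str)
    points = []
    pre = posteriors[np.char.startswith(labels, "pre")]
    if pre.size == 0:
        raise ValueError("no pre-session epochs in the trajectory")
    points.append(pre.mean())
    for b in range(1, block_count + 1):
        blk = posteriors[np.char.startswith(labels, f"block{b}")]
        if blk.size == 0:
            raise ValueError(f"no epochs for block {b}")
        points.extend(part.mean() for part in np.array_split(blk, 3))
    post = posteriors[np.char.startswith(labels, "post")]
    if post.size == 0:
        raise ValueError("no post-session epochs in the trajectory")
    points.append(post.mean())
    return np.array(points)


def fit_trend(points: np.ndarray) -> tuple[float, float]:
    """OLS line ``y = p1 x + p2`` over the stage index x = 1..len(points)."""
    points = np.asarray(points, dtype=float)
    if points.size < 2:
        raise ValueError("need >= 2 points to fit a trend")
    x = np.arange(1, points.size + 1, dtype=float)
    p1, p2 = np.polyfit(x, points, 1)
    return float(p1), float(p2)


@dataclass
class FatigueTrajectory:
    """Per-epoch fatigue posteriors with smoothing, block summary and trend."""

    posteriors: np.ndarray        # P(high fatigue) per epoch
    clean_fraction: np.ndarray
    smoothed: np.ndarray
    block_summary: np.ndarray     # 11 points for a 3-block session
    p1: float                     # trend slope per stage
    p2: float                     # trend intercept
    epoch_onsets: np.ndarray | None = None
    labels: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "onset_s": self.epoch_onsets,
            "posterior": self.posteriors,
            "clean_fraction": self.clean_fraction,
            "smoothed": self.smoothed,
        })


def fatigue_trajectory(posteriors: np.ndarray, clean_fraction: np.ndarray,
                       epoch_labels: np.ndarray, window: int = 100,
                       epoch_onsets: np.ndarray | None = None,
                       block_count: int = 3) -> FatigueTrajectory:
    """Assemble the full trajectory: smooth, summarize into 11 points, fit trend."""
    posteriors = np.asarray(posteriors, dtype=float)
    if np.any((posteriors < -1e-9) | (posteriors > 1 + 1e-9)):
        raise ValueError("posteriors must lie in [0, 1]")
    smoothed = smooth_trajectory(posteriors, window)
    summary = summarize_blocks(smoothed, epoch_labels, block_count)
    p1, p2 = fit_trend(summary)
    return FatigueTrajectory(posteriors=posteriors,
                             clean_fraction=np.asarray(clean_fraction, dtype=float),
                             smoothed=smoothed, block_summary=summary,
                             p1=p1, p2=p2, epoch_onsets=epoch_onsets,
                             labels=np.asarray(epoch_labels))


@dataclass
class ERDTimecourse:
    """Time-locked, baseline-corrected mu-score traces around imagery onsets."""

    times: np.ndarray                       # s relative to onset
    traces: dict                            # category -> mean trace
    n_trials: dict                          # category -> trial count


def erd_timecourse(scores: np.ndarray, score_times: np.ndarray,
                   onsets: np.ndarray, successes: np.ndarray,
                   window: tuple[float, float] = (-5.0, 20.0)) -> ERDTimecourse:
    """Average mu-atom scores time-locked to imagery onsets.

    ``scores`` is a per-epoch series sampled at ``score_times`` (a uniform
    epoch-step grid).  Each trial's trace is baseline-corrected by the mean
    of its pre-onset window; traces are averaged for successful,
    unsuccessful, and all trials.  Trials whose window is not fully covered
    by the score series are skipped.
    """
    scores = np.asarray(scores, dtype=float)
    score_times = np.asarray(score_times, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("no events supplied")
    step = float(np.median(np.diff(score_times)))
    n_pre = int(round(-window[0] / step))
    n_post = int(round(window[1] / step))
    rel_times = np.arange(-n_pre, n_post + 1) * step

    per_trial, flags = [], []
    for onset, ok in zip(onsets, np.asarray(successes, dtype=bool)):
        i = int(np.argmin(np.abs(score_times - onset)))
        if i - n_pre < 0 or i + n_post >= scores.size:
            continue
        tr = scores[i - n_pre:i + n_post + 1].copy()
        tr -= tr[:n_pre].mean() if n_pre > 0 else 0.0
        per_trial.append(tr)
        flags.append(ok)
    if not per_trial:
        raise ValueError("no trial window fully covered by the score series")
    arr = np.array(per_trial)
    flags = np.array(flags)
    traces = {"all": arr.mean(axis=0)}
    counts = {"all": arr.shape[0]}
    for name, mask in (("successful", flags), ("unsuccessful", ~flags)):
        if mask.any():
            traces[name] = arr[mask].mean(axis=0)
            counts[name] = int(mask.sum())
    return ERDTimecourse(times=rel_times, traces=traces, n_trials=counts)
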