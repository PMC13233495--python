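"""Cross-validation and evaluation: confusion metrics, PAM, Spearman, topography.

The Polygon Area Metric (PAM) summarizes seven classifier metrics —
classification accuracy (CA), sensitivity (SE), specificity (SP), area under
the ROC curve (AUC), Jaccard index (JI), Cohen's kappa (K, clipped below at
zero), and F-measure (FM) — as the area of the polygon they span on the
spokes of a regular heptagon with unit circumradius, divided by the full
heptagon's area.  A 6-metric mode is available for comparability with the
original formulation of the metric.

Cross-validation is stratified and leakage-aware: because epochs overlap in
time (0.5 s step on 2 s windows), each class's epochs are split into
contiguous chunks and whole chunks are assigned to folds (seeded), so that
train and test epochs share samples only at a few chunk boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.random import default_rng
from scipy import stats

from .classify import lda_fit, lda_posterior
from .multiway import Atom, NPLSModel, deflate_mu, npls_fit, npls_project
from .spectral import FeatureTensor

__all__ = [
    "MetricsReport",
    "CVResult",
    "confusion_metrics",
    "pam",
    "spearman_rho",
    "topography_test",
    "stratified_folds",
    "crossvalidate",
    "plot_polygon",
]

PAM_ORDER = ("ca", "se", "sp", "auc", "ji", "kappa", "fm")


@dataclass
class MetricsReport:
    """Binary-classification metrics; ``nan`` marks undefined entries."""

    ca: float = np.nan          # classification accuracy
    precision: float = np.nan
    recall: float = np.nan      # = SE (positive-class recall)
    f1: float = np.nan          # = FM
    se: float = np.nan          # sensitivity
    sp: float = np.nan          # specificity
    auc: float = np.nan
    ji: float = np.nan          # Jaccard index
    kappa: float = np.nan       # Cohen's kappa in [-1, 1]
    fm: float = np.nan          # F-measure
    pam: float = np.nan         # polygon area metric
    per_fold: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("ca", "precision", "recall", "f1", "se", "sp",
                 "auc", "ji", "kappa", "fm", "pam")}

    def pam_spokes(self) -> np.ndarray:
        """The 7 PAM inputs in canonical order, kappa clipped below at 0."""
        vals = np.array([self.ca, self.se, self.sp, self.auc,
                         self.ji, self.kappa, self.fm])
        vals[5] = max(vals[5], 0.0)
        return vals


def _rank_auc(posteriors: np.ndarray, y: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic with mid-ranks for ties."""
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = stats.rankdata(posteriors)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def confusion_metrics(y_true: np.ndarray, decisions: np.ndarray,
                      posteriors: np.ndarray | None = None) -> MetricsReport:
    """All listed metrics from the confusion matrix (labels 0/1).

    SE (= recall) or SP are reported as ``nan`` when the corresponding class
    is absent from ``y_true``; AUC requires ``posteriors``.  PAM is filled in
    only when all seven spokes are defined.
    """
    y_true = np.asarray(y_true).astype(int)
    decisions = np.asarray(decisions).astype(int)
    if y_true.shape != decisions.shape:
        raise ValueError("labels and decisions must have equal length")
    tp = int(np.sum((y_true == 1) & (decisions == 1)))
    fp = int(np.sum((y_true == 0) & (decisions == 1)))
    fn = int(np.sum((y_true == 1) & (decisions == 0)))
    tn = int(np.sum((y_true == 0) & (decisions == 0)))
    n = tp + fp + fn + tn

    def ratio(a, b):
        return a / b if b > 0 else np.nan

    ca = ratio(tp + tn, n)
    precision = ratio(tp, tp + fp)
    se = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    f1 = (2 * precision * se / (precision + se)
          if np.isfinite(precision) and np.isfinite(se) and (precision + se) > 0
          else (0.0 if (tp + fp > 0 and tp + fn > 0) else np.nan))
    ji = ratio(tp, tp + fp + fn)
    po = ca
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2 if n else np.nan
    kappa = (po - pe) / (1 - pe) if np.isfinite(pe) and pe < 1 else 0.0
    auc = _rank_auc(np.asarray(posteriors, dtype=float), y_true) \
        if posteriors is not None else np.nan

    report = MetricsReport(ca=ca, precision=precision, recall=se, f1=f1,
                           se=se, sp=sp, auc=auc, ji=ji, kappa=kappa, fm=f1)
    spokes = report.pam_spokes()
    if np.all(np.isfinite(spokes)):
        report.pam = pam(spokes)
    return report


def pam(metrics: Sequence[float]) -> float:
    """Polygon Area Metric: normalized area of the metric polygon.

    ``metrics`` are radii on the spokes of a regular n-gon (n >= 3, here
    usually the 7 metrics CA, SE, SP, AUC, JI, K, FM in that order), each in
    [0, 1] (clip kappa at 0 before calling).  The area of the polygon joining
    adjacent spokes, divided by the full n-gon area, is
    ``sum_i r_i r_{i+1} / n``.
    """
    r = np.asarray(metrics, dtype=float)
    if r.size < 3:
        raise ValueError("PAM needs at least 3 metrics")
    if np.any(r < -1e-12) or np.any(r > 1 + 1e-12):
        raise ValueError("PAM inputs must lie in [0, 1]")
    return float(np.sum(r * np.roll(r, -1)) / r.size)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with mid-ranks for ties.

    Returns ``nan`` for constant inputs (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def topography_test(pre_power: np.ndarray, block_power: np.ndarray,
                    alpha: float = 0.05,
                    correction: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-electrode two-sample Wilcoxon rank-sum test of band power.

    ``pre_power`` and ``block_power`` are (epochs, channels) arrays.  Returns
    ``(pvals, marked)`` with ``marked = pvals < alpha`` — uncorrected by
    default to match per-electrode significance marking on topographic maps;
    ``correction="fdr"`` applies Benjamini-Hochberg.
    """
    pre = np.atleast_2d(np.asarray(pre_power, dtype=float))
    blk = np.atleast_2d(np.asarray(block_power, dtype=float))
    if pre.shape[0] < 2 or blk.shape[0] < 2:
        raise ValueError("need >= 2 epochs per condition")
    if pre.shape[1] != blk.shape[1]:
        raise ValueError("electrode counts differ between conditions")
    pvals = np.array([stats.ranksums(pre[:, c], blk[:, c]).pvalue
                      for c in range(pre.shape[1])])
    if correction == "fdr":
        from statsmodels.stats.multitest import multipletests

        marked = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    elif correction is None:
        marked = pvals < alpha
    else:
        raise ValueError("correction must be None or 'fdr'")
    return pvals, marked


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def stratified_folds(y: np.ndarray, k: int = 5, seed: int = 0,
                     groups: np.ndarray | None = None) -> list[np.ndarray]:
    """Seeded stratified folds built from contiguous per-stratum chunks.

    Each stratum's (time-ordered) epochs are split into ``k`` contiguous
    chunks and one chunk per stratum is assigned to each fold in a seeded
    random order.  A stratum is a class, or a (class, group) pair when
    ``groups`` is given (e.g. eyes-closed vs eyes-open recording condition).
    This keeps folds stratified while limiting the sample sharing of
    temporally overlapping epochs to chunk boundaries; grouping prevents a
    strong within-class covariate from landing wholesale in a single fold.
    """
    y = np.asarray(y)
    rng = default_rng(seed)
    folds = [[] for _ in range(k)]
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        if idx.size < k:
            raise ValueError("every class needs at least k epochs")
        strata = [idx] if groups is None else \
            [idx[groups[idx] == g] for g in np.unique(np.asarray(groups)[idx])]
        for stratum in strata:
            chunks = np.array_split(stratum, k)
            order = rng.permutation(k)
            for f in range(k):
                folds[f].append(chunks[order[f]])
    return [np.sort(np.concatenate(parts)) for parts in folds]


@dataclass
class CVResult:
    """Per-fold models and metrics plus pooled test-set metrics."""

    models: list[NPLSModel]
    lda: list
    fold_metrics: list[MetricsReport]
    fold_indices: list[np.ndarray]
    fold_accuracy: np.ndarray
    overall: MetricsReport

    @property
    def accuracy_mean(self) -> float:
        return float(self.fold_accuracy.mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.fold_accuracy.std(ddof=1))


def crossvalidate(X: FeatureTensor, y: np.ndarray, k: int = 5,
                  n_factors: int = 4, mu_atom: Atom | None = None,
                  shrinkage: float = 1e-4, seed: int = 0,
                  groups: np.ndarray | None = None) -> CVResult:
    """Stratified k-fold evaluation of the N-PLS + LDA pipeline.

    Per fold: (optional) mu-atom deflation of train and test tensors, N-PLS
    fit on the training epochs, LDA on the training latent scores, and
    held-out evaluation.  Pooled held-out decisions across folds give the
    overall metrics, including PAM.  ``groups`` (e.g. eyes-closed/eyes-open
    condition tags) refines the fold stratification; see
    :func:`stratified_folds`.
    """
    y = np.asarray(y).astype(int)
    if X.n_epochs != y.size:
        raise ValueError("one label per epoch required")
    if mu_atom is not None:
        X = deflate_mu(X, mu_atom)
    folds = stratified_folds(y, k=k, seed=seed, groups=groups)
    all_idx = np.concatenate(folds)
    assert np.array_equal(np.sort(all_idx), np.arange(y.size)), \
        "folds must partition the epochs"

    models, ldas, reports = [], [], []
    pooled_y, pooled_dec, pooled_post = [], [], []
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.where(train_mask)[0]
        assert np.unique(y[test_idx]).size == 2 and np.unique(y[train_idx]).size == 2
        Xtr, Xte = X.select_epochs(train_idx), X.select_epochs(test_idx)
        model = npls_fit(Xtr, y[train_idx], n_factors)
        params = lda_fit(model.T, y[train_idx], shrinkage=shrinkage)
        T_te = npls_project(model, Xte)
        post, dec = lda_posterior(params, T_te)
        reports.append(confusion_metrics(y[test_idx], dec, post))
        models.append(model)
        ldas.append(params)
        pooled_y.append(y[test_idx])
        pooled_dec.append(dec)
        pooled_post.append(post)

    overall = confusion_metrics(np.concatenate(pooled_y),
                                np.concatenate(pooled_dec),
                                np.concatenate(pooled_post))
    overall.per_fold = reports
    return CVResult(models=models, lda=ldas, fold_metrics=reports,
                    fold_indices=folds,
                    fold_accuracy=np.array([r.ca for r in reports]),
                    overall=overall)


def plot_polygon(report: MetricsReport, ax=None, label: str | None = None):
    """Radar plot of the 7 PAM spokes; returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    spokes = report.pam_spokes()
    n = spokes.size
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    closed_a = np.concatenate([angles, angles[:1]])
    closed_r = np.concatenate([spokes, spokes[:1]])
    ax.plot(closed_a, closed_r, label=label)
    ax.fill(closed_a, closed_r, alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels([m.upper() for m in PAM_ORDER])
    ax.set_ylim(0, 1)
    if label:
        ax.legend(loc="lower right")
    return ax
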