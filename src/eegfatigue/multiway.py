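"""Multiway (tensor) models: PARAFAC atoms, N-PLS regression, mu-atom deflation.

The feature tensor ``X`` (epochs x frequency x channels) is modelled with two
trilinear tools:

* **PARAFAC** — an unsupervised decomposition
  ``X = sum_r  t_r o w_r(2) o w_r(3) + E`` into rank-1 "atoms", each an
  elementary oscillatory component with a frequency weight vector, a spatial
  (electrode) weight vector, and per-epoch scores.  Fit by alternating least
  squares (ALS) with random restarts.  Scale indeterminacy is resolved by
  unit-norm weight vectors (magnitude absorbed into the scores) and sign
  indeterminacy by making the largest-magnitude spatial weight positive.

* **N-PLS (tri-PLS1)** — a supervised variant for a binary response
  ``y`` (0 = low fatigue, 1 = high fatigue).  Per factor, the weight pair
  ``(w_freq, w_chan)`` maximizing ``cov(t, u)`` with
  ``t_i = <X_i, w_freq o w_chan>`` is the leading singular pair of
  ``Z = sum_i y_i X_i`` (both X and y centered); X is then deflated by the
  rank-1 factor contribution and y by its fitted part, and the regression
  coefficients ``B`` are obtained by least squares of y on the score matrix
  ``T``.

Task-related sensorimotor activity (the mu rhythm) that leaks into
fatigue models is removed by **deflation**: the PARAFAC mu atom, extracted
from a 10-electrode central subset, is zero-padded to the full montage and
its rank-1 contribution ``t_r o w_r(2) o w_r(3)`` subtracted from the tensor.
For epochs without training scores, the per-epoch score is the least-squares
projection ``t_i = <X_i, P> / <P, P>`` with ``P = w_freq o w_chan``, which
makes repeated deflation idempotent.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.random import default_rng

from .montage import CENTRAL_10
from .spectral import FeatureTensor

__all__ = [
    "Atom",
    "NPLSModel",
    "ParafacResult",
    "parafac_als",
    "extract_mu_atom",
    "npls_fit",
    "npls_project",
    "npls_predict",
    "deflate_mu",
    "average_atoms",
    "select_component_subset",
    "enumerate_subsets",
    "tucker_congruence",
]

logger = logging.getLogger(__name__)


@dataclass
class Atom:
    """A rank-1 oscillatory component: frequency x space weights + scores."""

    freq_weights: np.ndarray            # unit norm, over frequency bins
    spatial_weights: np.ndarray         # unit norm, over channel_support
    scores: np.ndarray | None = None    # per-epoch loadings (magnitude carrier)
    channel_support: tuple[str, ...] | None = None
    freq_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("freq_weights", "spatial_weights"):
            v = getattr(self, name)
            n = np.linalg.norm(v)
            if n > 0 and abs(n - 1.0) > 1e-6:
                raise ValueError(f"{name} must be unit norm")

    @property
    def peak_frequency(self) -> float | None:
        if self.freq_axis is None:
            return None
        return float(self.freq_axis[np.argmax(np.abs(self.freq_weights))])


@dataclass
class ParafacResult:
    """Atoms from an ALS fit plus convergence information (sequence-like)."""

    atoms: list[Atom]
    converged: bool
    n_iter: int
    fit: float  # 1 - ||X - Xhat|| / ||X||

    def __iter__(self):
        return iter(self.atoms)

    def __len__(self):
        return len(self.atoms)

    def __getitem__(self, i):
        return self.atoms[i]


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Signed cosine similarity between two weight vectors."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _normalize_factors(A: np.ndarray, B: np.ndarray, C: np.ndarray):
    """Unit-norm B and C columns, magnitude into A; fix signs.

    Sign convention: the largest-magnitude spatial weight (C) and frequency
    weight (B) are made positive; each flip is absorbed into the scores so the
    reconstructed tensor is unchanged.
    """
    for M in (B, C):
        norms = np.linalg.norm(M, axis=0)
        norms[norms == 0] = 1.0
        M /= norms
        A *= norms
    for M in (B, C):
        signs = np.sign(M[np.argmax(np.abs(M), axis=0), np.arange(M.shape[1])])
        signs[signs == 0] = 1.0
        M *= signs
        A *= signs
    return A, B, C


def parafac_als(X, rank: int, tol: float = 1e-8, max_iter: int = 500,
                n_restarts: int = 5, seed: int = 0) -> ParafacResult:
    """Rank-R PARAFAC decomposition of a 3-way tensor by ALS.

    Parameters
    ----------
    X : ndarray or FeatureTensor, shape (epochs, freqs, channels)
    rank : int
        Number of atoms R >= 1.
    tol : float
        Convergence threshold on the relative change of the fit.
    max_iter : int
        ALS iteration cap per restart; on non-convergence the best iterate is
        returned with ``converged=False``.
    n_restarts : int
        Random initializations; the best final fit wins.
    seed : int
        Seeds the initializations (reproducible results).
    """
    tensor = X if isinstance(X, FeatureTensor) else None
    vals = np.asarray(X.values if tensor is not None else X, dtype=float)
    if vals.ndim != 3:
        raise ValueError("PARAFAC input must be a 3-way tensor")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    norm_x = np.linalg.norm(vals)
    if norm_x == 0:
        raise ValueError("cannot decompose an all-zero tensor")
    rng = default_rng(seed)
    I, J, K = vals.shape

    best = None
    for restart in range(max(n_restarts, 1)):
        if restart == 0:
            # HOSVD initialization: leading singular vectors of each unfolding.
            # Random ALS inits can fall into two-factor degeneracies (two
            # components collapsing onto the strongest true factor); the
            # singular-vector start avoids that basin for well-separated
            # factors.  Remaining restarts stay random.
            A, B, C = (_svd_init(vals, mode, rank, rng) for mode in range(3))
        else:
            A = rng.standard_normal((I, rank))
            B = rng.standard_normal((J, rank))
            C = rng.standard_normal((K, rank))
        prev_fit = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            A = _ls_update(vals, B, C, "ijk,jr,kr->ir")
            B = _ls_update(vals, A, C, "ijk,ir,kr->jr")
            C = _ls_update(vals, A, B, "ijk,ir,jr->kr")
            A, B, C = _normalize_factors(A, B, C)
            xhat = np.einsum("ir,jr,kr->ijk", A, B, C)
            fit = 1.0 - np.linalg.norm(vals - xhat) / norm_x
            if abs(fit - prev_fit) < tol:
                converged = True
                break
            prev_fit = fit
        cand = (fit, converged, it, A, B, C)
        if best is None or cand[0] > best[0]:
            best = cand

    fit, converged, n_iter, A, B, C = best
    if not converged:
        logger.warning("PARAFAC ALS did not converge within %d iterations", max_iter)
    order = np.argsort(-np.linalg.norm(A, axis=0))
    atoms = [
        Atom(freq_weights=B[:, r], spatial_weights=C[:, r], scores=A[:, r],
             channel_support=tuple(tensor.channel_labels) if tensor is not None else None,
             freq_axis=tensor.freqs.copy() if tensor is not None else None)
        for r in order
    ]
    return ParafacResult(atoms=atoms, converged=converged, n_iter=n_iter, fit=fit)


def _svd_init(vals, mode, rank, rng):
    """Leading left singular vectors of the mode unfolding, padded if needed."""
    unf = np.moveaxis(vals, mode, 0).reshape(vals.shape[mode], -1)
    U, _, _ = np.linalg.svd(unf, full_matrices=False)
    M = U[:, :rank]
    if M.shape[1] < rank:
        pad = rng.standard_normal((M.shape[0], rank - M.shape[1]))
        M = np.hstack([M, pad])
    return M


def _ls_update(vals, M1, M2, pattern):
    """One ALS step: solve the mode's least-squares problem."""
    mttkrp = np.einsum(pattern, vals, M1, M2, optimize=True)
    gram = (M1.T @ M1) * (M2.T @ M2)
    return np.linalg.solve(gram.T, mttkrp.T).T if np.linalg.cond(gram) < 1e12 \
        else mttkrp @ np.linalg.pinv(gram)


def extract_mu_atom(tensor: FeatureTensor,
                    central_labels: Sequence[str] = CENTRAL_10,
                    mu_center: float = 10.75, rank: int = 3,
                    seed: int = 0, n_restarts: int = 5) -> Atom:
    """PARAFAC mu atom from the 10 central electrodes.

    Decomposes the tensor restricted to the sensorimotor subset and returns
    the atom whose frequency-weight peak lies closest to ``mu_center``.  The
    returned atom's ``channel_support`` names the subset, ready for
    zero-padded deflation.
    """
    sub = tensor.select_channels([lb for lb in central_labels
                                  if lb in tensor.channel_labels])
    res = parafac_als(sub, rank=rank, seed=seed, n_restarts=n_restarts)
    peaks = [a.peak_frequency for a in res.atoms]
    best = int(np.argmin([abs(p - mu_center) for p in peaks]))
    return res.atoms[best]


# --------------------------------------------------------------------------
# N-PLS (tri-PLS1)
# --------------------------------------------------------------------------

@dataclass
class NPLSModel:
    """A fitted tri-linear PLS model for a binary fatigue response."""

    n_factors: int
    freq_weights: np.ndarray        # (F, n_freqs), rows unit norm
    spatial_weights: np.ndarray     # (F, n_channels), rows unit norm
    T: np.ndarray                   # (n_epochs, F) latent X scores
    U: np.ndarray                   # (n_epochs, F) Y scores (residual-y per factor)
    q: np.ndarray                   # (F,) Y loadings (1 for a single column)
    B: np.ndarray                   # (F,) regression coefficients
    x_mean: np.ndarray              # (n_freqs, n_channels) training mean
    y_mean: float
    E: np.ndarray = None            # X residual after F factors
    C: np.ndarray = None            # y residual after per-factor deflation
    H: np.ndarray = None            # y - (T B + y_mean)
    freqs: np.ndarray = None
    channel_labels: tuple[str, ...] = None

    def atoms(self) -> list[Atom]:
        return [Atom(freq_weights=self.freq_weights[f],
                     spatial_weights=self.spatial_weights[f],
                     scores=self.T[:, f],
                     channel_support=self.channel_labels,
                     freq_axis=None if self.freqs is None else self.freqs.copy())
                for f in range(self.n_factors)]


def _check_axes(model: NPLSModel, tensor: FeatureTensor) -> None:
    if model.freqs is not None and (tensor.freqs.size != model.freqs.size
                                    or not np.allclose(tensor.freqs, model.freqs)):
        raise ValueError("frequency axis of the new tensor does not match training")
    if model.channel_labels is not None and tuple(tensor.channel_labels) != tuple(model.channel_labels):
        raise ValueError("channel axis of the new tensor does not match training")


def npls_fit(X: FeatureTensor, y: np.ndarray, n_factors: int) -> NPLSModel:
    """Fit a tri-PLS1 model of the binary labels on the feature tensor.

    Per factor the covariance-maximizing weights are the leading singular
    pair of ``Z = sum_i y_i X_i`` computed on centered data; X is deflated by
    the rank-1 factor contribution and y by its fitted part between factors.
    Constant labels raise (the covariance criterion is undefined); a factor
    request beyond the effective tensor rank truncates with a warning.
    """
    y = np.asarray(y, dtype=float)
    vals = np.asarray(X.values, dtype=float)
    if y.shape != (vals.shape[0],):
        raise ValueError("y must have one label per epoch")
    if np.ptp(y) == 0:
        raise ValueError("labels are constant; covariance with y is undefined")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")

    x_mean = vals.mean(axis=0)
    y_mean = float(y.mean())
    Xc = vals - x_mean
    yc = y - y_mean
    scale0 = None

    Wf, Wc, ts, us = [], [], [], []
    for f in range(n_factors):
        Z = np.einsum("i,ijk->jk", yc, Xc, optimize=True)
        zn = np.linalg.norm(Z)
        if scale0 is None:
            scale0 = zn
        if zn < 1e-12 * max(scale0, 1.0):
            warnings.warn(f"requested {n_factors} factors but the tensor supports "
                          f"only {f}; truncating", stacklevel=2)
            break
        U_, s_, Vt_ = np.linalg.svd(Z, full_matrices=False)
        wf, wc = U_[:, 0], Vt_[0, :]
        sgn = np.sign(wc[np.argmax(np.abs(wc))]) or 1.0
        wf, wc = wf * sgn, wc * sgn  # joint flip leaves wf o wc unchanged
        t = np.einsum("ijk,j,k->i", Xc, wf, wc, optimize=True)
        Wf.append(wf)
        Wc.append(wc)
        ts.append(t)
        us.append(yc.copy())
        Xc = Xc - t[:, None, None] * np.outer(wf, wc)[None, :, :]
        tt = t @ t
        if tt > 0:
            yc = yc - t * (t @ yc) / tt

    F = len(Wf)
    T = np.column_stack(ts)
    B, *_ = np.linalg.lstsq(T, y - y_mean, rcond=None)
    H = y - (T @ B + y_mean)
    return NPLSModel(n_factors=F, freq_weights=np.array(Wf),
                     spatial_weights=np.array(Wc), T=T, U=np.column_stack(us),
                     q=np.ones(F), B=B, x_mean=x_mean, y_mean=y_mean,
                     E=Xc, C=yc, H=H, freqs=X.freqs.copy(),
                     channel_labels=tuple(X.channel_labels))


def npls_project(model: NPLSModel, X_new: FeatureTensor) -> np.ndarray:
    """Latent scores of new data under a fixed model (no refitting).

    Subtracts the training X mean, then applies the training factor sequence
    with the same between-factor deflation.
    """
    _check_axes(model, X_new)
    Xc = np.asarray(X_new.values, dtype=float) - model.x_mean
    T = np.empty((Xc.shape[0], model.n_factors))
    for f in range(model.n_factors):
        wf, wc = model.freq_weights[f], model.spatial_weights[f]
        t = np.einsum("ijk,j,k->i", Xc, wf, wc, optimize=True)
        T[:, f] = t
        Xc = Xc - t[:, None, None] * np.outer(wf, wc)[None, :, :]
    return T


def npls_predict(model: NPLSModel, X_new: FeatureTensor,
                 factors: Sequence[int] | None = None) -> np.ndarray:
    """Regression prediction ``T B + y_mean`` (optionally on a factor subset)."""
    T = npls_project(model, X_new)
    if factors is None:
        return T @ model.B + model.y_mean
    factors = list(factors)
    y_centered = model.T @ model.B + model.H  # training y minus its mean
    B, *_ = np.linalg.lstsq(model.T[:, factors], y_centered, rcond=None)
    return T[:, factors] @ B + model.y_mean


# --------------------------------------------------------------------------
# deflation
# --------------------------------------------------------------------------

def deflate_mu(X: FeatureTensor, atom: Atom) -> FeatureTensor:
    """Remove a rank-1 atom's contribution from the tensor.

    The atom's spatial weights (possibly defined on an electrode subset such
    as the 10 central channels) are zero-padded to the tensor's montage
    without reordering; per-epoch scores are the least-squares projections
    ``t_i = <X_i, P> / <P, P>`` with ``P = w_freq o w_chan``, and
    ``X_deflated = X - t o P``.
    """
    if atom.freq_axis is not None:
        if atom.freq_axis.size != X.freqs.size or not np.allclose(atom.freq_axis, X.freqs):
            raise ValueError("atom frequency grid cannot be aligned with the tensor")
    elif atom.freq_weights.size != X.freqs.size:
        raise ValueError("atom frequency grid cannot be aligned with the tensor")

    wc_full = np.zeros(len(X.channel_labels))
    support = atom.channel_support or X.channel_labels
    missing = [lb for lb in support if lb not in X.channel_labels]
    if missing:
        raise ValueError(f"atom channels {missing} are not in the tensor montage")
    for w, lb in zip(atom.spatial_weights, support):
        wc_full[X.channel_labels.index(lb)] = w

    P = np.outer(atom.freq_weights, wc_full)
    pp = float(np.sum(P * P))
    vals = np.asarray(X.values, dtype=float)
    if pp == 0:
        return FeatureTensor(vals.copy(), X.freqs, X.channel_labels,
                             X.epoch_labels, X.component)
    t = np.einsum("ijk,jk->i", vals, P, optimize=True) / pp
    deflated = vals - t[:, None, None] * P[None, :, :]
    return FeatureTensor(deflated, X.freqs, X.channel_labels,
                         X.epoch_labels, X.component)


# --------------------------------------------------------------------------
# cross-fold aggregation and subset selection
# --------------------------------------------------------------------------

def average_atoms(models: Sequence[NPLSModel],
                  congruence_floor: float = 0.6) -> list[Atom]:
    """Average matching factors across cross-validation folds into general atoms.

    Factors are matched to the first fold's by greedy maximal Tucker
    congruence (product of frequency- and spatial-mode congruences), signs are
    aligned to the first fold per mode, and the matched weight vectors are
    averaged and re-normalized.  A reference factor whose mean congruence with
    its matches falls below ``congruence_floor`` is excluded and logged.
    """
    if len(models) < 2:
        raise ValueError("need at least two folds to average")
    ref = models[0]
    n_ref = ref.n_factors
    sums_f = [ref.freq_weights[r].copy() for r in range(n_ref)]
    sums_c = [ref.spatial_weights[r].copy() for r in range(n_ref)]
    congs = [[] for _ in range(n_ref)]

    for m in models[1:]:
        cmat = np.zeros((n_ref, m.n_factors))
        for r in range(n_ref):
            for s in range(m.n_factors):
                cf = tucker_congruence(ref.freq_weights[r], m.freq_weights[s])
                cc = tucker_congruence(ref.spatial_weights[r], m.spatial_weights[s])
                cmat[r, s] = abs(cf) * abs(cc)
        taken_r, taken_s = set(), set()
        flat = sorted(((cmat[r, s], r, s) for r in range(n_ref)
                       for s in range(m.n_factors)), reverse=True)
        for c, r, s in flat:
            if r in taken_r or s in taken_s:
                continue
            taken_r.add(r)
            taken_s.add(s)
            sf = np.sign(tucker_congruence(ref.freq_weights[r], m.freq_weights[s])) or 1.0
            sc = np.sign(tucker_congruence(ref.spatial_weights[r], m.spatial_weights[s])) or 1.0
            sums_f[r] += sf * m.freq_weights[s]
            sums_c[r] += sc * m.spatial_weights[s]
            congs[r].append(c)

    atoms = []
    for r in range(n_ref):
        mean_c = float(np.mean(congs[r])) if congs[r] else 0.0
        if mean_c < congruence_floor:
            logger.warning("factor %d excluded from the general atom "
                           "(mean congruence %.3f < %.2f)", r, mean_c, congruence_floor)
            continue
        wf = sums_f[r] / np.linalg.norm(sums_f[r])
        wc = sums_c[r] / np.linalg.norm(sums_c[r])
        atoms.append(Atom(freq_weights=wf, spatial_weights=wc, scores=None,
                          channel_support=ref.channel_labels,
                          freq_axis=None if ref.freqs is None else ref.freqs.copy()))
    return atoms


def enumerate_subsets(n_factors: int, max_size: int = 4):
    """All non-empty factor-index subsets of size <= max_size, ordered."""
    out = []
    for size in range(1, min(n_factors, max_size) + 1):
        out.extend(itertools.combinations(range(n_factors), size))
    return out


def select_component_subset(subset_scores: Mapping[tuple, float]) -> tuple:
    """Pick the factor subset with the highest mean validation accuracy.

    Ties break toward fewer factors, then toward lower factor indices.
    """
    if not subset_scores:
        raise ValueError("no candidate subsets supplied")
    return min(subset_scores,
               key=lambda s: (-subset_scores[s], len(s), tuple(s)))
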