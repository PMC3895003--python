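"""Eigen-optimized indicator vector via the method of snapshots.

Standard-form sequences restricted to the high-value loci are embedded in
Euclidean space (symbol 2 -> +1, symbol 1 -> -1), so the squared distance
between two embedded sequences is four times their Hamming distance.  The
indicator vector v is the unit vector maximizing the mean squared
projection of the disease rows minus that of the control rows,

    J(v) = <(x . v)^2>_D - <(x . v)^2>_C,   ||v|| = 1,

i.e. the leading eigenvector of K = D'D/n_d - C'C/n_c.  Because v must lie
in the span of the data rows, the L x L eigenproblem collapses to an
n x n one on the Gram matrix of the stacked data (the method of
snapshots), with n = n_d + n_c samples and L selected loci, L >> n.

Components of v rescale to pseudo-probabilities; only loci whose symbol is
"overprobable" (pseudo-probability beyond a retention level theta) are kept
in the refined classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .modal import (GaussianFits, LocusSelection, ModalIndicator, ROCResult,
                    _resolve_xy, fit_gaussians, mode_word, roc_error, score,
                    select_high_value)
from .standard_form import MISSING, AlleleMatrix
from . import locus_stats
from sklearn.base import BaseEstimator, ClassifierMixin

#: squared Euclidean distance per unit Hamming distance under the embedding
EUCLIDEAN_HAMMING_FACTOR = 4.0

_EMBED = {1: -1.0, 2: +1.0}


def embed(symbols: np.ndarray, selection: LocusSelection | None = None) -> np.ndarray:
    """Map symbols {1, 2} -> {-1, +1} on the selected loci.

    The cohort mean at a locus with P(symbol 2) = p is 2p - 1, and squared
    Euclidean distances equal ``EUCLIDEAN_HAMMING_FACTOR`` times Hamming
    distances.
    """
    sym = np.asarray(symbols)
    if selection is not None:
        sym = sym[:, selection.indices]
    if (sym == MISSING).any():
        raise ValueError("missing symbols cannot be embedded; impute first")
    return (2.0 * sym - 3.0).astype(float)


@dataclass
class IndicatorVector:
    """Leading solution of the disease-contrast criterion eigenproblem."""

    v: np.ndarray                 # unit vector, length L
    eigenvalue: float             # criterion value J(v)
    snapshot_coeffs: np.ndarray | None  # admixture coefficients a (length n), if snapshot path
    method: str                   # "snapshot" | "direct"

    def criterion(self, D: np.ndarray, C: np.ndarray) -> float:
        """Evaluate J(v) on given embedded cohorts."""
        return float(((D @ self.v) ** 2).mean() - ((C @ self.v) ** 2).mean())


def criterion_value(v: np.ndarray, D: np.ndarray, C: np.ndarray) -> float:
    """Mean-squared-projection contrast of a unit vector v."""
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    return float(((D @ v) ** 2).mean() - ((C @ v) ** 2).mean())


def solve_indicator(D: np.ndarray, C: np.ndarray, method: str = "auto") -> IndicatorVector:
    """Maximize the criterion functional over unit vectors.

    Parameters
    ----------
    D, C
        Embedded disease (n_d x L) and control (n_c x L) matrices.
    method
        "snapshot" solves the n x n problem W X X' a = lambda a with
        W = diag(+1/n_d, ..., -1/n_c, ...) and reconstructs v = X'a;
        "direct" densely diagonalizes K = D'D/n_d - C'C/n_c; "auto"
        picks direct when L <= n.

    Returns the largest-eigenvalue solution, oriented so that
    v . (mean(D) - mean(C)) >= 0.  Warns (instead of failing) when no
    positive eigenvalue exists — identical cohorts give K = 0.
    """
    D = np.asarray(D, dtype=float)
    C = np.asarray(C, dtype=float)
    n_d, n_c = D.shape[0], C.shape[0]
    if n_d < 2 or n_c < 2:
        raise ValueError("need at least 2 samples per cohort")
    if D.shape[1] != C.shape[1]:
        raise ValueError("D and C must share the locus dimension")
    L = D.shape[1]
    n = n_d + n_c
    if not (np.any(D) or np.any(C)):
        raise ValueError("all-zero data")
    if method == "auto":
        method = "direct" if L <= n else "snapshot"

    if method == "direct":
        K = D.T @ D / n_d - C.T @ C / n_c
        vals, vecs = scipy.linalg.eigh(K)
        lam = float(vals[-1])
        v = vecs[:, -1]
        a = None
    elif method == "snapshot":
        X = np.vstack([D, C])
        w = np.concatenate([np.full(n_d, 1.0 / n_d), np.full(n_c, -1.0 / n_c)])
        G = X @ X.T
        M = w[:, None] * G
        # ||K||_F^2 = trace(K^2) = trace((WG)^2): detect a vanishing
        # contrast (identical cohorts) before trusting the eigensolver,
        # whose spectrum for a numerically nilpotent M is pure noise.
        fro_k = float(np.sqrt(max(np.trace(M @ M), 0.0)))
        data_scale = np.linalg.norm(D) ** 2 / n_d + np.linalg.norm(C) ** 2 / n_c
        if fro_k <= 1e-10 * max(data_scale, 1.0):
            warnings.warn(
                "criterion has no positive eigenvalue: disease projections "
                "never exceed control; cohorts may be identical", stacklevel=2,
            )
            v = X[0] / np.linalg.norm(X[0])
            return IndicatorVector(v=v, eigenvalue=0.0, snapshot_coeffs=None,
                                   method="snapshot")
        vals, vecs = scipy.linalg.eig(M)
        # W indefinite -> M non-symmetric, but nonzero eigenvalues shared
        # with the symmetric K; take the largest (essentially) real one.
        real = np.abs(vals.imag) <= 1e-8 * (np.abs(vals.real) + 1.0)
        if not real.any():
            raise RuntimeError("snapshot eigenproblem returned no real eigenvalue")
        cand = np.where(real, vals.real, -np.inf)
        j = int(np.argmax(cand))
        lam = float(vals[j].real)
        a = vecs[:, j].real
        resid = np.linalg.norm(M @ a - lam * a)
        tol = 1e-8 * max(1.0, abs(lam)) * np.linalg.norm(a)
        if resid > tol:
            raise RuntimeError(
                f"snapshot eigenpair residual {resid:.3e} exceeds tolerance {tol:.3e}"
            )
        v = X.T @ a
        nv = np.linalg.norm(v)
        if nv == 0.0:
            raise RuntimeError("snapshot eigenvector reconstructs to zero")
        v = v / nv
        a = a / nv
    else:
        raise ValueError(f"unknown method {method!r}")

    # scale-aware zero test: identical cohorts give K = 0 up to rounding
    scale = np.linalg.norm(D) ** 2 / n_d + np.linalg.norm(C) ** 2 / n_c
    zero_tol = 1e-10 * max(scale, 1.0)
    if lam <= zero_tol:
        if abs(lam) <= zero_tol:
            lam = 0.0
        warnings.warn(
            "criterion has no positive eigenvalue: disease projections never "
            "exceed control; cohorts may be identical", stacklevel=2,
        )
    contrast = D.mean(axis=0) - C.mean(axis=0)
    if float(v @ contrast) < 0:
        v = -v
        if a is not None:
            a = -a
    return IndicatorVector(v=v, eigenvalue=lam, snapshot_coeffs=a, method=method)


@dataclass
class PseudoProbabilities:
    """Pseudo-probability refinement of an indicator vector."""

    theta: float
    v_scaled: np.ndarray        # v / max|v|
    p_star: np.ndarray          # (1 + v_scaled) / 2, in [0, 1]
    p_diagnostic: np.ndarray    # RMS-scaled version; may leave [0, 1]
    retained_mask: np.ndarray   # bool over the selection's loci
    word: np.ndarray            # symbols on retained loci


def pseudo_probabilities(iv: IndicatorVector, theta: float = 0.5) -> PseudoProbabilities:
    """Retain loci whose indicator component is overprobable.

    The unit vector is rescaled by its largest |component|, mapped
    affinely to [0, 1] as p* = (1 + v')/2, and a locus is retained when
    max(p*, 1 - p*) > theta; its word symbol is 2 where v' > 0, else 1.
    A second, RMS-based scaling (v * sqrt(L)) is reported as a diagnostic:
    those values can exceed 1 or go negative, which is what earns the
    name pseudo-probability.  The level theta is not critical; 0.5 keeps
    every locus with any signed signal.
    """
    if not (0.5 <= theta < 1.0):
        raise ValueError("theta must lie in [0.5, 1)")
    v = np.asarray(iv.v, dtype=float)
    vmax = np.abs(v).max()
    if vmax == 0.0:
        raise ValueError("zero indicator vector")
    v_scaled = v / vmax
    p_star = (1.0 + v_scaled) / 2.0
    p_diag = (1.0 + v * np.sqrt(v.size)) / 2.0
    retained = np.maximum(p_star, 1.0 - p_star) > theta
    word = np.where(v_scaled > 0, 2, 1).astype(np.int8)
    return PseudoProbabilities(theta, v_scaled, p_star, p_diag, retained, word)


class IndicatorClassifier(ClassifierMixin, BaseEstimator):
    """Refined classifier from the eigen-optimized indicator vector.

    fit() screens loci by allele odds ratio exactly as
    :class:`~akernel.modal.ModalClassifier`, embeds the selected
    sub-matrix, solves the criterion eigenproblem by the method of
    snapshots, retains loci with overprobable pseudo-probability
    (> ``theta``) and calibrates a score threshold on the retained word.

    Attributes (after fit)
    ----------------------
    selection_ : LocusSelection over all loci clearing odds_threshold
    indicator_vector_ : IndicatorVector
    pseudo_ : PseudoProbabilities
    retained_indices_ : absolute column indices kept after refinement
    word_ : ModalIndicator-compatible word on the retained loci
    delta_star_, e_min_, fits_, roc_ : score calibration
    """

    def __init__(self, odds_threshold: float = 2.4, theta: float = 0.5,
                 side: str = "one", method: str = "auto",
                 grid_points: int = 10_000):
        self.odds_threshold = odds_threshold
        self.theta = theta
        self.side = side
        self.method = method
        self.grid_points = grid_points

    def fit(self, X, y=None):
        sym, dmask, classes, pos = _resolve_xy(X, y)
        n_d, n_c = int(dmask.sum()), int((~dmask).sum())
        if n_d < 2 or n_c < 2:
            raise ValueError("need at least 2 samples in each cohort")
        p_d = (sym[dmask] == 2).mean(axis=0)
        p_c = (sym[~dmask] == 2).mean(axis=0)
        self.omega_ = locus_stats.allele_odds_ratio(p_d, p_c, n_d=n_d, n_c=n_c)
        self.selection_ = select_high_value(self.omega_, self.odds_threshold, self.side)
        if self.selection_.size == 0:
            raise ValueError(
                f"no locus clears odds_threshold={self.odds_threshold}; lower Lambda"
            )
        D = embed(sym[dmask], self.selection_)
        C = embed(sym[~dmask], self.selection_)
        self.indicator_vector_ = solve_indicator(D, C, method=self.method)
        self.pseudo_ = pseudo_probabilities(self.indicator_vector_, self.theta)
        keep = self.pseudo_.retained_mask
        if not keep.any():
            raise ValueError("no locus retained; lower theta")
        self.retained_indices_ = self.selection_.indices[keep]
        retained_sel = LocusSelection(
            self.selection_.lam, self.retained_indices_,
            self.selection_.omega[keep], self.selection_.side,
        )
        self.word_ = ModalIndicator(retained_sel, self.pseudo_.word[keep])
        s_d = score(sym[dmask], self.word_)
        s_c = score(sym[~dmask], self.word_)
        self.fits_ = fit_gaussians(s_d, s_c)
        self.roc_ = roc_error(self.fits_, n_d, n_c, self.grid_points,
                              scores_d=s_d, scores_c=s_c)
        self.delta_star_ = self.roc_.delta_star
        self.e_min_ = self.roc_.e_min
        self.classes_ = np.array([c for c in classes if c != pos] + [pos])
        self.n_features_in_ = sym.shape[1]
        return self

    def score_samples(self, X) -> np.ndarray:
        sym = X.symbols if isinstance(X, AlleleMatrix) else np.asarray(X)
        return score(sym, self.word_)

    def decision_function(self, X) -> np.ndarray:
        return self.score_samples(X) - self.delta_star_

    def predict(self, X) -> np.ndarray:
        neg, pos = self.classes_
        return np.where(self.decision_function(X) >= 0, pos, neg)
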