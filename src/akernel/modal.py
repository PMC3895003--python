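"""Modal indicator classifier: locus screening, mode word, scores, ROC.

High-value loci are the allele compartments whose disease/control odds
ratio omega clears a threshold Lambda.  The modal indicator is the word of
disease-cohort modal symbols over those loci; a sample's score is the
number of selected loci where its symbols agree with the word.  Scores of
each cohort are fit by gaussians (central limit theorem) and the decision
threshold Delta* minimizes the expected misclassification count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin

from . import locus_stats
from .standard_form import CONTROL, DISEASE, MISSING, AlleleMatrix


@dataclass(frozen=True)
class LocusSelection:
    """An ordered set of allele-locus indices with omega >= Lambda."""

    lam: float
    indices: np.ndarray          # ascending 0-based column indices
    omega: np.ndarray            # omega at the selected loci
    side: str = "one"
    risk_symbols: np.ndarray | None = None  # two-sided: enriched symbol per locus

    def __post_init__(self):
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.intp))
        object.__setattr__(self, "omega", np.asarray(self.omega, dtype=float))

    @property
    def size(self) -> int:
        return int(self.indices.size)


def select_high_value(omega: np.ndarray, lam: float, side: str = "one") -> LocusSelection:
    """Select allele loci whose odds ratio clears the threshold Lambda.

    One-sided (default) keeps loci with omega >= Lambda (symbol 2 enriched
    in disease); two-sided keeps max(omega, 1/omega) >= Lambda and records
    the disease-enriched symbol per locus.  Selections are nested in
    Lambda by construction.
    """
    omega = np.asarray(omega, dtype=float)
    if side == "one":
        if lam <= 1:
            raise ValueError("one-sided selection requires Lambda > 1")
        idx = np.flatnonzero(omega >= lam)
        return LocusSelection(float(lam), idx, omega[idx], side)
    if side == "two":
        if lam <= 1:
            raise ValueError("two-sided selection requires Lambda > 1")
        eff = np.maximum(omega, 1.0 / omega)
        idx = np.flatnonzero(eff >= lam)
        risk = np.where(omega[idx] >= 1.0, 2, 1).astype(np.int8)
        return LocusSelection(float(lam), idx, omega[idx], side, risk)
    raise ValueError(f"side must be 'one' or 'two', got {side!r}")


@dataclass(frozen=True)
class ModalIndicator:
    """The modal word over a locus selection."""

    selection: LocusSelection
    word: np.ndarray  # symbols in {1,2}, length == selection.size

    def __post_init__(self):
        object.__setattr__(self, "word", np.asarray(self.word, dtype=np.int8))
        if self.word.size != self.selection.size:
            raise ValueError("word length must equal selection size")


def mode_word(disease_symbols: np.ndarray, selection: LocusSelection,
              tie_symbol: int = 2) -> ModalIndicator:
    """Disease-cohort modal symbol at each selected locus (tie -> 2)."""
    sym = np.asarray(disease_symbols)
    if sym.shape[0] == 0:
        raise ValueError("disease cohort is empty")
    sub = sym[:, selection.indices]
    n2 = (sub == 2).sum(axis=0)
    n1 = (sub == 1).sum(axis=0)
    word = np.where(n2 > n1, 2, np.where(n1 > n2, 1, tie_symbol)).astype(np.int8)
    return ModalIndicator(selection, word)


def score(symbols: np.ndarray, indicator: ModalIndicator) -> np.ndarray:
    """Agreement count of each sequence with the classifier word.

    Equals selection size minus the Hamming distance of the projected
    sequence from the word.  Missing symbols at selected loci are an error.
    """
    sym = np.atleast_2d(np.asarray(symbols))
    sub = sym[:, indicator.selection.indices]
    if (sub == MISSING).any():
        raise ValueError("missing symbol at a selected locus; impute first")
    s = (sub == indicator.word).sum(axis=1)
    return s if np.asarray(symbols).ndim == 2 else int(s[0])


@dataclass(frozen=True)
class GaussianFits:
    mu_d: float
    sigma_d: float
    mu_c: float
    sigma_c: float
    degenerate: bool = False  # some sigma is 0


def fit_gaussians(scores_d: np.ndarray, scores_c: np.ndarray) -> GaussianFits:
    """Sample mean and unbiased SD per cohort; sigma=0 is flagged, not fatal."""
    scores_d = np.asarray(scores_d, dtype=float)
    scores_c = np.asarray(scores_c, dtype=float)
    if scores_d.size < 2 or scores_c.size < 2:
        raise ValueError("need at least 2 samples per cohort to fit gaussians")
    sd, sc = scores_d.std(ddof=1), scores_c.std(ddof=1)
    fits = GaussianFits(scores_d.mean(), sd, scores_c.mean(), sc,
                        degenerate=(sd == 0.0 or sc == 0.0))
    if fits.degenerate:
        warnings.warn("degenerate gaussian fit (sigma = 0)", stacklevel=2)
    return fits


@dataclass(frozen=True)
class ROCResult:
    """Grid ROC analysis of two fitted score gaussians."""

    deltas: np.ndarray
    tpr: np.ndarray           # fraction of disease with score >= Delta
    fpr: np.ndarray           # fraction of control with score >= Delta
    error: np.ndarray         # expected misclassified fraction at each Delta
    delta_star: float
    e_min: float
    expected_fn: float        # expected count n_d * (1 - TPR) at Delta*
    expected_fp: float        # expected count n_c * FPR at Delta*
    empirical_error: float | None = None  # from the actual scores at Delta*


def roc_error(
    fits: GaussianFits,
    n_d: int,
    n_c: int,
    grid_points: int = 10_000,
    scores_d: np.ndarray | None = None,
    scores_c: np.ndarray | None = None,
) -> ROCResult:
    """Expected-error curve and its minimizing threshold Delta*.

    T(Delta) is the disease-gaussian mass above Delta (true positives),
    FP(Delta) the control mass above; the error fraction is
    ``[n_d (1 - T) + n_c FP] / (n_d + n_c)``, minimized by grid search
    over the two means extended by 4 standard deviations each way.
    If the raw scores are supplied, the empirical error at Delta* is
    also computed directly from counts.
    """
    sig_d = fits.sigma_d if fits.sigma_d > 0 else 1e-12
    sig_c = fits.sigma_c if fits.sigma_c > 0 else 1e-12
    lo = min(fits.mu_d, fits.mu_c) - 4.0 * max(sig_d, sig_c)
    hi = max(fits.mu_d, fits.mu_c) + 4.0 * max(sig_d, sig_c)
    deltas = np.linspace(lo, hi, grid_points)
    tpr = norm.sf(deltas, loc=fits.mu_d, scale=sig_d)
    fpr = norm.sf(deltas, loc=fits.mu_c, scale=sig_c)
    err = (n_d * (1.0 - tpr) + n_c * fpr) / (n_d + n_c)
    j = int(np.argmin(err))
    delta_star = float(deltas[j])
    emp = None
    if scores_d is not None and scores_c is not None:
        fn = int((np.asarray(scores_d) < delta_star).sum())
        fp = int((np.asarray(scores_c) >= delta_star).sum())
        emp = (fn + fp) / (len(scores_d) + len(scores_c))
    return ROCResult(
        deltas, tpr, fpr, err, delta_star, float(err[j]),
        expected_fn=float(n_d * (1.0 - tpr[j])),
        expected_fp=float(n_c * fpr[j]),
        empirical_error=emp,
    )


def sweet_spot(
    lambdas: np.ndarray,
    counts: np.ndarray,
    rel_tol: float = 0.01,
    width: float = 0.1,
) -> list[tuple[float, float]]:
    """Plateaus of the threshold-set size curve N(Lambda).

    Returns intervals of width >= ``width`` over which N changes by less
    than ``rel_tol`` relative to its value at the interval's left edge —
    threshold ranges where the classifier is insensitive to Lambda.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    counts = np.asarray(counts, dtype=float)
    order = np.argsort(lambdas)
    lambdas, counts = lambdas[order], counts[order]
    plateaus: list[tuple[float, float]] = []
    i = 0
    while i < len(lambdas):
        j = i
        base = counts[i]
        while j + 1 < len(lambdas) and abs(counts[j + 1] - base) <= rel_tol * max(base, 1.0):
            j += 1
        if lambdas[j] - lambdas[i] >= width:
            plateaus.append((float(lambdas[i]), float(lambdas[j])))
        i = j + 1 if j > i else i + 1
    return plateaus


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

def _resolve_xy(X, y):
    """Accept (AlleleMatrix, None) or (ndarray, labels); return X, disease mask, classes."""
    if isinstance(X, AlleleMatrix):
        sym = X.symbols
        y = X.labels
    else:
        sym = np.asarray(X)
        if y is None:
            raise ValueError("y is required when X is a plain array")
    sym = np.asarray(sym)
    if sym.ndim != 2:
        raise ValueError("X must be 2-D (samples x allele loci)")
    vals = np.unique(sym)
    if not np.isin(vals, [1, 2]).all():
        raise ValueError("X must contain standard-form symbols 1 and 2 only")
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    # positive class: 'disease' if present, else the larger label
    pos = DISEASE if DISEASE in classes else classes[-1]
    return sym.astype(np.int8), y == pos, classes, pos


class ModalClassifier(ClassifierMixin, BaseEstimator):
    """Case/control classifier from the modal word over high-value loci.

    fit() screens every allele compartment by its disease/control odds
    ratio, keeps loci with omega >= ``odds_threshold``, builds the
    disease-modal word, and calibrates the score threshold Delta* that
    minimizes the expected gaussian error.  predict() labels a sample as
    disease when its agreement score is >= Delta* (ties to disease).

    Parameters
    ----------
    odds_threshold : float, default 2.4
        Lambda, the allele odds-ratio cut for high-value loci.
    side : {"one", "two"}, default "one"
        One-sided keeps disease-enriched symbol-2 loci; two-sided also
        keeps loci enriched for symbol 1.
    tie_symbol : int, default 2
        Modal-word symbol at an exact 50/50 disease split.
    grid_points : int, default 10000
        Resolution of the Delta* grid search.

    Attributes
    ----------
    selection_ : LocusSelection
    indicator_ : ModalIndicator
    omega_ : ndarray of per-locus allele odds ratios (all loci)
    fits_ : GaussianFits of the two cohorts' score distributions
    roc_ : ROCResult
    delta_star_ : float
    e_min_ : float
    classes_ : ndarray of the two labels, positive (disease) last
    """

    def __init__(self, odds_threshold: float = 2.4, side: str = "one",
                 tie_symbol: int = 2, grid_points: int = 10_000):
        self.odds_threshold = odds_threshold
        self.side = side
        self.tie_symbol = tie_symbol
        self.grid_points = grid_points

    def fit(self, X, y=None):
        sym, dmask, classes, pos = _resolve_xy(X, y)
        n_d, n_c = int(dmask.sum()), int((~dmask).sum())
        if n_d < 2 or n_c < 2:
            raise ValueError("need at least 2 samples in each cohort")
        p_d = (sym[dmask] == 2).mean(axis=0)
        p_c = (sym[~dmask] == 2).mean(axis=0)
        self.omega_, self.omega_corrected_ = locus_stats.allele_odds_ratio(
            p_d, p_c, n_d=n_d, n_c=n_c, return_flags=True
        )
        self.selection_ = select_high_value(self.omega_, self.odds_threshold, self.side)
        if self.selection_.size == 0:
            raise ValueError(
                f"no locus clears odds_threshold={self.odds_threshold}; lower Lambda"
            )
        self.indicator_ = mode_word(sym[dmask], self.selection_, self.tie_symbol)
        s_d = score(sym[dmask], self.indicator_)
        s_c = score(sym[~dmask], self.indicator_)
        self.fits_ = fit_gaussians(s_d, s_c)
        self.roc_ = roc_error(self.fits_, n_d, n_c, self.grid_points,
                              scores_d=s_d, scores_c=s_c)
        self.delta_star_ = self.roc_.delta_star
        self.e_min_ = self.roc_.e_min
        self.classes_ = np.array([c for c in classes if c != pos] + [pos])
        self.n_features_in_ = sym.shape[1]
        return self

    def score_samples(self, X) -> np.ndarray:
        """Raw agreement counts with the fitted word."""
        sym = X.symbols if isinstance(X, AlleleMatrix) else np.asarray(X)
        return score(sym, self.indicator_)

    def decision_function(self, X) -> np.ndarray:
        return self.score_samples(X) - self.delta_star_

    def predict(self, X) -> np.ndarray:
        neg, pos = self.classes_
        return np.where(self.decision_function(X) >= 0, pos, neg)
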