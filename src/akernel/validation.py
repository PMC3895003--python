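"""Consistency and predictability checks for an extracted classifier.

All procedures recompute the classifier (locus selection at the same
Lambda plus the disease-modal word) under a perturbation of the data and
compare it with the reference classifier:

* label permutation trials — phenotype labels shuffled with cohort sizes
  fixed, the one randomization that leaves every genotype statistic
  untouched; the symbol-matched locus overlap fraction with the reference
  classifier is recorded per trial.  Under an independence model in which
  each classifier locus survives three equiprobable binary alterations
  (symbol flip, major-locus drop-out, minor-locus entry) the expected
  overlap is 1/8.
* random baselines — L loci drawn uniformly without replacement, symbols
  modal or random; expected locus overlap is L / (2M), halved again for
  random symbols.
* train/test split — the classifier and its score threshold fitted on a
  training split and evaluated on held-out samples.
* reduced-classifier leave-two-out prediction — classifier loci ranked by
  the disease-minus-control frequency of the classifier symbol; the
  lowest-ranked n_bottom loci alone score one held-out case/control pair
  per trial.
* subsample extrapolation — mean selected-set size at nested cohort
  fractions fitted by L(n) = L_inf + beta / n, whose asymptote estimates
  the selected-set size free of finite-sample frequency noise.

All stochastic procedures are reproducible given (seed, n_trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from . import locus_stats
from .modal import LocusSelection, ModalIndicator, mode_word, select_high_value, score
from .indicator import IndicatorClassifier
from .standard_form import AlleleMatrix, CONTROL, DISEASE


def _as_xy(m, y=None):
    if isinstance(m, AlleleMatrix):
        return m.symbols, m.labels == DISEASE
    X = np.asarray(m)
    if y is None:
        raise ValueError("labels required with a plain symbol array")
    y = np.asarray(y)
    return X, (y == DISEASE) if y.dtype == object or y.dtype.kind == "U" else y.astype(bool)


def _classifier(X: np.ndarray, dmask: np.ndarray, lam: float) -> ModalIndicator:
    """Selection at Lambda plus disease-modal word from raw symbols."""
    n_d, n_c = int(dmask.sum()), int((~dmask).sum())
    p_d = (X[dmask] == 2).mean(axis=0)
    p_c = (X[~dmask] == 2).mean(axis=0)
    omega = locus_stats.allele_odds_ratio(p_d, p_c, n_d=n_d, n_c=n_c)
    sel = select_high_value(omega, lam)
    return mode_word(X[dmask], sel)


def _overlap_fraction(ref: ModalIndicator, other: ModalIndicator) -> float:
    """|loci AND symbols shared| / L_ref (symbol-matched overlap)."""
    if ref.selection.size == 0:
        raise ValueError("reference classifier is empty")
    ref_sym = dict(zip(ref.selection.indices.tolist(), ref.word.tolist()))
    hits = sum(
        1 for i, w in zip(other.selection.indices.tolist(), other.word.tolist())
        if ref_sym.get(i) == w
    )
    return hits / ref.selection.size


@dataclass
class RandomizationReport:
    n_trials: int
    overlap_fractions: np.ndarray
    baseline_mode: str
    reference_size: int

    @property
    def mean(self) -> float:
        return float(self.overlap_fractions.mean())

    @property
    def sd(self) -> float:
        return float(self.overlap_fractions.std(ddof=1)) if self.n_trials > 1 else 0.0


def permutation_trials(
    m, lam: float, n_trials: int = 50, seed: int | None = None,
    y=None, mode: str = "permute",
) -> RandomizationReport:
    """Phenotype-randomization trials against the reference classifier.

    ``mode='permute'`` shuffles labels with cohort sizes fixed;
    ``mode='bootstrap'`` resamples each cohort's membership with
    replacement from the pooled samples (genotypes never change).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    X, dmask = _as_xy(m, y)
    rng = np.random.default_rng(seed)
    ref = _classifier(X, dmask, lam)
    n = X.shape[0]
    n_d = int(dmask.sum())
    fracs = np.empty(n_trials)
    for t in range(n_trials):
        if mode == "permute":
            perm = rng.permutation(n)
            new_mask = np.zeros(n, dtype=bool)
            new_mask[perm[:n_d]] = True
        elif mode == "bootstrap":
            rows = rng.integers(0, n, size=n)
            new_mask = np.zeros(n, dtype=bool)
            new_mask[:n_d] = True
            X_t = X[rows]
            fracs[t] = _overlap_fraction(ref, _classifier(X_t, new_mask, lam))
            continue
        else:
            raise ValueError(f"unknown mode {mode!r}")
        fracs[t] = _overlap_fraction(ref, _classifier(X, new_mask, lam))
    return RandomizationReport(n_trials, fracs, mode, ref.selection.size)


def alteration_model_overlap(
    n_loci: int = 10_000, n_trials: int = 50, seed: int | None = None
) -> RandomizationReport:
    """Direct simulation of the three-alteration independence model.

    Each classifier locus independently survives randomization only if
    three equiprobable binary alterations (symbol flip; major-locus value
    drop; minor-locus value entry) all preserve it, so the per-locus
    survival probability is (1/2)^3 and the expected overlap fraction is
    1/8.
    """
    if n_trials < 1 or n_loci < 1:
        raise ValueError("n_loci and n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    keep = (rng.random((n_trials, n_loci, 3)) < 0.5).all(axis=2)
    return RandomizationReport(n_trials, keep.mean(axis=1), "alteration-model", n_loci)


def random_baseline(
    m, lam: float, mode: str = "random-loci-modal",
    n_trials: int = 50, seed: int | None = None, y=None,
) -> RandomizationReport:
    """Overlap of the reference classifier with random locus draws.

    L loci are drawn uniformly without replacement from all 2M; symbols
    are the disease-cohort modes ('random-loci-modal') or fair coins
    ('random-loci-random-symbol').  Hypergeometric expectation of the
    locus-only overlap is L/(2M); random symbols halve the matched
    overlap when modes are equiprobable.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    X, dmask = _as_xy(m, y)
    rng = np.random.default_rng(seed)
    ref = _classifier(X, dmask, lam)
    L, total = ref.selection.size, X.shape[1]
    if L > total:
        raise ValueError("classifier larger than the locus universe")
    d_sym = X[dmask]
    n2 = (d_sym == 2).sum(axis=0)
    n1 = d_sym.shape[0] - n2
    modal = np.where(n2 >= n1, 2, 1).astype(np.int8)
    fracs = np.empty(n_trials)
    for t in range(n_trials):
        idx = np.sort(rng.choice(total, size=L, replace=False))
        if mode == "random-loci-modal":
            word = modal[idx]
        elif mode == "random-loci-random-symbol":
            word = rng.integers(1, 3, size=L).astype(np.int8)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        sel = LocusSelection(lam, idx, np.ones(L))
        fracs[t] = _overlap_fraction(ref, ModalIndicator(sel, word))
    return RandomizationReport(n_trials, fracs, mode, L)


@dataclass
class SplitReport:
    n_train_d: int
    n_train_c: int
    n_test_d: int
    n_test_c: int
    train_error: float
    test_error: float
    delta_star: float
    classifier_size: int


def split_validate(
    m, lam: float,
    train_fraction: float | None = 0.85,
    train_sizes: tuple[int, int] | None = None,
    seed: int | None = None, y=None,
) -> SplitReport:
    """Train/test split of both cohorts with the classifier fit on train only.

    The locus selection, word and score threshold Delta* come from the
    training split alone; train and test error fractions are reported at
    that threshold.
    """
    from .modal import ModalClassifier

    X, dmask = _as_xy(m, y)
    rng = np.random.default_rng(seed)
    d_idx = np.flatnonzero(dmask)
    c_idx = np.flatnonzero(~dmask)
    if train_sizes is not None:
        t_d, t_c = train_sizes
    else:
        t_d = int(round(train_fraction * d_idx.size))
        t_c = int(round(train_fraction * c_idx.size))
    if not (2 <= t_d < d_idx.size and 2 <= t_c < c_idx.size):
        raise ValueError("split leaves an empty or degenerate train/test cohort")
    d_perm = rng.permutation(d_idx)
    c_perm = rng.permutation(c_idx)
    train = np.concatenate([d_perm[:t_d], c_perm[:t_c]])
    test = np.concatenate([d_perm[t_d:], c_perm[t_c:]])
    y_all = np.where(dmask, DISEASE, CONTROL)

    clf = ModalClassifier(odds_threshold=lam).fit(X[train], y_all[train])
    tr_err = float((clf.predict(X[train]) != y_all[train]).mean())
    te_err = float((clf.predict(X[test]) != y_all[test]).mean())
    return SplitReport(
        t_d, t_c, d_idx.size - t_d, c_idx.size - t_c,
        tr_err, te_err, clf.delta_star_, clf.selection_.size,
    )


@dataclass
class ReducedPredictionReport:
    n_trials: int
    n_correct: int
    n_ties: int
    rate: float
    p_value: float      # exact binomial sign test against 0.5
    n_bottom: int


def reduced_classifier_prediction(
    m, lam: float, n_bottom: int, n_trials: int = 1000,
    seed: int | None = None, y=None,
) -> ReducedPredictionReport:
    """Leave-two-out prediction with the bottom-ranked classifier loci.

    Per trial one disease and one control sample are held out, the
    classifier is recomputed on the rest, its loci are ranked by the
    disease-minus-control frequency of the classifier symbol, and only
    the ``n_bottom`` lowest-ranked loci score the held-out pair.  A trial
    is correct when the disease sample strictly outscores the control
    sample; the rate is tested against 0.5 by an exact binomial sign test.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    X, dmask = _as_xy(m, y)
    rng = np.random.default_rng(seed)
    d_idx = np.flatnonzero(dmask)
    c_idx = np.flatnonzero(~dmask)
    correct = ties = 0
    for _ in range(n_trials):
        hd = int(rng.choice(d_idx))
        hc = int(rng.choice(c_idx))
        keep = np.ones(X.shape[0], dtype=bool)
        keep[[hd, hc]] = False
        Xk, mk = X[keep], dmask[keep]
        ind = _classifier(Xk, mk, lam)
        if n_bottom > ind.selection.size:
            raise ValueError(
                f"n_bottom={n_bottom} exceeds classifier size {ind.selection.size}"
            )
        sub_d = Xk[mk][:, ind.selection.indices]
        sub_c = Xk[~mk][:, ind.selection.indices]
        f_d = (sub_d == ind.word).mean(axis=0)
        f_c = (sub_c == ind.word).mean(axis=0)
        rank = np.argsort(f_d - f_c, kind="stable")
        bottom = ind.selection.indices[rank[:n_bottom]]
        word = ind.word[rank[:n_bottom]]
        s_d = int((X[hd, bottom] == word).sum())
        s_c = int((X[hc, bottom] == word).sum())
        if s_d > s_c:
            correct += 1
        elif s_d == s_c:
            ties += 1
    rate = correct / n_trials
    p = binomtest(correct, n_trials, 0.5, alternative="greater").pvalue
    return ReducedPredictionReport(n_trials, correct, ties, rate, float(p), n_bottom)


@dataclass
class SubsampleCurve:
    fractions: np.ndarray
    n_total: np.ndarray          # mean subsample sizes at each fraction
    mean_L: np.ndarray
    n_repeats: int
    L_inf: float
    beta: float
    rel_residual: float          # ||fit residual|| / ||mean_L||


def subsample_extrapolation(
    m, lam: float,
    fractions: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9, 1.0),
    n_repeats: int = 5,
    seed: int | None = None, y=None,
) -> SubsampleCurve:
    """Selected-set size versus cohort size, extrapolated to unbounded data.

    For each fraction, both cohorts are subsampled without replacement
    ``n_repeats`` times and the mean count of loci with omega >= Lambda
    recorded.  The points are fit by L(n) = L_inf + beta / n with n the
    total subsample size; L_inf estimates the classifier size once the
    excess selections driven by finite-sample frequency noise vanish.
    """
    fr = np.asarray(fractions, dtype=float)
    if ((fr <= 0) | (fr > 1)).any():
        raise ValueError("fractions must lie in (0, 1]")
    X, dmask = _as_xy(m, y)
    rng = np.random.default_rng(seed)
    d_idx = np.flatnonzero(dmask)
    c_idx = np.flatnonzero(~dmask)
    mean_L = np.empty(fr.size)
    n_tot = np.empty(fr.size)
    for i, f in enumerate(fr):
        s_d = int(round(f * d_idx.size))
        s_c = int(round(f * c_idx.size))
        if min(s_d, s_c) < 10:
            raise ValueError(f"fraction {f} leaves fewer than 10 samples in a cohort")
        sizes = []
        for _ in range(n_repeats):
            dd = rng.choice(d_idx, size=s_d, replace=False)
            cc = rng.choice(c_idx, size=s_c, replace=False)
            p_d = (X[dd] == 2).mean(axis=0)
            p_c = (X[cc] == 2).mean(axis=0)
            omega = locus_stats.allele_odds_ratio(p_d, p_c, n_d=s_d, n_c=s_c)
            sizes.append(int((omega >= lam).sum()))
        mean_L[i] = np.mean(sizes)
        n_tot[i] = s_d + s_c
    A = np.column_stack([np.ones(fr.size), 1.0 / n_tot])
    coef, *_ = np.linalg.lstsq(A, mean_L, rcond=None)
    resid = mean_L - A @ coef
    rel = float(np.linalg.norm(resid) / max(np.linalg.norm(mean_L), 1e-300))
    return SubsampleCurve(fr, n_tot, mean_L, n_repeats,
                          float(coef[0]), float(coef[1]), rel)
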