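"""Per-locus probabilities, entropies and odds ratios.

In the standard organization every SNP contributes two allele compartments.
For a cohort, p_o and p_e are the frequencies of symbol 2 at the odd and
even compartment, and the SNP genotype pair takes values 22, 21 or 11 with
probabilities (p22, p21, p11).  The allele odds ratio

    omega = [p_d / (1 - p_d)] / [p_c / (1 - p_c)]

contrasts the symbol-2 odds between the disease (d) and control (c)
cohorts at one compartment; the SNP odds ratio Omega applies the same
formula to q, the SNP-level probability of the major-alias symbol.  By
default q is the mean symbol-2 frequency of the two compartments,
(p_o + p_e) / 2 — the one definition under which a SNP with a single
near-fixation risk compartment shows Omega near unity while omega is
large, as risk loci do; q = p22 + p21 (at least one major symbol) and
q = p22 are available as alternatives.

Allele-level ratios are markedly more sensitive risk locators than
SNP-level ones: when both cohorts' compartment probabilities sit near 1,
omega can be large while Omega stays near unity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .standard_form import CONTROL, DISEASE, MISSING, AlleleMatrix

_LN2 = np.log(2.0)

#: how q, the SNP-level major-symbol probability, is derived
Q_MODES = ("allele_mean", "pair", "p22")


def compartment_probabilities(m: AlleleMatrix, cohort: str) -> np.ndarray:
    """Frequency of symbol 2 at every allele locus within one cohort."""
    sym = m.cohort(cohort)
    if sym.shape[0] == 0:
        raise ValueError(f"cohort {cohort!r} is empty")
    if (sym == MISSING).any():
        raise ValueError("matrix contains missing symbols; clean it first")
    return (sym == 2).mean(axis=0)


def pair_probabilities(m: AlleleMatrix, cohort: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed (p22, p21, p11) per SNP from genotype pair counts."""
    sym = m.cohort(cohort)
    if sym.shape[0] == 0:
        raise ValueError(f"cohort {cohort!r} is empty")
    odd = sym[:, 0::2]
    even = sym[:, 1::2]
    p22 = ((odd == 2) & (even == 2)).mean(axis=0)
    p11 = ((odd == 1) & (even == 1)).mean(axis=0)
    p21 = 1.0 - p22 - p11
    return p22, p21, p11


def pair_probabilities_independent(
    p_o: np.ndarray, p_e: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic (p22, p21, p11) under compartment independence.

    Used for closed-form tests; real encoded data couples the compartments
    (the odd column receives the larger symbol), so observed pair counts
    are the default elsewhere.
    """
    p22 = p_o * p_e
    p11 = (1.0 - p_o) * (1.0 - p_e)
    return p22, 1.0 - p22 - p11, p11


def snp_major_probability(p22, p21, p11, p_o=None, p_e=None,
                          mode: str = "allele_mean"):
    """q, the SNP-level probability of the major-alias symbol."""
    if mode == "pair":
        return np.asarray(p22) + np.asarray(p21)
    if mode == "p22":
        return np.asarray(p22)
    if mode == "allele_mean":
        if p_o is None or p_e is None:
            raise ValueError("allele_mean mode needs p_o and p_e")
        return (np.asarray(p_o) + np.asarray(p_e)) / 2.0
    raise ValueError(f"unknown q mode {mode!r}; choose from {Q_MODES}")


def _odds(p: np.ndarray) -> np.ndarray:
    return p / (1.0 - p)


def odds_ratio_from_counts(k_d, n_d, k_c, n_c):
    """Odds ratio from 2x2 counts with Haldane-Anscombe continuity.

    Adds 0.5 to each of the four cells only when any cell is zero.
    Returns ``(ratio, corrected_flag)`` with array support.
    """
    k_d, k_c = np.asarray(k_d, dtype=float), np.asarray(k_c, dtype=float)
    n_d, n_c = np.asarray(n_d, dtype=float), np.asarray(n_c, dtype=float)
    zero = (k_d == 0) | (k_d == n_d) | (k_c == 0) | (k_c == n_c)
    add = np.where(zero, 0.5, 0.0)
    num = (k_d + add) / (n_d - k_d + add)
    den = (k_c + add) / (n_c - k_c + add)
    ratio = num / den
    if ratio.ndim == 0:
        return float(ratio), bool(zero)
    return ratio, zero


def allele_odds_ratio(p_d, p_c, n_d=None, n_c=None, return_flags: bool = False):
    """Allele odds ratio omega = odds_d(p) / odds_c(p) at one compartment.

    ``p_d``/``p_c`` are the symbol-2 frequencies in disease and control
    (scalars or arrays).  When a frequency hits 0 or 1 the ratio is
    undefined; if cohort sizes are supplied, the implied counts get the
    Haldane-Anscombe +0.5 correction and the locus is flagged, otherwise
    a ValueError is raised.
    """
    p_d = np.asarray(p_d, dtype=float)
    p_c = np.asarray(p_c, dtype=float)
    if ((p_d < 0) | (p_d > 1) | (p_c < 0) | (p_c > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    boundary = (p_d == 0) | (p_d == 1) | (p_c == 0) | (p_c == 1)
    if boundary.any():
        if n_d is None or n_c is None:
            raise ValueError(
                "frequency of 0 or 1 encountered; supply n_d and n_c so the "
                "Haldane-Anscombe correction can be applied"
            )
        k_d = np.round(p_d * n_d)
        k_c = np.round(p_c * n_c)
        omega, flag = odds_ratio_from_counts(k_d, n_d, k_c, n_c)
    else:
        omega = _odds(p_d) / _odds(p_c)
        flag = np.zeros_like(omega, dtype=bool)
    if return_flags:
        return omega, flag
    return omega


def snp_odds_ratio(q_d, q_c, n_d=None, n_c=None, return_flags: bool = False):
    """SNP odds ratio Omega on the major-symbol probability q."""
    return allele_odds_ratio(q_d, q_c, n_d=n_d, n_c=n_c, return_flags=return_flags)


def binary_entropy(p) -> np.ndarray:
    """Entropy in bits of a Bernoulli(p) symbol, with 0*log0 = 0."""
    p = np.asarray(p, dtype=float)
    return -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)) / _LN2


def information_content(p_o, p_e, pair_probs):
    """(H_o, H_e, H_snp) in bits for one or many SNPs.

    H_o and H_e are the binary entropies of the two allele compartments;
    H_snp is the entropy of the three-category genotype distribution
    ``pair_probs = (p22, p21, p11)``.  Because the two compartments
    resolve which symbol sits where, H_o + H_e >= H_snp always.
    """
    h_o = binary_entropy(p_o)
    h_e = binary_entropy(p_e)
    p22, p21, p11 = (np.asarray(x, dtype=float) for x in pair_probs)
    h_snp = -(xlogy(p22, p22) + xlogy(p21, p21) + xlogy(p11, p11)) / _LN2
    return h_o, h_e, h_snp


def compute_locus_stats(m: AlleleMatrix, q_mode: str = "allele_mean") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-locus and per-SNP statistics tables for a cleaned matrix.

    Returns ``(allele_df, snp_df)``: the allele table has one row per
    compartment (p_d, p_c, omega, correction flag); the SNP table has the
    pair probabilities per cohort, q, Omega and the pooled entropies.
    """
    n_d = int(m.disease_mask.sum())
    n_c = int(m.control_mask.sum())
    p_d = compartment_probabilities(m, DISEASE)
    p_c = compartment_probabilities(m, CONTROL)
    omega, flag = allele_odds_ratio(p_d, p_c, n_d=n_d, n_c=n_c, return_flags=True)

    allele_df = pd.DataFrame(
        {
            "locus_id": m.locus_ids,
            "snp_index": [lm.snp_index for lm in m.loci],
            "compartment": [lm.compartment for lm in m.loci],
            "p_d": p_d,
            "p_c": p_c,
            "omega": omega,
            "corrected": flag,
        }
    )

    p22_d, p21_d, p11_d = pair_probabilities(m, DISEASE)
    p22_c, p21_c, p11_c = pair_probabilities(m, CONTROL)
    q_d = snp_major_probability(p22_d, p21_d, p11_d, p_d[0::2], p_d[1::2], mode=q_mode)
    q_c = snp_major_probability(p22_c, p21_c, p11_c, p_c[0::2], p_c[1::2], mode=q_mode)
    Omega, oflag = snp_odds_ratio(q_d, q_c, n_d=n_d, n_c=n_c, return_flags=True)

    # pooled entropies describe the data irrespective of phenotype
    pool = (n_d * p_d + n_c * p_c) / (n_d + n_c)
    pool_pairs = tuple(
        (n_d * a + n_c * b) / (n_d + n_c)
        for a, b in ((p22_d, p22_c), (p21_d, p21_c), (p11_d, p11_c))
    )
    h_o, h_e, h_snp = information_content(pool[0::2], pool[1::2], pool_pairs)

    snp_df = pd.DataFrame(
        {
            "snp_id": [lid.rsplit(".", 1)[0] for lid in m.locus_ids[0::2]],
            "p22_d": p22_d, "p21_d": p21_d, "p11_d": p11_d,
            "p22_c": p22_c, "p21_c": p21_c, "p11_c": p11_c,
            "q_d": q_d, "q_c": q_c,
            "Omega": Omega, "corrected": oflag,
            "H_o": h_o, "H_e": h_e, "H_snp": h_snp,
        }
    )
    return allele_df, snp_df


@dataclass
class OddsHistogram:
    """Binned densities of allele (omega) and SNP (Omega) odds ratios."""

    allele_edges: np.ndarray
    allele_density: np.ndarray
    snp_edges: np.ndarray
    snp_density: np.ndarray
    n_of_lambda: dict[float, int]
    raw_range_allele: tuple[float, float]
    raw_range_snp: tuple[float, float]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        a = pd.DataFrame(
            {"bin_left": self.allele_edges[:-1], "bin_right": self.allele_edges[1:],
             "density": self.allele_density}
        )
        s = pd.DataFrame(
            {"bin_left": self.snp_edges[:-1], "bin_right": self.snp_edges[1:],
             "density": self.snp_density}
        )
        n = pd.DataFrame(
            {"Lambda": list(self.n_of_lambda), "N": list(self.n_of_lambda.values())}
        )
        return a, s, n


def _clipped_hist(values: np.ndarray, bins: int, clip_pct: float):
    lo = float(values.min())
    hi_raw = float(values.max())
    hi = float(np.percentile(values, clip_pct))
    if hi <= lo:
        hi = hi_raw if hi_raw > lo else lo + 1.0
    density, edges = np.histogram(np.clip(values, lo, hi), bins=bins,
                                  range=(lo, hi), density=True)
    return edges, density, (lo, hi_raw)


def odds_histograms(
    m: AlleleMatrix,
    bins: int = 2000,
    thresholds: np.ndarray | None = None,
    clip_pct: float = 99.99,
    q_mode: str = "allele_mean",
) -> OddsHistogram:
    """Density histograms of omega and Omega plus the threshold curve N(Lambda).

    ``bins`` equal-width bins span [min, percentile ``clip_pct``] of the
    observed ratios (raw extremes are kept in the result); N(Lambda) counts
    allele loci with omega >= Lambda on the requested threshold grid.
    """
    allele_df, snp_df = compute_locus_stats(m, q_mode=q_mode)
    omega = allele_df["omega"].to_numpy()
    Omega = snp_df["Omega"].to_numpy()
    a_edges, a_den, a_raw = _clipped_hist(omega, bins, clip_pct)
    s_edges, s_den, s_raw = _clipped_hist(Omega, bins, clip_pct)
    if thresholds is None:
        thresholds = np.round(np.arange(1.0, 6.0001, 0.05), 4)
    n_of_lambda = {float(t): int((omega >= t).sum()) for t in thresholds}
    return OddsHistogram(a_edges, a_den, s_edges, s_den, n_of_lambda, a_raw, s_raw)
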