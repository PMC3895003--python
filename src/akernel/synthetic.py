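"""Synthetic case/control genotype generator with planted risk loci.

Emulates the statistical shape of a large complex-disease case/control
SNP panel: two cohorts (defaults 919 cases / 787 controls), per-compartment
binary symbol frequencies drawn from a null distribution, a minority of
planted risk loci whose disease-cohort frequency is solved from a target
allele odds ratio, and sparse missingness with a few high-missingness
loci to exercise the cleaning rules.  Loci are generated independently
(no linkage disequilibrium).

Two compartment modes are offered.  ``genotypic`` draws each SNP's
genotype category {22, 21, 11} with P(22) = p_e, P(21) = p_o - p_e,
P(11) = 1 - p_o, which realizes the target compartment marginals exactly
while satisfying the standard-form constraint P(odd=2) >= P(even=2)
(it requires p_o >= p_e, enforced by clamping the unplanted partner
compartment).  ``independent`` draws the two compartments independently,
producing matrices that can violate the encoder's ordering — useful for
fixtures resembling externally encoded tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .standard_form import (CONTROL, DISEASE, MISSING, AlleleMatrix,
                            LocusMeta, SnpDef)


@dataclass(frozen=True)
class RiskLocus:
    """One planted risk compartment: 0-based allele-locus index, control
    frequency of symbol 2, and target allele odds ratio."""

    locus: int
    p_control: float
    omega: float

    def __post_init__(self):
        if not 0.0 < self.p_control < 1.0:
            raise ValueError("p_control must lie in (0, 1)")
        if self.omega <= 0:
            raise ValueError("target omega must be positive")


def invert_odds(p_c: float | np.ndarray, omega: float | np.ndarray):
    """Disease frequency with odds ratio ``omega`` against control ``p_c``."""
    odds = omega * np.asarray(p_c) / (1.0 - np.asarray(p_c))
    return odds / (1.0 + odds)


@dataclass
class SyntheticSpec:
    """Study-shaped generation parameters.

    ``null_p`` names the control-frequency distribution for null loci as
    ("beta", a, b) or ("uniform", lo, hi).  ``missing_rate`` is the
    per-genotype missingness probability (default matches the sparse
    observed mean of 1.4e-4); ``n_high_missing_snps`` SNPs additionally
    get ``high_missing_rate`` missingness (up to the 10% seen at the
    worst real loci).
    """

    n_cases: int = 919
    n_controls: int = 787
    n_snps: int = 1000
    risk_loci: Sequence[RiskLocus] = ()
    null_p: tuple = ("beta", 2.0, 2.0)
    compartment_mode: str = "genotypic"
    missing_rate: float = 1.4e-4
    n_high_missing_snps: int = 0
    high_missing_rate: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.compartment_mode not in ("genotypic", "independent"):
            raise ValueError("compartment_mode must be 'genotypic' or 'independent'")
        idx = [r.locus for r in self.risk_loci]
        if len(idx) != len(set(idx)):
            raise ValueError("risk locus indices must be distinct")
        if idx and (min(idx) < 0 or max(idx) >= 2 * self.n_snps):
            raise ValueError("risk locus index outside [0, 2*n_snps)")
        for r in self.risk_loci:
            p_d = float(invert_odds(r.p_control, r.omega))
            if not 0.0 < p_d < 1.0:
                raise ValueError(
                    f"locus {r.locus}: omega={r.omega} with p_c={r.p_control} "
                    "forces a degenerate disease frequency"
                )


def uniform_risk_loci(
    rng: np.random.Generator,
    n_snps: int,
    n_risk: int,
    omega: float,
    p_control_range: tuple[float, float] = (0.2, 0.8),
    compartment: str = "odd",
) -> list[RiskLocus]:
    """Convenience: plant ``n_risk`` risk compartments on distinct SNPs."""
    snps = rng.choice(n_snps, size=n_risk, replace=False)
    offs = 0 if compartment == "odd" else 1
    p = rng.uniform(*p_control_range, size=n_risk)
    return [RiskLocus(int(2 * s + offs), float(pc), float(omega))
            for s, pc in zip(np.sort(snps), p)]


def _draw_null(rng: np.random.Generator, spec: SyntheticSpec, size: int) -> np.ndarray:
    kind, *args = spec.null_p
    if kind == "beta":
        return rng.beta(args[0], args[1], size=size)
    if kind == "uniform":
        return rng.uniform(args[0], args[1], size=size)
    raise ValueError(f"unknown null_p distribution {kind!r}")


def generate(spec: SyntheticSpec) -> tuple[AlleleMatrix, pd.DataFrame]:
    """Generate an encoded case/control matrix plus its truth table.

    Returns ``(matrix, truth)`` where ``truth`` has one row per allele
    locus with the true disease/control symbol-2 probabilities, the true
    odds ratio, and a planted-risk flag.  With the seed fixed the output
    is reproducible bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    M = spec.n_snps
    L = 2 * M

    p_c = _draw_null(rng, spec, L)
    p_d = p_c.copy()
    planted = np.zeros(L, dtype=bool)
    for r in spec.risk_loci:
        p_c[r.locus] = r.p_control
        p_d[r.locus] = invert_odds(r.p_control, r.omega)
        planted[r.locus] = True

    if spec.compartment_mode == "genotypic":
        # enforce p_o >= p_e per SNP in every cohort, never moving a planted
        # value.  An unplanted partner compartment is clamped to the same
        # bound in both cohorts (the tighter of the two planted values), so
        # planting one risk compartment never creates an association at its
        # partner.
        od, ev = planted[0::2], planted[1::2]
        po_d, pe_d = p_d[0::2], p_d[1::2]
        po_c, pe_c = p_c[0::2], p_c[1::2]
        both = od & ev
        if (((po_d < pe_d) | (po_c < pe_c)) & both).any():
            raise ValueError(
                "genotypic mode: planted even-compartment frequency exceeds "
                "planted odd-compartment frequency at the same SNP"
            )
        bound_e = np.minimum(po_d, po_c)
        fix_e = od & ~ev & ((pe_d > bound_e) | (pe_c > bound_e))
        pe_d[fix_e] = np.minimum(pe_d[fix_e], bound_e[fix_e])
        pe_c[fix_e] = np.minimum(pe_c[fix_e], bound_e[fix_e])
        bound_o = np.maximum(pe_d, pe_c)
        fix_o = ev & ~od & ((po_d < bound_o) | (po_c < bound_o))
        po_d[fix_o] = np.maximum(po_d[fix_o], bound_o[fix_o])
        po_c[fix_o] = np.maximum(po_c[fix_o], bound_o[fix_o])
        # unplanted SNPs have identical cohort frequencies: sort the pair
        swap = ~od & ~ev & (po_d < pe_d)
        for po, pe in ((po_d, pe_d), (po_c, pe_c)):
            hi = np.maximum(po[swap], pe[swap])
            lo = np.minimum(po[swap], pe[swap])
            po[swap], pe[swap] = hi, lo

    def draw(n: int, p: np.ndarray) -> np.ndarray:
        sym = np.empty((n, L), dtype=np.int8)
        po, pe = p[0::2], p[1::2]
        if spec.compartment_mode == "genotypic":
            u = rng.random((n, M))
            odd = u < po
            even = u < pe          # coupled: even=2 implies odd=2
        else:
            odd = rng.random((n, M)) < po
            even = rng.random((n, M)) < pe
        sym[:, 0::2] = odd.astype(np.int8) + 1
        sym[:, 1::2] = even.astype(np.int8) + 1
        return sym

    sym = np.vstack([draw(spec.n_cases, p_d), draw(spec.n_controls, p_c)])
    labels = np.array([DISEASE] * spec.n_cases + [CONTROL] * spec.n_controls,
                      dtype=object)

    # missingness at the genotype level: both compartments of a SNP drop out
    n = spec.n_cases + spec.n_controls
    rate = np.full(M, spec.missing_rate)
    if spec.n_high_missing_snps > 0:
        risk_snps = {r.locus // 2 for r in spec.risk_loci}
        candidates = np.array([k for k in range(M) if k not in risk_snps])
        hm = rng.choice(candidates, size=min(spec.n_high_missing_snps, len(candidates)),
                        replace=False)
        rate[hm] = spec.high_missing_rate
    miss = rng.random((n, M)) < rate
    sym[:, 0::2][miss] = MISSING
    sym[:, 1::2][miss] = MISSING

    loci = []
    for k in range(M):
        snp = SnpDef(f"snp{k + 1:06d}", "1", k + 1, "T", "A")
        loci.append(LocusMeta(k + 1, "odd", snp))
        loci.append(LocusMeta(k + 1, "even", snp))
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    m = AlleleMatrix(sym, loci, sample_ids, labels)

    odds_d = p_d / (1 - p_d)
    odds_c = p_c / (1 - p_c)
    truth = pd.DataFrame(
        {
            "locus": np.arange(L),
            "locus_id": m.locus_ids,
            "compartment": ["odd", "even"] * M,
            "p_disease": p_d,
            "p_control": p_c,
            "omega_true": odds_d / odds_c,
            "is_risk": planted,
        }
    )
    return m, truth


def table2_fixture() -> pd.DataFrame:
    """Printed worked example: six compartment probability pairs of three
    risk SNPs (disease and control cohorts), for statistics tests."""
    rows = [
        (1, "odd", 0.2302, 0.2415),
        (1, "even", 0.9934, 0.9754),
        (2, "odd", 0.2329, 0.2354),
        (2, "even", 0.9947, 0.9785),
        (3, "odd", 0.9987, 0.9923),
        (3, "even", 0.1105, 0.1000),
    ]
    return pd.DataFrame(rows, columns=["snp", "compartment", "p_disease", "p_control"])
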