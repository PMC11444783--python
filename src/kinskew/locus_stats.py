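"""Per-locus diagnostics for a microsatellite panel.

Allele frequencies by gene counting, observed/expected heterozygosity (with
small-sample correction), Botstein polymorphic information content, a
chi-square Hardy-Weinberg test with rare-class pooling, the Chakraborty
summation null-allele estimator, and the multi-locus probability of identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "AlleleFrequencies",
    "allele_frequencies",
    "locus_summary",
    "probability_of_identity",
    "PanelIdentity",
]


@dataclass
class AlleleFrequencies:
    """Gene-count allele frequencies per locus.

    ``table[l]`` has shape (max_allele + 1,) and is indexed directly by allele
    label; index 0 (the missing code) is always zero.
    """

    loci: list[str]
    table: np.ndarray     # (L, max_allele + 1)
    n_typed: np.ndarray   # typed individuals per locus

    def as_dicts(self) -> list[dict[int, float]]:
        return [
            {a: float(f) for a, f in enumerate(row) if f > 0}
            for row in self.table
        ]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for locus, row, n in zip(self.loci, self.table, self.n_typed):
            for allele, freq in enumerate(row):
                if freq > 0:
                    records.append((locus, allele, float(freq), int(n)))
        return pd.DataFrame(records, columns=["locus", "allele", "frequency", "n_typed"])


def allele_frequencies(matrix: GenotypeMatrix) -> AlleleFrequencies:
    max_allele = int(matrix.alleles.max(initial=1))
    table = np.zeros((matrix.n_loci, max_allele + 1))
    n_typed = np.zeros(matrix.n_loci, dtype=np.int64)
    untyped = []
    for l in range(matrix.n_loci):
        calls = matrix.alleles[:, l, :]
        typed = calls[calls[:, 0] != MISSING]
        if typed.size == 0:
            untyped.append(matrix.loci[l])
            continue
        counts = np.bincount(typed.ravel(), minlength=max_allele + 1).astype(float)
        counts[MISSING] = 0
        table[l] = counts / counts.sum()
        n_typed[l] = typed.shape[0]
    if untyped:
        raise ValueError(f"loci with zero typed individuals: {untyped}")
    return AlleleFrequencies(list(matrix.loci), table, n_typed)


def _hwe_chisq(genotype_counts: dict[tuple[int, int], int],
               p: np.ndarray, n: int) -> tuple[float, int, float]:
    """Chi-square HWE test pooling genotype classes with expected count < 5.

    df = pooled classes - number of alleles; below 1 the test is undefined and
    p = 1 is returned (matches the monomorphic convention).
    """
    alleles = np.flatnonzero(p > 0)
    k = len(alleles)
    if k < 2:
        return float("nan"), 0, 1.0
    observed, expected = [], []
    for ai_ix, a in enumerate(alleles):
        for b in alleles[ai_ix:]:
            exp = n * (p[a] ** 2 if a == b else 2 * p[a] * p[b])
            observed.append(genotype_counts.get((min(a, b), max(a, b)), 0))
            expected.append(exp)
    observed = np.array(observed, dtype=float)
    expected = np.array(expected, dtype=float)
    small = expected < 5
    if small.any() and (~small).any():
        observed = np.append(observed[~small], observed[small].sum())
        expected = np.append(expected[~small], expected[small].sum())
    elif small.all():
        observed = np.array([observed.sum()])
        expected = np.array([expected.sum()])
    df = len(observed) - k
    if df < 1:
        return float("nan"), 0, 1.0
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, df, float(stats.chi2.sf(chi2, df))


def locus_summary(matrix: GenotypeMatrix,
                  freqs: AlleleFrequencies | None = None) -> pd.DataFrame:
    """Panel diagnostics table, one row per locus.

    Columns: n_typed, k, Ho, He (unbiased), He_uncorrected, PIC, hwe_chi2,
    hwe_df, hwe_p, null_freq.  Monomorphic loci get Ho = He = PIC = 0 and
    hwe_p = 1.
    """
    freqs = freqs or allele_frequencies(matrix)
    rows = []
    for l, locus in enumerate(matrix.loci):
        calls = matrix.alleles[:, l, :]
        typed = calls[calls[:, 0] != MISSING]
        n = typed.shape[0]
        p = freqs.table[l]
        k = int((p > 0).sum())
        sum_p2 = float((p ** 2).sum())
        he_u = 1.0 - sum_p2
        he = he_u * (2 * n) / (2 * n - 1) if n > 1 else he_u
        ho = float((typed[:, 0] != typed[:, 1]).mean()) if n else 0.0
        # Botstein PIC: 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2
        pa = p[p > 0]
        cross = (np.outer(pa ** 2, pa ** 2).sum() - (pa ** 4).sum()) / 2.0
        pic = he_u - 2.0 * cross if k > 1 else 0.0
        gcounts: dict[tuple[int, int], int] = {}
        for a, b in typed:
            key = (int(min(a, b)), int(max(a, b)))
            gcounts[key] = gcounts.get(key, 0) + 1
        chi2, df, pval = _hwe_chisq(gcounts, p, n)
        denom = he_u + ho
        null_freq = (he_u - ho) / denom if denom > 0 else 0.0
        rows.append((locus, n, k, ho, he, he_u, pic, chi2, df, pval, null_freq))
    return pd.DataFrame(rows, columns=[
        "locus", "n_typed", "k", "Ho", "He", "He_uncorrected", "PIC",
        "hwe_chi2", "hwe_df", "hwe_p", "null_freq"])


@dataclass
class PanelIdentity:
    per_locus: np.ndarray
    panel: float


def probability_of_identity(freqs: AlleleFrequencies) -> PanelIdentity:
    """PI per locus (sum p_i^4 + sum_{i<j} (2 p_i p_j)^2) and panel product."""
    per_locus = []
    for p in freqs.table:
        pa = p[p > 0]
        hom = float((pa ** 4).sum())
        het = float(2.0 * ((np.outer(pa, pa) ** 2).sum() - (pa ** 4).sum()))
        per_locus.append(hom + het)
    per_locus = np.array(per_locus)
    return PanelIdentity(per_locus, float(per_locus.prod()))
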