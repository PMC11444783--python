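"""Hierarchical F-statistics over social groups (Nei heterozygosity form).

Per locus: H_O is the fraction of heterozygotes among typed individuals, H_S
the sample-size-weighted mean within-group expected heterozygosity (unbiased
by default), H_T the expected heterozygosity of pooled (gene-count) allele
frequencies.  F_IS = (H_S - H_O)/H_S, F_ST = (H_T - H_S)/H_T,
F_IT = (H_T - H_O)/H_T, so (1 - F_IT) = (1 - F_IS)(1 - F_ST) holds exactly.
Overall statistics use across-locus mean components.  Significance comes from
label permutations: individuals among groups for F_ST, allele copies among
individuals within groups for F_IS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "FStatsResult",
    "f_statistics",
    "fstat_permutation",
    "pairwise_group_fst",
]


@dataclass
class FStatsResult:
    per_locus: pd.DataFrame
    overall: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0


def _group_codes(matrix: GenotypeMatrix,
                 groups: dict[str, str] | None) -> tuple[np.ndarray, list[str]]:
    mapping = groups if groups is not None else matrix.groups
    if mapping is None:
        raise ValueError("no group labels supplied")
    labels = sorted({mapping[i] for i in matrix.ids})
    code = {g: k for k, g in enumerate(labels)}
    return np.array([code[mapping[i]] for i in matrix.ids]), labels


def _locus_components(calls: np.ndarray, codes: np.ndarray, n_groups: int,
                      corrected: bool) -> tuple[float, float, float] | None:
    typed = calls[:, 0] != MISSING
    if typed.sum() < 2:
        return None
    calls = calls[typed]
    codes = codes[typed]
    max_allele = int(calls.max())
    ho = float((calls[:, 0] != calls[:, 1]).mean())
    total_counts = np.zeros(max_allele + 1)
    hs_num = 0.0
    n_total = 0
    for g in range(n_groups):
        sub = calls[codes == g]
        n_g = sub.shape[0]
        if n_g == 0:
            continue
        counts = np.bincount(sub.ravel(), minlength=max_allele + 1).astype(float)
        counts[MISSING] = 0
        p_g = counts / counts.sum()
        he_g = 1.0 - float((p_g ** 2).sum())
        if corrected and n_g > 1:
            he_g *= (2 * n_g) / (2 * n_g - 1)
        hs_num += n_g * he_g
        n_total += n_g
        total_counts += counts
    hs = hs_num / n_total
    p_bar = total_counts / total_counts.sum()
    ht = 1.0 - float((p_bar ** 2).sum())
    return ho, hs, ht


def f_statistics(matrix: GenotypeMatrix,
                 groups: dict[str, str] | None = None,
                 corrected: bool = True) -> FStatsResult:
    """Per-locus and overall F_IS / F_ST / F_IT with their H components.

    Loci where H_S = 0 have undefined F_IS (NaN per locus, excluded with a
    warning); they still contribute their components to the overall means.
    """
    codes, labels = _group_codes(matrix, groups)
    n_groups = len(labels)
    if n_groups < 2:
        raise ValueError("need at least two groups")
    rows = []
    for l, locus in enumerate(matrix.loci):
        comp = _locus_components(matrix.alleles[:, l, :], codes, n_groups, corrected)
        if comp is None:
            continue
        ho, hs, ht = comp
        fis = (hs - ho) / hs if hs > 0 else np.nan
        fst = (ht - hs) / ht if ht > 0 else np.nan
        fit = (ht - ho) / ht if ht > 0 else np.nan
        if hs == 0:
            warnings.warn(f"H_S = 0 at locus {locus}: F_IS undefined there")
        rows.append((locus, ho, hs, ht, fis, fst, fit))
    if not rows:
        raise ValueError("no locus had enough typed individuals")
    per_locus = pd.DataFrame(rows, columns=["locus", "Ho", "Hs", "Ht",
                                            "Fis", "Fst", "Fit"])
    ho, hs, ht = (per_locus[c].mean() for c in ("Ho", "Hs", "Ht"))
    overall = {
        "Ho": float(ho), "Hs": float(hs), "Ht": float(ht),
        "Fis": float((hs - ho) / hs) if hs > 0 else float("nan"),
        "Fst": float((ht - hs) / ht) if ht > 0 else float("nan"),
        "Fit": float((ht - ho) / ht) if ht > 0 else float("nan"),
    }
    return FStatsResult(per_locus, overall)


def _permute_alleles_within_groups(matrix: GenotypeMatrix, codes: np.ndarray,
                                   rng: np.random.Generator) -> GenotypeMatrix:
    alleles = matrix.alleles.copy()
    for l in range(matrix.n_loci):
        for g in np.unique(codes):
            rows = np.flatnonzero((codes == g) & (alleles[:, l, 0] != MISSING))
            if rows.size < 2:
                continue
            pool = alleles[rows, l, :].ravel()
            rng.shuffle(pool)
            alleles[rows, l, :] = np.sort(pool.reshape(-1, 2), axis=1)
    return GenotypeMatrix(list(matrix.ids), list(matrix.loci), alleles, matrix.groups)


def fstat_permutation(matrix: GenotypeMatrix,
                      groups: dict[str, str] | None = None,
                      n_perm: int = 999, seed: int = 0,
                      corrected: bool = True) -> FStatsResult:
    """F-statistics plus permutation p-values.

    F_ST: permute individuals among groups, upper tail.  F_IS: permute allele
    copies among individuals within groups, two-sided.
    p = (1 + hits) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    codes, labels = _group_codes(matrix, groups)
    result = f_statistics(matrix, groups, corrected=corrected)
    obs_fst = result.overall["Fst"]
    obs_fis = result.overall["Fis"]
    mapping = groups if groups is not None else matrix.groups

    hits_fst = 0
    hits_fis = 0
    for _ in range(n_perm):
        shuffled = codes.copy()
        rng.shuffle(shuffled)
        perm_groups = {i: labels[c] for i, c in zip(matrix.ids, shuffled)}
        perm = f_statistics(matrix, perm_groups, corrected=corrected)
        if perm.overall["Fst"] >= obs_fst:
            hits_fst += 1
        within = _permute_alleles_within_groups(matrix, codes, rng)
        perm_is = f_statistics(within, mapping, corrected=corrected)
        if abs(perm_is.overall["Fis"]) >= abs(obs_fis):
            hits_fis += 1
    result.p_values = {
        "Fst": (1 + hits_fst) / (n_perm + 1),
        "Fis": (1 + hits_fis) / (n_perm + 1),
    }
    result.n_permutations = n_perm
    return result


def pairwise_group_fst(matrix: GenotypeMatrix,
                       groups: dict[str, str] | None = None,
                       corrected: bool = True) -> pd.DataFrame:
    """Symmetric group x group overall F_ST matrix (diagonal 0)."""
    mapping = groups if groups is not None else matrix.groups
    if mapping is None:
        raise ValueError("no group labels supplied")
    labels = sorted(set(mapping.values()))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    members = {g: [i for i in matrix.ids if mapping[i] == g] for g in labels}
    for ai, a in enumerate(labels):
        for b in labels[ai + 1:]:
            ids = members[a] + members[b]
            sub = matrix.subset(ids)
            typed_a = sub.subset(members[a]).n_typed()
            typed_b = sub.subset(members[b]).n_typed()
            if (typed_a > 0).sum() < 2 or (typed_b > 0).sum() < 2:
                warnings.warn(f"pair ({a}, {b}) has a group with <2 typed individuals")
                out.loc[a, b] = out.loc[b, a] = np.nan
                continue
            res = f_statistics(sub, {i: mapping[i] for i in ids}, corrected=corrected)
            out.loc[a, b] = out.loc[b, a] = res.overall["Fst"]
    return out
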