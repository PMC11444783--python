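"""Likelihood parentage assignment with simulation-calibrated confidence.

Per locus the likelihood ratio compares P(offspring genotype | candidate is a
parent) against the background HWE genotype probability.  Mistyping at rate e
mixes the Mendelian transition probability with the background probability:

    T' = (1 - e) * T + e * P(g_offspring)

so LOD = sum over co-typed loci of ln(T'/P).  At e = 0 an opposite-homozygote
mismatch gives T = 0 and LOD = -inf, i.e. hard exclusion.  Parent pairs use
the joint trio transition probability; the pair is the primary assignment
unit and delta is the LOD gap between the best and second-best pair.

Confidence thresholds are calibrated Monte-Carlo style: cycles of simulated
families plus partially sampled, partially related candidate sets yield delta
distributions for correct and incorrect top assignments, and the smallest
cutoffs achieving the requested reliability (e.g. 95% / 80%) become the
strict / relaxed tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .locus_stats import AlleleFrequencies

__all__ = [
    "CandidateRules",
    "CandidateSet",
    "ConfidenceSimParams",
    "ConfidenceThresholds",
    "ParentageAssignment",
    "build_candidates",
    "candidates_from_simulation",
    "single_parent_lod",
    "pair_lod",
    "lod_table",
    "simulate_confidence",
    "assign_parentage",
    "skew_summary",
]

TIER_NONE, TIER_RELAXED, TIER_STRICT = "none", "80%", "95%"


# ---------------------------------------------------------------------------
# Candidate construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateRules:
    """Field rules for candidate parents.

    Mothers: same-group females recorded pregnant within
    ``pregnancy_window_days`` of the pup's birth.  Fathers: same-group males
    older than ``father_min_age_years`` at conception (birth minus
    ``gestation_days``); ``population_wide_fathers`` widens the father pool to
    every old-enough male regardless of group.
    """

    pregnancy_window_days: int = 61       # "within two months"
    father_min_age_years: float = 2.0
    gestation_days: int = 50
    population_wide_fathers: bool = False


@dataclass
class CandidateSet:
    pup: str
    mothers: list[str]
    fathers: list[str]
    provenance: dict[str, str] = field(default_factory=dict)


def build_candidates(pups: list[str], meta: pd.DataFrame,
                     pregnancies: pd.DataFrame,
                     rules: CandidateRules = CandidateRules(),
                     genotyped: set[str] | None = None) -> list[CandidateSet]:
    """Candidate mothers/fathers per pup from dated field metadata.

    ``meta`` columns: id, sex, group, birth_date (ISO).  ``pregnancies``
    columns: female_id, date.  Candidates are restricted to ``genotyped`` ids
    when given, and never include the pup itself.
    """
    m = meta.copy()
    m["id"] = m["id"].astype(str)
    m["birth_date"] = pd.to_datetime(m["birth_date"])
    info = m.set_index("id")
    preg = pregnancies.copy()
    preg["female_id"] = preg["female_id"].astype(str)
    preg["date"] = pd.to_datetime(preg["date"])
    out = []
    for pup in pups:
        if pup not in info.index or pd.isna(info.loc[pup, "group"]):
            raise ValueError(f"pup {pup!r} has no group")
        group = info.loc[pup, "group"]
        born = info.loc[pup, "birth_date"]
        conception = born - pd.Timedelta(days=rules.gestation_days)
        mothers, fathers = [], []
        for ident, row in info.iterrows():
            if ident == pup:
                continue
            if genotyped is not None and ident not in genotyped:
                continue
            if row["sex"] == "F":
                if row["group"] != group:
                    continue
                recs = preg[preg["female_id"] == ident]
                if ((recs["date"] - born).abs()
                        <= pd.Timedelta(days=rules.pregnancy_window_days)).any():
                    mothers.append(ident)
            else:
                if not rules.population_wide_fathers and row["group"] != group:
                    continue
                age_years = (conception - row["birth_date"]).days / 365.25
                if age_years > rules.father_min_age_years:
                    fathers.append(ident)
        out.append(CandidateSet(pup, mothers, fathers, {
            "mothers": f"same-group, pregnant within {rules.pregnancy_window_days}d",
            "fathers": ("population-wide" if rules.population_wide_fathers
                        else "same-group") + f", age > {rules.father_min_age_years}y",
        }))
    return out


def candidates_from_simulation(pop, genotyped: set[str] | None = None,
                               population_wide_fathers: bool = False) -> list[CandidateSet]:
    """Candidate sets from simulated truth: adults co-resident in the pup's
    group during its birth season (the season-stepped analogue of the dated
    field rules)."""
    from .simdata import ADULT_AGE_SEASONS, PUP as ROLE_PUP

    by_id = {ind.id: ind for ind in pop.individuals}
    out = []
    for ind in pop.individuals:
        if ind.role != ROLE_PUP:
            continue
        season = ind.birth_season
        mothers, fathers = [], []
        for other in pop.individuals:
            if other.id == ind.id:
                continue
            if genotyped is not None and other.id not in genotyped:
                continue
            if season - other.birth_season < ADULT_AGE_SEASONS:
                continue  # not adult at conception
            same_group = pop.group_at(other.id, season) == pop.group_at(ind.id, season)
            if other.sex == "F":
                if same_group:
                    mothers.append(other.id)
            elif same_group or population_wide_fathers:
                fathers.append(other.id)
        out.append(CandidateSet(ind.id, mothers, fathers,
                                {"source": "simulated truth"}))
    return out


# ---------------------------------------------------------------------------
# LOD scores
# ---------------------------------------------------------------------------

def _transmit(allele: np.ndarray, parent: np.ndarray) -> np.ndarray:
    """P(parent transmits `allele`): 0.5 * (I(p1=a) + I(p2=a)). Broadcasts."""
    return 0.5 * ((parent[..., 0] == allele).astype(float)
                  + (parent[..., 1] == allele))


def _locus_lods(off: np.ndarray, mom: np.ndarray | None,
                dad: np.ndarray | None, pf: np.ndarray,
                error_rate: float) -> np.ndarray:
    """Per-locus LOD contributions; NaN where any participant is untyped.

    ``off``/``mom``/``dad`` are (..., L, 2) allele arrays; ``pf`` is an
    (L, max_allele+1) frequency lookup.  One of mom/dad may be None for
    single-parent LODs (the other parental allele is drawn from the
    population).
    """
    o1, o2 = off[..., 0], off[..., 1]
    L = off.shape[-2]
    lix = np.arange(L)
    p1 = pf[lix, o1]
    p2 = pf[lix, o2]
    het = o1 != o2
    bg = np.where(het, 2.0 * p1 * p2, p1 * p2)  # HWE genotype probability
    if mom is not None and dad is not None:
        t1m, t2m = _transmit(o1, mom), _transmit(o2, mom)
        t1d, t2d = _transmit(o1, dad), _transmit(o2, dad)
        trans = np.where(het, t1m * t2d + t2m * t1d, t1m * t1d)
        typed = (off[..., 0] != MISSING) & (mom[..., 0] != MISSING) \
            & (dad[..., 0] != MISSING)
    else:
        par = mom if mom is not None else dad
        t1, t2 = _transmit(o1, par), _transmit(o2, par)
        trans = np.where(het, t1 * p2 + t2 * p1, t1 * p1)
        typed = (off[..., 0] != MISSING) & (par[..., 0] != MISSING)
    mixed = (1.0 - error_rate) * trans + error_rate * bg
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = np.log(mixed) - np.log(bg)
    return np.where(typed, lod, np.nan)


def _sum_lods(per_locus: np.ndarray) -> np.ndarray:
    """Sum LOD contributions over loci, ignoring NaN (untyped)."""
    return np.nansum(per_locus, axis=-1)


def single_parent_lod(off: np.ndarray, parent: np.ndarray,
                      pf: np.ndarray, error_rate: float = 0.0) -> float:
    return float(_sum_lods(_locus_lods(off, parent, None, pf, error_rate)))


def pair_lod(off: np.ndarray, mom: np.ndarray, dad: np.ndarray,
             pf: np.ndarray, error_rate: float = 0.0) -> float:
    return float(_sum_lods(_locus_lods(off, mom, dad, pf, error_rate)))


def mismatch_count(off: np.ndarray, parent: np.ndarray) -> int:
    """Loci where offspring and candidate share no allele (both typed)."""
    typed = (off[:, 0] != MISSING) & (parent[:, 0] != MISSING)
    share = ((off[:, 0:1] == parent[:, 0:2]) | (off[:, 1:2] == parent[:, 0:2])).any(axis=1)
    return int((typed & ~share).sum())


@dataclass
class LodTable:
    pup: str
    mother_lod: dict[str, float]
    father_lod: dict[str, float]
    pair_lods: dict[tuple[str | None, str | None], float]
    mismatches: dict[str, int]


def lod_table(matrix: GenotypeMatrix, candidates: CandidateSet,
              freqs: AlleleFrequencies, error_rate: float = 0.0) -> LodTable:
    """Per-candidate and per-pair LODs for one pup.

    When one side has no candidates, pairs degrade to single-parent entries
    keyed as (mother, None) / (None, father).
    """
    pf = freqs.table
    off = matrix.row(candidates.pup)
    mother_lod = {m: single_parent_lod(off, matrix.row(m), pf, error_rate)
                  for m in candidates.mothers}
    father_lod = {f: single_parent_lod(off, matrix.row(f), pf, error_rate)
                  for f in candidates.fathers}
    mism = {c: mismatch_count(off, matrix.row(c))
            for c in [*candidates.mothers, *candidates.fathers]}
    pair_lods: dict[tuple[str | None, str | None], float] = {}
    if candidates.mothers and candidates.fathers:
        for m in candidates.mothers:
            for f in candidates.fathers:
                pair_lods[(m, f)] = pair_lod(off, matrix.row(m),
                                             matrix.row(f), pf, error_rate)
    elif candidates.mothers:
        pair_lods = {(m, None): lod for m, lod in mother_lod.items()}
    elif candidates.fathers:
        pair_lods = {(None, f): lod for f, lod in father_lod.items()}
    return LodTable(candidates.pup, mother_lod, father_lod, pair_lods, mism)


# ---------------------------------------------------------------------------
# Confidence simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfidenceSimParams:
    n_candidate_mothers: int = 2
    n_candidate_fathers: int = 2
    prop_mothers_sampled: float = 0.48
    prop_fathers_sampled: float = 0.47
    prop_loci_typed: float = 0.91
    error_rate: float = 0.05
    min_typed_loci: int = 7
    prop_related_mothers: float = 0.8
    related_mother_r: float = 0.31
    prop_related_fathers: float = 0.8
    related_father_r: float = 0.27
    strict_level: float = 0.95
    relaxed_level: float = 0.80

    def __post_init__(self) -> None:
        for name in ("prop_mothers_sampled", "prop_fathers_sampled",
                     "prop_loci_typed", "error_rate", "prop_related_mothers",
                     "prop_related_fathers"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("related_mother_r", "related_father_r"):
            if not 0.0 <= getattr(self, name) <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5]")


@dataclass
class ConfidenceThresholds:
    strict: float
    relaxed: float
    strict_assignment_rate: float
    relaxed_assignment_rate: float
    n_cycles: int
    seed: int
    params: dict = field(default_factory=dict)

    def tier(self, delta: float) -> str:
        if delta >= self.strict:
            return TIER_STRICT
        if delta >= self.relaxed:
            return TIER_RELAXED
        return TIER_NONE


def _draw_hwe(pf: np.ndarray, rng: np.random.Generator,
              shape: tuple[int, ...]) -> np.ndarray:
    """Draw (..., L, 2) HWE genotypes from an (L, A+1) frequency lookup."""
    L = pf.shape[0]
    out = np.zeros(shape + (L, 2), dtype=np.int64)
    for l in range(L):
        p = pf[l]
        alleles = np.flatnonzero(p > 0)
        out[..., l, :] = rng.choice(alleles, size=shape + (2,), p=p[alleles] / p[alleles].sum())
    return np.sort(out, axis=-1)


def _mendel_offspring(mom: np.ndarray, dad: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    pick_m = rng.integers(2, size=mom.shape[:-1])
    pick_d = rng.integers(2, size=dad.shape[:-1])
    child = np.stack([np.take_along_axis(mom, pick_m[..., None], axis=-1)[..., 0],
                      np.take_along_axis(dad, pick_d[..., None], axis=-1)[..., 0]],
                     axis=-1)
    return np.sort(child, axis=-1)


def _related_candidate(focal: np.ndarray, pf: np.ndarray, r: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Candidate related to ``focal`` by expected QG relatedness ``r``.

    Per locus, with probability 2r the candidate carries one allele identical
    by descent from the focal (sharing one allele IBD at a fraction f of loci
    gives r = f/2, so f = 2r); the remaining alleles are population draws.
    """
    rand = _draw_hwe(pf, rng, focal.shape[:-2])
    share = rng.random(focal.shape[:-1]) < 2.0 * r
    which = rng.integers(2, size=focal.shape[:-1])
    ibd = np.take_along_axis(focal, which[..., None], axis=-1)[..., 0]
    out = rand.copy()
    out[..., 0] = np.where(share, ibd, rand[..., 0])
    return np.sort(out, axis=-1)


def _apply_typing_noise(g: np.ndarray, pf: np.ndarray, typed_prob: float,
                        error_rate: float, rng: np.random.Generator) -> np.ndarray:
    out = g.copy()
    untyped = rng.random(g.shape[:-1]) >= typed_prob
    out[untyped] = MISSING
    if error_rate > 0:
        err = (rng.random(g.shape[:-1]) < error_rate) & ~untyped
        rand = _draw_hwe(pf, rng, g.shape[:-2])
        out[err] = rand[err]
    return out


def _reliability_cutoff(deltas: np.ndarray, correct: np.ndarray,
                        level: float) -> tuple[float, float]:
    """Smallest delta cutoff whose accepted set is >= ``level`` correct.

    Returns (cutoff, assignment rate); cutoff is +inf when no prefix of the
    delta-ranked cycles reaches the requested reliability.
    """
    order = np.argsort(-deltas, kind="stable")
    d_sorted = deltas[order]
    frac = np.cumsum(correct[order]) / np.arange(1, len(order) + 1)
    ok = np.flatnonzero(frac >= level)
    if ok.size == 0:
        return float("inf"), 0.0
    i = ok.max()
    cutoff = float(d_sorted[i])
    rate = (i + 1) / len(deltas)
    return cutoff, float(rate)


def simulate_confidence(freqs: AlleleFrequencies,
                        params: ConfidenceSimParams = ConfidenceSimParams(),
                        n_cycles: int = 10_000,
                        seed: int = 0) -> ConfidenceThresholds:
    """Monte-Carlo calibration of delta confidence cutoffs.

    Each cycle simulates a true trio from the observed allele frequencies,
    builds candidate sets per the sampling / relatedness parameters, degrades
    genotypes (typed fraction, mistyping, minimum-loci filter) and assigns the
    top parent pair by trio LOD.  The strict / relaxed cutoffs are the
    smallest deltas achieving the requested reliability among accepted
    assignments.
    """
    rng = np.random.default_rng(seed)
    pf = freqs.table
    C = n_cycles
    mom = _draw_hwe(pf, rng, (C,))
    dad = _draw_hwe(pf, rng, (C,))
    off = _mendel_offspring(mom, dad, rng)

    def candidate_block(true_parent: np.ndarray, n_cand: int, prop_sampled: float,
                        prop_related: float, rel_r: float) -> tuple[np.ndarray, np.ndarray]:
        sampled = rng.random(C) < prop_sampled
        cands = np.zeros((n_cand, C) + true_parent.shape[1:], dtype=np.int64)
        for slot in range(n_cand):
            related = rng.random(C) < prop_related
            distract = np.where(
                related[:, None, None],
                _related_candidate(true_parent, pf, rel_r, rng),
                _draw_hwe(pf, rng, (C,)))
            if slot == 0:
                cands[slot] = np.where(sampled[:, None, None], true_parent, distract)
            else:
                cands[slot] = distract
        return cands, sampled

    moms, mom_sampled = candidate_block(
        mom, params.n_candidate_mothers, params.prop_mothers_sampled,
        params.prop_related_mothers, params.related_mother_r)
    dads, dad_sampled = candidate_block(
        dad, params.n_candidate_fathers, params.prop_fathers_sampled,
        params.prop_related_fathers, params.related_father_r)

    off_obs = _apply_typing_noise(off, pf, params.prop_loci_typed,
                                  params.error_rate, rng)
    moms_obs = np.stack([_apply_typing_noise(m, pf, params.prop_loci_typed,
                                             params.error_rate, rng) for m in moms])
    dads_obs = np.stack([_apply_typing_noise(d, pf, params.prop_loci_typed,
                                             params.error_rate, rng) for d in dads])

    def enough(g: np.ndarray) -> np.ndarray:
        return (g[..., 0] != MISSING).sum(axis=-1) >= params.min_typed_loci

    off_ok = enough(off_obs)
    mom_ok = np.stack([enough(m) for m in moms_obs])
    dad_ok = np.stack([enough(d) for d in dads_obs])

    n_pairs = params.n_candidate_mothers * params.n_candidate_fathers
    pair_lods = np.full((C, n_pairs), -np.inf)
    pair_ok = np.zeros((C, n_pairs), dtype=bool)
    k = 0
    for mi in range(params.n_candidate_mothers):
        for di in range(params.n_candidate_fathers):
            lods = _sum_lods(_locus_lods(off_obs, moms_obs[mi], dads_obs[di],
                                         pf, params.error_rate))
            ok = off_ok & mom_ok[mi] & dad_ok[di]
            pair_lods[:, k] = np.where(ok, lods, -np.inf)
            pair_ok[:, k] = ok
            k += 1

    usable = pair_ok.any(axis=1)
    top_ix = np.argmax(pair_lods, axis=1)
    sorted_lods = np.sort(pair_lods, axis=1)
    top = sorted_lods[:, -1]
    second = sorted_lods[:, -2] if n_pairs > 1 else np.full(C, -np.inf)
    sole = pair_ok.sum(axis=1) == 1
    with np.errstate(invalid="ignore"):
        delta = np.where(np.isfinite(second), top - second,
                         np.maximum(top, 0.0))
    delta = np.where(sole, np.maximum(top, 0.0), delta)
    # pair index 0 is (true mother slot, true father slot)
    correct = (top_ix == 0) & mom_sampled & dad_sampled

    deltas = delta[usable]
    corr = correct[usable]
    strict, strict_rate = _reliability_cutoff(deltas, corr, params.strict_level)
    relaxed, relaxed_rate = _reliability_cutoff(deltas, corr, params.relaxed_level)
    if np.isfinite(strict) and np.isfinite(relaxed):
        strict = max(strict, relaxed)
    return ConfidenceThresholds(strict, relaxed, strict_rate, relaxed_rate,
                                n_cycles, seed, asdict(params))


# ---------------------------------------------------------------------------
# Assignment and skew summaries
# ---------------------------------------------------------------------------

@dataclass
class ParentageAssignment:
    pup: str
    mother: str | None
    father: str | None
    lod: float
    delta: float
    tier: str
    mismatches: int
    reason: str = ""


def assign_parentage(tables: list[LodTable],
                     thresholds: ConfidenceThresholds) -> list[ParentageAssignment]:
    """Pick the top parent pair per pup and grade it by delta tier.

    Ties on LOD break by fewer combined mismatches, then lexical ids.  A sole
    candidate pair's delta is its LOD when positive, else 0.  Pairs at -inf
    (hard exclusions) are never assigned.
    """
    out = []
    for t in tables:
        entries = [(pair, lod) for pair, lod in t.pair_lods.items()
                   if np.isfinite(lod)]
        if not entries:
            out.append(ParentageAssignment(
                t.pup, None, None, float("nan"), 0.0, TIER_NONE, 0,
                "no candidate pair" if not t.pair_lods else "all pairs excluded"))
            continue

        def sort_key(entry):
            (m, f), lod = entry
            mism = t.mismatches.get(m, 0) + t.mismatches.get(f, 0)
            return (-lod, mism, m or "", f or "")

        entries.sort(key=sort_key)
        (mother, father), top = entries[0]
        if len(entries) > 1:
            delta = top - entries[1][1]
        else:
            delta = max(top, 0.0)
        mism = t.mismatches.get(mother, 0) + t.mismatches.get(father, 0)
        out.append(ParentageAssignment(t.pup, mother, father, top, delta,
                                       thresholds.tier(delta), mism))
    return out


def skew_summary(assignments: list[ParentageAssignment] | pd.DataFrame,
                 roles: dict[str, str],
                 litters: dict[str, str] | None = None) -> dict:
    """Reproductive-skew table from parentage assignments.

    ``roles`` maps parent id -> 'dominant' / 'subordinate' (at the pup's
    conception).  Returns counts and percentages of dominant vs subordinate
    maternity and paternity among resolved assignments, plus litter parental
    composition classes when a pup -> litter map is given.
    """
    if isinstance(assignments, pd.DataFrame):
        records = assignments.to_dict("records")
    else:
        records = [{"pup": a.pup, "mother": a.mother, "father": a.father}
                   for a in assignments]

    def tally(parent_key: str) -> dict:
        dom = sub = 0
        for rec in records:
            parent = rec.get(parent_key)
            if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                continue
            if roles.get(parent) == "dominant":
                dom += 1
            else:
                sub += 1
        total = dom + sub
        return {
            "n_dominant": dom,
            "n_subordinate": sub,
            "n_total": total,
            "pct_dominant": 100.0 * dom / total if total else float("nan"),
            "pct_subordinate": 100.0 * sub / total if total else float("nan"),
        }

    summary = {"maternity": tally("mother"), "paternity": tally("father"),
               "n_pups": len(records)}
    if litters is not None:
        classes = {"both_dominant": 0, "dom_male_sub_female": 0,
                   "dom_female_sub_male": 0, "both_subordinate": 0}
        for rec in records:
            m, f = rec.get("mother"), rec.get("father")
            if m is None or f is None:
                continue
            dm = roles.get(m) == "dominant"
            df_ = roles.get(f) == "dominant"
            if dm and df_:
                classes["both_dominant"] += 1
            elif df_ and not dm:
                classes["dom_male_sub_female"] += 1
            elif dm and not df_:
                classes["dom_female_sub_male"] += 1
            else:
                classes["both_subordinate"] += 1
        summary["pair_classes"] = classes
    return summary
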