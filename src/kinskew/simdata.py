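"""Synthetic cooperatively-breeding populations with known pedigree truth.

Generates season-stepped social groups, each holding exactly one dominant
pair, with configurable reproductive skew, sex-biased dispersal, Mendelian
genotype transmission at abstract microsatellite loci, and a faecal-DNA noise
channel (allelic dropout, false alleles, whole-locus failure) for replicate
genotypes.  Everything is reproducible bit-for-bit from a single seed; each
operation draws from its own RNG stream derived from the master seed via a
documented integer key, so replicate noise can be regenerated without
re-running the demography.

Default locus parameters (13 loci, 6 alleles, Dirichlet concentration 0.46)
are tuned so mean founder expected heterozygosity sits near 0.61; the
genotyping error-rate defaults are illustrative, not field estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, ReplicateSet

__all__ = [
    "SimConfig",
    "SimulatedPopulation",
    "SimulationError",
    "simulate_population",
    "simulate_replicates",
    "write_population",
]

# RNG stream keys: default_rng([seed, key]) per operation
_STREAM_POPULATION = 1
_STREAM_REPLICATES = 2

# seasons from birth until a pup is counted as adult
ADULT_AGE_SEASONS = 2

MALE, FEMALE = "M", "F"
DOMINANT, SUBORDINATE, PUP = "dominant", "subordinate", "pup"
NATAL, IMMIGRANT = "natal", "immigrant"


class SimulationError(RuntimeError):
    pass


def _check_proportion(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SimConfig:
    n_groups: int = 7
    group_size_mean: int = 10
    n_loci: int = 13
    alleles_per_locus: int = 6
    founder_freq_concentration: float = 0.46
    dominant_maternity_share: float = 0.886
    dominant_paternity_share: float = 0.875
    male_dispersal_prob: float = 0.15
    female_dispersal_prob: float = 0.05
    n_seasons: int = 4
    litters_per_season_mean: float = 2.0
    litter_size_mean: float = 3.5
    pup_survival: float = 1.0
    dropout_rate: float = 0.0
    false_allele_rate: float = 0.0
    locus_failure_rate: float = 0.0
    n_replicates: int = 3
    outside_immigrant_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "group_size_mean", "n_loci",
                     "alleles_per_locus", "n_seasons", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.alleles_per_locus < 2:
            raise ValueError("alleles_per_locus must be >= 2")
        if self.founder_freq_concentration <= 0:
            raise ValueError("founder_freq_concentration must be positive")
        if self.litters_per_season_mean <= 0 or self.litter_size_mean <= 0:
            raise ValueError("litter means must be positive")
        for name in ("dominant_maternity_share", "dominant_paternity_share",
                     "male_dispersal_prob", "female_dispersal_prob",
                     "pup_survival", "dropout_rate", "false_allele_rate",
                     "locus_failure_rate"):
            _check_proportion(name, getattr(self, name))
        if self.outside_immigrant_rate < 0:
            raise ValueError("outside_immigrant_rate must be >= 0")


@dataclass
class Individual:
    id: str
    sex: str
    group: str
    role: str
    birth_season: int
    origin: str


@dataclass
class SwitchRecord:
    ids: tuple[str, ...]
    season: int
    from_group: str
    to_group: str
    coalition: bool


@dataclass
class SimulatedPopulation:
    """Ground-truth container: roles, pedigree, residence history, genotypes."""

    individuals: list[Individual]
    pedigree: dict[str, tuple[str | None, str | None]]
    switch_events: list[SwitchRecord]
    true_genotypes: GenotypeMatrix
    litters: dict[str, str]                      # pup id -> litter id
    history: dict[str, list[tuple[int, str]]]    # id -> [(season joined, group)]
    founder_freqs: np.ndarray                    # (L, A)
    config: SimConfig

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(ind) for ind in self.individuals])

    def roles(self) -> dict[str, str]:
        return {ind.id: ind.role for ind in self.individuals}

    def group_at(self, individual: str, season: int) -> str | None:
        """Group of residence during ``season`` (None if not yet born)."""
        current = None
        for joined, group in self.history[individual]:
            if joined <= season:
                current = group
        return current

    def dominant_pairs(self) -> dict[str, tuple[str, str]]:
        """group -> (dominant male id, dominant female id)."""
        pairs: dict[str, dict[str, str]] = {}
        for ind in self.individuals:
            if ind.role == DOMINANT:
                pairs.setdefault(ind.group, {})[ind.sex] = ind.id
        return {g: (d[MALE], d[FEMALE]) for g, d in pairs.items()
                if MALE in d and FEMALE in d}


def _mendel(dam: np.ndarray, sire: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    L = dam.shape[0]
    pick_d = rng.integers(2, size=L)
    pick_s = rng.integers(2, size=L)
    child = np.stack([dam[np.arange(L), pick_d],
                      sire[np.arange(L), pick_s]], axis=1)
    return np.sort(child, axis=1)


def simulate_population(config: SimConfig) -> SimulatedPopulation:
    """Run the season-stepped demography and return full truth.

    Per season: pups old enough become subordinate adults, subordinate adults
    disperse between groups with sex-specific probabilities, then each group
    breeds.  Litter dams are the dominant female with probability
    ``dominant_maternity_share`` (else a uniform adult subordinate female);
    sires analogous.  Only pups passing the survival draw enter the output.
    """
    rng = np.random.default_rng([config.seed, _STREAM_POPULATION])
    L, A = config.n_loci, config.alleles_per_locus
    freqs = rng.dirichlet(np.full(A, config.founder_freq_concentration), size=L)

    groups = [f"G{g}" for g in range(config.n_groups)]
    individuals: dict[str, Individual] = {}
    genotypes: dict[str, np.ndarray] = {}
    pedigree: dict[str, tuple[str | None, str | None]] = {}
    litters: dict[str, str] = {}
    history: dict[str, list[tuple[int, str]]] = {}
    switch_events: list[SwitchRecord] = []
    counter = 0

    def founder_genotype() -> np.ndarray:
        g = np.stack([
            np.array([rng.choice(A, p=freqs[l]) + 1 for l in range(L)]),
            np.array([rng.choice(A, p=freqs[l]) + 1 for l in range(L)]),
        ], axis=1)
        return np.sort(g, axis=1)

    def add_individual(sex: str, group: str, role: str, birth_season: int,
                       origin: str, genotype: np.ndarray,
                       parents: tuple[str | None, str | None]) -> str:
        nonlocal counter
        ident = f"I{counter:04d}"
        counter += 1
        individuals[ident] = Individual(ident, sex, group, role, birth_season, origin)
        genotypes[ident] = genotype
        pedigree[ident] = parents
        history[ident] = [(max(birth_season, 0), group)]
        return ident

    # founders: one dominant pair per group plus subordinates of alternating sex
    for group in groups:
        add_individual(MALE, group, DOMINANT, -ADULT_AGE_SEASONS, NATAL,
                       founder_genotype(), (None, None))
        add_individual(FEMALE, group, DOMINANT, -ADULT_AGE_SEASONS, NATAL,
                       founder_genotype(), (None, None))
        for k in range(max(config.group_size_mean - 2, 0)):
            sex = MALE if k % 2 == 0 else FEMALE
            add_individual(sex, group, SUBORDINATE, -ADULT_AGE_SEASONS, NATAL,
                           founder_genotype(), (None, None))

    def adults(group: str, sex: str) -> list[str]:
        return [i for i, ind in individuals.items()
                if ind.group == group and ind.sex == sex and ind.role != PUP]

    for season in range(config.n_seasons):
        # promote pups that have reached adulthood
        for ind in individuals.values():
            if ind.role == PUP and season - ind.birth_season >= ADULT_AGE_SEASONS:
                ind.role = SUBORDINATE

        # dispersal of subordinate adults
        if len(groups) > 1:
            for ident in sorted(individuals):
                ind = individuals[ident]
                if ind.role != SUBORDINATE:
                    continue
                prob = (config.male_dispersal_prob if ind.sex == MALE
                        else config.female_dispersal_prob)
                if prob > 0 and rng.random() < prob:
                    others = [g for g in groups if g != ind.group]
                    target = others[rng.integers(len(others))]
                    switch_events.append(SwitchRecord(
                        (ident,), season, ind.group, target, False))
                    ind.group = target
                    ind.origin = IMMIGRANT
                    history[ident].append((season, target))

        # immigrants from outside the study system (novel founders)
        if config.outside_immigrant_rate > 0:
            for group in groups:
                for _ in range(rng.poisson(config.outside_immigrant_rate)):
                    sex = MALE if rng.random() < 0.5 else FEMALE
                    add_individual(sex, group, SUBORDINATE, season - ADULT_AGE_SEASONS,
                                   IMMIGRANT, founder_genotype(), (None, None))

        # breeding
        for group in groups:
            females = adults(group, FEMALE)
            males = adults(group, MALE)
            if not females:
                raise SimulationError(
                    f"no adult females in group {group} at season {season}")
            if not males:
                raise SimulationError(
                    f"no adult males in group {group} at season {season}")
            dom_f = next(i for i in females if individuals[i].role == DOMINANT)
            dom_m = next(i for i in males if individuals[i].role == DOMINANT)
            sub_f = [i for i in females if i != dom_f]
            sub_m = [i for i in males if i != dom_m]
            n_litters = rng.poisson(config.litters_per_season_mean)
            for lit in range(n_litters):
                if sub_f and rng.random() >= config.dominant_maternity_share:
                    dam = sub_f[rng.integers(len(sub_f))]
                else:
                    dam = dom_f
                if sub_m and rng.random() >= config.dominant_paternity_share:
                    sire = sub_m[rng.integers(len(sub_m))]
                else:
                    sire = dom_m
                litter_id = f"{group}-s{season}-l{lit}"
                size = max(1, rng.poisson(config.litter_size_mean))
                for _ in range(size):
                    if rng.random() >= config.pup_survival:
                        continue
                    sex = MALE if rng.random() < 0.5 else FEMALE
                    child = _mendel(genotypes[dam], genotypes[sire], rng)
                    pid = add_individual(sex, group, PUP, season, NATAL,
                                         child, (dam, sire))
                    litters[pid] = litter_id

    # final promotion so roles reflect the end of the run
    for ind in individuals.values():
        if ind.role == PUP and config.n_seasons - ind.birth_season >= ADULT_AGE_SEASONS:
            ind.role = SUBORDINATE

    ids = sorted(individuals)
    matrix = GenotypeMatrix(
        ids, [f"L{l:02d}" for l in range(L)],
        np.stack([genotypes[i] for i in ids]),
        {i: individuals[i].group for i in ids})
    return SimulatedPopulation(
        [individuals[i] for i in ids], pedigree, switch_events, matrix,
        litters, history, freqs, config)


def simulate_replicates(pop: SimulatedPopulation,
                        config: SimConfig | None = None) -> ReplicateSet:
    """Overlay the faecal-DNA error process on the true genotypes.

    Per replicate and locus: whole-locus failure with ``locus_failure_rate``;
    in surviving heterozygous calls each allele drops independently with
    ``dropout_rate`` (one survivor -> apparent homozygote, both dropped ->
    missing); with ``false_allele_rate`` one allele of the surviving call is
    replaced by a uniformly chosen other allele of that locus.
    """
    config = config or pop.config
    rng = np.random.default_rng([config.seed, _STREAM_REPLICATES])
    A = config.alleles_per_locus
    matrix = pop.true_genotypes
    replicates: dict[str, list[tuple[str, np.ndarray]]] = {}
    for ix, ident in enumerate(matrix.ids):
        truth = matrix.alleles[ix]
        reps = []
        for r in range(config.n_replicates):
            g = truth.copy()
            for l in range(g.shape[0]):
                if rng.random() < config.locus_failure_rate:
                    g[l] = (MISSING, MISSING)
                    continue
                a, b = g[l]
                if a != b:  # heterozygote: independent per-allele dropout
                    drop_a = rng.random() < config.dropout_rate
                    drop_b = rng.random() < config.dropout_rate
                    if drop_a and drop_b:
                        g[l] = (MISSING, MISSING)
                        continue
                    if drop_a:
                        g[l] = (b, b)
                    elif drop_b:
                        g[l] = (a, a)
                if rng.random() < config.false_allele_rate:
                    which = rng.integers(2)
                    current = g[l, which]
                    other = 1 + rng.integers(A - 1)
                    if other >= current:
                        other += 1
                    g[l, which] = other
                g[l] = np.sort(g[l])
            reps.append((f"{ident}-rep{r}", g))
        replicates[ident] = reps
    return ReplicateSet(list(matrix.loci), replicates)


def write_population(pop: SimulatedPopulation, outdir: str | Path,
                     reps: ReplicateSet | None = None) -> dict[str, Path]:
    """Serialize truth (and optionally replicates) as plain CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    frame = pop.true_genotypes.to_frame()
    paths["genotypes"] = outdir / "true_genotypes.csv"
    frame.to_csv(paths["genotypes"], index=False)
    paths["metadata"] = outdir / "metadata.csv"
    pop.metadata().to_csv(paths["metadata"], index=False)
    ped = pd.DataFrame(
        [(k, d or "", s or "") for k, (d, s) in pop.pedigree.items()],
        columns=["individual_id", "dam_id", "sire_id"])
    ped["litter_id"] = ped["individual_id"].map(pop.litters).fillna("")
    paths["pedigree"] = outdir / "pedigree.csv"
    ped.to_csv(paths["pedigree"], index=False)
    switches = pd.DataFrame(
        [(";".join(e.ids), e.season, e.from_group, e.to_group, e.coalition)
         for e in pop.switch_events],
        columns=["ids", "season", "from_group", "to_group", "coalition"])
    paths["switches"] = outdir / "switch_events.csv"
    switches.to_csv(paths["switches"], index=False)
    if reps is not None:
        paths["replicates"] = outdir / "replicates.csv"
        reps.to_frame().to_csv(paths["replicates"], index=False)
    return paths
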