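"""Diploid microsatellite genotype containers, file I/O and consensus calling.

Genotypes are stored as integer allele labels (``1..k`` per locus) in an
``(n_individuals, n_loci, 2)`` array; ``0`` encodes a missing allele.  A cell
is either fully typed (both alleles > 0) or fully missing (both 0); allele
pairs are kept sorted so genotypes are unordered.

Consensus calling reconciles replicate amplifications of the same individual
(e.g. repeated faecal extracts) under an allelic-dropout-aware rule set:
heterozygotes may be confirmed across replicates even when individual
replicates show apparent homozygotes, while irreconcilable replicates are
flagged as conflicts and left missing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "ReplicateSet",
    "ConsensusRules",
    "ConsensusResult",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "read_genepop",
    "write_genepop",
    "call_consensus",
    "consensus_matrix",
    "flag_regenotyping",
    "filter_min_loci",
]


class GenotypeParseError(ValueError):
    """Raised for malformed genotype files; carries a line number when known."""


def _as_sorted_pairs(alleles: np.ndarray) -> np.ndarray:
    alleles = np.asarray(alleles, dtype=np.int64)
    if alleles.ndim != 3 or alleles.shape[2] != 2:
        raise ValueError("allele array must have shape (n, n_loci, 2)")
    half = (alleles == MISSING).sum(axis=2) == 1
    if half.any():
        i, l = np.argwhere(half)[0]
        raise ValueError(
            f"half-missing genotype at individual index {i}, locus index {l}: "
            "alleles must be both present or both missing"
        )
    return np.sort(alleles, axis=2)


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotype grid (ploidy fixed at 2)."""

    ids: list[str]
    loci: list[str]
    alleles: np.ndarray  # (n, L, 2) int, 0 = missing
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.loci = [str(l) for l in self.loci]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus ids")
        self.alleles = _as_sorted_pairs(self.alleles)
        if self.alleles.shape[:2] != (len(self.ids), len(self.loci)):
            raise ValueError("allele array shape does not match ids/loci")
        if (self.alleles < 0).any():
            raise ValueError("negative allele labels are not allowed")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, L) mask of non-missing calls."""
        return self.alleles[:, :, 0] != MISSING

    def n_typed(self) -> np.ndarray:
        """Number of typed loci per individual."""
        return self.typed_mask().sum(axis=1)

    def group_array(self) -> np.ndarray:
        if self.groups is None:
            raise ValueError("matrix carries no group labels")
        return np.array([self.groups[i] for i in self.ids])

    def subset(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {i: k for k, i in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        groups = None
        if self.groups is not None:
            groups = {i: self.groups[i] for i in ids if i in self.groups}
        return GenotypeMatrix(list(ids), list(self.loci),
                              self.alleles[rows].copy(), groups)

    def row(self, individual: str) -> np.ndarray:
        return self.alleles[self.ids.index(individual)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: individual_id, locus, allele1, allele2[, group]."""
        n, L = self.n_individuals, self.n_loci
        frame = pd.DataFrame({
            "individual_id": np.repeat(self.ids, L),
            "locus": np.tile(self.loci, n),
            "allele1": self.alleles[:, :, 0].ravel(),
            "allele2": self.alleles[:, :, 1].ravel(),
        })
        if self.groups is not None:
            frame["group"] = frame["individual_id"].map(self.groups)
        return frame


def _frame_to_matrix(frame: pd.DataFrame) -> GenotypeMatrix:
    required = {"individual_id", "locus", "allele1", "allele2"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise GenotypeParseError(f"missing columns: {sorted(missing_cols)}")
    ids = list(dict.fromkeys(frame["individual_id"].astype(str)))
    loci = list(dict.fromkeys(frame["locus"].astype(str)))
    alleles = np.zeros((len(ids), len(loci), 2), dtype=np.int64)
    seen = np.zeros((len(ids), len(loci)), dtype=bool)
    id_ix = {i: k for k, i in enumerate(ids)}
    loc_ix = {l: k for k, l in enumerate(loci)}
    for row in frame.itertuples(index=False):
        i = id_ix[str(row.individual_id)]
        l = loc_ix[str(row.locus)]
        if seen[i, l]:
            raise GenotypeParseError(
                f"duplicate call for individual {row.individual_id!r} at locus {row.locus!r}")
        seen[i, l] = True
        alleles[i, l] = (int(row.allele1), int(row.allele2))
    groups = None
    if "group" in frame.columns:
        groups = dict(zip(frame["individual_id"].astype(str),
                          frame["group"].astype(str)))
    return GenotypeMatrix(ids, loci, alleles, groups)


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype table from CSV (long format) or GenePop.

    Format is inferred from the extension when not given (``.gen``/``.genepop``
    select GenePop, everything else CSV).
    """
    path = Path(path)
    if format is None:
        format = "genepop" if path.suffix.lower() in {".gen", ".genepop", ".txt"} else "csv"
    if format == "csv":
        try:
            frame = pd.read_csv(path)
        except pd.errors.ParserError as exc:  # ragged rows etc.
            raise GenotypeParseError(str(exc)) from exc
        return _frame_to_matrix(frame)
    if format == "genepop":
        return read_genepop(path)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GenePop dialect: title line, locus names (one per line or comma separated),
# "Pop" separators, then "id ,  0101 0102 ...".  2- or 3-digit allele codes
# are auto-detected from token length; 00/000 encodes missing.
# ---------------------------------------------------------------------------

def read_genepop(path: str | Path) -> GenotypeMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeParseError("empty GenePop file")
    # locus names: lines 1..first "Pop" (may be comma-separated on one line)
    loci: list[str] = []
    body_start = None
    for k, line in enumerate(lines[1:], start=1):
        if line.strip().lower() == "pop":
            body_start = k
            break
        loci.extend(tok.strip() for tok in line.split(",") if tok.strip())
    if body_start is None:
        raise GenotypeParseError("no 'Pop' separator found")
    ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    groups: dict[str, str] = {}
    pop = 0
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pop += 1
            continue
        if "," not in stripped:
            raise GenotypeParseError(f"line {lineno}: expected 'id , genotypes'")
        ident, geno = stripped.split(",", 1)
        ident = ident.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenotypeParseError(
                f"line {lineno}: {len(tokens)} genotypes for {len(loci)} loci")
        calls = []
        for tok in tokens:
            if len(tok) == 4:
                width = 2
            elif len(tok) == 6:
                width = 3
            else:
                raise GenotypeParseError(f"line {lineno}: bad genotype token {tok!r}")
            if not re.fullmatch(r"\d+", tok):
                raise GenotypeParseError(f"line {lineno}: bad genotype token {tok!r}")
            calls.append((int(tok[:width]), int(tok[width:])))
        if ident in ids:
            raise GenotypeParseError(f"line {lineno}: duplicate id {ident!r}")
        ids.append(ident)
        rows.append(calls)
        groups[ident] = f"pop{pop + 1}"
    alleles = np.array(rows, dtype=np.int64).reshape(len(ids), len(loci), 2)
    # half-missing tokens like 0102 vs 0100 are rejected by the container
    return GenotypeMatrix(ids, loci, alleles, groups)


def write_genepop(matrix: GenotypeMatrix, path: str | Path,
                  title: str = "kinskew export") -> None:
    width = 3 if int(matrix.alleles.max(initial=0)) > 99 else 2
    out = [title]
    out.extend(matrix.loci)
    if matrix.groups is not None:
        order: dict[str, list[str]] = {}
        for i in matrix.ids:
            order.setdefault(matrix.groups.get(i, "pop1"), []).append(i)
        blocks = list(order.values())
    else:
        blocks = [list(matrix.ids)]
    for block in blocks:
        out.append("Pop")
        for ident in block:
            g = matrix.row(ident)
            toks = "".join(
                f" {a1:0{width}d}{a2:0{width}d}" for a1, a2 in g)
            out.append(f"{ident} , {toks.strip()}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Replicates and consensus
# ---------------------------------------------------------------------------

@dataclass
class ReplicateSet:
    """Per-individual replicate genotype grids sharing one locus panel."""

    loci: list[str]
    replicates: dict[str, list[tuple[str, np.ndarray]]]  # id -> [(sample_id, (L,2))]

    def __post_init__(self) -> None:
        for ind, reps in self.replicates.items():
            if not reps:
                raise ValueError(f"individual {ind!r} has zero replicates")
            for sample_id, grid in reps:
                grid = _as_sorted_pairs(grid[None])[0]
                if grid.shape != (len(self.loci), 2):
                    raise ValueError(
                        f"replicate {sample_id!r} does not match the locus panel")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReplicateSet":
        """Build from long format: sample_id, individual_id, locus, allele1, allele2."""
        loci = list(dict.fromkeys(frame["locus"].astype(str)))
        loc_ix = {l: k for k, l in enumerate(loci)}
        reps: dict[str, list[tuple[str, np.ndarray]]] = {}
        for (ind, sample), sub in frame.groupby(["individual_id", "sample_id"], sort=False):
            grid = np.zeros((len(loci), 2), dtype=np.int64)
            for row in sub.itertuples(index=False):
                grid[loc_ix[str(row.locus)]] = (int(row.allele1), int(row.allele2))
            reps.setdefault(str(ind), []).append((str(sample), grid))
        return cls(loci, reps)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for ind, reps in self.replicates.items():
            for sample_id, grid in reps:
                for l, locus in enumerate(self.loci):
                    records.append((sample_id, ind, locus,
                                    int(grid[l, 0]), int(grid[l, 1])))
        return pd.DataFrame(records, columns=[
            "sample_id", "individual_id", "locus", "allele1", "allele2"])


@dataclass(frozen=True)
class ConsensusRules:
    """Consensus calling knobs.

    ``min_homozygote_replicates`` follows the multi-tubes tradition: a
    homozygote is accepted only when the sole observed allele recurs in at
    least this many replicates (a single observation could be a dropped-out
    heterozygote).
    """

    min_homozygote_replicates: int = 2


# per-locus consensus flags
CONFIRMED = "confirmed"
DROPOUT_RESOLVED = "dropout_resolved"
CONFLICT = "conflict"
MISSING_FLAG = "missing"

REASON_TOO_FEW_LOCI = "failed_min_loci"
REASON_CONFLICT = "unexplained_mismatch"


@dataclass
class ConsensusResult:
    individual: str
    genotype: np.ndarray  # (L, 2)
    flags: list[str]      # per locus
    loci_typed: int
    needs_regenotyping: bool = False
    reasons: list[str] = field(default_factory=list)


def _consensus_locus(calls: list[tuple[int, int]],
                     rules: ConsensusRules) -> tuple[tuple[int, int], str]:
    """Consensus for one locus given non-missing replicate calls."""
    if not calls:
        return (MISSING, MISSING), MISSING_FLAG
    alleles = sorted({a for call in calls for a in call})
    if len(alleles) >= 3:
        # includes the disjoint-heterozygote case
        return (MISSING, MISSING), CONFLICT
    if len(alleles) == 2:
        a, b = alleles
        # both alleles observed; every call is {a,b}, {a,a} or {b,b} by
        # construction, i.e. jointly consistent under dropout
        if all(set(call) == {a, b} for call in calls):
            return (a, b), CONFIRMED
        return (a, b), DROPOUT_RESOLVED
    a = alleles[0]
    if len(calls) >= rules.min_homozygote_replicates:
        return (a, a), CONFIRMED
    return (MISSING, MISSING), MISSING_FLAG


def call_consensus(reps: ReplicateSet,
                   rules: ConsensusRules = ConsensusRules()) -> list[ConsensusResult]:
    """Combine replicate genotypes into per-individual consensus genotypes.

    Heterozygote (a, b): both alleles observed across replicates and every
    replicate consistent under dropout.  Homozygote (a, a): sole observed
    allele seen in >= ``min_homozygote_replicates`` replicates.  Three or more
    distinct alleles at a locus is an unexplained conflict -> missing.
    """
    if not reps.replicates:
        raise ValueError("empty ReplicateSet")
    results = []
    L = len(reps.loci)
    for ind, rep_list in reps.replicates.items():
        genotype = np.zeros((L, 2), dtype=np.int64)
        flags = []
        for l in range(L):
            calls = [(int(g[l, 0]), int(g[l, 1]))
                     for _, g in rep_list if g[l, 0] != MISSING]
            call, flag = _consensus_locus(calls, rules)
            genotype[l] = call
            flags.append(flag)
        loci_typed = int((genotype[:, 0] != MISSING).sum())
        results.append(ConsensusResult(ind, genotype, flags, loci_typed))
    return results


def consensus_matrix(results: Iterable[ConsensusResult], loci: Sequence[str],
                     groups: Mapping[str, str] | None = None) -> GenotypeMatrix:
    results = list(results)
    ids = [r.individual for r in results]
    alleles = np.stack([r.genotype for r in results])
    grp = {i: groups[i] for i in ids if i in groups} if groups else None
    return GenotypeMatrix(ids, list(loci), alleles, grp)


def flag_regenotyping(results: Iterable[ConsensusResult],
                      min_loci: int = 10) -> dict[str, list[str]]:
    """Flag individuals needing further replicates.

    Rule (i): fewer than ``min_loci`` loci typed; rule (ii): any locus with an
    unexplained replicate mismatch (conflict).  Mutates ``needs_regenotyping``
    on the results and returns flagged id -> reasons.
    """
    flagged: dict[str, list[str]] = {}
    for res in results:
        reasons = []
        if res.loci_typed < min_loci:
            reasons.append(REASON_TOO_FEW_LOCI)
        if CONFLICT in res.flags:
            reasons.append(REASON_CONFLICT)
        res.needs_regenotyping = bool(reasons)
        res.reasons = reasons
        if reasons:
            flagged[res.individual] = reasons
    return flagged


def filter_min_loci(matrix: GenotypeMatrix, min_loci: int = 7) -> GenotypeMatrix:
    """Drop individuals typed at fewer than ``min_loci`` loci (order kept)."""
    keep = [i for i, n in zip(matrix.ids, matrix.n_typed()) if n >= min_loci]
    if not keep:
        raise ValueError(f"no individuals typed at >= {min_loci} loci")
    return matrix.subset(keep)
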