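"""End-to-end pipeline: simulate -> consensus -> filter -> diagnostics ->
F-stats -> relatedness -> parentage -> clustering -> report.

Plain directory-of-CSV/JSON artifacts, no workflow engine.  One master seed
drives every stage; a rerun with the same config produces an identical
report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .genotypes import (ConsensusRules, call_consensus, consensus_matrix,
                        filter_min_loci, flag_regenotyping, write_genotypes)
from .locus_stats import allele_frequencies, locus_summary, probability_of_identity
from .fstats import fstat_permutation
from .relatedness import (breeder_permutation_test, class_relatedness,
                          qg_relatedness)
from .parentage import (ConfidenceSimParams, assign_parentage,
                        candidates_from_simulation, lod_table,
                        simulate_confidence, skew_summary)
from .clustering import fit_admixture, select_k
from .simdata import SimConfig, simulate_population, simulate_replicates, write_population

log = logging.getLogger("kinskew")

REPORT_KEYS = {"version", "seed", "stages", "inputs_hash"}


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    min_loci: int = 7
    regenotype_min_loci: int = 10
    error_rate: float = 0.01
    n_fstat_perms: int = 199
    n_breeder_perms: int = 1000
    confidence_cycles: int = 2000
    cluster_ks: tuple[int, ...] = ()
    cluster_runs: int = 2
    cluster_burn_in: int = 300
    cluster_iters: int = 300
    stages: tuple[str, ...] = ("simulate", "consensus", "locus_stats",
                               "fstats", "relatedness", "parentage", "clustering")


def validate_report(report: dict) -> None:
    """Light structural check of the report schema."""
    missing = REPORT_KEYS - set(report)
    if missing:
        raise ValueError(f"report missing keys: {sorted(missing)}")
    for stage, payload in report["stages"].items():
        if not isinstance(payload, dict):
            raise ValueError(f"stage {stage} payload is not a mapping")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    cfg_blob = json.dumps(asdict(config.sim), sort_keys=True).encode()
    report["inputs_hash"] = hashlib.sha256(cfg_blob).hexdigest()[:16]

    sim_cfg = SimConfig(**{**asdict(config.sim), "seed": config.seed})
    t0 = time.time()
    pop = simulate_population(sim_cfg)
    reps = simulate_replicates(pop, sim_cfg)
    if "simulate" in config.stages:
        write_population(pop, outdir, reps)
        report["stages"]["simulate"] = {
            "n_individuals": pop.true_genotypes.n_individuals,
            "n_groups": sim_cfg.n_groups,
            "n_switch_events": len(pop.switch_events),
        }
    log.info("simulate: %.1fs", time.time() - t0)

    results = call_consensus(reps, ConsensusRules())
    flagged = flag_regenotyping(results, config.regenotype_min_loci)
    matrix = consensus_matrix(results, reps.loci, pop.true_genotypes.groups)
    filtered = filter_min_loci(matrix, config.min_loci)
    if "consensus" in config.stages:
        write_genotypes(filtered, outdir / "consensus_genotypes.csv")
        report["stages"]["consensus"] = {
            "n_individuals": matrix.n_individuals,
            "n_after_filter": filtered.n_individuals,
            "n_flagged_for_regenotyping": len(flagged),
        }

    freqs = allele_frequencies(filtered)
    if "locus_stats" in config.stages:
        summary = locus_summary(filtered, freqs)
        summary.to_csv(outdir / "locus_summary.csv", index=False)
        pid = probability_of_identity(freqs)
        report["stages"]["locus_stats"] = {
            "mean_He": float(summary["He"].mean()),
            "mean_PIC": float(summary["PIC"].mean()),
            "panel_PI": pid.panel,
        }

    if "fstats" in config.stages:
        fres = fstat_permutation(filtered, n_perm=config.n_fstat_perms,
                                 seed=config.seed)
        report["stages"]["fstats"] = {**fres.overall,
                                      "p_values": fres.p_values,
                                      "n_permutations": fres.n_permutations}

    rel = None
    if "relatedness" in config.stages or "parentage" in config.stages:
        rel = qg_relatedness(filtered, freqs)
    if "relatedness" in config.stages:
        meta = pop.metadata().rename(columns={"id": "id"})
        meta = meta[meta["id"].isin(filtered.ids)]
        classes = class_relatedness(rel, meta, pop.litters)
        classes.to_csv(outdir / "class_relatedness.csv", index=False)
        rel.to_frame().to_csv(outdir / "relatedness_matrix.csv")
        btest = breeder_permutation_test(rel, meta, n=config.n_breeder_perms,
                                         seed=config.seed)
        report["stages"]["relatedness"] = {
            "breeder_observed": btest.observed,
            "breeder_p": btest.p_value,
            "classes": {c: (None if np.isnan(v) else float(v))
                        for c, v in zip(classes["class"], classes["mean_r"])},
        }

    if "parentage" in config.stages:
        genotyped = set(filtered.ids)
        cands = [c for c in candidates_from_simulation(pop, genotyped)
                 if c.pup in genotyped]
        thresholds = simulate_confidence(
            freqs, ConfidenceSimParams(error_rate=max(config.error_rate, 0.01)),
            n_cycles=config.confidence_cycles, seed=config.seed)
        tables = [lod_table(filtered, c, freqs, config.error_rate) for c in cands]
        assignments = assign_parentage(tables, thresholds)
        roles = {}
        for ind in pop.individuals:
            roles[ind.id] = "dominant" if ind.role == "dominant" else "subordinate"
        skew = skew_summary(assignments, roles, pop.litters)
        with open(outdir / "parentage_thresholds.json", "w") as fh:
            json.dump({"strict": thresholds.strict, "relaxed": thresholds.relaxed},
                      fh, indent=2)
        report["stages"]["parentage"] = {
            "n_pups": len(assignments),
            "skew": skew,
            "thresholds": {"strict": thresholds.strict,
                           "relaxed": thresholds.relaxed},
        }

    if "clustering" in config.stages and config.cluster_ks:
        runs = []
        for k in config.cluster_ks:
            for r in range(config.cluster_runs):
                runs.append(fit_admixture(
                    filtered, k, burn_in=config.cluster_burn_in,
                    iters=config.cluster_iters,
                    seed=int(np.random.default_rng([config.seed, k, r]).integers(2**31))))
        sel = select_k(runs)
        sel.evanno.to_csv(outdir / "evanno.csv", index=False)
        report["stages"]["clustering"] = {
            "best_by_lnpd": sel.best_by_lnpd,
            "best_by_delta_k": sel.best_by_delta_k,
        }

    validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
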