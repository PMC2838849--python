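"""End-to-end pipelines: headline reproduction and simulate-and-recover.

``run_reproduce`` recomputes every headline quantity of the screening study
from its printed scalar inputs (no randomness on this path); ``run_simulate_
and_recover`` generates a synthetic screen, clusters it, estimates the class
count and reports truth vs estimate — the closed-loop validation of the
whole stack.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass

from . import study
from .genotyping import GenotypeTable, cluster_genotypes, count_distinct
from .librarystats import (
    LibraryParams,
    coverage,
    enrichment_ratio,
    max_haplotypes_per_locus,
    min_loci_from_estimate,
    min_loci_from_observed,
)
from .richness import ObservedRichness, estimate_richness
from .synthetic import simulate_screen

__all__ = ["PipelineConfig", "run_reproduce", "run_simulate_and_recover"]


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable knobs of the simulate-and-recover loop."""

    seed: int = 0
    theta: int = 1240
    n_clones: int = 342
    jitter_prob: float = 0.0
    tolerance: int = 1
    linkage: str = "strict"
    alpha: float = 0.05
    min_separation: int = 3
    size_range: tuple[int, int] = (80, 400)


def run_reproduce(alphas: tuple[float, ...] = (0.05, 0.10)) -> dict:
    """Recompute the study's headline numbers from its printed inputs."""
    t0 = time.perf_counter()
    obs = ObservedRichness(n=study.N_CLONES_GENOTYPED, k=study.K_DISTINCT_GENOTYPES)
    richness = {}
    for alpha in alphas:
        est = estimate_richness(obs, alpha=alpha)
        richness[f"ci_{100 * (1 - alpha):.0f}"] = [est.ci_low, est.ci_high]
    est = estimate_richness(obs, alpha=alphas[0])
    lib = study.LIBRARY
    fold_full, total_full = coverage(lib)
    sub = LibraryParams(
        n_clones=study.N_CLONES_GENOTYPING_SUBSET,
        mean_insert_kb=lib.mean_insert_kb,
        genome_size_mbp=lib.genome_size_mbp,
        n_individuals=lib.n_individuals,
    )
    fold_sub, _ = coverage(sub)
    from .librarystats import _round_half_up

    report = {
        "inputs": {
            "n_clones_genotyped": obs.n,
            "k_distinct_genotypes": obs.k,
            "library": asdict(lib),
            "n_clones_genotyping_subset": study.N_CLONES_GENOTYPING_SUBSET,
            "hybridization": {"positive": study.HYB_POSITIVE, "total": study.HYB_TOTAL},
            "ggtta_rates_percent": [study.GGTTA_RATE_FMR_POSITIVE, study.GGTTA_RATE_ALL],
        },
        "richness": {
            "theta_hat": est.theta_hat,
            **richness,
            "alpha_levels": list(alphas),
        },
        "loci": {
            "max_haplotypes_per_locus": max_haplotypes_per_locus(lib.n_individuals),
            "min_loci_from_observed": min_loci_from_observed(obs.k, lib.n_individuals),
            "min_loci_from_estimate": min_loci_from_estimate(est.theta_hat, lib.n_individuals),
        },
        "library": {
            "coverage_fold": fold_full,
            "total_insert_mbp": total_full,
            "genotyping_subset_coverage_fold": fold_sub,
        },
        "redundancy": {
            "positive_percent": _round_half_up(
                100.0 * study.HYB_POSITIVE / study.HYB_TOTAL, 1
            ),
        },
        "ggtta_enrichment_fold": enrichment_ratio(
            study.GGTTA_RATE_FMR_POSITIVE, study.GGTTA_RATE_ALL
        ),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    return report


def run_simulate_and_recover(config: PipelineConfig) -> dict:
    """Synthetic screen -> clustering -> richness estimate, truth vs estimate."""
    t0 = time.perf_counter()
    truth, screen = simulate_screen(
        theta=config.theta,
        n_clones=config.n_clones,
        jitter_prob=config.jitter_prob,
        size_range=config.size_range,
        min_separation=config.min_separation,
        seed=config.seed,
    )
    table = GenotypeTable.from_dataframe(screen.table)
    assignment = cluster_genotypes(table, tolerance=config.tolerance, linkage=config.linkage)
    obs = count_distinct(assignment)
    est = estimate_richness(obs, alpha=config.alpha)
    contained = (
        not est.unbounded
        and est.ci_low <= config.theta <= est.ci_high
    )
    return {
        "config": asdict(config),
        "true_theta": config.theta,
        "true_distinct_sampled": int(screen.n_true_distinct()),
        "observed": {"N": obs.n, "K": obs.k},
        "estimate": {
            "theta_hat": est.theta_hat,
            "ci": [est.ci_low, est.ci_high],
            "alpha": est.alpha,
            "unbounded": est.unbounded,
        },
        "ci_contains_truth": bool(contained),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
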