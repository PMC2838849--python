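"""Library-level screening statistics.

Coverage arithmetic for the BAC library, probe-hybridization pattern
grouping over the 120-kb reference segment, minimum chromosomal-locus bounds
implied by genotype richness, and the telomeric-repeat enrichment ratio.

Three probes tile the reference in order: F (5'-end), M (middle), R
(3'-end).  A contiguous clone insert overlapping the ordered probes can only
produce the six patterns F, F+M, M, F+M+R, M+R, R; a clone hitting F and R
but not M is physically impossible for a contiguous insert and is labelled
``anomalous``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from collections.abc import Iterable, Sequence

__all__ = [
    "LibraryParams",
    "HybridizationRecord",
    "PROBE_ORDER",
    "DEFAULT_PROBES",
    "classify_pattern",
    "group_from_hits",
    "group_patterns",
    "coverage",
    "max_haplotypes_per_locus",
    "min_loci_from_observed",
    "min_loci_from_estimate",
    "enrichment_ratio",
]

PROBE_ORDER = ("F", "M", "R")
# probe intervals (bp, 0-based half-open) on the 120-kb reference; the exact
# physical positions are configurable — only the F < M < R order matters
DEFAULT_PROBES = {"F": (0, 2_000), "M": (59_000, 61_000), "R": (118_000, 120_000)}

GROUPS = ("F", "F+M", "M", "F+M+R", "M+R", "R")


def _round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 52.45 -> 52.5), not banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LibraryParams:
    """Scalar description of a BAC library and its source animals."""

    n_clones: int
    mean_insert_kb: float
    genome_size_mbp: float
    n_individuals: int

    def __post_init__(self) -> None:
        for name in ("n_clones", "mean_insert_kb", "genome_size_mbp", "n_individuals"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class HybridizationRecord:
    """Which of the ordered probes F, M, R a clone hybridizes to."""

    clone_id: str
    hits: frozenset[str]
    group: str


def classify_pattern(
    interval: tuple[int, int],
    probes: dict[str, tuple[int, int]] | None = None,
    clone_id: str = "",
) -> HybridizationRecord:
    """Group a clone by which probe intervals its insert overlaps (half-open)."""
    probes = DEFAULT_PROBES if probes is None else probes
    if set(probes) != set(PROBE_ORDER):
        raise ValueError(f"probes must be exactly {PROBE_ORDER}")
    spans = [probes[p] for p in PROBE_ORDER]
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if not (a0 < a1 and a1 <= b0 and b0 < b1):
            raise ValueError("probe intervals must be ordered and non-overlapping")
    s, e = interval
    if e <= s:
        raise ValueError(f"empty clone interval {interval}")
    hits = frozenset(p for p in PROBE_ORDER if s < probes[p][1] and probes[p][0] < e)
    return HybridizationRecord(clone_id=clone_id, hits=hits, group=group_from_hits(hits))


def group_from_hits(hits: frozenset[str] | set[str]) -> str:
    """Group label for a probe-hit set; F+R without M violates contiguity."""
    if not set(hits) <= set(PROBE_ORDER):
        raise ValueError(f"unknown probes in {hits!r}")
    if not hits:
        return "negative"
    if set(hits) == {"F", "R"}:
        return "anomalous"  # contiguity violated: M lies between F and R
    return "+".join(p for p in PROBE_ORDER if p in hits)


def group_patterns(records: Iterable[HybridizationRecord]) -> dict:
    """Counts per hybridization group and the positive fraction.

    Positive fraction = clones in the six contiguous groups (not negative,
    not anomalous) / all clones screened, as a percentage rounded half-up to
    one decimal.
    """
    records = list(records)
    if not records:
        raise ValueError("no hybridization records")
    counts = {g: 0 for g in (*GROUPS, "negative", "anomalous")}
    for r in records:
        counts[r.group] += 1
    positives = sum(counts[g] for g in GROUPS)
    return {
        "counts": counts,
        "n_total": len(records),
        "n_positive": positives,
        "positive_percent": _round_half_up(100.0 * positives / len(records), 1),
    }


def coverage(params: LibraryParams) -> tuple[float, float]:
    """(fold coverage rounded to one decimal, total insert size in Mbp)."""
    total_mbp = params.n_clones * params.mean_insert_kb / 1000.0
    fold = _round_half_up(total_mbp / params.genome_size_mbp, 1)
    return fold, total_mbp


def max_haplotypes_per_locus(n_individuals: int) -> int:
    """Diploid bound: one locus can show at most 2 haplotypes per animal."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    return 2 * n_individuals


def min_loci_from_observed(k: int, n_individuals: int) -> int:
    """Floor of K / (2 * individuals), min 1: loci certainly present given K.

    Uses the floor convention: K observed genotypes could be explained by
    this many fully haplotype-saturated loci.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    return max(1, k // max_haplotypes_per_locus(n_individuals))


def min_loci_from_estimate(theta_hat: int, n_individuals: int) -> int:
    """Ceiling of theta_hat / (2 * individuals): loci needed to carry theta_hat.

    Uses the ceiling convention: the estimated total genotype count cannot
    fit into fewer loci than this.
    """
    if theta_hat < 1:
        raise ValueError("theta_hat must be >= 1")
    return math.ceil(theta_hat / max_haplotypes_per_locus(n_individuals))


def enrichment_ratio(rate_subset: float, rate_background: float) -> float:
    """Fold enrichment of a positive rate in a subset over the background."""
    for r in (rate_subset, rate_background):
        if not 0 < r <= 100:
            raise ValueError("rates must be percentages in (0, 100]")
    return rate_subset / rate_background


def classify_intervals(
    intervals: Sequence[tuple[int, int]],
    probes: dict[str, tuple[int, int]] | None = None,
    clone_ids: Sequence[str] | None = None,
) -> list[HybridizationRecord]:
    """Vector convenience: classify many clone intervals at once."""
    ids = clone_ids if clone_ids is not None else [f"C{i + 1:05d}" for i in range(len(intervals))]
    return [classify_pattern(tuple(iv), probes, clone_id=c) for iv, c in zip(intervals, ids)]
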