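"""Synthetic screen generator.

Emulates the statistical structure the downstream analysis assumes: ``theta``
equally abundant genotype classes, clones sampled uniformly with replacement,
+/-1 bp allele-sizing error, contiguous clone intervals on a 120-kb reference
segment, and qPCR Ct values on a log-linear standard curve with Gaussian
noise.  Every generator takes an explicit integer seed and is byte-stable:
the same seed and parameters always give the same tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .copynumber import StandardCurve

__all__ = [
    "TrueGenotypeSet",
    "SimulatedScreen",
    "PackingError",
    "simulate_genotype_classes",
    "simulate_bac_sampling",
    "simulate_clone_intervals",
    "simulate_qpcr",
    "simulate_screen",
]

DEFAULT_MARKERS = ("MS02", "MS33", "MS64")
DEFAULT_REFERENCE_LENGTH = 120_000  # bp, the sequenced reference segment


class PackingError(ValueError):
    """theta classes cannot be placed in size_range at min_separation."""


@dataclass(frozen=True)
class TrueGenotypeSet:
    """theta ground-truth genotype classes, one integer size per marker each.

    Classes are pairwise separated by at least ``min_separation`` bp at at
    least one marker, so +/-1 bp jitter plus tolerance-1 clustering can never
    merge two distinct truths.
    """

    genotype_ids: np.ndarray  # (theta,), dense integers 1..theta
    allele_sizes: np.ndarray  # (theta, n_markers), bp
    markers: tuple[str, ...] = DEFAULT_MARKERS

    @property
    def theta(self) -> int:
        return len(self.genotype_ids)

    def min_pairwise_separation(self) -> int:
        """Minimum over class pairs of the max per-marker size difference."""
        if self.theta < 2:
            return np.iinfo(np.int64).max
        best = np.iinfo(np.int64).max
        sizes = self.allele_sizes
        for i in range(self.theta - 1):
            d = np.abs(sizes[i + 1 :] - sizes[i]).max(axis=1).min()
            best = min(best, int(d))
        return best


@dataclass(frozen=True)
class SimulatedScreen:
    """One synthetic screen: clones with true class, observed sizes, interval."""

    table: pd.DataFrame  # clone_id, <markers...>, true_genotype, start, end
    markers: tuple[str, ...]
    reference_length: int
    seed: int

    @property
    def n_clones(self) -> int:
        return len(self.table)

    def n_true_distinct(self) -> int:
        return self.table["true_genotype"].nunique()

    def to_tsv(self, path: str | Path) -> None:
        cols = ["clone_id", *self.markers, "true_genotype", "start", "end"]
        self.table[cols].to_csv(path, sep="\t", index=False)


def simulate_genotype_classes(
    theta: int,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
    size_range: tuple[int, int] = (80, 400),
    min_separation: int = 3,
    seed: int = 0,
) -> TrueGenotypeSet:
    """Draw theta pairwise-separated genotype classes uniformly in size_range.

    Rejection sampling: a candidate size tuple is kept only if its Chebyshev
    distance to every accepted class is at least ``min_separation``.  Raises
    :class:`PackingError` when the range cannot hold theta such classes.
    """
    if theta < 1:
        raise ValueError("theta must be >= 1")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    lo, hi = size_range
    if hi <= lo:
        raise ValueError("size_range must be a non-empty interval")
    m = len(markers)
    # disjoint min_separation-cells bound the number of placeable classes
    cells = math.ceil((hi - lo + 1) / min_separation) ** m
    if theta > cells:
        raise PackingError(
            f"cannot place {theta} classes at separation {min_separation} in {size_range}"
        )
    rng = np.random.default_rng(seed)
    accepted = np.empty((theta, m), dtype=np.int64)
    count = 0
    attempts = 0
    max_attempts = 2000 * theta + 10_000
    while count < theta:
        if attempts >= max_attempts:
            raise PackingError(
                f"failed to place {theta} classes after {attempts} attempts; "
                f"size_range {size_range} too tight for separation {min_separation}"
            )
        cand = rng.integers(lo, hi + 1, size=m)
        attempts += 1
        if count == 0 or np.abs(accepted[:count] - cand).max(axis=1).min() >= min_separation:
            accepted[count] = cand
            count += 1
    return TrueGenotypeSet(
        genotype_ids=np.arange(1, theta + 1),
        allele_sizes=accepted,
        markers=tuple(markers),
    )


def simulate_bac_sampling(
    truth: TrueGenotypeSet,
    n_clones: int,
    jitter_prob: float = 0.0,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sample clones uniformly with replacement from the truth, with sizing error.

    Each observed marker size is shifted by +/-1 bp (equiprobable sign) with
    probability ``jitter_prob``, independently per marker.  ``weights`` opts in
    to unequal class abundances — a deliberate misspecification of the
    equal-abundance model, for stress tests only.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if not 0.0 <= jitter_prob <= 1.0:
        raise ValueError("jitter_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if weights is None:
        idx = rng.integers(0, truth.theta, size=n_clones)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (truth.theta,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be theta non-negative numbers with positive sum")
        idx = rng.choice(truth.theta, size=n_clones, p=w / w.sum())
    observed = truth.allele_sizes[idx].copy()
    if jitter_prob > 0:
        hit = rng.random(observed.shape) < jitter_prob
        sign = rng.choice(np.array([-1, 1]), size=observed.shape)
        observed += hit * sign
    df = pd.DataFrame(observed, columns=list(truth.markers))
    df.insert(0, "clone_id", [f"C{i + 1:05d}" for i in range(n_clones)])
    df["true_genotype"] = truth.genotype_ids[idx]
    return df


def simulate_clone_intervals(
    n_clones: int,
    reference_length: int = DEFAULT_REFERENCE_LENGTH,
    insert_mean: float = 135_000.0,
    insert_sd: float = 13_500.0,
    seed: int = 0,
) -> np.ndarray:
    """Contiguous clone intervals on the reference, 0-based half-open.

    Insert lengths are truncated-normal (never below 1 bp); an insert longer
    than the reference is clipped to the whole reference.  Returns an
    ``(n_clones, 2)`` integer array of (start, end).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if reference_length < 1:
        raise ValueError("reference_length must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.round(rng.normal(insert_mean, insert_sd, size=n_clones)).astype(np.int64)
    lengths = np.clip(lengths, 1, reference_length)
    starts = rng.integers(0, reference_length - lengths + 1)
    return np.column_stack([starts, starts + lengths])


def simulate_qpcr(
    true_ratio: float,
    reference_copies: float,
    curve: StandardCurve,
    sigma_ct: float = 0.1,
    reps: int = 3,
    seed: int = 0,
    sample: str = "S1",
) -> pd.DataFrame:
    """Replicate Ct values for a target/reference gene pair at a known copy ratio.

    Ct = curve(copies) + N(0, sigma_ct); target copies = true_ratio *
    reference_copies.  Returns the long-format table sample,gene,replicate,ct.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if sigma_ct < 0:
        raise ValueError("sigma_ct must be >= 0")
    if reference_copies <= 0 or true_ratio <= 0:
        raise ValueError("copy numbers must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for gene, copies in (("target", true_ratio * reference_copies),
                         ("reference", reference_copies)):
        ct_true = curve.predict_ct(copies)
        for r in range(1, reps + 1):
            rows.append((sample, gene, r, ct_true + rng.normal(0.0, sigma_ct) if sigma_ct > 0 else ct_true))
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])


def simulate_screen(
    theta: int,
    n_clones: int,
    jitter_prob: float = 0.0,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
    size_range: tuple[int, int] = (80, 400),
    min_separation: int = 3,
    reference_length: int = DEFAULT_REFERENCE_LENGTH,
    insert_mean: float = 135_000.0,
    insert_sd: float = 13_500.0,
    seed: int = 0,
) -> tuple[TrueGenotypeSet, SimulatedScreen]:
    """Compose a full synthetic screen from one master seed.

    Per-stage substreams are spawned from the master seed so stages stay
    independently reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_truth, s_sample, s_iv = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    truth = simulate_genotype_classes(theta, markers, size_range, min_separation, seed=s_truth)
    table = simulate_bac_sampling(truth, n_clones, jitter_prob, seed=s_sample)
    iv = simulate_clone_intervals(n_clones, reference_length, insert_mean, insert_sd, seed=s_iv)
    table = table.assign(start=iv[:, 0], end=iv[:, 1])
    screen = SimulatedScreen(
        table=table, markers=tuple(markers), reference_length=reference_length, seed=seed
    )
    return truth, screen
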