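"""Collapse per-clone microsatellite fragment sizes into genotype classes.

Each BAC clone carries one haploid genomic fragment, scored as one integer
fragment size (bp) per microsatellite marker.  Two clones represent the same
genotype when their sizes agree at every marker up to a sizing tolerance
(default 1 bp, the allowance for electrophoretic sizing error).  Because the
1-bp rule is pairwise, chains such as 100/101/102 are ambiguous; two linkage
modes are provided:

``strict``
    Classes are anchored to a representative (the per-marker modal size of
    current members, ties toward the smallest size) and a clone joins a class
    only if it is within tolerance of the representative at every marker.
    Clones are processed in a canonical order (sorted by size tuple then
    clone id) so the partition does not depend on input order.

``single``
    Single-linkage: the pairwise rule is extended transitively, i.e. the
    connected components of the within-tolerance graph.

On well-separated genotypes (minimum inter-class Chebyshev distance of at
least ``2 * tolerance + 1``) the two modes agree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .richness import ObservedRichness

__all__ = ["GenotypeTable", "GenotypeAssignment", "cluster_genotypes", "count_distinct"]

DEFAULT_MARKERS = ("MS02", "MS33", "MS64")


@dataclass(frozen=True)
class GenotypeTable:
    """Per-clone fragment sizes: one row per clone, one column per marker."""

    clone_ids: tuple[str, ...]
    sizes: np.ndarray  # (n_clones, n_markers), positive integers
    markers: tuple[str, ...] = DEFAULT_MARKERS
    excluded: tuple[str, ...] = ()  # clones dropped for missing markers

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes)
        if sizes.ndim != 2 or sizes.shape != (len(self.clone_ids), len(self.markers)):
            raise ValueError("sizes must be (n_clones, n_markers)")
        if not np.issubdtype(sizes.dtype, np.integer):
            raise TypeError("fragment sizes must be integers (bp)")
        if len(self.clone_ids) and (sizes <= 0).any():
            raise ValueError("fragment sizes must be positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, markers: tuple[str, ...] = DEFAULT_MARKERS,
                       clone_col: str = "clone_id") -> "GenotypeTable":
        """Build a table from a DataFrame; clones missing any marker are excluded."""
        missing = [m for m in markers if m not in df.columns]
        if missing:
            raise ValueError(f"marker columns absent from table: {missing}")
        ok = df[list(markers)].notna().all(axis=1)
        excluded = tuple(df.loc[~ok, clone_col].astype(str))
        kept = df.loc[ok]
        sizes = kept[list(markers)].to_numpy()
        if not np.allclose(sizes, np.round(sizes)):
            raise TypeError("fragment sizes must be integers (bp)")
        return cls(
            clone_ids=tuple(kept[clone_col].astype(str)),
            sizes=sizes.astype(np.int64),
            markers=tuple(markers),
            excluded=excluded,
        )

    @classmethod
    def from_tsv(cls, path: str | Path, markers: tuple[str, ...] = DEFAULT_MARKERS) -> "GenotypeTable":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"), markers=markers)


@dataclass(frozen=True)
class GenotypeAssignment:
    """Total assignment of non-excluded clones to dense class labels 1..K."""

    labels: dict[str, int]
    k: int
    n: int
    excluded: tuple[str, ...] = ()
    tolerance: int = 1
    linkage: str = "strict"

    def __post_init__(self) -> None:
        if self.k > self.n:
            raise ValueError("K cannot exceed N")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"clone_id": list(self.labels), "genotype_label": list(self.labels.values())}
        )

    def summary(self) -> dict:
        return {"N": self.n, "K": self.k, "excluded": list(self.excluded),
                "tolerance": self.tolerance, "linkage": self.linkage}

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def _strict_labels(sizes: np.ndarray, order: np.ndarray, tolerance: int) -> np.ndarray:
    """Greedy representative clustering in canonical order.

    A class representative is the per-marker mode of its members, ties broken
    toward the smallest size; a clone joins the first class whose
    representative it matches within tolerance at every marker.
    """
    labels = np.empty(len(sizes), dtype=np.int64)
    reps: list[np.ndarray] = []
    members: list[list[np.ndarray]] = []
    for idx in order:
        row = sizes[idx]
        assigned = -1
        for ci, rep in enumerate(reps):
            if np.max(np.abs(row - rep)) <= tolerance:
                assigned = ci
                break
        if assigned < 0:
            reps.append(row.copy())
            members.append([row])
            assigned = len(reps) - 1
        else:
            members[assigned].append(row)
            stack = np.vstack(members[assigned])
            # per-marker mode, smallest value on ties
            rep = np.empty(stack.shape[1], dtype=np.int64)
            for j in range(stack.shape[1]):
                vals, counts = np.unique(stack[:, j], return_counts=True)
                rep[j] = vals[np.argmax(counts)]  # np.unique sorts, so ties -> smallest
            reps[assigned] = rep
        labels[idx] = assigned
    return labels


def cluster_genotypes(table: GenotypeTable, tolerance: int = 1,
                      linkage: str = "strict") -> GenotypeAssignment:
    """Partition clones into genotype classes under the per-marker tolerance rule."""
    if len(table.clone_ids) == 0:
        raise ValueError("empty genotype table")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if linkage not in ("strict", "single"):
        raise ValueError(f"linkage must be 'strict' or 'single', got {linkage!r}")

    sizes = table.sizes
    n = len(table.clone_ids)
    if linkage == "single":
        if n == 1:
            raw = np.zeros(1, dtype=np.int64)
        else:
            dm = squareform(pdist(sizes.astype(float), metric="chebyshev"))
            adj = (dm <= tolerance).astype(np.int8)
            _, raw = connected_components(adj, directed=False)
    else:
        order = np.lexsort(
            (np.asarray(table.clone_ids),) + tuple(sizes[:, j] for j in range(sizes.shape[1] - 1, -1, -1))
        )
        raw = _strict_labels(sizes, order, tolerance)

    # relabel densely 1..K in order of first appearance in the input
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for cid, lab in zip(table.clone_ids, raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[cid] = remap[lab]
    return GenotypeAssignment(
        labels=labels, k=len(remap), n=n, excluded=table.excluded,
        tolerance=tolerance, linkage=linkage,
    )


def count_distinct(assignment: GenotypeAssignment) -> ObservedRichness:
    """Reduce an assignment to the (N, K) pair the richness estimator consumes."""
    return ObservedRichness(n=assignment.n, k=assignment.k)
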