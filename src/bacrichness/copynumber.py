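"""qPCR absolute quantification.

A standard curve Ct = intercept + slope * log10(copies) is fit by least
squares to a plasmid dilution series; sample Cts are inverted through the
curve to absolute copy numbers, and a gene's copy number is expressed
relative to a putative single-copy reference gene (TGase), with mean +/- SD
over the PCR replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = ["StandardCurve", "CopyNumberResult", "fit_standard_curve", "quantify",
           "relative_copy_number"]


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear qPCR calibration: Ct = intercept + slope * log10(copies)."""

    intercept: float  # Ct at 1 copy
    slope: float      # Ct per log10(copies); ~ -3.32 at perfect doubling
    r_squared: float = 1.0
    ct_range: tuple[float, float] | None = None  # Ct span of the fitted series

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, 10^(-1/slope) - 1 (1.0 = doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def predict_ct(self, copies: float) -> float:
        if copies <= 0:
            raise ValueError("copies must be positive")
        return self.intercept + self.slope * math.log10(copies)

    def in_range(self, ct: float) -> bool:
        """Whether a Ct lies inside the fitted dilution series (no extrapolation)."""
        if self.ct_range is None:
            return True
        return self.ct_range[0] <= ct <= self.ct_range[1]


@dataclass(frozen=True)
class CopyNumberResult:
    """Copy number of one gene relative to the reference, over replicates."""

    gene: str
    sample: str
    ratios: tuple[float, ...]  # per-replicate gene/reference copy ratios
    mean: float
    sd: float
    n_replicates: int


def fit_standard_curve(dilution_series: Sequence[tuple[float, float]],
                       efficiency_band: tuple[float, float] = (0.8, 1.1)) -> StandardCurve:
    """Least-squares standard curve from (copies, Ct) dilution points.

    Requires >= 3 distinct dilution points spanning >= 2 log10 units of copy
    number.  Warns if the implied amplification efficiency falls outside
    ``efficiency_band``.
    """
    pts = list(dilution_series)
    copies = np.asarray([c for c, _ in pts], dtype=float)
    cts = np.asarray([t for _, t in pts], dtype=float)
    if (copies <= 0).any():
        raise ValueError("dilution copies must be positive")
    if len(np.unique(copies)) < 3:
        raise ValueError("need >= 3 distinct dilution points")
    logc = np.log10(copies)
    if logc.max() - logc.min() < 2.0:
        raise ValueError("dilution series must span >= 2 log10 units")
    fit = linregress(logc, cts)
    curve = StandardCurve(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue) ** 2,
        ct_range=(float(cts.min()), float(cts.max())),
    )
    lo, hi = efficiency_band
    if not lo <= curve.efficiency <= hi:
        warnings.warn(
            f"amplification efficiency {curve.efficiency:.3f} outside [{lo}, {hi}]",
            stacklevel=2,
        )
    return curve


def quantify(ct: float, curve: StandardCurve) -> float:
    """Invert a Ct through the curve: copies = 10^((ct - intercept)/slope)."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def relative_copy_number(
    gene_cts: Sequence[float],
    ref_cts: Sequence[float],
    gene_curve: StandardCurve,
    ref_curve: StandardCurve,
    gene: str = "target",
    sample: str = "S1",
) -> CopyNumberResult:
    """Per-replicate gene/reference copy ratios, summarised as mean +/- SD.

    Replicates are paired by index (replicate i of the gene against replicate
    i of the reference), matching how repeated experiments are summarised
    with per-experiment ratios and error bars.
    """
    if len(gene_cts) == 0:
        raise ValueError("need at least one replicate")
    if len(gene_cts) != len(ref_cts):
        raise ValueError(
            f"replicate counts differ: {len(gene_cts)} gene vs {len(ref_cts)} reference"
        )
    ratios = tuple(
        quantify(g, gene_curve) / quantify(r, ref_curve) for g, r in zip(gene_cts, ref_cts)
    )
    arr = np.asarray(ratios)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return CopyNumberResult(
        gene=gene, sample=sample, ratios=ratios,
        mean=float(arr.mean()), sd=sd, n_replicates=len(arr),
    )


def relative_copy_numbers_from_table(
    cts: pd.DataFrame,
    curves: dict[str, StandardCurve],
    reference_gene: str = "reference",
) -> pd.DataFrame:
    """Apply :func:`relative_copy_number` per (sample, gene) of a long Ct table.

    ``cts`` has columns sample,gene,replicate,ct; every non-reference gene in
    a sample is ratioed against that sample's reference-gene replicates.
    """
    out = []
    for sample, sub in cts.groupby("sample"):
        ref = sub[sub["gene"] == reference_gene].sort_values("replicate")["ct"].to_numpy()
        if len(ref) == 0:
            raise ValueError(f"sample {sample!r} has no {reference_gene!r} replicates")
        for gene, gsub in sub[sub["gene"] != reference_gene].groupby("gene"):
            g = gsub.sort_values("replicate")["ct"].to_numpy()
            res = relative_copy_number(
                g, ref, curves[gene], curves[reference_gene], gene=gene, sample=str(sample)
            )
            out.append((res.sample, res.gene, res.mean, res.sd, res.n_replicates))
    return pd.DataFrame(out, columns=["sample", "gene", "mean_ratio", "sd", "n_replicates"])
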