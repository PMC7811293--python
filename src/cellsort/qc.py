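"""Quality control and normalization.

Per-cell QC metrics are count depth (total reads), gene count (number of
detected genes) and the mitochondrial read fraction.  Cells are flagged as
low quality when depth or gene count fall below 50% of the cohort median,
or when the mitochondrial fraction exceeds a cutoff placed where a straight
line through two points of the mito-fraction density — at the median and at
the median plus 1.5 population standard deviations — crosses zero density.
The density is a Gaussian KDE with Scott's-rule bandwidth; if the line does
not descend (non-negative slope) or the fractions are degenerate the mito
rule is disabled with a warning.

Normalization rescales each cell to the median pre-scaling count depth and
applies log(1 + x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io import ExpressionMatrix

__all__ = ["QCMetrics", "QCResult", "compute_qc_metrics", "qc_filter", "normalize"]


@dataclass
class QCMetrics:
    """Per-cell QC metrics, one row per cell.

    ``table`` columns: ``count_depth``, ``gene_count``, ``mito_fraction``.
    """

    table: pd.DataFrame

    @property
    def cells(self) -> list[str]:
        return list(self.table.index)


@dataclass
class QCResult:
    """Pass/fail mask with per-rule reasons and the thresholds applied."""

    passed: pd.Series              # bool per cell
    reasons: pd.DataFrame          # bool per (cell, rule)
    thresholds: dict               # rule -> threshold value (mito may be None)


def compute_qc_metrics(matrix: ExpressionMatrix, mito_genes) -> QCMetrics:
    """Compute count depth, gene count and mito fraction per cell.

    Only mitochondrial genes present in ``matrix`` contribute; an empty
    (or fully absent) mito list yields zero fractions with a warning.
    """
    values = matrix.values
    depth = values.sum(axis=0)
    gene_count = (values > 0).sum(axis=0)
    present = [g for g in mito_genes if g in values.index]
    if not present:
        if list(mito_genes):
            warnings.warn("no mitochondrial genes found in the dataset")
        else:
            warnings.warn("empty mitochondrial gene list; mito_fraction set to 0")
        mito_fraction = pd.Series(0.0, index=values.columns)
    else:
        mito = values.loc[present].sum(axis=0)
        with np.errstate(invalid="ignore"):
            mito_fraction = (mito / depth).fillna(0.0)
    return QCMetrics(
        pd.DataFrame(
            {
                "count_depth": depth.astype(float),
                "gene_count": gene_count.astype(int),
                "mito_fraction": mito_fraction.astype(float),
            }
        )
    )


def _mito_cutoff(mito_fraction: np.ndarray, sd_mult: float) -> float | None:
    """X-intercept of the line through the density at median and median+k·sd.

    Returns None (rule disabled) when the fractions are degenerate or the
    line does not descend.
    """
    mf = np.asarray(mito_fraction, dtype=float)
    sd = mf.std()  # population form
    if sd == 0 or np.allclose(mf, mf[0]):
        warnings.warn("mitochondrial fractions are constant; mito rule disabled")
        return None
    med = float(np.median(mf))
    x1, x2 = med, med + sd_mult * sd
    try:
        kde = gaussian_kde(mf)  # Scott's rule bandwidth
    except np.linalg.LinAlgError:
        warnings.warn("degenerate mito-fraction density; mito rule disabled")
        return None
    d1, d2 = float(kde(x1)[0]), float(kde(x2)[0])
    slope = (d2 - d1) / (x2 - x1)
    if slope >= 0:
        warnings.warn("mito-fraction density not descending; mito rule disabled")
        return None
    # line: d(x) = d1 + slope * (x - x1); zero at
    return x1 - d1 / slope


def qc_filter(
    metrics: QCMetrics,
    depth_fraction: float = 0.5,
    gene_fraction: float = 0.5,
    mito_sd_mult: float = 1.5,
) -> QCResult:
    """Flag low-quality cells.

    A cell fails if its count depth or gene count is below the stated
    fraction of the cohort median, or its mito fraction exceeds the
    density-line cutoff (see module docstring).
    """
    t = metrics.table
    if len(t) < 2:
        raise ValueError("qc_filter needs metrics for at least 2 cells")
    depth_thr = depth_fraction * float(np.median(t["count_depth"]))
    gene_thr = gene_fraction * float(np.median(t["gene_count"]))
    mito_thr = _mito_cutoff(t["mito_fraction"].to_numpy(), mito_sd_mult)

    reasons = pd.DataFrame(index=t.index)
    reasons["low_depth"] = t["count_depth"] < depth_thr
    reasons["low_gene_count"] = t["gene_count"] < gene_thr
    if mito_thr is None:
        reasons["high_mito"] = False
    else:
        reasons["high_mito"] = t["mito_fraction"] > mito_thr
    passed = ~reasons.any(axis=1)
    return QCResult(
        passed=passed,
        reasons=reasons,
        thresholds={
            "count_depth": depth_thr,
            "gene_count": gene_thr,
            "mito_fraction": mito_thr,
        },
    )


def normalize(
    matrix: ExpressionMatrix, scale_target: float | None = None
) -> ExpressionMatrix:
    """Median-depth scaling followed by log(1 + x).

    Each cell's counts are rescaled so its total equals ``scale_target``
    (default: the median pre-scaling count depth), then log1p-transformed.
    Cells with zero depth are an error — they should have been removed by QC.
    """
    if matrix.is_lognormalized:
        raise ValueError("matrix is already log-normalized")
    values = matrix.values
    depth = values.sum(axis=0)
    if (depth == 0).any():
        bad = list(depth.index[depth == 0])[:5]
        raise ValueError(f"cells with zero count depth: {bad} (run QC first)")
    target = float(np.median(depth)) if scale_target is None else float(scale_target)
    scaled = values * (target / depth)
    return ExpressionMatrix(np.log1p(scaled), is_lognormalized=True)
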