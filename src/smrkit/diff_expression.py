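"""Case/control differential expression of candidate genes, per brain region.

Third stage of the workflow: for each prioritized gene and each region, fit
expression ~ diagnosis by ordinary least squares on cross-platform-normalized
data. The reported "FC" is the diagnosis coefficient on the normalized scale
(a signed case-minus-control difference, not a ratio), its p-value the
classical two-sided t-test of that coefficient, and q-values are
Benjamini-Hochberg within each region across the genes tested there.

Cross-platform normalization is per-dataset, per-gene z-scoring followed by
concatenation on the shared gene set, which removes dataset-level location
and scale differences before pooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .multiple_testing import bh_fdr

__all__ = ["ExpressionMatrix", "DeResult", "cross_platform_normalize",
           "de_test", "de_table"]


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with per-sample metadata.

    ``values``: DataFrame, index = gene IDs, columns = sample IDs.
    ``metadata``: DataFrame indexed by sample ID with at least columns
    ``diagnosis`` ("case"/"control"), ``region``, and optionally ``dataset``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")
        for col in ("diagnosis", "region"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")

    def region_samples(self, region: str) -> pd.DataFrame:
        meta = self.metadata.loc[list(self.values.columns)]
        return meta[meta["region"] == region]


@dataclass
class DeResult:
    gene: str
    region: str
    fc: float | None          # diagnosis coefficient on the normalized scale
    p: float | None
    fdr: float | None = None
    status: str = "ok"        # "ok" | "insufficient" | "missing_gene"


def cross_platform_normalize(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Z-score each dataset per gene, then concatenate on the gene intersection.

    Genes absent from any dataset are dropped; an empty intersection raises.
    Constant genes within a dataset would produce a zero denominator and are
    z-scored with the convention 0/0 -> 0 after centering.
    """
    if not matrices:
        raise ValueError("no matrices given")
    common = set(matrices[0].values.index)
    for m in matrices[1:]:
        common &= set(m.values.index)
    if not common:
        raise ValueError("empty gene intersection across datasets")
    genes = sorted(common)
    blocks, metas = [], []
    for m in matrices:
        x = m.values.loc[genes].astype(float)
        mu = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1).replace(0.0, np.nan)
        z = x.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
        blocks.append(z)
        metas.append(m.metadata.loc[list(m.values.columns)])
    values = pd.concat(blocks, axis=1)
    metadata = pd.concat(metas, axis=0)
    if values.columns.duplicated().any():
        raise ValueError("duplicate sample IDs across datasets")
    return ExpressionMatrix(values, metadata)


def de_test(matrix: ExpressionMatrix, gene: str, region: str) -> DeResult:
    """OLS of one gene's expression on a case indicator within one region.

    fc is the indicator coefficient (equal to the case-control mean
    difference when there are no covariates), p the two-sided t-test of that
    coefficient. Requires at least 2 cases and 2 controls with residual
    variance; otherwise status is ``insufficient``.
    """
    if gene not in matrix.values.index:
        return DeResult(gene, region, None, None, status="missing_gene")
    meta = matrix.region_samples(region)
    cases = meta[meta["diagnosis"] == "case"].index
    controls = meta[meta["diagnosis"] == "control"].index
    if len(cases) < 2 or len(controls) < 2:
        return DeResult(gene, region, None, None, status="insufficient")
    samples = list(cases) + list(controls)
    y = matrix.values.loc[gene, samples].to_numpy(dtype=float)
    x = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    fc = float(fit.params[1])
    p = float(fit.pvalues[1])
    if math.isnan(p):  # zero residual variance
        return DeResult(gene, region, fc, None, status="insufficient")
    return DeResult(gene, region, fc, p)


def de_table(matrix: ExpressionMatrix, genes: Sequence[str],
             regions: Sequence[str]) -> list[DeResult]:
    """DE across a gene x region grid, BH-corrected within each region.

    Genes absent from the matrix appear as NA rows (status ``missing_gene``)
    and do not enter the FDR family of their region.
    """
    results: list[DeResult] = []
    for region in regions:
        region_results = [de_test(matrix, g, region) for g in genes]
        tested = [r for r in region_results if r.status == "ok"]
        if tested:
            q = bh_fdr([r.p for r in tested])
            for r, qv in zip(tested, q):
                r.fdr = float(qv)
        results.extend(region_results)
    return results


def de_frame(results: Sequence[DeResult]) -> pd.DataFrame:
    """DE results as a DataFrame with gene, region, FC, P, FDR columns."""
    return pd.DataFrame(
        [{"gene": r.gene, "region": r.region, "FC": r.fc, "P": r.p,
          "FDR": r.fdr, "status": r.status} for r in results]
    )
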