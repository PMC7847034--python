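"""Staged multiple-testing rules for the SMR/HEIDI discovery workflow.

Discovery uses a family-wise Bonferroni threshold over all SMR tests pooled
across tissues, a second Bonferroni family over the HEIDI tests actually
performed, and Benjamini-Hochberg FDR for the downstream differential
expression stage. Both SMR and HEIDI comparisons are strict inequalities:
a gene survives with p_SMR < alpha/n_SMR and p_HEIDI > alpha/n_HEIDI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .smr import SmrResult

__all__ = ["ThresholdConfig", "bonferroni_threshold", "apply_smr_heidi_filter",
           "bh_fdr", "count_unique"]


@dataclass(frozen=True)
class ThresholdConfig:
    """Test counts and family-wise level for the staged filters."""

    alpha: float = 0.05
    n_smr_tests: int = 1
    n_heidi_tests: int = 1
    n_replication_snps: int = 1

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha = {self.alpha} outside (0, 1)")
        for name in ("n_smr_tests", "n_heidi_tests", "n_replication_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def smr_threshold(self) -> float:
        return bonferroni_threshold(self.n_smr_tests, self.alpha)

    @property
    def heidi_threshold(self) -> float:
        return bonferroni_threshold(self.n_heidi_tests, self.alpha)


def bonferroni_threshold(n: int, alpha: float = 0.05) -> float:
    """Family-wise p threshold alpha/n for n tests."""
    if n < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / n


def apply_smr_heidi_filter(results: Sequence[SmrResult], thresholds: ThresholdConfig
                           ) -> tuple[list[SmrResult], dict]:
    """Keep rows passing the pooled SMR Bonferroni cut and the HEIDI cut.

    A row survives when p_SMR < alpha/n_SMR_tests (strict) and
    p_HEIDI > alpha/n_HEIDI_tests (strict). Rows without a HEIDI p-value are
    excluded and listed in the report. Returns (survivors, report) where the
    report carries the thresholds and per-tissue survivor counts.
    """
    smr_cut = thresholds.smr_threshold
    heidi_cut = thresholds.heidi_threshold
    survivors: list[SmrResult] = []
    missing_heidi: list[str] = []
    for r in results:
        if not (r.p_smr < smr_cut):
            continue
        if r.p_heidi is None:
            missing_heidi.append(r.gene)
            continue
        if r.p_heidi > heidi_cut:
            survivors.append(r)
    per_tissue: dict[str, int] = {}
    for r in survivors:
        key = r.tissue if r.tissue is not None else "all"
        per_tissue[key] = per_tissue.get(key, 0) + 1
    report = {
        "smr_threshold": smr_cut,
        "heidi_threshold": heidi_cut,
        "n_input": len(results),
        "n_survivors": len(survivors),
        "survivors_per_tissue": per_tissue,
        "excluded_missing_heidi": missing_heidi,
    }
    return survivors, report


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforced.

    q_i = min over j with p_(j) >= p_(i) of p_(j) * n / j on the sorted scale.
    All p must lie in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def count_unique(results: Iterable[SmrResult], field: str) -> int:
    """Distinct SNPs or genes across result rows, tissues pooled."""
    attr = {"snp": "top_snp", "gene": "gene"}.get(field)
    if attr is None:
        raise ValueError(f"field must be 'snp' or 'gene', got {field!r}")
    return len({getattr(r, attr) for r in results})
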