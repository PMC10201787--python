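"""Tissue-specific expression enrichment of peak-associated gene classes.

Genes are called enriched in a target tissue when their FPKM there is at
least ``fold`` times the FPKM in the other tissue (and non-zero); the two
exclusive gene classes are then compared with a Pearson chi-squared test
on the resulting 2x2 table (1 df, no continuity correction by default,
matching the large-sample setting it is used in).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


def fold_enrichment_class(fpkm_target: float, fpkm_other: float, fold: float = 10.0) -> str:
    """'enriched' iff fpkm_target >= fold * fpkm_other and fpkm_target > 0.

    'At least fold-times higher' is read inclusively; a gene expressed in
    the target tissue but silent in the other is enriched, while a gene
    silent in both is not.
    """
    if fpkm_target < 0 or fpkm_other < 0:
        raise ValueError("FPKM must be non-negative")
    return "enriched" if (fpkm_target > 0 and fpkm_target >= fold * fpkm_other) else "not_enriched"


def classify_enrichment(
    expression: pd.DataFrame, target_tissue: str, other_tissue: str, fold: float = 10.0
) -> pd.Series:
    """Boolean enriched-in-target flag per gene."""
    t = expression[target_tissue]
    o = expression[other_tissue]
    if (t < 0).any() or (o < 0).any():
        raise ValueError("FPKM must be non-negative")
    return (t > 0) & (t >= fold * o)


def chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-squared on [[a,b],[c,d]]: n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("zero marginal in 2x2 table")
    return n * (a * d - b * c) ** 2 / denom


@dataclass
class EnrichmentTestResult:
    """2x2 class-by-enrichment table with the chi-squared test and proportions."""

    table: np.ndarray  # rows: class A, class B; cols: enriched, not enriched
    chi2: float
    p_value: float
    proportion_a: float
    proportion_b: float


def class_enrichment_test(
    class_a_genes: Iterable[str],
    class_b_genes: Iterable[str],
    enrichment_labels: Mapping[str, bool] | pd.Series,
    continuity_correction: bool = False,
) -> EnrichmentTestResult:
    """Test whether class A genes are enriched more often than class B genes.

    Builds the 2x2 table of gene class x enrichment status and returns
    Pearson's chi-squared (1 df) with a two-sided p-value and the per-class
    enriched proportions a/(a+b) and c/(c+d).
    """
    labels = pd.Series(enrichment_labels).astype(bool)
    a_genes = list(class_a_genes)
    b_genes = list(class_b_genes)
    if not a_genes or not b_genes:
        raise ValueError("both gene classes must be non-empty")
    a = int(sum(labels.get(g, False) for g in a_genes))
    b = len(a_genes) - a
    c = int(sum(labels.get(g, False) for g in b_genes))
    d = len(b_genes) - c
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    margins = {"enriched column": a + c, "not-enriched column": b + d}
    for name, m in margins.items():
        if m == 0:
            raise ValueError(f"degenerate 2x2 table: {name} sums to zero")
    if continuity_correction:
        n = a + b + c + d
        num = n * max(abs(a * d - b * c) - n / 2, 0) ** 2
        stat = num / ((a + b) * (c + d) * (a + c) * (b + d))
    else:
        stat = chi2_2x2(a, b, c, d)
    p = float(stats.chi2.sf(stat, df=1))
    return EnrichmentTestResult(
        table=table,
        chi2=float(stat),
        p_value=p,
        proportion_a=a / (a + b),
        proportion_b=c / (c + d),
    )
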