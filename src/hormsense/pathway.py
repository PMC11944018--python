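"""DEG filtering, pathway-level Total Weighted Contribution Scores (TWCS),
and microarray-vs-qPCR concordance.

A gene counts as differentially expressed when its linear fold change lies
outside (0.5, 2.0) — strictly — with p < 0.05. The TWCS of a pathway is a
weighted mean of log2 fold changes over its differentially expressed genes,
with direct-effect genes (biosynthetic enzymes / pathway regulators) at
weight 1.0 and indirect-effect genes at weight 0.5:

    TWCS = (1/n) Σ_direct log2(FC_g) · 1.0  +  (1/m) Σ_indirect log2(FC_g) · 0.5

An effect class with no genes contributes 0 (its term is dropped), so
pathways lacking, say, indirect DEGs still receive a finite score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError
from .io_tables import DegTable, PathwayAnnotation, PATHWAYS


@dataclass(frozen=True)
class DegThresholds:
    """DEG filter: keep fold_change < low or > high (strict), with p < alpha."""

    low: float = 0.5
    high: float = 2.0
    alpha: float = 0.05


@dataclass
class TwcsRecord:
    """Weighted contribution score of one pathway in one tissue/dose contrast."""

    pathway: str
    tissue: str
    dose: float
    n_direct: int
    m_indirect: int
    score: float


def filter_degs(table: DegTable, thresholds: DegThresholds = DegThresholds()) -> DegTable:
    """Keep significantly differential genes and annotate their direction.

    Boundary fold changes (exactly ``low`` or ``high``) are excluded; the
    thresholds are strict on both the ratio and the p-value.
    """
    df = table.rows
    fc = df["fold_change"]
    keep = ((fc < thresholds.low) | (fc > thresholds.high)) & (df["p_value"] < thresholds.alpha)
    out = df.loc[keep].copy()
    out["direction"] = np.where(out["fold_change"] > thresholds.high, "up", "down")
    return DegTable(rows=out)


def compute_twcs(
    filtered: DegTable,
    annotation: PathwayAnnotation,
    pathway: str,
    tissue: str | None = None,
    dose: float | None = None,
    w_direct: float = 1.0,
    w_indirect: float = 0.5,
) -> TwcsRecord:
    """TWCS for one pathway, optionally restricted to a tissue/dose contrast.

    A gene annotated to several pathways contributes to each independently;
    an empty effect class drops its term rather than dividing by zero.
    """
    df = filtered.rows
    if tissue is not None:
        df = df[df["tissue"] == tissue]
    if dose is not None:
        df = df[df["dose_mg_L"].astype(float) == float(dose)]
    direct = set(annotation.genes_for(pathway, "direct"))
    indirect = set(annotation.genes_for(pathway, "indirect"))
    log2fc = np.log2(df["fold_change"].to_numpy(dtype=float))
    genes = df["gene_id"].to_numpy()
    d_mask = np.isin(genes, list(direct))
    i_mask = np.isin(genes, list(indirect))
    n, m = int(d_mask.sum()), int(i_mask.sum())
    score = 0.0
    if n:
        score += log2fc[d_mask].sum() / n * w_direct
    if m:
        score += log2fc[i_mask].sum() / m * w_indirect
    return TwcsRecord(
        pathway=pathway,
        tissue=tissue if tissue is not None else "all",
        dose=float(dose) if dose is not None else float("nan"),
        n_direct=n,
        m_indirect=m,
        score=float(score),
    )


def compute_twcs_table(
    degs: DegTable,
    annotation: PathwayAnnotation,
    thresholds: DegThresholds = DegThresholds(),
    w_direct: float = 1.0,
    w_indirect: float = 0.5,
    pathways: tuple[str, ...] = PATHWAYS,
) -> pd.DataFrame:
    """TWCS for every (pathway, tissue, dose) contrast present in the DEG table."""
    filtered = filter_degs(degs, thresholds)
    rows = []
    tissues = sorted(set(degs.rows["tissue"]))
    doses = sorted(set(degs.rows["dose_mg_L"].astype(float)))
    for tissue in tissues:
        for dose in doses:
            for pw in pathways:
                rec = compute_twcs(
                    filtered, annotation, pw, tissue, dose, w_direct, w_indirect
                )
                rows.append(
                    {
                        "pathway": pw,
                        "tissue": tissue,
                        "dose_mg_L": dose,
                        "n_direct": rec.n_direct,
                        "m_indirect": rec.m_indirect,
                        "twcs": rec.score,
                    }
                )
    return pd.DataFrame(rows)


def compute_relative_expression(delta_ct_control: float, delta_ct_treated: float) -> float:
    """Relative expression by the 2^-ddCT method."""
    ddct = float(delta_ct_treated) - float(delta_ct_control)
    if not np.isfinite(ddct):
        raise ValueError("delta-CT values must be finite")
    return float(2.0 ** (-ddct))


def critical_pearson_r(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical Pearson correlation for n pairs at level alpha.

    Derived from the t distribution with n−2 degrees of freedom:
    r_crit = t_crit / sqrt(t_crit² + n − 2).
    """
    if n < 3:
        raise ValueError("need at least 3 pairs")
    t_crit = stats.t.ppf(1 - alpha / 2, n - 2)
    return float(t_crit / np.sqrt(t_crit**2 + n - 2))


def platform_concordance(
    microarray_log2fc: np.ndarray, qpcr_log2fc: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Pearson concordance between microarray and qPCR log2 fold changes.

    Returns (r, critical_r, significant); significance is judged by
    comparing |r| against the critical correlation for the sample size.
    """
    a = np.asarray(microarray_log2fc, dtype=float)
    b = np.asarray(qpcr_log2fc, dtype=float)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("zero variance in a platform's fold changes")
    r = float(np.corrcoef(a, b)[0, 1])
    r_crit = critical_pearson_r(len(a), alpha)
    return r, r_crit, bool(abs(r) > r_crit)
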