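"""Self-contained differential-abundance stage ("DE-lite").

Two-group negative-binomial comparison producing per-gene log2 fold change,
a Wald-type p-value and BH-adjusted p.  The model is deliberately simple and
fully documented: median-of-ratios size factors, method-of-moments
dispersion shrunk 50/50 toward a fitted mean-dispersion trend (and floored
at the trend), a delta-method standard error for the log2 fold change and a
standard-normal Wald reference.  Externally computed results tables (gene_id,
log2fc, pvalue, padj) can be ingested instead via :func:`ribointerplay.io.read_table`
with schema ``differential``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CountMatrix

LN2 = np.log(2.0)
_PSEUDO = 0.5  # normalized-count pseudocount protecting the log ratio


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    For each sample j, the factor is the median over genes (expressed in
    every sample) of ``count_gj / geometric_mean_g``.
    """
    data = counts.data if isinstance(counts, CountMatrix) else counts
    arr = data.to_numpy(dtype=float)
    expressed = (arr > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene expressed in all samples; cannot normalize")
    logs = np.log(arr[expressed])
    geomean = np.exp(logs.mean(axis=1))
    factors = np.median(arr[expressed] / geomean[:, None], axis=0)
    return pd.Series(factors, index=data.columns, name="size_factor")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries are preserved."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def _dispersion_trend(mu: np.ndarray, alpha_hat: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by least squares on positive estimates."""
    use = (alpha_hat > 0) & (mu > 0)
    if use.sum() < 3:  # e.g. replicate-identical data: no dispersion signal
        return np.full_like(mu, 1e-8)
    X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
    coef, *_ = np.linalg.lstsq(X, alpha_hat[use], rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu, 1e-12)
    return np.maximum(trend, 1e-8)


@dataclass
class DifferentialResult:
    """Per-gene differential statistics for one contrast."""

    table: pd.DataFrame  # index gene_id; log2fc, se, pvalue, padj, mean_expression
    assay: str = "rna"

    def __post_init__(self) -> None:
        required = {"log2fc", "se", "pvalue", "padj", "mean_expression"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DifferentialResult missing columns {sorted(missing)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, assay: str = "rna") -> "DifferentialResult":
        df = df.copy()
        for col in ("se", "mean_expression"):
            if col not in df.columns:
                df[col] = np.nan
        return cls(df, assay=assay)


def test_differential(counts_ref: pd.DataFrame, counts_alt: pd.DataFrame, *,
                      assay: str = "rna", mean_count_floor: float = 1.0,
                      shrink_weight: float = 0.5,
                      dispersion: float | np.ndarray | None = None) -> DifferentialResult:
    """Two-group NB comparison (alt vs ref) on raw count slices.

    Both inputs are genes x replicates with identical gene indices.  Genes
    whose overall mean normalized count falls below ``mean_count_floor`` get
    an NA adjusted p (and become NOT_ASSESSED downstream).  With a single
    replicate per group a ``dispersion`` must be supplied.
    """
    if not counts_ref.index.equals(counts_alt.index):
        raise ValueError("gene universes differ between the two groups")
    n1, n2 = counts_ref.shape[1], counts_alt.shape[1]
    if (n1 < 2 or n2 < 2) and dispersion is None:
        raise ValueError("need >=2 replicates per group unless a dispersion is supplied")

    joint = pd.concat([counts_ref, counts_alt], axis=1)
    sf = size_factors(joint)
    norm = joint.div(sf, axis=1).to_numpy(dtype=float)
    x1, x2 = norm[:, :n1], norm[:, n1:]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    mean_expression = norm.mean(axis=1)

    lfc = np.log2(m2 + _PSEUDO) - np.log2(m1 + _PSEUDO)

    if dispersion is not None:
        alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), m1.shape).copy()
    else:
        # method-of-moments NB dispersion per group, pooled, then shrunk
        # toward the fitted mean-dispersion trend
        v1 = x1.var(axis=1, ddof=1)
        v2 = x2.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a1 = (v1 - m1) / np.square(m1)
            a2 = (v2 - m2) / np.square(m2)
        stacked = np.column_stack([a1, a2])
        valid = ~np.isnan(stacked)
        with np.errstate(invalid="ignore"):
            a_gene = np.where(valid.any(axis=1),
                              np.nansum(np.where(valid, stacked, 0.0), axis=1)
                              / np.maximum(valid.sum(axis=1), 1), 0.0)
        a_gene = np.clip(a_gene, 0.0, None)
        trend = _dispersion_trend(mean_expression, a_gene)
        # shrink toward the trend but never below it: gene-wise moment
        # estimates at 2-3 replicates scatter far under the truth, and
        # underestimated dispersions are what breaks type-I control
        alpha = np.maximum(shrink_weight * a_gene + (1.0 - shrink_weight) * trend, trend)

    inv_sf = 1.0 / sf.to_numpy()
    s1, s2 = inv_sf[:n1].mean(), inv_sf[n1:].mean()
    var_m1 = (m1 * s1 + alpha * np.square(m1)) / n1
    var_m2 = (m2 * s2 + alpha * np.square(m2)) / n2
    se = np.sqrt(var_m1 / np.square(m1 + _PSEUDO) + var_m2 / np.square(m2 + _PSEUDO)) / LN2

    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.where(np.isnan(z), 1.0, pvalue)           # 0/0: no evidence
    pvalue = np.where(np.isinf(z), 0.0, pvalue)           # zero SE, nonzero FC
    pvalue = np.minimum(pvalue, 1.0)

    low = mean_expression < mean_count_floor
    padj = np.full_like(pvalue, np.nan)
    padj[~low] = bh_adjust(pvalue[~low])

    table = pd.DataFrame(
        {"log2fc": lfc, "se": se, "pvalue": pvalue, "padj": padj,
         "mean_expression": mean_expression},
        index=counts_ref.index,
    )
    return DifferentialResult(table, assay=assay)
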