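"""Regulatory-class assignment and translational-efficiency statistics.

A gene's regulatory class compares its transcript (RNA-seq) and ribosome
footprint (Ribo-seq) responses in one contrast (stationary vs early
exponential phase by default):

* ``TC+/TC-``  - both significant, same sign: transcription-driven.
* ``COMP-``    - transcript significantly up, footprints flat: negative
  compensation (translation buffers a transcript increase).
* ``COMP+``    - transcript significantly down, footprints flat: positive
  compensation (ribosome loading maintained on a falling transcript).
* ``TL+/TL-``  - footprints significant, transcript flat: translation-only.
* ``NR``       - neither significant.
* ``DISCORDANT`` - both significant with opposite signs (surfaced rather
  than silently mis-binned).
* ``NOT_ASSESSED`` - missing adjusted p in either assay.

Translational efficiency (TE) is the log2 ratio of footprint TPM over
transcript TPM; its negative regression on log10(TPM + 1) quantifies
preferential ribosome loading of low-abundance transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import PipelineConfig
from .datamodel import AbundanceMatrix, SampleDesign
from .differential import DifferentialResult

BIN_LABELS = ("low", "medium", "high")


def classify_regulation(mrna: DifferentialResult, ribo: DifferentialResult,
                        cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Assign every gene exactly one regulatory class from the two contrasts."""
    cfg = cfg or PipelineConfig()
    if set(mrna.table.index) != set(ribo.table.index):
        raise ValueError("mRNA and footprint results cover different gene universes")
    m = mrna.table
    r = ribo.table.reindex(m.index)

    thr, alpha = cfg.fc_threshold, cfg.alpha
    m_lfc, r_lfc = m["log2fc"].to_numpy(), r["log2fc"].to_numpy()
    m_padj, r_padj = m["padj"].to_numpy(), r["padj"].to_numpy()

    m_sig = (np.abs(m_lfc) > thr) & (m_padj < alpha)
    r_sig = (np.abs(r_lfc) > thr) & (r_padj < alpha)
    na = np.isnan(m_padj) | np.isnan(r_padj)
    m_sig, r_sig = m_sig & ~na, r_sig & ~na

    cls = np.full(len(m), "NR", dtype=object)
    both = m_sig & r_sig
    same = np.sign(m_lfc) == np.sign(r_lfc)
    cls[both & same & (m_lfc > 0)] = "TC+"
    cls[both & same & (m_lfc < 0)] = "TC-"
    cls[both & ~same] = "DISCORDANT"
    cls[m_sig & ~r_sig & (m_lfc > 0)] = "COMP-"
    cls[m_sig & ~r_sig & (m_lfc < 0)] = "COMP+"
    cls[r_sig & ~m_sig & (r_lfc > 0)] = "TL+"
    cls[r_sig & ~m_sig & (r_lfc < 0)] = "TL-"
    cls[na] = "NOT_ASSESSED"

    return pd.DataFrame(
        {"class": cls, "mrna_lfc": m_lfc, "mrna_padj": m_padj,
         "ribo_lfc": r_lfc, "ribo_padj": r_padj},
        index=m.index,
    )


def compute_te(rna: AbundanceMatrix, ribo: AbundanceMatrix, design: SampleDesign,
               time_point: str, *, average: str = "median") -> pd.DataFrame:
    """Per-gene TE = log2(footprint TPM / transcript TPM) at one time point.

    Replicate TPMs are pooled (median by default) within the time point
    before the ratio.  TE is defined only where both abundances are
    positive; genes with zero footprints are flagged NA and excluded from
    regression downstream.
    """
    if set(rna.gene_ids) != set(ribo.gene_ids):
        raise ValueError("transcript and footprint gene sets differ")
    pool = np.median if average == "median" else np.mean
    rna_cols = design.samples_for(time_point, "rna")
    ribo_cols = design.samples_for(time_point, "ribo")
    if not rna_cols or not ribo_cols:
        raise ValueError(f"no samples at {time_point} for both assays")
    tpm_rna = rna.data[rna_cols].apply(pool, axis=1)
    tpm_ribo = ribo.data.reindex(rna.gene_ids)[ribo_cols].apply(pool, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.log2(tpm_ribo / tpm_rna)
    te = te.where((tpm_rna > 0) & (tpm_ribo > 0))
    return pd.DataFrame({"te": te, "tpm_rna": tpm_rna, "tpm_ribo": tpm_ribo,
                         "time_point": time_point})


@dataclass
class RegressionFit:
    """Simple OLS fit with residuals and per-point 95% prediction interval."""

    slope: float
    intercept: float
    r: float
    pvalue: float
    residuals: pd.Series
    pi_lower: pd.Series
    pi_upper: pd.Series
    n: int
    x: pd.Series = field(repr=False)
    y: pd.Series = field(repr=False)

    @property
    def outliers(self) -> pd.Index:
        out = (self.y < self.pi_lower) | (self.y > self.pi_upper)
        return self.y.index[out]


def _ols_with_pi(x: pd.Series, y: pd.Series, level: float = 0.95) -> RegressionFit:
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if float(np.ptp(x)) == 0.0:
        raise ValueError("degenerate predictor: all x equal")
    X = sm.add_constant(x.to_numpy())
    model = sm.OLS(y.to_numpy(), X).fit()
    pred = model.get_prediction(X).summary_frame(alpha=1.0 - level)
    r = float(np.corrcoef(x, y)[0, 1]) if float(np.ptp(y)) > 0 else 0.0
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r=r,
        pvalue=float(model.pvalues[1]),
        residuals=pd.Series(model.resid, index=y.index, name="residual"),
        pi_lower=pd.Series(pred["obs_ci_lower"].to_numpy(), index=y.index),
        pi_upper=pd.Series(pred["obs_ci_upper"].to_numpy(), index=y.index),
        n=len(x),
        x=x,
        y=y,
    )


def regress_te_on_abundance(te: pd.DataFrame, *, level: float = 0.95) -> RegressionFit:
    """OLS of TE on log10(transcript TPM + 1) over genes with defined TE.

    The slope quantifies how strongly TE falls with transcript abundance
    (around -1.1 per decade in stationary-to-exponential comparisons of
    H. salinarum); residuals measure each gene's deviation from the TE
    expected at its expression level.
    """
    ok = te["te"].notna()
    x = np.log10(te.loc[ok, "tpm_rna"] + 1.0)
    x.name = "log10_tpm"
    return _ols_with_pi(x, te.loc[ok, "te"], level=level)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration for small untied samples,
    normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = (len(x) + len(y)) <= 8
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def te_deviation_by_group(fit: RegressionFit, classes: pd.DataFrame,
                          cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Compare TE residual distributions across transcription groups per
    abundance bin.

    Groups: transcriptionally up (mRNA log2FC > threshold, padj < alpha),
    down (mirror), and non-DET (mRNA padj >= alpha regardless of
    footprints).  Bins on transcript TPM: low (10, 100], medium (100,
    1000], high (1000, 10000].  Per bin, two-sided Mann-Whitney U tests of
    up vs down and each vs non-DET; bins with fewer than 3 genes in a group
    are reported untestable (NA p).
    """
    cfg = cfg or PipelineConfig()
    resid = fit.residuals
    genes = resid.index.intersection(classes.index)
    cl = classes.loc[genes]
    up = (cl["mrna_lfc"] > cfg.fc_threshold) & (cl["mrna_padj"] < cfg.alpha)
    down = (cl["mrna_lfc"] < -cfg.fc_threshold) & (cl["mrna_padj"] < cfg.alpha)
    nondet = ~(cl["mrna_padj"] < cfg.alpha)
    groups = {"up": genes[up.fillna(False)], "down": genes[down.fillna(False)],
              "non_det": genes[nondet.fillna(True)]}

    tpm = (10.0 ** fit.x - 1.0).reindex(genes)
    edges = cfg.abundance_bins
    rows = []
    for lab, lo, hi in zip(BIN_LABELS, edges[:-1], edges[1:]):
        in_bin = genes[(tpm > lo) & (tpm <= hi)]
        samples = {name: resid.loc[in_bin.intersection(idx)].to_numpy()
                   for name, idx in groups.items()}
        for a, b in (("up", "down"), ("up", "non_det"), ("down", "non_det")):
            xa, xb = samples[a], samples[b]
            if len(xa) < 3 or len(xb) < 3:
                u = p = np.nan
            else:
                u, p = mann_whitney_u(xa, xb)
            stars = ("**" if p < 0.01 else "*" if p < 0.05 else "ns") if p == p else "NA"
            rows.append({"bin": lab, "group_a": a, "group_b": b,
                         "n_a": len(xa), "n_b": len(xb), "U": u, "pvalue": p,
                         "significance": stars})
    return pd.DataFrame(rows)


def permutation_abundance_test(gene_set, abundance: pd.Series, *, n_perm: int,
                               seed: int, tail: str = "lower",
                               chunk: int | None = None) -> dict:
    """Empirical test of whether a gene set's mean abundance is extreme.

    Draws ``n_perm`` uniform gene sets of the same size (without replacement
    within each draw) from the universe and compares their means with the
    observed one; the plus-one-corrected empirical p is returned, with
    ``tail`` choosing the direction (``lower`` asks whether the set is less
    abundant than expected).
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = set(gene_set) - set(abundance.index)
    if missing:
        raise ValueError(f"genes outside the universe: {sorted(missing)[:3]}")
    k, values = len(gene_set), abundance.to_numpy(dtype=float)
    n_universe = len(values)
    if k > n_universe:
        raise ValueError("gene set larger than the universe")
    observed = float(abundance.loc[gene_set].mean())

    rng = np.random.default_rng(seed)
    if chunk is None:
        chunk = max(1, int(8_000_000 // max(n_universe, 1)))  # bound scratch memory
    null_means = np.empty(n_perm)
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        keys = rng.random((c, n_universe))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null_means[done:done + c] = values[idx].mean(axis=1)
        done += c

    # float-summation order differs between the observed and resampled means,
    # so ties are recognised with a tiny relative tolerance
    atol = 1e-9 * max(1.0, abs(observed))
    n_le = int((null_means <= observed + atol).sum())
    n_ge = int((null_means >= observed - atol).sum())
    p_lower = (n_le + 1) / (n_perm + 1)
    p_upper = (n_ge + 1) / (n_perm + 1)
    if tail == "lower":
        p = p_lower
    elif tail == "upper":
        p = p_upper
    elif tail == "two":
        p = min(1.0, 2.0 * min(p_lower, p_upper))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return {"observed_mean": observed, "pvalue": p, "n_perm": n_perm,
            "null_mean": float(null_means.mean()), "null_sd": float(null_means.std()),
            "tail": tail, "set_size": k}


def prediction_interval_outliers(x: pd.Series, y: pd.Series, *,
                                 level: float = 0.95) -> RegressionFit:
    """OLS of y on x with per-point prediction interval; points with y
    outside the interval are flagged via ``fit.outliers``.

    Used for the footprint-vs-transcript fold-change fit of RP genes, where
    a gene outside the interval (e.g. a transcript down 26-fold whose
    footprints fall only sevenfold) is a candidate for translation-level
    decoupling.
    """
    x = pd.Series(x)
    y = pd.Series(y).reindex(x.index)
    return _ols_with_pi(x, y, level=level)


def log2fc_to_fold(lfc: float) -> tuple[float, str]:
    """Convert a log2 fold change to a positive fold change and a direction.

    ``-4.70`` becomes (26.0, "down") to the precision the unit implies.
    """
    if not np.isfinite(lfc):
        raise ValueError("log2 fold change must be finite")
    direction = "down" if lfc < 0 else "up" if lfc > 0 else "none"
    return float(2.0 ** abs(lfc)), direction
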