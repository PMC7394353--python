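"""Ribosomal-protein abundance trends and stoichiometry-deviation calls.

The input is a protein x sample intensity table from the ribosome-enriched
fraction.  Per RP and time point we compute the log2 fold change of the
replicate-median intensity versus the reference time point.  The
stoichiometry ratio (SR) of an RP at a time point is its log2 FC minus the
per-time-point median log2 FC over all detected RPs, i.e. its deviation
from the collective trend of the assembled-ribosome pool; by construction
the median SR per time point is zero.  A deviation event is an SR outside
the central 95% percentile interval of the cross-RP SR distribution at that
time point, and an RP is flagged when it accumulates at least
``min_deviation_events`` events across non-reference time points.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import ProteinIntensityMatrix

log = logging.getLogger("ribointerplay")


def protein_log2fc(protein: ProteinIntensityMatrix,
                   reference_tp: str | None = None) -> pd.DataFrame:
    """RP x time-point log2 fold change of replicate-median intensities.

    Zero or missing intensities propagate as NA (SWATH dropouts are
    informative and are never imputed).  Detection counts per time point
    are logged.
    """
    design = protein.design
    ref = reference_tp or design.reference_time_point
    tps = design.time_points("protein")
    if ref not in tps:
        raise ValueError(f"reference time point {ref} absent from protein design")

    medians = {}
    for tp in tps:
        cols = design.samples_for(tp, "protein")
        med = protein.data[cols].median(axis=1)
        medians[tp] = med.where(med > 0)
    med = pd.DataFrame(medians)
    if med[ref].isna().all():
        raise ValueError(f"no protein detected at reference time point {ref}")
    lfc = np.log2(med.div(med[ref], axis=0))
    detected = med.notna().sum(axis=0)
    log.info("protein detection per time point: %s", detected.to_dict())
    return lfc


def stoichiometry_ratio(log2fc: pd.DataFrame, *, centering: str = "median") -> pd.DataFrame:
    """Long-form stoichiometry table with SR = log2FC - per-TP center.

    ``centering`` is ``median`` (default) or ``mean`` over detected RPs.
    """
    if centering not in ("median", "mean"):
        raise ValueError("centering must be 'median' or 'mean'")
    if log2fc.notna().sum(axis=0).min() < 5:
        raise ValueError("need at least 5 detected RPs per time point")
    center = log2fc.median(axis=0) if centering == "median" else log2fc.mean(axis=0)
    sr = log2fc.sub(center, axis=1)
    out = (
        pd.concat({"log2fc_protein": log2fc, "sr": sr}, axis=1)
        .stack(level=1, future_stack=True)
        .reset_index()
    )
    out.columns = ["rp_name", "time_point", "log2fc_protein", "sr"]
    return out


def _interval(srs: np.ndarray, ci_level: float, method: str,
              rng: np.random.Generator | None = None) -> tuple[float, float]:
    tail = 100.0 * (1.0 - ci_level) / 2.0
    if method == "robust":
        # Gaussian interval with robust scale: contaminating deviants cannot
        # widen it, so genuinely deviating RPs near the edge stay detectable
        from scipy import stats as _st
        center = np.median(srs)
        scale = _st.median_abs_deviation(srs, scale="normal")
        z = _st.norm.ppf(1.0 - (1.0 - ci_level) / 2.0)
        return center - z * scale, center + z * scale
    if method == "percentile":
        lo, hi = np.percentile(srs, [tail, 100.0 - tail])
        return float(lo), float(hi)
    if method == "bootstrap_median":
        rng = rng or np.random.default_rng(0)
        meds = np.median(rng.choice(srs, size=(2000, len(srs)), replace=True), axis=1)
        lo, hi = np.percentile(meds, [tail, 100.0 - tail])
        return float(lo), float(hi)
    raise ValueError(f"unknown interval method {method!r}")


def flag_deviant_rps(table: pd.DataFrame, *, ci_level: float = 0.95,
                     min_events: int = 2, reference_tp: str = "TP1",
                     method: str = "robust") -> pd.DataFrame:
    """Mark deviation events and flag RPs with repeated events.

    Per non-reference time point, an event is an SR outside the central
    ``ci_level`` interval of the cross-RP SR distribution.  The default
    interval is the robust Gaussian one (median +/- z * 1.4826 * MAD), which
    stays calibrated to the bulk trend when a few RPs genuinely deviate;
    ``percentile`` (empirical percentile interval) and ``bootstrap_median``
    (percentile bootstrap of the median) are available alternatives.
    ``flagged`` RPs have >= ``min_events`` events over non-reference time
    points.
    """
    table = table.copy()
    table["deviation_event"] = False
    for tp, sub in table.groupby("time_point"):
        if tp == reference_tp:
            continue
        srs = sub["sr"].dropna()
        if len(srs) < 20:
            log.warning("only %d RPs at %s: percentile interval unstable", len(srs), tp)
        lo, hi = _interval(srs.to_numpy(), ci_level, method)
        events = (sub["sr"] < lo) | (sub["sr"] > hi)
        table.loc[sub.index, "deviation_event"] = events.fillna(False)
    n_events = table.groupby("rp_name")["deviation_event"].sum()
    table["n_events"] = table["rp_name"].map(n_events).astype(int)
    table["flagged"] = table["n_events"] >= min_events
    return table


def flagged_rps(table: pd.DataFrame) -> list[str]:
    """Names of RPs flagged as stoichiometry deviants."""
    return sorted(table.loc[table["flagged"], "rp_name"].unique())
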