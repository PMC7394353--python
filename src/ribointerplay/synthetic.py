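"""Synthetic data generators with planted ground truth.

Every generator returns its truth alongside the data so downstream stages
can be tested without any external download; no analysis stage may peek at
truth outside tests.  Defaults mirror the study conditions: four growth
time points (early/mid/late exponential, stationary) with three biological
replicates, negative-binomial counts, a planted TE-abundance slope of
-1.10 log2 units per log10(TPM+1) decade, a ribosomal-protein pool whose
median log2 fold change drifts to -1.04 by stationary phase with five
planted stoichiometry deviants (SR magnitudes 0.94, 0.39, 0.94, 0.35,
0.30), a 4-class corem membership block structure sized 38/7/6/3, and a
planted-partition bait->prey interaction graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceMatrix,
    CoremMembershipMatrix,
    CountMatrix,
    EdgeList,
    ProteinIntensityMatrix,
    SampleDesign,
)
from .io import tpm_from_counts

#: Regulatory-class mix observed in the stationary-vs-early-exponential
#: contrast (transcription-only split evenly between up and down).
DEFAULT_CLASS_COUNTS = {
    "TC+": 437, "TC-": 438, "COMP-": 110, "COMP+": 79,
    "TL+": 15, "TL-": 24, "NR": 304,
}


def default_class_proportions() -> dict[str, float]:
    total = sum(DEFAULT_CLASS_COUNTS.values())
    return {k: v / total for k, v in DEFAULT_CLASS_COUNTS.items()}


def make_design(n_reps: int = 3, assays: tuple[str, ...] = ("rna", "ribo"),
                time_points: tuple[str, ...] = ("TP1", "TP2", "TP3", "TP4")
                ) -> SampleDesign:
    """Full-factorial sample sheet: time point x replicate x assay."""
    rows = [
        {"sample_id": f"{assay}_{tp}_r{rep}", "time_point": tp,
         "replicate": rep, "assay": assay}
        for assay in assays for tp in time_points for rep in range(1, n_reps + 1)
    ]
    return SampleDesign(pd.DataFrame(rows), time_point_order=time_points)


@dataclass
class SimulationParams:
    """Conditions for the paired RNA-seq / Ribo-seq simulation."""

    n_genes: int = 2000
    class_proportions: dict[str, float] = field(default_factory=default_class_proportions)
    te_slope: float = -1.10       # log2 TE per log10(TPM+1) decade
    te_intercept: float = 2.5
    te_scatter_sd: float = 1.5    # gene-level TE scatter about the line (log2)
    nb_dispersion: float = 0.05
    library_size: float = 2e7  # per-library depth typical of the platform
    log10_abundance_mean: float = 2.0
    log10_abundance_sd: float = 0.8
    low_abundance_shift: float = 0.8   # log10 shift applied to TL+ genes
    lfc_range: tuple[float, float] = (1.5, 3.0)  # planted significant |log2 FC|
    lfc_null_max: float = 0.4          # planted non-significant |log2 FC|
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def make_truth(params: SimulationParams) -> pd.DataFrame:
    """Draw the per-gene ground truth implied by the class proportions.

    Fold-change patterns respect the class definitions with a margin:
    significant planted |log2 FC| lies in ``lfc_range`` (above the 1.0 call
    threshold), non-significant ones below ``lfc_null_max``.
    """
    rng = np.random.default_rng(params.seed)
    classes = list(params.class_proportions)
    probs = np.array([params.class_proportions[c] for c in classes])
    # largest-remainder allocation keeps counts deterministic
    raw = probs * params.n_genes
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: params.n_genes - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(classes, counts)
    rng.shuffle(labels)

    lo, hi = params.lfc_range
    strong = rng.uniform(lo, hi, size=params.n_genes)
    weak = rng.uniform(0.0, params.lfc_null_max, size=params.n_genes)
    weak_sign = rng.choice([-1.0, 1.0], size=params.n_genes)

    lfc_m = np.where(np.isin(labels, ["TC+", "COMP-"]), strong,
             np.where(np.isin(labels, ["TC-", "COMP+"]), -strong, weak * weak_sign))
    lfc_r = np.where(labels == "TC+", lfc_m,
             np.where(labels == "TC-", lfc_m,
             np.where(labels == "TL+", strong,
             np.where(labels == "TL-", -strong, weak * rng.choice([-1.0, 1.0],
                                                                  size=params.n_genes)))))

    log10_base = rng.normal(params.log10_abundance_mean, params.log10_abundance_sd,
                            size=params.n_genes)
    log10_base = log10_base - np.where(labels == "TL+", params.low_abundance_shift, 0.0)
    te_scatter = rng.normal(0.0, params.te_scatter_sd, size=params.n_genes)

    gene_ids = [f"VNG{i:04d}G" for i in range(1, params.n_genes + 1)]
    return pd.DataFrame({
        "true_class": labels,
        "base_abundance_tpm": 10.0 ** log10_base,
        "true_lfc_mrna": lfc_m,
        "true_lfc_ribo": lfc_r,
        "te_scatter": te_scatter,
        "is_rp": False,
    }, index=pd.Index(gene_ids, name="gene_id"))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0.0:
        return np.rint(mu).astype(np.int64)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, np.clip(p, 1e-12, 1.0)).astype(np.int64)


def simulate_paired_counts(params: SimulationParams, truth: pd.DataFrame,
                           design: SampleDesign
                           ) -> tuple[CountMatrix, CountMatrix, AbundanceMatrix, AbundanceMatrix]:
    """Simulate paired mRNA and footprint counts plus their TPM tables.

    The mRNA mean at the reference time point equals the base abundance and
    scales to ``2^true_lfc_mrna`` times that by the final time point
    (intermediate points interpolate the log2 effect linearly).  Footprint
    means couple to mRNA on the mean scale through the planted TE line
    ``te_intercept + te_slope * log10(base TPM + 1)`` plus per-gene scatter,
    with the translation effect ``true_lfc_ribo - true_lfc_mrna`` applied
    on top (so the footprint log2 FC is exactly ``true_lfc_ribo``).  Counts are negative-binomial at the shared dispersion
    (dispersion 0 gives deterministic rounded means).
    """
    rng = np.random.default_rng(params.seed + 1)
    tps = design.time_points("rna")
    base = truth["base_abundance_tpm"].to_numpy()
    lfc_m = truth["true_lfc_mrna"].to_numpy()
    lfc_r = truth["true_lfc_ribo"].to_numpy()
    scatter = truth["te_scatter"].to_numpy()

    # TE is planted from the reference-time-point abundance so that the
    # footprint fold change equals true_lfc_ribo exactly (a TE term tied to
    # the instantaneous mRNA level would leak -slope * delta_log10(mRNA)
    # into every DE gene's footprint fold change)
    te = params.te_intercept + params.te_slope * np.log10(base + 1.0) + scatter
    counts = {"rna": {}, "ribo": {}}
    for t_idx, tp in enumerate(tps):
        f = t_idx / (len(tps) - 1) if len(tps) > 1 else 1.0
        mrna_rel = base * 2.0 ** (f * lfc_m)
        ribo_rel = mrna_rel * 2.0 ** (te + f * (lfc_r - lfc_m))
        for assay, rel in (("rna", mrna_rel), ("ribo", ribo_rel)):
            mu_unit = rel / rel.sum() * params.library_size
            for sample in design.samples_for(tp, assay):
                counts[assay][sample] = _nb_draw(rng, mu_unit, params.nb_dispersion)

    gene_index = truth.index
    mrna = CountMatrix(pd.DataFrame(counts["rna"], index=gene_index))
    ribo = CountMatrix(pd.DataFrame(counts["ribo"], index=gene_index))
    lengths = pd.Series(1.0, index=gene_index)
    return (mrna, ribo,
            tpm_from_counts(mrna, lengths, zero_policy="zero"),
            tpm_from_counts(ribo, lengths, zero_policy="zero"))


#: Planted stoichiometry deviants with the observed SR magnitudes, applied
#: at the two latest time points.
DEFAULT_DEVIANTS = (
    ("S28E", {"TP3": 0.94, "TP4": 0.94}),
    ("L44E", {"TP3": 0.39, "TP4": 0.39}),
    ("S10-like", {"TP3": -0.94, "TP4": -0.94}),
    ("S13", {"TP3": -0.35, "TP4": -0.35}),
    ("L24E", {"TP3": -0.30, "TP4": -0.30}),
)


@dataclass
class StoichSimParams:
    """Conditions for the ribosome-enriched-fraction proteomics simulation."""

    n_rp: int = 50
    global_trend: dict[str, float] = field(
        default_factory=lambda: {"TP1": 0.0, "TP2": -0.3, "TP3": -0.7, "TP4": -1.04})
    deviants: tuple = DEFAULT_DEVIANTS
    replicate_sd: float = 0.1
    n_reps: int = 3
    seed: int = 0


def simulate_rp_proteomics(params: StoichSimParams,
                           design: SampleDesign | None = None
                           ) -> tuple[ProteinIntensityMatrix, pd.DataFrame]:
    """Simulate RP intensities: a shared downward trend plus planted
    per-RP stoichiometry offsets and log-normal replicate noise.

    Returns the intensity matrix and a truth table of planted offsets.
    """
    tps = tuple(params.global_trend)
    if design is None:
        design = make_design(params.n_reps, assays=("protein",), time_points=tps)
    rng = np.random.default_rng(params.seed)

    deviant_names = [name for name, _ in params.deviants]
    n_other = params.n_rp - len(deviant_names)
    if n_other < 0:
        raise ValueError("more deviants than simulated RPs")
    others = []
    i = 1
    while len(others) < n_other:
        cand = f"{'S' if i % 2 else 'L'}{i:02d}"
        if cand not in deviant_names:
            others.append(cand)
        i += 1
    rp_names = deviant_names + others
    offsets = pd.DataFrame(0.0, index=rp_names, columns=list(tps))
    for name, per_tp in params.deviants:
        for tp, off in per_tp.items():
            offsets.loc[name, tp] = off

    base = 10.0 ** rng.uniform(4.0, 6.0, size=params.n_rp)
    data = {}
    for tp in tps:
        trend = params.global_trend[tp]
        for sample in design.samples_for(tp, "protein"):
            noise = rng.normal(0.0, params.replicate_sd, size=params.n_rp)
            data[sample] = base * 2.0 ** (trend + offsets[tp].to_numpy() + noise)
    mat = ProteinIntensityMatrix(pd.DataFrame(data, index=rp_names),
                                 design.subset("protein"))
    truth = offsets.rename_axis("rp_name")
    return mat, truth


def simulate_corems(n_genes: int = 54, n_corems: int = 72,
                    class_sizes: tuple[int, ...] = (38, 7, 6, 3),
                    noise_rate: float = 0.05, n_conditions: int = 180,
                    n_categories: int = 6, seed: int = 0,
                    class_effect_sd: float = 1.5, gene_noise_sd: float = 0.5
                    ) -> tuple[CoremMembershipMatrix, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Block-structured corem membership with planted gene classes, plus a
    condition compendium in which corems of one class respond coherently.

    Each gene belongs to the corems of its class block; every membership
    bit is flipped independently with probability ``noise_rate``.  Returns
    (membership, compendium, condition categories, planted labels).
    """
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must lie in [0, 0.5)")
    if sum(class_sizes) != n_genes:
        raise ValueError("class sizes must sum to n_genes")
    rng = np.random.default_rng(seed)

    gene_ids = [f"rp{i:03d}" for i in range(1, n_genes + 1)]
    corem_ids = [f"corem{j:03d}" for j in range(1, n_corems + 1)]
    sizes = np.array(class_sizes, dtype=float)
    blocks = np.floor(sizes / sizes.sum() * n_corems).astype(int)
    blocks[np.argmax(sizes)] += n_corems - blocks.sum()

    gene_class = np.repeat(np.arange(len(class_sizes)), class_sizes)
    corem_class = np.repeat(np.arange(len(class_sizes)), blocks)
    member = (gene_class[:, None] == corem_class[None, :]).astype(np.int8)
    flips = rng.random(member.shape) < noise_rate
    member = np.where(flips, 1 - member, member).astype(np.int8)
    membership = CoremMembershipMatrix(
        pd.DataFrame(member, index=pd.Index(gene_ids, name="gene_id"), columns=corem_ids))

    cond_ids = [f"cond{c:04d}" for c in range(1, n_conditions + 1)]
    class_resp = rng.normal(0.0, class_effect_sd, size=(len(class_sizes), n_conditions))
    expr = (class_resp[gene_class]
            + rng.normal(0.0, gene_noise_sd, size=(n_genes, n_conditions)))
    compendium = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"),
                              columns=cond_ids)
    categories = pd.DataFrame({
        "condition": cond_ids,
        "category": [f"cat{(i % n_categories) + 1}" for i in range(n_conditions)],
    })
    roman = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")
    labels = pd.Series([roman[c] for c in gene_class], index=gene_ids, name="true_class")
    return membership, compendium, categories, labels


def simulate_ppi(n_nodes: int = 126, n_modules: int = 7, p_in: float = 0.8,
                 p_out: float = 0.05, seed: int = 0
                 ) -> tuple[EdgeList, pd.Series]:
    """Planted-partition interaction graph with directed bait->prey edges.

    Unordered node pairs within a module are connected with probability
    ``p_in``, across modules with ``p_out``; each edge is oriented from a
    uniformly chosen endpoint (every node is a potential tagged bait).
    Returns the edge list and the planted module labels.
    """
    if not p_in > p_out:
        raise ValueError("p_in must exceed p_out")
    rng = np.random.default_rng(seed)
    nodes = [f"P{i:03d}" for i in range(1, n_nodes + 1)]
    module = np.array([i * n_modules // n_nodes for i in range(n_nodes)])

    rows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            p = p_in if module[i] == module[j] else p_out
            if rng.random() < p:
                a, b = (i, j) if rng.random() < 0.5 else (j, i)
                rows.append({"bait": nodes[a], "prey": nodes[b], "bait_role": "other"})
    edges = EdgeList(pd.DataFrame(rows, columns=["bait", "prey", "bait_role"]))
    truth = pd.Series(module, index=nodes, name="true_module")
    return edges, truth
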