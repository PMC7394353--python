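"""Corem-membership clustering and condition-specific similarity of corem classes.

Genes are clustered by their presence/absence pattern over corems
(conditionally coregulated modules mined from an ensemble regulatory-network
model).  The distance is the binary (asymmetric-mismatch / union) metric,
the linkage is UPGMA, and clade robustness is assessed by resampling corems
(columns) with replacement; classes are maximal clades whose bootstrap
support reaches the threshold (0.95 by default).  Support here is the plain
bootstrap probability of the clade.

Corem expression signatures are per-condition medians over member genes;
two corems are "similar" (no significant expression difference) when their
signatures correlate positively and significantly by Spearman rank
(SRCC > 0.4, P < 0.05) and a two-sample Kolmogorov-Smirnov test finds no
distributional difference (P > 0.05).  Class-level similarity per condition
category is the proportion of similar corem pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from .config import PipelineConfig
from .datamodel import CoremMembershipMatrix

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def binary_distance(membership: CoremMembershipMatrix) -> pd.DataFrame:
    """Gene x gene binary distance: mismatches over corems where at least
    one gene is present (genes in no corem must be excluded beforehand)."""
    mm = membership.drop_unassigned_genes()
    if mm.data.shape[0] < 2:
        raise ValueError("need at least 2 genes with nonzero membership")
    d = pdist(mm.data.to_numpy(dtype=bool), metric="jaccard")
    return pd.DataFrame(squareform(d), index=mm.gene_ids, columns=mm.gene_ids)


@dataclass
class Dendrogram:
    """UPGMA merge tree over labelled leaves."""

    linkage_matrix: np.ndarray
    leaf_ids: list[str]

    def clades(self, *, include_singletons: bool = False,
               include_root: bool = False) -> list[frozenset]:
        """Leaf-label sets of every internal node (root/singletons optional)."""
        n = len(self.leaf_ids)
        sets: list[frozenset] = [frozenset([lab]) for lab in self.leaf_ids]
        for a, b, *_ in self.linkage_matrix:
            sets.append(sets[int(a)] | sets[int(b)])
        internal = sets[n:]
        out = list(internal[:-1]) if not include_root else list(internal)
        if include_singletons:
            out = sets[:n] + out
        return out

    def cophenetic(self) -> pd.DataFrame:
        d = cophenet(self.linkage_matrix)
        return pd.DataFrame(squareform(d), index=self.leaf_ids, columns=self.leaf_ids)


def upgma_cluster(dist: pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a symmetric distance matrix."""
    arr = dist.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(arr, arr.T) or not np.allclose(np.diag(arr), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    lm = linkage(squareform(arr, checks=False), method="average")
    return Dendrogram(lm, list(dist.index))


def bootstrap_cluster_support(membership: CoremMembershipMatrix, *,
                              n_boot: int = 10_000, seed: int = 0,
                              support_threshold: float = 0.95) -> pd.DataFrame:
    """Bootstrap clade support by corem (column) resampling; class calls.

    Returns a per-gene table with ``class_label`` (roman numerals in
    decreasing class size, ``unassigned`` otherwise) and the supporting
    clade's bootstrap probability.  Classes are maximal supported clades:
    clades with support >= threshold not contained in a larger qualifying
    clade, excluding the root, singletons and clades merged at the binary
    metric's maximum height (their children share no corem).
    """
    import logging
    if n_boot < 100:
        logging.getLogger("ribointerplay").warning(
            "n_boot=%d is small; clade supports will be unstable", n_boot)
    mm = membership.drop_unassigned_genes()
    base = upgma_cluster(binary_distance(mm))
    # a clade merged at the metric's maximum height joins groups that share
    # no corem at all; reproducible or not, that is no cluster
    n_leaves = len(base.leaf_ids)
    sets_h: list[frozenset] = [frozenset([g]) for g in base.leaf_ids]
    heights: dict[frozenset, float] = {}
    for a, b, h, _ in base.linkage_matrix:
        merged = sets_h[int(a)] | sets_h[int(b)]
        sets_h.append(merged)
        heights[merged] = float(h)
    observed = [c for c in base.clades() if heights[c] < 1.0 - 1e-9]

    rng = np.random.default_rng(seed)
    arr = mm.data.to_numpy(dtype=bool)
    n_genes, n_corems = arr.shape
    counts: Counter = Counter()
    for _ in range(n_boot):
        cols = rng.integers(0, n_corems, size=n_corems)
        sub = arr[:, cols]
        # genes empty in this resample carry no information but stay as leaves
        d = pdist(sub, metric="jaccard")
        d = np.nan_to_num(d, nan=1.0)
        lm = linkage(d, method="average")
        sets: list[frozenset] = [frozenset([g]) for g in mm.gene_ids]
        for a, b, *_ in lm:
            sets.append(sets[int(a)] | sets[int(b)])
        counts.update(set(sets[n_genes:-1]))

    support = {clade: counts[clade] / n_boot for clade in observed}
    qualifying = [c for c, s in support.items() if s >= support_threshold]
    maximal = [c for c in qualifying
               if not any(c < other for other in qualifying)]
    maximal.sort(key=lambda c: (-len(c), sorted(c)))

    label = {g: "unassigned" for g in mm.gene_ids}
    supp = {g: np.nan for g in mm.gene_ids}
    for i, clade in enumerate(maximal):
        name = ROMAN[i] if i < len(ROMAN) else f"class{i + 1}"
        for g in clade:
            label[g] = name
            supp[g] = support[clade]
    return pd.DataFrame({
        "class_label": pd.Series(label),
        "cluster_support": pd.Series(supp),
    }).rename_axis("gene_id")


def corem_signature(compendium: pd.DataFrame, member_genes) -> pd.DataFrame:
    """Per-condition median and IQR of expression across a corem's genes."""
    genes = [g for g in set(member_genes) if g in compendium.index]
    if not genes:
        raise ValueError("no member gene present in the compendium")
    sub = compendium.loc[genes]
    return pd.DataFrame({
        "median": sub.median(axis=0),
        "q1": sub.quantile(0.25, axis=0),
        "q3": sub.quantile(0.75, axis=0),
    })


@dataclass
class SimilarityDecision:
    srcc: float
    srcc_p: float
    ks_p: float
    similar: bool
    degenerate: bool = False


def corem_pair_similarity(sig_a: pd.DataFrame, sig_b: pd.DataFrame,
                          cfg: PipelineConfig | None = None) -> SimilarityDecision:
    """Decide whether two corems show no significant expression differences."""
    cfg = cfg or PipelineConfig()
    a = sig_a["median"].to_numpy(dtype=float)
    b = sig_b["median"].reindex(sig_a.index).to_numpy(dtype=float)
    if len(a) != len(b) or np.isnan(b).any():
        raise ValueError("signatures cover different condition sets")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return SimilarityDecision(np.nan, np.nan, np.nan, False, degenerate=True)
    rho, rho_p = stats.spearmanr(a, b)
    ks = stats.ks_2samp(a, b, method="auto")
    similar = bool(rho > cfg.srcc_threshold and rho_p < cfg.alpha
                   and ks.pvalue > cfg.alpha)
    return SimilarityDecision(float(rho), float(rho_p), float(ks.pvalue), similar)


def corem_classes(membership: CoremMembershipMatrix,
                  assignment: pd.DataFrame) -> pd.Series:
    """Assign each corem the majority class among its classified member genes."""
    labels = assignment["class_label"]
    out = {}
    for corem in membership.corem_ids:
        members = membership.data.index[membership.data[corem] == 1]
        cls = labels.reindex(members).dropna()
        cls = cls[cls != "unassigned"]
        out[corem] = cls.value_counts().idxmax() if len(cls) else "unassigned"
    return pd.Series(out, name="class_label")


def class_similarity_matrix(assignment: pd.DataFrame,
                            membership: CoremMembershipMatrix,
                            compendium: pd.DataFrame,
                            condition_categories: pd.DataFrame,
                            cfg: PipelineConfig | None = None) -> dict[str, pd.DataFrame]:
    """Per-condition-category class x class similarity matrices.

    Entry (i, j) is the proportion of corem pairs (one corem from class i,
    one from class j; unordered within-class pairs excluding self-pairs)
    whose signatures over the category's conditions are "similar".
    Categories with fewer than 3 conditions are reported untestable (all-NA).
    """
    cfg = cfg or PipelineConfig()
    corem_cls = corem_classes(membership, assignment)
    classes = sorted(set(corem_cls) - {"unassigned"})
    by_class = {c: [k for k in corem_cls.index if corem_cls[k] == c] for c in classes}

    sigs = {corem: corem_signature(
        compendium, membership.data.index[membership.data[corem] == 1])
        for corem in corem_cls.index}

    result = {}
    for cat, sub in condition_categories.groupby("category"):
        conds = [c for c in sub["condition"] if c in compendium.columns]
        mat = pd.DataFrame(np.nan, index=classes, columns=classes)
        if len(conds) >= 3:
            cache: dict[tuple[str, str], bool] = {}

            def similar(a: str, b: str) -> bool:
                key = (a, b) if a <= b else (b, a)
                if key not in cache:
                    cache[key] = corem_pair_similarity(
                        sigs[key[0]].loc[conds], sigs[key[1]].loc[conds], cfg).similar
                return cache[key]

            for i, ci in enumerate(classes):
                for cj in classes[i:]:
                    if ci == cj:
                        pairs = [(a, b) for ai, a in enumerate(by_class[ci])
                                 for b in by_class[ci][ai + 1:]]
                    else:
                        pairs = [(a, b) for a in by_class[ci] for b in by_class[cj]]
                    if pairs:
                        frac = float(np.mean([similar(a, b) for a, b in pairs]))
                        mat.loc[ci, cj] = mat.loc[cj, ci] = frac
        result[cat] = mat
    return result
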