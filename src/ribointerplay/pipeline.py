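"""End-to-end orchestration: fixture generation, stage execution, reporting.

``make_fixture`` writes a complete synthetic input directory from a seed;
``run_all`` executes differential -> interplay -> stoichiometry -> corems ->
ppi on whatever inputs are present, skipping (and logging) stages whose
inputs are missing, and writes a plain-text report plus a machine-readable
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import corems as corems_mod
from . import interplay, ppi, stoichiometry, synthetic
from .config import PipelineConfig
from .datamodel import EdgeList, GeneAnnotation
from .differential import test_differential
from .io import read_table, write_table

log = logging.getLogger("ribointerplay")

FIXTURE_FILES = {
    "design": "design.tsv",
    "mrna_counts": "mrna_counts.tsv",
    "ribo_counts": "ribo_counts.tsv",
    "mrna_tpm": "mrna_tpm.tsv",
    "ribo_tpm": "ribo_tpm.tsv",
    "annotation": "annotation.tsv",
    "protein": "protein_intensity.tsv",
    "membership": "membership.tsv",
    "compendium": "compendium.tsv",
    "categories": "categories.tsv",
    "edges": "edges.tsv",
    "ppi_annotation": "ppi_annotation.tsv",
}

SCALES = {
    "tiny": dict(n_genes=300, n_rp=24, corem_genes=20, corem_sizes=(8, 6, 4, 2),
                 n_corems=24, n_conditions=60, ppi_nodes=36, ppi_modules=4,
                 n_permutations=10_000, n_bootstrap=200),
    "paper_like": dict(n_genes=2663, n_rp=50, corem_genes=54, corem_sizes=(38, 7, 6, 3),
                       n_corems=72, n_conditions=180, ppi_nodes=128, ppi_modules=7,
                       n_permutations=100_000, n_bootstrap=10_000),
}


def make_fixture(seed: int, scale: str, outdir: str | Path) -> Path:
    """Write a complete synthetic input set (plus truth tables) for one seed."""
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {sorted(SCALES)}")
    s = SCALES[scale]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    cfg = PipelineConfig(random_seed=seed, n_permutations=s["n_permutations"],
                         n_bootstrap=s["n_bootstrap"])
    cfg.to_yaml(outdir / "config.yaml")

    # paired counts
    params = synthetic.SimulationParams(n_genes=s["n_genes"], seed=cfg.stage_seed("counts"))
    truth = synthetic.make_truth(params)
    n_rp_genes = min(58, s["n_genes"])
    rp_rows = truth.index[: n_rp_genes]
    truth.loc[rp_rows, "is_rp"] = True
    design = synthetic.make_design(assays=("rna", "ribo", "protein"))
    mrna, ribo, mrna_tpm, ribo_tpm = synthetic.simulate_paired_counts(
        params, truth, design)
    annotation = pd.DataFrame({
        "gene_id": truth.index,
        "is_rp": truth["is_rp"].to_numpy(),
        "rp_name": [f"{'S' if i % 2 else 'L'}{i:02d}" if truth["is_rp"].iloc[i] else ""
                    for i in range(len(truth))],
        "operon_id": "",
    })
    annotation.loc[~annotation["is_rp"], "rp_name"] = pd.NA

    # proteomics
    sp = synthetic.StoichSimParams(n_rp=s["n_rp"], seed=cfg.stage_seed("proteomics"))
    protein, rp_truth = synthetic.simulate_rp_proteomics(sp, design)

    # corems
    membership, compendium, categories, corem_truth = synthetic.simulate_corems(
        n_genes=s["corem_genes"], n_corems=s["n_corems"], class_sizes=s["corem_sizes"],
        n_conditions=s["n_conditions"], seed=cfg.stage_seed("corems"))

    # ppi with roles and RP annotation for the TF-RP extraction
    edges, ppi_truth = synthetic.simulate_ppi(
        n_nodes=s["ppi_nodes"], n_modules=s["ppi_modules"], seed=cfg.stage_seed("ppi"))
    tab = edges.table.copy()
    baits = list(pd.unique(tab["bait"]))
    roles = {b: ("TBP" if i % 3 == 0 else "TFB" if i % 3 == 1 else "Bat")
             for i, b in enumerate(baits[:9])}
    tab["bait_role"] = tab["bait"].map(roles).fillna("other")
    edges = EdgeList(tab)
    prey_only = sorted(set(tab["prey"]) - set(roles))
    rp_nodes = prey_only[:10]
    ppi_annot = pd.DataFrame({
        "gene_id": sorted(set(tab["bait"]) | set(tab["prey"])),
    }).set_index("gene_id")
    ppi_annot["is_rp"] = ppi_annot.index.isin(rp_nodes)
    ppi_annot["rp_name"] = [f"{'S' if i % 2 else 'L'}{i + 1:02d}" if g in rp_nodes else pd.NA
                            for i, g in enumerate(ppi_annot.index)]
    ppi_annot["operon_id"] = ""

    write_table(design, outdir / FIXTURE_FILES["design"])
    write_table(mrna, outdir / FIXTURE_FILES["mrna_counts"])
    write_table(ribo, outdir / FIXTURE_FILES["ribo_counts"])
    write_table(mrna_tpm, outdir / FIXTURE_FILES["mrna_tpm"])
    write_table(ribo_tpm, outdir / FIXTURE_FILES["ribo_tpm"])
    annotation.to_csv(outdir / FIXTURE_FILES["annotation"], sep="\t", index=False, na_rep="NA")
    write_table(protein, outdir / FIXTURE_FILES["protein"])
    write_table(membership, outdir / FIXTURE_FILES["membership"])
    write_table(compendium, outdir / FIXTURE_FILES["compendium"])
    categories.to_csv(outdir / FIXTURE_FILES["categories"], sep="\t", index=False)
    tab.to_csv(outdir / FIXTURE_FILES["edges"], sep="\t", index=False)
    ppi_annot.to_csv(outdir / FIXTURE_FILES["ppi_annotation"], sep="\t", na_rep="NA")

    truth.to_csv(outdir / "truth" / "genes.tsv", sep="\t", na_rep="NA")
    rp_truth.to_csv(outdir / "truth" / "rp_offsets.tsv", sep="\t")
    corem_truth.rename_axis("gene_id").to_csv(outdir / "truth" / "corem_classes.tsv", sep="\t")
    ppi_truth.rename_axis("node").to_csv(outdir / "truth" / "ppi_modules.tsv", sep="\t")
    return outdir


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(input_dir: str | Path, output_dir: str | Path,
            config: PipelineConfig | None = None) -> dict:
    """Run every stage whose inputs exist; return the manifest dict."""
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    if config is None:
        cfg_path = input_dir / "config.yaml"
        config = PipelineConfig.from_yaml(cfg_path) if cfg_path.exists() else PipelineConfig()

    paths = {k: input_dir / v for k, v in FIXTURE_FILES.items()}
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "seed": config.random_seed,
        "inputs": {k: _sha256(p) for k, p in paths.items() if p.exists()},
        "stages": {},
        "outputs": [],
    }
    report: list[str] = ["ribointerplay pipeline report", "=" * 30, ""]

    def emit(name: str, obj) -> None:
        path = output_dir / name
        write_table(obj, path)
        manifest["outputs"].append(name)

    design = read_table(paths["design"], "design") if paths["design"].exists() else None

    # ---- differential + interplay ------------------------------------
    classification = None
    if design and paths["mrna_counts"].exists() and paths["ribo_counts"].exists():
        try:
            mrna = read_table(paths["mrna_counts"], "counts", design=design)
            ribo = read_table(paths["ribo_counts"], "counts", design=design)
            ref, alt = design.reference_time_point, design.time_points("rna")[-1]
            results = {}
            for assay, cm in (("rna", mrna), ("ribo", ribo)):
                cols_ref = design.samples_for(ref, assay)
                cols_alt = design.samples_for(alt, assay)
                res = test_differential(cm.data[cols_ref], cm.data[cols_alt],
                                        assay=assay,
                                        mean_count_floor=config.mean_count_floor)
                results[assay] = res
                emit(f"differential_{assay}.tsv", res.table)
            classification = interplay.classify_regulation(
                results["rna"], results["ribo"], config)
            emit("classification.tsv", classification)
            counts = classification["class"].value_counts()
            report += [f"[differential] contrast {alt} vs {ref}",
                       "class counts: " + ", ".join(f"{k}={v}" for k, v in counts.items()),
                       ""]
            manifest["stages"]["differential"] = "ok"
        except Exception as exc:  # pragma: no cover - stage-scoped failure path
            manifest["stages"]["differential"] = f"failed: {exc}"
            raise RuntimeError(f"stage differential failed: {exc}") from exc
    else:
        manifest["stages"]["differential"] = "skipped (missing inputs)"
        log.warning("differential stage skipped: inputs missing")

    if design and classification is not None and paths["mrna_tpm"].exists() \
            and paths["ribo_tpm"].exists():
        rna_tpm = read_table(paths["mrna_tpm"], "abundance")
        ribo_tpm = read_table(paths["ribo_tpm"], "abundance")
        ref = design.reference_time_point
        last = design.time_points("rna")[-1]
        te_ref = interplay.compute_te(rna_tpm, ribo_tpm, design, ref,
                                      average=config.replicate_average)
        fit = interplay.regress_te_on_abundance(te_ref)
        summary = pd.DataFrame([{
            "time_point": ref, "slope": fit.slope, "intercept": fit.intercept,
            "R": fit.r, "pvalue": fit.pvalue, "n": fit.n,
        }]).set_index("time_point")
        emit("te_regression.tsv", summary)
        te_last = interplay.compute_te(rna_tpm, ribo_tpm, design, last,
                                       average=config.replicate_average)
        fit_last = interplay.regress_te_on_abundance(te_last)
        bins = interplay.te_deviation_by_group(fit_last, classification, config)
        emit("te_deviation_bins.tsv", bins.set_index("bin"))

        perm_report = {}
        tl_up = classification.index[classification["class"] == "TL+"]
        if len(tl_up):
            abund = te_ref["tpm_rna"]
            res = interplay.permutation_abundance_test(
                list(tl_up), abund, n_perm=config.n_permutations,
                seed=config.stage_seed("permutation"), tail="lower")
            perm_report = res
            emit("permutation_tl_up.tsv", pd.DataFrame([res]).set_index("tail"))
        report += [f"[interplay] TE~abundance at {ref}: slope={fit.slope:.3f}, "
                   f"R={fit.r:.3f}, p={fit.pvalue:.3g}, n={fit.n}",
                   f"TL+ abundance permutation p={perm_report.get('pvalue', 'NA')}", ""]
        manifest["stages"]["interplay"] = "ok"
    else:
        manifest["stages"]["interplay"] = "skipped (missing inputs)"
        log.warning("interplay stage skipped: inputs missing")

    # ---- stoichiometry ----------------------------------------------
    if design and paths["protein"].exists():
        protein = read_table(paths["protein"], "protein", design=design)
        lfc = stoichiometry.protein_log2fc(protein)
        table = stoichiometry.stoichiometry_ratio(lfc, centering=config.sr_centering)
        table = stoichiometry.flag_deviant_rps(
            table, ci_level=config.ci_level, min_events=config.min_deviation_events,
            reference_tp=design.reference_time_point)
        emit("stoichiometry.tsv", table.set_index("rp_name"))
        flagged = stoichiometry.flagged_rps(table)
        report += ["[stoichiometry] flagged RPs: " + (", ".join(flagged) or "none"), ""]
        manifest["stages"]["stoichiometry"] = "ok"
    else:
        manifest["stages"]["stoichiometry"] = "skipped (missing inputs)"
        log.warning("stoichiometry stage skipped: inputs missing")

    # ---- corems ------------------------------------------------------
    if paths["membership"].exists() and paths["compendium"].exists() \
            and paths["categories"].exists():
        membership = read_table(paths["membership"], "membership")
        compendium = read_table(paths["compendium"], "compendium")
        categories = read_table(paths["categories"], "categories")
        assignment = corems_mod.bootstrap_cluster_support(
            membership, n_boot=config.n_bootstrap, seed=config.stage_seed("corems"),
            support_threshold=config.support_threshold)
        emit("corem_classes.tsv", assignment)
        sims = corems_mod.class_similarity_matrix(
            assignment, membership.drop_unassigned_genes(), compendium, categories, config)
        for cat, mat in sims.items():
            emit(f"class_similarity_{cat}.tsv", mat)
        n_classes = assignment.loc[assignment["class_label"] != "unassigned",
                                   "class_label"].nunique()
        report += [f"[corems] {n_classes} classes; "
                   f"{(assignment['class_label'] == 'unassigned').sum()} unassigned genes", ""]
        manifest["stages"]["corems"] = "ok"
    else:
        manifest["stages"]["corems"] = "skipped (missing inputs)"
        log.warning("corems stage skipped: inputs missing")

    # ---- ppi ---------------------------------------------------------
    if paths["edges"].exists():
        edges = read_table(paths["edges"], "edges")
        annot = (read_table(paths["ppi_annotation"], "annotation")
                 if paths["ppi_annotation"].exists() else None)
        net = ppi.build_network(edges, annot)
        modules = ppi.girvan_newman_modules(net)
        emit("ppi_modules.tsv", modules.to_frame().rename_axis("node"))
        line = (f"[ppi] {net.n_nodes} nodes, {net.n_edges} edges, "
                f"{modules.nunique()} modules")
        if net.rp_names:
            tf_rp, counts = ppi.extract_bait_prey_subnetwork(net)
            emit("tf_rp_edges.tsv", tf_rp.set_index("bait") if len(tf_rp) else tf_rp)
            line += f", {len(tf_rp)} TF-RP edges"
        report += [line, ""]
        manifest["stages"]["ppi"] = "ok"
    else:
        manifest["stages"]["ppi"] = "skipped (missing inputs)"
        log.warning("ppi stage skipped: inputs missing")

    (output_dir / "report.txt").write_text("\n".join(report))
    (output_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
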