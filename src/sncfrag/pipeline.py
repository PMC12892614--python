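"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order (simulate -> annotate -> profile -> diff ->
score -> cv -> coexpress -> diverge) and communicate only through their
declared output files in the output directory, so any subset can be re-run.
All randomness flows from a single master seed through named per-stage
substreams (adding a stage never perturbs earlier streams).  A manifest with
input hashes, seeds and versions is written at the end; identical
configuration and seed reproduce the bundle bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotation, coexpression, differential, divergence, landscape, risk
from .cohort import (CohortConfig, GeneMatrixConfig, generate_cohort,
                     generate_gene_matrix, read_gmt, write_gmt)
from .references import (ReferenceConfig, generate_references,
                         read_reference_fasta, write_reference_fasta)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "annotate", "profile", "diff", "score", "cv",
          "coexpress", "diverge")

DEFAULT_CONFIG = {
    "seed": 0,
    "alpha": 0.05,
    "eps": 0.01,
    "precedence": list(annotation.DEFAULT_PRECEDENCE),
    "denominator_policy": "retained_total",
    "signature_direction": None,       # None = both directions recorded
    "cv": {"k": 5, "rounds": 1000, "baseline_population": "train"},
    "coexpression": {"alpha": 0.05, "min_families": 20, "pair_p_threshold": 0.05},
    "plots": False,
    "synthetic": None,                 # synthetic-mode generator configs
    "inputs": None,                    # real-data input paths
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the master seed."""
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([int(master_seed), h])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load and schema-validate a pipeline configuration (YAML or JSON)."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key in user:
            if key not in DEFAULT_CONFIG:
                raise ValueError(f"unknown configuration key {key!r}")
        for key, val in user.items():
            if isinstance(cfg.get(key), dict) and isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        cfg[key] = val
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    if not 0 < cfg["alpha"] < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if cfg["eps"] <= 0:
        raise ValueError("eps must be > 0")
    if cfg["denominator_policy"] not in ("retained_total", "annotated_total"):
        raise ValueError("denominator_policy must be retained_total or annotated_total")
    if cfg["cv"]["k"] < 2 or cfg["cv"]["rounds"] < 1:
        raise ValueError("cv.k must be >= 2 and cv.rounds >= 1")
    if cfg["synthetic"] is None:
        inputs = cfg["inputs"]
        if inputs is None:
            raise ValueError("config needs either 'synthetic' or 'inputs'")
        for key in ("references", "reads_dir", "metadata"):
            if key not in inputs:
                raise ValueError(f"inputs.{key} is required in real-data mode")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(f"inputs.{key}: {inputs[key]} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages

def _write_reads(reads_by_sample: dict, reads_dir: Path) -> None:
    reads_dir.mkdir(parents=True, exist_ok=True)
    for sample, reads in reads_by_sample.items():
        annotation.write_collapsed_fasta(
            [(rid, seq, c) for rid, seq, c in reads], reads_dir / f"{sample}.fasta")


def stage_simulate(cfg: dict, out: Path) -> None:
    syn = cfg["synthetic"] or {}
    seed = stage_seed(cfg["seed"], "simulate")
    ref_cfg = ReferenceConfig(**{**syn.get("reference", {}), "seed": seed})
    refs = generate_references(ref_cfg)
    write_reference_fasta(refs, out / "references.fasta")

    cohort_kwargs = dict(syn.get("cohort", {}))
    effect = [tuple(e) if not isinstance(e, tuple) else e
              for e in cohort_kwargs.pop("effect_families", [])]
    cohort_cfg = CohortConfig(**cohort_kwargs, effect_families=tuple(
        (f, float(d), tuple(g)) for f, d, g in effect),
        seed=stage_seed(cfg["seed"], "simulate/cohortA"))
    cohort = generate_cohort(refs, cohort_cfg)
    cohort.metadata.to_csv(out / "metadata.tsv", sep="\t")
    _write_reads(cohort.to_reads(), out / "reads")

    truth = {
        "planted_up_families": sorted(cohort.truth.planted_up_families),
        "planted_effects": cohort.truth.planted_effects,
        "seeds_used": list(cohort.truth.seeds_used),
    }
    if syn.get("second_cohort") is not None:
        b_kwargs = dict(syn["second_cohort"])
        b_kwargs.setdefault("cohort_label", "cohortB")
        cohort_b = generate_cohort(refs, CohortConfig(
            **b_kwargs, seed=stage_seed(cfg["seed"], "simulate/cohortB")),
            template=cohort)
        cohort_b.metadata.to_csv(out / "metadata_b.tsv", sep="\t")
        _write_reads(cohort_b.to_reads(), out / "reads_b")
        truth["second_cohort"] = True
    if syn.get("genes") is not None:
        gene_cfg = GeneMatrixConfig(**{**syn["genes"],
                                       "seed": stage_seed(cfg["seed"], "simulate/genes")})
        expr, sets = generate_gene_matrix(cohort.truth, gene_cfg)
        expr.to_csv(out / "gene_matrix.tsv", sep="\t")
        write_gmt(sets, out / "gene_sets.gmt")
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def _annotate_one(refs, reads_dir: Path, metadata: pd.DataFrame,
                  cfg: dict, out: Path, suffix: str = "") -> None:
    reads_by_sample = {
        s: annotation.read_collapsed_fasta(reads_dir / f"{s}.fasta")
        for s in metadata.index}
    table = annotation.annotate_samples(reads_by_sample, refs,
                                        precedence=tuple(cfg["precedence"]))
    annotation.write_species_table(table, out / f"species_table{suffix}.tsv")
    fam_rpm, class_totals, denom = annotation.aggregate_families(
        table, cfg["denominator_policy"])
    fam_rpm.to_csv(out / f"family_rpm{suffix}.tsv", sep="\t")
    class_totals.to_csv(out / f"class_totals{suffix}.tsv", sep="\t")
    denom.rename("denominator").to_csv(out / f"denominators{suffix}.tsv", sep="\t")


def stage_annotate(cfg: dict, out: Path) -> None:
    if cfg["synthetic"] is not None:
        refs = read_reference_fasta(out / "references.fasta")
        meta = pd.read_csv(out / "metadata.tsv", sep="\t", index_col="sample_id")
        _annotate_one(refs, out / "reads", meta, cfg, out)
        if (out / "metadata_b.tsv").exists():
            meta_b = pd.read_csv(out / "metadata_b.tsv", sep="\t",
                                 index_col="sample_id")
            _annotate_one(refs, out / "reads_b", meta_b, cfg, out, suffix="_b")
    else:
        inputs = cfg["inputs"]
        refs = read_reference_fasta(inputs["references"])
        meta = pd.read_csv(inputs["metadata"], sep="\t", index_col="sample_id")
        meta.to_csv(out / "metadata.tsv", sep="\t")
        _annotate_one(refs, Path(inputs["reads_dir"]), meta, cfg, out)
        if inputs.get("second"):
            meta_b = pd.read_csv(inputs["second"]["metadata"], sep="\t",
                                 index_col="sample_id")
            meta_b.to_csv(out / "metadata_b.tsv", sep="\t")
            _annotate_one(refs, Path(inputs["second"]["reads_dir"]), meta_b,
                          cfg, out, suffix="_b")


def _load_core(out: Path):
    meta = pd.read_csv(out / "metadata.tsv", sep="\t", index_col="sample_id")
    fam_rpm = pd.read_csv(out / "family_rpm.tsv", sep="\t", index_col="family")
    class_totals = pd.read_csv(out / "class_totals.tsv", sep="\t", index_col=0)
    return meta, fam_rpm, class_totals


def _noncanonical(fam_rpm: pd.DataFrame) -> pd.DataFrame:
    from .cohort import class_of_family
    return fam_rpm[fam_rpm.index.map(class_of_family) != "miRNA"]


def _present_contrasts(meta: pd.DataFrame):
    return tuple((a, b) for a, b in landscape.DEFAULT_CONTRASTS
                 if (meta["group"] == a).any() and (meta["group"] == b).any())


def stage_profile(cfg: dict, out: Path) -> None:
    meta, fam_rpm, class_totals = _load_core(out)
    contrasts = _present_contrasts(meta)
    t_table, rho_table = landscape.class_total_tests(class_totals, meta, contrasts)
    t_table.to_csv(out / "class_tests.tsv", sep="\t", index=False)
    rho_table.to_csv(out / "class_correlations.tsv", sep="\t", index=False)

    species = annotation.read_species_table(out / "species_table.tsv")
    denom = pd.read_csv(out / "denominators.tsv", sep="\t", index_col=0)["denominator"]
    ld = landscape.length_distribution(species, denom, meta)
    ld.to_csv(out / "length_distribution.tsv", sep="\t", index=False)

    nc = _noncanonical(fam_rpm)
    pca, pca_tests = landscape.pca_categories(nc, meta, contrasts)
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    pca_tests.to_csv(out / "pca_pc1_tests.tsv", sep="\t", index=False)

    if (meta["group"] == "UC").any() and (meta["group"] == "CD").any():
        fc, rho, p = landscape.fold_change_concordance(nc, meta, eps=cfg["eps"])
        fc.to_csv(out / "fold_change.tsv", sep="\t")
        (out / "fold_change_summary.json").write_text(
            json.dumps({"spearman_rho": rho, "p": p}, indent=1))


def stage_diff(cfg: dict, out: Path) -> None:
    meta, fam_rpm, _ = _load_core(out)
    nc = _noncanonical(fam_rpm)
    mir = fam_rpm[~fam_rpm.index.isin(nc.index)]
    for label, matrix, direction in (
            ("", nc, cfg["signature_direction"]), ("_mirna", mir, None)):
        if matrix.empty:
            logger.warning("diff: no %s families, skipping",
                           "miRNA" if label else "noncanonical")
            continue
        tab_uc = differential.fit_all_families(matrix, meta, ("HC", "UC"))
        tab_cd = differential.fit_all_families(matrix, meta, ("HC", "CD"))
        tab_uc.to_csv(out / f"differential_HC_vs_UC{label}.tsv", sep="\t")
        tab_cd.to_csv(out / f"differential_HC_vs_CD{label}.tsv", sep="\t")
        sig = differential.derive_signature(tab_uc, tab_cd, alpha=cfg["alpha"],
                                            direction=direction)
        payload = {
            "alpha": cfg["alpha"],
            "contrasts": list(sig.contrasts),
            "entries": [
                {"family": f, "direction": d,
                 "p_bonferroni_uc": float(tab_uc.loc[f, "p_bonferroni"]),
                 "p_bonferroni_cd": float(tab_cd.loc[f, "p_bonferroni"])}
                for f, d in sig.entries],
        }
        (out / f"signature{label}.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True))


def _load_signature(path: Path, alpha: float) -> differential.Signature:
    payload = json.loads(path.read_text())
    return differential.Signature(
        entries=[(e["family"], e["direction"]) for e in payload["entries"]],
        contrasts=tuple(payload["contrasts"]), alpha=payload["alpha"])


def stage_score(cfg: dict, out: Path) -> None:
    meta, fam_rpm, _ = _load_core(out)
    log_expr = risk.log_expression(fam_rpm)
    core = meta.index[meta["group"].isin(["HC", "UC", "CD"])]
    summary: dict = {}
    scores = {}
    for label in ("", "_mirna"):
        sig_path = out / f"signature{label}.json"
        if not sig_path.exists():
            continue
        sig = _load_signature(sig_path, cfg["alpha"])
        if len(sig) == 0:
            logger.warning("score: empty signature%s, skipped", label)
            continue
        baseline = risk.compute_baseline(log_expr, core, sig)
        baseline.to_csv(out / f"risk_baseline{label}.tsv", sep="\t")
        s = risk.risk_scores(log_expr, baseline)
        scores[label] = s
        frame = meta.loc[s.index, ["group"]].assign(score=s)
        frame.to_csv(out / f"risk_scores{label}.tsv", sep="\t")
        for case in ("UC", "CD"):
            mask = meta["group"].isin(["HC", case])
            if not (meta.loc[mask, "group"] == case).any():
                continue
            auc, points = risk.roc_auc(
                s[meta.index[mask]].to_numpy(),
                (meta.loc[mask, "group"] == case).to_numpy())
            points.to_csv(out / f"roc_HC_vs_{case}{label}.tsv", sep="\t", index=False)
            summary[f"auc_hc_{case.lower()}{label}"] = auc
    if "" in scores and "_mirna" in scores:
        for case in ("UC", "CD"):
            mask = meta["group"].isin(["HC", case])
            ids = meta.index[mask]
            res = risk.delong_test(
                scores[""][ids].to_numpy(), scores["_mirna"][ids].to_numpy(),
                (meta.loc[ids, "group"] == case).to_numpy())
            summary[f"delong_hc_{case.lower()}"] = {
                "delta_auc": res.delta, "z": res.z, "p": res.p}
    (out / "risk_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


def stage_cv(cfg: dict, out: Path) -> None:
    meta, fam_rpm, _ = _load_core(out)
    nc = _noncanonical(fam_rpm)
    report = risk.cross_validate(
        nc, meta, k=cfg["cv"]["k"], rounds=cfg["cv"]["rounds"],
        alpha=cfg["alpha"], seed=stage_seed(cfg["seed"], "cv"),
        baseline_population=cfg["cv"]["baseline_population"],
        direction=cfg["signature_direction"])
    (out / "cv_report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True))
    if cfg["plots"]:
        from .plots import cv_auc_histogram
        cv_auc_histogram(report, out / "cv_auc_histogram.png")


def stage_coexpress(cfg: dict, out: Path) -> None:
    gene_path = out / "gene_matrix.tsv"
    if cfg["synthetic"] is None and cfg["inputs"].get("gene_matrix"):
        gene_path = Path(cfg["inputs"]["gene_matrix"])
    if not gene_path.exists():
        logger.warning("coexpress: gene matrix not available, stage skipped")
        return
    meta, fam_rpm, _ = _load_core(out)
    genes = pd.read_csv(gene_path, sep="\t", index_col=0)
    nc = _noncanonical(fam_rpm)
    cc = cfg["coexpression"]
    table = coexpression.spearman_pair_table(risk.log_expression(nc), genes)
    table[table["p_bh"] < cc["pair_p_threshold"]].to_csv(
        out / "coexpression_pairs.tsv", sep="\t", index=False)
    pos, neg, counts = coexpression.select_coexpressed_genes(
        table, alpha=cc["alpha"], min_families=cc["min_families"])
    counts.to_csv(out / "coexpressed_gene_counts.tsv", sep="\t")
    (out / "coexpressed_genes.json").write_text(json.dumps(
        {"positive": sorted(pos), "negative": sorted(neg)}, indent=1))

    gmt_path = out / "gene_sets.gmt"
    if cfg["synthetic"] is None and cfg["inputs"].get("gene_sets"):
        gmt_path = Path(cfg["inputs"]["gene_sets"])
    if gmt_path.exists():
        sets = read_gmt(gmt_path)
        universe = set(genes.index)
        for name, lst in (("positive", pos), ("negative", neg)):
            if lst:
                enr = coexpression.hypergeometric_enrichment(lst, sets, universe)
                enr.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
        scores = coexpression.faime_scores(genes, sets)
        scores.to_csv(out / "pathway_scores.tsv", sep="\t")
        contrasts = _present_contrasts(meta)
        tests = coexpression.pathway_group_comparison(scores, meta, contrasts)
        tests.to_csv(out / "pathway_tests.tsv", sep="\t", index=False)
    else:
        logger.warning("coexpress: no gene sets (GMT), enrichment/pathway "
                       "scoring skipped")


def stage_diverge(cfg: dict, out: Path) -> None:
    if not (out / "family_rpm_b.tsv").exists():
        logger.warning("diverge: no second cohort available, stage skipped")
        return
    meta, fam_rpm, _ = _load_core(out)
    meta_b = pd.read_csv(out / "metadata_b.tsv", sep="\t", index_col="sample_id")
    fam_b = pd.read_csv(out / "family_rpm_b.tsv", sep="\t", index_col="family")
    table, summary = divergence.divergence_table(fam_rpm, meta, fam_b, meta_b,
                                                 eps=cfg["eps"])
    table.to_csv(out / "divergence.tsv", sep="\t")
    (out / "divergence_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=1, sort_keys=True))


_STAGE_FUNCS = {
    "simulate": stage_simulate, "annotate": stage_annotate,
    "profile": stage_profile, "diff": stage_diff, "score": stage_score,
    "cv": stage_cv, "coexpress": stage_coexpress, "diverge": stage_diverge,
}


def run_pipeline(cfg: dict, out_dir, stages=STAGES) -> dict:
    """Run the requested stages and write the reproducibility manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ran = []
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        if stage == "simulate" and cfg["synthetic"] is None:
            logger.info("simulate: real-data mode, stage skipped")
            continue
        logger.info("running stage %s", stage)
        _STAGE_FUNCS[stage](cfg, out)
        ran.append(stage)
    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "stage_seeds": {s: stage_seed(cfg["seed"], s) for s in STAGES},
        "config": cfg,
        "stages_run": ran,
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
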