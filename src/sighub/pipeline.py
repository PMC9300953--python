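"""End-to-end orchestration: fixtures, full runs, reproducibility manifest.

A run is driven by a single declarative config (YAML on disk, dict in
memory).  Stages execute in order — discovery, validation, microenvironment,
genomic context — each writing its outputs before the next starts; the
manifest records input checksums, every parameter, and the per-stage gene
funnel so a run is reproducible and auditable.  Defaults mirror the
published analysis parameters: 50:50 stratification, 0.2 contrast floor,
alpha 0.05, dependency thresholds -0.5 (<=) and -3 (strict <).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .context import coessential_signaling, filter_dependent_lines, \
    mutation_frequency_by_group
from .discovery import build_hub_signature
from .errors import ParameterError, SighubError
from .microenv import estimate_like_scores, group_marker_contrast, \
    marker_correlation_matrix, score_group_comparison
from .discovery import stratify_by_seed
from .synthetic import CohortParams, generate_cohort, \
    generate_dependency_table, generate_mutation_table
from .validation import cross_dataset_coexpression, validate_signature

__all__ = ["RunConfig", "run_all", "make_fixture", "FIXTURE_PRESETS"]


@dataclass
class RunConfig:
    """Declarative configuration for :func:`run_all`."""

    expression: str
    clinical: str
    annotation: str
    seed_gene: str
    out_dir: str
    percentile: float = 50.0
    min_rho_high: float = 0.2
    alpha: float = 0.05
    p_adjust: str = "raw"
    score_method: str = "zscore"
    include_seed: bool = True
    ks_map: str | None = None
    validation_expression: str | None = None
    validation_clinical: str | None = None
    markers: str | None = None
    gene_sets: str | None = None
    mutations: str | None = None
    dependencies: str | None = None
    dep_threshold_lines: float = -0.5
    dep_threshold_essential: float = -3.0
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _km_frame(curve) -> pd.DataFrame:
    return pd.DataFrame({"time": curve.times, "survival": curve.survival,
                         "at_risk": curve.at_risk, "n_events": curve.n_events})


def run_all(config: RunConfig) -> dict:
    """Execute every configured stage; returns the manifest dict.

    Any stage failure raises :class:`SighubError` naming the stage; outputs
    written by earlier stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "inputs": {}, "parameters": {
        k: getattr(config, k) for k in config.__dataclass_fields__}}
    for key in ("expression", "clinical", "annotation", "ks_map",
                "validation_expression", "validation_clinical", "markers",
                "gene_sets", "mutations", "dependencies"):
        path = getattr(config, key)
        if path:
            if not Path(path).exists():
                raise ParameterError(f"input path missing: {key}={path}")
            manifest["inputs"][key] = {"path": str(path),
                                       "sha256": _sha256(path)}

    stage = "discovery"
    try:
        expr = sio.read_expression(config.expression)
        clinical = sio.read_clinical(config.clinical)
        annotation = sio.read_annotation(config.annotation)
        overlap = sio.check_sample_overlap(expr, clinical)
        ks_map = (sio.read_kinase_substrates(config.ks_map)
                  if config.ks_map else None)
        signature = build_hub_signature(
            expr, clinical, annotation, config.seed_gene,
            percentile=config.percentile, min_rho_high=config.min_rho_high,
            alpha=config.alpha, ks_map=ks_map, p_adjust=config.p_adjust)
        signature.to_tsv(out / "signature.tsv")
        with open(out / "provenance.json", "w") as fh:
            json.dump(signature.provenance, fh, indent=2, sort_keys=True)
        manifest["stages"].append({
            "name": stage, "funnel": signature.provenance["funnel"],
            "n_partners": len(signature),
            "samples_clinical_only": len(overlap["clinical_only"]),
            "outputs": ["signature.tsv", "provenance.json"]})
    except Exception as exc:
        _fail(manifest, out, stage, exc)

    stage = "validation"
    try:
        results = {}
        if len(signature):
            results["discovery_cohort"] = validate_signature(
                expr, clinical, signature, include_seed=config.include_seed,
                method=config.score_method)
            if config.validation_expression and config.validation_clinical:
                vexpr = sio.read_expression(config.validation_expression)
                vclin = sio.read_clinical(config.validation_clinical)
                results["validation_cohort"] = validate_signature(
                    vexpr, vclin, signature,
                    include_seed=config.include_seed,
                    method=config.score_method)
                cross = pd.DataFrame({
                    "discovery": cross_dataset_coexpression(
                        expr, signature),
                    "validation": cross_dataset_coexpression(
                        vexpr, signature)})
                cross.to_csv(out / "cross_cohort_rho.tsv", sep="\t")
            summary = {}
            for name, res in results.items():
                res.scores.to_csv(out / f"risk_scores_{name}.tsv", sep="\t")
                _km_frame(res.km_low).to_csv(
                    out / f"km_low_{name}.tsv", sep="\t", index=False)
                _km_frame(res.km_high).to_csv(
                    out / f"km_high_{name}.tsv", sep="\t", index=False)
                summary[name] = {
                    "beta": res.cox.beta, "hr": res.cox.hr,
                    "ci95": list(res.cox.ci95), "p": res.cox.p_value,
                    "logrank_p": res.logrank.p_value,
                    "n_genes_used": res.n_genes_used,
                    "genes_missing": res.genes_missing,
                    "converged": res.cox.converged}
            with open(out / "cox_summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
            manifest["stages"].append({
                "name": stage, "cohorts": sorted(results),
                "outputs": ["cox_summary.json"]})
        else:
            manifest["stages"].append({"name": stage, "skipped":
                                       "empty signature"})
    except Exception as exc:
        _fail(manifest, out, stage, exc)

    stage = "microenvironment"
    try:
        if config.markers or config.gene_sets:
            low_ids, high_ids = stratify_by_seed(expr, config.seed_gene,
                                                 config.percentile)
            outputs = []
            if config.markers:
                panel = {row["gene"]: row["cell_type"] for _, row in
                         pd.read_csv(config.markers, sep="\t").iterrows()}
                genes = ([signature.seed_gene] + signature.genes
                         if len(signature) else [signature.seed_gene])
                marker_correlation_matrix(expr, genes, panel).to_csv(
                    out / "marker_rho.tsv", sep="\t")
                group_marker_contrast(expr, low_ids, high_ids,
                                      config.seed_gene, panel).to_csv(
                    out / "marker_contrast.tsv", sep="\t")
                outputs += ["marker_rho.tsv", "marker_contrast.tsv"]
            if config.gene_sets:
                sets = sio.read_gene_sets(config.gene_sets)
                scores = estimate_like_scores(expr, sets)
                scores.to_csv(out / "enrichment_scores.tsv", sep="\t")
                comparisons = {
                    name: {"p": (r := score_group_comparison(
                        scores[name], low_ids, high_ids)).p_value,
                        "statistic": r.statistic,
                        "direction": r.extra["direction"]}
                    for name in scores.columns}
                with open(out / "enrichment_comparison.json", "w") as fh:
                    json.dump(comparisons, fh, indent=2, sort_keys=True)
                outputs += ["enrichment_scores.tsv",
                            "enrichment_comparison.json"]
            manifest["stages"].append({"name": stage, "outputs": outputs})
        else:
            manifest["stages"].append({"name": stage, "skipped":
                                       "no marker panel or gene sets"})
    except Exception as exc:
        _fail(manifest, out, stage, exc)

    stage = "context"
    try:
        if config.mutations or config.dependencies:
            outputs = []
            low_ids, high_ids = stratify_by_seed(expr, config.seed_gene,
                                                 config.percentile)
            if config.mutations:
                mut = sio.read_mutations(config.mutations)
                freq = mutation_frequency_by_group(
                    mut, low_ids, high_ids, sorted(mut["gene"].unique()))
                freq.to_csv(out / "mutation_frequencies.tsv", sep="\t",
                            index=False)
                outputs.append("mutation_frequencies.tsv")
            if config.dependencies:
                dep = sio.read_dependencies(config.dependencies)
                hits = coessential_signaling(
                    dep, annotation, config.dep_threshold_essential)
                hits.to_csv(out / "coessential_signaling.tsv", sep="\t",
                            index=False)
                if config.seed_gene in set(dep["gene"]):
                    lines = filter_dependent_lines(
                        dep, config.seed_gene, config.dep_threshold_lines)
                    (out / "dependent_lines.txt").write_text(
                        "\n".join(lines) + "\n")
                    outputs.append("dependent_lines.txt")
                outputs.append("coessential_signaling.tsv")
            manifest["stages"].append({"name": stage, "outputs": outputs})
        else:
            manifest["stages"].append({"name": stage, "skipped":
                                       "no mutation or dependency input"})
    except Exception as exc:
        _fail(manifest, out, stage, exc)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _fail(manifest: dict, out: Path, stage: str, exc: Exception):
    manifest["stages"].append({"name": stage, "error": str(exc)})
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    raise SighubError(f"stage {stage!r} failed: {exc}") from exc


#: fixture presets: small complete cohorts with known ground truth
FIXTURE_PRESETS = {
    "null": CohortParams(n_samples=200, n_genes=400, n_partners=0,
                         rho_high=0.0, rho_low=0.0, beta=0.0,
                         censor_frac=0.3),
    "planted_hub": CohortParams(n_samples=200, n_genes=400, n_partners=12,
                                rho_high=0.55, rho_low=0.05, beta=1.2,
                                censor_frac=0.3),
    "planted_hub_with_validation": CohortParams(
        n_samples=200, n_genes=400, n_partners=12, rho_high=0.55,
        rho_low=0.05, beta=1.2, censor_frac=0.3),
}


def make_fixture(out_dir, preset: str, rng_seed: int = 0) -> dict:
    """Write a complete small cohort (expression/clinical/annotation, plus
    mutation and dependency tables) for tests and documentation.

    ``planted_hub_with_validation`` also writes a second, independent
    cohort sharing the planted hub.  Returns the written paths.
    """
    if preset not in FIXTURE_PRESETS:
        raise ParameterError(f"unknown preset {preset!r}; choose from "
                             f"{sorted(FIXTURE_PRESETS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = FIXTURE_PRESETS[preset]
    params = CohortParams(**{**base.__dict__, "rng_seed": rng_seed})
    expr, clinical, annotation, truth = generate_cohort(params)
    paths = {
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "annotation": out / "annotation.tsv",
        "truth": out / "truth.json",
    }
    sio.write_expression(expr, paths["expression"])
    sio.write_clinical(clinical, paths["clinical"])
    sio.write_annotation(annotation, paths["annotation"])
    mut = generate_mutation_table(
        params.n_samples, ["M001", "M002", "M003"], 0.02, 0.2,
        truth.high_samples, rng_seed + 1)
    paths["mutations"] = out / "mutations.tsv"
    sio.write_mutations(mut, paths["mutations"])
    lines = [f"CL{i:02d}" for i in range(1, 9)]
    dep_genes = sorted(truth.partner_genes)[:4] + ["G000399", "G000400"]
    planted = {(g, lines[0]): -3.5 for g in dep_genes[:2]}
    dep = generate_dependency_table(lines, dep_genes or ["G000001"],
                                    planted if dep_genes else {},
                                    0.8, rng_seed + 2)
    paths["dependencies"] = out / "dependencies.tsv"
    sio.write_dependencies(dep, paths["dependencies"])
    truth_payload = {
        "seed_gene": truth.seed_gene,
        "partner_genes": sorted(truth.partner_genes),
        "high_samples": sorted(truth.high_samples),
        "params": {k: v for k, v in params.__dict__.items()},
    }
    if preset == "planted_hub_with_validation":
        vparams = CohortParams(**{**base.__dict__,
                                  "rng_seed": rng_seed + 10_000})
        vexpr, vclin, _, _ = generate_cohort(vparams)
        paths["validation_expression"] = out / "validation_expression.tsv"
        paths["validation_clinical"] = out / "validation_clinical.tsv"
        sio.write_expression(vexpr, paths["validation_expression"])
        sio.write_clinical(vclin, paths["validation_clinical"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth_payload, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
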