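"""End-to-end orchestration: simulate -> QC -> normalize -> differential ->
classify -> identify -> proteomics -> enrichment -> network.

A single :class:`PipelineConfig` carries every stage threshold with the
study defaults (CV 50%, blank ratio 5, S/N 3, peak width 6 scans;
fold-change tiers 2 for metabolites, 1.5 for proteins, 2 for clearance;
p and FDR 0.05; 1/2 ppm mass tolerance; MS2 score 0.7) and a master seed.
``run_pipeline`` writes per-stage TSVs, a JSON summary and a log into a
run directory, and returns the summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import FeatureTable
from .cytotox import fit_four_param_logistic
from .dialysis_classifier import classify_table, summarize_categories
from .differential_stats import normalize_intensities, run_contrasts
from .enrichment import enrich_all, write_gmt
from .feature_qc import FilterThresholds, apply_feature_filters
from .identification import match_feature_to_standard
from .network import build_disease_network, export_graph, write_edges
from .proteomics_quant import test_differential_proteins
from .synthetic_data import (
    SynthConfig,
    generate_association_edges,
    generate_cohort,
    generate_dose_response,
    generate_pathway_sets,
    generate_reference_library,
    generate_tmt_proteome,
    perturb_spectrum,
    synthetic_spectrum,
)

logger = logging.getLogger("uremia_omics")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, defaulting to the study thresholds."""

    seed: int = 0
    # synthetic cohort
    synth: SynthConfig = field(default_factory=SynthConfig)
    # feature QC
    cv_max: float = 50.0
    blank_ratio_min: float = 5.0
    snr_min: float = 3.0
    peak_width_min: float = 6.0
    # differential / classification
    fc_min: float = 2.0
    clear_fc: float = 2.0
    alpha: float = 0.05
    q_alpha: float = 0.05
    # identification
    rt_window: float = 2.0
    ppm_tol_pos: float = 1.0
    ppm_tol_neg: float = 2.0
    score_min: float = 0.7
    spectrum_jitter_da: float = 0.005
    spectrum_drop_frac: float = 0.1
    # proteomics
    protein_fc_min: float = 1.5
    n_proteins: int = 600
    n_diff_proteins: int = 83
    protein_fc: float = 2.0
    protein_noise_sigma: float = 0.2
    # network / enrichment
    edge_score_min: float = 0.4
    edge_density: float = 0.002
    # cytotoxicity
    ic50_uM: float = 30.0
    dose_noise_sd: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        return cls(synth=synth, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full synthetic-cohort analysis; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _stage(name):
    logger.info("stage: %s", name)


def _run(config: PipelineConfig, out: Path) -> dict:
    logger.info("uremia-omics %s, seed %d", __version__, config.seed)
    logger.info("thresholds: %s", json.dumps(config.to_dict(), default=str))

    _stage("simulate")
    synth = config.synth
    synth.seed = config.seed
    standards = generate_reference_library()
    table, truth = generate_cohort(synth, standards=standards)
    table.to_tsv(out / "features.tsv", out / "samples.tsv")
    truth.to_csv(out / "ground_truth.tsv", sep="\t")

    _stage("feature_qc")
    thresholds = FilterThresholds(
        cv_max=config.cv_max, blank_ratio_min=config.blank_ratio_min,
        snr_min=config.snr_min, peak_width_min=config.peak_width_min,
    )
    filtered, qc_report = apply_feature_filters(table, thresholds)
    logger.info("QC: %d/%d features survive", qc_report.n_surviving, qc_report.n_input)

    _stage("normalize+differential")
    normalized = normalize_intensities(filtered, method="median")
    records = run_contrasts(
        normalized, fc_min=config.fc_min, alpha=config.alpha, q_alpha=config.q_alpha
    )
    records.to_csv(out / "differential.tsv", sep="\t")

    _stage("classify")
    categories = classify_table(
        records, elev_fc=config.fc_min, clear_fc=config.clear_fc,
        alpha=config.alpha, q_alpha=config.q_alpha,
    )
    categories.to_frame().to_csv(out / "categories.tsv", sep="\t")
    summary_cat = summarize_categories(categories)

    _stage("identify")
    by_name = {s.name: s for s in standards}
    id_rows = []
    planted = truth["planted_identity"]
    jitter_seed = config.seed + 1
    for feature_id, name in planted[planted != ""].items():
        if feature_id not in filtered.features.index:
            continue
        std = by_name[name]
        spec = perturb_spectrum(
            synthetic_spectrum(name, std.observed_mz, std.mode),
            jitter_da=config.spectrum_jitter_da,
            drop_frac=config.spectrum_drop_frac,
            seed=jitter_seed,
        )
        jitter_seed += 1
        row = filtered.features.loc[feature_id]
        m = match_feature_to_standard(
            feature_id, row["mz"], row["rt_min"], row["mode"], spec, std,
            rt_window=config.rt_window, ppm_tol_pos=config.ppm_tol_pos,
            ppm_tol_neg=config.ppm_tol_neg, score_min=config.score_min,
        )
        id_rows.append({
            "feature_id": m.feature_id, "standard": m.standard_name,
            "ppm_error": m.ppm_error, "rt_delta": m.rt_delta,
            "ms2_score": m.ms2_score, "confirmed": m.confirmed,
        })
    matches = pd.DataFrame(id_rows)
    matches.to_csv(out / "identifications.tsv", sep="\t", index=False)
    n_confirmed = int(matches["confirmed"].sum()) if len(matches) else 0

    _stage("proteomics")
    proteome, protein_truth = generate_tmt_proteome(
        n_proteins=config.n_proteins, n_diff=config.n_diff_proteins,
        fc=config.protein_fc, noise_sigma=config.protein_noise_sigma,
        seed=config.seed + 1000,
    )
    proteome.to_tsv(out / "proteins.tsv", out / "channels.tsv")
    protein_records = test_differential_proteins(
        proteome, fc_min=config.protein_fc_min,
        alpha=config.alpha, q_alpha=config.q_alpha,
    )
    protein_records.to_csv(out / "protein_differential.tsv", sep="\t")
    diff_proteins = protein_records.index[
        protein_records["flag_pre_ctrl"] != "ns"
    ].tolist()

    _stage("enrichment")
    elevated = categories.index[categories.isin(["I", "II"])].tolist()
    identified = planted[planted != ""]
    universe = [f for f in identified.index if f in records.index]
    query = [f for f in elevated if f in universe]
    pathways = generate_pathway_sets(
        universe_ids=universe,
        planted_members=query[: max(3, len(query) // 3)] if query else universe[:3],
        seed=config.seed + 2000,
    )
    write_gmt(pathways, out / "pathways.gmt")
    from .enrichment import read_gmt
    enrichment = (
        enrich_all(set(query), read_gmt(out / "pathways.gmt"), set(universe))
        if query else pd.DataFrame()
    )
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    _stage("network")
    planted_pairs = [(m, p) for m, p in zip(elevated[:20], diff_proteins[:20])]
    edges = generate_association_edges(
        metabolite_ids=elevated, protein_ids=list(protein_records.index),
        density=config.edge_density, planted_pairs=planted_pairs,
        seed=config.seed + 3000,
    )
    write_edges(edges, out / "edges.tsv")
    net = build_disease_network(
        elevated, {p: ("down" if protein_records.loc[p, "flag_pre_ctrl"] == "down"
                       else "up") for p in diff_proteins},
        [e for e in edges if e.score >= config.edge_score_min],
        include_neighbors=True,
        metabolite_categories=categories.to_dict(),
    )
    export_graph(net, out / "network.sif", fmt="sif")
    export_graph(net, out / "network.graphml", fmt="graphml")

    _stage("cytotox")
    dr = generate_dose_response(
        ic50=config.ic50_uM, noise_sd=config.dose_noise_sd,
        seed=config.seed + 4000, compound="synthetic_toxin",
    )
    dr.to_csv(out / "dose_response.csv")
    fit = fit_four_param_logistic(dr)

    summary = {
        "seed": config.seed,
        "n_features_input": qc_report.n_input,
        "n_features_surviving_qc": qc_report.n_surviving,
        "category_counts": summary_cat.counts,
        "category_total_changed": summary_cat.total_changed,
        "category_fractions_percent": summary_cat.fractions,
        "n_standards_tested": len(matches),
        "n_standards_confirmed": n_confirmed,
        "n_differential_proteins": len(diff_proteins),
        "n_network_nodes": net.number_of_nodes(),
        "n_network_edges": net.number_of_edges(),
        "top_pathway": (enrichment.iloc[0]["pathway"] if len(enrichment) else None),
        "ic50_fit_uM": fit.ic50,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("done: %s", json.dumps(summary))
    return summary
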