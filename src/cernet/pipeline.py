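"""End-to-end orchestration: simulate/load → filter → DE → screen → export.

The stage order mirrors the analysis funnel: lncRNA identification,
TPM conversion, expressed-transcript filtering, threshold DE
classification (mRNA and lncRNA modes; miRNAs are taken as an
already-selected set), the three-layer correlation screen, triplet
assembly, optional enrichment and morphometric statistics. Every run
writes a manifest (package/library versions, config hash, seed,
per-stage row counts) and a machine-readable ``summary.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .diffexpr import (
    LNCRNA_THRESHOLDS,
    MRNA_THRESHOLDS,
    DEThresholds,
    audit_de,
    classify_de,
    counts_to_tpm,
    de_counts,
    de_records_to_frame,
    expressed_filter,
    read_external_stats,
    simple_de_test,
)
from .enrichment import enrichment_to_frame, fisher_enrich
from .io import (
    ExpressionMatrix,
    ValidationError,
    read_expression_matrix,
    read_group_table,
    read_measurement_table,
    read_pair_whitelist,
    read_term_annotations,
    read_transcript_records,
    write_expression_matrix,
)
from .lncrna import identify_lncrnas
from .model import CeRNAScreen
from .morphometrics import compare_groups, comparisons_to_frame
from .network import audit_triplets
from .simulate import (
    PlantedTruth,
    SimulationConfig,
    generate_bundle,
    synthetic_annotations,
    synthetic_morphometrics,
    truth_confusion,
    write_bundle,
)

logger = logging.getLogger("cernet")

DEFAULT_THRESHOLDS: dict[str, Any] = {
    "tpm_expressed": 0.01,
    "mrna": {"fc_min": 2.0, "use_fdr": True, "alpha": 0.05},
    "lncrna": {"fc_min": 1.5, "use_fdr": False, "alpha": 0.05},
    "rho_max": -0.5,
    "edge_alpha": 0.05,
    "r_min": 0.85,
}


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("pipeline config must be a mapping")
    return cfg


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _merge_thresholds(overrides: Optional[Mapping]) -> dict:
    merged = json.loads(json.dumps(DEFAULT_THRESHOLDS))
    for key, val in (overrides or {}).items():
        if isinstance(val, Mapping) and key in merged:
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _de_select(tpm: ExpressionMatrix, expressed: set[str], thresholds: DEThresholds,
               biotype: str, external: Optional[pd.DataFrame]) -> tuple[list, pd.DataFrame]:
    feats = [f for f in tpm.feature_ids if f in expressed]
    if external is not None:
        stats_tab = external.loc[[f for f in feats if f in external.index]].copy()
    else:
        stats_tab = simple_de_test(tpm, feats)
    records = classify_de(stats_tab, thresholds, biotype=biotype)
    audit_de(records, thresholds)
    return records, de_records_to_frame(records)


def run_pipeline(config: Mapping | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute the full pipeline from a config mapping or YAML path.

    Returns the run directory. Any stage error aborts with the stage name
    in the exception message.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    if "seed" not in config:
        raise ValidationError("config must set 'seed'")
    seed = int(config["seed"])
    rundir = Path(outdir or config.get("outdir", "cernet_run"))
    rundir.mkdir(parents=True, exist_ok=True)
    thr = _merge_thresholds(config.get("thresholds"))
    counts_log: dict[str, Any] = {}
    stage = "setup"

    try:
        # ------------------------------------------------------------------
        stage = "simulate/load"
        truth: Optional[PlantedTruth] = None
        if "simulate" in config:
            sim_cfg = SimulationConfig(seed=seed, **(config["simulate"] or {}))
            bundle = generate_bundle(sim_cfg)
            write_bundle(bundle, rundir / "inputs")
            lnc_counts, mir_counts, mrna_counts = bundle.lnc, bundle.mir, bundle.mrna
            records, truth = bundle.records, bundle.truth
            lengths = bundle.lengths()
            lnc_mir_cand = bundle.lnc_mir_candidates
            mir_mrna_cand = bundle.mir_mrna_candidates
        else:
            paths = config["inputs"]
            groups = read_group_table(paths["groups"])
            lnc_counts = read_expression_matrix(paths["lnc_counts"], "count", groups)
            mir_counts = read_expression_matrix(paths["mir_counts"], "count", groups)
            mrna_counts = read_expression_matrix(paths["mrna_counts"], "count", groups)
            records = read_transcript_records(paths["records"])
            lengths = {r.id: r.length_bp for r in records}
            lnc_mir_cand = read_pair_whitelist(paths["lnc_mir_candidates"]) \
                if paths.get("lnc_mir_candidates") else None
            mir_mrna_cand = read_pair_whitelist(paths["mir_mrna_candidates"]) \
                if paths.get("mir_mrna_candidates") else None
        counts_log["input_features"] = {
            "lnc": len(lnc_counts.feature_ids), "mir": len(mir_counts.feature_ids),
            "mrna": len(mrna_counts.feature_ids)}

        # ------------------------------------------------------------------
        stage = "filter-lncrna"
        lnc_candidates = [r for r in records if r.biotype in ("lncRNA", "novel")
                          and r.id in set(lnc_counts.feature_ids)]
        kept = identify_lncrnas(lnc_candidates) if lnc_candidates else []
        lnc_counts = lnc_counts.subset([r.id for r in kept])
        counts_log["lncrna_identified"] = len(kept)

        # ------------------------------------------------------------------
        stage = "tpm"
        lnc_tpm = counts_to_tpm(lnc_counts, lengths)
        mir_tpm = counts_to_tpm(mir_counts, lengths)
        mrna_tpm = counts_to_tpm(mrna_counts, lengths)
        for name, m in (("lnc_tpm", lnc_tpm), ("mir_tpm", mir_tpm), ("mrna_tpm", mrna_tpm)):
            write_expression_matrix(m, rundir / f"{name}.tsv")

        stage = "expressed-filter"
        tpm_floor = float(thr["tpm_expressed"])
        per_group_mrna, expressed_mrna = expressed_filter(mrna_tpm, tpm_floor)
        per_group_lnc, expressed_lnc = expressed_filter(lnc_tpm, tpm_floor)
        counts_log["expressed"] = {
            "mrna_LE": len(per_group_mrna["LE"]), "mrna_HE": len(per_group_mrna["HE"]),
            "mrna_both": len(expressed_mrna),
            "lnc_LE": len(per_group_lnc["LE"]), "lnc_HE": len(per_group_lnc["HE"]),
            "lnc_both": len(expressed_lnc)}

        # ------------------------------------------------------------------
        stage = "diffexpr"
        ext = config.get("external_stats") or {}
        mrna_thr = DEThresholds(**thr["mrna"])
        lnc_thr = DEThresholds(**thr["lncrna"])
        mrna_de, mrna_tab = _de_select(
            mrna_tpm, expressed_mrna, mrna_thr, "mRNA",
            read_external_stats(ext["mrna"]) if ext.get("mrna") else None)
        lnc_de, lnc_tab = _de_select(
            lnc_tpm, expressed_lnc, lnc_thr, "lncRNA",
            read_external_stats(ext["lncrna"]) if ext.get("lncrna") else None)
        mrna_tab.to_csv(rundir / "de_mrna.tsv", sep="\t", index=False, float_format="%.6g")
        lnc_tab.to_csv(rundir / "de_lncrna.tsv", sep="\t", index=False, float_format="%.6g")
        de_mrna_ids = {r.feature_id for r in mrna_de if r.status != "ns"}
        de_lnc_ids = {r.feature_id for r in lnc_de if r.status != "ns"}
        counts_log["de"] = {"mrna": de_counts(mrna_de), "lncrna": de_counts(lnc_de)}

        # ------------------------------------------------------------------
        stage = "correlate/cerna"
        de_filter = bool(config.get("de_filter", True))
        sel_lnc = lnc_tpm.subset(de_lnc_ids if de_filter else expressed_lnc)
        sel_mrna = mrna_tpm.subset(de_mrna_ids if de_filter else expressed_mrna)
        screen = CeRNAScreen(
            sel_lnc, mir_tpm, sel_mrna,
            lnc_mir_candidates=lnc_mir_cand, mir_mrna_candidates=mir_mrna_cand,
            rho_max=float(thr["rho_max"]), alpha=float(thr["edge_alpha"]),
            r_min=float(thr["r_min"]))
        results = screen.fit()
        audit_triplets(results.triplets, screen.rho_max, screen.alpha, screen.r_min)
        results.edges_frame().to_csv(rundir / "edges_screened.tsv", sep="\t",
                                     index=False, float_format="%.6g")
        results.export(rundir / "network_edges.tsv", rundir / "sankey.json",
                       rundir / "triplets.tsv")
        net_counts = results.counts()
        counts_log["network"] = net_counts

        # ------------------------------------------------------------------
        stage = "enrich"
        enr_cfg = config.get("enrichment")
        enrich_summary = None
        if enr_cfg is not None or truth is not None:
            if enr_cfg and enr_cfg.get("annotations"):
                terms = read_term_annotations(enr_cfg["annotations"])
            elif truth is not None:
                planted_mrna = [m for _, _, m in truth.triplets]
                terms = synthetic_annotations(mrna_tpm.feature_ids, planted_mrna, seed)
            else:
                terms = []
            if terms:
                universe = expressed_mrna
                enr = fisher_enrich(de_mrna_ids & universe, terms, universe,
                                    alpha=float(thr["edge_alpha"]))
                enrichment_to_frame(enr).to_csv(rundir / "enrichment.tsv", sep="\t",
                                                index=False, float_format="%.6g")
                enrich_summary = {"n_terms": len(enr),
                                  "n_significant": sum(r.significant for r in enr)}
        counts_log["enrichment"] = enrich_summary

        # ------------------------------------------------------------------
        stage = "phenostats"
        pheno_summary = None
        pheno_cfg = config.get("morphometrics")
        table = None
        if pheno_cfg == "synthetic" or (pheno_cfg is None and "simulate" in config):
            table = synthetic_morphometrics(seed)
        elif pheno_cfg:
            table = read_measurement_table(pheno_cfg)
        if table is not None:
            comps = compare_groups(table)
            comparisons_to_frame(comps).to_csv(rundir / "morphometrics.tsv", sep="\t",
                                               index=False, float_format="%.6g")
            pheno_summary = {c.trait: {"p_value": c.p_value, "significant": c.significant}
                             for c in comps}
        counts_log["morphometrics"] = pheno_summary

        # ------------------------------------------------------------------
        stage = "summarize"
        summary: dict[str, Any] = {
            "seed": seed,
            "de": counts_log["de"],
            "expressed": counts_log["expressed"],
            "edges": {k: net_counts[k] for k in ("lnc_mir_pairs", "mir_mrna_pairs",
                                                 "lnc_mrna_pairs")},
            "triplets": net_counts["triplets"],
            "cerna_pairs": net_counts["cerna_pairs"],
        }
        if truth is not None:
            recall, false_triplets = truth_confusion(results.triplets, truth)
            summary["recall"] = recall
            summary["false_triplets"] = false_triplets
        (rundir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        manifest = {
            "cernet_version": __version__,
            "numpy": np.__version__, "scipy": scipy.__version__, "pandas": pd.__version__,
            "seed": seed,
            "config_hash": _config_hash(dict(config)),
            "thresholds": thr,
            "stage_counts": counts_log,
        }
        (rundir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    return rundir


def read_summary(rundir: str | Path) -> dict:
    return json.loads((Path(rundir) / "summary.json").read_text())
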