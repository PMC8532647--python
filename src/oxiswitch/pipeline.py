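"""End-to-end pipeline orchestration and JSON reporting.

Stage order follows the reference workflow: drift correction (per mode)
-> blank/RSD/drug filtering (per mode) -> mode concatenation -> FTOE
correlation screening and multivariate analysis -> pathway enrichment.
The run is a pure function of (inputs, config, seed): repeated runs
produce byte-identical reports.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from oxiswitch import enrichment as enr
from oxiswitch import screen
from oxiswitch.drift import correct_batch
from oxiswitch.errors import StageError
from oxiswitch.filters import DrugEntry, apply_filter_cascade, read_drug_list
from oxiswitch.ions import NEGATIVE, POSITIVE
from oxiswitch.oximetry import derive_oximetry, ftoe_lookup, read_clinical
from oxiswitch.peaktable import (
    STUDY,
    FeatureTable,
    PipelineConfig,
    concatenate_modes,
    read_feature_table,
)

STAGES = ("load", "oximetry", "drift_correction", "filtering", "concatenation",
          "correlation_screen", "multivariate", "enrichment")


def _round12(obj):
    """Recursively serialize floats at 12 significant digits."""
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if math.isnan(x):
            return None
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        return float(f"{x:.12g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def report_to_json(report: dict) -> str:
    return json.dumps(_round12(report), sort_keys=True, indent=1)


def run_pipeline_tables(
    tables: dict[str, FeatureTable],
    clinical: pd.DataFrame,
    library: enr.PathwayLibrary,
    drugs: list[DrugEntry],
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage on in-memory inputs; returns the report bundle."""
    config = config or PipelineConfig()
    report: dict = {"stage_log": [], "config": {
        "blank_ratio": config.blank_ratio,
        "rsd_threshold_percent": config.rsd_threshold_percent,
        "drug_mz_tolerance": config.drug_mz_tolerance,
        "annotation_ppm": config.annotation_ppm,
        "sig_top_fraction": config.sig_top_fraction,
        "corr_p_threshold": config.corr_p_threshold,
        "corr_r_threshold": config.corr_r_threshold,
        "permutations": config.permutations,
        "rng_seed": config.rng_seed,
    }}

    def log(stage: str, **info):
        report["stage_log"].append({"stage": stage, **info})

    try:
        oxi = derive_oximetry(clinical)
        ftoe = ftoe_lookup(oxi)
        log("oximetry", n_records=len(oxi), n_negative_ceo2=int(oxi["ceo2_negative"].sum()))
    except Exception as exc:  # noqa: BLE001
        raise StageError("oximetry", str(exc)) from exc

    corrected: dict[str, FeatureTable] = {}
    for mode in (POSITIVE, NEGATIVE):
        if mode not in tables:
            continue
        try:
            table, drift_report = correct_batch(tables[mode], config)
        except Exception as exc:  # noqa: BLE001
            raise StageError("drift_correction", f"{mode}: {exc}") from exc
        corrected[mode] = table
        log(
            "drift_correction",
            mode=mode,
            n_features=len(table.features),
            n_study=int(table.role_mask(STUDY).sum()),
            median_pre_rsd=float(np.median(drift_report["pre_rsd"])),
            median_post_rsd=float(np.median(drift_report["post_rsd"])),
        )

    filtered: dict[str, FeatureTable] = {}
    for mode, table in corrected.items():
        try:
            out, frep = apply_filter_cascade(table, config, drugs)
        except Exception as exc:  # noqa: BLE001
            raise StageError("filtering", f"{mode}: {exc}") from exc
        filtered[mode] = out
        log(
            "filtering",
            mode=mode,
            n_input=frep.n_input,
            n_removed_blank=frep.n_removed_blank,
            n_removed_rsd=frep.n_removed_rsd,
            n_removed_drug=frep.n_removed_drug,
            n_surviving=frep.n_surviving,
        )

    try:
        if len(filtered) == 2:
            combined = concatenate_modes(filtered[POSITIVE], filtered[NEGATIVE])
        else:
            combined = next(iter(filtered.values()))
        log("concatenation", n_features=len(combined.features),
            n_study=int(combined.role_mask(STUDY).sum()))
    except Exception as exc:  # noqa: BLE001
        raise StageError("concatenation", str(exc)) from exc

    try:
        corr = screen.pearson_with_ftoe(combined, ftoe)
        corr = screen.classify_significant(corr, config)
        n_pos = int((corr["class"] == screen.CLASS_POSITIVE).sum())
        n_neg = int((corr["class"] == screen.CLASS_NEGATIVE).sum())
        log("correlation_screen", n_features=len(corr), n_positive=n_pos, n_negative=n_neg)
    except Exception as exc:  # noqa: BLE001
        raise StageError("correlation_screen", str(exc)) from exc

    try:
        sig_mask = (corr["class"] != screen.CLASS_NONSIG).to_numpy()
        if len(combined.features) == 0:
            multivariate: dict = {
                "explained_variance_fraction": [],
                "pc1_scores": {},
                "ward_k2_labels": None,
            }
        else:
            study = combined.study_samples()
            scaled, _flags = screen.autoscale(study.intensities)
            pca = screen.pca_scores(scaled, n_components=2, sample_ids=study.injection_ids)
            multivariate = {
                "explained_variance_fraction": [
                    float(v) for v in pca.explained_variance_fraction
                ],
                "pc1_scores": {
                    sid: float(s) for sid, s in zip(pca.sample_ids, pca.scores[:, 0])
                },
            }
            if sig_mask.sum() >= 2:
                labels, _Z = screen.ward_cluster(scaled[sig_mask], k=2)
                multivariate["ward_k2_labels"] = {
                    sid: int(lab) for sid, lab in zip(study.injection_ids, labels)
                }
            else:
                multivariate["ward_k2_labels"] = None
        log("multivariate", n_significant=int(sig_mask.sum()))
    except Exception as exc:  # noqa: BLE001
        raise StageError("multivariate", str(exc)) from exc

    try:
        results = enr.enrich(corr, library, config)
        log("enrichment", n_pathways=len(results))
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrichment", str(exc)) from exc

    report["feature_counts"] = {
        "input": {mode: len(t.features) for mode, t in tables.items()},
        "after_filtering": {mode: len(t.features) for mode, t in filtered.items()},
        "combined": len(combined.features),
    }
    report["correlation"] = [
        {
            "feature_id": fid,
            "mz": float(mz),
            "rt": float(rt),
            "mode": mode,
            "r": float(r) if pd.notna(r) else None,
            "p": float(p) if pd.notna(p) else None,
            "class": cls,
        }
        for fid, mz, rt, mode, r, p, cls in zip(
            corr["feature_id"], corr["mz"], corr["rt"], corr["mode"],
            corr["r"], corr["p"], corr["class"]
        )
    ]
    report["multivariate"] = multivariate
    report["enrichment"] = [
        {
            "pathway_id": r.pathway_id,
            "name": r.name,
            "n_hits": r.n_hits,
            "n_sig_hits": r.n_sig_hits,
            "sig_codes": list(r.sig_codes),
            "raw_p": r.raw_p,
            "adj_p": r.adj_p,
        }
        for r in results
    ]
    return report


def run_pipeline(
    config: PipelineConfig,
    pos: str | Path,
    pos_meta: str | Path,
    neg: str | Path,
    neg_meta: str | Path,
    clinical: str | Path,
    pathways: str | Path,
    drugs: str | Path,
    outdir: str | Path | None = None,
) -> dict:
    """File-path front end of :func:`run_pipeline_tables`.

    When ``outdir`` is given, writes ``report.json`` plus the correlation
    and enrichment tables as TSV.
    """
    try:
        tables = {
            POSITIVE: read_feature_table(pos, pos_meta),
            NEGATIVE: read_feature_table(neg, neg_meta),
        }
        clin = read_clinical(clinical)
        library = enr.read_pathway_library(pathways)
        drug_list = read_drug_list(drugs)
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", str(exc)) from exc

    report = run_pipeline_tables(tables, clin, library, drug_list, config)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report_to_json(report))
        pd.DataFrame(report["correlation"]).to_csv(
            outdir / "correlation.tsv", sep="\t", index=False
        )
        pd.DataFrame(report["enrichment"]).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
    return report
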