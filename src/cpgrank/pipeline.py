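"""Config-driven orchestration of the five end-to-end analyses.

Each ``run_*`` entry point chains the library stages on conforming input
tables, logs the probe counts at every stage and writes plain TSV/JSON
outputs plus a machine-readable run manifest (config, package versions,
seed, SHA-256 of every input) so a run can be reproduced bit-for-bit.

Analyses:

* ``patients_vs_controls`` — site statistics, threshold filter, promoter
  summaries and PCA for the neoplastic-vs-healthy comparison;
* ``response_signature`` — top-K combined-rank signature separating
  azacitidine responders from non-responders at diagnosis, clustered with
  a purity report;
* ``survival_signature`` — the same machinery on the longer/shorter
  survival groups defined by the arm's median OS, plus a log-rank test
  between the resulting clusters;
* ``followup_application`` — applies a stored signature to follow-up
  samples and reports centroid margins and per-subject global methylation
  change;
* ``survival_curves`` — KM curves / log-rank for a grouping column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import cpgrank
from cpgrank import diffmeth, regions, signature_cluster as sc, survival as surv
from cpgrank.core_io import (
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
    reference_concordance,
)

log = logging.getLogger("cpgrank")


@dataclass
class PipelineConfig:
    """Inputs, constants and output location of one pipeline run."""

    beta_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    signature_path: str | None = None
    analysis: str = "patients_vs_controls"
    k: int = 200
    min_abs_diff: float = 0.2
    alpha: float = 0.05
    epsilon: float = 0.01
    test: str = "moderated"
    seed: int = 0
    out_dir: str = "cpgrank_out"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(cfg: PipelineConfig, out_dir: Path, stage_counts: dict) -> Path:
    inputs = {}
    for name in ("beta_path", "samples_path", "annotation_path", "signature_path"):
        p = getattr(cfg, name)
        if p and Path(p).exists():
            inputs[name] = {"path": str(p), "sha256": _sha256(p)}
    manifest = {
        "config": dataclasses.asdict(cfg),
        "inputs": inputs,
        "versions": {
            "cpgrank": cpgrank.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stage_counts": stage_counts,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _load_inputs(cfg: PipelineConfig) -> tuple[BetaMatrix, SampleSheet, ProbeAnnotation | None]:
    beta = read_beta_matrix(cfg.beta_path)
    sheet = read_sample_sheet(cfg.samples_path)
    ann = read_probe_annotation(cfg.annotation_path) if cfg.annotation_path else None
    return beta, sheet, ann


def _prepare(beta: BetaMatrix, sample_ids) -> BetaMatrix:
    """Restrict to the analysis samples and apply the missingness filter."""
    m = beta.subset_samples([s for s in sample_ids if s in beta.sample_ids])
    return m.drop_high_missing_probes(0.2)


def run_patients_vs_controls(
    cfg: PipelineConfig,
    beta: BetaMatrix | None = None,
    sheet: SampleSheet | None = None,
    ann: ProbeAnnotation | None = None,
) -> dict:
    """Patients (MDS + sAML) vs healthy controls at diagnosis."""
    if beta is None:
        beta, sheet, ann = _load_inputs(cfg)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    dx = sheet.table[
        (sheet.table["timepoint"] == "diagnosis")
        & (sheet.table["subject_id"] != "reference")
    ]
    labels = pd.Series(
        np.where(dx["disease"] == "control", "control", "patient"),
        index=dx["sample_id"].to_numpy(),
    )
    m = _prepare(beta, labels.index)

    concordance = reference_concordance(beta, sheet)
    stats, untestable = diffmeth.site_statistics(
        m, labels, groups=("patient", "control"), epsilon=cfg.epsilon, test=cfg.test
    )
    hyper, hypo = diffmeth.threshold_filter(stats, cfg.min_abs_diff, cfg.alpha)
    n_sig = int((stats["p_value"] < cfg.alpha).sum())
    counts = {
        "input_probes": beta.shape[0],
        "analysis_probes": m.shape[0],
        "testable_probes": len(stats),
        "untestable_probes": len(untestable),
        "significant_probes": n_sig,
        "filtered_probes": len(hyper) + len(hypo),
        "hyper_probes": len(hyper),
        "hypo_probes": len(hypo),
    }

    result: dict = {"stats": stats, "hyper": hyper, "hypo": hypo, "concordance": concordance}
    if ann is not None:
        membership = regions.assign_probes_to_promoters(ann)
        summary, lists = regions.summarize_promoters(hyper, hypo, membership)
        counts.update(
            genes_ge1_hyper=len(lists.hyper_ge1),
            genes_ge1_hypo=len(lists.hypo_ge1),
            genes_ge4_hyper=len(lists.hyper_ge4),
        )
        summary.to_csv(out_dir / "promoter_summary.tsv", sep="\t", index=False)
        result.update(promoter_summary=summary, gene_lists=lists)

    coords, evr = sc.pca_embed(m)
    coords.assign(group=labels.reindex(coords.index)).to_csv(
        out_dir / "pca.tsv", sep="\t", index_label="sample_id"
    )
    result.update(pca=coords, explained_variance=evr)

    stats.to_csv(out_dir / "stats.tsv", sep="\t", index_label="probe_id")
    hyper.to_csv(out_dir / "hyper.tsv", sep="\t", index_label="probe_id")
    hypo.to_csv(out_dir / "hypo.tsv", sep="\t", index_label="probe_id")
    for stage, n in counts.items():
        log.info("patients_vs_controls: %s = %s", stage, n)
    result["manifest"] = write_manifest(cfg, out_dir, counts)
    result["counts"] = counts
    return result


def _signature_run(
    cfg: PipelineConfig,
    m: BetaMatrix,
    labels: pd.Series,
    groups: tuple[str, str],
    extra_samples: pd.Index | None = None,
) -> dict:
    """Shared tail of the response/survival signature analyses."""
    stats, untestable = diffmeth.site_statistics(
        m.subset_samples(labels.index), labels, groups=groups,
        epsilon=cfg.epsilon, test=cfg.test,
    )
    top = diffmeth.select_top_k(stats, cfg.k)
    sig = sc.Signature.from_stats(top, group_names=groups)

    cluster_samples = list(labels.index)
    if extra_samples is not None:
        cluster_samples += [s for s in extra_samples if s in m.sample_ids]
    z = sc.zscore_rows(m.subset_samples(cluster_samples).subset_probes(top.index))
    tree = sc.hierarchical_cluster(z)
    cl = sc.cut_clusters(tree, k=2)
    purity = sc.cluster_purity(cl, labels)
    counts = {
        "testable_probes": len(stats),
        "untestable_probes": len(untestable),
        "signature_probes": len(sig),
    }
    return {
        "stats": stats,
        "signature": sig,
        "zscores": z,
        "tree": tree,
        "clusters": cl,
        "purity": purity,
        "counts": counts,
    }


def run_response_signature(
    cfg: PipelineConfig,
    beta: BetaMatrix | None = None,
    sheet: SampleSheet | None = None,
    include_controls: bool = True,
) -> dict:
    """Top-K signature separating AZA responders from non-responders."""
    if beta is None:
        beta, sheet, _ = _load_inputs(cfg)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    dx = sheet.table[(sheet.table["timepoint"] == "diagnosis")]
    aza = dx[(dx["treatment"] == "AZA") & dx["response"].isin(["responder", "nonresponder"])]
    labels = pd.Series(aza["response"].to_numpy(), index=aza["sample_id"].to_numpy())
    m = _prepare(beta, dx["sample_id"])

    extra = None
    if include_controls:
        extra = pd.Index(
            dx.loc[(dx["disease"] == "control") & (dx["subject_id"] != "reference"), "sample_id"]
        )
    res = _signature_run(cfg, m, labels, ("responder", "nonresponder"), extra)

    res["signature"].to_tsv(out_dir / "signature.tsv")
    res["clusters"].to_csv(out_dir / "labels.tsv", sep="\t", header=True)
    res["purity"].to_csv(out_dir / "purity.tsv", sep="\t")
    res["manifest"] = write_manifest(cfg, out_dir, res["counts"])
    return res


def run_survival_signature(
    cfg: PipelineConfig,
    beta: BetaMatrix | None = None,
    sheet: SampleSheet | None = None,
) -> dict:
    """Signature for longer vs shorter survival in the AZA arm, with log-rank."""
    if beta is None:
        beta, sheet, _ = _load_inputs(cfg)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pairs = surv.define_os_pfs(sheet)
    arm = pairs[pairs["treatment"] == "AZA"]
    os_group = surv.dichotomize_by_median_os(arm)
    determinate = os_group[os_group != "indeterminate"]

    dx = sheet.table[
        (sheet.table["timepoint"] == "diagnosis")
        & (sheet.table["subject_id"] != "reference")
    ].set_index("subject_id")
    sample_of = dx["sample_id"]
    labels = pd.Series(
        determinate.to_numpy(), index=sample_of.reindex(determinate.index).to_numpy()
    )
    m = _prepare(beta, labels.index)
    res = _signature_run(cfg, m, labels, ("longer", "shorter"))

    # Log-rank between the two signature clusters.
    subj_of_sample = dx.reset_index().set_index("sample_id")["subject_id"]
    cl = res["clusters"]
    cl_subjects = subj_of_sample.reindex(cl.index)
    merged = arm.set_index("subject_id").loc[cl_subjects]
    chi2, p = surv.logrank_test(
        merged["os_months"].to_numpy(), merged["os_event"].to_numpy(), cl.to_numpy()
    )
    res["logrank"] = {"chi_square": chi2, "p_value": p}
    res["os_group"] = os_group
    res["counts"]["indeterminate_subjects"] = int((os_group == "indeterminate").sum())

    res["signature"].to_tsv(out_dir / "signature.tsv")
    res["clusters"].to_csv(out_dir / "labels.tsv", sep="\t", header=True)
    (out_dir / "survfit.json").write_text(json.dumps(res["logrank"], indent=2) + "\n")
    res["manifest"] = write_manifest(cfg, out_dir, res["counts"])
    return res


def run_followup_application(
    cfg: PipelineConfig,
    sig: sc.Signature | None = None,
    beta: BetaMatrix | None = None,
    sheet: SampleSheet | None = None,
) -> dict:
    """Apply a stored signature to follow-up samples; report margins and
    per-subject global methylation change."""
    if beta is None:
        beta, sheet, _ = _load_inputs(cfg)
    if sig is None:
        sig = sc.Signature.from_tsv(cfg.signature_path)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fu = sheet.table[sheet.table["timepoint"] == "followup"]
    dx = sheet.table[
        (sheet.table["timepoint"] == "diagnosis")
        & (sheet.table["subject_id"] != "reference")
    ]
    m_new = beta.subset_samples([s for s in fu["sample_id"] if s in beta.sample_ids])
    m_ref = beta.subset_samples([s for s in dx["sample_id"] if s in beta.sample_ids])

    z, tree, assignment = sc.apply_signature(sig, m_new, m_reference=m_ref)
    change = sc.global_methylation_change(beta, sheet)

    assignment.to_csv(out_dir / "applied.tsv", sep="\t")
    change.to_csv(out_dir / "global_change.tsv", sep="\t", index=False)
    counts = {
        "followup_samples": m_new.shape[1],
        "signature_probes_used": z.shape[0],
        "subjects_with_change": len(change),
    }
    manifest = write_manifest(cfg, out_dir, counts)
    return {
        "assignment": assignment,
        "zscores": z,
        "tree": tree,
        "global_change": change,
        "counts": counts,
        "manifest": manifest,
    }


def run_survival_curves(
    cfg: PipelineConfig,
    sheet: SampleSheet | None = None,
    group_col: str = "treatment",
    endpoint: str = "os",
) -> dict:
    """KM curves per group of ``group_col`` plus a log-rank when two groups."""
    if sheet is None:
        sheet = read_sample_sheet(cfg.samples_path)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pairs = surv.define_os_pfs(sheet)
    tcol, ecol = (f"{endpoint}_months", f"{endpoint}_event")
    meta = sheet.table[
        (sheet.table["timepoint"] == "diagnosis")
        & (sheet.table["subject_id"] != "reference")
    ].set_index("subject_id")
    pairs = pairs.assign(group=meta[group_col].reindex(pairs["subject_id"]).to_numpy())

    curves = {}
    payload: dict = {"endpoint": endpoint, "groups": {}}
    for g, sub in pairs.groupby("group"):
        c = surv.km_estimate(sub[tcol], sub[ecol])
        curves[g] = c
        payload["groups"][str(g)] = {
            "n": c.n,
            "median": None if np.isnan(c.median) else c.median,
            "median_ci": [None if np.isnan(v) else v for v in c.median_ci],
        }
    if pairs["group"].nunique() == 2:
        chi2, p = surv.logrank_test(pairs[tcol], pairs[ecol], pairs["group"])
        payload["logrank"] = {"chi_square": chi2, "p_value": p}
    (out_dir / "survfit.json").write_text(json.dumps(payload, indent=2) + "\n")
    manifest = write_manifest(cfg, out_dir, {"subjects": len(pairs)})
    return {"curves": curves, "summary": payload, "manifest": manifest}


ANALYSES = {
    "patients_vs_controls": run_patients_vs_controls,
    "response_signature": run_response_signature,
    "survival_signature": run_survival_signature,
    "followup_application": run_followup_application,
    "survival_curves": run_survival_curves,
}


def run(cfg: PipelineConfig) -> dict:
    """Dispatch on ``cfg.analysis``."""
    try:
        fn = ANALYSES[cfg.analysis]
    except KeyError:
        raise ValueError(
            f"unknown analysis {cfg.analysis!r}; choose from {sorted(ANALYSES)}"
        ) from None
    return fn(cfg)
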