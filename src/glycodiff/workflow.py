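"""End-to-end orchestration of the two analysis arms.

``run_full`` executes the proteomics arm (group-presence filter ->
imputation -> volcano -> ANOVA/Tukey -> clustering -> grade-scheme
correlation) and the glycoproteomics arm (RT/AUC/presence filters ->
quotient total-area normalization -> log transform -> site metrics ->
descriptors -> differential tests), writing every output table as TSV
plus a JSON provenance record sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glycodiff import glyco as gl
from glycodiff import io as gio
from glycodiff import proteomics as prot
from glycodiff.glycans import GlycanParseError, parse_composition

logger = logging.getLogger("glycodiff")


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run (defaults match the study)."""

    protein_path: str = "proteins.tsv"
    glyco_path: str = "glycopeptides.tsv"
    metadata_path: str = "metadata.tsv"
    out_dir: str = "results"
    scheme: str = "pathological"          # pathological | gleason | two_group
    auc_min: float = 1000.0
    min_samples: int = 5
    min_glycopeptides: int = 10
    presence_fraction: float = 0.6
    presence_all_groups: bool = False
    impute_down_shift: float = 1.8
    impute_width: float = 0.3
    fdr_alpha: float = 0.05
    fc_over: float = 2.0
    fc_under: float = 0.5
    log_base: float = 2.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_inputs(protein_path, glyco_path, metadata_path) -> list[dict]:
    """Structural checks on the three input TSVs.

    Returns a machine-readable issue list (empty when everything is
    well-formed); never raises for content problems.
    """
    issues: list[dict] = []

    def issue(kind: str, **info) -> None:
        issues.append({"kind": kind, **info})

    try:
        meta = gio.read_metadata(metadata_path)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        issue("metadata_unreadable", error=str(exc))
        meta = None
    if meta is not None:
        bad_grade = meta.loc[~meta["grade"].isin(gio.GRADES)]
        for _, row in bad_grade.iterrows():
            issue("unknown_grade", sample_id=row["sample_id"], grade=row["grade"])
        bad_gg = meta.loc[~meta["gleason"].isin(["NA", *gio.GLEASON_GRADES])]
        for _, row in bad_gg.iterrows():
            issue("unknown_gleason", sample_id=row["sample_id"], gleason=row["gleason"])
        if meta["sample_id"].duplicated().any():
            issue("duplicate_sample_ids",
                  samples=list(meta.loc[meta["sample_id"].duplicated(), "sample_id"]))

    try:
        glyco = gio.read_glyco_table(glyco_path)
    except Exception as exc:  # noqa: BLE001
        issue("glyco_table_unreadable", error=str(exc))
        glyco = None
    if glyco is not None:
        for glycan in glyco["glycan"].unique():
            try:
                parse_composition(glycan)
            except GlycanParseError as exc:
                rows = glyco.index[glyco["glycan"] == glycan]
                issue("unparseable_glycan", glycan=glycan,
                      first_row=int(rows[0]), error=str(exc))
        dup = glyco.duplicated(subset=["sample_id", *gl.GLYCOPEPTIDE_KEY])
        if dup.any():
            issue("duplicate_quant_records", n=int(dup.sum()),
                  resolution="keep max AUC")
        if (glyco["auc"] < 0).any():
            issue("negative_auc", n=int((glyco["auc"] < 0).sum()))
        if (glyco["rt"] <= 0).any():
            issue("nonpositive_rt", n=int((glyco["rt"] <= 0).sum()))
        if meta is not None:
            unknown = set(glyco["sample_id"]) - set(meta["sample_id"])
            if unknown:
                issue("glyco_samples_missing_metadata", samples=sorted(unknown))

    try:
        proteins = gio.read_protein_matrix(protein_path)
    except Exception as exc:  # noqa: BLE001
        issue("protein_matrix_unreadable", error=str(exc))
        proteins = None
    if proteins is not None and meta is not None:
        unknown = set(proteins.columns) - set(meta["sample_id"])
        if unknown:
            issue("protein_samples_missing_metadata", samples=sorted(unknown))
    return issues


def run_full(config: RunConfig) -> dict:
    """Run both analysis arms and write all outputs under ``out_dir``.

    Returns the run report (also written as ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": []}

    def stage(name: str, **info) -> None:
        logger.info("stage %s: %s", name, info)
        report["stages"].append({"stage": name, **info})

    meta = gio.read_metadata(config.metadata_path)
    protein_df = gio.read_protein_matrix(config.protein_path)
    glyco_df = gio.read_glyco_table(config.glyco_path)

    meta_samples = set(meta["sample_id"])
    offenders = sorted((set(protein_df.columns) | set(glyco_df["sample_id"]))
                       - meta_samples)
    if offenders:
        raise ValueError(f"samples without metadata: {offenders}")

    groups = gio.group_series(meta, scheme=config.scheme)
    two_group = gio.group_series(meta, scheme="two_group")
    stage("load", n_proteins=int(protein_df.shape[0]),
          n_glyco_records=int(len(glyco_df)), n_samples=len(meta))

    # ---- proteomics arm -------------------------------------------------
    pmat = prot.ProteinMatrix(data=protein_df,
                              groups=groups.reindex(protein_df.columns))
    pmat = prot.group_presence_filter(pmat, fraction=config.presence_fraction,
                                      require_all_groups=config.presence_all_groups)
    stage("group_presence_filter", **pmat.provenance[-1])
    pmat = prot.impute_missing(pmat, down_shift=config.impute_down_shift,
                               width=config.impute_width, seed=config.seed)
    stage("impute_missing", **{k: v for k, v in pmat.provenance[-1].items()
                               if k != "step"})

    volcano = prot.two_group_volcano(pmat, alpha=config.fdr_alpha,
                                     fc_over=config.fc_over,
                                     fc_under=config.fc_under,
                                     log_base=config.log_base)
    gio.write_tsv(volcano, out / "protein_volcano.tsv")
    stage("two_group_volcano",
          n_significant=int(volcano["significant"].sum()) if len(volcano) else 0)

    anova, tukey = prot.multigroup_anova_tukey(pmat, alpha=config.fdr_alpha)
    gio.write_tsv(anova, out / "protein_anova.tsv")
    gio.write_tsv(tukey, out / "protein_tukey.tsv")
    significant = list(anova.loc[anova["significant"], "protein"]) if len(anova) else []
    stage("multigroup_anova_tukey", n_significant=len(significant))

    group_order = [g for g in (gio.GRADES if config.scheme != "two_group"
                               else ["Normal", "PCa"])
                   if g in set(pmat.groups)]
    if len(significant) >= 2:
        clusters = prot.cluster_significant(pmat, significant,
                                            group_order=group_order)
        gio.write_tsv(clusters, out / "protein_clusters.tsv")
        stage("cluster_significant",
              n_up=int((clusters["direction"] == "up").sum()),
              n_down=int((clusters["direction"] == "down").sum()))
        zmat = prot.zscore_rows(
            prot.group_mean_profiles(
                dataclasses.replace(pmat, data=pmat.data.loc[significant]),
                order=group_order))
        gio.write_tsv(zmat.reset_index(), out / "protein_heatmap_zscores.tsv")
    else:
        stage("cluster_significant", skipped="fewer than 2 significant proteins")

    if config.scheme == "pathological":
        gleason_groups = gio.group_series(meta, scheme="gleason")
        corr = prot.grade_scheme_correlation(
            pmat, list(pmat.data.index), groups, gleason_groups,
            pairs=gio.GLEASON_SCHEME_PAIRS)
        gio.write_tsv(corr, out / "grade_scheme_correlation.tsv")
        stage("grade_scheme_correlation",
              correlations=[None if np.isnan(r) else float(r)
                            for r in corr["pearson_r"]])

    # ---- glycoproteomics arm --------------------------------------------
    glyco_df, n_dup = gio.dedupe_records(glyco_df)
    kept, removed = gl.rt_outlier_filter(glyco_df)
    stage("rt_outlier_filter", records_removed=int(len(removed)),
          duplicates_resolved=n_dup)
    n_before = len(kept)
    kept = gl.auc_filter(kept, min_auc=config.auc_min)
    stage("auc_filter", records_removed=int(n_before - len(kept)))

    gmat = gl.records_to_matrix(kept, groups=groups)
    gmat = gl.presence_filter(gmat, min_samples=config.min_samples,
                              min_glycopeptides=config.min_glycopeptides)
    stage("presence_filter", **{k: v for k, v in gmat.provenance[-1].items()
                                if k != "step"})
    gmat_norm = gl.quotient_total_area_normalize(gmat)
    gmat_log = gl.log_transform(gmat_norm, base=config.log_base)
    stage("normalize", n_glycopeptides=gmat_norm.n_glycopeptides,
          n_samples=gmat_norm.n_samples)

    flat = gmat_log.data.copy()
    flat.index = ["|".join(t) for t in flat.index]
    flat.index.name = "glycopeptide"
    gio.write_tsv(flat.reset_index(), out / "glyco_matrix_log.tsv")

    metrics = gl.site_metric_degrees(gmat_norm)
    gio.write_tsv(metrics, out / "site_metrics.tsv")
    desc = gl.dataset_descriptors(gmat_norm)
    (out / "dataset_descriptors.json").write_text(
        json.dumps(dataclasses.asdict(desc), indent=2, sort_keys=True))
    stage("site_metrics", n_sites=int(metrics.groupby(["protein", "glycosite"])
                                      .ngroups),
          average_fucosylation=desc.average_fucosylation,
          average_antenna_sialylation=desc.average_antenna_sialylation)

    sample_groups = groups.reindex(gmat_log.data.columns)
    abundance_diff, abundance_tukey, skipped_a = gl.differential(
        flat, sample_groups, alpha=config.fdr_alpha)
    if len(abundance_diff):
        gio.write_tsv(abundance_diff, out / "glyco_abundance_diff.tsv")
        gio.write_tsv(abundance_tukey, out / "glyco_abundance_tukey.tsv")

    metric_features = gl.metric_table_to_features(metrics)
    metric_diff, metric_tukey, skipped_m = gl.differential(
        metric_features, sample_groups.reindex(metric_features.columns),
        alpha=config.fdr_alpha)
    if len(metric_diff):
        gio.write_tsv(metric_diff, out / "site_metric_diff.tsv")
        gio.write_tsv(metric_tukey, out / "site_metric_tukey.tsv")
    stage("glyco_differential",
          n_abundance_significant=(int(abundance_diff["significant"].sum())
                                   if len(abundance_diff) else 0),
          n_metric_significant=(int(metric_diff["significant"].sum())
                                if len(metric_diff) else 0),
          skipped=len(skipped_a) + len(skipped_m))

    provenance = {
        "config": config.to_dict(),
        "proteomics": pmat.provenance,
        "glyco": gmat_log.provenance,
        "skipped_features": {"abundance": skipped_a, "metrics": skipped_m},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                    sort_keys=True, default=str))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                default=str))
    return report
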