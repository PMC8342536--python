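"""Glycopeptide quantification pipeline.

Filtering, normalization, site-specific metric degrees, cohort-level
descriptors and differential statistics for a long-format glycopeptide
quant table. The canonical stage order is::

    RT outlier filter -> AUC filter -> glycopeptide presence filter
    -> sample presence filter -> quotient total-area normalization
    -> log transform

Site metric degrees are computed from the *raw* (pre-log) filtered
abundances, since they are ratios of ion-current areas; the log matrix is
used only for abundance-level differential tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from glycodiff import stats as gstats
from glycodiff.glycans import GlycanFeatures, derive_features, parse_composition

GLYCOPEPTIDE_KEY = ["protein", "glycosite", "glycan"]

DEFAULT_AUC_MIN = 1000.0
DEFAULT_MIN_SAMPLES = 5
DEFAULT_MIN_GLYCOPEPTIDES = 10
RT_MIN_GROUP = 4  # RT outlier filter needs at least this many observations


class EmptyMatrixError(ValueError):
    """All rows or columns were removed by filtering."""


@dataclass
class GlycoMatrix:
    """Glycopeptide x sample abundance matrix with provenance.

    ``data`` rows are indexed by (protein, glycosite, glycan); columns are
    sample ids. ``scale`` tracks whether values are raw areas, normalized
    areas or logs. Every transformation appends to ``provenance``.
    """

    data: pd.DataFrame
    groups: pd.Series | None = None
    scale: str = "raw"
    provenance: list = field(default_factory=list)

    def log(self, step: str, **info) -> "GlycoMatrix":
        return replace(self, provenance=self.provenance + [{"step": step, **info}])

    @property
    def n_glycopeptides(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def rt_outlier_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove per-glycopeptide retention-time outliers.

    For each glycopeptide (protein, glycosite, glycan) with at least 4
    observations, records with RT outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] are
    dropped; bounds inclusive, quartiles by linear interpolation (type 7).
    Smaller groups pass through unfiltered.
    """
    keep_mask = np.ones(len(records), dtype=bool)
    for _, idx in records.groupby(GLYCOPEPTIDE_KEY, sort=False).groups.items():
        rts = records.loc[idx, "rt"].to_numpy(dtype=float)
        if len(rts) < RT_MIN_GROUP:
            continue
        q1, q3 = np.percentile(rts, [25, 75], method="linear")
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        bad = (rts < lo) | (rts > hi)
        keep_mask[records.index.get_indexer(idx)] &= ~bad
    kept = records.loc[keep_mask].reset_index(drop=True)
    removed = records.loc[~keep_mask].reset_index(drop=True)
    return kept, removed


def auc_filter(records: pd.DataFrame, min_auc: float = DEFAULT_AUC_MIN) -> pd.DataFrame:
    """Drop records with AUC strictly below ``min_auc`` (boundary kept)."""
    return records.loc[records["auc"] >= min_auc].reset_index(drop=True)


def records_to_matrix(records: pd.DataFrame, groups: pd.Series | None = None) -> GlycoMatrix:
    """Pivot long records into a glycopeptide x sample abundance matrix.

    Duplicate (sample, glycopeptide) records must be resolved beforehand
    (see :func:`glycodiff.io.dedupe_records`); duplicates here are an error.
    """
    dup = records.duplicated(subset=["sample_id", *GLYCOPEPTIDE_KEY])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (sample, glycopeptide) records; "
            "deduplicate before pivoting"
        )
    wide = records.pivot_table(
        index=GLYCOPEPTIDE_KEY, columns="sample_id", values="auc", aggfunc="first"
    )
    wide.columns.name = None
    m = GlycoMatrix(data=wide, groups=groups, scale="raw")
    return m.log("pivot", n_glycopeptides=wide.shape[0], n_samples=wide.shape[1])


def presence_filter(
    matrix: GlycoMatrix,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_glycopeptides: int = DEFAULT_MIN_GLYCOPEPTIDES,
) -> GlycoMatrix:
    """Drop sparse glycopeptide rows, then sparse sample columns.

    A glycopeptide must be observed in >= ``min_samples`` samples; then a
    sample must retain >= ``min_glycopeptides`` glycopeptides. Applied once
    in that order (no iteration to a fixpoint).
    """
    data = matrix.data
    row_ok = data.notna().sum(axis=1) >= min_samples
    data = data.loc[row_ok]
    n_rows_dropped = int((~row_ok).sum())
    col_ok = data.notna().sum(axis=0) >= min_glycopeptides
    data = data.loc[:, col_ok]
    n_cols_dropped = int((~col_ok).sum())
    if data.empty:
        raise EmptyMatrixError(
            "presence filter removed everything; review min_samples/"
            "min_glycopeptides thresholds"
        )
    out = replace(matrix, data=data)
    return out.log(
        "presence_filter",
        min_samples=min_samples,
        min_glycopeptides=min_glycopeptides,
        glycopeptides_removed=n_rows_dropped,
        samples_removed=n_cols_dropped,
    )


def quotient_total_area_normalize(matrix: GlycoMatrix) -> GlycoMatrix:
    """Total-area scaling followed by probabilistic quotient normalization.

    Step 1 scales every sample column so its non-missing total equals the
    cohort-median total. Step 2 divides every column by the median of its
    value/reference quotients, the reference being the per-glycopeptide
    median across samples of the step-1 matrix.
    """
    if matrix.scale != "raw":
        raise ValueError(f"expected raw-scale matrix, got {matrix.scale!r}")
    data = matrix.data
    totals = data.sum(axis=0, skipna=True)
    if data.isna().all(axis=0).any():
        bad = list(data.columns[data.isna().all(axis=0)])
        raise ValueError(f"samples with no quantified glycopeptides: {bad}")
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with non-positive total area: {bad}")
    target = float(totals.median())
    step1 = data * (target / totals)

    reference = step1.median(axis=1, skipna=True)
    quotients = step1.div(reference, axis=0)
    dilution = quotients.median(axis=0, skipna=True)
    if (dilution <= 0).any() or dilution.isna().any():
        bad = list(dilution.index[(dilution <= 0) | dilution.isna()])
        raise ValueError(f"undefined quotient dilution factor for samples: {bad}")
    normalized = step1.div(dilution, axis=1)

    out = replace(matrix, data=normalized, scale="normalized")
    return out.log(
        "quotient_total_area_normalize",
        target_total=target,
        dilution_factors={str(k): float(v) for k, v in dilution.items()},
    )


def log_transform(matrix: GlycoMatrix, base: float = 2.0) -> GlycoMatrix:
    """Elementwise logarithm; missing values stay missing."""
    data = matrix.data
    nonpos = (data <= 0).any(axis=None)
    if nonpos:
        rows, cols = np.where((data <= 0).to_numpy())
        cell = (data.index[rows[0]], data.columns[cols[0]])
        raise ValueError(f"non-positive value at {cell}; cannot log-transform")
    out = replace(matrix, data=np.log(data) / np.log(base), scale="log")
    return out.log("log_transform", base=base)


def glycan_features_for(matrix: GlycoMatrix) -> dict[str, GlycanFeatures]:
    """Derive glycan features for every distinct glycan string in the matrix."""
    glycans = matrix.data.index.get_level_values("glycan").unique()
    return {g: derive_features(parse_composition(g)) for g in glycans}


def site_metric_degrees(
    matrix: GlycoMatrix, features: dict[str, GlycanFeatures] | None = None
) -> pd.DataFrame:
    """Per-(glycosite, sample) metric degrees from raw abundances.

    Returns a long table with columns ``protein, glycosite, sample_id,
    fucosylation, sialylation, galactosylation``:

    - fucosylation: abundance fraction of glycoforms with >= 1 fucose,
    - sialylation: abundance-weighted fraction of antennae carrying sialic
      acid, over antenna-bearing glycoforms,
    - galactosylation: abundance-weighted galactoses per antenna, over
      complex glycoforms.

    A degree is NaN when its denominator is zero (no eligible glycoforms
    quantified for that site and sample).
    """
    if matrix.scale == "log":
        raise ValueError("degrees must be computed on raw/normalized areas, not logs")
    if features is None:
        features = glycan_features_for(matrix)
    data = matrix.data
    idx = data.index
    glycans = idx.get_level_values("glycan")
    missing_ann = set(glycans) - set(features)
    if missing_ann:
        raise KeyError(f"no glycan annotation for: {sorted(missing_ann)[:5]}")

    fuc = np.array([float(features[g].is_fucosylated) for g in glycans])
    ant = np.array([float(features[g].antennae) for g in glycans])
    sia = np.array([float(features[g].sialic_antennae) for g in glycans])
    gal = np.array([
        float(features[g].galactoses) if features[g].glycan_class.value == "complex" else 0.0
        for g in glycans
    ])
    is_complex = np.array([features[g].glycan_class.value == "complex" for g in glycans])

    values = data.to_numpy(dtype=float)
    present = ~np.isnan(values)
    ab = np.where(present, values, 0.0)

    site_codes = pd.MultiIndex.from_arrays(
        [idx.get_level_values("protein"), idx.get_level_values("glycosite")]
    )
    rows = []
    for site in site_codes.unique():
        sel = (site_codes == site)
        w = ab[sel]
        tot = w.sum(axis=0)
        fuc_num = (w * fuc[sel, None]).sum(axis=0)
        ant_den = (w * ant[sel, None]).sum(axis=0)
        sia_num = (w * sia[sel, None]).sum(axis=0)
        cplx = sel.copy()
        cplx[sel] = is_complex[sel]
        wc = ab[cplx]
        gal_num = (wc * gal[cplx][:, None]).sum(axis=0)
        gal_den = (wc * ant[cplx][:, None]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frame = pd.DataFrame({
                "protein": site[0],
                "glycosite": site[1],
                "sample_id": data.columns,
                "fucosylation": np.where(tot > 0, fuc_num / np.where(tot > 0, tot, 1), np.nan),
                "sialylation": np.where(ant_den > 0, sia_num / np.where(ant_den > 0, ant_den, 1), np.nan),
                "galactosylation": np.where(gal_den > 0, gal_num / np.where(gal_den > 0, gal_den, 1), np.nan),
            })
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class DatasetDescriptors:
    """Cohort-level, abundance-weighted glycosylation summary."""

    fraction_complex: float
    average_antenna_sialylation: float
    fraction_antennary_sialylated: float
    average_fucosylation: float
    type_ratio: dict[str, float]
    branching_distribution: dict[int, float]


def dataset_descriptors(
    matrix: GlycoMatrix, features: dict[str, GlycanFeatures] | None = None
) -> DatasetDescriptors:
    """Dataset-level metric summary over all samples, abundance-weighted."""
    if matrix.scale == "log":
        raise ValueError("descriptors must be computed on raw/normalized areas")
    if features is None:
        features = glycan_features_for(matrix)
    glycans = matrix.data.index.get_level_values("glycan")
    feats = [features[g] for g in glycans]
    ab = np.nan_to_num(matrix.data.to_numpy(dtype=float), nan=0.0).sum(axis=1)
    total = ab.sum()
    if total <= 0:
        raise ValueError("matrix has no positive abundance")

    fuc = np.array([f.is_fucosylated for f in feats], dtype=float)
    sia_ant = np.array([f.sialic_antennae for f in feats], dtype=float)
    ant = np.array([f.antennae for f in feats], dtype=float)
    has_ant = ant >= 1
    is_sial = np.array([f.is_sialylated for f in feats], dtype=float)
    cls = np.array([f.glycan_class.value for f in feats])

    ant_total = float((ab * ant).sum())
    ant_ab = float(ab[has_ant].sum())
    type_ratio = {
        c: float(ab[cls == c].sum() / total)
        for c in sorted(set(cls))
    }
    branching = {
        int(a): float(ab[ant == a].sum() / total)
        for a in sorted(set(ant.astype(int)))
    }
    return DatasetDescriptors(
        fraction_complex=float(ab[cls == "complex"].sum() / total),
        average_antenna_sialylation=(
            float((ab * sia_ant).sum() / ant_total) if ant_total > 0 else 0.0
        ),
        fraction_antennary_sialylated=(
            float((ab[has_ant] * is_sial[has_ant]).sum() / ant_ab) if ant_ab > 0 else 0.0
        ),
        average_fucosylation=float((ab * fuc).sum() / total),
        type_ratio=type_ratio,
        branching_distribution=branching,
    )


def metric_table_to_features(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long site-metric table into a feature x sample matrix.

    Feature ids are ``protein|glycosite|metric``.
    """
    frames = []
    for metric in ("fucosylation", "sialylation", "galactosylation"):
        wide = metrics.pivot_table(
            index=["protein", "glycosite"], columns="sample_id", values=metric,
            aggfunc="first",
        )
        wide.index = [f"{p}|{s}|{metric}" for p, s in wide.index]
        frames.append(wide)
    out = pd.concat(frames)
    out.columns.name = None
    return out


def differential(
    feature_matrix: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    min_per_group: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Per-feature differential testing across sample groups.

    Two groups: pooled-variance t-test. More: one-way ANOVA, with a Tukey
    HSD pairwise table for every BH-significant feature. Features lacking
    ``min_per_group`` non-missing values in every group are skipped with a
    logged reason. Returns (result table, tukey table, skip log).
    """
    groups = groups.reindex(feature_matrix.columns)
    if groups.isna().any():
        bad = list(feature_matrix.columns[groups.isna()])
        raise ValueError(f"samples without group labels: {bad[:5]}")
    level_names = list(pd.unique(groups))
    rows, skipped = [], []
    pvals = []
    per_feature_groups = {}
    for feat, values in feature_matrix.iterrows():
        by_group = {
            g: values[groups == g].dropna().to_numpy(dtype=float)
            for g in level_names
        }
        if any(len(v) < min_per_group for v in by_group.values()):
            skipped.append({"feature": feat, "reason": "fewer than "
                            f"{min_per_group} non-missing values in some group"})
            continue
        concat = np.concatenate(list(by_group.values()))
        if np.ptp(concat) == 0.0:
            skipped.append({"feature": feat, "reason": "zero variance across all groups"})
            continue
        if len(level_names) == 2:
            res = gstats.student_t_test(by_group[level_names[0]], by_group[level_names[1]])
        else:
            res = gstats.one_way_anova([by_group[g] for g in level_names])
        row = {"feature": feat, "statistic": res.statistic, "p": res.pvalue}
        for g in level_names:
            row[f"mean_{g}"] = float(np.mean(by_group[g]))
        rows.append(row)
        pvals.append(res.pvalue)
        per_feature_groups[feat] = by_group

    result = pd.DataFrame(rows)
    tukey_rows = []
    if not result.empty:
        fdr = gstats.bh_fdr(np.array(pvals), alpha=alpha)
        result["q"] = fdr.qvalues
        result["significant"] = fdr.significant
        if len(level_names) > 2:
            for feat in result.loc[result["significant"], "feature"]:
                by_group = per_feature_groups[feat]
                for pair in gstats.tukey_hsd(
                    [by_group[g] for g in level_names], labels=level_names
                ):
                    tukey_rows.append({
                        "feature": feat,
                        "group_a": pair.group_a,
                        "group_b": pair.group_b,
                        "diff": pair.diff,
                        "p_adj": pair.pvalue,
                    })
    tukey = pd.DataFrame(tukey_rows,
                         columns=["feature", "group_a", "group_b", "diff", "p_adj"])
    return result, tukey, skipped
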