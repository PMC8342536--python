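"""Protein-level expression analysis.

Group-presence filtering, left-censored (down-shifted normal) imputation,
two-group volcano statistics, multi-group ANOVA with Tukey HSD post-hoc,
correlation-distance clustering of significant proteins into up/down
groups, grading-scheme correlation and row Z-scoring. Matrices are
proteins x samples on log2 scale with NaN for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from glycodiff import stats as gstats
from glycodiff.glyco import differential


@dataclass
class ProteinMatrix:
    """Log-intensity matrix with missingness mask and provenance."""

    data: pd.DataFrame
    groups: pd.Series | None = None
    imputed_mask: pd.DataFrame | None = None
    provenance: list = field(default_factory=list)

    def log(self, step: str, **info) -> "ProteinMatrix":
        return replace(self, provenance=self.provenance + [{"step": step, **info}])


def group_presence_filter(
    matrix: ProteinMatrix,
    fraction: float = 0.6,
    require_all_groups: bool = False,
) -> ProteinMatrix:
    """Keep proteins quantified in >= ``fraction`` of samples of a group.

    The default keeps a protein if at least one group meets the fraction;
    ``require_all_groups=True`` switches to the stricter every-group
    reading.
    """
    if matrix.groups is None:
        raise ValueError("matrix has no group labels")
    groups = matrix.groups.reindex(matrix.data.columns)
    frac_by_group = pd.DataFrame({
        g: matrix.data.loc[:, groups.index[groups == g]].notna().mean(axis=1)
        for g in pd.unique(groups)
    })
    ok = (frac_by_group >= fraction)
    keep = ok.all(axis=1) if require_all_groups else ok.any(axis=1)
    if not keep.any():
        raise ValueError("group presence filter removed every protein")
    out = replace(matrix, data=matrix.data.loc[keep])
    return out.log(
        "group_presence_filter",
        fraction=fraction,
        require_all_groups=require_all_groups,
        proteins_removed=int((~keep).sum()),
    )


def impute_missing(
    matrix: ProteinMatrix,
    down_shift: float = 1.8,
    width: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> ProteinMatrix:
    """Impute missing cells from a down-shifted normal distribution.

    With mu and sigma the mean and standard deviation of all observed
    values of the whole matrix, missing cells are drawn i.i.d. from
    ``Normal(mu - down_shift * sigma, (width * sigma)^2)``. Observed cells
    are never modified; imputed positions are recorded in
    ``imputed_mask``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = matrix.data.to_numpy(dtype=float)
    observed = values[~np.isnan(values)]
    if observed.size == 0:
        raise ValueError("matrix has no observed values")
    mu = float(observed.mean())
    sigma = float(observed.std(ddof=0))
    mask = np.isnan(values)
    note = ""
    if sigma == 0.0 and mask.any():
        note = "zero observed spread; imputed all missing cells at the mean"
    draws = rng.normal(mu - down_shift * sigma, width * sigma, size=int(mask.sum()))
    filled = values.copy()
    filled[mask] = draws
    out = replace(
        matrix,
        data=pd.DataFrame(filled, index=matrix.data.index, columns=matrix.data.columns),
        imputed_mask=pd.DataFrame(mask, index=matrix.data.index,
                                  columns=matrix.data.columns),
    )
    return out.log(
        "impute_missing",
        down_shift=down_shift, width=width,
        n_imputed=int(mask.sum()), mu=mu, sigma=sigma, note=note,
    )


def two_group_volcano(
    matrix: ProteinMatrix,
    alpha: float = 0.05,
    fc_over: float = 2.0,
    fc_under: float = 0.5,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Normal-vs-PCa volcano table.

    Fold change is ``log_base ** (mean_PCa - mean_Normal)``; classes are
    ``over2x`` (fold > fc_over and significant), ``under0.5x`` (fold <
    fc_under and significant), ``significant_only``, ``ns``. Boundaries
    are strict.
    """
    if matrix.groups is None:
        raise ValueError("matrix has no group labels")
    groups = matrix.groups.reindex(matrix.data.columns)
    two = groups.map(lambda g: "Normal" if g == "Normal" else "PCa")
    result, _, skipped = differential(matrix.data, two, alpha=alpha)
    if result.empty:
        return pd.DataFrame(columns=["protein", "log_fc", "fold_change", "p", "q",
                                     "significant", "volcano_class"])
    log_fc = result["mean_PCa"] - result["mean_Normal"]
    fold = np.power(log_base, log_fc)
    cls = np.where(
        ~result["significant"], "ns",
        np.where(fold > fc_over, "over2x",
                 np.where(fold < fc_under, "under0.5x", "significant_only")),
    )
    out = pd.DataFrame({
        "protein": result["feature"],
        "mean_Normal": result["mean_Normal"],
        "mean_PCa": result["mean_PCa"],
        "log_fc": log_fc,
        "fold_change": fold,
        "p": result["p"],
        "q": result["q"],
        "significant": result["significant"],
        "volcano_class": cls,
    })
    return out


def multigroup_anova_tukey(
    matrix: ProteinMatrix, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA per protein across grade groups, BH over proteins,
    Tukey HSD pairwise table for the significant set."""
    if matrix.groups is None:
        raise ValueError("matrix has no group labels")
    groups = matrix.groups.reindex(matrix.data.columns)
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError(f"groups with < 2 samples: {list(counts.index[counts < 2])}")
    result, tukey, _ = differential(matrix.data, groups, alpha=alpha)
    result = result.rename(columns={"feature": "protein"})
    tukey = tukey.rename(columns={"feature": "protein"})
    return result, tukey


def group_mean_profiles(matrix: ProteinMatrix, order: list | None = None) -> pd.DataFrame:
    """Per-protein mean intensity per group (columns in ``order``)."""
    groups = matrix.groups.reindex(matrix.data.columns)
    prof = matrix.data.T.groupby(groups).mean().T
    if order is not None:
        prof = prof[order]
    return prof


def cluster_significant(
    matrix: ProteinMatrix,
    significant: list,
    group_order: list | None = None,
    use_sample_profiles: bool = False,
) -> pd.DataFrame:
    """Split significant proteins into up/down clusters.

    Average-linkage hierarchical clustering with 1 - Spearman correlation
    distance over per-group mean profiles (or full per-sample profiles),
    cut at 2 clusters. The cluster whose mean PCa-minus-Normal difference
    is positive is labelled ``up``.
    """
    if len(significant) < 2:
        raise ValueError("need at least 2 significant proteins to cluster")
    sub = matrix.data.loc[list(significant)]
    groups = matrix.groups.reindex(matrix.data.columns)
    if use_sample_profiles:
        profiles = sub
    else:
        profiles = group_mean_profiles(replace(matrix, data=sub), order=group_order)
    labels = gstats.hier_cluster(profiles.to_numpy(), method="spearman", k=2)

    normal_cols = groups.index[groups == "Normal"]
    cancer_cols = groups.index[groups != "Normal"]
    delta = sub[cancer_cols].mean(axis=1) - sub[normal_cols].mean(axis=1)
    mean_delta = {c: float(delta[labels == c].mean()) for c in (0, 1)}
    up_cluster = max(mean_delta, key=mean_delta.get)
    direction = np.where(labels == up_cluster, "up", "down")
    return pd.DataFrame({
        "protein": list(significant),
        "cluster": labels,
        "direction": direction,
    })


def grade_scheme_correlation(
    matrix: ProteinMatrix,
    proteins: list,
    scheme_a: pd.Series,
    scheme_b: pd.Series,
    pairs: list[tuple[tuple, str]],
) -> pd.DataFrame:
    """Pearson correlation of group-mean vectors between grading schemes.

    ``pairs`` lists (scheme-B group tuple, scheme-A group) comparisons,
    e.g. ``[(("GG3", "GG4"), "G2")]`` pools GG3 and GG4 samples before
    averaging. Undefined correlations (zero-variance vector) are NaN.
    """
    sub = matrix.data.loc[list(proteins)]
    rows = []
    for b_labels, a_label in pairs:
        cols_a = scheme_a.index[scheme_a == a_label]
        cols_b = scheme_b.index[scheme_b.isin(b_labels)]
        va = sub[sub.columns.intersection(cols_a)].mean(axis=1).to_numpy()
        vb = sub[sub.columns.intersection(cols_b)].mean(axis=1).to_numpy()
        r = gstats.correlation(va, vb, method="pearson")
        rows.append({
            "scheme_b_groups": "+".join(b_labels),
            "scheme_a_group": a_label,
            "pearson_r": r,
        })
    return pd.DataFrame(rows)


def zscore_rows(data: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores; constant rows become all zeros."""
    values = data.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("zscore_rows requires a complete (imputed) matrix")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore"):
        z = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=data.index, columns=data.columns)
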