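"""Single-cell feature-table QC, power transformation, scaling and
correlation-based feature-set partitioning.

The table holds cells × features plus cell metadata (plate/well/field,
donor, control group) and feature metadata following the
``object_category_subtype_channel`` naming convention. QC runs sequentially
at the image, feature and cell level; features are then Box–Cox transformed
(λ chosen by maximum profile likelihood on a grid, snapped to the log or
identity transform within a fudge factor), z-scored, and partitioned into
"feature sets" — complete-linkage clusters of the positive-correlation
dissimilarity cut at 0.3 — so redundant features are reported jointly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

IMAGE_KEYS = ["plate", "well", "field"]


@dataclass
class FeatureTable:
    """Cells × features matrix with aligned cell and feature metadata."""

    values: pd.DataFrame                 # index: cell id, columns: feature names
    cell_meta: pd.DataFrame              # index: cell id
    feature_meta: pd.DataFrame = None    # index: feature name

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("cell ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("feature names must be unique")
        if not self.values.index.equals(self.cell_meta.index):
            self.cell_meta = self.cell_meta.loc[self.values.index]
        if self.feature_meta is None:
            self.feature_meta = parse_feature_names(self.values.columns)
        else:
            self.feature_meta = self.feature_meta.loc[self.values.columns]

    @property
    def n_cells(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, index) -> "FeatureTable":
        return FeatureTable(self.values.loc[index], self.cell_meta.loc[index],
                            self.feature_meta)

    def subset_features(self, names) -> "FeatureTable":
        names = list(names)
        return FeatureTable(self.values[names], self.cell_meta,
                            self.feature_meta.loc[names])

    def image_ids(self) -> pd.Series:
        keys = [k for k in IMAGE_KEYS if k in self.cell_meta.columns]
        if not keys:
            raise ValueError(f"cell metadata lacks image keys {IMAGE_KEYS}")
        return self.cell_meta[keys].astype(str).agg("/".join, axis=1)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.values.join(self.cell_meta, how="left").to_csv(path)
        return path

    def to_parquet(self, path: str | Path) -> Path:
        path = Path(path)
        self.values.join(self.cell_meta, how="left").to_parquet(path)
        return path


def parse_feature_names(names) -> pd.DataFrame:
    """Split object_category_subtype_channel feature names into metadata."""
    rows = []
    for name in names:
        parts = str(name).split("_")
        rows.append({
            "object": parts[0] if len(parts) > 0 else "",
            "category": parts[1] if len(parts) > 1 else "",
            "subtype": "_".join(parts[2:-1]) if len(parts) > 3 else
                       (parts[2] if len(parts) == 4 else ""),
            "channel": parts[-1] if len(parts) > 2 else "",
        })
    return pd.DataFrame(rows, index=pd.Index(names, name="feature"))


@dataclass
class QCReport:
    stage: str
    n_in: int
    n_removed: int
    n_out: int
    reasons: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_in != self.n_out + self.n_removed:
            raise ValueError("QC counts must conserve: in = out + removed")

    def as_dict(self) -> dict:
        return vars(self)


def image_qc(table: FeatureTable, min_cells: int = 5, max_cells: int = 1000
             ) -> tuple[FeatureTable, QCReport]:
    """Drop images (and their cells) with < min_cells or > max_cells cells.

    Boundary counts (exactly min_cells or max_cells) are retained.
    """
    ids = table.image_ids()
    counts = ids.value_counts()
    bad = counts[(counts < min_cells) | (counts > max_cells)].index
    keep = ~ids.isin(bad)
    report = QCReport(
        stage="image_qc",
        n_in=table.n_cells,
        n_removed=int((~keep).sum()),
        n_out=int(keep.sum()),
        reasons={"images_removed": int(len(bad)), "images_in": int(len(counts))},
        thresholds={"min_cells": min_cells, "max_cells": max_cells},
    )
    if keep.sum() == 0:
        raise ValueError(f"image QC removed every cell: {report.as_dict()}")
    return table.subset_cells(table.values.index[keep]), report


def find_outlier_pca(
    table: FeatureTable,
    features: list[str] | None = None,
    by: str = "control_group",
    var_target: float = 0.75,
    fdr: float = 0.05,
) -> pd.Series:
    """Flag multivariate outliers per control group in PCA space.

    Within each group the feature subset is z-scored, PCA retains the
    smallest number of components reaching ``var_target`` cumulative
    variance, and each observation's squared Euclidean distance over the
    standardized retained scores is referred to a χ²(k) distribution;
    Benjamini–Hochberg adjusted p-values below ``fdr`` are flagged.
    """
    feats = list(features) if features is not None else list(table.values.columns)
    flags = pd.Series(False, index=table.values.index)
    groups = table.cell_meta[by] if by in table.cell_meta.columns else pd.Series(
        "all", index=table.values.index)
    for gname, idx in groups.groupby(groups).groups.items():
        X = table.values.loc[idx, feats].to_numpy(dtype=np.float64)
        if len(idx) < 3:
            warnings.warn(f"group {gname!r} has < 3 members; skipped", stacklevel=2)
            continue
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        k_max = min(Z.shape) - 1
        if k_max < 1:
            continue
        pca = PCA(n_components=k_max)
        scores = pca.fit_transform(Z)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, var_target) + 1)
        k = min(k, k_max)
        sc_sd = scores[:, :k].std(axis=0)
        sc_sd[sc_sd == 0] = 1.0
        d2 = ((scores[:, :k] / sc_sd) ** 2).sum(axis=1)
        pvals = stats.chi2.sf(d2, df=k)
        rej = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
        flags.loc[idx] = rej
    return flags


@dataclass
class FeatureFilterSpec:
    blacklist: tuple = ()
    max_missing_fraction: float = 0.5
    min_unique_values: int = 2
    min_cv: float = 0.0


def apply_feature_filters(table: FeatureTable, spec: FeatureFilterSpec
                          ) -> tuple[FeatureTable, QCReport]:
    """Remove blacklisted, near-constant, missing-heavy or low-CV features."""
    vals = table.values
    reasons = {}
    bad: set[str] = set()

    blk = set(spec.blacklist) & set(vals.columns)
    reasons["blacklist"] = len(blk)
    bad |= blk

    miss = vals.isna().mean()
    hit = set(miss.index[miss > spec.max_missing_fraction])
    reasons["missing"] = len(hit - bad)
    bad |= hit

    nuniq = vals.nunique(dropna=True)
    hit = set(nuniq.index[nuniq < spec.min_unique_values])
    reasons["unique_values"] = len(hit - bad)
    bad |= hit

    if spec.min_cv > 0:
        mean = vals.mean().abs()
        cv = vals.std() / mean.replace(0, np.nan)
        hit = set(cv.index[cv.fillna(np.inf) < spec.min_cv])
        reasons["low_cv"] = len(hit - bad)
        bad |= hit

    keep = [c for c in vals.columns if c not in bad]
    report = QCReport("feature_filters", table.n_features, len(bad), len(keep),
                      reasons=reasons, thresholds=vars(spec).copy())
    if not keep:
        raise ValueError("feature filters removed every feature")
    return table.subset_features(keep), report


def apply_cell_filters(
    table: FeatureTable,
    thresholds: dict[str, tuple[float | None, float | None]],
    registration_column: str | None = "registration_r",
    registration_threshold: float = 0.6,
) -> tuple[FeatureTable, QCReport]:
    """Hard-threshold cell filters (size, nucleus count, missingness, ...).

    ``thresholds`` maps a cell-metadata column to (min, max); None disables a
    bound. Cells failing registration QC (r < 0.6) are removed when the
    registration column is present.
    """
    meta = table.cell_meta
    keep = pd.Series(True, index=meta.index)
    reasons = {}
    for col, (lo, hi) in thresholds.items():
        if col not in meta.columns:
            raise KeyError(f"cell filter references missing column {col!r}")
        v = meta[col]
        bad = pd.Series(False, index=meta.index)
        if lo is not None:
            bad |= v < lo
        if hi is not None:
            bad |= v > hi
        reasons[col] = int((bad & keep).sum())
        keep &= ~bad
    if registration_column and registration_column in meta.columns:
        bad = meta[registration_column] < registration_threshold
        reasons["registration"] = int((bad & keep).sum())
        keep &= ~bad
    report = QCReport("cell_filters", table.n_cells, int((~keep).sum()),
                      int(keep.sum()), reasons=reasons,
                      thresholds={k: list(v) for k, v in thresholds.items()})
    return table.subset_cells(meta.index[keep]), report


# ---------------------------------------------------------------------------
# Box-Cox transformation


@dataclass
class FeatureTransform:
    shift: float          # additive offset applied before the power transform
    lambda_raw: float     # grid maximizer before snapping
    lambda_: float        # after fudge snapping
    snapped: str          # "log" | "identity" | "none"


@dataclass
class TransformSpec:
    per_feature: dict[str, FeatureTransform]
    grid: tuple[float, float, float] = (-5.0, 5.0, 0.1)
    fudge: float = 0.2
    subsample: int = 20000
    seed: int = 0

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "grid": list(self.grid), "fudge": self.fudge,
            "subsample": self.subsample, "seed": self.seed,
            "per_feature": {k: vars(v) for k, v in self.per_feature.items()},
        }, indent=1))
        return path


def positivity_shift(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Map a vector with non-positive minimum onto [1, ∞): if min(x) ≤ 0 then
    x ← |min(x)| + x + 1, making the new minimum exactly 1."""
    x = np.asarray(x, dtype=np.float64)
    finite = x[np.isfinite(x)]
    mn = finite.min() if finite.size else 1.0
    if mn <= 0:
        # |min(x)| + x + 1 == x - min(x) + 1; subtracting first keeps the
        # minimum element at exactly 1.0 in floating point
        return x - mn + 1.0, abs(mn) + 1.0
    return x, 0.0


def _boxcox_apply(x: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def select_boxcox_lambda(
    x: np.ndarray,
    grid: tuple[float, float, float] = (-5.0, 5.0, 0.1),
    fudge: float = 0.2,
) -> tuple[float, float]:
    """Profile-log-likelihood grid search for the Box–Cox exponent.

    Returns (lambda_raw, lambda_snapped): |λ| ≤ fudge snaps to 0 (log) and
    |λ − 1| ≤ fudge snaps to 1 (identity). Ties break toward the λ closest
    to 1, then the smaller λ.
    """
    x = np.asarray(x, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.min() <= 0:
        raise ValueError("Box-Cox requires positive values; shift first")
    lo, hi, step = grid
    lams = np.round(np.arange(lo, hi + step / 2, step), 10)
    llf = np.array([stats.boxcox_llf(l, x) for l in lams])
    best = llf.max()
    cand = lams[np.isclose(llf, best, rtol=0, atol=1e-9)]
    lam = cand[np.lexsort((cand, np.abs(cand - 1.0)))][0]
    if abs(lam) <= fudge:
        return float(lam), 0.0
    if abs(lam - 1.0) <= fudge:
        return float(lam), 1.0
    return float(lam), float(lam)


def boxcox_transform(
    table: FeatureTable,
    grid: tuple[float, float, float] = (-5.0, 5.0, 0.1),
    fudge: float = 0.2,
    subsample: int = 20000,
    seed: int = 0,
) -> tuple[FeatureTable, TransformSpec]:
    """Box–Cox transform every feature toward normality.

    λ is selected on a seeded random subsample of up to ``subsample`` cells
    and the chosen transform applied to all rows. Features producing
    non-finite values are flagged with a warning.
    """
    rng = np.random.default_rng(seed)
    n = table.n_cells
    rows = (np.sort(rng.choice(n, size=subsample, replace=False))
            if n > subsample else np.arange(n))
    out = {}
    per_feature = {}
    for name in table.values.columns:
        full = table.values[name].to_numpy(dtype=np.float64)
        shifted, shift = positivity_shift(full)
        sample = shifted[rows]
        sample = sample[np.isfinite(sample)]
        lam_raw, lam = select_boxcox_lambda(sample, grid, fudge)
        transformed = _boxcox_apply(shifted, lam) if lam != 1.0 else shifted
        snapped = "log" if lam == 0 and abs(lam_raw) <= fudge else (
            "identity" if lam == 1.0 and lam_raw != 1.0 else "none")
        if not np.isfinite(transformed[np.isfinite(full)]).all():
            warnings.warn(f"feature {name}: non-finite values after transform",
                          stacklevel=2)
        out[name] = transformed
        per_feature[name] = FeatureTransform(shift, lam_raw, lam, snapped)
    values = pd.DataFrame(out, index=table.values.index)
    spec = TransformSpec(per_feature, grid, fudge, subsample, seed)
    return (FeatureTable(values, table.cell_meta, table.feature_meta), spec)


def scale_features(table: FeatureTable) -> FeatureTable:
    """Z-score every feature (mean 0, sd 1); constant features become 0."""
    vals = table.values
    mean = vals.mean()
    sd = vals.std(ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance features set to 0",
                      stacklevel=2)
    sd = sd.replace(0, 1.0)
    scaled = (vals - mean) / sd
    scaled.loc[:, zero[zero].index] = 0.0
    return FeatureTable(scaled, table.cell_meta, table.feature_meta)


# ---------------------------------------------------------------------------
# Feature sets


@dataclass
class FeatureSetPartition:
    assignments: pd.Series        # feature name → set id (string)
    cut: float
    scope: str
    linkage_records: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assignments.isna().any():
            raise ValueError("every feature must belong to a set")

    def sets(self) -> dict[str, list[str]]:
        return {sid: list(idx) for sid, idx in
                self.assignments.groupby(self.assignments).groups.items()}

    @property
    def n_sets(self) -> int:
        return self.assignments.nunique()


def _cluster_scope(vals: pd.DataFrame, cut: float) -> pd.Series:
    names = list(vals.columns)
    if len(names) == 1:
        return pd.Series([1], index=names)
    corr = np.corrcoef(vals.to_numpy(dtype=np.float64), rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    corr = np.clip(corr, 0.0, 1.0)  # negative correlations → dissimilarity 1
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2
    Z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(Z, t=cut, criterion="distance")
    return pd.Series(labels, index=names)


def partition_feature_sets(
    table: FeatureTable,
    scope: str = "channel",
    cut: float = 0.3,
) -> FeatureSetPartition:
    """Group correlated features into sets by complete-linkage clustering.

    Within each scope (``channel``, ``channel_category`` or ``all``) the
    Pearson correlation matrix of the transformed assay is computed, negative
    correlations are set to 0, dissimilarity = 1 − correlation, and the
    complete-linkage dendrogram is cut at ``cut``. Set ids are numbered
    deterministically by first feature appearance within each scope.
    """
    meta = table.feature_meta
    if scope == "channel":
        scoping = meta["channel"].astype(str)
    elif scope == "channel_category":
        scoping = meta["channel"].astype(str) + "_" + meta["category"].astype(str)
    elif scope == "all":
        scoping = pd.Series("all", index=meta.index)
    else:
        raise ValueError(f"unknown scope {scope!r}")

    assignments = pd.Series(index=table.values.columns, dtype=object)
    for sname in scoping.unique():
        cols = [c for c in table.values.columns if scoping[c] == sname]
        labels = _cluster_scope(table.values[cols], cut)
        # renumber by first appearance for determinism
        remap, nxt = {}, 1
        for c in cols:
            lab = labels[c]
            if lab not in remap:
                remap[lab] = nxt
                nxt += 1
        for c in cols:
            assignments[c] = f"{sname}__{remap[labels[c]]}"
    return FeatureSetPartition(assignments, cut=cut, scope=scope)


def summarize_feature_sets(
    results: pd.DataFrame,
    partition: FeatureSetPartition,
    alpha: float = 0.05,
    coef_col: str = "coef",
    padj_col: str = "p_adj",
    feature_col: str = "feature",
) -> pd.DataFrame:
    """Per-set summary of per-feature model statistics.

    A set is significant if any member is; the effect size is the mean
    coefficient over members; the representative feature is the member with
    the smallest adjusted p.
    """
    orphans = set(results[feature_col]) - set(partition.assignments.index)
    if orphans:
        raise ValueError(f"features missing from the partition: {sorted(orphans)}")
    res = results.copy()
    res["feature_set"] = res[feature_col].map(partition.assignments)
    rows = []
    for sid, grp in res.groupby("feature_set", sort=True):
        best = grp.loc[grp[padj_col].idxmin()]
        rows.append({
            "feature_set": sid,
            "n_features": grp[feature_col].nunique(),
            "significant": bool((grp[padj_col] < alpha).any()),
            "mean_coef": float(grp[coef_col].mean()),
            "representative_feature": best[feature_col],
            "min_p_adj": float(grp[padj_col].min()),
        })
    return pd.DataFrame(rows).set_index("feature_set")
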