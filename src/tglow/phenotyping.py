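"""Cell-cycle gating, per-feature linear modelling with marker contrasts,
composition (proportion) models and representative-cell selection.

Cell-cycle phases are assigned flow-cytometry style, with manually drawn
polygon gates in the plane of raw integrated nuclear DNA intensity (x)
versus log10 integrated nuclear Ki67 intensity (y); G0 cells sit at 2N DNA /
low Ki67, G1 at 2N / high Ki67, S between 2N and 4N, G2M at 4N. Cells in no
gate are labelled "Other".

Per-feature associations are fit feature-by-feature with a fixed-effects
linear model; marker detection uses a no-intercept class-means model with a
contrast testing one class against the mean of the rest (or a reference
class). The record shape is backend-agnostic so a mixed-model engine can be
plugged in without changing downstream summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .features import FeatureTable

PHASES = ("G0", "G1", "S", "G2M")
OTHER_LABEL = "Other"


@dataclass
class GateSet:
    """Ordered named polygon gates in the DNA × log10(Ki67) plane.

    Evaluation is first-wins in declaration order; polygon boundaries count
    as inside; points in no polygon get the fallback label "Other".
    """

    gates: dict[str, Polygon] = field(default_factory=dict)
    x_column: str = "nucleus_intensity_integrated_dna"
    y_column: str = "nucleus_intensity_integrated_ki67"
    log10_y: bool = True

    def __post_init__(self) -> None:
        for name, poly in self.gates.items():
            if not poly.is_valid:
                raise ValueError(f"gate {name!r}: polygon is not simple/valid")

    @classmethod
    def from_vertices(cls, vertices: dict[str, list[tuple[float, float]]],
                      **kwargs) -> "GateSet":
        return cls({name: Polygon(pts) for name, pts in vertices.items()}, **kwargs)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "x_column": self.x_column,
            "y_column": self.y_column,
            "log10_y": self.log10_y,
            "gates": {name: list(map(list, poly.exterior.coords))
                      for name, poly in self.gates.items()},
        }, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GateSet":
        d = json.loads(Path(path).read_text())
        return cls.from_vertices(d["gates"], x_column=d["x_column"],
                                 y_column=d["y_column"], log10_y=d["log10_y"])

    def assign(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized first-wins point-in-polygon assignment."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        labels = np.full(len(x), OTHER_LABEL, dtype=object)
        unassigned = np.ones(len(x), dtype=bool)
        for name, poly in self.gates.items():
            if not unassigned.any():
                break
            # intersects includes the polygon boundary
            hit = shapely.intersects_xy(poly, x[unassigned], y[unassigned])
            idx = np.flatnonzero(unassigned)[hit]
            labels[idx] = name
            unassigned[idx] = False
        return labels


def assign_cell_cycle(
    table: FeatureTable,
    gates: GateSet,
    sample_column: str = "donor",
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each cell a cell-cycle phase and tabulate per-sample fractions.

    Returns (labels, fractions) where fractions has one row per sample and
    one column per phase, in percent (rows sum to 100).
    """
    for col in (gates.x_column, gates.y_column):
        if col not in table.values.columns and col not in table.cell_meta.columns:
            raise KeyError(f"gating column {col!r} not found")

    def fetch(col):
        src = table.values if col in table.values.columns else table.cell_meta
        return src[col].to_numpy(dtype=np.float64)

    x = fetch(gates.x_column)
    y = fetch(gates.y_column)
    if gates.log10_y:
        y = np.log10(np.clip(y, 1e-12, None))
    labels = pd.Series(gates.assign(x, y), index=table.values.index, name="phase")

    samples = (table.cell_meta[sample_column] if sample_column in table.cell_meta
               else pd.Series("all", index=labels.index))
    frac = (pd.crosstab(samples, labels, normalize="index") * 100.0)
    return labels, frac


# ---------------------------------------------------------------------------
# Per-feature linear models


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def fit_feature_model(
    table: FeatureTable,
    term: str,
    covariates: list[str] | None = None,
    reduced_covariates_only: bool = True,
) -> pd.DataFrame:
    """Fit ``feature ~ term + covariates`` by OLS for every feature.

    For each feature the coefficient, standard error and p-value of ``term``
    are reported, together with a likelihood-ratio test between the full
    model and the reduced model without the term. Benjamini–Hochberg
    adjustment is applied across features. Categorical terms are expanded to
    treatment-coded indicators; the LRT then covers the whole group of
    coefficients.
    """
    covariates = covariates or []
    meta = table.cell_meta
    for col in [term] + covariates:
        if col not in meta.columns:
            raise KeyError(f"model term {col!r} missing from cell metadata")
        if meta[col].nunique() < 2:
            raise ValueError(f"model term {col!r} has < 2 distinct values")

    X_red = pd.get_dummies(meta[covariates], drop_first=True, dtype=float) \
        if covariates else pd.DataFrame(index=meta.index)
    X_red.insert(0, "Intercept", 1.0)
    term_block = (pd.get_dummies(meta[[term]], drop_first=True, dtype=float)
                  if not pd.api.types.is_numeric_dtype(meta[term])
                  else meta[[term]].astype(float))
    X_full = pd.concat([X_red, term_block], axis=1)
    term_cols = list(term_block.columns)

    rows = []
    for name in table.values.columns:
        y = table.values[name].to_numpy(dtype=np.float64)
        ok = np.isfinite(y)
        full = sm.OLS(y[ok], X_full.to_numpy(dtype=np.float64)[ok]).fit()
        red = sm.OLS(y[ok], X_red.to_numpy(dtype=np.float64)[ok]).fit()
        lr = 2.0 * (full.llf - red.llf)
        lr = max(lr, 0.0)
        from scipy import stats as sps
        lrt_p = sps.chi2.sf(lr, df=len(term_cols)) if lr > 0 else 1.0
        j = list(X_full.columns).index(term_cols[0])
        rows.append({
            "feature": name,
            "term": term,
            "coef": float(full.params[j]),
            "se": float(full.bse[j]),
            "p": float(full.pvalues[j]),
            "lrt_stat": float(lr),
            "lrt_p": float(lrt_p),
            "formula": f"{name} ~ {' + '.join(X_full.columns[1:])}",
            "backend": "ols",
        })
    out = pd.DataFrame(rows)
    out["p_adj"] = _bh(out["p"].to_numpy())
    out["lrt_p_adj"] = _bh(out["lrt_p"].to_numpy())
    return out


def find_markers(
    table: FeatureTable,
    labels: pd.Series | str,
    mode: str = "vs-rest",
    reference: str | None = None,
    min_cells: int = 2,
) -> pd.DataFrame:
    """Marker features per class via contrasts on a no-intercept class model.

    The model regresses each feature on class indicator columns without an
    intercept, so each coefficient is a class mean. The vs-rest contrast puts
    1 on the class of interest and −1/(K−1) on every other class; vs-reference
    puts 1 on the class and −1 on the reference. p-values are BH-adjusted
    across features within each class.
    """
    if isinstance(labels, str):
        labels = table.cell_meta[labels]
    labels = labels.astype(str)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if mode == "vs-reference":
        if reference is None or reference not in classes:
            raise ValueError("vs-reference mode needs a valid reference class")
    counts = labels.value_counts()

    D = pd.get_dummies(labels, dtype=float)[classes].to_numpy()
    Y = table.values.to_numpy(dtype=np.float64)
    rows = []
    for ci, cls in enumerate(classes):
        if counts[cls] < min_cells:
            continue
        c = np.zeros(len(classes))
        if mode == "vs-rest":
            c[:] = -1.0 / (len(classes) - 1)
            c[ci] = 1.0
        elif mode == "vs-reference":
            if cls == reference:
                continue
            c[ci] = 1.0
            c[classes.index(reference)] = -1.0
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for fi, name in enumerate(table.values.columns):
            y = Y[:, fi]
            ok = np.isfinite(y)
            fit = sm.OLS(y[ok], D[ok]).fit()
            tt = fit.t_test(c)
            rows.append({
                "class": cls,
                "feature": name,
                "coef": float(np.atleast_1d(tt.effect)[0]),
                "se": float(np.atleast_1d(tt.sd).ravel()[0]),
                "p": float(np.atleast_1d(tt.pvalue).ravel()[0]),
                "mode": mode,
                "contrast": " ".join(f"{w:+.3g}·{k}" for w, k in zip(c, classes) if w),
            })
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for cls, idx in out.groupby("class").groups.items():
        out.loc[idx, "p_adj"] = _bh(out.loc[idx, "p"].to_numpy())
    return out


def proportion_model(
    fractions: pd.DataFrame,
    design: pd.Series | pd.DataFrame,
) -> pd.DataFrame:
    """Linear regression of per-sample composition on a design variable.

    ``fractions`` holds percentages (rows = samples, columns = categories,
    rows summing to ~100); ``design`` is aligned on the sample index.
    Coefficients are in percentage points per design unit.
    """
    if isinstance(design, pd.Series):
        design = design.to_frame()
    design = design.loc[fractions.index].astype(float)
    X = sm.add_constant(design.to_numpy())
    if X.shape[0] <= X.shape[1]:
        raise ValueError("fewer samples than model parameters")
    rows = []
    for cat in fractions.columns:
        fit = sm.OLS(fractions[cat].to_numpy(dtype=np.float64), X).fit()
        for j, dname in enumerate(design.columns, start=1):
            rows.append({
                "category": cat,
                "term": str(dname),
                "coef": float(fit.params[j]),
                "se": float(fit.bse[j]),
                "p": float(fit.pvalues[j]),
            })
    out = pd.DataFrame(rows)
    out["p_adj"] = _bh(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Representative cells


def representative_cells_categorical(
    scores: pd.DataFrame,
    labels: pd.Series,
    k: int = 8,
) -> dict[str, dict]:
    """Index cell and neighbours per group, nearest the group centroid.

    ``scores`` is the reduced space (e.g. 30 PCs, rows = cells). Per group,
    PCs are centred to the group mean and the cell with the smallest sum of
    squares is the index cell; its k nearest neighbours (within the group, in
    the same space) extend the set.
    """
    labels = labels.loc[scores.index]
    out = {}
    for g, idx in labels.groupby(labels).groups.items():
        S = scores.loc[idx].to_numpy(dtype=np.float64)
        if len(idx) == 0:
            raise ValueError(f"group {g!r} is empty")
        centered = S - S.mean(axis=0)
        d2 = (centered ** 2).sum(axis=1)
        i0 = int(np.argmin(d2))
        index_cell = idx[i0]
        if len(idx) > 1:
            nn = NearestNeighbors(n_neighbors=min(k + 1, len(idx))).fit(S)
            _, nbr = nn.kneighbors(S[i0][None])
            neighbours = [idx[j] for j in nbr[0] if idx[j] != index_cell][:k]
        else:
            neighbours = []
        out[g] = {"index_cell": index_cell, "neighbours": neighbours,
                  "distance_sq": float(d2[i0])}
    return out


def representative_cells_continuous(
    values: pd.Series,
    quantiles: list[float] = (0.05, 0.50, 0.95),
    k: int = 8,
) -> dict[float, dict]:
    """Index cells at the requested quantiles of a feature, extended by the
    k cells ranked immediately below and above each index cell."""
    for q in quantiles:
        if not 0 < q < 1:
            raise ValueError("quantiles must lie in (0, 1)")
    order = values.sort_values(kind="mergesort")
    n = len(order)
    out = {}
    for q in quantiles:
        pos = int(round(q * (n - 1)))
        index_cell = order.index[pos]
        lo = max(pos - k, 0)
        hi = min(pos + k + 1, n)
        neighbours = [c for c in order.index[lo:hi] if c != index_cell]
        out[q] = {"index_cell": index_cell, "neighbours": neighbours,
                  "value": float(order.iloc[pos]), "rank": pos}
    return out
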