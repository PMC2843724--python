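"""Probe-level preprocessing: raw intensities to a genes x arrays log2 matrix.

The chain is fixed and order-checked::

    log2 -> spatial correction -> quantile normalization
         -> probe-effect removal -> gene summarization

Each numeric stage is a scikit-learn style transformer operating on
``X`` of shape ``(n_arrays, n_probes)`` (arrays are samples, probes are
features).  The module-level functions are thin wrappers that keep the
field's conventional probes-x-arrays orientation, carry probe metadata
(grid coordinates, probe-to-gene map) alongside the values, and record
provenance so that running stages out of order raises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from whorlstat.io import ProbeIntensityTable, StudyDesign


class PipelineOrderError(RuntimeError):
    """A preprocessing stage was applied out of its fixed position."""


@dataclass
class ProbeMatrix:
    """Intermediate probe-level matrix with metadata.

    values: probes x arrays DataFrame (log2 units once past the first
    stage); coords: per-probe 1-based grid position (shared array layout);
    gene_map: probe_id -> gene_id; provenance: applied stage names with
    parameters, in order.
    """

    values: pd.DataFrame
    coords: pd.DataFrame  # index probe_id, columns x, y
    gene_map: pd.Series  # index probe_id, value gene_id
    grid_shape: tuple[int, int]
    provenance: list[str] = field(default_factory=list)

    def _require_last_stage(self, expected: str, applying: str) -> None:
        last = self.provenance[-1].split("(")[0] if self.provenance else "<raw>"
        if last != expected:
            raise PipelineOrderError(
                f"cannot apply {applying} after {last}; the pipeline order is "
                "log_transform -> spatial_correct -> quantile_normalize -> "
                "probe_center -> summarize_genes"
            )


@dataclass
class ExpressionMatrix:
    """Summarized genes x arrays log2 expression with design metadata."""

    values: pd.DataFrame  # genes x arrays
    design: StudyDesign | None = None
    provenance: list[str] = field(default_factory=list)
    dropped_genes: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("ExpressionMatrix must not contain missing values")


# ---------------------------------------------------------------------------
# transformers


class SpatialMedianCorrector(BaseEstimator, TransformerMixin):
    """Remove smooth spatial artifacts from each array.

    Per array, residuals from the array median are smoothed with a
    window x window two-dimensional moving median over the probe grid
    (edge-truncated: near edges the window simply contains fewer cells)
    and the smoothed surface is subtracted.  The array median is preserved
    exactly, so only spatial structure -- not overall level -- is removed.

    Parameters
    ----------
    coords : array-like of shape (n_probes, 2)
        1-based (x, y) grid position of each feature; the layout is assumed
        shared by all arrays of the platform.
    window : odd int >= 3, default 15
        Side of the square moving-median neighborhood, in grid cells.
    grid_shape : (int, int), optional
        (max_x, max_y); inferred from coords when omitted.
    """

    def __init__(self, coords=None, window: int = 15, grid_shape=None):
        self.coords = coords
        self.window = window
        self.grid_shape = grid_shape

    def _validate(self, X):
        X = check_array(X, ensure_2d=True, dtype=float)
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        coords = np.asarray(self.coords, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be (n_probes, 2)")
        if coords.shape[0] != X.shape[1]:
            raise ValueError(
                f"coords has {coords.shape[0]} probes but X has {X.shape[1]} features"
            )
        if (coords < 1).any():
            raise ValueError("grid coordinates are 1-based and must be >= 1")
        return X, coords

    def fit(self, X, y=None):
        X, coords = self._validate(X)
        self.n_features_in_ = X.shape[1]
        if self.grid_shape is None:
            self.grid_shape_ = (int(coords[:, 0].max()), int(coords[:, 1].max()))
        else:
            self.grid_shape_ = tuple(self.grid_shape)
        return self

    def transform(self, X):
        check_is_fitted(self, "grid_shape_")
        X, coords = self._validate(X)
        ncol, nrow = self.grid_shape_  # x bound, y bound
        rows = coords[:, 1] - 1
        cols = coords[:, 0] - 1
        out = np.empty_like(X)
        for a in range(X.shape[0]):
            vals = X[a]
            med = np.median(vals)
            grid = np.full((nrow, ncol), np.nan)
            grid[rows, cols] = vals - med
            surface = _moving_nanmedian_2d(grid, self.window)
            corrected = vals - surface[rows, cols]
            corrected += med - np.median(corrected)
            out[a] = corrected
        return out


def _moving_nanmedian_2d(grid: np.ndarray, window: int) -> np.ndarray:
    """Edge-truncated 2-D moving median ignoring empty (NaN) grid cells.

    Processed in row blocks to bound the memory of the sliding-window view.
    """
    half = window // 2
    padded = np.pad(grid, half, constant_values=np.nan)
    out = np.empty_like(grid)
    nrow = grid.shape[0]
    block = max(1, int(2_000_000 / (grid.shape[1] * window * window)) or 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        for r0 in range(0, nrow, block):
            r1 = min(r0 + block, nrow)
            view = np.lib.stride_tricks.sliding_window_view(
                padded[r0 : r1 + 2 * half, :], (window, window)
            )
            out[r0:r1] = np.nanmedian(view, axis=(2, 3))
    return out


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Force every array onto a common reference distribution.

    The reference is the across-array mean of the order statistics
    (Bolstad's quantile normalization).  Tied values within an array
    receive the mean of the reference quantiles their ranks span.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True, dtype=float)
        if X.shape[0] < 2:
            warnings.warn(
                "quantile normalization of a single array is the identity",
                stacklevel=2,
            )
        self.n_features_in_ = X.shape[1]
        self.reference_quantiles_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_quantiles_")
        X = check_array(X, ensure_2d=True, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        ref = self.reference_quantiles_
        out = np.empty_like(X)
        for a in range(X.shape[0]):
            out[a] = _map_to_reference(X[a], ref)
        return out


def _map_to_reference(vals: np.ndarray, ref: np.ndarray) -> np.ndarray:
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    assigned = ref.copy()
    # tie runs share the mean of the reference values they span
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(vals)]))
    for s, e in zip(starts, ends):
        if e - s > 1:
            assigned[s:e] = assigned[s:e].mean()
    out = np.empty_like(vals)
    out[order] = assigned
    return out


class ProbeCenterer(BaseEstimator, TransformerMixin):
    """Subtract per-probe means across arrays (probe-effect removal)."""

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.probe_means_ = X.mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "probe_means_")
        X = check_array(X, ensure_2d=True, dtype=float)
        return X - self.probe_means_


class GeneSummarizer(BaseEstimator, TransformerMixin):
    """Average probe-level values into gene-level values.

    Genes represented by fewer than ``min_probes`` probes are dropped and
    recorded in ``dropped_genes_``.
    """

    def __init__(self, gene_map=None, min_probes: int = 4):
        self.gene_map = gene_map
        self.min_probes = min_probes

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True, dtype=float)
        genes = np.asarray(self.gene_map)
        if genes.shape[0] != X.shape[1]:
            raise ValueError("gene_map must assign a gene to every probe")
        self.n_features_in_ = X.shape[1]
        uniq, inv, counts = np.unique(genes, return_inverse=True, return_counts=True)
        keep = counts >= self.min_probes
        self.genes_ = uniq[keep]
        self.dropped_genes_ = pd.DataFrame(
            {"gene_id": uniq[~keep], "n_probes": counts[~keep]}
        )
        self._inv = inv
        self._counts = counts
        self._keep = keep
        return self

    def transform(self, X):
        check_is_fitted(self, "genes_")
        X = check_array(X, ensure_2d=True, dtype=float)
        n_genes = self._counts.shape[0]
        sums = np.zeros((X.shape[0], n_genes))
        np.add.at(sums.T, self._inv, X.T)
        means = sums / self._counts
        return means[:, self._keep]


# ---------------------------------------------------------------------------
# pipeline functions (probes x arrays orientation, provenance-checked)


def log_transform(
    tables: list[ProbeIntensityTable], floor: float = 1.0
) -> ProbeMatrix:
    """Align probes across arrays and take log2 of floored intensities.

    Every array must carry exactly the same probe set; a mismatch reports
    the symmetric difference.
    """
    if not tables:
        raise ValueError("no probe tables given")
    ref = tables[0]
    ref_probes = ref.records["probe_id"]
    ref_set = set(ref_probes)
    for t in tables[1:]:
        s = set(t.records["probe_id"])
        if s != ref_set:
            diff = sorted(ref_set.symmetric_difference(s))
            raise ValueError(
                f"probe sets differ between arrays {ref.array_id!r} and "
                f"{t.array_id!r}; symmetric difference: {diff[:10]}"
                + ("..." if len(diff) > 10 else "")
            )
    cols = {}
    for t in tables:
        rec = t.records.set_index("probe_id").loc[ref_probes]
        inten = np.maximum(rec["intensity"].to_numpy(float), floor)
        if (inten <= 0).any():
            raise ValueError("nonpositive intensity after floor substitution")
        cols[t.array_id] = np.log2(inten)
    values = pd.DataFrame(cols, index=ref_probes)
    coords = ref.records.set_index("probe_id")[["x", "y"]]
    gene_map = ref.records.set_index("probe_id")["gene_id"]
    grid = (
        max(t.grid_shape[0] for t in tables),
        max(t.grid_shape[1] for t in tables),
    )
    return ProbeMatrix(
        values=values,
        coords=coords,
        gene_map=gene_map,
        grid_shape=grid,
        provenance=[f"log_transform(floor={floor})"],
    )


def spatial_correct(matrix, coords=None, window: int = 15, grid_shape=None):
    """Subtract a moving-median spatial surface per array.

    Accepts a :class:`ProbeMatrix` (order-checked, metadata carried along)
    or a plain probes x arrays array with explicit ``coords``.
    """
    if isinstance(matrix, ProbeMatrix):
        matrix._require_last_stage("log_transform", "spatial_correct")
        corr = SpatialMedianCorrector(
            coords=matrix.coords.to_numpy(int),
            window=window,
            grid_shape=matrix.grid_shape,
        )
        new_vals = corr.fit_transform(matrix.values.to_numpy(float).T).T
        return ProbeMatrix(
            values=pd.DataFrame(
                new_vals, index=matrix.values.index, columns=matrix.values.columns
            ),
            coords=matrix.coords,
            gene_map=matrix.gene_map,
            grid_shape=matrix.grid_shape,
            provenance=matrix.provenance + [f"spatial_correct(window={window})"],
        )
    X = np.asarray(matrix, dtype=float)
    corr = SpatialMedianCorrector(coords=coords, window=window, grid_shape=grid_shape)
    return corr.fit_transform(X.T).T


def quantile_normalize(matrix):
    """Quantile-normalize arrays (columns) to their mean order statistics."""
    if isinstance(matrix, ProbeMatrix):
        matrix._require_last_stage("spatial_correct", "quantile_normalize")
        qn = QuantileNormalizer()
        new_vals = qn.fit_transform(matrix.values.to_numpy(float).T).T
        return ProbeMatrix(
            values=pd.DataFrame(
                new_vals, index=matrix.values.index, columns=matrix.values.columns
            ),
            coords=matrix.coords,
            gene_map=matrix.gene_map,
            grid_shape=matrix.grid_shape,
            provenance=matrix.provenance + ["quantile_normalize()"],
        )
    X = np.asarray(matrix, dtype=float)
    return QuantileNormalizer().fit_transform(X.T).T


def probe_center(matrix):
    """Subtract each probe's mean over arrays."""
    if isinstance(matrix, ProbeMatrix):
        matrix._require_last_stage("quantile_normalize", "probe_center")
        new_vals = ProbeCenterer().fit_transform(matrix.values.to_numpy(float).T).T
        return ProbeMatrix(
            values=pd.DataFrame(
                new_vals, index=matrix.values.index, columns=matrix.values.columns
            ),
            coords=matrix.coords,
            gene_map=matrix.gene_map,
            grid_shape=matrix.grid_shape,
            provenance=matrix.provenance + ["probe_center()"],
        )
    X = np.asarray(matrix, dtype=float)
    return ProbeCenterer().fit_transform(X.T).T


def summarize_genes(
    matrix,
    gene_map=None,
    min_probes: int = 4,
    design: StudyDesign | None = None,
) -> ExpressionMatrix:
    """Average each gene's probes per array; drop genes with fewer than
    ``min_probes`` probes (default 4, i.e. genes kept only when represented
    by more than three probes)."""
    if isinstance(matrix, ProbeMatrix):
        matrix._require_last_stage("probe_center", "summarize_genes")
        gene_map = matrix.gene_map
        X = matrix.values.to_numpy(float).T
        array_ids = list(matrix.values.columns)
        provenance = matrix.provenance
    else:
        X = np.asarray(matrix, dtype=float).T
        array_ids = [f"array_{i}" for i in range(X.shape[0])]
        provenance = []
        if gene_map is None:
            raise ValueError("gene_map required for plain-array input")
    gs = GeneSummarizer(gene_map=np.asarray(gene_map), min_probes=min_probes)
    vals = gs.fit_transform(X)
    values = pd.DataFrame(vals.T, index=list(gs.genes_), columns=array_ids)
    return ExpressionMatrix(
        values=values,
        design=design,
        provenance=provenance + [f"summarize_genes(min_probes={min_probes})"],
        dropped_genes=gs.dropped_genes_,
    )


def preprocess_study(
    tables: list[ProbeIntensityTable],
    design: StudyDesign,
    window: int = 15,
    min_probes: int = 4,
    floor: float = 1.0,
) -> ExpressionMatrix:
    """Run the full fixed chain on one study's probe tables."""
    table_ids = {t.array_id for t in tables}
    design_ids = set(design.array_ids)
    if table_ids != design_ids:
        raise ValueError(
            "arrays in design and probe tables differ: "
            f"{sorted(table_ids.symmetric_difference(design_ids))}"
        )
    order = {aid: i for i, aid in enumerate(design.array_ids)}
    tables = sorted(tables, key=lambda t: order[t.array_id])
    pm = log_transform(tables, floor=floor)
    pm = spatial_correct(pm, window=window)
    pm = quantile_normalize(pm)
    pm = probe_center(pm)
    return summarize_genes(pm, min_probes=min_probes, design=design)
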