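"""Multi-view construction from annotated single-cell counts.

Turns a cell-by-gene UMI matrix with per-cell annotations into QC-filtered,
TMM-normalized, background-cleaned pseudobulk views (one per cell type),
plus structural views encoding cell-type composition (CLR) and spatial
dependencies, ready for group factor analysis.

Orientation convention throughout the package: samples are rows, features
are columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CellProfileMatrix",
    "PseudobulkView",
    "MultiViewDataset",
    "MarkerTable",
    "build_pseudobulk",
    "qc_filter_genes",
    "tmm_normalize",
    "select_hvg",
    "detect_markers",
    "exclude_background",
    "assemble_views",
    "make_structural_views",
    "clr_transform",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CellProfileMatrix:
    """Raw UMI counts (cells x genes) with per-cell annotations.

    ``cell_meta`` must contain ``sample_id`` and ``cell_type`` columns;
    ``cell_state``, ``condition``, ``group_id`` and ``batch`` are optional.
    Duplicate gene identifiers must be summed before construction (the
    loaders in :mod:`mcfa.io` do this).
    """

    counts: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValueError("duplicate gene_ids; sum duplicates at load time")
        if self.counts.shape != (len(self.cell_meta), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_meta)} cells x {len(self.gene_ids)} genes"
            )
        for col in ("sample_id", "cell_type"):
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta missing required column {col!r}")
            if self.cell_meta[col].isna().any():
                raise ValueError(f"cell_meta column {col!r} has missing values")
        dense = self.counts.toarray() if sp.issparse(self.counts) else self.counts
        if np.any(dense < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class PseudobulkView:
    """Per-cell-type pseudobulk profiles across samples.

    ``counts`` rows are samples, columns genes.  ``size_factors`` and
    ``logexpr`` are populated by :func:`tmm_normalize`; ``hvg`` by
    :func:`select_hvg`.
    """

    cell_type: str
    counts: pd.DataFrame
    n_cells: pd.Series
    sample_meta: pd.DataFrame
    size_factors: pd.Series | None = None
    logexpr: pd.DataFrame | None = None
    hvg: list[str] = field(default_factory=list)
    discarded_genes: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def genes(self) -> pd.Index:
        return self.counts.columns


@dataclass
class MultiViewDataset:
    """Named sample-by-feature views aligned on sample ids.

    Each view's DataFrame contains only the samples observed in that view;
    a sample absent from a view is missing, never zero-filled.  Entry-level
    missingness (e.g. features dropped from one group's likelihood) is
    encoded as NaN.  ``centers``/``scales`` record the per-group
    transformation applied by :func:`assemble_views` so reconstructions can
    be mapped back to the original scale.
    """

    views: dict[str, pd.DataFrame]
    groups: pd.Series
    view_kind: dict[str, str] = field(default_factory=dict)
    centers: dict[str, pd.DataFrame] = field(default_factory=dict)
    scales: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mat in self.views.items():
            if mat.index.duplicated().any():
                raise ValueError(f"duplicated sample_ids in view {name!r}")
            if mat.columns.duplicated().any():
                raise ValueError(f"duplicated features in view {name!r}")
            self.view_kind.setdefault(name, "expression")

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for mat in self.views.values():
            for s in mat.index:
                seen.setdefault(s, None)
        return sorted(seen)

    @property
    def group_names(self) -> list[str]:
        return sorted(pd.unique(self.groups.loc[self.sample_ids]))

    def n_observed(self) -> int:
        return int(sum(m.notna().sum().sum() for m in self.views.values()))


class MarkerTable:
    """Marker genes per class with log fold change and BH-adjusted p."""

    def __init__(self, table: pd.DataFrame, level: str):
        required = {"class_id", "gene", "lfc", "pval", "padj"}
        if not required.issubset(table.columns):
            raise ValueError(f"marker table missing columns {required - set(table.columns)}")
        self.table = table.reset_index(drop=True)
        self.level = level

    def markers_of(self, class_id: str) -> list[str]:
        sub = self.table[self.table["class_id"] == class_id]
        return list(sub["gene"])

    @property
    def classes(self) -> list[str]:
        return sorted(self.table["class_id"].unique())

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Pseudobulk construction
# ---------------------------------------------------------------------------

def build_pseudobulk(
    cells: CellProfileMatrix,
    min_cells: int = 25,
    ontology_map: dict[str, str] | None = None,
) -> dict[str, PseudobulkView]:
    """Sum UMI counts over all cells of each (sample, cell type) pair.

    Profiles built from fewer than ``min_cells`` cells are discarded.
    ``ontology_map`` optionally renames cell-type labels; labels present in
    the data but absent from the map raise an error.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    meta = cells.cell_meta.copy()
    ctypes = meta["cell_type"].astype(str)
    if ontology_map is not None:
        unknown = sorted(set(ctypes) - set(ontology_map))
        if unknown:
            raise ValueError(f"cell types missing from ontology map: {unknown}")
        ctypes = ctypes.map(ontology_map)

    counts = cells.counts
    if sp.issparse(counts):
        counts = counts.tocsr()
    sample_ids = meta["sample_id"].astype(str).to_numpy()
    # per-sample metadata: first value of each sample-constant column
    meta_cols = [c for c in meta.columns if c not in ("cell_type", "cell_state")]
    sample_meta_all = meta[meta_cols].groupby(meta["sample_id"].astype(str)).first()

    out: dict[str, PseudobulkView] = {}
    for ct in sorted(pd.unique(ctypes)):
        sel = (ctypes == ct).to_numpy()
        sub = counts[sel]
        samples_ct = sample_ids[sel]
        uniq = sorted(pd.unique(samples_ct))
        rows, ncell, dropped = [], [], []
        kept_samples = []
        for s in uniq:
            mask = samples_ct == s
            n = int(mask.sum())
            if n < min_cells:
                dropped.append(s)
                continue
            block = sub[mask]
            total = np.asarray(block.sum(axis=0)).ravel()
            rows.append(total)
            ncell.append(n)
            kept_samples.append(s)
        if not rows:
            warnings.warn(f"cell type {ct!r}: no sample reached min_cells={min_cells}; view omitted")
            continue
        mat = pd.DataFrame(
            np.vstack(rows).astype(np.int64), index=pd.Index(kept_samples, name="sample_id"),
            columns=pd.Index(cells.gene_ids, name="gene"),
        )
        out[ct] = PseudobulkView(
            cell_type=ct,
            counts=mat,
            n_cells=pd.Series(ncell, index=mat.index, name="n_cells"),
            sample_meta=sample_meta_all.loc[mat.index],
            dropped_samples=dropped,
        )
    return out


def qc_filter_genes(
    view: PseudobulkView, min_count: int = 100, min_detection: float = 0.25
) -> PseudobulkView:
    """Discard genes with max count across samples below ``min_count`` or
    detected (count > 0) in fewer than ``min_detection`` of the samples.

    A gene detected in exactly ``min_detection`` of samples is kept (the
    cut is strict: "detected in less than" the fraction).  Idempotent.
    """
    if view.counts.shape[0] < 2:
        raise ValueError("gene QC undefined with fewer than 2 samples")
    c = view.counts
    max_ok = c.max(axis=0) >= min_count
    det_ok = (c > 0).mean(axis=0) >= min_detection
    keep = max_ok & det_ok
    discarded = list(c.columns[~keep])
    return PseudobulkView(
        cell_type=view.cell_type,
        counts=c.loc[:, keep],
        n_cells=view.n_cells,
        sample_meta=view.sample_meta,
        discarded_genes=discarded,
        dropped_samples=view.dropped_samples,
    )


# ---------------------------------------------------------------------------
# TMM normalization (Robinson & Oshlack)
# ---------------------------------------------------------------------------

def _tmm_pair_factor(
    y: np.ndarray, yr: np.ndarray, lib: float, libr: float,
    trim_m: float = 0.30, trim_a: float = 0.05,
) -> float:
    """Trimmed mean of M-values factor of one sample against the reference.

    Genes positive in both libraries enter; the M values (log2 ratio of
    depth-scaled counts) are double-trimmed — 30% two-sided on M and 5%
    two-sided on A — and averaged with inverse approximate-variance
    weights.  Rank trimming keeps 1-based ordinal ranks in
    [floor(n*t)+1, n - floor(n*t)].
    """
    pos = (y > 0) & (yr > 0)
    if pos.sum() == 0:
        return 1.0
    yj, yk = y[pos].astype(float), yr[pos].astype(float)
    m = np.log2((yj / lib) / (yk / libr))
    a = 0.5 * np.log2((yj / lib) * (yk / libr))
    w = (lib - yj) / (lib * yj) + (libr - yk) / (libr * yk)
    n = len(m)
    lo_m, lo_a = int(np.floor(n * trim_m)) + 1, int(np.floor(n * trim_a)) + 1
    rank_m = stats.rankdata(m, method="ordinal")
    rank_a = stats.rankdata(a, method="ordinal")
    keep = (rank_m >= lo_m) & (rank_m <= n - lo_m + 1) & \
           (rank_a >= lo_a) & (rank_a <= n - lo_a + 1)
    if keep.sum() == 0 or w[keep].sum() == 0:
        return 1.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    return float(2.0 ** f)


def tmm_normalize(view: PseudobulkView, prior_count: float = 1.0) -> PseudobulkView:
    """TMM size factors and log2-CPM expression for a pseudobulk view.

    The reference sample is the one whose 75th percentile of library-scaled
    counts is closest to the mean of those percentiles.  Factors are
    rescaled to geometric mean 1, then
    ``logexpr = log2(1e6 * y / (lib * factor) + prior_count)``.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be > 0")
    c = view.counts.to_numpy(dtype=float)
    n_samples = c.shape[0]
    if n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = c.sum(axis=1)
    if np.any(lib == 0):
        bad = list(view.counts.index[lib == 0])
        raise ValueError(f"samples with zero library size: {bad}")
    f75 = np.array([np.quantile(c[j] / lib[j], 0.75) for j in range(n_samples)])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        factors[j] = _tmm_pair_factor(c[j], c[ref], lib[j], lib[ref])
    factors = factors / np.exp(np.mean(np.log(factors)))
    eff = lib * factors
    logexpr = np.log2(1e6 * c / eff[:, None] + prior_count)
    return PseudobulkView(
        cell_type=view.cell_type,
        counts=view.counts,
        n_cells=view.n_cells,
        sample_meta=view.sample_meta,
        size_factors=pd.Series(factors, index=view.counts.index, name="size_factor"),
        logexpr=pd.DataFrame(logexpr, index=view.counts.index, columns=view.counts.columns),
        discarded_genes=view.discarded_genes,
        dropped_samples=view.dropped_samples,
    )


# ---------------------------------------------------------------------------
# Highly variable genes
# ---------------------------------------------------------------------------

def _variance_trend(means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Smooth trend of per-gene variance as a function of mean log-expression.

    Local (lowess, span 0.3) regression for >= 30 genes, quadratic
    polynomial otherwise; the trend is floored at a small positive value so
    variance ratios stay defined.
    """
    if len(means) >= 30:
        fitted = lowess(variances, means, frac=0.3, return_sorted=True)
        trend = np.interp(means, fitted[:, 0], fitted[:, 1])
    else:
        coef = np.polyfit(means, variances, deg=2)
        trend = np.polyval(coef, means)
    return np.maximum(trend, 1e-12)


def select_hvg(
    view: PseudobulkView, method: str = "biovar", threshold: float | None = None
) -> list[str]:
    """Highly variable genes across samples of a pseudobulk view.

    ``normvar`` keeps genes whose variance/trend ratio exceeds the
    threshold (default 1.5); ``biovar`` keeps genes whose variance above
    the trend (biological variance) exceeds the threshold (default 0).
    """
    if view.logexpr is None:
        raise ValueError("run tmm_normalize before select_hvg")
    if method not in ("normvar", "biovar"):
        raise ValueError(f"unknown HVG method {method!r}")
    if threshold is None:
        threshold = 1.5 if method == "normvar" else 0.0
    X = view.logexpr
    if X.shape[0] < 5:
        warnings.warn(f"{view.cell_type}: HVG selection on fewer than 5 samples is unstable")
    means = X.mean(axis=0).to_numpy()
    variances = X.var(axis=0, ddof=1).to_numpy()
    if np.allclose(variances, 0):
        warnings.warn(f"{view.cell_type}: all genes constant; no HVGs")
        return []
    trend = _variance_trend(means, variances)
    if method == "normvar":
        stat = variances / trend
    else:
        stat = variances - trend
    return list(X.columns[stat > threshold])


# ---------------------------------------------------------------------------
# Marker detection and background exclusion
# ---------------------------------------------------------------------------

def _one_vs_rest_t(
    X: np.ndarray, in_class: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Welch t-test per column, class vs rest; returns (lfc, p)."""
    a, b = X[in_class], X[~in_class]
    lfc = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    return lfc, p


def detect_markers(
    data,
    level: str = "celltype_pseudobulk",
    lfc_min: float | None = None,
    fdr_max: float | None = None,
) -> MarkerTable:
    """One-vs-rest marker genes at the cell-type or cell-state level.

    ``celltype_pseudobulk``: ``data`` is a map cell type -> normalized
    PseudobulkView; Welch t-tests on log-CPM, markers need lfc > 1 and BH
    FDR < 0.01.  ``cellstate_cells``: ``data`` is a CellProfileMatrix with
    a ``cell_state`` column; cells are library-normalized (counts per 10k,
    log1p) and each state is contrasted with the other cells of its type,
    markers need lfc >= 0.5 and BH-adjusted p < 0.05.
    """
    if level == "celltype_pseudobulk":
        lfc_min = 1.0 if lfc_min is None else lfc_min
        fdr_max = 0.01 if fdr_max is None else fdr_max
        views: dict[str, PseudobulkView] = data
        shared = None
        for v in views.values():
            if v.logexpr is None:
                raise ValueError("marker detection needs normalized views")
            cols = set(v.logexpr.columns)
            shared = cols if shared is None else shared & cols
        shared = sorted(shared or [])
        if not shared:
            raise ValueError("no genes shared across views for marker detection")
        blocks, labels = [], []
        for ct, v in sorted(views.items()):
            blocks.append(v.logexpr[shared].to_numpy())
            labels += [ct] * v.logexpr.shape[0]
        X = np.vstack(blocks)
        labels = np.array(labels)
        rows = []
        for ct in sorted(views):
            in_class = labels == ct
            if in_class.sum() < 2 or (~in_class).sum() < 2:
                warnings.warn(f"cell type {ct!r}: fewer than 2 replicates; skipped")
                continue
            lfc, p = _one_vs_rest_t(X, in_class)
            padj = multipletests(p, method="fdr_bh")[1]
            hit = (lfc > lfc_min) & (padj < fdr_max)
            for g, l_, pv, pa in zip(np.array(shared)[hit], lfc[hit], p[hit], padj[hit]):
                rows.append((ct, g, l_, pv, pa))
    elif level == "cellstate_cells":
        lfc_min = 0.5 if lfc_min is None else lfc_min
        fdr_max = 0.05 if fdr_max is None else fdr_max
        cells: CellProfileMatrix = data
        if "cell_state" not in cells.cell_meta.columns:
            raise ValueError("cell_meta has no cell_state column")
        counts = cells.counts.toarray() if sp.issparse(cells.counts) else np.asarray(cells.counts)
        depth = counts.sum(axis=1, keepdims=True).astype(float)
        depth[depth == 0] = 1.0
        logn = np.log1p(counts / depth * 1e4)
        meta = cells.cell_meta
        rows = []
        for ct in sorted(meta["cell_type"].unique()):
            sel = (meta["cell_type"] == ct).to_numpy()
            sub, states = logn[sel], meta.loc[sel, "cell_state"].to_numpy()
            for st in sorted(pd.unique(states)):
                in_class = states == st
                if in_class.sum() < 3 or (~in_class).sum() < 3:
                    warnings.warn(f"state {st!r} of {ct!r}: fewer than 3 cells; skipped")
                    continue
                lfc, p = _one_vs_rest_t(sub, in_class)
                padj = multipletests(p, method="fdr_bh")[1]
                hit = (lfc >= lfc_min) & (padj < fdr_max)
                for g, l_, pv, pa in zip(cells.gene_ids[hit], lfc[hit], p[hit], padj[hit]):
                    rows.append((st, g, l_, pv, pa))
    else:
        raise ValueError(f"unknown marker level {level!r}")
    table = pd.DataFrame(rows, columns=["class_id", "gene", "lfc", "pval", "padj"])
    return MarkerTable(table, level=level)


def exclude_background(
    hvg_by_type: dict[str, list[str]], markers: MarkerTable
) -> dict[str, list[str]]:
    """Remove putative ambient-contamination genes from per-type HVG sets.

    For cell type c the returned set is hvg(c) minus every gene that is a
    marker of some *other* cell type and not a marker of c itself — marker
    genes of the cell type under consideration are exempt.  Output sets are
    always subsets of the inputs; empty markers give the identity.
    """
    marker_sets = {ct: set(markers.markers_of(ct)) for ct in markers.classes}
    out: dict[str, list[str]] = {}
    for ct, genes in hvg_by_type.items():
        if ct not in marker_sets:
            warnings.warn(f"no markers recorded for {ct!r}; treating as empty")
        own = marker_sets.get(ct, set())
        other = set().union(*(s for c2, s in marker_sets.items() if c2 != ct)) \
            if len(marker_sets) > (1 if ct in marker_sets else 0) else set()
        banned = other - own
        out[ct] = [g for g in genes if g not in banned]
    return out


# ---------------------------------------------------------------------------
# View assembly
# ---------------------------------------------------------------------------

def assemble_views(
    views: dict[str, PseudobulkView],
    gene_sets: dict[str, list[str]] | None = None,
    group_id: pd.Series | None = None,
    scale_per_group: bool | None = None,
    extra_views: dict[str, pd.DataFrame] | None = None,
    extra_kinds: dict[str, str] | None = None,
) -> MultiViewDataset:
    """Center (and, for multi-group data, scale) views into a dataset.

    Each feature is centered per group; with ``scale_per_group`` (default:
    on when there is more than one group) each feature is also divided by
    its per-group standard deviation.  Features with zero variance within a
    group are dropped from that group's likelihood contribution (set to
    NaN).  Samples absent from a view stay missing; nothing is imputed.
    ``extra_views`` (e.g. from :func:`make_structural_views`) are processed
    the same way.
    """
    mats: dict[str, pd.DataFrame] = {}
    kinds: dict[str, str] = {}
    for ct, v in views.items():
        if v.logexpr is None:
            raise ValueError(f"view {ct!r} not normalized; run tmm_normalize")
        genes = gene_sets.get(ct, list(v.logexpr.columns)) if gene_sets else list(v.logexpr.columns)
        genes = [g for g in genes if g in v.logexpr.columns]
        mats[ct] = v.logexpr[genes].copy()
        kinds[ct] = "expression"
    for name, mat in (extra_views or {}).items():
        mats[name] = mat.copy()
        kinds[name] = (extra_kinds or {}).get(name, "expression")

    all_samples = sorted(set().union(*(set(m.index) for m in mats.values())))
    if group_id is None:
        group_id = pd.Series("group0", index=pd.Index(all_samples, name="sample_id"))
    group_id = group_id.astype(str)
    missing_groups = [s for s in all_samples if s not in group_id.index]
    if missing_groups:
        raise ValueError(f"samples without group label: {missing_groups[:5]}")
    n_groups = group_id.loc[all_samples].nunique()
    if scale_per_group is None:
        scale_per_group = n_groups > 1

    centers: dict[str, pd.DataFrame] = {}
    scales: dict[str, pd.DataFrame] = {}
    for name, mat in mats.items():
        if mat.index.duplicated().any():
            raise ValueError(f"duplicated sample_ids within view {name!r}")
        g = group_id.loc[mat.index]
        mu = mat.groupby(g.to_numpy()).mean()
        mats[name] = mat - mu.loc[g.to_numpy()].set_axis(mat.index)
        centers[name] = mu
        if scale_per_group:
            sd = mat.groupby(g.to_numpy()).std(ddof=0)
            zero = sd <= 0
            sd_safe = sd.where(~zero, np.nan)
            mats[name] = mats[name] / sd_safe.loc[g.to_numpy()].set_axis(mat.index)
            scales[name] = sd_safe
            if zero.any().any():
                n_flag = int(zero.sum().sum())
                warnings.warn(
                    f"view {name!r}: {n_flag} (group, feature) cells with zero "
                    "variance dropped from that group's likelihood"
                )
    return MultiViewDataset(
        views=mats, groups=group_id, view_kind=kinds, centers=centers, scales=scales
    )


# ---------------------------------------------------------------------------
# Structural views: composition (CLR) and spatial dependencies
# ---------------------------------------------------------------------------

def clr_transform(compositions: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform with multiplicative zero replacement.

    Rows are closed to sum 1; zeros are replaced by half the smallest
    positive part of the row, the row re-closed, then
    ``clr(x)_i = ln(x_i / geometric_mean(x))``.  Output rows sum to 0.
    """
    X = compositions.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("compositions must be non-negative")
    if np.any(X.sum(axis=1) <= 0):
        raise ValueError("composition rows must have positive sum")
    X = X / X.sum(axis=1, keepdims=True)
    out = np.empty_like(X)
    for i, row in enumerate(X):
        if (row == 0).any():
            repl = 0.5 * row[row > 0].min()
            row = np.where(row == 0, repl, row)
            row = row / row.sum()
        lr = np.log(row)
        out[i] = lr - lr.mean()
    return pd.DataFrame(out, index=compositions.index, columns=compositions.columns)


def make_structural_views(
    compositions: pd.DataFrame | None = None,
    importances: dict[str, pd.DataFrame] | None = None,
    top_n: int = 21,
) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Composition (CLR) and spatial-dependency views for the model.

    ``compositions`` is a sample x cell-type fraction table (closed to 1);
    ``importances`` maps a spatial context name to a sample x interaction
    table of standardized importances, of which the ``top_n`` most variable
    interaction columns are retained per context.
    """
    views: dict[str, pd.DataFrame] = {}
    kinds: dict[str, str] = {}
    if compositions is not None:
        views["composition"] = clr_transform(compositions)
        kinds["composition"] = "composition"
    for ctx, table in (importances or {}).items():
        k = top_n
        if table.shape[1] < top_n:
            warnings.warn(
                f"context {ctx!r}: only {table.shape[1]} interactions available "
                f"(top_n={top_n}); using all"
            )
            k = table.shape[1]
        var = table.var(axis=0, ddof=1)
        keep = var.sort_values(ascending=False, kind="stable").index[:k]
        keep = [c for c in table.columns if c in set(keep)]  # original order
        name = f"spatial_{ctx}"
        views[name] = table[keep].copy()
        kinds[name] = "spatial_dependency"
    return views, kinds
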