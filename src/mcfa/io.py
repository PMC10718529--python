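"""Configuration, file I/O, model persistence and the end-to-end pipeline.

All outputs are plain CSV/TSV/HDF5/JSON so downstream tooling in any
language can consume them.  Every randomized stage draws a named seed
derived deterministically from the global seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import gfa, programs, synthetic, views
from .gfa import GFAHyperparams, GFAModel
from .views import CellProfileMatrix, MultiViewDataset

__all__ = [
    "PipelineConfig",
    "load_cell_data",
    "save_views",
    "load_views",
    "save_model",
    "load_model",
    "run_pipeline",
    "stage_seed",
]

MODEL_FORMAT_VERSION = "mcfa-gfa-1"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All pipeline constants in one place.

    Defaults follow the analysis conventions of the package: pseudobulk
    profiles need 25 cells; genes need a maximum count of 100 in some
    sample and detection in 25% of samples; cell-type markers need
    lfc > 1 at FDR < 0.01 (cell-state markers lfc >= 0.5, adjusted
    p < 0.05); 6 factors; loadings below |0.1| are zeroed for signatures;
    spatial scoring masks spots below 10% cell-type proportion and calls
    spots active above z = 2; 1000 permutations for functional scoring and
    100 for spatial/bulk; 21 top spatial interactions per context.
    """

    min_cells: int = 25
    min_count: int = 100
    min_detection: float = 0.25
    hvg_method: str = "biovar"
    hvg_threshold: float | None = None
    marker_lfc_min: float = 1.0
    marker_fdr_max: float = 0.01
    state_lfc_min: float = 0.5
    state_fdr_max: float = 0.05
    K: int = 6
    loading_threshold: float = 0.1
    prop_threshold: float = 0.1
    score_threshold: float = 2.0
    n_perm_functional: int = 1000
    n_perm_spatial: int = 100
    n_perm_bulk: int = 100
    top_n_interactions: int = 21
    alpha_bh: float = 0.05
    alpha_state_anova: float = 0.01
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 1
    paths: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    h = np.uint64(1469598103934665603)
    for ch in f"{global_seed}:{stage}".encode():
        h = np.uint64((int(h) ^ ch) * 1099511628211 % (1 << 64))
    return int(h % (1 << 31))


# ---------------------------------------------------------------------------
# Loading raw cell data
# ---------------------------------------------------------------------------

def _dedupe_and_order(
    counts: np.ndarray, gene_ids: np.ndarray, meta: pd.DataFrame
) -> CellProfileMatrix:
    """Sum duplicate genes, drop cells with incomplete metadata, and order
    rows/columns lexicographically."""
    df = pd.DataFrame(counts, columns=gene_ids, index=meta.index)
    if pd.Index(gene_ids).duplicated().any():
        df = df.T.groupby(level=0).sum().T
    df = df[sorted(df.columns)]
    ok = meta["sample_id"].notna() & meta["cell_type"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} cells with missing sample_id/cell_type")
    df, meta = df.loc[ok], meta.loc[ok]
    order = sorted(df.index)
    df, meta = df.loc[order], meta.loc[order]
    return CellProfileMatrix(
        counts=df.to_numpy(dtype=np.int64),
        gene_ids=df.columns.to_numpy(dtype=object),
        cell_meta=meta,
    )


def load_cell_data(
    path: str | Path,
    fmt: str = "mtx_dir",
    meta_path: str | Path | None = None,
    column_map: dict[str, str] | None = None,
) -> CellProfileMatrix:
    """Load a cell-by-gene count matrix with per-cell metadata.

    Formats: ``mtx_dir`` (matrix.mtx + features.tsv + barcodes.tsv, genes
    in rows as in the 10x convention, plus a metadata CSV/TSV keyed by
    barcode), ``csv`` (cells x genes with barcode index, plus metadata
    CSV), ``h5ad`` (metadata taken from ``.obs``).  Duplicate gene ids are
    summed; cells with missing required metadata are dropped with a count;
    rows and columns are ordered lexicographically.
    """
    path = Path(path)
    if fmt == "mtx_dir":
        from scipy.io import mmread
        mtx = path / "matrix.mtx"
        if not mtx.exists() or mtx.stat().st_size == 0:
            raise FileNotFoundError(f"missing or empty {mtx}")
        mat = mmread(mtx).tocsr().T  # -> cells x genes
        genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].to_numpy(object)
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        meta = _read_meta(meta_path or path / "metadata.csv", column_map)
        counts = np.asarray(mat.todense())
        if counts.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"matrix is {counts.shape} but there are {len(barcodes)} barcodes "
                f"and {len(genes)} features"
            )
        meta = meta.reindex(barcodes)
        meta.index = barcodes
    elif fmt == "csv":
        if path.stat().st_size == 0:
            raise ValueError(f"empty file {path}")
        df = pd.read_csv(path, index_col=0)
        genes = df.columns.to_numpy(object)
        counts = df.to_numpy()
        if meta_path is None:
            raise ValueError("csv format requires meta_path")
        meta = _read_meta(meta_path, column_map).reindex(df.index.astype(str))
        meta.index = df.index
    elif fmt == "h5ad":
        import anndata as ad
        adata = ad.read_h5ad(path)
        X = adata.X
        counts = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
        genes = adata.var_names.to_numpy(object)
        meta = adata.obs.copy()
        if column_map:
            meta = meta.rename(columns=column_map)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if meta.shape[0] != counts.shape[0]:
        raise ValueError(
            f"metadata has {meta.shape[0]} rows but matrix has {counts.shape[0]} cells"
        )
    for col in ("sample_id", "cell_type"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    return _dedupe_and_order(np.asarray(counts), np.asarray(genes, dtype=object), meta)


def _read_meta(path: str | Path, column_map: dict[str, str] | None) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    meta = pd.read_csv(path, sep=sep, index_col=0)
    meta.index = meta.index.astype(str)
    if column_map:
        meta = meta.rename(columns=column_map)
    return meta


# ---------------------------------------------------------------------------
# Multi-view container (HDF5)
# ---------------------------------------------------------------------------

def save_views(data: MultiViewDataset, path: str | Path) -> None:
    """Write a multi-view dataset to one HDF5 container.

    Layout: /views/<name>/{data,features,samples}, /samples, /groups.
    Missing entries are stored as NaN.
    """
    with h5py.File(path, "w") as f:
        f.attrs["version"] = MODEL_FORMAT_VERSION
        grp = f.create_group("views")
        for name, mat in data.views.items():
            g = grp.create_group(name)
            g.create_dataset("data", data=mat.to_numpy(dtype=float))
            g.create_dataset("features", data=np.array(mat.columns, dtype="S"))
            g.create_dataset("samples", data=np.array(mat.index, dtype="S"))
            g.attrs["kind"] = data.view_kind.get(name, "expression")
        f.create_dataset("samples", data=np.array(data.sample_ids, dtype="S"))
        f.create_dataset(
            "groups",
            data=np.array(data.groups.loc[data.sample_ids], dtype="S"),
        )


def load_views(path: str | Path) -> MultiViewDataset:
    with h5py.File(path, "r") as f:
        mats, kinds = {}, {}
        for name in f["views"]:
            g = f["views"][name]
            feats = [s.decode() for s in g["features"][...]]
            samps = [s.decode() for s in g["samples"][...]]
            mats[name] = pd.DataFrame(g["data"][...], index=samps, columns=feats)
            kinds[name] = g.attrs.get("kind", "expression")
        samples = [s.decode() for s in f["samples"][...]]
        groups = pd.Series([s.decode() for s in f["groups"][...]], index=samples)
    return MultiViewDataset(views=mats, groups=groups, view_kind=kinds)


# ---------------------------------------------------------------------------
# Model persistence (HDF5)
# ---------------------------------------------------------------------------

def _write_frame(g: h5py.Group, name: str, df: pd.DataFrame) -> None:
    sub = g.create_group(name)
    sub.create_dataset("data", data=df.to_numpy(dtype=float))
    sub.create_dataset("index", data=np.array([str(i) for i in df.index], dtype="S"))
    sub.create_dataset("columns", data=np.array([str(c) for c in df.columns], dtype="S"))


def _read_frame(g: h5py.Group, name: str) -> pd.DataFrame:
    sub = g[name]
    return pd.DataFrame(
        sub["data"][...],
        index=[s.decode() for s in sub["index"][...]],
        columns=[s.decode() for s in sub["columns"][...]],
    )


def save_model(model: GFAModel, path: str | Path) -> None:
    """Persist a fitted model to HDF5 (exact float round-trip).

    Layout: /weights/<view>, /wcov/<view>, /scores/<group>,
    /zcov/<group>, /alpha/<view>, /beta/<group>, /tau/<view>/<group>,
    /elbo, /r2, /config, plus feature/sample names and any centering
    metadata needed by :func:`mcfa.gfa.reconstruct`.
    """
    with h5py.File(path, "w") as f:
        f.attrs["version"] = MODEL_FORMAT_VERSION
        f.attrs["beta_learned"] = model.beta_learned
        cfg = f.create_group("config")
        for k, v in dataclasses.asdict(model.hp).items():
            cfg.attrs[k] = v
        for key, store in (("weights", model.W), ("wcov", model.Wcov),
                           ("alpha", model.alpha)):
            g = f.create_group(key)
            for m, arr in store.items():
                g.create_dataset(m, data=arr)
        for key, store in (("scores", model.Z), ("zcov", model.Zcov),
                           ("beta", model.beta)):
            g = f.create_group(key)
            for gr, arr in store.items():
                g.create_dataset(gr, data=arr)
        g = f.create_group("tau")
        for (m, gr), arr in model.tau.items():
            g.require_group(m).create_dataset(gr, data=arr)
        f.create_dataset("elbo", data=model.elbo_trace)
        names = f.create_group("names")
        for m, feats in model.features.items():
            names.create_dataset(f"features_{m}", data=np.array(feats, dtype="S"))
        for gr, samps in model.samples.items():
            names.create_dataset(f"samples_{gr}", data=np.array(samps, dtype="S"))
        names.attrs["views"] = [str(v) for v in model.view_names]
        names.attrs["groups"] = [str(g_) for g_ in model.group_names]
        if model.r2 is not None:
            r2 = model.r2.reset_index()
            g = f.create_group("r2")
            g.create_dataset("values", data=model.r2.to_numpy(dtype=float))
            g.create_dataset("view", data=np.array(r2["view"], dtype="S"))
            g.create_dataset("group", data=np.array(r2["group"], dtype="S"))
            g.create_dataset("factor_r2", data=np.asarray(model.factor_r2, dtype=float))
            g.create_dataset("r2_total", data=model.r2_total.to_numpy(dtype=float))
        meta = f.create_group("scaling")
        for kind, store in (("centers", model.centers), ("scales", model.scales)):
            g = meta.create_group(kind)
            for m, df in store.items():
                _write_frame(g, m, df)


def load_model(path: str | Path) -> GFAModel:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format version mismatch: found {version!r}, "
                f"expected {MODEL_FORMAT_VERSION!r}"
            )
        for required in ("weights", "scores", "elbo", "names"):
            if required not in f:
                raise ValueError(f"model file truncated: missing group {required!r}")
        hp = GFAHyperparams(**{k: (int(v) if k in ("K", "max_iter", "seed") else float(v))
                               for k, v in f["config"].attrs.items()})
        view_names = [str(v) for v in f["names"].attrs["views"]]
        group_names = [str(g) for g in f["names"].attrs["groups"]]
        features = {m: [s.decode() for s in f["names"][f"features_{m}"][...]]
                    for m in view_names}
        samples = {g: [s.decode() for s in f["names"][f"samples_{g}"][...]]
                   for g in group_names}
        model = GFAModel(
            hp=hp, view_names=view_names, group_names=group_names,
            features=features, samples=samples,
            W={m: f["weights"][m][...] for m in view_names},
            Wcov={m: f["wcov"][m][...] for m in view_names},
            Z={g: f["scores"][g][...] for g in group_names},
            Zcov={g: f["zcov"][g][...] for g in group_names},
            alpha={m: f["alpha"][m][...] for m in view_names},
            beta={g: f["beta"][g][...] for g in group_names},
            tau={(m, g): f["tau"][m][g][...] for m in view_names for g in group_names},
            elbo_trace=f["elbo"][...],
            beta_learned=bool(f.attrs["beta_learned"]),
        )
        if "r2" in f:
            K = hp.K
            idx = pd.MultiIndex.from_arrays(
                [[s.decode() for s in f["r2"]["view"][...]],
                 [s.decode() for s in f["r2"]["group"][...]]],
                names=["view", "group"],
            )
            model.r2 = pd.DataFrame(f["r2"]["values"][...], index=idx,
                                    columns=[f"Factor{k + 1}" for k in range(K)])
            model.factor_r2 = f["r2"]["factor_r2"][...]
            model.r2_total = pd.Series(f["r2"]["r2_total"][...], index=idx)
        for kind in ("centers", "scales"):
            store = {}
            if "scaling" in f and kind in f["scaling"]:
                for m in f["scaling"][kind]:
                    store[m] = _read_frame(f["scaling"][kind], m)
            setattr(model, kind, store)
    return model


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def make_views_from_cells(
    cells: CellProfileMatrix, config: PipelineConfig
) -> tuple[MultiViewDataset, dict]:
    """Pseudobulk -> QC -> TMM -> HVG -> marker-based background exclusion
    -> centered multi-view dataset.  Returns the dataset and a stage log."""
    log: dict = {}
    pb = views.build_pseudobulk(cells, min_cells=config.min_cells)
    log["pseudobulk_views"] = {ct: int(v.counts.shape[0]) for ct, v in pb.items()}
    if not pb:
        raise RuntimeError("no views: every (sample, cell type) profile was discarded")
    normed: dict[str, views.PseudobulkView] = {}
    for ct, v in pb.items():
        v = views.qc_filter_genes(v, config.min_count, config.min_detection)
        if v.counts.shape[1] == 0:
            warnings.warn(f"view {ct!r}: no genes passed QC; omitted")
            continue
        normed[ct] = views.tmm_normalize(v)
    if not normed:
        raise RuntimeError("no views: no genes passed QC in any cell type")
    hvg = {ct: views.select_hvg(v, method=config.hvg_method,
                                threshold=config.hvg_threshold)
           for ct, v in normed.items()}
    markers = views.detect_markers(
        normed, level="celltype_pseudobulk",
        lfc_min=config.marker_lfc_min, fdr_max=config.marker_fdr_max,
    )
    final_sets = views.exclude_background(hvg, markers)
    log["genes_per_view"] = {ct: len(g) for ct, g in final_sets.items()}
    group_series = None
    any_view = next(iter(normed.values()))
    if "group_id" in any_view.sample_meta.columns:
        group_series = pd.concat(
            [v.sample_meta["group_id"] for v in normed.values()]
        ).groupby(level=0).first()
    dataset = views.assemble_views(normed, gene_sets=final_sets, group_id=group_series)
    return dataset, log


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    cells: CellProfileMatrix | None = None,
    covariates: pd.DataFrame | None = None,
) -> Path:
    """Run the full workflow and write artifacts to ``out_dir``.

    Stages: makeviews -> fit -> postprocess -> associate -> signatures.
    When no input cells are given, a synthetic atlas is generated from the
    configured seed.  Identical config and seed give identical outputs.
    Any stage failure aborts with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.jsonl"
    records: list[dict] = []

    def log_stage(stage: str, **info) -> None:
        records.append({"stage": stage, **info})
        with open(log_path, "w") as fh:
            for r in records:
                fh.write(json.dumps(r, default=str) + "\n")

    def run_stage(stage, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            log_stage(stage, error=str(exc))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config.to_yaml(out / "config.yaml")
    if cells is None:
        cells, truth = synthetic.simulate_single_cell(seed=stage_seed(config.seed, "simulate"))
        if covariates is None:
            covariates = truth.condition.to_frame("condition")
        log_stage("simulate", n_cells=cells.n_cells, n_genes=cells.n_genes)

    dataset, mv_log = run_stage("makeviews", lambda: make_views_from_cells(cells, config))
    log_stage("makeviews", **mv_log)
    for name, mat in dataset.views.items():
        mat.to_csv(out / f"view_{name}.csv")
    save_views(dataset, out / "views.h5")

    hp = GFAHyperparams(K=config.K, max_iter=config.max_iter, tol=config.tol,
                        seed=stage_seed(config.seed, "fit"))
    model = run_stage("fit", lambda: gfa.fit_gfa(dataset, hp))
    model = run_stage("postprocess", lambda: gfa.postprocess_factors(model))
    save_model(model, out / "model.h5")
    log_stage("fit", elbo_iterations=len(model.elbo_trace),
              factor_r2=[float(x) for x in model.factor_r2])

    if covariates is None:
        meta_cols = [c for c in cells.cell_meta.columns
                     if c not in ("sample_id", "cell_type", "cell_state")]
        covariates = cells.cell_meta.groupby(
            cells.cell_meta["sample_id"].astype(str)
        )[meta_cols].first() if meta_cols else None
    assoc = None
    if covariates is not None and covariates.shape[1] > 0:
        assoc = run_stage(
            "associate", lambda: programs.associate_factors(model.scores(), covariates)
        )
        assoc.to_csv(out / "associations.csv", index=False)
        log_stage("associate", n_tests=len(assoc))

    if assoc is not None and len(assoc):
        best = assoc.sort_values("padj").iloc[0]
        factor_ix = int(best["factor"].replace("Factor", "")) - 1
    else:
        factor_ix = 0
    sigs = run_stage(
        "signatures",
        lambda: programs.extract_signatures(model, factor_ix,
                                            threshold=config.loading_threshold),
    )
    sig_dir = out / "signatures"
    sig_dir.mkdir(exist_ok=True)
    for sig in sigs:
        sig.weights.rename("weight").to_csv(
            sig_dir / f"{sig.cell_type}_Factor{factor_ix + 1}_{sig.sign}.tsv", sep="\t"
        )
    log_stage("signatures", factor=factor_ix + 1, n_signatures=len(sigs),
              sizes={s.name: len(s) for s in sigs})
    return out
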