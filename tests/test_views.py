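"""Pseudobulk construction, normalization, markers, and view assembly."""

import numpy as np
import pandas as pd
import pytest

from mcfa import synthetic, views
from mcfa.views import (
    CellProfileMatrix,
    MultiViewDataset,
    PseudobulkView,
    assemble_views,
    build_pseudobulk,
    clr_transform,
    detect_markers,
    exclude_background,
    make_structural_views,
    qc_filter_genes,
    select_hvg,
    tmm_normalize,
)


def _cells(counts, sample_ids, cell_types, genes=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    meta = pd.DataFrame({"sample_id": sample_ids, "cell_type": cell_types})
    meta.index = [f"c{i}" for i in range(len(meta))]
    return CellProfileMatrix(counts=counts, gene_ids=np.array(genes, dtype=object),
                             cell_meta=meta)


class TestBuildPseudobulk:
    def test_sums_member_cells(self):
        cells = _cells([[1, 2], [3, 4]], ["S", "S"], ["T", "T"])
        pb = build_pseudobulk(cells, min_cells=1)
        assert pb["T"].counts.loc["S"].tolist() == [4, 6]
        assert pb["T"].n_cells.loc["S"] == 2

    def test_min_cells_threshold_drops_small_profiles(self):
        n = 24
        cells = _cells(np.ones((n + 30, 2), dtype=int),
                       ["A"] * n + ["B"] * 30, ["T"] * (n + 30))
        pb = build_pseudobulk(cells, min_cells=25)
        assert "A" not in pb["T"].counts.index
        assert "B" in pb["T"].counts.index
        assert pb["T"].dropped_samples == ["A"]

    def test_matches_groupby_sum_oracle(self):
        cells, _ = synthetic.simulate_single_cell(
            n_types=2, n_samples_per_condition=2, n_cells=40, seed=1
        )
        pb = build_pseudobulk(cells, min_cells=1)
        df = pd.DataFrame(cells.counts, columns=cells.gene_ids)
        df["sample_id"] = cells.cell_meta["sample_id"].to_numpy()
        df["cell_type"] = cells.cell_meta["cell_type"].to_numpy()
        oracle = df.groupby(["cell_type", "sample_id"]).sum()
        for ct, view in pb.items():
            for s in view.counts.index:
                np.testing.assert_array_equal(
                    view.counts.loc[s].to_numpy(),
                    oracle.loc[(ct, s)].to_numpy(),
                )

    def test_count_conservation(self):
        cells, _ = synthetic.simulate_single_cell(
            n_types=2, n_samples_per_condition=2, n_cells=40, seed=2
        )
        pb = build_pseudobulk(cells, min_cells=1)
        total = sum(v.counts.to_numpy().sum() for v in pb.values())
        assert total == cells.counts.sum()

    def test_unknown_ontology_label_errors(self):
        cells = _cells([[1, 2]] * 30, ["S"] * 30, ["T"] * 30)
        with pytest.raises(ValueError, match="ontology"):
            build_pseudobulk(cells, min_cells=1, ontology_map={"other": "x"})


class TestQCFilter:
    def test_stated_rule_boundaries(self, simple_counts_view):
        out = qc_filter_genes(simple_counts_view)
        # g0: counts (120,0,0,0): max>=100 and detection exactly 25% -> kept
        # g1: max 99 < 100 -> dropped; g2 all zero -> dropped
        # g3: max 40 < 100 -> dropped; g4 passes both
        assert list(out.counts.columns) == ["g0", "g4"]
        assert set(out.discarded_genes) == {"g1", "g2", "g3"}

    def test_idempotent(self, simple_counts_view):
        once = qc_filter_genes(simple_counts_view)
        twice = qc_filter_genes(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_too_few_samples_errors(self, simple_counts_view):
        v = PseudobulkView("ct", simple_counts_view.counts.iloc[:1],
                           simple_counts_view.n_cells.iloc[:1],
                           simple_counts_view.sample_meta.iloc[:1])
        with pytest.raises(ValueError):
            qc_filter_genes(v)


def _tmm_oracle(counts: np.ndarray) -> np.ndarray:
    """Direct reimplementation of the trimmed-mean-of-M-values factors."""
    lib = counts.sum(axis=1).astype(float)
    f75 = np.array([np.quantile(c / l, 0.75) for c, l in zip(counts, lib)])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(len(counts))
    for j in range(len(counts)):
        if j == ref:
            continue
        y, yr = counts[j].astype(float), counts[ref].astype(float)
        ok = (y > 0) & (yr > 0)
        y, yr = y[ok], yr[ok]
        m = np.log2((y / lib[j]) / (yr / lib[ref]))
        a = 0.5 * np.log2((y / lib[j]) * (yr / lib[ref]))
        w = (lib[j] - y) / (lib[j] * y) + (lib[ref] - yr) / (lib[ref] * yr)
        n = len(m)
        # ordinal ranks via stable sort (ties broken by position)
        rank_m = np.empty(n, dtype=int)
        rank_m[np.argsort(m, kind="stable")] = np.arange(1, n + 1)
        rank_a = np.empty(n, dtype=int)
        rank_a[np.argsort(a, kind="stable")] = np.arange(1, n + 1)
        lo_m, lo_a = int(np.floor(n * 0.3)) + 1, int(np.floor(n * 0.05)) + 1
        keep = ((rank_m >= lo_m) & (rank_m <= n - lo_m + 1)
                & (rank_a >= lo_a) & (rank_a <= n - lo_a + 1))
        if keep.sum() and w[keep].sum() > 0:
            factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    @staticmethod
    def _view(counts):
        counts = pd.DataFrame(np.asarray(counts))
        counts.columns = [f"g{i}" for i in counts.columns]
        counts.index = [f"s{i}" for i in counts.index]
        return PseudobulkView("ct", counts, pd.Series(50, index=counts.index),
                              pd.DataFrame(index=counts.index))

    def test_identical_libraries_give_unit_factors(self, rng):
        row = rng.poisson(20, size=60) + 1
        v = tmm_normalize(self._view(np.tile(row, (4, 1))))
        np.testing.assert_allclose(v.size_factors.to_numpy(), 1.0, atol=1e-12)

    def test_depth_scaling_absorbed(self, rng):
        row = rng.poisson(30, size=80) + 1
        v = tmm_normalize(self._view(np.vstack([row, 2 * row, row, row])))
        np.testing.assert_allclose(v.size_factors.to_numpy(), 1.0, atol=1e-12)

    def test_matches_independent_oracle(self, rng):
        for _ in range(20):
            counts = rng.poisson(rng.uniform(5, 50), size=(4, 50)) + rng.integers(0, 3, (4, 50))
            counts[0, :10] *= 3  # composition bias so trimming matters
            v = tmm_normalize(self._view(counts))
            np.testing.assert_allclose(
                v.size_factors.to_numpy(), _tmm_oracle(counts.astype(np.int64)),
                atol=1e-10,
            )

    def test_geometric_mean_one(self, normalized_views):
        for v in normalized_views.values():
            assert abs(np.mean(np.log(v.size_factors))) < 1e-9

    def test_zero_library_errors(self):
        counts = np.array([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="zero library"):
            tmm_normalize(self._view(counts))


class TestHVG:
    def test_planted_high_dispersion_genes_recovered(self, rng):
        n_samples, n_genes = 20, 500
        means = rng.uniform(2, 10, n_genes)
        X = means + rng.standard_normal((n_samples, n_genes)) * 0.3
        planted = rng.choice(n_genes, 20, replace=False)
        X[:, planted] += rng.standard_normal((n_samples, 20)) * 3.0
        v = PseudobulkView(
            "ct", pd.DataFrame(np.ones_like(X, dtype=int)),
            pd.Series(50, index=range(n_samples)), pd.DataFrame(index=range(n_samples)),
            logexpr=pd.DataFrame(X, columns=[f"g{i}" for i in range(n_genes)]),
        )
        hits = set(select_hvg(v, method="biovar", threshold=0.0))
        assert len(hits & {f"g{i}" for i in planted}) >= 18

    def test_flat_profile_yields_no_hvgs(self, rng):
        # every gene is the same pattern: identical mean and variance
        pattern = rng.standard_normal(20) * 0.5
        X = 5.0 + np.tile(pattern[:, None], (1, 100))
        v = PseudobulkView(
            "ct", pd.DataFrame(np.ones_like(X, dtype=int)),
            pd.Series(50, index=range(20)), pd.DataFrame(index=range(20)),
            logexpr=pd.DataFrame(X, columns=[f"g{i}" for i in range(100)]),
        )
        assert select_hvg(v, method="normvar", threshold=1.5) == []
        assert select_hvg(v, method="normvar", threshold=np.inf) == []


class TestMarkers:
    def test_strong_marker_detected(self, rng):
        genes = [f"g{i}" for i in range(30)]
        base = rng.standard_normal((12, 30)) * 0.2 + 2.0
        base[:4, 0] += 8.0  # gene 0 marks type A (first 4 samples)
        mk_views = {}
        for name, rows in (("A", slice(0, 4)), ("B", slice(4, 8)), ("C", slice(8, 12))):
            X = pd.DataFrame(base[rows], columns=genes,
                             index=[f"{name}{i}" for i in range(4)])
            mk_views[name] = PseudobulkView(
                name, X.astype(int), pd.Series(50, index=X.index),
                pd.DataFrame(index=X.index), logexpr=X,
            )
        table = detect_markers(mk_views)
        assert "g0" in table.markers_of("A")
        assert "g0" not in table.markers_of("B")

    def test_planted_marker_recovery(self, normalized_views, tiny_atlas):
        _, truth = tiny_atlas
        table = detect_markers(normalized_views)
        for ct, planted in truth.markers.items():
            found = set(table.markers_of(ct))
            assert set(planted) <= found
        # no planted marker of one type called for another type
        for ct in truth.markers:
            others = set().union(*(truth.markers[c] for c in truth.markers if c != ct))
            assert not (others & set(table.markers_of(ct)))

    def test_cellstate_markers(self, tiny_atlas):
        cells, truth = tiny_atlas
        table = detect_markers(cells, level="cellstate_cells")
        hit = 0
        total = 0
        for st, planted in truth.state_markers.items():
            total += len(planted)
            hit += len(set(planted) & set(table.markers_of(st)))
        assert hit / total >= 0.8


class TestExcludeBackground:
    def test_cross_type_marker_removed_own_kept(self):
        hvg = {"A": ["G", "H"], "B": ["G"]}
        table = views.MarkerTable(pd.DataFrame(
            {"class_id": ["B"], "gene": ["G"], "lfc": [2.0],
             "pval": [1e-5], "padj": [1e-4]}), "celltype_pseudobulk")
        out = exclude_background(hvg, table)
        assert out["A"] == ["H"]      # G is B's marker, removed from A
        assert out["B"] == ["G"]      # own markers exempt

    def test_own_marker_shared_with_other_type_kept(self):
        hvg = {"A": ["G"]}
        table = views.MarkerTable(pd.DataFrame(
            {"class_id": ["A", "B"], "gene": ["G", "G"], "lfc": [2.0, 2.0],
             "pval": [1e-5] * 2, "padj": [1e-4] * 2}), "celltype_pseudobulk")
        assert exclude_background(hvg, table)["A"] == ["G"]

    def test_empty_markers_is_identity(self):
        hvg = {"A": ["x", "y"], "B": ["z"]}
        empty = views.MarkerTable(
            pd.DataFrame(columns=["class_id", "gene", "lfc", "pval", "padj"]),
            "celltype_pseudobulk")
        with pytest.warns(UserWarning):
            assert exclude_background(hvg, empty) == hvg

    def test_output_subset_of_input(self, normalized_views):
        hvg = {ct: select_hvg(v) for ct, v in normalized_views.items()}
        table = detect_markers(normalized_views)
        out = exclude_background(hvg, table)
        for ct in hvg:
            assert set(out[ct]) <= set(hvg[ct])


class TestAssembleViews:
    def test_single_group_centering(self, normalized_views):
        ds = assemble_views(normalized_views)
        for mat in ds.views.values():
            assert np.nanmax(np.abs(np.nanmean(mat.to_numpy(), axis=0))) < 1e-8

    def test_per_group_centering_hides_group_offset(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 3)),
                         index=[f"s{i}" for i in range(10)],
                         columns=["a", "b", "c"])
        X.iloc[:5] += 10.0
        X.iloc[5:] -= 10.0
        groups = pd.Series(["g1"] * 5 + ["g2"] * 5, index=X.index)
        v = PseudobulkView("ct", X.astype(int), pd.Series(50, index=X.index),
                           pd.DataFrame(index=X.index), logexpr=X)
        ds = assemble_views({"ct": v}, group_id=groups)
        out = ds.views["ct"]
        for g in ("g1", "g2"):
            sub = out.loc[groups == g]
            assert np.abs(sub.mean(axis=0)).max() < 1e-8

    def test_missing_view_not_imputed(self, normalized_views):
        # drop one sample from one view before assembly
        name = next(iter(normalized_views))
        v = normalized_views[name]
        trimmed = PseudobulkView(
            v.cell_type, v.counts.iloc[1:], v.n_cells.iloc[1:],
            v.sample_meta.iloc[1:], logexpr=v.logexpr.iloc[1:],
            size_factors=v.size_factors.iloc[1:],
        )
        sub = dict(normalized_views)
        sub[name] = trimmed
        ds = assemble_views(sub)
        dropped = v.logexpr.index[0]
        assert dropped not in ds.views[name].index
        assert dropped in ds.sample_ids
        n_in = sum(m.logexpr.size for m in sub.values())
        assert ds.n_observed() == n_in

    def test_duplicate_sample_ids_error(self, rng):
        X = pd.DataFrame(rng.standard_normal((2, 2)), index=["s", "s"],
                         columns=["a", "b"])
        with pytest.raises(ValueError, match="duplicated"):
            MultiViewDataset(views={"v": X}, groups=pd.Series({"s": "g"}))


class TestStructuralViews:
    def test_clr_symmetry_and_formula(self):
        even = clr_transform(pd.DataFrame([[0.5, 0.5]]))
        np.testing.assert_allclose(even.to_numpy(), 0.0, atol=1e-12)
        skew = clr_transform(pd.DataFrame([[0.8, 0.2]]))
        np.testing.assert_allclose(
            skew.to_numpy()[0], [np.log(2), -np.log(2)], atol=1e-12)

    def test_clr_rows_sum_to_zero(self, rng):
        comp = pd.DataFrame(rng.dirichlet(np.ones(5), size=20))
        comp.iloc[0, 0] = 0.0  # exercise zero replacement
        out = clr_transform(comp)
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_negative_composition_errors(self):
        with pytest.raises(ValueError):
            clr_transform(pd.DataFrame([[-0.1, 1.1]]))

    def test_top_interactions_by_variance(self, rng):
        imp = pd.DataFrame(rng.standard_normal((15, 30)),
                           columns=[f"i{k}" for k in range(30)])
        imp *= np.linspace(0.1, 3.0, 30)  # increasing variance left to right
        vs, kinds = make_structural_views(importances={"colocal": imp}, top_n=21)
        kept = vs["spatial_colocal"].columns
        assert len(kept) == 21
        dropped = set(imp.columns) - set(kept)
        assert len(dropped) == 9
        assert max(imp[list(dropped)].var()) <= min(imp[list(kept)].var())
        assert kinds["spatial_colocal"] == "spatial_dependency"

    def test_top_n_larger_than_available_warns(self, rng):
        imp = pd.DataFrame(rng.standard_normal((5, 4)))
        imp.columns = [f"i{k}" for k in range(4)]
        with pytest.warns(UserWarning):
            vs, _ = make_structural_views(importances={"c": imp}, top_n=21)
        assert vs["spatial_c"].shape[1] == 4
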