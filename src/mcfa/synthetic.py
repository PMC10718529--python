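"""Synthetic fixtures with planted ground truth.

Generates the four kinds of input the pipeline consumes — multi-view
sample matrices, annotated single-cell counts, spatial slides, and bulk
cohorts — each returning a ``SimTruth`` that records what was planted so
recovery can be tested without external downloads.  The single-cell
generator emulates the structure of cross-condition atlases: several
samples per condition, a handful of cell types with cell states, ambient
(cell-free mRNA) contamination that leaks marker genes across types,
condition-driven multicellular programs shared by all cell types, and
log-normal sequencing depths.  All generators are bitwise reproducible
from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .spatial import SpatialSlide
from .transfer import BulkStudy
from .views import CellProfileMatrix, MultiViewDataset

__all__ = [
    "SimTruth",
    "simulate_multiview",
    "simulate_single_cell",
    "simulate_slides",
    "simulate_bulk_cohort",
]


@dataclass
class SimTruth:
    """Ground truth planted by a generator (fields unused by a given
    generator stay None)."""

    Z: dict[str, np.ndarray] | None = None
    W: dict[str, np.ndarray] | None = None
    activity: np.ndarray | None = None
    noise_sd: float | None = None
    markers: dict[str, list[str]] | None = None
    state_markers: dict[str, list[str]] | None = None
    program_up: list[str] | None = None
    program_down: list[str] | None = None
    ambient_rate: float | None = None
    condition: pd.Series | None = None
    condition_fold: float | None = None
    activation_masks: dict[str, pd.Series] | None = None
    true_relative_area: dict[str, float] | None = None
    compositions: pd.DataFrame | None = None
    missing: dict[str, list[str]] | None = None


# ---------------------------------------------------------------------------
# Multi-view data straight from the factor model
# ---------------------------------------------------------------------------

def _center_scale(
    frames: dict[str, pd.DataFrame], groups: pd.Series, scale: bool
) -> MultiViewDataset:
    centers, scales, out = {}, {}, {}
    for name, mat in frames.items():
        g = groups.loc[mat.index]
        mu = mat.groupby(g.to_numpy()).mean()
        cen = mat - mu.loc[g.to_numpy()].set_axis(mat.index)
        centers[name] = mu
        if scale:
            sd = mat.groupby(g.to_numpy()).std(ddof=0)
            sd = sd.where(sd > 0, np.nan)
            cen = cen / sd.loc[g.to_numpy()].set_axis(mat.index)
            scales[name] = sd
        out[name] = cen
    return MultiViewDataset(views=out, groups=groups, centers=centers, scales=scales)


def _default_activity(n_views: int, K: int) -> np.ndarray:
    """Distinct view-activity pattern per factor.

    Factor 1 is active everywhere; subsequent factors each silence a
    different subset of views.  Distinct patterns make the factors
    identifiable up to sign (a rotation mixing two factors would leak
    signal into views where one of them is inactive), mirroring real
    multicellular programs that involve different cell-type subsets.
    """
    if n_views == 1:
        return np.ones((1, K), dtype=bool)
    patterns = [np.ones(n_views, dtype=bool)]
    # drop one view, then two, ... cycling through combinations
    from itertools import combinations
    n_off = 1
    while len(patterns) < K:
        added = False
        for off in combinations(range(n_views), n_off):
            p = np.ones(n_views, dtype=bool)
            p[list(off)] = False
            if p.any():
                patterns.append(p)
                added = True
            if len(patterns) == K:
                break
        n_off += 1
        if n_off >= n_views and not added:
            patterns.append(np.ones(n_views, dtype=bool))
    return np.column_stack(patterns[:K])


def simulate_multiview(
    n_samples: int = 50,
    view_features: Sequence[int] = (300, 300, 300),
    K_true: int = 4,
    activity: np.ndarray | None = None,
    noise_sd: float = 0.3,
    n_groups: int = 1,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[MultiViewDataset, SimTruth]:
    """Draw data from the group factor analysis generative model.

    Z ~ Normal(0,1) per group, W columns Normal(0,1) zeroed where the
    (view, factor) activity pattern is off, Y = Z W^T + Normal(0,
    noise_sd^2).  ``missing_fraction`` of all samples each lose one
    randomly chosen view.  Views are returned centered per group (and unit
    scaled per group when ``n_groups > 1``), as the model expects.
    """
    if K_true < 1:
        raise ValueError("K_true must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_views = len(view_features)
    if activity is None:
        activity = _default_activity(n_views, K_true)
    activity = np.asarray(activity, dtype=bool)
    if activity.shape != (n_views, K_true):
        raise ValueError("activity must be (n_views, K_true)")

    view_names = [f"view{m}" for m in range(n_views)]
    group_names = [f"group{g}" for g in range(n_groups)]
    W = {}
    for m, D in enumerate(view_features):
        w = rng.standard_normal((D, K_true))
        w[:, ~activity[m]] = 0.0
        W[view_names[m]] = w
    Z, frames, groups_idx = {}, {v: [] for v in view_names}, []
    sample_ids_all = []
    for g in group_names:
        Zg = rng.standard_normal((n_samples, K_true))
        Z[g] = Zg
        ids = [f"{g}_s{i:03d}" for i in range(n_samples)]
        sample_ids_all += ids
        groups_idx += [g] * n_samples
        for m, v in enumerate(view_names):
            Y = Zg @ W[v].T + noise_sd * rng.standard_normal((n_samples, len(W[v])))
            frames[v].append(pd.DataFrame(
                Y, index=ids, columns=[f"{v}_f{d:03d}" for d in range(len(W[v]))]
            ))
    groups = pd.Series(groups_idx, index=sample_ids_all, name="group")
    mats = {v: pd.concat(parts, axis=0) for v, parts in frames.items()}

    missing: dict[str, list[str]] = {v: [] for v in view_names}
    if missing_fraction > 0:
        n_miss = int(round(missing_fraction * len(sample_ids_all)))
        lost = rng.choice(len(sample_ids_all), size=n_miss, replace=False)
        for i in lost:
            v = view_names[rng.integers(len(view_names))]
            sid = sample_ids_all[i]
            mats[v] = mats[v].drop(index=sid)
            missing[v].append(sid)

    data = _center_scale(mats, groups, scale=n_groups > 1)
    truth = SimTruth(Z=Z, W=W, activity=activity, noise_sd=noise_sd,
                     missing=missing)
    return data, truth


# ---------------------------------------------------------------------------
# Annotated single-cell counts
# ---------------------------------------------------------------------------

def simulate_single_cell(
    n_types: int = 3,
    states_per_type: int = 2,
    n_genes: int = 300,
    n_marker: int = 10,
    n_state_marker: int = 5,
    n_program: int = 10,
    conditions: Sequence[str] = ("healthy", "disease"),
    n_samples_per_condition: int = 10,
    n_cells: int = 80,
    depth_median: float = 2500.0,
    depth_sigma: float = 0.35,
    ambient: float = 0.1,
    condition_fold: float = 3.0,
    marker_fold: float = 30.0,
    state_fold: float = 4.0,
    sample_noise_sd: float = 0.15,
    seed: int = 0,
) -> tuple[CellProfileMatrix, SimTruth]:
    """Simulate a cross-condition single-cell atlas with planted structure.

    Each cell's counts are Multinomial(depth, (1 - lambda) * pi + lambda *
    pi_ambient), where pi depends on (cell type, state, condition, sample)
    and pi_ambient is the cell-weighted mean profile of the sample (the
    cell-free mRNA pool).  Planted structure: ``n_marker`` genes exclusive
    to each type (structural zeros elsewhere when lambda = 0),
    ``n_state_marker`` genes per state, and a multicellular program of
    ``n_program`` up- and ``n_program`` down-regulated genes whose rates
    shift by ``condition_fold`` in every cell type of case samples.
    Per-sample log-normal rate jitter makes genes variable across samples.
    """
    if not 0 <= ambient <= 0.5:
        raise ValueError("ambient rate must be in [0, 0.5]")
    needed = n_types * n_marker + n_types * states_per_type * n_state_marker + 2 * n_program
    if needed > n_genes:
        raise ValueError(f"n_genes={n_genes} too small for planted structure ({needed})")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:04d}" for i in range(n_genes)], dtype=object)
    types = [f"ct{t}" for t in range(n_types)]
    states = {t: [f"{t}_state{s}" for s in range(states_per_type)] for t in types}

    pos = 0
    markers = {}
    for t in types:
        markers[t] = list(genes[pos:pos + n_marker]); pos += n_marker
    state_markers = {}
    for t in types:
        for s in states[t]:
            state_markers[s] = list(genes[pos:pos + n_state_marker]); pos += n_state_marker
    program_up = list(genes[pos:pos + n_program]); pos += n_program
    program_down = list(genes[pos:pos + n_program]); pos += n_program

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes) + 0.05
    # planted genes are solidly expressed: programs and markers in real
    # atlases are defined over detectable genes, not the noise floor
    planted = np.zeros(n_genes, dtype=bool)
    planted[:needed] = True
    base[planted] = rng.lognormal(mean=0.7, sigma=0.5, size=int(planted.sum())) + 0.5
    gidx = {g: i for i, g in enumerate(genes)}

    # rate templates per (type, state, condition)
    def rates(t: str, s: str, cond_is_case: bool) -> np.ndarray:
        r = base.copy()
        for t2 in types:
            ix = [gidx[g] for g in markers[t2]]
            r[ix] = base[ix] * marker_fold if t2 == t else 0.0
        ix = [gidx[g] for g in state_markers[s]]
        r[ix] = r[ix] * state_fold
        if cond_is_case:
            r[[gidx[g] for g in program_up]] *= condition_fold
            r[[gidx[g] for g in program_down]] /= condition_fold
        return r

    sample_rows, meta_rows, count_rows = [], [], []
    cond_per_sample = {}
    for ci, cond in enumerate(conditions):
        is_case = ci > 0
        for j in range(n_samples_per_condition):
            sid = f"{cond}_s{j:02d}"
            cond_per_sample[sid] = cond
            jitter = rng.lognormal(mean=0.0, sigma=sample_noise_sd, size=n_genes)
            # cell-type/state rate vectors for this sample
            pis, cell_specs = [], []
            for t in types:
                for _ in range(n_cells):
                    s = states[t][rng.integers(states_per_type)]
                    cell_specs.append((t, s))
            uniq = {}
            for t, s in cell_specs:
                if (t, s) not in uniq:
                    r = rates(t, s, is_case) * jitter
                    uniq[(t, s)] = r / r.sum()
            pi_amb = np.mean([uniq[spec] for spec in cell_specs], axis=0)
            for t, s in cell_specs:
                p = (1.0 - ambient) * uniq[(t, s)] + ambient * pi_amb
                depth = int(np.round(np.exp(np.log(depth_median)
                                            + depth_sigma * rng.standard_normal())))
                depth = max(depth, 100)
                count_rows.append(rng.multinomial(depth, p))
                meta_rows.append({"sample_id": sid, "cell_type": t,
                                  "cell_state": s, "condition": cond})
    counts = np.vstack(count_rows).astype(np.int64)
    meta = pd.DataFrame(meta_rows)
    meta.index = [f"cell{i:06d}" for i in range(len(meta))]
    cells = CellProfileMatrix(counts=counts, gene_ids=genes, cell_meta=meta)
    truth = SimTruth(
        markers=markers, state_markers=state_markers,
        program_up=program_up, program_down=program_down,
        ambient_rate=ambient,
        condition=pd.Series(cond_per_sample, name="condition"),
        condition_fold=condition_fold,
    )
    return cells, truth


# ---------------------------------------------------------------------------
# Spatial slides
# ---------------------------------------------------------------------------

def simulate_slides(
    n_slides_per_condition: int = 3,
    grid: tuple[int, int] = (12, 12),
    cell_types: Sequence[str] = ("ct0", "ct1", "ct2"),
    target_type: str = "ct0",
    n_genes: int = 200,
    n_sig: int = 10,
    active_fraction: float = 0.4,
    effect: float = 1.5,
    baseline_sd: float = 0.5,
    prop_threshold: float = 0.1,
    conditions: Sequence[str] = ("control", "case"),
    seed: int = 0,
) -> tuple[list[SpatialSlide], SimTruth]:
    """Simulate spatial slides with a program active in part of a niche.

    Spot cell-type proportions are Dirichlet draws, with the target type
    favored in the upper half of the grid (a simple two-niche layout).  In
    case slides, ``active_fraction`` of the spots where the target type is
    present (proportion >= ``prop_threshold``) get the program's up genes
    shifted by +``effect`` and the down genes by -``effect``.  The truth
    stores per-spot activation masks and each slide's true relative area.
    """
    if grid[0] < 4 or grid[1] < 4:
        raise ValueError("grid must be at least 4x4")
    if not 0 <= active_fraction <= 1:
        raise ValueError("active_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    sig_up, sig_down = genes[:n_sig], genes[n_sig:2 * n_sig]
    gene_mean = rng.normal(5.0, 1.0, size=n_genes)
    t_ix = list(cell_types).index(target_type)
    slides, masks, true_area = [], {}, {}
    for ci, cond in enumerate(conditions):
        is_case = ci > 0
        for j in range(n_slides_per_condition):
            sid = f"{cond}_slide{j}"
            nx, ny = grid
            xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
            coords = pd.DataFrame(
                {"x": xs.ravel(), "y": ys.ravel()},
                index=[f"{sid}_spot{i:04d}" for i in range(nx * ny)],
            )
            alpha = np.ones((len(coords), len(cell_types)))
            upper = (coords["y"] >= ny // 2).to_numpy()
            alpha[upper, t_ix] = 4.0
            props = np.vstack([rng.dirichlet(a) for a in alpha])
            props = pd.DataFrame(props, index=coords.index, columns=list(cell_types))
            expr = gene_mean[None, :] + baseline_sd * rng.standard_normal(
                (len(coords), n_genes))
            eff_mask = (props[target_type] >= prop_threshold).to_numpy()
            active = np.zeros(len(coords), dtype=bool)
            if is_case:
                eff_idx = np.where(eff_mask)[0]
                n_act = int(round(active_fraction * len(eff_idx)))
                act_idx = rng.choice(eff_idx, size=n_act, replace=False)
                active[act_idx] = True
                up_ix = [genes.index(g) for g in sig_up]
                dn_ix = [genes.index(g) for g in sig_down]
                expr[np.ix_(active, up_ix)] += effect
                expr[np.ix_(active, dn_ix)] -= effect
            expr = pd.DataFrame(expr, index=coords.index, columns=genes)
            slides.append(SpatialSlide(slide_id=sid, expr=expr, props=props,
                                       coords=coords, condition=cond))
            masks[sid] = pd.Series(active, index=coords.index)
            true_area[sid] = float(active.sum() / eff_mask.sum()) if eff_mask.sum() else np.nan
    truth = SimTruth(program_up=sig_up, program_down=sig_down,
                     activation_masks=masks, true_relative_area=true_area)
    return slides, truth


# ---------------------------------------------------------------------------
# Bulk cohorts
# ---------------------------------------------------------------------------

def simulate_bulk_cohort(
    n_per_condition: int = 20,
    cell_types: Sequence[str] = ("ct0", "ct1", "ct2"),
    n_genes: int = 300,
    n_program: int = 10,
    composition_alpha: dict[str, Sequence[float]] | None = None,
    effect_fold: float = 2.0,
    noise_sd: float = 0.3,
    conditions: Sequence[str] = ("nonfailing", "failing"),
    study_id: str = "synthetic_bulk",
    seed: int = 0,
) -> tuple[BulkStudy, SimTruth]:
    """Simulate a bulk cohort convolving composition and program activity.

    Each sample's linear expression is the composition-weighted mixture of
    cell-type profiles; in case samples the program's up genes are
    multiplied by ``effect_fold`` and the down genes divided by it, then
    log-normal noise is applied.  With identical composition priors across
    conditions (the default), only the program separates the groups.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    program_up, program_down = genes[:n_program], genes[n_program:2 * n_program]
    profiles = pd.DataFrame(
        rng.lognormal(mean=2.0, sigma=1.0, size=(len(cell_types), n_genes)),
        index=list(cell_types), columns=genes,
    )
    if composition_alpha is None:
        composition_alpha = {c: np.full(len(cell_types), 5.0) for c in conditions}
    cols, comps, labels = [], [], {}
    expr = {}
    for ci, cond in enumerate(conditions):
        is_case = ci > 0
        alpha = np.asarray(composition_alpha[cond], dtype=float)
        if len(alpha) != len(cell_types):
            raise ValueError("composition_alpha length must match cell_types")
        for j in range(n_per_condition):
            sid = f"{study_id}_{cond}_s{j:02d}"
            frac = rng.dirichlet(alpha)
            if not np.isclose(frac.sum(), 1.0):
                raise ValueError("composition fractions must sum to 1")
            bulk = frac @ profiles.to_numpy()
            if is_case:
                up_ix = [genes.index(g) for g in program_up]
                dn_ix = [genes.index(g) for g in program_down]
                bulk[up_ix] *= effect_fold
                bulk[dn_ix] /= effect_fold
            bulk = bulk * rng.lognormal(0.0, noise_sd, size=n_genes)
            cols.append(sid)
            expr[sid] = bulk
            comps.append(frac)
            labels[sid] = cond
    expr_df = pd.DataFrame(expr, index=genes)
    study = BulkStudy(study_id=study_id, expr=expr_df,
                      condition=pd.Series(labels, name="condition"))
    truth = SimTruth(
        program_up=program_up, program_down=program_down,
        condition=pd.Series(labels, name="condition"),
        condition_fold=effect_fold,
        compositions=pd.DataFrame(comps, index=cols, columns=list(cell_types)),
    )
    return study, truth
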