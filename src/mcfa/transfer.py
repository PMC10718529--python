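"""Transfer of a reference latent space to new cohorts and bulk data.

Projects new samples into a fitted model's factor space through the
Moore-Penrose pseudoinverse of the concatenated view weights, scores
factor signatures on bulk transcriptomics studies (per-study centered and
scaled), and evaluates label separation with silhouette widths and
rank-sum tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_samples

from .programs import EnrichmentResult, FactorSignature, bh_adjust, score_signatures
from .views import MultiViewDataset

__all__ = [
    "ProjectionResult",
    "BulkStudy",
    "project_samples",
    "score_bulk_signatures",
    "silhouette_by_label",
    "compare_groups_wilcoxon",
    "wilcoxon_family",
]


@dataclass
class ProjectionResult:
    """New-cohort factor scores obtained by pseudoinverse projection."""

    scores: pd.DataFrame               # sample x factor
    features_used: dict[str, int]      # per view, shared features found
    coverage: dict[str, float]         # per view, fraction of reference features
    rank_deficient: bool = False


@dataclass
class BulkStudy:
    """One bulk transcriptomics cohort (genes x samples)."""

    study_id: str
    expr: pd.DataFrame
    condition: pd.Series
    platform: str = ""

    def __post_init__(self) -> None:
        if self.expr.index.duplicated().any():
            raise ValueError("duplicate gene ids in bulk study")
        if self.expr.shape[1] < 2:
            raise ValueError("bulk study needs >= 2 samples")


def project_samples(
    reference_W: pd.DataFrame, new_data: MultiViewDataset
) -> ProjectionResult:
    """Project processed new-cohort views into the reference factor space.

    ``reference_W`` is the concatenated weight matrix indexed by
    (view, feature) — see :meth:`GFAModel.concatenated_weights`.  For each
    sample, the weights are restricted to the (view, feature) pairs the
    sample actually has, and the scores are the minimal-norm least-squares
    solution ``z = W_obs^+ y_obs``.  New data must be centered with its own
    per-feature means (process each study independently).
    """
    if not isinstance(reference_W.index, pd.MultiIndex):
        raise ValueError("reference_W must be indexed by (view, feature)")
    ref_views = reference_W.index.get_level_values("view").unique()
    shared: dict[str, list[str]] = {}
    features_used, coverage = {}, {}
    for v in ref_views:
        ref_feats = reference_W.loc[v].index
        if v in new_data.views:
            found = [f for f in ref_feats if f in set(new_data.views[v].columns)]
        else:
            found = []
        shared[v] = found
        features_used[v] = len(found)
        coverage[v] = len(found) / len(ref_feats) if len(ref_feats) else 0.0
        if 0 < coverage[v] < 0.5:
            warnings.warn(f"view {v!r}: only {coverage[v]:.0%} of reference features found")
    if sum(features_used.values()) == 0:
        raise ValueError("no reference features found in any view of the new data")

    # long vector per sample over all shared (view, feature) pairs
    samples = new_data.sample_ids
    blocks_w, blocks_y = [], []
    for v in ref_views:
        if not shared[v]:
            continue
        blocks_w.append(reference_W.loc[v].loc[shared[v]].to_numpy(dtype=float))
        blocks_y.append(new_data.views[v].reindex(index=samples, columns=shared[v])
                        .to_numpy(dtype=float))
    W = np.vstack(blocks_w)
    Y = np.hstack(blocks_y)  # samples x total features (NaN where missing)

    K = W.shape[1]
    rank_deficient = np.linalg.matrix_rank(W) < K
    if rank_deficient:
        warnings.warn("shared-feature weight matrix is rank deficient; "
                      "minimal-norm solution returned")
    scores = np.empty((len(samples), K))
    obs = ~np.isnan(Y)
    # group samples by missingness pattern so the pseudoinverse is reused
    pattern_ids = {}
    for i in range(len(samples)):
        pattern_ids.setdefault(obs[i].tobytes(), []).append(i)
    for key, idx in pattern_ids.items():
        o = obs[idx[0]]
        if o.sum() == 0:
            scores[idx] = np.nan
            continue
        pinv = np.linalg.pinv(W[o])
        scores[idx] = (pinv @ Y[np.ix_(idx, np.where(o)[0])].T).T
    return ProjectionResult(
        scores=pd.DataFrame(scores, index=samples,
                            columns=[f"Factor{k + 1}" for k in range(K)]),
        features_used=features_used,
        coverage=coverage,
        rank_deficient=rank_deficient,
    )


def score_bulk_signatures(
    study: BulkStudy,
    sigs: list[FactorSignature],
    n_perm: int = 100,
    seed: int = 0,
    min_coverage: float = 0.1,
) -> EnrichmentResult:
    """Normalized weighted-mean signature scores for one bulk study.

    Expression is z-scored per gene across the study's samples (constant
    genes dropped) before scoring; studies are never pooled.  Signatures
    with fewer than ``min_coverage`` of their genes measured are skipped
    with a warning.
    """
    X = study.expr.T  # samples x genes
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = (X.loc[:, keep] - X.loc[:, keep].mean(axis=0)) / sd[keep]
    usable = []
    for sig in sigs:
        frac = np.mean([g in set(X.columns) for g in sig.genes])
        if frac < min_coverage:
            warnings.warn(
                f"signature {sig.name}: only {frac:.0%} of genes measured in "
                f"study {study.study_id!r}; skipped"
            )
            continue
        usable.append(sig)
    if not usable:
        raise ValueError(f"no scorable signatures for study {study.study_id!r}")
    return score_signatures(X, usable, n_perm=n_perm, seed=seed)


def silhouette_by_label(X: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Silhouette width per sample on Euclidean distances.

    ``s(i) = (b - a) / max(a, b)`` with a the mean within-label distance
    and b the smallest mean distance to another label; samples in
    singleton labels (and degenerate 0/0 cases) get width 0.
    """
    lab = labels.loc[X.index]
    if lab.nunique() < 2:
        raise ValueError("silhouette needs at least 2 labels")
    vals = silhouette_samples(X.to_numpy(dtype=float), lab.to_numpy())
    vals = np.nan_to_num(vals, nan=0.0)
    return pd.Series(vals, index=X.index, name="silhouette")


def compare_groups_wilcoxon(
    values: pd.Series, labels: pd.Series
) -> tuple[float, float]:
    """Two-sided rank-sum test (tie-corrected) between two labeled groups.

    Returns (statistic, p); constant pooled values give p = 1.
    """
    lab = labels.loc[values.index]
    levels = sorted(pd.unique(lab.dropna()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    a = values[lab == levels[0]].dropna()
    b = values[lab == levels[1]].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    if pd.concat([a, b]).nunique() == 1:
        return float(len(a) * len(b) / 2.0), 1.0
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(stat), float(p)


def wilcoxon_family(
    items: dict[str, tuple[pd.Series, pd.Series]]
) -> pd.DataFrame:
    """Rank-sum tests over a named family with BH adjustment across it."""
    rows = []
    for name, (values, labels) in items.items():
        stat, p = compare_groups_wilcoxon(values, labels)
        rows.append({"name": name, "statistic": stat, "pval": p})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["pval"])
    return out
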