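"""Interpretation of the multicellular latent space.

Associates factor scores with sample covariates, extracts cell-type-specific
factor signatures from the loading matrices, scores signatures on new
expression data with a permutation-normalized weighted mean, enriches
cell-state markers in signatures, and partitions gene variance between
sample condition and cell state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gfa import GFAModel

__all__ = [
    "FactorSignature",
    "EnrichmentResult",
    "StateVarianceResult",
    "associate_factors",
    "extract_signatures",
    "score_wmean",
    "score_signatures",
    "enrich_hypergeometric",
    "variance_partition_states",
    "signature_jaccard",
    "bh_adjust",
]


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment within one family."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Factor-covariate association
# ---------------------------------------------------------------------------

def associate_factors(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    kinds: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Associate factor scores with sample covariates.

    Categorical covariates use tie-corrected Kruskal-Wallis tests
    (chi-square p with df = levels - 1); continuous covariates a simple
    linear-regression F-test.  BH adjustment is applied across factors
    within each covariate.  Returns a table with one row per
    (factor, covariate).
    """
    common = scores.index.intersection(covariates.index)
    if len(common) < 4:
        raise ValueError("fewer than 4 samples shared between scores and covariates")
    scores = scores.loc[common]
    covariates = covariates.loc[common]
    kinds = kinds or {}
    rows = []
    for cov in covariates.columns:
        vals = covariates[cov].dropna()
        kind = kinds.get(
            cov, "continuous" if pd.api.types.is_numeric_dtype(vals) else "categorical"
        )
        sub_scores = scores.loc[vals.index]
        if vals.nunique() < 2:
            warnings.warn(f"covariate {cov!r} is constant; skipped")
            continue
        cov_rows = []
        for f in scores.columns:
            x = sub_scores[f].to_numpy(dtype=float)
            if kind == "categorical":
                levels = [x[(vals == lv).to_numpy()] for lv in pd.unique(vals)]
                levels = [lv for lv in levels if len(lv) >= 2]
                if len(levels) < 2:
                    warnings.warn(f"covariate {cov!r}: fewer than 2 usable levels; skipped")
                    cov_rows = []
                    break
                stat, p = stats.kruskal(*levels)
            else:
                c = pd.to_numeric(vals, errors="coerce").to_numpy(dtype=float)
                ok = np.isfinite(c)
                if ok.sum() < 4:
                    warnings.warn(f"covariate {cov!r}: fewer than 4 numeric samples; skipped")
                    cov_rows = []
                    break
                res = stats.linregress(c[ok], x[ok])
                # slope F-test of the univariate linear model (F = t^2)
                with np.errstate(divide="ignore", invalid="ignore"):
                    tval = res.slope / res.stderr if res.stderr > 0 else 0.0
                stat, p = float(tval ** 2), float(res.pvalue)
            cov_rows.append({"factor": f, "covariate": cov, "kind": kind,
                             "statistic": float(stat), "pval": float(p)})
        if cov_rows:
            sub = pd.DataFrame(cov_rows)
            sub["padj"] = bh_adjust(sub["pval"])
            rows.append(sub)
    if not rows:
        return pd.DataFrame(columns=["factor", "covariate", "kind", "statistic", "pval", "padj"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Factor signatures
# ---------------------------------------------------------------------------

@dataclass
class FactorSignature:
    """Genes of one cell type whose factor loadings survive the threshold,
    split by loading sign."""

    cell_type: str
    factor: int
    sign: str  # "positive" | "negative"
    weights: pd.Series
    threshold: float

    def __post_init__(self) -> None:
        if self.sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")
        w = self.weights
        if self.sign == "positive" and not (w > 0).all():
            raise ValueError("positive signature contains non-positive weights")
        if self.sign == "negative" and not (w < 0).all():
            raise ValueError("negative signature contains non-negative weights")
        if (w.abs() < self.threshold).any():
            raise ValueError("signature contains weights below the threshold")

    @property
    def name(self) -> str:
        return f"{self.cell_type}|Factor{self.factor + 1}|{self.sign}"

    @property
    def genes(self) -> list[str]:
        return list(self.weights.index)

    def __len__(self) -> int:
        return len(self.weights)


def extract_signatures(
    model: GFAModel,
    factor: int,
    threshold: float = 0.1,
    views: list[str] | None = None,
) -> list[FactorSignature]:
    """Cell-type-specific signatures of one factor.

    Loadings with absolute value below ``threshold`` (default 0.1) are set
    to zero; the survivors are split into a positive and a negative
    signature per cell type.  Only expression views are meaningful here —
    restrict with ``views`` if the model includes structural views.
    """
    if not 0 <= factor < model.K:
        raise IndexError(f"factor {factor} out of range for K={model.K}")
    views = views if views is not None else model.view_names
    out: list[FactorSignature] = []
    for ct in views:
        w = model.weights(ct)[f"Factor{factor + 1}"]
        surv = w[w.abs() >= threshold]
        pos, neg = surv[surv > 0], surv[surv < 0]
        if len(pos):
            out.append(FactorSignature(ct, factor, "positive", pos, threshold))
        if len(neg):
            out.append(FactorSignature(ct, factor, "negative", neg, threshold))
    return out


# ---------------------------------------------------------------------------
# Permutation-normalized weighted-mean scoring
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Raw weighted-mean scores and permutation-normalized z per signature."""

    scores: pd.DataFrame    # samples x signatures, raw weighted means
    z: pd.DataFrame         # samples x signatures, permutation z-scores
    degenerate: pd.DataFrame  # boolean; True where the null sd was zero
    n_perm: int
    seed: int


def _wmean_one(
    X: np.ndarray, genes: pd.Index, weights: pd.Series, n_perm: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted-mean score and permutation z for one signature.

    The null permutes gene identity: each permutation draws ``len(sig)``
    genes uniformly without replacement from the measured universe and
    assigns the signature's weights to them in fixed order.  The index
    sequence depends only on (seed, signature size, universe size), so a
    single sample scored alone gets bitwise the same z as within a batch.
    """
    pos = genes.get_indexer(weights.index)
    present = pos >= 0
    if present.sum() < len(weights):
        warnings.warn(
            f"{int((~present).sum())} signature genes absent from the data; dropped"
        )
    pos, w = pos[present], weights.to_numpy(dtype=float)[present]
    if len(w) == 0:
        raise ValueError("empty effective signature: no genes measured")
    denom = np.abs(w).sum()
    s = X[:, pos] @ w / denom
    rng = np.random.default_rng(seed)
    n_univ, n_sig = X.shape[1], len(w)
    null_sum = np.zeros(X.shape[0])
    null_sumsq = np.zeros(X.shape[0])
    for _ in range(n_perm):
        idx = rng.choice(n_univ, size=n_sig, replace=False)
        sp = X[:, idx] @ w / denom
        null_sum += sp
        null_sumsq += sp ** 2
    mean_null = null_sum / n_perm
    var_null = (null_sumsq - n_perm * mean_null ** 2) / (n_perm - 1)
    sd_null = np.sqrt(np.maximum(var_null, 0.0))
    degenerate = sd_null == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(degenerate, 0.0, (s - mean_null) / np.where(degenerate, 1.0, sd_null))
    return s, z, degenerate


def score_wmean(
    X: pd.DataFrame, sig: FactorSignature, n_perm: int = 1000, seed: int = 0
) -> EnrichmentResult:
    """Permutation-normalized weighted-mean score of one signature.

    Raw score per sample: ``s = sum_g x_g w_g / sum_g |w_g|`` over the
    signature genes measured in ``X``.  ``z`` standardizes ``s`` against
    ``n_perm`` random gene sets of the same size drawn from the measured
    universe; a zero null sd yields z = 0 with a degenerate flag.
    """
    s, z, deg = _wmean_one(X.to_numpy(dtype=float), X.columns, sig.weights, n_perm, seed)
    name = sig.name
    return EnrichmentResult(
        scores=pd.DataFrame({name: s}, index=X.index),
        z=pd.DataFrame({name: z}, index=X.index),
        degenerate=pd.DataFrame({name: deg}, index=X.index),
        n_perm=n_perm, seed=seed,
    )


def score_signatures(
    X: pd.DataFrame, sigs: list[FactorSignature], n_perm: int = 1000, seed: int = 0
) -> EnrichmentResult:
    """Score several signatures; each uses its own generator from ``seed``,
    so per-signature columns match :func:`score_wmean` bitwise."""
    Xv = X.to_numpy(dtype=float)
    s_cols, z_cols, d_cols = {}, {}, {}
    for sig in sigs:
        s, z, deg = _wmean_one(Xv, X.columns, sig.weights, n_perm, seed)
        s_cols[sig.name], z_cols[sig.name], d_cols[sig.name] = s, z, deg
    return EnrichmentResult(
        scores=pd.DataFrame(s_cols, index=X.index),
        z=pd.DataFrame(z_cols, index=X.index),
        degenerate=pd.DataFrame(d_cols, index=X.index),
        n_perm=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# Cell-state enrichment (hypergeometric)
# ---------------------------------------------------------------------------

def enrich_hypergeometric(
    sig_genes: set[str] | list[str],
    marker_sets: dict[str, set[str] | list[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of marker sets in a signature.

    ``p = P(X >= k)`` with X ~ Hypergeometric(N=|universe|, K=|markers|,
    n=|signature|) and k the observed overlap; BH adjustment across the
    tested states.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    sig = set(sig_genes) & universe
    rows = []
    for state, markers in sorted(marker_sets.items()):
        mk = set(markers) & universe
        k = len(sig & mk)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(mk), len(sig)))
        rows.append({"state": state, "overlap": k, "n_markers": len(mk),
                     "n_signature": len(sig), "pval": p})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["pval"])
    return out


# ---------------------------------------------------------------------------
# Cell-state-independence variance partition
# ---------------------------------------------------------------------------

@dataclass
class StateVarianceResult:
    """Per-gene eta-squared for condition vs cell state, their log2 ratio,
    and the cell-type-level one-sample t-test of the log ratios."""

    per_gene: pd.DataFrame
    t_statistic: float
    t_pval: float
    shapiro_pval: float
    n_ratio_excluded: int


def _eta_squared(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA eta^2 (SS_between / SS_total) and F-test p."""
    grand = values.mean()
    ss_tot = float(((values - grand) ** 2).sum())
    if ss_tot == 0:
        return np.nan, np.nan
    groups = [values[labels == lv] for lv in pd.unique(labels)]
    ss_b = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    dfb, dfw = len(groups) - 1, len(values) - len(groups)
    ss_w = ss_tot - ss_b
    if ss_w <= 0 or dfw <= 0:
        p = 0.0 if ss_b > 0 else np.nan
    else:
        F = (ss_b / dfb) / (ss_w / dfw)
        p = float(stats.f.sf(F, dfb, dfw))
    return ss_b / ss_tot, p


def variance_partition_states(
    cond_expr: pd.DataFrame,
    cond_labels: pd.Series,
    state_expr: pd.DataFrame,
    state_labels: pd.Series,
    genes: list[str],
    alpha: float = 0.01,
) -> StateVarianceResult:
    """Partition signature-gene variance between condition and cell state.

    ``cond_expr`` holds per-sample pseudobulk profiles labeled by
    condition; ``state_expr`` per-(sample, state) pseudobulk profiles
    labeled by state (both within one cell type; profiles from < 25 cells
    should already be excluded upstream).  Per gene and grouping: one-way
    ANOVA eta^2 and BH-adjusted p (significance at adjusted p < ``alpha``);
    ``r = log2(eta2_cond / eta2_state)`` where both eta^2 are positive;
    values above 0 mean condition explains more variance than state.  The
    per-cell-type one-sample t-test asks whether mean(r) differs from 0; a
    Shapiro-Wilk p on r is reported alongside.
    """
    for labels, name in ((cond_labels, "condition"), (state_labels, "state")):
        counts = labels.value_counts()
        if (counts >= 2).sum() < 2:
            raise ValueError(f"need >= 2 {name} groups with >= 2 profiles each")
    genes = [g for g in genes if g in cond_expr.columns and g in state_expr.columns]
    rows = []
    for g in genes:
        e_c, p_c = _eta_squared(cond_expr[g].to_numpy(dtype=float),
                                cond_labels.loc[cond_expr.index].to_numpy())
        e_s, p_s = _eta_squared(state_expr[g].to_numpy(dtype=float),
                                state_labels.loc[state_expr.index].to_numpy())
        if np.isnan(e_c) and np.isnan(e_s):
            continue  # zero total variance in both groupings
        rows.append({"gene": g, "eta2_cond": e_c, "eta2_state": e_s,
                     "pval_cond": p_c, "pval_state": p_s})
    per_gene = pd.DataFrame(rows)
    if per_gene.empty:
        raise ValueError("no testable genes")
    for col in ("cond", "state"):
        ok = per_gene[f"pval_{col}"].notna()
        padj = np.full(len(per_gene), np.nan)
        padj[ok.to_numpy()] = bh_adjust(per_gene.loc[ok, f"pval_{col}"])
        per_gene[f"padj_{col}"] = padj
        per_gene[f"significant_{col}"] = per_gene[f"padj_{col}"] < alpha
    both_pos = (per_gene["eta2_cond"] > 0) & (per_gene["eta2_state"] > 0)
    ratio = np.where(
        both_pos, np.log2(per_gene["eta2_cond"] / per_gene["eta2_state"]), np.nan
    )
    per_gene["log2_ratio"] = ratio
    r = per_gene["log2_ratio"].dropna().to_numpy()
    if len(r) >= 3:
        t_stat, t_p = stats.ttest_1samp(r, 0.0)
        sh_p = stats.shapiro(r).pvalue if len(r) <= 5000 else np.nan
    else:
        t_stat, t_p, sh_p = np.nan, np.nan, np.nan
    return StateVarianceResult(
        per_gene=per_gene,
        t_statistic=float(t_stat), t_pval=float(t_p),
        shapiro_pval=float(sh_p),
        n_ratio_excluded=int((~both_pos).sum()),
    )


# ---------------------------------------------------------------------------
# Signature overlap
# ---------------------------------------------------------------------------

def signature_jaccard(sets: dict[str, set[str] | list[str]]) -> pd.DataFrame:
    """Pairwise Jaccard index |A∩B| / |A∪B|; NaN when both sets are empty."""
    names = list(sets)
    mats = {n: set(s) for n, s in sets.items()}
    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i:]:
            union = mats[a] | mats[b]
            if union:
                j = len(mats[a] & mats[b]) / len(union)
            else:
                j = np.nan
            out.loc[a, b] = out.loc[b, a] = j
    return out
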