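"""Variational Bayesian group factor analysis with ARD priors.

The generative model for view m (features d), group g (samples n):

    y[n,d] = sum_k z[n,k] w[d,k] + eps,   eps ~ Normal(0, 1/tau[m,g,d])

with automatic relevance determination on both sides of the factorization:

    w[d,k] ~ Normal(0, 1/alpha[m,k]),  alpha[m,k] ~ Gamma(a0, b0)
    z[n,k] ~ Normal(0, 1/beta[g,k]),   beta[g,k]  ~ Gamma(c0, d0)
    tau[m,g,d] ~ Gamma(e0, f0)

For single-group data beta is fixed at 1 (standard-normal score prior);
with multiple groups it is learned per (group, factor), which lets a factor
be active in some cohorts and shrunk away in others.  No feature-wise
(spike-and-slab) sparsity is imposed.  Inference is mean-field coordinate
ascent with closed-form Gaussian updates for the rows of Z and W and Gamma
updates for alpha, beta and tau; missing entries — including samples that
lack a view entirely — are masked out of every sufficient statistic, so the
ELBO is exact for the observed data and increases monotonically.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .views import MultiViewDataset

__all__ = [
    "GFAHyperparams",
    "GFAModel",
    "fit_gfa",
    "explained_variance",
    "postprocess_factors",
    "reconstruct",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GFAHyperparams:
    """Hyperparameters of the variational group factor analysis.

    K is the number of latent factors (the models in this package default
    to 6); the Gamma shape/rate pairs are uninformative at 1e-3; ``tol`` is
    the relative ELBO change that stops coordinate ascent.
    """

    K: int = 6
    a0: float = 1e-3
    b0: float = 1e-3
    c0: float = 1e-3
    d0: float = 1e-3
    e0: float = 1e-3
    f0: float = 1e-3
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 1
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        for name in ("a0", "b0", "c0", "d0", "e0", "f0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class GFAModel:
    """Fitted model: posterior means/covariances and diagnostics."""

    hp: GFAHyperparams
    view_names: list[str]
    group_names: list[str]
    features: dict[str, list[str]]
    samples: dict[str, list[str]]
    W: dict[str, np.ndarray]
    Wcov: dict[str, np.ndarray]
    Z: dict[str, np.ndarray]
    Zcov: dict[str, np.ndarray]
    alpha: dict[str, np.ndarray]
    beta: dict[str, np.ndarray]
    tau: dict[tuple[str, str], np.ndarray]
    elbo_trace: np.ndarray
    beta_learned: bool
    centers: dict[str, pd.DataFrame] = field(default_factory=dict)
    scales: dict[str, pd.DataFrame] = field(default_factory=dict)
    r2: pd.DataFrame | None = None
    r2_total: pd.Series | None = None
    factor_r2: np.ndarray | None = None
    inactive_threshold: float = 0.005

    @property
    def K(self) -> int:
        return self.hp.K

    def scores(self) -> pd.DataFrame:
        """All factor scores stacked across groups (samples x factors)."""
        frames = [
            pd.DataFrame(self.Z[g], index=self.samples[g],
                         columns=[f"Factor{k + 1}" for k in range(self.K)])
            for g in self.group_names
        ]
        return pd.concat(frames, axis=0)

    def weights(self, view: str) -> pd.DataFrame:
        if view not in self.W:
            raise KeyError(f"unknown view {view!r}")
        return pd.DataFrame(self.W[view], index=self.features[view],
                            columns=[f"Factor{k + 1}" for k in range(self.K)])

    def concatenated_weights(self, views: list[str] | None = None) -> pd.DataFrame:
        """Weights stacked over views, indexed by (view, feature)."""
        views = views or self.view_names
        frames = []
        for m in views:
            w = self.weights(m)
            w.index = pd.MultiIndex.from_product([[m], w.index], names=["view", "feature"])
            frames.append(w)
        return pd.concat(frames, axis=0)

    def inactive_factors(self) -> list[int]:
        """Factors whose overall explained variance is below the threshold."""
        if self.factor_r2 is None:
            raise ValueError("run explained_variance first")
        return [k for k, r in enumerate(self.factor_r2) if r < self.inactive_threshold]


# ---------------------------------------------------------------------------
# Data marshalling
# ---------------------------------------------------------------------------

def _prepare(data: MultiViewDataset):
    """Align views/groups into dense arrays with observation masks."""
    view_names = list(data.views)
    groups = data.groups
    sample_order = data.sample_ids
    group_names = sorted(pd.unique(groups.loc[sample_order]))
    samples = {g: [s for s in sample_order if groups.loc[s] == g] for g in group_names}
    features = {m: list(data.views[m].columns) for m in view_names}
    Y: dict[tuple[str, str], np.ndarray] = {}
    O: dict[tuple[str, str], np.ndarray] = {}
    for m in view_names:
        mat = data.views[m]
        for g in group_names:
            idx = samples[g]
            sub = mat.reindex(idx)
            arr = sub.to_numpy(dtype=float)
            obs = ~np.isnan(arr)
            arr = np.where(obs, arr, 0.0)
            Y[(m, g)] = arr
            O[(m, g)] = obs
    return view_names, group_names, features, samples, Y, O


def _row_pattern(obs: np.ndarray):
    """Classify mask rows: fully observed, empty, or partial (list of idx)."""
    full = obs.all(axis=1)
    none = ~obs.any(axis=1)
    partial = np.where(~full & ~none)[0]
    return full, none, partial


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_gfa(data: MultiViewDataset, hp: GFAHyperparams | None = None) -> GFAModel:
    """Fit the group factor analysis by mean-field coordinate ascent.

    Per sweep the update order is Z, W, alpha, beta, tau, then the ELBO;
    the first sweep starts at W so the random initialization of Z (seeded
    standard normal) drives the first weight update.  Stops when the
    relative ELBO change falls below ``hp.tol`` or after ``hp.max_iter``
    sweeps.  Deterministic given (data, hyperparameters, seed).

    Coordinate ascent can stall in local optima where a factor splits in
    two; with ``hp.n_restarts > 1`` the model is refitted from consecutive
    seeds (seed, seed+1, ...) and the restart with the highest final ELBO
    is returned — still fully deterministic.
    """
    hp = hp or GFAHyperparams()
    if hp.n_restarts > 1:
        import dataclasses as _dc
        best = None
        for i in range(hp.n_restarts):
            cand = fit_gfa(data, _dc.replace(hp, seed=hp.seed + i, n_restarts=1))
            if best is None or cand.elbo_trace[-1] > best.elbo_trace[-1]:
                best = cand
        return best
    view_names, group_names, features, samples, Y, O = _prepare(data)
    K = hp.K

    for m in view_names:
        for g in group_names:
            obs = O[(m, g)]
            if obs.sum() == 0 and len(group_names) == 1:
                raise ValueError(f"view {m!r} has no observed entries")
        if all(O[(m, g)].sum() == 0 for g in group_names):
            raise ValueError(f"view {m!r} has no observed entries")
        for g in group_names:
            obs, y = O[(m, g)], Y[(m, g)]
            nobs = obs.sum(axis=0)
            with np.errstate(invalid="ignore"):
                mu = np.where(nobs > 0, y.sum(axis=0) / np.maximum(nobs, 1), 0.0)
            if np.any(np.abs(mu[nobs > 1]) > 1e-4):
                raise ValueError(
                    f"view {m!r}, group {g!r} is not centered; run assemble_views first"
                )
    n_total = sum(len(s) for s in samples.values())
    if K > n_total:
        warnings.warn(f"K={K} exceeds the number of samples ({n_total})")

    rng = np.random.default_rng(hp.seed)
    beta_learned = len(group_names) > 1

    Zm = {g: rng.standard_normal((len(samples[g]), K)) for g in group_names}
    Zc = {g: np.broadcast_to(np.eye(K), (len(samples[g]), K, K)).copy() for g in group_names}
    Wm = {m: np.zeros((len(features[m]), K)) for m in view_names}
    Wc = {m: np.broadcast_to(np.eye(K), (len(features[m]), K, K)).copy() for m in view_names}

    def gamma_moments(shape, rate):
        return shape / rate, digamma(shape) - np.log(rate)

    alpha = {m: {"shape": np.full(K, hp.a0), "rate": np.full(K, hp.b0)} for m in view_names}
    beta = {g: {"shape": np.full(K, hp.c0), "rate": np.full(K, hp.d0)} for g in group_names}
    tau = {
        (m, g): {"shape": np.full(len(features[m]), hp.e0),
                 "rate": np.full(len(features[m]), hp.f0)}
        for m in view_names for g in group_names
    }

    patterns = {key: _row_pattern(O[key]) for key in O}
    elbo_trace: list[float] = []
    sq_cache: dict[tuple[str, str], np.ndarray] = {}

    def Etau(key):
        return tau[key]["shape"] / tau[key]["rate"]

    def M2(mean, cov):
        return mean[:, :, None] * mean[:, None, :] + cov

    for it in range(hp.max_iter):
        # ---- Z update (skipped on the first sweep: W is still zero) ----
        if it > 0:
            for g in group_names:
                N = len(samples[g])
                Ebeta = beta[g]["shape"] / beta[g]["rate"] if beta_learned else np.ones(K)
                prec = np.broadcast_to(np.diag(Ebeta), (N, K, K)).copy()
                b = np.zeros((N, K))
                for m in view_names:
                    key = (m, g)
                    obs, y = O[key], Y[key]
                    et = Etau(key)
                    M2w = M2(Wm[m], Wc[m])
                    full, none, partial = patterns[key]
                    T_full = np.einsum("d,dij->ij", et, M2w)
                    prec[full] += T_full
                    for n in partial:
                        od = obs[n]
                        prec[n] += np.einsum("d,dij->ij", et[od], M2w[od])
                    b += (y * et[None, :]) @ Wm[m]
                Zc[g] = np.linalg.inv(prec)
                Zm[g] = np.einsum("nij,nj->ni", Zc[g], b)

        # ---- W update ----
        for m in view_names:
            D = len(features[m])
            Ealpha = alpha[m]["shape"] / alpha[m]["rate"]
            prec = np.broadcast_to(np.diag(Ealpha), (D, K, K)).copy()
            b = np.zeros((D, K))
            for g in group_names:
                key = (m, g)
                obs, y = O[key], Y[key]
                et = Etau(key)
                M2z = M2(Zm[g], Zc[g])
                full, none, partial = patterns[key]
                A_base = M2z[full].sum(axis=0)
                if len(partial) == 0:
                    prec += et[:, None, None] * A_base[None, :, :]
                else:
                    A = np.broadcast_to(A_base, (D, K, K)).copy()
                    for n in partial:
                        od = obs[n]
                        A[od] += M2z[n]
                    prec += et[:, None, None] * A
                b += et[:, None] * (y.T @ Zm[g])
            Wc[m] = np.linalg.inv(prec)
            Wm[m] = np.einsum("dij,dj->di", Wc[m], b)

        # ---- alpha update ----
        for m in view_names:
            D = len(features[m])
            Ew2 = Wm[m] ** 2 + np.einsum("dkk->dk", Wc[m])
            alpha[m]["shape"] = np.full(K, hp.a0 + 0.5 * D)
            alpha[m]["rate"] = hp.b0 + 0.5 * Ew2.sum(axis=0)

        # ---- beta update (multi-group only) ----
        if beta_learned:
            for g in group_names:
                N = len(samples[g])
                Ez2 = Zm[g] ** 2 + np.einsum("nkk->nk", Zc[g])
                beta[g]["shape"] = np.full(K, hp.c0 + 0.5 * N)
                beta[g]["rate"] = hp.d0 + 0.5 * Ez2.sum(axis=0)

        # ---- tau update ----
        for m in view_names:
            M2w = M2(Wm[m], Wc[m])
            for g in group_names:
                key = (m, g)
                obs, y = O[key], Y[key]
                M2z = M2(Zm[g], Zc[g])
                P = Zm[g] @ Wm[m].T
                tr = M2z.reshape(len(Zm[g]), -1) @ M2w.reshape(len(M2w), -1).T
                sq = (obs * (y ** 2 - 2.0 * y * P + tr)).sum(axis=0)
                sq = np.maximum(sq, 0.0)
                sq_cache[key] = sq
                nobs = obs.sum(axis=0)
                tau[key]["shape"] = hp.e0 + 0.5 * nobs
                tau[key]["rate"] = hp.f0 + 0.5 * sq

        # ---- ELBO ----
        elbo = 0.0
        for m in view_names:
            for g in group_names:
                key = (m, g)
                et, elt = gamma_moments(tau[key]["shape"], tau[key]["rate"])
                nobs = O[key].sum(axis=0)
                elbo += float(np.sum(0.5 * nobs * (elt - _LOG2PI)
                                     - 0.5 * et * sq_cache[key]))
                # tau prior + entropy
                elbo += float(np.sum(
                    hp.e0 * np.log(hp.f0) - gammaln(hp.e0)
                    + (hp.e0 - 1.0) * elt - hp.f0 * et
                ))
                sh, ra = tau[key]["shape"], tau[key]["rate"]
                elbo += float(np.sum(sh - np.log(ra) + gammaln(sh) + (1.0 - sh) * digamma(sh)))
        for m in view_names:
            ea, ela = gamma_moments(alpha[m]["shape"], alpha[m]["rate"])
            Ew2 = Wm[m] ** 2 + np.einsum("dkk->dk", Wc[m])
            elbo += float(np.sum(0.5 * (ela[None, :] - _LOG2PI) - 0.5 * ea[None, :] * Ew2))
            sign, logdet = np.linalg.slogdet(Wc[m])
            elbo += float(np.sum(0.5 * (logdet + K * (1.0 + _LOG2PI))))
            elbo += float(np.sum(hp.a0 * np.log(hp.b0) - gammaln(hp.a0)
                                 + (hp.a0 - 1.0) * ela - hp.b0 * ea))
            sh, ra = alpha[m]["shape"], alpha[m]["rate"]
            elbo += float(np.sum(sh - np.log(ra) + gammaln(sh) + (1.0 - sh) * digamma(sh)))
        for g in group_names:
            Ez2 = Zm[g] ** 2 + np.einsum("nkk->nk", Zc[g])
            if beta_learned:
                eb, elb = gamma_moments(beta[g]["shape"], beta[g]["rate"])
                elbo += float(np.sum(hp.c0 * np.log(hp.d0) - gammaln(hp.c0)
                                     + (hp.c0 - 1.0) * elb - hp.d0 * eb))
                sh, ra = beta[g]["shape"], beta[g]["rate"]
                elbo += float(np.sum(sh - np.log(ra) + gammaln(sh) + (1.0 - sh) * digamma(sh)))
            else:
                eb, elb = np.ones(K), np.zeros(K)
            elbo += float(np.sum(0.5 * (elb[None, :] - _LOG2PI) - 0.5 * eb[None, :] * Ez2))
            sign, logdet = np.linalg.slogdet(Zc[g])
            elbo += float(np.sum(0.5 * (logdet + K * (1.0 + _LOG2PI))))
        elbo_trace.append(elbo)
        if it >= 1:
            prev = elbo_trace[-2]
            if abs(elbo - prev) < hp.tol * abs(elbo):
                break

    model = GFAModel(
        hp=hp,
        view_names=view_names,
        group_names=group_names,
        features=features,
        samples=samples,
        W=Wm, Wcov=Wc, Z=Zm, Zcov=Zc,
        alpha={m: alpha[m]["shape"] / alpha[m]["rate"] for m in view_names},
        beta={g: (beta[g]["shape"] / beta[g]["rate"]) if beta_learned else np.ones(K)
              for g in group_names},
        tau={key: tau[key]["shape"] / tau[key]["rate"] for key in tau},
        elbo_trace=np.array(elbo_trace),
        beta_learned=beta_learned,
        centers=data.centers,
        scales=data.scales,
    )
    explained_variance(model, data)
    return model


# ---------------------------------------------------------------------------
# Explained variance
# ---------------------------------------------------------------------------

def explained_variance(model: GFAModel, data: MultiViewDataset) -> pd.DataFrame:
    """Fraction of each view/group's variance recovered by each factor.

    Per (view, group, factor): ``r2 = 1 - SS(y - z_k w_k^T) / SS(y)`` over
    observed entries only; totals use the full ``Z W^T`` reconstruction.
    Raw values are reported (single-factor r2 can be negative when factors
    are correlated); the per-factor overall r2 used for ordering pools all
    views and groups.  The result is stored on the model and returned.
    """
    view_names, group_names, features, samples, Y, O = _prepare_like(model, data)
    K = model.K
    rows = []
    totals = {}
    num_all = np.zeros(K)
    den_all = 0.0
    for m in view_names:
        for g in group_names:
            key = (m, g)
            y, obs = Y[key], O[key]
            if obs.sum() == 0:
                rows.append((m, g) + tuple(np.full(K, np.nan)))
                totals[key] = np.nan
                continue
            Zg = model.Z[g]
            ss_tot = float((obs * y ** 2).sum())
            r2_k = np.empty(K)
            for k in range(K):
                recon = np.outer(Zg[:, k], model.W[m][:, k])
                res = float((obs * (y - recon) ** 2).sum())
                r2_k[k] = 1.0 - res / ss_tot if ss_tot > 0 else np.nan
                if ss_tot > 0:
                    num_all[k] += res
            full = Zg @ model.W[m].T
            res_full = float((obs * (y - full) ** 2).sum())
            totals[key] = 1.0 - res_full / ss_tot if ss_tot > 0 else np.nan
            den_all += ss_tot
            rows.append((m, g) + tuple(r2_k))
    r2 = pd.DataFrame(
        rows, columns=["view", "group"] + [f"Factor{k + 1}" for k in range(K)]
    ).set_index(["view", "group"])
    model.r2 = r2
    model.r2_total = pd.Series(totals).rename_axis(["view", "group"])
    model.factor_r2 = 1.0 - num_all / den_all if den_all > 0 else np.full(K, np.nan)
    return r2


def _prepare_like(model: GFAModel, data: MultiViewDataset):
    """Prepare arrays from data, checking consistency with the model."""
    view_names, group_names, features, samples, Y, O = _prepare(data)
    if set(view_names) != set(model.view_names) or set(group_names) != set(model.group_names):
        raise ValueError("dataset views/groups do not match the model")
    for g in group_names:
        if samples[g] != model.samples[g]:
            raise ValueError(f"sample set of group {g!r} does not match the model")
    for m in view_names:
        if features[m] != model.features[m]:
            raise ValueError(f"features of view {m!r} do not match the model")
    return model.view_names, model.group_names, features, samples, Y, O


# ---------------------------------------------------------------------------
# Post-processing and reconstruction
# ---------------------------------------------------------------------------

def postprocess_factors(model: GFAModel) -> GFAModel:
    """Deterministic presentation: order factors by decreasing overall r2
    and fix each factor's sign so the skewness of its weights is positive
    in the view where it explains most variance.  The reconstruction
    ``E[Z] E[W]^T`` is invariant; idempotent.
    """
    if model.factor_r2 is None or model.r2 is None:
        raise ValueError("run explained_variance before postprocess_factors")
    m2 = copy.deepcopy(model)
    order = np.argsort(-np.nan_to_num(m2.factor_r2), kind="stable")
    _permute_factors(m2, order)
    # sign convention per factor
    for k in range(m2.K):
        col = m2.r2[f"Factor{k + 1}"]
        per_view = col.groupby(level="view").sum()
        best = per_view.idxmax()
        if float(np.sum(m2.W[best][:, k] ** 3)) < 0:
            _flip_factor(m2, k)
    return m2


def _permute_factors(m: GFAModel, order: np.ndarray) -> None:
    for v in m.view_names:
        m.W[v] = m.W[v][:, order]
        m.Wcov[v] = m.Wcov[v][:, order][:, :, order]
        m.alpha[v] = m.alpha[v][order]
    for g in m.group_names:
        m.Z[g] = m.Z[g][:, order]
        m.Zcov[g] = m.Zcov[g][:, order][:, :, order]
        m.beta[g] = m.beta[g][order]
    if m.r2 is not None:
        cols = [f"Factor{k + 1}" for k in range(m.K)]
        m.r2 = m.r2[[cols[i] for i in order]]
        m.r2.columns = cols
    if m.factor_r2 is not None:
        m.factor_r2 = m.factor_r2[order]


def _flip_factor(m: GFAModel, k: int) -> None:
    for v in m.view_names:
        m.W[v][:, k] *= -1.0
        m.Wcov[v][:, k, :] *= -1.0
        m.Wcov[v][:, :, k] *= -1.0
    for g in m.group_names:
        m.Z[g][:, k] *= -1.0
        m.Zcov[g][:, k, :] *= -1.0
        m.Zcov[g][:, :, k] *= -1.0


def reconstruct(
    model: GFAModel, view: str, group: str, original_scale: bool = False
) -> pd.DataFrame:
    """Posterior-mean reconstruction ``E[Z^g] E[W^m]^T`` of one view/group.

    With ``original_scale`` the per-group feature scaling and centering
    recorded at assembly time are re-applied.
    """
    if view not in model.view_names:
        raise KeyError(f"unknown view {view!r}")
    if group not in model.group_names:
        raise KeyError(f"unknown group {group!r}")
    rec = model.Z[group] @ model.W[view].T
    out = pd.DataFrame(rec, index=model.samples[group], columns=model.features[view])
    if original_scale:
        if view in model.scales and not model.scales[view].empty:
            out = out * model.scales[view].loc[group]
        if view in model.centers and not model.centers[view].empty:
            out = out + model.centers[view].loc[group]
    return out
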