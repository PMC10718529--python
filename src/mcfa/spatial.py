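"""Spatial mapping of cell-type-specific factor signatures.

Scores factor signatures on spatial transcriptomics spots, masks spots
where the signature's cell type is essentially absent, and summarizes
per-slide activation as the relative activation area (active spots over
effective spots), compared across conditions with rank-sum tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .programs import FactorSignature, bh_adjust, score_signatures

__all__ = [
    "SpatialSlide",
    "AreaSummary",
    "score_spots",
    "relative_activation_area",
    "summarize_areas",
    "compare_area_by_condition",
]


@dataclass
class SpatialSlide:
    """One spatial slide: spot expression, cell-type proportions, coordinates."""

    slide_id: str
    expr: pd.DataFrame    # spot x gene, log-normalized
    props: pd.DataFrame   # spot x cell_type, fractions in [0, 1]
    coords: pd.DataFrame  # spot x (x, y)
    condition: str = ""

    def __post_init__(self) -> None:
        if not (self.expr.index.equals(self.props.index)
                and self.expr.index.equals(self.coords.index)):
            raise ValueError("spots must align across expr, props and coords")
        p = self.props.to_numpy(dtype=float)
        if np.any(p < 0) or np.any(p > 1 + 1e-9):
            raise ValueError("proportions must lie in [0, 1]")

    @property
    def spots(self) -> pd.Index:
        return self.expr.index


@dataclass
class AreaSummary:
    """Activation-area summary of one (slide, signature) pair."""

    slide_id: str
    cell_type: str
    sign: str
    effective_spots: int
    active_spots: int

    @property
    def relative_area(self) -> float:
        if self.effective_spots == 0:
            return np.nan
        return self.active_spots / self.effective_spots


def score_spots(
    slide: SpatialSlide,
    sigs: list[FactorSignature],
    prop_threshold: float = 0.1,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-normalized signature z per spot, masked by cell presence.

    The weighted-mean score is computed over the slide's measured genes;
    spots where the signature's cell type has proportion below
    ``prop_threshold`` get NaN (score undefined, not zero).  The null uses
    this slide's own gene universe.
    """
    for sig in sigs:
        if sig.cell_type not in slide.props.columns:
            raise KeyError(
                f"cell type {sig.cell_type!r} not in slide {slide.slide_id!r} proportions"
            )
    res = score_signatures(slide.expr, sigs, n_perm=n_perm, seed=seed)
    z = res.z.copy()
    for sig in sigs:
        mask = slide.props[sig.cell_type] < prop_threshold
        z.loc[mask.to_numpy(), sig.name] = np.nan
    return z


def relative_activation_area(
    z: pd.Series,
    props: pd.Series,
    score_threshold: float = 2.0,
    prop_threshold: float = 0.1,
    slide_id: str = "",
    cell_type: str = "",
    sign: str = "",
) -> AreaSummary:
    """Active fraction of a cell type's effective area in one slide.

    ``effective`` counts spots where the cell type's proportion is at
    least ``prop_threshold``; ``active`` counts effective spots whose
    normalized score is strictly greater than ``score_threshold`` (default
    2, i.e. two null standard deviations; spots at exactly the threshold
    count as inactive).
    """
    eff = props >= prop_threshold
    effective = int(eff.sum())
    active = int(((z > score_threshold) & eff & z.notna()).sum())
    return AreaSummary(slide_id, cell_type, sign, effective, active)


def summarize_areas(
    slides: list[SpatialSlide],
    sigs: list[FactorSignature],
    prop_threshold: float = 0.1,
    score_threshold: float = 2.0,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative activation areas for every (slide, signature) pair."""
    rows = []
    for slide in slides:
        z = score_spots(slide, sigs, prop_threshold=prop_threshold,
                        n_perm=n_perm, seed=seed)
        for sig in sigs:
            a = relative_activation_area(
                z[sig.name], slide.props[sig.cell_type],
                score_threshold=score_threshold, prop_threshold=prop_threshold,
                slide_id=slide.slide_id, cell_type=sig.cell_type, sign=sig.sign,
            )
            rows.append({
                "slide_id": a.slide_id, "cell_type": a.cell_type, "sign": a.sign,
                "condition": slide.condition,
                "effective_spots": a.effective_spots, "active_spots": a.active_spots,
                "relative_area": a.relative_area,
            })
    return pd.DataFrame(rows)


def compare_area_by_condition(
    areas: pd.DataFrame, conditions: dict[str, str] | None = None
) -> pd.DataFrame:
    """Two-sided rank-sum tests of slide-level relative areas by condition.

    ``areas`` is the output of :func:`summarize_areas`; ``conditions``
    optionally overrides the slide -> condition mapping.  For every
    condition pair, each (cell_type, sign) is tested and BH-adjusted within
    that pair.  Conditions with fewer than 2 slides are skipped.
    """
    df = areas.copy()
    if conditions is not None:
        df["condition"] = df["slide_id"].map(conditions)
    conds = sorted(df["condition"].dropna().unique())
    rows = []
    for i, c1 in enumerate(conds):
        for c2 in conds[i + 1:]:
            pair_rows = []
            for (ct, sign), sub in df.groupby(["cell_type", "sign"]):
                a = sub.loc[sub["condition"] == c1, "relative_area"].dropna()
                b = sub.loc[sub["condition"] == c2, "relative_area"].dropna()
                if len(a) < 2 or len(b) < 2:
                    warnings.warn(
                        f"{ct}/{sign}: fewer than 2 slides in a condition; skipped"
                    )
                    continue
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
                pair_rows.append({
                    "cell_type": ct, "sign": sign,
                    "condition_a": c1, "condition_b": c2,
                    "statistic": float(stat), "pval": float(p),
                })
            if pair_rows:
                sub = pd.DataFrame(pair_rows)
                sub["padj"] = bh_adjust(sub["pval"])
                rows.append(sub)
    if not rows:
        return pd.DataFrame(columns=["cell_type", "sign", "condition_a",
                                     "condition_b", "statistic", "pval", "padj"])
    return pd.concat(rows, ignore_index=True)
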