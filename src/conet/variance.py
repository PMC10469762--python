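"""Attributing network-ensemble variance to workflow-step choices.

Given W networks produced by different combinations of workflow choices
(e.g. denoising tool, taxonomy database, filtering level, inference
method), the flattened edge-weight matrix is reduced by PCA — networks as
observations over edge features — and each retained component is modeled
as an additive linear function of the categorical workflow factors.
ANOVA sums of squares per factor, aggregated across components with each
component weighted by its explained-variance share, give the percentage
of network variance attributable to every workflow step; the remainder is
reported as residual.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

from .network import NetworkStack

__all__ = ["DesignTable", "VarianceReport", "variance_decomposition"]


class DesignTable:
    """Categorical workflow-step levels for each network in an ensemble.

    One row per network (aligned with the stack order), one column per
    factor (e.g. DC, CC, TA, OP, NI), cells holding level labels.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        frame = frame.astype(str)
        if frame.shape[0] < 2:
            raise ValueError("a design needs at least 2 networks")
        if frame.shape[1] < 1:
            raise ValueError("a design needs at least 1 factor")
        if frame.isna().any().any():
            raise ValueError("design has missing cells")
        self.frame = frame

    @classmethod
    def from_tsv(cls, path) -> "DesignTable":
        """First column network name/index, remaining columns factors."""
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    @property
    def factors(self) -> list[str]:
        return list(self.frame.columns)

    def factor_df(self, factor: str) -> int:
        return self.frame[factor].nunique() - 1


@dataclass
class VarianceReport:
    """Per-factor variance percentages; factors + residual sum to 100."""

    factor_percent: dict[str, float]
    residual_percent: float
    n_components_used: int
    component_variance_explained: float

    def as_dict(self) -> dict:
        out = dict(self.factor_percent)
        out["residual"] = self.residual_percent
        return out


def _check_aliasing(design: DesignTable) -> None:
    """Reject designs where two factors are confounded (aliased)."""
    from itertools import combinations

    frame = design.frame
    for fa, fb in combinations(frame.columns, 2):
        tab = pd.crosstab(frame[fa], frame[fb])
        # aliased iff the level of one determines the level of the other
        if ((tab > 0).sum(axis=1) == 1).all() and ((tab > 0).sum(axis=0) == 1).all():
            if frame[fa].nunique() > 1 and frame[fb].nunique() > 1:
                raise ValueError(
                    f"design factors {fa!r} and {fb!r} are aliased "
                    "(their levels are perfectly confounded)"
                )


def variance_decomposition(
    stack: NetworkStack,
    design: DesignTable,
    variance_explained_target: float = 0.95,
    ss_type: int = 2,
) -> VarianceReport:
    """PCA + per-component ANOVA attribution of ensemble variance.

    Components are retained up to the smallest number whose cumulative
    explained variance reaches ``variance_explained_target``.  Each
    component score vector is regressed on all design factors additively;
    per-factor ANOVA sums of squares (Type II by default, robust to
    imbalance; ``ss_type=1`` for sequential) are converted to fractions of
    that component's total sum of squares and averaged across components
    with explained-variance weights.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from sklearn.decomposition import PCA

    if not 0 < variance_explained_target <= 1:
        raise ValueError("variance_explained_target must be in (0, 1]")
    w = stack.w
    if design.frame.shape[0] != w:
        raise ValueError(
            f"design has {design.frame.shape[0]} rows but the stack holds {w} networks"
        )
    n_levels = sum(design.frame[f].nunique() for f in design.factors)
    model_df = 1 + sum(design.factor_df(f) for f in design.factors)
    if w <= model_df:
        raise ValueError(
            f"model not identifiable: {w} networks for {model_df} parameters"
        )
    _check_aliasing(design)

    x = stack.flattened.T  # W x q^2, networks as observations
    pca = PCA(n_components=min(w - 1, x.shape[1]))
    scores = pca.fit_transform(x)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    c = int(np.searchsorted(cum, variance_explained_target - 1e-12) + 1)
    c = min(c, scores.shape[1])
    if c == 0 or ratios[:c].sum() <= 0:
        raise ValueError("no principal components with nonzero variance")

    factors = design.factors
    active = [f for f in factors if design.frame[f].nunique() > 1]
    df = design.frame.reset_index(drop=True).copy()
    frac = {f: np.zeros(c) for f in factors}
    resid_frac = np.zeros(c)
    for j in range(c):
        df["_score"] = scores[:, j]
        formula = "_score ~ " + " + ".join(f"C(Q('{f}'))" for f in active)
        fit = smf.ols(formula, data=df).fit()
        anova = sm.stats.anova_lm(fit, typ=ss_type)
        ss = anova["sum_sq"]
        total = float(ss.sum())
        if total <= 0:
            continue
        for f in active:
            key = f"C(Q('{f}'))"
            frac[f][j] = float(ss.get(key, 0.0)) / total
        resid_frac[j] = float(ss.get("Residual", 0.0)) / total

    weights = ratios[:c] / ratios[:c].sum()
    factor_percent = {
        f: float(100.0 * np.dot(weights, frac[f])) for f in factors
    }
    residual = 100.0 - sum(factor_percent.values())
    return VarianceReport(
        factor_percent=factor_percent,
        residual_percent=float(residual),
        n_components_used=c,
        component_variance_explained=float(ratios[:c].sum()),
    )
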