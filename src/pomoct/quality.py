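"""PCA-weighted composite fruit-quality index and radar-chart data.

Quality traits (diameter, weight, firmness, sugar, color, seed traits,
porosity, cell/pore diameter, ...) are Z-scored, a PCA of the correlation
structure yields per-trait loadings, and loading magnitudes weighted by
explained variance over the first k components give nonnegative weights
``w_i`` summing to 1. The composite index per sample is

    Q = Σ_i  w_i · z_i

Traits are grouped by which of the first two components dominates their
loading (A: PC1-dominated, C: PC2-dominated, B: balanced), and radar-chart
axes are ordered by group with min–max scaled per-treatment means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class QualityTable:
    """Samples × traits matrix with treatment labels and optional units."""

    params: pd.DataFrame             # numeric traits, index = sample ids
    treatments: pd.DataFrame         # categorical labels, same index
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.params.shape[0] < 2 or self.params.shape[1] < 2:
            raise ValueError("need >= 2 samples and >= 2 parameters")
        if self.params.isna().any().any():
            n_before = len(self.params)
            keep = ~self.params.isna().any(axis=1)
            self.params = self.params.loc[keep]
            self.treatments = self.treatments.loc[keep]
            import logging
            logging.getLogger(__name__).warning(
                "dropped %d rows with missing cells", n_before - len(self.params))
            if len(self.params) < 2:
                raise ValueError("fewer than 2 complete samples remain")


def zscore(
    table: QualityTable | pd.DataFrame,
    ddof_mode: Literal["population", "sample"] = "population",
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-wise Z-score transform ``z = (x − μ) / σ``.

    ``population`` mode (default) uses the population standard deviation
    (ddof=0); ``sample`` uses ddof=1. Returns (z, μ, σ).
    """
    df = table.params if isinstance(table, QualityTable) else table
    ddof = 0 if ddof_mode == "population" else 1
    mu = df.mean()
    sigma = df.std(ddof=ddof)
    if (sigma == 0).any():
        bad = list(sigma.index[sigma == 0])
        raise ValueError(f"zero variance column(s): {bad}")
    return (df - mu) / sigma, mu, sigma


@dataclass
class PCAResult:
    """Loadings are trait–component correlations (entries in [−1, 1])."""

    loadings: pd.DataFrame           # traits × components
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame             # samples × components


def pca(z: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of a standardized matrix with a fixed sign convention.

    Loadings are reported as eigenvector × √eigenvalue (the correlation of
    each trait with each component score for Z-scored input). Each
    component's sign is fixed so its largest-magnitude loading is positive.
    Variance fractions sum to 1 over all retained components.
    """
    X = np.asarray(z, dtype=np.float64)
    if np.allclose(X, 0):
        raise ValueError("degenerate: rank-0 matrix")
    k = n_components or min(X.shape)
    model = PCA(n_components=k)
    scores = model.fit_transform(X)
    evr = model.explained_variance_ratio_
    # correlation-style loadings: eigvec scaled by component SD / trait SD (=1)
    comp_sd = np.sqrt(model.explained_variance_)
    loadings = model.components_.T * comp_sd[None, :]
    trait_sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        loadings = np.where(trait_sd[:, None] > 0, loadings / trait_sd[:, None], 0.0)
    for j in range(loadings.shape[1]):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=z.columns, columns=cols),
        explained_variance_ratio=evr,
        scores=pd.DataFrame(scores, index=z.index, columns=cols),
    )


@dataclass
class QualityWeights:
    weights: pd.Series               # per trait, >= 0, sums to 1
    components_used: int
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        w = self.weights
        if (w < 0).any() or abs(float(w.sum()) - 1.0) > 1e-12:
            raise ValueError("weights must be nonnegative and sum to 1")


def derive_weights(
    pca_result: PCAResult,
    k: int = 2,
    strategy: Literal["loading_x_variance", "pc1_only"] = "loading_x_variance",
) -> QualityWeights:
    """Trait weights from PCA loading magnitudes.

    Default: ``w_i ∝ Σ_{j ≤ k} |loading_ij| · varfrac_j`` (traits loading
    strongly on high-variance components weigh more). ``pc1_only`` uses
    |PC1 loadings| alone. Weights are normalized to sum to 1.
    """
    L = pca_result.loadings
    if k > L.shape[1]:
        raise ValueError("k exceeds number of components")
    if strategy == "pc1_only":
        raw = L.iloc[:, 0].abs()
    elif strategy == "loading_x_variance":
        vf = pca_result.explained_variance_ratio[:k]
        raw = (L.iloc[:, :k].abs() * vf[None, :]).sum(axis=1)
    else:
        raise ValueError(f"unknown strategy: {strategy!r}")
    total = float(raw.sum())
    if total == 0:
        raise ValueError("degenerate weights: all loadings zero")
    return QualityWeights(raw / total, k, pca_result.explained_variance_ratio[:k])


@dataclass
class QualityScore:
    q: pd.Series                     # composite index per sample
    z: pd.DataFrame


def quality_score(z: pd.DataFrame, weights: QualityWeights) -> QualityScore:
    """Composite index ``Q = Σ w_i z_i`` per sample."""
    w = weights.weights
    if set(w.index) != set(z.columns):
        raise ValueError("weight/parameter mismatch")
    q = (z[w.index] * w).sum(axis=1)
    return QualityScore(q, z)


def assign_groups(
    pca_result: PCAResult,
    dominance_margin: float = 0.35,
) -> dict[str, str]:
    """Map each trait to radar group A, B or C from its first two loadings.

    A trait is A if |PC1 loading| exceeds |PC2 loading| by more than the
    dominance margin, C if the reverse, otherwise B (balanced loadings).
    The default margin is deliberately generous — roughly twice the loading
    standard error at moderate sample sizes — so that a balanced trait is
    not pushed into A or C by sampling noise.
    """
    L = pca_result.loadings
    if L.shape[1] < 2:
        raise ValueError("need at least two components for grouping")
    out: dict[str, str] = {}
    for trait in L.index:
        l1, l2 = abs(L.loc[trait, "PC1"]), abs(L.loc[trait, "PC2"])
        if l1 - l2 > dominance_margin:
            out[trait] = "A"
        elif l2 - l1 > dominance_margin:
            out[trait] = "C"
        else:
            out[trait] = "B"
    return out


@dataclass
class RadarData:
    values: pd.DataFrame             # levels × traits, min-max scaled to [0,1]
    axis_order: list[str]            # group A block, then B, then C
    degenerate_axes: list[str]       # traits whose level means were all equal


def radar_export(
    table: QualityTable,
    groups: dict[str, str],
    treatment_factor: str,
) -> RadarData:
    """Per-treatment-level trait means, min–max scaled across levels.

    Axes are ordered group A, then B, then C (alphabetical within each
    block). A trait whose means are identical across levels scales to 0 on
    every level and is flagged as degenerate.
    """
    if treatment_factor not in table.treatments.columns:
        raise KeyError(f"unknown treatment factor: {treatment_factor!r}")
    levels = table.treatments[treatment_factor]
    if levels.nunique() < 2:
        raise ValueError("nothing to compare: single treatment level")
    means = table.params.groupby(levels, observed=True).mean()
    lo, hi = means.min(), means.max()
    span = hi - lo
    degenerate = list(span.index[span == 0])
    scaled = (means - lo).div(span.replace(0, np.nan)).fillna(0.0)
    order = sorted(table.params.columns,
                   key=lambda t: (groups.get(t, "B"), t))
    return RadarData(scaled[order], order, degenerate)


def radar_plot(radar: RadarData, ax=None, **line_kw):
    """Minimal polar plot of radar data (requires matplotlib)."""
    import matplotlib.pyplot as plt

    n = len(radar.axis_order)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for level, row in radar.values.iterrows():
        vals = row[radar.axis_order].to_numpy()
        ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]],
                label=str(level), **line_kw)
    ax.set_xticks(angles)
    ax.set_xticklabels(radar.axis_order, fontsize=7)
    ax.legend(fontsize=7, loc="upper right", bbox_to_anchor=(1.3, 1.1))
    return ax
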