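"""Statistical workflow for grouped metabolomic tables.

Mirrors the conventional metabolomics screen: per-metabolite one-way ANOVA
with Benjamini–Hochberg FDR control and Fisher's protected LSD post hoc,
PCA for unsupervised structure, PLS-DA with VIP feature ranking, Spearman
correlation profiles against a reference metabolite, and hierarchical
clustering on one-minus-Pearson distance for heatmap ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .enrichment_metrics import SampleTable

__all__ = [
    "UnivariateResult",
    "ProjectionResult",
    "VIPResult",
    "CorrelationProfile",
    "anova_fdr_lsd",
    "pca_scores",
    "plsda_vip",
    "spearman_profile",
    "cluster_order",
]


@dataclass(frozen=True)
class UnivariateResult:
    metabolite: str
    f_statistic: float
    p_value: float
    q_value: float
    degenerate: bool = False
    # (group_a, group_b) -> significant by LSD at alpha; empty unless omnibus q <= alpha
    lsd_pairs: tuple[tuple[str, str, bool], ...] = ()


@dataclass(frozen=True)
class ProjectionResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: tuple[float, ...]


@dataclass(frozen=True)
class VIPResult:
    scores: pd.Series
    n_components: int

    def top(self, k: int) -> pd.Series:
        return self.scores.sort_values(ascending=False).head(k)


@dataclass(frozen=True)
class CorrelationProfile:
    reference: str
    rho: pd.Series
    p_value: pd.Series


def _autoscale(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def anova_fdr_lsd(
    table: SampleTable, alpha: float = 0.05, log_transform: bool = True
) -> list[UnivariateResult]:
    """Per-metabolite one-way ANOVA with BH adjustment and protected LSD.

    Pools are log2-transformed by default (the conventional scale for pool
    intensities). Pairwise Fisher LSD comparisons use the pooled within-group
    mean square and are reported only for metabolites whose omnibus q-value
    passes ``alpha`` (the protected-LSD convention). Metabolites with
    degenerate variance (all values identical) are flagged with p = 1.
    """
    values = table.log2_pools() if log_transform else table.pools
    groups = table.groups
    names = sorted(groups.unique())
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for g in names:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    split = {g: values.loc[groups[groups == g].index] for g in names}

    f_stats, p_vals, degenerate = {}, {}, {}
    for met in values.columns:
        samples = [split[g][met].to_numpy() for g in names]
        pooled = np.concatenate(samples)
        if np.allclose(pooled, pooled[0]):
            f_stats[met], p_vals[met], degenerate[met] = 0.0, 1.0, True
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = sps.f_oneway(*samples)
        if not np.isfinite(p):
            f, p, degenerate[met] = 0.0, 1.0, True
        else:
            degenerate[met] = False
        f_stats[met], p_vals[met] = float(f), float(p)

    mets = list(values.columns)
    _, q_vals, _, _ = multipletests([p_vals[m] for m in mets], method="fdr_bh")
    q = dict(zip(mets, q_vals))

    n_total = len(values)
    k = len(names)
    df_within = n_total - k
    results = []
    for met in mets:
        pairs: list[tuple[str, str, bool]] = []
        if q[met] <= alpha and not degenerate[met]:
            samples = {g: split[g][met].to_numpy() for g in names}
            mse = sum(((s - s.mean()) ** 2).sum() for s in samples.values()) / df_within
            for a, b in combinations(names, 2):
                na, nb = samples[a].size, samples[b].size
                se = np.sqrt(mse * (1 / na + 1 / nb))
                if se == 0:
                    pairs.append((a, b, False))
                    continue
                t = (samples[a].mean() - samples[b].mean()) / se
                p_pair = 2 * sps.t.sf(abs(t), df_within)
                pairs.append((a, b, bool(p_pair <= alpha)))
        results.append(
            UnivariateResult(
                met, f_stats[met], p_vals[met], float(q[met]), degenerate[met], tuple(pairs)
            )
        )
    return results


def pca_scores(table: SampleTable, scale: bool = True, n_components: int | None = None) -> ProjectionResult:
    """Centered (optionally autoscaled) PCA of pool sizes.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making score plots deterministic.
    """
    x = table.log2_pools().to_numpy()
    if np.allclose(x, x[0]):
        raise ValueError("constant matrix: PCA undefined")
    if scale:
        x = _autoscale(x)
    else:
        x = x - x.mean(axis=0)
    n_comp = n_components or min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(x)
    loadings = pca.components_.T.copy()
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return ProjectionResult(
        pd.DataFrame(scores, index=table.pools.index, columns=cols),
        pd.DataFrame(loadings, index=table.pools.columns, columns=cols),
        tuple(float(v) for v in pca.explained_variance_ratio_),
    )


def _vip(pls: PLSRegression, x: np.ndarray) -> np.ndarray:
    """Variable importance in projection from a fitted PLS model.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ), where
    SSY_a is the response sum of squares explained by component a. The mean of
    squared VIPs is 1 by construction.
    """
    t = pls.x_scores_
    w = pls.x_weights_
    q = pls.y_loadings_
    p, a = w.shape
    ssy = np.array([(t[:, i] ** 2).sum() * (q[:, i] ** 2).sum() for i in range(a)])
    wnorm = w / np.linalg.norm(w, axis=0, keepdims=True)
    return np.sqrt(p * (wnorm ** 2 @ ssy) / ssy.sum())


def plsda_vip(
    table: SampleTable,
    n_components: int = 2,
    scale: bool = True,
) -> tuple[VIPResult, ProjectionResult]:
    """PLS-DA on a class-indicator response plus VIP feature ranking.

    Classes come from the sample groups; the response is the one-hot class
    matrix (a single column for two classes). The NIPALS fit is deterministic,
    so rankings are reproducible without a seed.
    """
    classes = sorted(table.groups.unique())
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    x = table.log2_pools().to_numpy()
    x = _autoscale(x) if scale else x - x.mean(axis=0)
    if len(classes) == 2:
        y = (table.groups == classes[1]).to_numpy(dtype=float)[:, None]
    else:
        y = np.stack([(table.groups == c).to_numpy(dtype=float) for c in classes], axis=1)
    y = y - y.mean(axis=0)
    n_comp = min(n_components, x.shape[0] - 1, x.shape[1])
    pls = PLSRegression(n_components=n_comp, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(x, y)
    vip = pd.Series(_vip(pls, x), index=table.pools.columns, name="VIP")
    total_ss = (x ** 2).sum()
    expl = []
    for i in range(n_comp):
        recon = np.outer(pls.x_scores_[:, i], pls.x_loadings_[:, i])
        expl.append(float((recon ** 2).sum() / total_ss))
    cols = [f"LV{i + 1}" for i in range(n_comp)]
    proj = ProjectionResult(
        pd.DataFrame(pls.x_scores_, index=table.pools.index, columns=cols),
        pd.DataFrame(pls.x_loadings_, index=table.pools.columns, columns=cols),
        tuple(expl),
    )
    return VIPResult(vip, n_comp), proj


def spearman_profile(table: SampleTable, reference: str) -> CorrelationProfile:
    """Spearman rho (and p) of every metabolite against a reference pool."""
    if reference not in table.pools.columns:
        raise KeyError(f"reference metabolite {reference!r} not in table")
    ref = table.pools[reference].to_numpy()
    if np.allclose(ref, ref[0]):
        raise ValueError("constant reference metabolite: correlation undefined")
    rho, pv = {}, {}
    for met in table.pools.columns:
        x = table.pools[met].to_numpy()
        if np.allclose(x, x[0]):
            rho[met], pv[met] = np.nan, np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = sps.spearmanr(ref, x)
        rho[met], pv[met] = float(r), float(p)
    return CorrelationProfile(
        reference, pd.Series(rho, name="rho"), pd.Series(pv, name="p")
    )


def cluster_order(
    data: pd.DataFrame, axis: str = "rows"
) -> tuple[list[str], np.ndarray]:
    """Hierarchical clustering on one-minus-Pearson distance, average linkage.

    Returns (leaf order as labels, linkage matrix). Items are pre-sorted by id
    so ties break deterministically; zero-variance items are assigned distance
    1 to everything (uncorrelated) with a warning.
    """
    mat = data if axis == "rows" else data.T
    mat = mat.sort_index()
    labels = list(mat.index)
    if len(labels) < 2:
        raise ValueError("need at least two items to cluster")
    x = mat.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"zero-variance items treated as uncorrelated: "
            f"{[labels[i] for i in np.where(flat)[0]]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    condensed = dist[np.triu_indices(len(labels), k=1)]
    link = hierarchy.linkage(condensed, method="average")
    order = hierarchy.leaves_list(link)
    return [labels[i] for i in order], link
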