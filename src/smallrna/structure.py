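"""Sample structure exploration: embeddings, correlation, clustering, PVCA.

PVCA (principal variance component analysis) decomposes expression variance
into per-annotation-variable proportions: PCA is run on the standardized
expression matrix, the leading components covering a cumulative variance
threshold are retained, a variance-components mixed model (random effect per
annotation variable and per pairwise interaction, plus residual) is fitted to
each retained component, and the per-term variance fractions are averaged
across components weighted by their eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats as sps
from sklearn.decomposition import PCA

from .stats import GroupDesign, NormalizedMatrix


@dataclass
class Embedding2D:
    sample_ids: list[str]
    coords: np.ndarray  # n x 2
    method: str
    explained_variance: tuple[float, float] | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=self.sample_ids, columns=["dim1", "dim2"])


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix
    leaf_ids: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.leaf_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.leaf_ids[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


@dataclass
class VarianceDecomposition:
    terms: list[tuple[str, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.terms, columns=["term", "proportion"]).set_index("term")

    def proportion(self, term: str) -> float:
        return dict(self.terms)[term]


def pca_embed(norm: NormalizedMatrix) -> Embedding2D:
    """Project samples onto the top two principal components.

    Deterministic up to sign; the sign of each component is fixed by making
    its largest-magnitude loading positive.
    """
    X = norm.values.T  # samples x features
    if X.shape[0] < 3:
        raise ValueError("PCA embedding needs at least 3 samples")
    if np.allclose(np.var(X, axis=0), 0):
        raise ValueError("expression matrix is constant; PCA undefined")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(2):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    ev = pca.explained_variance_ratio_
    return Embedding2D(list(norm.sample_ids), coords, "pca", (float(ev[0]), float(ev[1])))


def umap_embed(norm: NormalizedMatrix, n_neighbors: int = 15, min_dist: float = 0.1,
               seed: int = 42) -> Embedding2D:
    """2-D UMAP embedding; falls back to PCA when samples are too few."""
    n = len(norm.sample_ids)
    if n < n_neighbors + 1:
        warnings.warn(f"{n} samples < n_neighbors+1 ({n_neighbors + 1}); falling back to PCA")
        emb = pca_embed(norm)
        return Embedding2D(emb.sample_ids, emb.coords, "pca", emb.explained_variance, seed)
    import umap

    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
                        random_state=seed, init="spectral")
    coords = reducer.fit_transform(norm.values.T)
    return Embedding2D(list(norm.sample_ids), np.asarray(coords, dtype=float), "umap", None, seed)


def sample_correlation(rpm_matrix: np.ndarray, sample_ids: list[str]) -> pd.DataFrame:
    """Spearman correlation between samples' feature vectors (ties mid-ranked).

    Constant samples have undefined rank correlation; their entries are NaN
    except the diagonal.
    """
    n = len(sample_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n == 2:
            rho = sps.spearmanr(rpm_matrix[:, 0], rpm_matrix[:, 1]).statistic
            mat = np.array([[1.0, rho], [rho, 1.0]])
        else:
            mat = sps.spearmanr(rpm_matrix).statistic
    mat = np.asarray(mat, dtype=float)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=sample_ids, columns=sample_ids)


def hierarchical_cluster(dist_matrix: np.ndarray, ids: list[str]) -> Dendrogram:
    """Complete-linkage agglomeration of a symmetric distance matrix."""
    condensed = squareform(np.asarray(dist_matrix, dtype=float), checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(Z, list(ids))


def cluster_samples_by_correlation(norm: NormalizedMatrix) -> Dendrogram:
    """Sample clustering: Euclidean distance between the rows of the sample
    Spearman-correlation matrix, agglomerated with complete linkage."""
    corr = sample_correlation(norm.rpm, norm.sample_ids).to_numpy()
    n = corr.shape[0]
    dist = np.sqrt(((corr[:, None, :] - corr[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(dist, 0.0)
    return hierarchical_cluster(dist, norm.sample_ids)


def top_variance_subset(norm: NormalizedMatrix, k: int) -> NormalizedMatrix:
    """The k features of largest sample variance (ties by feature id order)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    nfeat = len(norm.feature_ids)
    if k > nfeat:
        warnings.warn(f"k={k} exceeds feature count {nfeat}; returning all features")
        k = nfeat
    var = np.var(norm.values, axis=1, ddof=1) if norm.values.shape[1] > 1 else np.zeros(nfeat)
    order = sorted(range(nfeat), key=lambda i: (-var[i], norm.feature_ids[i]))
    sel = sorted(order[:k])
    return NormalizedMatrix([norm.feature_ids[i] for i in sel], list(norm.sample_ids),
                            norm.values[sel], norm.depth_per_sample, norm.rna_class)


# ---------------------------------------------------------------------------
# PVCA

def _vc_fit_reml(pc_scores: np.ndarray, factors: pd.DataFrame) -> dict[str, float] | None:
    """REML variance components for one principal component via MixedLM."""
    import statsmodels.api as sm

    df = factors.copy()
    df["_y"] = pc_scores
    df["_g"] = 1  # single trivial group: all random effects are crossed VCs
    vc_formula = {col: f"0 + C({col})" for col in factors.columns}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula("_y ~ 1", groups="_g",
                                            vc_formula=vc_formula, re_formula="0", data=df)
            fit = model.fit(reml=True, method="lbfgs", maxiter=200, disp=False)
        if not np.all(np.isfinite(fit.params)):
            return None
        comps = {col: max(float(fit.vcomp[i]), 0.0) for i, col in enumerate(model.exog_vc.names)}
        comps["residual"] = max(float(fit.scale), 0.0)
        return comps
    except Exception:
        return None


def _vc_fit_moments(pc_scores: np.ndarray, factors: pd.DataFrame) -> dict[str, float]:
    """Method-of-moments fallback: per-term between-level variance of level
    means (capped below at zero), residual = within-cell variance."""
    y = pc_scores - pc_scores.mean()
    total = float(np.var(y)) or 1.0
    comps = {}
    explained = 0.0
    for col in factors.columns:
        means = pd.Series(y).groupby(factors[col].to_numpy()).mean()
        sizes = pd.Series(y).groupby(factors[col].to_numpy()).size()
        between = float(np.average((means - y.mean()) ** 2, weights=sizes))
        comps[col] = max(between, 0.0)
        explained = max(explained, between)
    comps["residual"] = max(total - explained, total * 0.05)
    return comps


def pvca(norm: NormalizedMatrix, annotations: list[GroupDesign],
         pc_variance_threshold: float = 0.6,
         standardize: bool = True) -> VarianceDecomposition:
    """Principal variance component analysis.

    Returns the eigenvalue-weighted, normalized proportions of expression
    variance attributable to each annotation variable, each pairwise
    interaction, and the residual.
    """
    X = norm.values.T.astype(float)  # samples x features
    n = X.shape[0]
    # internal column names are formula-safe; display names keep the user's
    factors = pd.DataFrame(index=norm.sample_ids)
    display_names: dict[str, str] = {}
    internal = {}
    for i, design in enumerate(annotations):
        col = f"v{i}"
        internal[design.variable_name] = col
        factors[col] = [design.assignment[s] for s in norm.sample_ids]
        display_names[col] = design.variable_name
    for a, b in combinations([d.variable_name for d in annotations], 2):
        col = f"{internal[a]}_x_{internal[b]}"
        factors[col] = factors[internal[a]].astype(str) + "/" + factors[internal[b]].astype(str)
        display_names[col] = f"{a}:{b}"

    X = X - X.mean(axis=0, keepdims=True)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd

    n_comp = min(n - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    n_keep = int(np.searchsorted(cum, pc_variance_threshold) + 1)
    n_keep = min(n_keep, n_comp)

    term_names = list(factors.columns) + ["residual"]
    weighted = {t: 0.0 for t in term_names}
    weight_sum = 0.0
    for i in range(n_keep):
        comps = _vc_fit_reml(scores[:, i], factors)
        if comps is None:
            comps = _vc_fit_moments(scores[:, i], factors)
        total = sum(comps.values())
        if total <= 0:
            comps = {t: (1.0 if t == "residual" else 0.0) for t in term_names}
            total = 1.0
        w = float(evr[i])
        for t in term_names:
            weighted[t] += w * comps.get(t, 0.0) / total
        weight_sum += w

    props = {t: v / weight_sum for t, v in weighted.items()}
    norm_sum = sum(props.values())
    display_names["residual"] = "residual"
    terms = [(display_names.get(t, t), props[t] / norm_sum) for t in term_names]
    return VarianceDecomposition(terms)
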