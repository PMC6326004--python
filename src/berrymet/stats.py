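"""Multivariate and univariate statistics for the designed experiment.

Implements the combined inference scheme used on the quality-assured
peak-ratio matrix:

* conventional PCA (unit-variance scaled) with total-explained-variance
  percentages and a deterministic loading sign convention;
* per-feature Friedman tests (tie-corrected, chi-square approximation)
  with Benjamini-Hochberg FDR control at 5%;
* a multiblock hierarchical (consensus) PCA whose block structure removes
  the temperature main effect so that patterns shared across temperature
  groups — the day-length response — surface in the super loadings;
* selection of features that are both FDR-significant and prominent in
  the relevant loadings, and classification of their temperature trends.

The Friedman treatment/block construction for the temperature factor uses
replicate blocks with cell values averaged over photoperiods, and ambient
as a fourth treatment level; for the day-length factor the blocks are the
temperature x replicate cells and ambient is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA as _SkPCA

ALPHA = 0.05
PROMINENCE_PCT = 60.0
AMBIENT_FACTOR = 1.5

CONTROLLED_TEMPS = ("12", "18", "24")


# ---------------------------------------------------------------------------
# univariate machinery
# ---------------------------------------------------------------------------


def friedman_from_table(table: np.ndarray) -> tuple[float, int, float]:
    """Tie-corrected Friedman statistic from a blocks x treatments table.

    Within-block mid-ranks; Q = [12/(n k (k+1))] * sum R_j^2 - 3 n (k+1),
    divided by the tie-correction factor 1 - sum(t^3 - t)/(n k (k^2 - 1));
    p from the chi-square upper tail with k - 1 degrees of freedom.
    """
    table = np.asarray(table, float)
    n, k = table.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 treatments and 2 blocks")
    ranks = sps.rankdata(table, axis=1)
    rank_sums = ranks.sum(axis=0)
    q_raw = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    tie_sum = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    df = k - 1
    if correction <= 0:  # every block fully tied
        return 0.0, df, 1.0
    q = q_raw / correction
    if q <= 0:
        return 0.0, df, 1.0
    return float(q), df, float(sps.chi2.sf(q, df))


def friedman_test(values, treatments, blocks) -> tuple[float, int, float]:
    """Friedman test from long-form (value, treatment, block) triples.

    Every (block, treatment) cell must hold exactly one value; average
    replicates upstream.
    """
    df = pd.DataFrame({"value": values, "treatment": treatments, "block": blocks})
    counts = df.groupby(["block", "treatment"]).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index.tolist()
        raise ValueError(f"cells must hold exactly one value; offending cells: {bad}")
    table = df.pivot(index="block", columns="treatment", values="value")
    if table.isna().any().any():
        raise ValueError("incomplete block design: missing cells")
    return friedman_from_table(table.to_numpy())


def bh_fdr(pvalues, alpha: float = ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and rejection flags.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; reject iff q < alpha.
    """
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q < alpha


def correlate_methods(x, y) -> tuple[float, float]:
    """Pearson correlation between two paired measurement vectors.

    Used to compare untargeted peak-response ratios against targeted
    concentrations of the same compounds.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def _scale_matrix(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-centred, optionally scaled copy; returns (Xs, means, scales)."""
    means = X.mean(axis=0)
    if scaling == "uv":
        scales = X.std(axis=0, ddof=1)
    elif scaling == "pareto":
        scales = np.sqrt(X.std(axis=0, ddof=1))
    elif scaling == "none":
        scales = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return (X - means) / scales, means, scales


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make the largest-|loading| element of each component positive."""
    for j in range(loadings.shape[1]):
        idx = np.argmax(np.abs(loadings[:, j]))
        if loadings[idx, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return loadings, scores


class PeakRatioPCA(BaseEstimator):
    """PCA of a complete (imputed) samples x features ratio matrix.

    Columns are mean-centred and unit-variance scaled by default; the
    decomposition runs on singular values and TEV_i is the percentage of
    total variance explained by component i.  Zero-variance columns are
    dropped with a warning under uv scaling.  Loading signs follow the
    largest-|element|-positive convention so results are reproducible
    across linear-algebra backends.

    Attributes (after fit): ``scores_``, ``loadings_``, ``tev_``,
    ``means_``, ``scales_``, ``dropped_features_``.
    """

    def __init__(self, n_components: int = 5, scaling: str = "uv"):
        self.n_components = n_components
        self.scaling = scaling

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ValueError("PCA requires a complete (imputed) matrix")
        variances = X.std(axis=0, ddof=1)
        self.dropped_features_ = list(X.columns[variances == 0]) if self.scaling == "uv" else []
        if self.dropped_features_:
            import warnings

            warnings.warn(
                f"dropping {len(self.dropped_features_)} zero-variance feature(s) under uv scaling",
                stacklevel=2,
            )
            X = X.drop(columns=self.dropped_features_)
        # centring consumes one sample degree of freedom
        k = min(self.n_components, X.shape[1], max(X.shape[0] - 1, 1))
        Xs, means, scales = _scale_matrix(X.to_numpy(float), self.scaling)
        pca = _SkPCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(Xs)
        loadings = pca.components_.T.copy()
        loadings, scores = _fix_signs(loadings, scores)
        comp = [f"PC{i + 1}" for i in range(k)]
        self.feature_names_ = list(X.columns)
        self.means_ = pd.Series(means, index=X.columns)
        self.scales_ = pd.Series(scales, index=X.columns)
        self.scores_ = pd.DataFrame(scores, index=X.index, columns=comp)
        self.loadings_ = pd.DataFrame(loadings, index=X.columns, columns=comp)
        self.tev_ = pd.Series(pca.explained_variance_ratio_ * 100.0, index=comp, name="tev_pct")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)[self.feature_names_]
        Xs = (X.to_numpy(float) - self.means_.to_numpy()) / self.scales_.to_numpy()
        return pd.DataFrame(Xs @ self.loadings_.to_numpy(), index=X.index, columns=self.scores_.columns)


# ---------------------------------------------------------------------------
# multiblock hierarchical (consensus) PCA
# ---------------------------------------------------------------------------


class ConvergenceError(RuntimeError):
    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


class HierarchicalPCA(BaseEstimator):
    """Multiblock hierarchical (consensus) PCA over a sample partition.

    Samples are partitioned into blocks (here: one block per cultivation
    temperature group); the matrix is globally unit-variance scaled and
    then centred within each block, which removes the block main effect.
    Per component, an iterative consensus scheme fits block scores and
    block loadings and condenses them into a shared super loading — the
    direction of variation common to the blocks — initialised from the SVD
    of the concatenated centred matrix and iterated to ``tol``.

    Attributes (after fit): ``super_loadings_``, ``super_scores_``,
    ``block_scores_`` (dict block -> scores), ``blocks_``, ``n_iter_``.
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-10, max_iter: int = 1000):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, blocks: pd.Series):
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ValueError("HPCA requires a complete (imputed) matrix")
        blocks = pd.Series(blocks)
        if not set(X.index) <= set(blocks.index):
            raise ValueError("every sample needs a block label")
        blocks = blocks.loc[X.index]

        # global uv scaling, then within-block centring
        values = X.to_numpy(float)
        scales = values.std(axis=0, ddof=1)
        scales[scales == 0] = 1.0
        Xs = values / scales
        labels = sorted(blocks.unique())
        idx_of = {b: np.flatnonzero((blocks == b).to_numpy()) for b in labels}
        Xb = {}
        for b in labels:
            sub = Xs[idx_of[b]]
            Xb[b] = sub - sub.mean(axis=0)

        n_feat = values.shape[1]
        comp = [f"PC{i + 1}" for i in range(self.n_components)]
        super_loadings = np.zeros((n_feat, self.n_components))
        block_scores = {b: np.zeros((len(idx_of[b]), self.n_components)) for b in labels}
        n_iter = []

        for c in range(self.n_components):
            concat = np.vstack([Xb[b] for b in labels])
            # deterministic init: dominant right singular vector
            _, _, vt = np.linalg.svd(concat, full_matrices=False)
            p_t = vt[0]
            trace = []
            for it in range(self.max_iter):
                t_b = {b: Xb[b] @ p_t for b in labels}
                p_b = {}
                w = {}
                for b in labels:
                    denom = t_b[b] @ t_b[b]
                    p_b[b] = Xb[b].T @ t_b[b] / denom if denom > 0 else np.zeros(n_feat)
                    w[b] = np.sqrt(denom)
                bundle = np.column_stack([w[b] * p_b[b] for b in labels])
                u, _, _ = np.linalg.svd(bundle, full_matrices=False)
                p_new = u[:, 0]
                p_new /= np.linalg.norm(p_new)
                if p_new @ p_t < 0:
                    p_new = -p_new
                delta = float(np.linalg.norm(p_new - p_t))
                trace.append(delta)
                p_t = p_new
                if delta < self.tol:
                    break
            else:
                raise ConvergenceError(
                    f"HPCA component {c + 1} did not converge in {self.max_iter} iterations",
                    trace,
                )
            n_iter.append(it + 1)
            # sign convention as for conventional PCA
            if p_t[np.argmax(np.abs(p_t))] < 0:
                p_t = -p_t
            for b in labels:
                t = Xb[b] @ p_t
                block_scores[b][:, c] = t
                Xb[b] = Xb[b] - np.outer(t, p_t)
            super_loadings[:, c] = p_t

        self.blocks_ = labels
        self.n_iter_ = n_iter
        self.super_loadings_ = pd.DataFrame(super_loadings, index=X.columns, columns=comp)
        self.block_scores_ = {
            b: pd.DataFrame(block_scores[b], index=X.index[idx_of[b]], columns=comp) for b in labels
        }
        scores = np.zeros((len(X), self.n_components))
        for b in labels:
            scores[idx_of[b]] = block_scores[b]
        self.super_scores_ = pd.DataFrame(scores, index=X.index, columns=comp)
        return self


# ---------------------------------------------------------------------------
# design construction, per-feature testing, selection, trends
# ---------------------------------------------------------------------------


def _bio_meta(meta: pd.DataFrame) -> pd.DataFrame:
    bio = meta[meta["type"] == "biological"].drop_duplicates("sample_id")
    return bio.set_index("sample_id")


def friedman_cells(
    X: pd.DataFrame, meta: pd.DataFrame, factor: str, include_ambient: bool = True
) -> tuple[np.ndarray, list[str], list[str]]:
    """Blocks x treatments x features cell-mean array for one design factor.

    temperature: treatments = temperature levels (ambient as a fourth level
    when ``include_ambient``), blocks = replicate blocks, cell = mean over
    photoperiods.  daylength: treatments = photoperiods, blocks =
    temperature x replicate (ambient excluded).
    """
    bio = _bio_meta(meta)
    bio = bio.loc[[s for s in X.index if s in bio.index]]
    if factor == "temperature":
        levels = (*CONTROLLED_TEMPS, "ambient") if include_ambient else CONTROLLED_TEMPS
        treatments = [t for t in levels if t in set(bio["temperature"])]
        bio = bio[bio["temperature"].isin(treatments)]
        block_ids = sorted(bio["block"].unique())
        key = lambda row: (row["block"], row["temperature"])
        blocks = block_ids
    elif factor == "daylength":
        bio = bio[bio["temperature"] != "ambient"]
        treatments = sorted(bio["daylength"].unique())
        blocks = sorted({(t, b) for t, b in zip(bio["temperature"], bio["block"])})
        key = lambda row: ((row["temperature"], row["block"]), row["daylength"])
        block_ids = blocks
    else:
        raise ValueError(f"unknown factor {factor!r}")

    cells = np.full((len(block_ids), len(treatments), X.shape[1]), np.nan)
    t_index = {t: j for j, t in enumerate(treatments)}
    b_index = {b: i for i, b in enumerate(block_ids)}
    grouped: dict[tuple, list[str]] = {}
    for sid, row in bio.iterrows():
        b, t = key(row)
        grouped.setdefault((b, t), []).append(sid)
    for (b, t), sids in grouped.items():
        cells[b_index[b], t_index[t]] = X.loc[sids].to_numpy(float).mean(axis=0)
    if np.isnan(cells).any():
        raise ValueError(f"incomplete design for factor {factor}: empty cells")
    return cells, [str(b) for b in block_ids], [str(t) for t in treatments]


class FriedmanSelector(BaseEstimator):
    """Per-feature Friedman tests with BH-FDR over one design factor.

    fit(X, meta) expects a samples x features ratio matrix restricted to
    (or containing) the biological samples, plus the sample metadata.
    Attributes: ``results_`` with columns Q, df, p, q, significant.
    """

    def __init__(self, factor: str = "temperature", alpha: float = ALPHA, include_ambient: bool = True):
        self.factor = factor
        self.alpha = alpha
        self.include_ambient = include_ambient

    def fit(self, X: pd.DataFrame, meta: pd.DataFrame):
        cells, _, treatments = friedman_cells(X, meta, self.factor, self.include_ambient)
        stats = [friedman_from_table(cells[:, :, f]) for f in range(cells.shape[2])]
        q_stat, df, p = map(np.asarray, zip(*stats))
        qvals, reject = bh_fdr(p, self.alpha)
        self.treatments_ = treatments
        self.results_ = pd.DataFrame(
            {
                "Q": q_stat,
                "df": df.astype(int),
                "p": p,
                "q": qvals,
                "significant": reject,
            },
            index=X.columns,
        )
        return self


def prominent_loadings(loadings: pd.DataFrame, components: list[str], pct: float = PROMINENCE_PCT) -> pd.Series:
    """Features whose |loading| reaches the pct-percentile on any listed component."""
    mask = pd.Series(False, index=loadings.index)
    for c in components:
        absl = loadings[c].abs()
        mask |= absl >= np.percentile(absl, pct)
    return mask


def select_significant(
    friedman_results: pd.DataFrame,
    loadings: pd.DataFrame,
    components: list[str],
    prominence_pct: float = PROMINENCE_PCT,
    alpha: float = ALPHA,
) -> pd.Series:
    """FDR-significant AND loading-prominent features for one factor."""
    prominent = prominent_loadings(loadings, components, prominence_pct)
    sig = friedman_results["q"] < alpha
    return sig.reindex(prominent.index, fill_value=False) & prominent


def group_means(X: pd.DataFrame, meta: pd.DataFrame, factor: str = "temperature") -> pd.DataFrame:
    """Per-level mean ratios over biological samples (features x levels)."""
    bio = _bio_meta(meta)
    bio = bio.loc[[s for s in X.index if s in bio.index]]
    means = {}
    for level, sids in bio.groupby(factor).groups.items():
        means[str(level)] = X.loc[list(sids)].mean(axis=0)
    return pd.DataFrame(means)


def classify_trends(
    means: pd.DataFrame,
    selected: pd.Series | None = None,
    ambient_factor: float = AMBIENT_FACTOR,
) -> pd.Series:
    """Temperature trend class per feature from its level means.

    temp-up: strictly increasing over 12 < 18 < 24 degC; temp-down:
    strictly decreasing; ambient-up: ambient mean above ambient_factor x
    the highest controlled mean.  Classes are assigned in that priority
    order; everything else is 'none'.  When ``selected`` is given,
    unselected features are classed 'none' outright.
    """
    m12, m18, m24 = (means[t] for t in CONTROLLED_TEMPS)
    classes = pd.Series("none", index=means.index)
    if "ambient" in means:
        amb_up = means["ambient"] > ambient_factor * means[list(CONTROLLED_TEMPS)].max(axis=1)
    else:
        amb_up = pd.Series(False, index=means.index)
    up = (m12 < m18) & (m18 < m24)
    down = (m12 > m18) & (m18 > m24)
    # later assignments win: priority temp-up > temp-down > ambient-up
    classes[amb_up] = "ambient-up"
    classes[down] = "temp-down"
    classes[up] = "temp-up"
    if selected is not None:
        classes[~selected.reindex(classes.index, fill_value=False)] = "none"
    return classes


@dataclass
class StatReport:
    """Bundle of all per-feature statistics for one analysed matrix."""

    results: pd.DataFrame
    pca: PeakRatioPCA
    hpca: HierarchicalPCA
    temp_selected: pd.Series
    day_selected: pd.Series
    trend_classes: pd.Series
    means: pd.DataFrame


def analyse(
    X_bio: pd.DataFrame,
    meta: pd.DataFrame,
    prominence_pct: float = PROMINENCE_PCT,
    ambient_factor: float = AMBIENT_FACTOR,
    alpha: float = ALPHA,
    n_components: int = 5,
) -> StatReport:
    """Run the full statistical chain on a complete biological ratio matrix."""
    pca = PeakRatioPCA(n_components=n_components).fit(X_bio)

    bio = _bio_meta(meta)
    controlled = [s for s in X_bio.index if bio.loc[s, "temperature"] != "ambient"]
    hpca_blocks = bio.loc[controlled, "temperature"]
    hpca = HierarchicalPCA(n_components=2).fit(X_bio.loc[controlled], hpca_blocks)

    temp = FriedmanSelector("temperature", alpha).fit(X_bio, meta)
    day = FriedmanSelector("daylength", alpha).fit(X_bio, meta)

    temp_selected = select_significant(
        temp.results_, pca.loadings_, ["PC1", "PC2"], prominence_pct, alpha
    )
    day_selected = select_significant(
        day.results_, hpca.super_loadings_, ["PC1"], prominence_pct, alpha
    )
    means = group_means(X_bio, meta, "temperature")
    trends = classify_trends(means, selected=temp_selected, ambient_factor=ambient_factor)

    results = pd.DataFrame(
        {
            "Q_temp": temp.results_["Q"],
            "p_temp": temp.results_["p"],
            "q_temp": temp.results_["q"],
            "Q_day": day.results_["Q"],
            "p_day": day.results_["p"],
            "q_day": day.results_["q"],
            "pc1_loading": pca.loadings_["PC1"].reindex(X_bio.columns),
            "pc2_loading": pca.loadings_["PC2"].reindex(X_bio.columns),
            "hpca_loading": hpca.super_loadings_["PC1"],
            "selected_temperature": temp_selected,
            "selected_daylength": day_selected,
            "trend_class": trends,
        },
        index=X_bio.columns,
    )
    results = results.join(means.add_prefix("mean_"))
    return StatReport(
        results=results,
        pca=pca,
        hpca=hpca,
        temp_selected=temp_selected,
        day_selected=day_selected,
        trend_classes=trends,
        means=means,
    )
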