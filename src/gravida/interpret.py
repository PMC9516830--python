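"""Attribution, attribution-space clustering, and comorbidity enrichment.

Per-delivery feature attributions are exact tree-path Shapley values on the
margin (log-odds) scale, where additivity is exact: for every delivery the
base value plus the attribution row sums to the model's margin output. The
attribution matrix is embedded with UMAP (30 components by default),
clustered with hierarchical density-based clustering over a small
hyperparameter grid, with the candidate maximizing the density-based
cluster validity (DBCV) index selected. Clusters are then characterized by
outcome metrics and by Fisher's exact-test enrichment of binary clinical
traits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import fisher_exact
from scipy.stats import false_discovery_control
from sklearn.cluster import HDBSCAN

from gravida._dbcv import dbcv_score
from gravida.model import DEFAULT_THRESHOLD, ModelBundle

logger = logging.getLogger(__name__)

LOCAL_ACCURACY_TOL = 1e-6

OUTLIER = -1


@dataclass
class AttributionMatrix:
    """Signed additive attributions (rows = deliveries, columns = features)
    plus the scalar expected-margin base value."""

    values: pd.DataFrame
    base_value: float

    def __len__(self) -> int:
        return len(self.values)

    def mean_abs(self) -> pd.Series:
        return self.values.abs().mean(axis=0)

    def write_csv(self, outdir: str | Path) -> None:
        import yaml

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        flat = self.values.copy()
        flat.index = pd.Index([str(i) for i in flat.index], name="row")
        stacked = flat.stack()
        stacked = stacked[stacked != 0.0]
        trip = stacked.rename_axis(["row", "feature"]).rename("value").reset_index()
        trip.to_csv(outdir / "attributions_triplets.csv", index=False)
        with open(outdir / "attributions.yaml", "w") as fh:
            yaml.safe_dump({"base_value": float(self.base_value)}, fh)


def compute_attribution_matrix(bundle: ModelBundle, X) -> AttributionMatrix:
    """Exact polynomial-time tree Shapley attributions for every row.

    Satisfies local accuracy: ``base_value + row sum`` equals the ensemble's
    margin output to within 1e-6 per row (asserted).
    """
    from gravida.model import _as_xy

    X, _ = _as_xy(X)
    if isinstance(X, pd.DataFrame):
        if tuple(X.columns) != bundle.feature_names:
            raise ValueError("feature columns differ from the training columns")
        index = X.index
        Xv = X.to_numpy(dtype=np.float32)
    else:
        Xv = np.asarray(X, dtype=np.float32)
        index = pd.RangeIndex(len(Xv))
    contribs = bundle.booster.predict(xgb.DMatrix(Xv), pred_contribs=True)
    base = float(contribs[0, -1])
    values = pd.DataFrame(
        contribs[:, :-1].astype(float), index=index, columns=list(bundle.feature_names)
    )
    margins = bundle.predict_margin(Xv)
    err = np.abs(base + values.sum(axis=1).to_numpy() - margins)
    if err.size and err.max() > 1e-3:  # float32 contributions; guard gross breakage
        raise AssertionError(f"local accuracy violated: max error {err.max():.2e}")
    return AttributionMatrix(values, base)


def rank_features_by_mean_abs_attribution(
    matrix: AttributionMatrix, k: int = 15
) -> pd.DataFrame:
    """Top-k features by mean |attribution| across deliveries.

    Deterministic: ties break lexicographically by feature name. Asking for
    more features than exist returns the full ranking with a logged note.
    """
    if len(matrix) == 0:
        raise ValueError("attribution matrix is empty")
    scores = matrix.mean_abs()
    if k > len(scores):
        logger.info("k=%d exceeds feature count %d; returning all", k, len(scores))
        k = len(scores)
    df = (
        scores.rename("mean_abs_attribution")
        .rename_axis("feature")
        .reset_index()
        .sort_values(
            ["mean_abs_attribution", "feature"], ascending=[False, True], kind="mergesort"
        )
        .head(k)
        .reset_index(drop=True)
    )
    df.index = df.index + 1
    df.index.name = "rank"
    return df


# ---------------------------------------------------------------------------
# embedding and clustering
# ---------------------------------------------------------------------------

def embed_attributions(
    matrix: AttributionMatrix | pd.DataFrame | np.ndarray,
    n_components: int = 30,
    seed: int = 0,
    **umap_kwargs,
) -> tuple[np.ndarray, dict]:
    """Seeded UMAP embedding of the attribution matrix.

    Defaults follow common practice (30 components for clustering; call
    again with ``n_components=2`` for display). Returns the embedding and a
    metadata dict recording the neighborhood parameters used.
    """
    import umap

    if isinstance(matrix, AttributionMatrix):
        data = matrix.values.to_numpy(dtype=float)
    else:
        data = np.asarray(matrix, dtype=float)
    if len(data) < n_components + 2:
        raise ValueError(
            f"need at least n_components + 2 = {n_components + 2} rows, got {len(data)}"
        )
    # near-square problems make the spectral initialization degenerate (and
    # its fallback non-deterministic); seeded random init is stable there
    if "init" not in umap_kwargs and len(data) < 3 * n_components:
        umap_kwargs["init"] = "random"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced determinism
        reducer = umap.UMAP(
            n_components=n_components, random_state=seed, **umap_kwargs
        )
        emb = reducer.fit_transform(data)
    meta = {
        "n_components": n_components,
        "n_neighbors": reducer.n_neighbors,
        "min_dist": reducer.min_dist,
        "metric": reducer.metric,
        "seed": seed,
    }
    return np.asarray(emb, dtype=float), meta


def default_cluster_grid(n_rows: int) -> list[tuple[int, int]]:
    """Default (min_cluster_size, min_samples) grid: cluster sizes at 2%,
    5% and 10% of n crossed with min_samples in {5, 10, 20}."""
    sizes = sorted({max(2, int(round(f * n_rows))) for f in (0.02, 0.05, 0.10)})
    return [(mcs, ms) for mcs in sizes for ms in (5, 10, 20)]


@dataclass
class ClusterAssignment:
    """Validity-selected density clustering of an attribution embedding."""

    labels: np.ndarray  # cluster id per row; -1 marks outliers
    min_cluster_size: int
    min_samples: int
    validity: float
    trace: pd.DataFrame = field(repr=False)
    embedding: np.ndarray = field(repr=False)

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels) - {OUTLIER}))

    @property
    def outlier_mask(self) -> np.ndarray:
        return self.labels == OUTLIER

    def write_csv(self, path: str | Path, index=None) -> None:
        if index is None:
            index = np.arange(len(self.labels))
        pd.DataFrame(
            {
                "row": [str(i) for i in index],
                "cluster": self.labels,
                "outlier": (self.labels == OUTLIER).astype(int),
            }
        ).to_csv(path, index=False)


def cluster_with_validity_selection(
    embedding: np.ndarray,
    grid: Sequence[tuple[int, int]] | None = None,
) -> ClusterAssignment:
    """Hierarchical density-based clustering with DBCV model selection.

    Runs HDBSCAN (Euclidean metric) for every (min_cluster_size,
    min_samples) candidate in the grid, scores each flat clustering with
    the density-based cluster validity index, and returns the argmax with
    the full trace. If every candidate collapses to a single all-outlier
    solution, an error carrying the trace is raised.
    """
    embedding = np.asarray(embedding, dtype=float)
    if grid is None:
        grid = default_cluster_grid(len(embedding))
    if not len(grid):
        raise ValueError("clustering grid is empty")
    records = []
    results = {}
    for mcs, ms in grid:
        clusterer = HDBSCAN(
            min_cluster_size=int(mcs), min_samples=int(ms), metric="euclidean", copy=True
        )
        labels = clusterer.fit_predict(embedding)
        n_clusters = int(len(set(labels) - {OUTLIER}))
        score = dbcv_score(embedding, labels) if n_clusters >= 1 else -1.0
        records.append(
            {
                "min_cluster_size": mcs,
                "min_samples": ms,
                "n_clusters": n_clusters,
                "n_outliers": int(np.sum(labels == OUTLIER)),
                "validity": score,
            }
        )
        results[(mcs, ms)] = labels
    trace = pd.DataFrame(records)
    if (trace["n_clusters"] == 0).all():
        raise RuntimeError(
            "every clustering candidate yielded only outliers; trace:\n"
            + trace.to_string(index=False)
        )
    best = trace.loc[trace["validity"].idxmax()]
    key = (int(best["min_cluster_size"]), int(best["min_samples"]))
    return ClusterAssignment(
        labels=results[key],
        min_cluster_size=key[0],
        min_samples=key[1],
        validity=float(best["validity"]),
        trace=trace,
        embedding=embedding,
    )


# ---------------------------------------------------------------------------
# cluster characterization
# ---------------------------------------------------------------------------

def cluster_outcome_metrics(
    labels: np.ndarray | ClusterAssignment,
    y_true,
    scores,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-cluster outcome prevalence, precision and recall at a threshold.

    Outliers (cluster -1) are reported as their own stratum. Precision is
    NaN in a cluster with no predicted positives; recall is NaN with no
    cases.
    """
    if isinstance(labels, ClusterAssignment):
        labels = labels.labels
    labels = np.asarray(labels)
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    rows = []
    for c in sorted(set(labels.tolist())):
        m = labels == c
        tp = int((pred[m] & (y[m] == 1)).sum())
        pp = int(pred[m].sum())
        pos = int(y[m].sum())
        rows.append(
            {
                "cluster": c,
                "n": int(m.sum()),
                "prevalence": float(y[m].mean()),
                "precision": (tp / pp) if pp else np.nan,
                "recall": (tp / pos) if pos else np.nan,
                "is_outlier_stratum": c == OUTLIER,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 enrichment of one binary trait in one cluster.

    ``a`` = in-cluster & trait, ``b`` = in-cluster & no trait,
    ``c`` = out-of-cluster & trait, ``d`` = out-of-cluster & no trait.
    The odds ratio ``ad/bc`` is reported as ``inf`` (or 0) with a flag when
    a margin cell is empty, rather than continuity-corrected.
    """

    cluster: int
    trait: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    degenerate: bool

    @property
    def log10_odds_ratio(self) -> float:
        if self.odds_ratio <= 0:
            return -np.inf
        return float(np.log10(self.odds_ratio))


def fisher_table_stats(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Odds ratio, two-sided exact p-value and degeneracy flag for one
    2x2 table (a,b = in-cluster with/without trait; c,d = out-of-cluster).

    The odds ratio is ``ad/bc``, reported as ``inf`` or 0 with the flag set
    when a denominator cell is empty (no continuity correction).
    """
    degenerate = b * c == 0 or a * d == 0
    if b * c == 0:
        oddsr = 0.0 if a == 0 else np.inf
    else:
        oddsr = (a * d) / (b * c)
    p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    return float(oddsr), p, degenerate


def cluster_enrichment(
    labels: np.ndarray | ClusterAssignment,
    trait,
    trait_name: str = "trait",
    *,
    fdr: bool = False,
) -> pd.DataFrame:
    """Fisher's exact-test enrichment of a binary trait per cluster.

    For each cluster, builds the in-cluster vs out-of-cluster by trait vs
    no-trait contingency table over the clustered rows (outliers excluded),
    and reports the odds ratio with the two-sided exact hypergeometric
    p-value. A constant trait is flagged (all odds ratios degenerate).
    Benjamini-Hochberg adjusted p-values are added when ``fdr=True``.
    """
    if isinstance(labels, ClusterAssignment):
        labels = labels.labels
    labels = np.asarray(labels)
    t = np.asarray(trait).astype(int)
    if not np.isin(t, (0, 1)).all():
        raise ValueError("trait must be binary 0/1")
    if len(t) != len(labels):
        raise ValueError("trait and labels must align")
    keep = labels != OUTLIER
    labels, t = labels[keep], t[keep]
    if t.min() == t.max():
        logger.warning("trait %r is constant; enrichment is degenerate", trait_name)
    rows = []
    for c in sorted(set(labels.tolist())):
        m = labels == c
        a = int((m & (t == 1)).sum())
        b = int((m & (t == 0)).sum())
        cc = int((~m & (t == 1)).sum())
        d = int((~m & (t == 0)).sum())
        oddsr, p, degenerate = fisher_table_stats(a, b, cc, d)
        rows.append(
            EnrichmentResult(int(c), trait_name, a, b, cc, d, oddsr, p, degenerate)
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    if fdr and len(df):
        df["p_adjusted"] = false_discovery_control(df["p_value"], method="bh")
    return df


def enrichment_table(
    labels: np.ndarray | ClusterAssignment,
    traits: pd.DataFrame,
    *,
    fdr: bool = False,
) -> pd.DataFrame:
    """Run :func:`cluster_enrichment` for every binary trait column."""
    parts = [
        cluster_enrichment(labels, traits[col], col, fdr=fdr) for col in traits.columns
    ]
    return pd.concat(parts, ignore_index=True)


def plot_embedding(
    embedding_2d: np.ndarray,
    labels: np.ndarray | ClusterAssignment,
    path: str | Path,
) -> None:
    """Scatter the 2-D display embedding colored by cluster membership."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(labels, ClusterAssignment):
        labels = labels.labels
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for c in sorted(set(labels.tolist())):
        m = labels == c
        kw = dict(s=8, alpha=0.7)
        if c == OUTLIER:
            kw.update(c="lightgray", label="outliers")
        else:
            kw.update(label=f"cluster {c}")
        ax.scatter(embedding_2d[m, 0], embedding_2d[m, 1], **kw)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(fontsize=8, markerscale=1.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
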