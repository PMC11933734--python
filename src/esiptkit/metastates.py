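"""Metastable-state identification from dihedral descriptors.

The procedure mirrors the standard conformational-analysis chain: principal
component analysis of the per-frame descriptor matrix, clustering of the
scores into long-lived metastates, optional decomposition of each metastate
into two shorter-lived sub-states along a chosen component, and population
accounting.

Angular descriptors are handled on the circle: before (covariance) PCA each
torsion column is unwrapped with the seam placed in the middle of its largest
angular gap, so that no populated basin is torn apart at ±180°, and
per-metastate torsion means are circular means.  A ``sincos`` embedding is available for landscapes where
unwrapping is not enough.

Column scaling is ``auto`` by default: no scaling when every descriptor has
the same kind (all torsions — the homogeneous-unit case), unit-variance
scaling when kinds are mixed so degrees and Å become commensurable.  With
exactly two standardized columns a correlation PCA would always return the
±45° diagonals as axes regardless of the data, which is why homogeneous
matrices are analysed on the covariance scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DegenerateGeometryError, ParameterError, ValidationError
from .geometry import DescriptorMatrix, circular_mean, wrap_degrees

__all__ = [
    "PcaModel",
    "MetastateModel",
    "fit_pca",
    "cluster_metastates",
    "assign_frames",
    "decompose_substates",
    "population_report",
    "export_biplot",
    "plot_biplot",
]


@dataclass
class PcaModel:
    """Fitted PCA of a descriptor matrix, with its preprocessing state."""

    feature_names: list[str]
    feature_kinds: list[str]
    component_loadings: np.ndarray  # (features, components), columns orthonormal
    explained_variance_percent: np.ndarray  # non-increasing, sums to 100
    scores: np.ndarray  # (frames, components)
    descriptor_means: np.ndarray  # per feature, after embedding
    descriptor_scales: np.ndarray  # per feature divisor (1.0 when unscaled)
    embedding: str
    unwrap_centers: dict  # torsion name -> circular-mean center (raw_degrees only)
    source: DescriptorMatrix

    @property
    def n_components(self) -> int:
        return self.component_loadings.shape[1]

    def _embed(self, matrix: DescriptorMatrix) -> np.ndarray:
        cols = []
        for name, kind in zip(matrix.descriptor_names, matrix.kinds):
            col = matrix.column(name)
            if kind == "torsion":
                if self.embedding == "sincos":
                    cols.append(np.sin(np.radians(col)))
                    cols.append(np.cos(np.radians(col)))
                    continue
                col = _unwrap_at(col, self.unwrap_centers.get(name, -180.0))
            cols.append(col)
        return np.column_stack(cols)

    def transform(self, matrix: DescriptorMatrix) -> np.ndarray:
        """Project a (possibly new) descriptor matrix onto the fitted components."""
        if matrix.descriptor_names != self.source.descriptor_names:
            raise ValidationError("descriptor names do not match the fitted matrix")
        x = self._embed(matrix)
        x = (x - self.descriptor_means) / self.descriptor_scales
        return x @ self.component_loadings


@dataclass
class MetastateModel:
    """Cluster labels, populations, and per-metastate descriptor means."""

    labels: np.ndarray  # (frames,) metastate id strings
    populations: dict  # id -> frame count
    population_fractions: dict  # id -> percent of frames
    descriptor_means: dict  # id -> {descriptor name: mean}
    centroids: dict  # id -> centroid vector in score space
    hierarchy: Optional[dict] = None  # sub-state id -> parent id
    warnings: list = field(default_factory=list)
    seed: Optional[int] = None

    @property
    def metastate_ids(self) -> list[str]:
        return list(self.populations.keys())

    @property
    def n_frames(self) -> int:
        return len(self.labels)


def _gap_cut(angles_deg: np.ndarray) -> float:
    """Seam position (degrees) for unwrapping a torsion column.

    The circle is cut in the middle of the largest angular gap of the sample,
    so no populated basin straddles the seam.  (Cutting at the circular mean
    ±180° fails for symmetric multi-basin landscapes, whose mean direction
    can point straight at a basin.)
    """
    s = np.sort(wrap_degrees(angles_deg))
    if s.size == 1:
        return float(wrap_degrees(s[0] + 180.0))
    gaps = np.diff(s)
    wrap_gap = s[0] + 360.0 - s[-1]
    i = int(np.argmax(gaps)) if gaps.size and gaps.max() > wrap_gap else None
    if i is None:
        return float(wrap_degrees(s[-1] + wrap_gap / 2.0))
    return float(s[i] + gaps[i] / 2.0)


def _unwrap_at(angles_deg: np.ndarray, cut: float) -> np.ndarray:
    """Map angles to the contiguous interval [cut, cut + 360)."""
    return cut + np.remainder(np.asarray(angles_deg, dtype=float) - cut, 360.0)


def _metastate_means(matrix: DescriptorMatrix, labels: np.ndarray, ids) -> dict:
    """Per-metastate descriptor means: circular for torsions, arithmetic otherwise."""
    means: dict = {}
    for mid in ids:
        mask = labels == mid
        entry = {}
        for name, kind in zip(matrix.descriptor_names, matrix.kinds):
            col = matrix.column(name)[mask]
            if kind == "torsion":
                try:
                    entry[name] = circular_mean(col)
                except DegenerateGeometryError:
                    entry[name] = float("nan")
            else:
                entry[name] = float(np.mean(col))
        means[mid] = entry
    return means


def fit_pca(
    matrix: DescriptorMatrix,
    embedding: Literal["raw_degrees", "sincos"] = "raw_degrees",
    scaling: Literal["auto", "unit", "none"] = "auto",
) -> PcaModel:
    """Principal component analysis of a descriptor matrix.

    Under ``raw_degrees`` each torsion column is first unwrapped at its
    largest angular gap; under ``sincos`` each torsion expands to a (sin, cos) pair
    before centering.  The result is deterministic: each component's sign is
    fixed by forcing its largest-magnitude loading positive.
    """
    if matrix.n_frames < 2:
        raise ValidationError("PCA needs at least 2 frames")
    if not matrix.descriptor_names:
        raise ValidationError("PCA needs at least 1 descriptor")

    feature_names: list[str] = []
    feature_kinds: list[str] = []
    unwrap_centers: dict = {}
    cols = []
    for name, kind in zip(matrix.descriptor_names, matrix.kinds):
        col = matrix.column(name)
        if kind == "torsion" and embedding == "sincos":
            cols.append(np.sin(np.radians(col)))
            cols.append(np.cos(np.radians(col)))
            feature_names += [f"{name}_sin", f"{name}_cos"]
            feature_kinds += ["sincos", "sincos"]
            continue
        if kind == "torsion":
            cut = _gap_cut(col)
            unwrap_centers[name] = cut
            col = _unwrap_at(col, cut)
        cols.append(col)
        feature_names.append(name)
        feature_kinds.append(kind)
    x = np.column_stack(cols)

    variances = np.var(x, axis=0)
    if np.all(variances < 1e-24):
        raise DegenerateGeometryError("descriptor matrix has zero variance")

    means = x.mean(axis=0)
    if scaling == "auto":
        scaling = "none" if len(set(matrix.kinds)) <= 1 else "unit"
    if scaling == "unit":
        scales = np.std(x, axis=0, ddof=1)
        scales[scales < 1e-12] = 1.0
    else:
        scales = np.ones(x.shape[1])
    z = (x - means) / scales

    n_components = min(z.shape[0], z.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_.T  # (features, components)
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaModel(
        feature_names=feature_names,
        feature_kinds=feature_kinds,
        component_loadings=loadings,
        explained_variance_percent=100.0 * pca.explained_variance_ratio_,
        scores=scores,
        descriptor_means=means,
        descriptor_scales=scales,
        embedding=embedding,
        unwrap_centers=unwrap_centers,
        source=matrix,
    )


def _order_ids(labels_raw: np.ndarray, pca: PcaModel, order: str) -> dict:
    """Map raw cluster labels to ids '1'..'k'.

    ``population``: descending population, ties by ascending PC1 centroid.
    ``pc1``: numbering follows the leading structural coordinate — when PC1 is
    dominated by a torsion, clusters are ordered by that torsion's wrapped
    circular mean (so the numbering is independent of where the angular seam
    fell); otherwise by ascending PC1 centroid.
    """
    raw_ids = np.unique(labels_raw)
    scores = pca.scores
    axis_key = None
    if order == "pc1":
        dom = int(np.argmax(np.abs(pca.component_loadings[:, 0])))
        feat = pca.feature_names[dom]
        src = feat.removesuffix("_sin").removesuffix("_cos")
        if src in pca.source.descriptor_names and pca.source.kind_of(src) == "torsion":
            col = pca.source.column(src)
            axis_key = {}
            for rid in raw_ids:
                try:
                    axis_key[rid] = float(circular_mean(col[labels_raw == rid]))
                except DegenerateGeometryError:
                    axis_key = None
                    break
    elif order != "population":
        raise ParameterError(f"unknown metastate ordering {order!r}")
    stats = []
    for rid in raw_ids:
        mask = labels_raw == rid
        pc1 = float(scores[mask, 0].mean())
        if order == "population":
            stats.append((-int(mask.sum()), pc1, rid))
        else:
            stats.append((axis_key[rid] if axis_key is not None else pc1, 0, rid))
    stats.sort()
    return {rid: str(i + 1) for i, (_, _, rid) in enumerate(stats)}


def cluster_metastates(
    pca: PcaModel,
    method: Literal["kmeans", "density"] = "kmeans",
    k: Optional[int] = None,
    seed: int = 0,
    components: Optional[int] = None,
    order: Literal["population", "pc1"] = "population",
) -> MetastateModel:
    """Cluster PCA scores into metastates.

    ``kmeans`` (default) requires ``k`` and is reproducible for a fixed seed;
    ``density`` infers the cluster count with DBSCAN on a k-distance
    heuristic, then assigns noise frames to the nearest cluster centroid.
    ``components`` restricts clustering to that many leading score columns —
    pass 1 to separate long-lived metastates along PC1 only, leaving the
    next component free for the sub-state decomposition.  Metastate ids are
    '1'..'k', ordered by descending population (ties broken by ascending PC1
    centroid).
    """
    scores = pca.scores
    if components is not None:
        if not (1 <= components <= pca.n_components):
            raise ParameterError(f"components must be in [1, {pca.n_components}]")
        scores = scores[:, :components]
    n = scores.shape[0]
    if method == "kmeans":
        if k is None:
            raise ParameterError("kmeans clustering requires k")
        if k < 1:
            raise ParameterError("k must be >= 1")
        if k > n:
            raise ParameterError(f"k={k} exceeds the frame count {n}")
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels_raw = km.fit_predict(scores)
    elif method == "density":
        from sklearn.cluster import DBSCAN
        from sklearn.neighbors import NearestNeighbors

        min_samples = max(5, n // 1000)
        nn = NearestNeighbors(n_neighbors=min_samples).fit(scores)
        dist, _ = nn.kneighbors(scores)
        eps = float(np.percentile(dist[:, -1], 90)) * 1.5
        labels_raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(scores)
        if np.all(labels_raw == -1):
            labels_raw = np.zeros(n, dtype=int)
        elif np.any(labels_raw == -1):
            # attach noise frames to the nearest cluster centroid
            ids = [c for c in np.unique(labels_raw) if c != -1]
            cents = np.stack([scores[labels_raw == c].mean(axis=0) for c in ids])
            noise = labels_raw == -1
            d = np.linalg.norm(scores[noise, None, :] - cents[None, :, :], axis=2)
            labels_raw[noise] = np.asarray(ids)[np.argmin(d, axis=1)]
    else:
        raise ParameterError(f"unknown clustering method {method!r}")

    mapping = _order_ids(labels_raw, pca, order)
    labels = np.array([mapping[r] for r in labels_raw], dtype=object)
    ids = sorted(set(mapping.values()), key=int)
    populations = {mid: int(np.sum(labels == mid)) for mid in ids}
    fractions = {mid: 100.0 * c / n for mid, c in populations.items()}
    # centroids live in the full score space so new frames can be assigned
    centroids = {mid: pca.scores[labels == mid].mean(axis=0) for mid in ids}
    return MetastateModel(
        labels=labels,
        populations=populations,
        population_fractions=fractions,
        descriptor_means=_metastate_means(pca.source, labels, ids),
        centroids=centroids,
        seed=seed,
    )


def assign_frames(model: MetastateModel, pca: PcaModel, matrix: DescriptorMatrix) -> np.ndarray:
    """Assign (new) frames to the fitted metastates by nearest score-space centroid."""
    scores = pca.transform(matrix)
    ids = model.metastate_ids
    cents = np.stack([model.centroids[mid] for mid in ids])
    d = np.linalg.norm(scores[:, None, :] - cents[None, :, :], axis=2)
    return np.array([ids[j] for j in np.argmin(d, axis=1)], dtype=object)


def _two_means_1d(x: np.ndarray):
    """Exact 1D 2-means: minimise within-cluster SSE over all sorted splits.

    Deterministic, no seed: returns a boolean mask of membership in the
    upper cluster.  Ties go to the smallest upper cluster.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    prefix = np.cumsum(xs)
    prefix2 = np.cumsum(xs**2)
    best = (np.inf, n - 1)
    for i in range(1, n):  # lower cluster = xs[:i]
        s1, q1 = prefix[i - 1], prefix2[i - 1]
        s2, q2 = prefix[-1] - s1, prefix2[-1] - q1
        sse = (q1 - s1**2 / i) + (q2 - s2**2 / (n - i))
        if sse < best[0] - 1e-12:
            best = (sse, i)
    split = best[1]
    upper = np.zeros(n, dtype=bool)
    upper[order[split:]] = True
    return upper


def decompose_substates(model: MetastateModel, pca: PcaModel, axis: int = 1) -> MetastateModel:
    """Split each metastate into two sub-states along one PCA component.

    Clustering is an exact 1D 2-means on the chosen component within each
    parent; the sub-state with the lower centroid on that component is
    labelled "<parent>A", the other "<parent>B".  For a unimodal parent the
    split falls near the median — this is documented behaviour, not an
    error.  Parents with fewer than 2 frames are left undivided with a
    warning record.
    """
    if axis >= pca.n_components:
        raise ParameterError(f"axis {axis} out of range for {pca.n_components} components")
    labels = np.asarray(model.labels, dtype=object).copy()
    hierarchy: dict = {}
    warnings: list = []
    for pid in model.metastate_ids:
        mask = model.labels == pid
        n_members = int(mask.sum())
        if n_members < 2:
            hierarchy[pid] = pid
            warnings.append(f"metastate {pid}: {n_members} frame(s), cannot split")
            continue
        comp = pca.scores[mask, axis]
        upper = _two_means_1d(comp)
        sub = np.where(upper, f"{pid}B", f"{pid}A")
        labels[np.flatnonzero(mask)] = sub
        hierarchy[f"{pid}A"] = pid
        hierarchy[f"{pid}B"] = pid
    ids = sorted(set(labels.tolist()))
    n = len(labels)
    populations = {mid: int(np.sum(labels == mid)) for mid in ids}
    fractions = {mid: 100.0 * c / n for mid, c in populations.items()}
    centroids = {mid: pca.scores[labels == mid].mean(axis=0) for mid in ids}
    return MetastateModel(
        labels=labels,
        populations=populations,
        population_fractions=fractions,
        descriptor_means=_metastate_means(pca.source, labels, ids),
        centroids=centroids,
        hierarchy=hierarchy,
        warnings=warnings,
        seed=model.seed,
    )


def population_report(model: MetastateModel) -> pd.DataFrame:
    """Tabulate per-metastate counts, percents (2 decimals) and display percents."""
    total = model.n_frames
    rows = []
    for mid in model.metastate_ids:
        count = model.populations[mid]
        percent = 100.0 * count / total
        rows.append(
            {
                "metastate": mid,
                "count": count,
                "percent": round(percent, 2),
                "display_percent": int(round(percent)),
            }
        )
    return pd.DataFrame(rows)


def export_biplot(pca: PcaModel, model: Optional[MetastateModel] = None) -> dict:
    """Biplot data (scores, loadings, explained variance) as plain dict/lists."""
    out = {
        "explained_variance_percent": [float(v) for v in pca.explained_variance_percent],
        "feature_names": list(pca.feature_names),
        "loadings": pca.component_loadings.tolist(),
        "scores": pca.scores.tolist(),
    }
    if model is not None:
        out["labels"] = [str(l) for l in model.labels]
    return out


def plot_biplot(pca: PcaModel, model: Optional[MetastateModel], path) -> None:
    """Render a PC1/PC2 biplot (scores coloured by metastate, loading arrows)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    scores = pca.scores
    if model is not None:
        for mid in model.metastate_ids:
            mask = model.labels == mid
            ax.scatter(scores[mask, 0], scores[mask, 1], s=4, label=f"Meta {mid}")
        ax.legend(markerscale=3, fontsize=8)
    else:
        ax.scatter(scores[:, 0], scores[:, 1], s=4)
    span = np.abs(scores[:, :2]).max() or 1.0
    for name, vec in zip(pca.feature_names, pca.component_loadings):
        ax.annotate(
            name,
            xy=(vec[0] * span * 0.8, vec[1] * span * 0.8 if pca.n_components > 1 else 0),
            xytext=(0, 0),
            textcoords="data",
            arrowprops=dict(arrowstyle="<-", color="black"),
            fontsize=8,
        )
    ev = pca.explained_variance_percent
    ax.set_xlabel(f"PC1 ({ev[0]:.1f}%)")
    if len(ev) > 1:
        ax.set_ylabel(f"PC2 ({ev[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
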