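"""Population structure from a shared-k-mer count matrix.

The pipeline mirrors standard SNP-based population stratification, but the
features are canonical k-mer counts instead of genotypes: per-feature
z-scoring, principal component analysis, K-means clustering on the leading
components with the cluster number chosen by the elbow heuristic on
inertia, and adjusted mutual information (AMI) against known labels when
they are available.

Clustering defaults to the first two principal components.  On genome-scale
k-mer matrices the variance tends to be spread thinly across many
components, and clustering in the full 80%-variance space can be unstable;
the two leading components carry the between-population signal.  The
80%-cumulative-variance component choice remains available via
``target_variance``.

The elbow heuristic (usually applied visually) is formalised as the
interior point of the inertia curve lying farthest below the chord
joining its endpoints, with a reported *strength* (the discrete second
difference at the chosen k divided by the k=1 inertia) so weak,
ambiguous elbows can be flagged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_mutual_info_score
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from .kmerprof import KmerMatrix, KmerParams, matrix_from_manifest

__all__ = [
    "StandardizedMatrix",
    "PCAResult",
    "ElbowScan",
    "ElbowPoint",
    "ClusterResult",
    "StructureReport",
    "standardize",
    "pca",
    "select_components",
    "kmeans",
    "elbow_scan",
    "elbow_k",
    "ami",
    "run_structure_pipeline",
]

#: below this elbow strength the selected cluster number is considered
#: unreliable (an inertia curve that is already near-linear has no elbow)
WEAK_ELBOW_STRENGTH = 0.05


@dataclass
class StandardizedMatrix:
    """Per-feature z-scored matrix; constant features map to all-zero columns."""

    values: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    n_constant: int = 0


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_samples, n_components)
    loadings: np.ndarray  # (n_components, n_features), rows orthonormal
    explained_variance_ratio: np.ndarray


@dataclass
class ElbowScan:
    k_values: np.ndarray
    inertias: np.ndarray


class ElbowPoint(NamedTuple):
    k: int
    strength: float
    weak: bool


@dataclass
class ClusterResult:
    K: int
    labels: np.ndarray
    centers: np.ndarray
    inertia: float


def standardize(matrix: KmerMatrix | np.ndarray, method: str = "zscore") -> StandardizedMatrix:
    """Per-feature scaling of the count matrix.

    ``zscore`` (default) centres each feature and divides by its population
    standard deviation; zero-variance features become all-zero columns (and
    are counted, not dropped).  ``minmax`` rescales each feature to [0, 1]
    instead.
    """
    values = matrix.counts if isinstance(matrix, KmerMatrix) else np.asarray(matrix)
    values = values.astype(float)
    if values.shape[0] < 2:
        raise ValueError("standardization needs at least 2 samples")
    if method == "zscore":
        scaler = StandardScaler()
    elif method == "minmax":
        scaler = MinMaxScaler()
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    scaled = scaler.fit_transform(values)
    sds = values.std(axis=0)
    n_constant = int((sds == 0).sum())
    means = values.mean(axis=0)
    return StandardizedMatrix(scaled, means, sds, n_constant)


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Flip each component so its largest-|loading| entry is positive."""
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0


def pca(data: StandardizedMatrix | np.ndarray, n_components: int) -> PCAResult:
    """Top principal components of the (already scaled) data.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive, making output deterministic across platforms.
    """
    values = data.values if isinstance(data, StandardizedMatrix) else np.asarray(data, float)
    n, p = values.shape
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}] for {n} samples x {p} features, "
            f"got {n_components}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(values)
    loadings = model.components_.copy()
    _fix_signs(scores, loadings)
    evr = model.explained_variance_ratio_.copy()
    return PCAResult(scores, loadings, evr)


def select_components(evr: Sequence[float], target: float = 0.80) -> int:
    """Smallest component count whose cumulative explained variance >= target."""
    evr = np.asarray(evr, float)
    if evr.size == 0:
        raise ValueError("empty explained-variance vector")
    if not 0 < target <= 1:
        raise ValueError(f"target must be in (0, 1], got {target}")
    cum = np.cumsum(evr)
    reached = np.nonzero(cum >= target - 1e-12)[0]
    if reached.size == 0:
        warnings.warn(
            f"cumulative explained variance tops out at {cum[-1]:.3f} < {target}; "
            "using all components"
        )
        return int(evr.size)
    return int(reached[0] + 1)


def _canonical_labels(labels: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters by first appearance in sample order."""
    mapping: dict[int, int] = {}
    for lab in labels:
        if int(lab) not in mapping:
            mapping[int(lab)] = len(mapping)
    # clusters never assigned (possible when K > occupied clusters) keep order
    for orig in range(centers.shape[0]):
        if orig not in mapping:
            mapping[orig] = len(mapping)
    new_labels = np.array([mapping[int(l)] for l in labels])
    order = sorted(mapping, key=mapping.get)
    return new_labels, centers[order]


def kmeans(points: np.ndarray, K: int, seed: int = 0, restarts: int = 10) -> ClusterResult:
    """Best-inertia K-means solution over k-means++ restarts; seeded."""
    points = np.asarray(points, float)
    if points.ndim == 1:
        points = points[:, None]
    if K > points.shape[0]:
        raise ValueError(f"K={K} exceeds number of points {points.shape[0]}")
    model = KMeans(n_clusters=K, n_init=restarts, random_state=seed)
    raw = model.fit_predict(points)
    labels, centers = _canonical_labels(raw, model.cluster_centers_)
    return ClusterResult(K, labels, centers, float(model.inertia_))


def elbow_scan(points: np.ndarray, k_max: int = 10, seed: int = 0, restarts: int = 10) -> ElbowScan:
    """Best K-means inertia for every cluster number 1..k_max."""
    points = np.asarray(points, float)
    if points.ndim == 1:
        points = points[:, None]
    if k_max > points.shape[0]:
        raise ValueError(f"k_max={k_max} exceeds number of points {points.shape[0]}")
    ks = np.arange(1, k_max + 1)
    inertias = np.array([kmeans(points, int(k), seed=seed, restarts=restarts).inertia for k in ks])
    return ElbowScan(ks, inertias)


def elbow_k(scan: ElbowScan) -> ElbowPoint:
    """Cluster number at the elbow of the inertia curve.

    The elbow — the point after which inertia decreases roughly linearly —
    is located as the interior k whose inertia lies farthest below the
    chord joining the first and last scanned points (the standard "knee"
    formalization of the visual heuristic).  Unlike the raw maximum of the
    discrete second difference, this is not fooled when one cluster lies
    much farther out than the rest, which makes the k=1 to k=2 inertia
    drop dominate every later drop.

    The reported strength is the discrete second difference at the chosen
    k, ``inertia[k-1] - 2*inertia[k] + inertia[k+1]``, divided by the k=1
    inertia; a near-linear curve gives strength about zero and is flagged
    weak.
    """
    inert = np.asarray(scan.inertias, float)
    ks = np.asarray(scan.k_values, float)
    if inert.size < 3:
        raise ValueError("elbow detection needs at least 3 scanned k values")
    # vertical distance below the chord from (k_1, i_1) to (k_n, i_n)
    slope = (inert[-1] - inert[0]) / (ks[-1] - ks[0])
    chord = inert[0] + slope * (ks - ks[0])
    below = chord - inert
    idx = int(np.argmax(below[1:-1])) + 1
    k = int(scan.k_values[idx])
    second = float(inert[idx - 1] - 2 * inert[idx] + inert[idx + 1])
    total = inert[0]
    strength = float(second / total) if total > 0 else 0.0
    return ElbowPoint(k, strength, bool(strength < WEAK_ELBOW_STRENGTH))


def ami(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Adjusted mutual information between two labelings.

    Chance-corrected under the permutation model, normalised by the larger
    of the two label entropies; 1 means identical partitions up to
    renaming, about 0 means independent labelings.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    return float(adjusted_mutual_info_score(a, b, average_method="max"))


@dataclass
class StructureReport:
    """Everything the frequency-PCA pipeline computed for one run."""

    matrix: KmerMatrix
    standardized: StandardizedMatrix
    pca: PCAResult
    scan: ElbowScan
    elbow: ElbowPoint
    clusters: ClusterResult
    labels: list[str] | None = None
    ami_score: float | None = None
    params: KmerParams | None = None
    n_pcs: int = 2
    seed: int = 0

    def summary(self) -> dict:
        return {
            "n_samples": len(self.matrix.sample_ids),
            "n_shared_kmers": len(self.matrix.features),
            "k": self.params.k if self.params else None,
            "min_count": self.params.min_count if self.params else None,
            "n_pcs": self.n_pcs,
            "seed": self.seed,
            "explained_variance_ratio": [float(v) for v in self.pca.explained_variance_ratio],
            "K": self.clusters.K,
            "elbow_strength": self.elbow.strength,
            "weak_elbow": self.elbow.weak,
            "ami": self.ami_score,
        }

    def write(self, out_dir: str | Path) -> None:
        """Write scores / explained variance / elbow scan / labels TSVs + JSON report."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ids = self.matrix.sample_ids
        pcs = pd.DataFrame(
            self.pca.scores,
            index=ids,
            columns=[f"PC{i + 1}" for i in range(self.pca.scores.shape[1])],
        )
        pcs.rename_axis("sample_id").to_csv(out / "pc_scores.tsv", sep="\t")
        pd.DataFrame(
            {
                "component": np.arange(1, len(self.pca.explained_variance_ratio) + 1),
                "explained_variance_ratio": self.pca.explained_variance_ratio,
            }
        ).to_csv(out / "explained_variance.tsv", sep="\t", index=False)
        pd.DataFrame({"k": self.scan.k_values, "inertia": self.scan.inertias}).to_csv(
            out / "elbow_scan.tsv", sep="\t", index=False
        )
        lab = pd.DataFrame({"sample_id": ids, "cluster": self.clusters.labels})
        if self.labels is not None:
            lab["label"] = self.labels
        lab.to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def plot(self, path: str | Path) -> None:
        """PC1/PC2 scatter coloured by cluster (marker shape by true label)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        xy = self.pca.scores[:, :2]
        markers = "osD^vP*X"
        if self.labels is not None:
            uniq = sorted(set(self.labels))
            for li, lab in enumerate(uniq):
                sel = np.array([l == lab for l in self.labels])
                ax.scatter(
                    xy[sel, 0], xy[sel, 1], c=self.clusters.labels[sel],
                    marker=markers[li % len(markers)], cmap="tab10",
                    vmin=0, vmax=9, label=lab, edgecolor="k", linewidth=0.3,
                )
            ax.legend(title="label", fontsize=8)
        else:
            ax.scatter(xy[:, 0], xy[:, 1], c=self.clusters.labels, cmap="tab10")
        evr = self.pca.explained_variance_ratio
        ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
        if len(evr) > 1:
            ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
        ax.set_title(f"K-means K={self.clusters.K} on first two PCs")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def run_structure_pipeline(
    manifest,
    params: KmerParams,
    n_pcs: int = 2,
    k_max: int = 10,
    seed: int = 0,
    target_variance: float | None = None,
    scaling: str = "zscore",
) -> StructureReport:
    """End-to-end frequency-PCA pipeline on a manifest of FASTA samples.

    Chains: count -> filter -> intersect -> matrix -> standardize -> PCA ->
    elbow scan -> K-means on the first ``n_pcs`` score columns (or, when
    ``target_variance`` is given, on however many components reach that
    cumulative explained variance).  When the manifest carries labels the
    report includes the AMI between clusters and labels.
    """
    matrix, labels = matrix_from_manifest(manifest, params)
    n = len(matrix.sample_ids)
    if n < 3:
        raise ValueError(f"pipeline needs at least 3 samples, got {n}")
    std = standardize(matrix, method=scaling)
    total_var = float(std.values.var(axis=0).sum())
    max_comp = min(n - 1, std.values.shape[1])
    if total_var <= 1e-12:
        # all features constant across samples: nothing to ordinate
        warnings.warn("standardized matrix has no variance; degenerate run")
        ncomp = min(max(n_pcs, 2), max_comp)
        pca_res = PCAResult(
            np.zeros((n, ncomp)),
            np.zeros((ncomp, std.values.shape[1])),
            np.zeros(ncomp),
        )
    else:
        pca_res = pca(std, max_comp)
    if target_variance is not None:
        dims = select_components(pca_res.explained_variance_ratio, target_variance)
    else:
        dims = min(n_pcs, pca_res.scores.shape[1])
    points = pca_res.scores[:, :dims]
    scan = elbow_scan(points, k_max=min(k_max, n), seed=seed)
    elbow = elbow_k(scan)
    clusters = kmeans(points, elbow.k, seed=seed)
    score = ami(labels, clusters.labels) if labels is not None else None
    return StructureReport(
        matrix=matrix,
        standardized=std,
        pca=pca_res,
        scan=scan,
        elbow=elbow,
        clusters=clusters,
        labels=labels,
        ami_score=score,
        params=params,
        n_pcs=dims,
        seed=seed,
    )
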