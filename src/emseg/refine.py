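"""Split/merge refinement of a segmentation.

Automatic clustering sometimes leaves one cluster spanning several tissues
(under-segmentation) or several clusters covering one tissue
(over-segmentation).  The remedy here is deliberately simple and
reproducible: a user — or a scripted sequence of commands — selects a
cluster to *split*, its pixels are re-clustered into two sub-clusters by a
two-component mixture fit restricted to that cluster, and finally every
leaf cluster is *merged* onto a target tissue id.  Sub-cluster ids follow
the decimal-digit convention: splitting cluster 3 produces children 31 and
32, splitting 31 produces 311 and 312, and so on.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import gmm, spatial
from .io import ImageVolume, LabelVolume


class CannotSplitError(ValueError):
    """Raised when a cluster has too few distinct intensities to split."""


@dataclass
class ClusterTree:
    """A label map whose clusters form a tree under repeated splitting.

    ``labels`` assigns every pixel to a *leaf* cluster id; ``parent`` maps
    each child id back to the cluster it was split from; ``tissue_map``
    (possibly many-to-one) assigns leaves to tissue ids when finalized.
    """

    labels: np.ndarray
    parent: Dict[int, int] = field(default_factory=dict)
    tissue_map: Dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_labels(cls, labels, relabel_from_one: bool = True) -> "ClusterTree":
        """Start a tree from a segmentation.

        Initial clusters are relabelled 1..K (in ascending original-id
        order) so that decimal-digit child naming never collides; the
        original ids are retained in ``original_ids``.
        """
        arr = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
        ids = [int(c) for c in np.unique(arr)]
        tree = cls(labels=arr.astype(np.int64).copy())
        if relabel_from_one:
            if len(ids) > 9:
                raise ValueError("more than 9 initial clusters; relabelling "
                                 "would collide with child naming")
            new = np.zeros_like(tree.labels)
            for k, c in enumerate(ids, start=1):
                new[arr == c] = k
            tree.labels = new
            tree.original_ids = {k: c for k, c in enumerate(ids, start=1)}
        else:
            tree.original_ids = {c: c for c in ids}
        return tree

    @property
    def leaves(self) -> list:
        return [int(c) for c in np.unique(self.labels)]


def split_cluster(image, tree: ClusterTree, cluster_id: int,
                  method: str = "gmm2", seed: int = 0,
                  config: Optional[spatial.SpatialConfig] = None) -> ClusterTree:
    """Re-cluster one leaf into two sub-clusters; all other pixels untouched.

    ``method="gmm2"`` fits a plain two-component mixture to the cluster's
    intensities; ``method="em1"`` uses the spatially blended E-step with the
    neighbourhood average precomputed on the full image, restricted to the
    cluster's pixels.  Children are named by appending digits 1 and 2 to the
    parent id.  Initialization is by the two intensity quantiles (1/4, 3/4)
    of the cluster, so the split is deterministic for a given seed.
    """
    data = image.data if isinstance(image, ImageVolume) else np.asarray(image, float)
    if data.shape != tree.labels.shape:
        raise ValueError("image and labels shapes differ")
    cluster_id = int(cluster_id)
    if cluster_id not in tree.leaves:
        raise ValueError(f"cluster {cluster_id} is not a leaf")
    mask = tree.labels == cluster_id
    vals = data[mask]
    if vals.size < 2 or np.unique(vals).size < 2:
        raise CannotSplitError(f"cluster {cluster_id} has fewer than 2 distinct "
                               "intensities")
    child1, child2 = cluster_id * 10 + 1, cluster_id * 10 + 2
    if child1 in tree.leaves or child2 in tree.leaves:
        raise ValueError(f"child ids {child1}/{child2} already exist")

    init = _quantile_init(vals)
    if method == "gmm2":
        fit = gmm.fit_gmm(vals, 2, init=init, seed=seed)
        sub = fit.labels
    elif method == "em1":
        cfg = config or spatial.SpatialConfig()
        avg = spatial.neighborhood_average(data, cfg)
        beta = spatial.resolve_beta(data, cfg) if cfg.beta is None else cfg.beta
        fit = _fit_subset(vals, avg[mask], init, seed, beta, cfg)
        sub = fit.labels
    else:
        raise ValueError(f"unknown split method {method!r}")
    # order children by mean intensity so naming is stable
    m0 = vals[sub == 0].mean() if np.any(sub == 0) else np.inf
    m1 = vals[sub == 1].mean() if np.any(sub == 1) else np.inf
    lo, hi = (0, 1) if m0 <= m1 else (1, 0)

    out = ClusterTree(labels=tree.labels.copy(), parent=dict(tree.parent),
                      tissue_map=dict(tree.tissue_map))
    out.original_ids = dict(getattr(tree, "original_ids", {}))
    sub_full = np.where(sub == lo, child1, child2)
    out.labels[mask] = sub_full
    out.parent[child1] = cluster_id
    out.parent[child2] = cluster_id
    out.tissue_map.pop(cluster_id, None)
    return out


def _quantile_init(vals: np.ndarray) -> gmm.MixtureParams:
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    if q3 <= q1:
        q1, q3 = vals.min(), vals.max()
    var = max(np.var(vals) / 4.0, gmm.VARIANCE_FLOOR)
    return gmm.MixtureParams.from_scalars([0.5, 0.5], [q1, q3], [var, var])


def _fit_subset(vals, avg_vals, init, seed, beta, cfg):
    X = vals.reshape(-1, 1)
    Xb = avg_vals.reshape(-1, 1)
    out = gmm._fit(X, 2, init, seed, tol=1e-6, max_iter=200, Xb=Xb, beta=beta,
                   normalize_covariance=cfg.normalize_covariance)
    labels = np.argmax(out["responsibilities"], axis=1)
    return gmm.FitResult(params=out["params"], responsibilities=out["responsibilities"],
                         labels=labels, log_likelihood_trace=out["trace"],
                         n_iterations=out["n_iterations"], converged=out["converged"],
                         beta=beta)


def merge_clusters(tree: ClusterTree, assignment: Dict[int, int]) -> LabelVolume:
    """Map every leaf cluster onto its tissue id and return the label volume.

    ``assignment`` must cover every leaf; pixel counts are conserved (the
    sum of tissue sizes equals the sum of leaf sizes).
    """
    leaves = tree.leaves
    for leaf in leaves:
        if leaf not in assignment:
            raise ValueError(f"leaf cluster {leaf} has no tissue assignment")
    out = np.zeros_like(tree.labels)
    for leaf in leaves:
        out[tree.labels == leaf] = int(assignment[leaf])
    return LabelVolume(out)
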