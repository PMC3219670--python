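"""Segmentation evaluation: similarity index, false-positive/negative
ratios and Jaccard, with background exclusion and cluster-to-truth matching.

For truth class X_i and the matched predicted class Y_i:

    rho_i  = 2|X_i ∩ Y_i| / (|X_i| + |Y_i|)        (Dice similarity index)
    rfp_i  = (|Y_i| - |X_i ∩ Y_i|) / |X_i|          (extra pixels)
    rfn_i  = (|X_i| - |X_i ∩ Y_i|) / |X_i|          (lost pixels)
    J_i    = |X_i ∩ Y_i| / |X_i ∪ Y_i|

Both ratios are normalized by the truth class size |X_i|.  Per-volume
indices are unweighted means over the scored classes.  Background handling
follows the usual brain-MRI protocol: the predicted cluster with the lowest
mean grey value is taken as background and excluded from scoring, as is the
truth background class.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import ImageVolume, LabelVolume


def _label_array(x) -> np.ndarray:
    if isinstance(x, LabelVolume):
        return x.labels
    return np.asarray(x)


@dataclass
class EvalReport:
    """Per-class and averaged evaluation indices plus the matching used."""

    per_class: dict
    averages: dict
    matching: dict
    excluded_background: bool
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "averages": self.averages,
            "matching": {str(k): v for k, v in self.matching.items()},
            "excluded_background": self.excluded_background,
            "flags": self.flags,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def table(self) -> str:
        lines = [f"{'class':>8} {'rho':>8} {'rfp':>8} {'rfn':>8} {'jaccard':>8}"]
        for c, v in sorted(self.per_class.items()):
            lines.append(f"{c:>8} {v['rho']:8.4f} {v['rfp']:8.4f} "
                         f"{v['rfn']:8.4f} {v['jaccard']:8.4f}")
        a = self.averages
        lines.append(f"{'average':>8} {a['rho']:8.4f} {a['rfp']:8.4f} "
                     f"{a['rfn']:8.4f} {a['jaccard']:8.4f}")
        return "\n".join(lines)


def _pred_background(pred: np.ndarray, image: Optional[np.ndarray],
                     pred_background: Optional[int]) -> int:
    if pred_background is not None:
        return int(pred_background)
    ids = np.unique(pred)
    if image is not None:
        means = [image[pred == c].mean() for c in ids]
        return int(ids[int(np.argmin(means))])
    return int(ids.min())


def match_clusters(pred, truth, exclude_background: bool = True,
                   image=None, pred_background: Optional[int] = None,
                   truth_background: int = 0) -> dict:
    """Optimal one-to-one maximum-overlap matching of predicted clusters to
    truth classes.

    When background exclusion is on, the predicted background cluster (the
    one with lowest mean intensity when an image is supplied, else
    ``pred_background``, else the lowest id) and the truth background class
    are removed before matching.  Exhaustive search over assignments for up
    to six classes (lexicographically-lowest tie-break), Hungarian beyond.
    Truth classes with no matching cluster map to ``None``.
    """
    P = _label_array(pred)
    T = _label_array(truth)
    if P.shape != T.shape:
        raise ValueError("pred and truth shapes differ")
    img = image.data if isinstance(image, ImageVolume) else (
        np.asarray(image, float) if image is not None else None)
    pred_ids = [int(c) for c in np.unique(P)]
    truth_ids = [int(c) for c in np.unique(T)]
    if exclude_background:
        if isinstance(pred, LabelVolume) and pred.background_id is not None \
                and pred_background is None:
            pred_background = pred.background_id
        bg = _pred_background(P, img, pred_background)
        pred_ids = [c for c in pred_ids if c != bg]
        truth_ids = [c for c in truth_ids if c != truth_background]
    overlap = np.zeros((len(truth_ids), len(pred_ids)), dtype=np.int64)
    for a, tc in enumerate(truth_ids):
        tm = T == tc
        for b, pc in enumerate(pred_ids):
            overlap[a, b] = int(np.count_nonzero(tm & (P == pc)))
    n_t, n_p = overlap.shape
    matching: dict = {}
    if n_p == 0:
        return {tc: None for tc in truth_ids}
    if max(n_t, n_p) <= 6:
        best, best_assign = -1, None
        if n_t <= n_p:
            for cols in itertools.permutations(range(n_p), n_t):
                total = sum(overlap[a, cols[a]] for a in range(n_t))
                if total > best:
                    best, best_assign = total, cols
            for a in range(n_t):
                matching[truth_ids[a]] = pred_ids[best_assign[a]]
        else:
            for rows in itertools.permutations(range(n_t), n_p):
                total = sum(overlap[rows[b], b] for b in range(n_p))
                if total > best:
                    best, best_assign = total, rows
            for b in range(n_p):
                matching[truth_ids[best_assign[b]]] = pred_ids[b]
    else:
        rows, cols = linear_sum_assignment(-overlap)
        for a, b in zip(rows, cols):
            matching[truth_ids[a]] = pred_ids[b]
    for tc in truth_ids:
        matching.setdefault(tc, None)
    return matching


def evaluate(pred, truth, exclude_background: bool = True, image=None,
             pred_background: Optional[int] = None,
             truth_background: int = 0) -> EvalReport:
    """Score a segmentation against ground truth with exact set counting."""
    P = _label_array(pred)
    T = _label_array(truth)
    matching = match_clusters(pred, truth, exclude_background, image,
                              pred_background, truth_background)
    per_class: dict = {}
    flags: list = []
    for tc, pc in sorted(matching.items()):
        X = T == tc
        nX = int(np.count_nonzero(X))
        if nX == 0:
            flags.append(f"truth class {tc} is empty; skipped")
            continue
        if pc is None:
            flags.append(f"truth class {tc} has no matching cluster")
            nY, nI = 0, 0
        else:
            Y = P == pc
            nY = int(np.count_nonzero(Y))
            nI = int(np.count_nonzero(X & Y))
        union = nX + nY - nI
        per_class[tc] = {
            "rho": 2.0 * nI / (nX + nY),
            "rfp": (nY - nI) / nX,
            "rfn": (nX - nI) / nX,
            "jaccard": nI / union if union else 1.0,
        }
    if not per_class:
        raise ValueError("no truth classes to score")
    averages = {k: float(np.mean([v[k] for v in per_class.values()]))
                for k in ("rho", "rfp", "rfn", "jaccard")}
    return EvalReport(per_class=per_class, averages=averages,
                      matching=matching, excluded_background=exclude_background,
                      flags=flags)
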