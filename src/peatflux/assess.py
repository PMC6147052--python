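"""Map-accuracy assessment: confusion matrices, accuracy statistics and
polygon-level percentage-bin agreement between two maps."""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "confusion_matrix", "confusion_from_map", "accuracy_stats",
    "polygon_bin_comparison",
]


def confusion_matrix(
    truth: Sequence, predicted: Sequence, classes: Optional[Sequence] = None
) -> pd.DataFrame:
    """Square count matrix; rows = ground truth, columns = prediction."""
    truth = pd.Series(list(truth))
    predicted = pd.Series(list(predicted))
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lengths differ")
    if classes is None:
        classes = sorted(set(truth) | set(predicted))
    cm = pd.crosstab(truth, predicted).reindex(
        index=classes, columns=classes, fill_value=0
    )
    cm.index.name = "truth"
    cm.columns.name = "predicted"
    return cm.astype(int)


def confusion_from_map(
    points: pd.DataFrame,
    class_map: np.ndarray,
    code_names: dict,
    nodata: int = 255,
    classes: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Confusion matrix of labeled points against a categorical grid.

    ``points`` carries integer ``row``/``col`` grid indices and a
    ``true_class`` label. Off-grid points and points on nodata cells are
    excluded with a warning.
    """
    h, w = class_map.shape
    on_grid = (
        (points["row"] >= 0) & (points["row"] < h)
        & (points["col"] >= 0) & (points["col"] < w)
    )
    if not on_grid.all():
        warnings.warn(f"{int((~on_grid).sum())} points off-grid, excluded")
    pts = points[on_grid]
    codes = class_map[pts["row"].to_numpy(), pts["col"].to_numpy()]
    keep = codes != nodata
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} points on nodata cells, excluded")
    predicted = [code_names[c] for c in codes[keep]]
    return confusion_matrix(pts.loc[keep, "true_class"], predicted, classes=classes)


def accuracy_stats(cm: pd.DataFrame) -> dict:
    """Overall, producer's and user's accuracies (%) and Cohen's kappa.

    Overall = 100 x trace / n. Producer's accuracy for a class is the
    diagonal count over the column total (omission error view); user's is
    over the row total (commission error view). Kappa is the standard
    unweighted chance-corrected agreement; classes with a zero column total
    contribute nothing to expected agreement and have no producer's accuracy.
    """
    m = cm.to_numpy(dtype=float)
    n = m.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(m)
    rows = m.sum(axis=1)
    cols = m.sum(axis=0)
    overall = 100.0 * diag.sum() / n

    producer = {
        c: (100.0 * d / ct if ct > 0 else np.nan)
        for c, d, ct in zip(cm.columns, diag, cols)
    }
    user = {
        c: (100.0 * d / rt if rt > 0 else np.nan)
        for c, d, rt in zip(cm.index, diag, rows)
    }
    p_o = diag.sum() / n
    p_e = float((rows * cols).sum()) / n**2
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return {
        "n": int(n),
        "overall_pct": overall,
        "producer_pct": producer,
        "user_pct": user,
        "kappa": kappa,
    }


def polygon_bin_comparison(
    pcts_a: Sequence[float], pcts_b: Sequence[float], bin_width: float = 10.0
) -> dict:
    """Bin two per-polygon percentage vectors and cross-tabulate.

    Bins are [0,10), [10,20), ..., [90,100]; a value of exactly 100 joins the
    top bin. Returns the count matrix and the share of polygons whose bins
    differ by at most one (the near-1:1-line agreement share).
    """
    a = np.asarray(pcts_a, dtype=float)
    b = np.asarray(pcts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("percentage vectors differ in length")
    for v in (a, b):
        if ((v < 0) | (v > 100)).any():
            raise ValueError("percentages outside [0, 100]")
    nbins = int(round(100 / bin_width))
    bin_a = np.minimum((a // bin_width).astype(int), nbins - 1)
    bin_b = np.minimum((b // bin_width).astype(int), nbins - 1)
    matrix = np.zeros((nbins, nbins), dtype=int)
    np.add.at(matrix, (bin_a, bin_b), 1)
    within_one = float(np.mean(np.abs(bin_a - bin_b) <= 1)) * 100.0 if len(a) else np.nan
    return {
        "matrix": pd.DataFrame(matrix,
                               index=pd.RangeIndex(nbins, name="bin_a"),
                               columns=pd.RangeIndex(nbins, name="bin_b")),
        "within_one_pct": within_one,
        "n_polygons": int(len(a)),
    }
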