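"""Puncta detection, positivity classification and two-channel ratios.

Implements the galectin-3 / LC3 puncta pipeline: a white top-hat transform
(disk structuring element) suppresses the smooth cytoplasmic background and
edge-of-cell accumulation so that only compact bright spots survive
thresholding; detections are size-filtered and assigned to the cell
containing their centroid. A cell is puncta-positive when it carries at
least ``min_puncta`` detections (3 for the lysosomal-leakage readout).

Ratiometric readouts (tfLC3 eGFP/mRFP per punctum; dextran FITC/TMR per
lysosome) are per-object mean-intensity ratios, optionally cleaned with an
iterative Grubbs outlier test applied per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.measure import label as cc_label
from skimage.morphology import disk, white_tophat

from .image import LabelMask, MultiChannelImage

__all__ = [
    "PunctaTable",
    "PositivityResult",
    "detect_puncta",
    "classify_positive",
    "channel_ratio",
    "grubbs_critical",
    "grubbs_filter",
]


@dataclass
class PunctaTable:
    """Detected puncta plus the label image of their pixel support.

    ``df`` has one row per punctum: owning ``cell`` label, centroid
    ``row``/``col``, ``area`` (px^2), detection ``score`` (peak top-hat
    response) and one ``mean_<channel>`` column per image channel.
    """

    df: pd.DataFrame
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.df)

    def counts_per_cell(self, cells: LabelMask) -> pd.Series:
        """Puncta count for every cell in the mask (zeros included)."""
        counts = pd.Series(0, index=pd.Index(cells.ids, name="cell"), dtype=int)
        if len(self.df):
            got = self.df["cell"].value_counts()
            counts.loc[got.index] = got.astype(int)
        return counts


@dataclass
class PositivityResult:
    total_cells: int
    positive_cells: int
    percent_positive: float
    puncta_per_positive: list[int]
    min_puncta: int


def detect_puncta(
    image: MultiChannelImage,
    channel: str,
    cells: LabelMask,
    tophat_radius: float = 5,
    intensity_thresh: float = 15.0,
    min_size: float = 3,
    max_size: float = 400,
) -> PunctaTable:
    """Detect bright puncta inside whole cells via top-hat + threshold.

    The white top-hat with a disk of ``tophat_radius`` px removes any
    structure broader than the disk (flat background, slow gradients, rims
    of accumulated fluorescence at cell edges); remaining peaks above
    ``intensity_thresh`` are labelled, filtered to ``[min_size, max_size]``
    px^2 and assigned to the cell containing their centroid. Detections
    outside any cell are discarded. ``cells`` should come from
    :func:`~lysoquant.segmentation.remove_border_objects` so only whole
    cells are scored.
    """
    if tophat_radius <= 0:
        raise ValueError("tophat_radius must be positive")
    chan = image.channel(channel)
    cols = ["cell", "row", "col", "area", "score"] + [
        f"mean_{c}" for c in image.channels
    ]
    if cells.n_objects == 0:
        return PunctaTable(
            df=pd.DataFrame(columns=cols), labels=np.zeros(chan.shape, np.int32)
        )
    th = white_tophat(chan, footprint=disk(int(round(tophat_radius))))
    bw = th >= intensity_thresh
    labels = cc_label(bw, connectivity=2)
    if labels.max() == 0:
        return PunctaTable(
            df=pd.DataFrame(columns=cols), labels=np.zeros(chan.shape, np.int32)
        )
    ids = np.arange(1, labels.max() + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=ids)
    centroids = np.asarray(ndimage.center_of_mass(bw, labels, index=ids))
    scores = ndimage.maximum(th, labels, index=ids)
    rows = []
    kept = np.zeros_like(labels)
    new_id = 0
    for i, lab in enumerate(ids):
        if not (min_size <= areas[i] <= max_size):
            continue
        r, c = centroids[i]
        cell = int(cells.labels[int(round(r)), int(round(c))])
        if cell == 0:
            continue
        new_id += 1
        kept[labels == lab] = new_id
        rec = {
            "cell": cell,
            "row": r,
            "col": c,
            "area": float(areas[i]),
            "score": float(scores[i]),
        }
        for cname, carr in image.channels.items():
            rec[f"mean_{cname}"] = float(carr[labels == lab].mean())
        rows.append(rec)
    df = pd.DataFrame(rows, columns=cols)
    return PunctaTable(df=df, labels=kept.astype(np.int32))


def classify_positive(
    puncta: PunctaTable, cells: LabelMask, min_puncta: int = 3
) -> PositivityResult:
    """Fraction of cells carrying >= ``min_puncta`` puncta.

    Returns the total and positive cell counts, the percentage positive and
    the puncta count of every positive cell. Zero cells is an error; zero
    positive cells is a valid 0% result.
    """
    if min_puncta < 1:
        raise ValueError("min_puncta must be >= 1")
    if cells.n_objects == 0:
        raise ValueError("no cells to classify")
    counts = puncta.counts_per_cell(cells)
    positive = counts[counts >= min_puncta]
    return PositivityResult(
        total_cells=int(len(counts)),
        positive_cells=int(len(positive)),
        percent_positive=100.0 * len(positive) / len(counts),
        puncta_per_positive=positive.sort_index().tolist(),
        min_puncta=min_puncta,
    )


def channel_ratio(
    objects: PunctaTable | LabelMask,
    image: MultiChannelImage,
    numerator: str,
    denominator: str,
) -> pd.DataFrame:
    """Per-object mean-intensity ratio between two channels.

    ``objects`` is either a :class:`PunctaTable` (per-punctum mode; rows keep
    the owning cell so per-cell means can be taken downstream) or a
    :class:`LabelMask` of organelle ROIs (per-lysosome mode). A zero
    denominator mean yields NaN with ``undefined=True``; the ratio is
    invariant under common rescaling of both channels.
    """
    num = image.channel(numerator)
    den = image.channel(denominator)
    if isinstance(objects, PunctaTable):
        labels = objects.labels
        cell_of = objects.df["cell"].to_numpy() if len(objects.df) else np.array([])
    else:
        labels = objects.labels
        cell_of = None
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("no objects to measure")
    num_means = np.asarray(ndimage.mean(num, labels, index=ids), dtype=float)
    den_means = np.asarray(ndimage.mean(den, labels, index=ids), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den_means > 0, num_means / den_means, np.nan)
    out = pd.DataFrame(
        {
            "object": ids,
            f"mean_{numerator}": num_means,
            f"mean_{denominator}": den_means,
            "ratio": ratio,
            "undefined": den_means <= 0,
        }
    )
    if cell_of is not None and len(cell_of) == len(out):
        out.insert(1, "cell", cell_of)
    return out


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size ``n``.

    Closed form from the Student-t quantile at significance ``alpha/(2n)``
    with ``n - 2`` degrees of freedom:
    ``G = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2))``.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values, alpha: float = 0.0001
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs outlier removal.

    Repeatedly removes the single most extreme point (max ``|x - mean|/SD``;
    ties broken by first index) while its G statistic exceeds the critical
    value at ``alpha`` for the current n, stopping when nothing is removed or
    fewer than 3 points remain. Zero-variance samples and n < 3 are returned
    untouched. Apply per replicate, never on pooled replicates. Returns
    ``(kept, removed)`` with kept values in their original order.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1D")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    keep = np.ones(x.size, dtype=bool)
    while keep.sum() >= 3:
        cur = x[keep]
        sd = cur.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(cur - cur.mean())
        g = dev.max() / sd
        if g <= grubbs_critical(cur.size, alpha):
            break
        worst_local = int(np.argmax(dev))  # first index wins ties
        keep[np.flatnonzero(keep)[worst_local]] = False
    return x[keep], x[~keep]
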