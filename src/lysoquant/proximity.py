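"""Juxtanuclear proximity scoring for organelle markers (LAMP2, EEA1).

The score for one nucleus is the mean marker intensity in the innermost
perinuclear ring divided by the average of the mean intensities in the outer
rings; a value above 1 indicates clustering of the organelle at the nuclear
periphery. Inference is done SuperPlot-style: per-cell scores are reported
for display, but statistics downstream consume per-experiment means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import MultiChannelImage
from .segmentation import RingSet

__all__ = ["ring_means", "proximity_score", "superplot_aggregate"]


def ring_means(
    image: MultiChannelImage, channel: str, rings: RingSet
) -> pd.DataFrame:
    """Arithmetic mean of ``channel`` intensity over each ring of each nucleus.

    Returns a DataFrame indexed by nucleus label with columns ``ring1`` ..
    ``ring{n}``. An empty (fully clipped) ring yields NaN and is noted in the
    ``flags`` column together with any geometry flags from ring construction.
    """
    chan = image.channel(channel)
    ids = rings.ids
    n = rings.n_rings
    out = pd.DataFrame(
        index=pd.Index(ids, name="nucleus"),
        columns=[f"ring{k}" for k in range(1, n + 1)],
        dtype=float,
    )
    for k in range(1, n + 1):
        sel = rings.ring == k
        if not sel.any():
            continue
        sums = ndimage.sum_labels(chan, rings.nucleus * sel, index=ids)
        counts = ndimage.sum_labels(sel.astype(float), rings.nucleus * sel, index=ids)
        with np.errstate(invalid="ignore"):
            out[f"ring{k}"] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    flags = []
    for lab in ids:
        f = list(rings.flags.get(int(lab), []))
        empty = [c for c in out.columns if np.isnan(out.loc[lab, c])]
        if empty:
            f.append("empty:" + ",".join(empty))
        flags.append(";".join(f))
    out["flags"] = flags
    return out


def proximity_score(means: pd.DataFrame) -> pd.DataFrame:
    """Score each nucleus as ring1 / mean(ring2..ringN).

    ``means`` is the output of :func:`ring_means`. Missing outer rings are
    excluded from the average (flagged); a zero or undefined outer-ring
    average yields a NaN score (never +/-inf). The ratio is dimensionless and
    invariant under global rescaling of the channel.
    """
    ring_cols = [c for c in means.columns if c.startswith("ring")]
    outer_cols = ring_cols[1:]
    if not outer_cols:
        raise ValueError("need at least one outer ring")
    res = means.copy()
    outer = means[outer_cols].mean(axis=1, skipna=True)  # mean over present rings
    with np.errstate(invalid="ignore", divide="ignore"):
        score = means["ring1"] / outer
    score[(outer <= 0) | outer.isna() | means["ring1"].isna()] = np.nan
    res["score"] = score
    bad = (outer <= 0) & outer.notna()
    if "flags" in res:
        res.loc[bad, "flags"] = (
            res.loc[bad, "flags"].astype(str).str.cat(["zero_outer"] * int(bad.sum()), sep=";").str.strip(";")
        )
    return res


def superplot_aggregate(
    records: pd.DataFrame,
    value: str = "score",
    experiment: str = "experiment",
) -> tuple[pd.DataFrame, pd.Series]:
    """Split per-cell values by experiment and compute per-experiment means.

    Returns ``(per_cell, per_experiment)`` where ``per_cell`` keeps one row
    per cell (for the SuperPlot scatter) and ``per_experiment`` holds one
    mean per experiment — the unit on which downstream t-tests operate, so a
    3-experiment design contributes exactly 3 values per condition.
    """
    if experiment not in records.columns:
        raise KeyError(f"records lack an {experiment!r} column")
    per_cell = records[[experiment, value]].dropna(subset=[value]).copy()
    if per_cell.empty:
        raise ValueError("no finite values to aggregate")
    per_exp = per_cell.groupby(experiment)[value].mean()
    per_exp.name = f"mean_{value}"
    return per_cell, per_exp
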