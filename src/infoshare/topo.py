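"""Topographic reductions of per-subject connectivity matrices.

Three summaries feed the group statistics:

* **ROI-pair means** — for every unordered pair of the seven scalp ROIs, the
  mean connectivity over all inter-electrode links joining the two regions
  (21 values per subject).
* **Distance profiles** — connectivity of a seed ROI's electrodes to all
  ROI-external electrodes, binned by inter-electrode distance (tertile bins
  for the short/mid/long summary, or a sliding fine grid for p-versus-
  distance curves).
* **Electrode-set means** — mean connectivity between two disjoint electrode
  sets; the building block of the connectivity classifier features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import DistanceBins, Montage, distance_matrix, roi_pairs

__all__ = [
    "DistanceProfile",
    "roi_pair_means",
    "roi_pair_labels",
    "distance_profile",
    "sliding_profile",
    "range_mean",
    "set_pair_mean",
]


def _check_match(c: np.ndarray, m: Montage) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if c.shape[0] != m.n_channels:
        raise ValueError(
            f"matrix has {c.shape[0]} channels but montage has {m.n_channels}"
        )
    return c


def roi_pair_labels() -> list[str]:
    return [f"{a}-{b}" for a, b in roi_pairs()]


def roi_pair_means(c: np.ndarray, m: Montage) -> pd.Series:
    """Mean connectivity for each of the 21 unordered ROI pairs.

    Within-ROI electrode pairs are excluded; only links crossing the two
    regions contribute.
    """
    c = _check_match(c, m)
    members = {roi: [m.index(ch) for ch in m.roi_channels(roi)] for roi in
               {r for pair in roi_pairs() for r in pair}}
    vals = {}
    for ra, rb in roi_pairs():
        if not members[ra] or not members[rb]:
            vals[f"{ra}-{rb}"] = float("nan")  # ROI absent from montage
            continue
        block = c[np.ix_(members[ra], members[rb])]
        vals[f"{ra}-{rb}"] = float(block.mean())
    return pd.Series(vals, name="wsmi")


@dataclass(frozen=True)
class DistanceProfile:
    """Per-bin mean connectivity of one seed ROI for one subject.

    Empty bins carry ``NaN`` means and zero counts rather than zeros, so
    they are distinguishable from genuinely null connectivity.
    """

    roi: str
    bin_edges: tuple[float, ...]  # length n_bins + 1
    means: np.ndarray  # (n_bins,), NaN for empty bins
    counts: np.ndarray  # (n_bins,), connections per bin

    @property
    def bin_centers(self) -> np.ndarray:
        e = np.asarray(self.bin_edges)
        return (e[:-1] + e[1:]) / 2.0

    @property
    def n_bins(self) -> int:
        return len(self.means)


def _roi_connections(
    c: np.ndarray, m: Montage, roi: str
) -> tuple[np.ndarray, np.ndarray]:
    """Values and distances of all links from ROI-internal electrodes to
    every ROI-external electrode (within-ROI links excluded)."""
    internal = [m.index(ch) for ch in m.roi_channels(roi)]
    if not internal:
        raise ValueError(f"ROI {roi} has no electrodes in this montage")
    external = [i for i in range(m.n_channels) if i not in internal]
    if not external:
        raise ValueError(f"ROI {roi} covers the whole montage")
    dmat = distance_matrix(m)
    block = c[np.ix_(internal, external)]
    dists = dmat[np.ix_(internal, external)]
    return block.ravel(), dists.ravel()


def distance_profile(
    c: np.ndarray, m: Montage, roi: str, bins: DistanceBins
) -> DistanceProfile:
    """Bin a seed ROI's external connectivity by electrode distance."""
    c = _check_match(c, m)
    vals, dists = _roi_connections(c, m, roi)
    idx = bins.assign(dists)
    means = np.full(bins.n_bins, np.nan)
    counts = np.zeros(bins.n_bins, dtype=int)
    for b in range(bins.n_bins):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            means[b] = float(vals[sel].mean())
    return DistanceProfile(
        roi=roi, bin_edges=bins.edges, means=means, counts=counts
    )


def sliding_profile(
    c: np.ndarray,
    m: Montage,
    roi: str,
    width: float = 0.15,
    step: float = 0.05,
) -> DistanceProfile:
    """Fine-grained profile with overlapping bins of ``width`` every ``step``.

    Used for p-value-versus-distance curves; the "bin edges" reported are
    the window centers shifted by half a width on either side of the range.
    """
    c = _check_match(c, m)
    vals, dists = _roi_connections(c, m, roi)
    starts = np.arange(0.0, dists.max() - width + step, step)
    means, counts, centers = [], [], []
    for s in starts:
        sel = (dists >= s) & (dists < s + width)
        n = int(sel.sum())
        counts.append(n)
        centers.append(s + width / 2.0)
        means.append(float(vals[sel].mean()) if n else np.nan)
    edges = tuple(np.concatenate([starts, [starts[-1] + width]]))
    return DistanceProfile(
        roi=roi, bin_edges=edges,
        means=np.asarray(means), counts=np.asarray(counts),
    )


def range_mean(
    c: np.ndarray, m: Montage, roi: str, d_min: float, d_max: float
) -> float:
    """Mean connectivity of ROI-anchored links with distance in [d_min, d_max).

    Returns ``NaN`` when no connection falls in the range.
    """
    if not d_min < d_max:
        raise ValueError("require d_min < d_max")
    c = _check_match(c, m)
    vals, dists = _roi_connections(c, m, roi)
    sel = (dists >= d_min) & (dists < d_max)
    if not sel.any():
        return float("nan")
    return float(vals[sel].mean())


def set_pair_mean(
    c: np.ndarray, m: Montage, set_a: list[str], set_b: list[str]
) -> float:
    """Mean connectivity over the |A| x |B| links between two electrode sets."""
    c = _check_match(c, m)
    if not set_a or not set_b:
        raise ValueError("electrode sets must be non-empty")
    if set(set_a) & set(set_b):
        raise ValueError("electrode sets must be disjoint")
    ia = [m.index(ch) for ch in set_a]
    ib = [m.index(ch) for ch in set_b]
    return float(c[np.ix_(ia, ib)].mean())
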