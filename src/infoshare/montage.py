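"""Electrode montages, scalp regions of interest, and inter-electrode geometry.

All topographic analyses in this package are scalp-level and only use the
*relative* geometry of the electrode layout.  Electrodes therefore live on an
idealized unit-radius head sphere (x: left→right, y: posterior→anterior,
z: down→up, all dimensionless) and distances between electrodes are chordal
(straight-line) distances, which range over [0, 2].

Two layouts are provided:

``standard1020``
    The 20 scalp electrodes of the international 10/20 system, placed at the
    classical spherical angles (outer ring on the equator, Cz at the vertex,
    intermediate electrodes on the connecting arcs).

``dense128``
    A deterministic 128-channel cap built from equal-area-style azimuthal
    rings covering the head down to slightly below the equator, labelled
    ``E001``…``E128``.

Every channel is assigned to exactly one of seven scalp regions of interest
(ROIs): left/right frontal (R1/R2), right/left temporal (R3/R6), right/left
posterior (R4/R5) and central (R7).  Assignment is purely geometric, by
elevation and azimuth sectors, so it applies uniformly to both layouts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROI_IDS",
    "ROI_NAMES",
    "Montage",
    "DistanceBins",
    "build_montage",
    "electrode_distance",
    "distance_matrix",
    "tertile_bins",
    "subset_montage",
    "ten_twenty_subset",
    "roi_pairs",
]

ROI_IDS = ("R1", "R2", "R3", "R4", "R5", "R6", "R7")

ROI_NAMES = {
    "R1": "left frontal",
    "R2": "right frontal",
    "R3": "right temporal",
    "R4": "right posterior",
    "R5": "left posterior",
    "R6": "left temporal",
    "R7": "central",
}

# Geometric sector rule (degrees).  Channels at elevation >= _CENTRAL_ELEV
# form the central ROI; the remainder are split by absolute azimuth from the
# anterior axis into frontal / temporal / posterior bands, and by the sign of
# x into left/right.  Exact-midline channels at low elevation break the tie
# to the right hemisphere.
_CENTRAL_ELEV = 40.0
_FRONTAL_AZ = 60.0
_TEMPORAL_AZ = 130.0


class MontageError(ValueError):
    """Unknown layout or channel lookup failure."""


@dataclass(frozen=True)
class Montage:
    """An electrode layout on the unit sphere with a 7-ROI partition."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm rows
    roi_of: dict[str, str]  # channel label -> ROI id in ROI_IDS

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise MontageError(
                f"positions shape {pos.shape} does not match "
                f"{len(self.labels)} labels"
            )
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise MontageError("positions must lie on the unit sphere")
        if set(self.roi_of) != set(self.labels):
            raise MontageError("roi_of must assign every channel exactly once")
        if not set(self.roi_of.values()) <= set(ROI_IDS):
            raise MontageError(f"ROI ids must be within {ROI_IDS}")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise MontageError(f"unknown channel {label!r}") from None

    def roi_channels(self, roi: str) -> tuple[str, ...]:
        """Channels belonging to ``roi``, in montage order."""
        if roi not in ROI_IDS:
            raise MontageError(f"unknown ROI {roi!r}")
        return tuple(lb for lb in self.labels if self.roi_of[lb] == roi)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Montage):
            return NotImplemented
        return (
            self.labels == other.labels
            and np.allclose(self.positions, other.positions, atol=1e-12)
            and self.roi_of == other.roi_of
        )


@dataclass(frozen=True)
class DistanceBins:
    """Ordered distance bins over [edges[0], edges[-1]].

    ``edges`` includes both outer boundaries; ``inner_edges`` are the cut
    points between bins.  Bins are half-open ``[e_i, e_{i+1})`` except the
    last, which includes its right edge.
    """

    edges: tuple[float, ...]
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or len(e) < 2:
            raise ValueError("edges must contain at least two cut points")
        if not np.all(np.diff(e) > 0):
            raise ValueError("edges must be strictly increasing")
        if e[0] < 0:
            raise ValueError("first edge must be >= 0")
        object.__setattr__(self, "edges", tuple(float(x) for x in e))
        object.__setattr__(self, "n_bins", len(e) - 1)

    @property
    def inner_edges(self) -> tuple[float, ...]:
        return self.edges[1:-1]

    @property
    def centers(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    def assign(self, distances: np.ndarray) -> np.ndarray:
        """Bin index for each distance (-1 when outside [first, last] edge)."""
        d = np.asarray(distances, dtype=float)
        idx = np.digitize(d, self.edges[1:-1])
        out = np.where((d < self.edges[0]) | (d > self.edges[-1]), -1, idx)
        # right edge of the final bin is inclusive
        return out.astype(int)


def _sph(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Unit vector; azimuth from the anterior axis toward the right ear."""
    az = np.deg2rad(azimuth_deg)
    el = np.deg2rad(elevation_deg)
    return np.array([np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)])


def _assign_roi(pos: np.ndarray) -> str:
    x, y, z = pos
    elevation = np.rad2deg(np.arcsin(np.clip(z, -1.0, 1.0)))
    if elevation >= _CENTRAL_ELEV:
        return "R7"
    azimuth = abs(np.rad2deg(np.arctan2(x, y)))
    right = x >= 0.0  # exact midline ties break right
    if azimuth < _FRONTAL_AZ:
        return "R2" if right else "R1"
    if azimuth <= _TEMPORAL_AZ:
        return "R3" if right else "R6"
    return "R4" if right else "R5"


def _ten_twenty_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    # outer ring: equator, 10/20 azimuth steps of 36 degrees
    outer = {
        "Fp1": -18, "Fp2": 18, "F7": -54, "F8": 54, "T7": -90, "T8": 90,
        "P7": -126, "P8": 126, "O1": -162, "O2": 162, "Oz": 180,
    }
    for name, az in outer.items():
        pos[name] = _sph(az, 0.0)
    pos["Cz"] = _sph(0.0, 90.0)
    pos["Fz"] = _sph(0.0, 45.0)
    pos["Pz"] = _sph(180.0, 45.0)
    pos["C3"] = _sph(-90.0, 45.0)
    pos["C4"] = _sph(90.0, 45.0)
    # intermediate electrodes sit on the arc between the midline and the
    # outer ring: normalized chord midpoints
    for name, (a, b) in {
        "F3": ("Fz", "F7"), "F4": ("Fz", "F8"),
        "P3": ("Pz", "P7"), "P4": ("Pz", "P8"),
    }.items():
        mid = pos[a] + pos[b]
        pos[name] = mid / np.linalg.norm(mid)
    return pos


_TEN_TWENTY_ORDER = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
)

# dense cap: one vertex channel plus five azimuthal rings; counts scale
# roughly with the ring circumference so coverage is near equal-area
_DENSE_RINGS = ((75.0, 9), (55.0, 20), (35.0, 29), (15.0, 34), (-5.0, 35))


def _dense_positions() -> list[np.ndarray]:
    points = [np.array([0.0, 0.0, 1.0])]
    for elevation, count in _DENSE_RINGS:
        for j in range(count):
            az = -180.0 + (j + 0.5) * 360.0 / count
            points.append(_sph(az, elevation))
    return points


def build_montage(layout: str) -> Montage:
    """Build one of the two supported electrode layouts.

    Parameters
    ----------
    layout
        ``"dense128"`` for the deterministic 128-channel cap or
        ``"standard1020"`` for the 20-channel 10/20 set.
    """
    if layout == "standard1020":
        pos_map = _ten_twenty_positions()
        labels = _TEN_TWENTY_ORDER
        positions = np.array([pos_map[lb] for lb in labels])
    elif layout == "dense128":
        points = _dense_positions()
        labels = tuple(f"E{i + 1:03d}" for i in range(len(points)))
        positions = np.array(points)
    else:
        raise MontageError(f"unknown layout {layout!r}; "
                           "expected 'dense128' or 'standard1020'")
    roi_of = {lb: _assign_roi(p) for lb, p in zip(labels, positions)}
    return Montage(labels=labels, positions=positions, roi_of=roi_of)


def electrode_distance(m: Montage, a: str, b: str) -> float:
    """Chordal distance between two channels (symmetric, in [0, 2])."""
    pa = m.positions[m.index(a)]
    pb = m.positions[m.index(b)]
    return float(np.linalg.norm(pa - pb))


def distance_matrix(m: Montage) -> np.ndarray:
    """Full chordal distance matrix, channels in montage order."""
    diff = m.positions[:, None, :] - m.positions[None, :, :]
    return np.linalg.norm(diff, axis=-1)


def tertile_bins(max_distance: float) -> DistanceBins:
    """Split [0, max_distance] into short/mid/long equal-width ranges."""
    if not max_distance > 0:
        raise ValueError("max_distance must be positive")
    step = max_distance / 3.0
    return DistanceBins(edges=(0.0, step, 2 * step, float(max_distance)))


def subset_montage(m: Montage, keep: list[str] | tuple[str, ...]) -> Montage:
    """Restrict a montage to ``keep`` (order preserved, ROIs unchanged)."""
    keep = tuple(keep)
    unknown = [lb for lb in keep if lb not in m.labels]
    if unknown:
        raise MontageError(f"unknown channels {unknown}")
    if len(set(keep)) != len(keep):
        raise MontageError("duplicate channels in keep list")
    idx = [m.labels.index(lb) for lb in keep]
    return Montage(
        labels=keep,
        positions=m.positions[idx],
        roi_of={lb: m.roi_of[lb] for lb in keep},
    )


def ten_twenty_subset(dense: Montage) -> tuple[str, ...]:
    """Labels of the 20 dense-cap channels closest to 10/20 positions.

    Greedy nearest-position matching; each dense channel is used at most
    once.  Useful for the low-density replication mode when starting from a
    dense recording.
    """
    targets = _ten_twenty_positions()
    taken: set[int] = set()
    chosen: list[str] = []
    for name in _TEN_TWENTY_ORDER:
        d = np.linalg.norm(dense.positions - targets[name], axis=1)
        order = np.argsort(d, kind="stable")
        for i in order:
            if int(i) not in taken:
                taken.add(int(i))
                chosen.append(dense.labels[int(i)])
                break
    return tuple(chosen)


def roi_pairs() -> list[tuple[str, str]]:
    """The 21 unordered ROI pairs, in lexicographic order."""
    return list(itertools.combinations(ROI_IDS, 2))
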