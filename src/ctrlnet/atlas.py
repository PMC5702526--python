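"""Region-of-interest atlas handling for the control-related networks.

The analysis graph is defined by 34 spherical ROIs spanning four
task-control subsystems: the frontoparietal network (FPN), the
cingulo-opercular network (CON), the cerebellar network (CN) and the
default mode network (DMN).  Each region carries an MNI millimetre
coordinate; inter-regional Euclidean distances between sphere centres
classify connections as long-range (> 75 mm) and, from the network
labels, as inter-network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NETWORKS = ("FPN", "CON", "CN", "DMN")

#: connections spanning more than this centre-to-centre distance (mm)
#: are long-range; the cutoff is strict, ties are short-range.
LONG_RANGE_MM = 75.0

#: |x| at or below this (mm) puts a region on the midline.
MIDLINE_MM = 3.0


class AtlasError(ValueError):
    """Raised when an atlas file or region table fails validation."""


@dataclass(frozen=True)
class Region:
    """A single ROI: sphere centre in MNI mm plus a network label."""

    name: str
    abbreviation: str
    coordinate: tuple[float, float, float]
    network: str

    def __post_init__(self) -> None:
        if len(self.coordinate) != 3 or not np.all(np.isfinite(self.coordinate)):
            raise AtlasError(
                f"region {self.abbreviation!r}: coordinate must have 3 finite "
                f"components, got {self.coordinate!r}"
            )
        if self.network not in NETWORKS:
            raise AtlasError(
                f"region {self.abbreviation!r}: unknown network "
                f"{self.network!r} (expected one of {NETWORKS})"
            )

    @property
    def hemisphere(self) -> str:
        """'L', 'R' or 'midline', derived from the sign of x (|x| <= 3 -> midline)."""
        x = self.coordinate[0]
        if abs(x) <= MIDLINE_MM:
            return "midline"
        return "L" if x < 0 else "R"

    @property
    def label(self) -> str:
        """Abbreviation with a hemisphere suffix for lateral regions, e.g. ``IPL.L``."""
        hemi = self.hemisphere
        return self.abbreviation if hemi == "midline" else f"{self.abbreviation}.{hemi}"


@dataclass(frozen=True)
class Atlas:
    """An ordered ROI list; list order defines node indices 0..N-1."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        if len(self.regions) < 2:
            raise AtlasError(f"atlas needs at least 2 regions, got {len(self.regions)}")
        keys = [(r.abbreviation, r.hemisphere) for r in self.regions]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise AtlasError(f"duplicate (abbreviation, hemisphere) pairs: {dupes}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 3) array of MNI mm coordinates in node order."""
        return np.array([r.coordinate for r in self.regions], dtype=float)

    @property
    def networks(self) -> np.ndarray:
        return np.array([r.network for r in self.regions])

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regions]

    def index_of(self, label: str) -> int:
        """Resolve a region label to its node index.

        Accepts either the hemisphere-suffixed form (``IPL.L``) or a bare
        abbreviation when it is unique in the atlas (``retro splen``).
        """
        label = label.strip()
        labels = self.labels
        if label in labels:
            return labels.index(label)
        matches = [i for i, r in enumerate(self.regions) if r.abbreviation == label]
        if len(matches) == 1:
            return matches[0]
        if len(matches) > 1:
            raise AtlasError(
                f"label {label!r} is ambiguous (matches {len(matches)} regions); "
                "use a hemisphere suffix"
            )
        raise AtlasError(f"label {label!r} not found in atlas")

    def network_counts(self) -> dict[str, int]:
        nets, counts = np.unique(self.networks, return_counts=True)
        return dict(zip(nets.tolist(), counts.tolist()))


def load_atlas(path) -> Atlas:
    """Load an atlas from comma- or tab-separated text.

    Requires columns ``name, abbreviation, x, y, z, network``; node index
    order is file row order.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = ["name", "abbreviation", "x", "y", "z", "network"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AtlasError(f"atlas file {path}: missing columns {missing}")
    if len(df) == 0:
        raise AtlasError(f"atlas file {path}: no regions")
    regions = []
    for i, row in df.iterrows():
        coord = []
        for c in ("x", "y", "z"):
            v = pd.to_numeric(pd.Series([row[c]]), errors="coerce").iloc[0]
            if pd.isna(v):
                raise AtlasError(
                    f"atlas file {path}, row {i}: non-numeric coordinate {c}={row[c]!r}"
                )
            coord.append(float(v))
        try:
            regions.append(
                Region(
                    name=str(row["name"]),
                    abbreviation=str(row["abbreviation"]),
                    coordinate=tuple(coord),
                    network=str(row["network"]).strip(),
                )
            )
        except AtlasError as e:
            raise AtlasError(f"atlas file {path}, row {i}: {e}") from e
    return Atlas(regions=tuple(regions))


def is_long_range(d) -> bool | np.ndarray:
    """True iff distance d (mm) is strictly greater than 75."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    out = d > LONG_RANGE_MM
    return bool(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EdgeDistanceTable:
    """Per-pair Euclidean distances and long-range / inter-network flags.

    ``distance``, ``long_range`` and ``inter_network`` are dense symmetric
    N x N arrays (diagonal: 0 / False); ``pairs`` iterates the
    N(N-1)/2 unordered pairs in lexicographic order.
    """

    atlas: Atlas
    distance: np.ndarray = field(repr=False)
    long_range: np.ndarray = field(repr=False)
    inter_network: np.ndarray = field(repr=False)

    @property
    def n_pairs(self) -> int:
        n = self.atlas.n_regions
        return n * (n - 1) // 2

    def pairs(self):
        n = self.atlas.n_regions
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j

    def condensed(self) -> np.ndarray:
        """Distances of the unordered pairs, lexicographic order."""
        iu = np.triu_indices(self.atlas.n_regions, k=1)
        return self.distance[iu]

    def to_frame(self) -> pd.DataFrame:
        labels = self.atlas.labels
        rows = [
            {
                "regionA": labels[i],
                "regionB": labels[j],
                "distance": self.distance[i, j],
                "long_range": bool(self.long_range[i, j]),
                "inter_network": bool(self.inter_network[i, j]),
            }
            for i, j in self.pairs()
        ]
        return pd.DataFrame(rows)


def pairwise_distances(atlas: Atlas) -> EdgeDistanceTable:
    """Euclidean distances between region centres, with edge flags."""
    xyz = atlas.coordinates
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    nets = atlas.networks
    inter = nets[:, None] != nets[None, :]
    long_range = dist > LONG_RANGE_MM
    np.fill_diagonal(long_range, False)
    return EdgeDistanceTable(
        atlas=atlas, distance=dist, long_range=long_range, inter_network=inter
    )
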