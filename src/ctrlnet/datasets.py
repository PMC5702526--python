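"""Bundled reference fixtures.

Two small text tables ship with the package:

* the 34-region control-network atlas (FPN / CON / CN / DMN spheres with
  MNI centre coordinates from the task-control literature);
* the reference hypoconnectivity component — the 30-edge connected set of
  region pairs reported to show reduced connectivity in children with
  ADHD, with its published per-edge p-values, centre-to-centre distances
  and network-pair categories.

The published distance column was computed on a voxel grid and deviates
by up to ~1.3 mm from direct Euclidean distances between the printed
sphere centres; both are available and the published column is kept
verbatim.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .atlas import Atlas, load_atlas

_DATA = resources.files("ctrlnet") / "data"

#: two category labels in the published edge list are truncated
_CATEGORY_FIXES = {"CO": "CON"}


def load_reference_atlas() -> Atlas:
    """The bundled 34-region control-network atlas."""
    with resources.as_file(_DATA / "control_atlas_34.csv") as p:
        return load_atlas(p)


def load_reference_component(atlas: Atlas | None = None) -> pd.DataFrame:
    """The bundled 30-edge hypoconnectivity component.

    Returns a DataFrame with columns ``regionA, regionB, p, distance,
    category`` plus parsed helpers: ``node_a, node_b`` (atlas indices),
    ``network_a, network_b`` (normalized from the category column) and
    ``inter_network``.
    """
    if atlas is None:
        atlas = load_reference_atlas()
    with resources.as_file(_DATA / "hypoconnectivity_component.csv") as p:
        df = pd.read_csv(p)
    df["node_a"] = [atlas.index_of(s) for s in df["regionA"]]
    df["node_b"] = [atlas.index_of(s) for s in df["regionB"]]
    nets = df["category"].str.split("-", expand=True)
    for col, new in ((0, "network_a"), (1, "network_b")):
        df[new] = nets[col].map(lambda s: _CATEGORY_FIXES.get(s, s))
    df["inter_network"] = df["network_a"] != df["network_b"]
    return df


def reference_component_edges(atlas: Atlas | None = None) -> list[tuple[int, int]]:
    """The component as (i, j) node-index pairs, i < j."""
    df = load_reference_component(atlas)
    return [tuple(sorted((a, b))) for a, b in zip(df["node_a"], df["node_b"])]
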