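"""Relative land-use indexes: local buffer proportions minus the regional mean.

Sampling by volunteers is spatially biased toward human-dense areas, so a
collection's raw buffer composition conflates taxon preference with where
people sample.  The relative land-use index controls for this by expressing
each collection's local land-use proportion relative to the mean proportion
over all collections within a regional radius (default 100 km)::

    M_{c,l} = P_{c,l} - (1/R) * sum_{r in N(c)} P_{r,l}

where ``N(c)`` is the set of collections within the regional radius of
collection ``c`` (the focal collection included, so ``R >= 1``).  Collections
with fewer than ``min_neighbours`` (default 30) regional neighbours are
discarded: their regional mean would be too noisy to anchor the index.

When every neighbour's three proportions sum to 1 (no water in any buffer),
the three M values of a collection sum to 0 exactly — the index is a centred
composition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .landuse import LandUseMap, buffer_proportions

__all__ = [
    "neighbour_sets",
    "relative_index",
    "apply_min_neighbour_filter",
    "compute_relative_indexes",
    "M_COLUMNS",
    "P_COLUMNS",
]

P_COLUMNS = ["P_urban", "P_agri", "P_natural"]
M_COLUMNS = ["M_urban", "M_agri", "M_natural"]


def _coords_frame(collections: pd.DataFrame | list) -> pd.DataFrame:
    if isinstance(collections, pd.DataFrame):
        df = collections[["collection_id", "x", "y"]].copy()
    else:
        df = pd.DataFrame(collections, columns=["collection_id", "x", "y"])
    df["collection_id"] = df["collection_id"].astype(str)
    if df["collection_id"].duplicated().any():
        dupes = df.loc[df["collection_id"].duplicated(), "collection_id"]
        raise ValueError(f"duplicate collection ids: {sorted(set(dupes))}")
    xy = df[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite collection coordinates")
    return df


def neighbour_sets(
    collections: pd.DataFrame | list,
    radius: float = 100_000.0,
) -> dict[str, set[str]]:
    """Regional neighbour set of every collection (focal included).

    Membership is Euclidean distance <= ``radius`` (inclusive boundary;
    floating-point ties are accepted as-is).  Returns a mapping
    ``collection_id -> set of neighbour ids``; symmetry and ``R >= 1`` hold
    by construction.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    df = _coords_frame(collections)
    xy = df[["x", "y"]].to_numpy(dtype=float)
    ids = df["collection_id"].to_numpy()
    # All-pairs squared distances; ~2000 collections -> 32 MB, fine.
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    within = d2 <= radius**2
    return {ids[i]: set(ids[within[i]]) for i in range(len(ids))}


def relative_index(
    compositions: pd.DataFrame,
    neighbours: dict[str, set[str]],
    include_focal: bool = True,
) -> pd.DataFrame:
    """Relative land-use index of each collection.

    Parameters
    ----------
    compositions
        One row per collection with columns ``collection_id`` and
        ``P_urban, P_agri, P_natural``.
    neighbours
        Output of :func:`neighbour_sets`; every referenced id must have a
        composition row.
    include_focal
        Whether the focal collection enters its own regional mean (default
        True).  ``False`` is provided for sensitivity analysis; collections
        with no other neighbour then get undefined (NaN) M values.

    Returns the composition table with added ``M_urban, M_agri, M_natural``
    and neighbour-count ``R`` columns.
    """
    comp = compositions.copy()
    comp["collection_id"] = comp["collection_id"].astype(str)
    p = comp.set_index("collection_id")[P_COLUMNS]
    missing = set().union(*neighbours.values()) - set(p.index)
    if missing:
        raise ValueError(
            f"no buffer composition for neighbour collection(s): "
            f"{sorted(missing)}"
        )
    m_rows = np.empty((len(comp), 3))
    r_counts = np.empty(len(comp), dtype=int)
    pvals = p.to_numpy()
    pos = {cid: k for k, cid in enumerate(p.index)}
    for k, cid in enumerate(comp["collection_id"]):
        nb = neighbours[cid]
        if not include_focal:
            nb = nb - {cid}
        r_counts[k] = len(nb) + (0 if include_focal else 1)
        if nb:
            idx = [pos[j] for j in nb]
            regional_mean = pvals[idx].mean(axis=0)
            m_rows[k] = pvals[pos[cid]] - regional_mean
        else:
            m_rows[k] = np.nan
    comp[M_COLUMNS] = m_rows
    comp["R"] = r_counts
    return comp


def apply_min_neighbour_filter(
    table: pd.DataFrame,
    min_neighbours: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the index table into retained and discarded collections.

    A collection is retained when its neighbour count ``R`` (focal included)
    is at least ``min_neighbours`` — the threshold is inclusive.  Returns
    ``(retained, discarded)``; the discarded frame keeps ``collection_id``
    and ``R`` for diagnostics.
    """
    if min_neighbours < 1:
        raise ValueError(f"min_neighbours must be >= 1, got {min_neighbours}")
    keep = table["R"] >= min_neighbours
    retained = table[keep].copy()
    retained["retained"] = 1
    discarded = table.loc[~keep, ["collection_id", "R"]].copy()
    return retained, discarded


def compute_relative_indexes(
    collections: pd.DataFrame,
    lmap: LandUseMap,
    buffer_radius: float = 1000.0,
    regional_radius: float = 100_000.0,
    min_neighbours: int = 30,
    include_focal: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end index stage: buffers, regional means and the R filter.

    ``collections`` needs columns ``collection_id, x, y``.  Returns
    ``(retained, discarded)`` where ``retained`` carries the spec output
    columns: id, coordinates, R, buffer proportions, M values, retained flag.
    """
    df = _coords_frame(collections)
    comps = []
    for row in df.itertuples(index=False):
        bc = buffer_proportions(
            lmap, row.x, row.y, radius=buffer_radius, collection_id=row.collection_id
        )
        comps.append((row.collection_id, row.x, row.y, bc.p_urban, bc.p_agri, bc.p_natural))
    comp = pd.DataFrame(
        comps, columns=["collection_id", "x", "y", *P_COLUMNS]
    )
    nb = neighbour_sets(df, radius=regional_radius)
    table = relative_index(comp, nb, include_focal=include_focal)
    return apply_min_neighbour_filter(table, min_neighbours=min_neighbours)
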