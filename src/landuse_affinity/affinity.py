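"""Taxon affinities, BCa bootstrap intervals and specialist/tolerant/avoider labels.

The affinity of taxon *t* with land-use type *l* is the mean relative
land-use index over the collections where the taxon was recorded::

    A_{t,l} = (1/K) * sum_{c in occupied(t)} M_{c,l}

A positive affinity reflects preference, a negative one avoidance.  Each
affinity gets a 95% bias-corrected accelerated (BCa) bootstrap confidence
interval; the taxon is a *specialist* of land-use ``l`` when the interval is
entirely positive, an *avoider* when entirely negative, and *tolerant* when
the interval overlaps zero (endpoints inclusive).

Taxa are further classed as *frequent* or *infrequent*: infrequent means
present in strictly less than a threshold fraction (default 2%) of the
collections made in *each* land-use type, with collections counted by the
category at the sampling point; presence at or above the threshold in at
least one type makes a taxon frequent.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .landuse import CATEGORIES, Category

__all__ = [
    "frequency_class",
    "frequency_table",
    "affinity",
    "bootstrap_means",
    "bca_from_replicates",
    "bca_interval",
    "classify",
    "classify_taxa",
    "AffinityResult",
    "taxon_rng",
    "LANDUSE_NAMES",
]

LANDUSE_NAMES = ("urban", "agri", "natural")

_ORDERS = ("Coleoptera", "Diptera", "Hymenoptera", "Lepidoptera")


# ---------------------------------------------------------------------------
# Frequency classification

def frequency_class(
    occupancy: np.ndarray | list,
    totals: np.ndarray | list,
    threshold: float = 0.02,
) -> str:
    """Classify one taxon as ``"frequent"`` or ``"infrequent"``.

    ``occupancy[l]`` is the number of occupied collections whose sampling
    point lies in land-use type ``l``; ``totals[l]`` the number of
    collections made in that type.  Infrequent means occupancy/total is
    strictly below ``threshold`` for *all* three types; reaching the
    threshold in at least one type makes the taxon frequent.
    """
    occ = np.asarray(occupancy, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if occ.shape != (3,) or tot.shape != (3,):
        raise ValueError("occupancy and totals must have one entry per land-use type")
    if (occ > tot).any():
        raise ValueError(f"occupancy {occ} exceeds totals {tot}")
    if ((occ > 0) & (tot == 0)).any():
        raise ValueError("non-zero occupancy in a land-use type with zero collections")
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(tot > 0, occ / np.where(tot > 0, tot, 1), 0.0)
    return "frequent" if (rates >= threshold).any() else "infrequent"


def frequency_table(
    taxa: pd.DataFrame,
    observations: pd.DataFrame,
    point_category: pd.Series,
    threshold: float = 0.02,
) -> pd.DataFrame:
    """Per-taxon frequency class over the retained collections.

    Parameters
    ----------
    taxa
        One row per taxon with columns ``taxon_id, order``.
    observations
        Occurrence rows with columns ``collection_id, taxon_id``; rows in
        collections absent from ``point_category`` are ignored (they were
        discarded upstream).
    point_category
        ``collection_id -> Category`` at the sampling point, for retained
        collections.  Collections on excluded (water) cells do not count
        toward any type's total.
    """
    cat = point_category[point_category != Category.EXCLUDED]
    totals = np.array([(cat == c).sum() for c in CATEGORIES], dtype=float)
    obs = observations[observations["collection_id"].isin(cat.index)]
    cat_of = cat.to_dict()
    rows = []
    for taxon_id, grp in obs.groupby("taxon_id", sort=False):
        cats = np.array([cat_of[c] for c in set(grp["collection_id"])])
        occ = np.array([(cats == c).sum() for c in CATEGORIES], dtype=float)
        rows.append((taxon_id, frequency_class(occ, totals, threshold)))
    freq = pd.DataFrame(rows, columns=["taxon_id", "frequency_class"])
    out = taxa.merge(freq, on="taxon_id", how="left")
    # Taxa never observed in a retained collection are trivially infrequent.
    out["frequency_class"] = out["frequency_class"].fillna("infrequent")
    return out


# ---------------------------------------------------------------------------
# Affinity (mean relative index over occupied collections)

def affinity(values: np.ndarray | list) -> float:
    """Mean relative land-use index over a taxon's occupied collections."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("affinity of a taxon with no occupied collections")
    return float(v.mean())


# ---------------------------------------------------------------------------
# BCa bootstrap

def taxon_rng(seed: int, taxon_id: str, landuse: str) -> np.random.Generator:
    """Independent, order-invariant RNG substream for one taxon x land-use.

    The stream is derived from the master seed and stable hashes of the
    taxon id and land-use name, so results do not depend on the order in
    which taxa are evaluated.
    """
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(seed), zlib.crc32(taxon_id.encode()), zlib.crc32(landuse.encode())]
        )
    )


def bootstrap_means(
    values: np.ndarray,
    B: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """``B`` bootstrap replicate means of ``values`` (resampled with replacement)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    out = np.empty(B)
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        idx = rng.integers(0, n, size=(hi - lo, n))
        out[lo:hi] = v[idx].mean(axis=1)
    return out


def _jackknife_acceleration(values: np.ndarray) -> float:
    """Acceleration constant from the skewness of leave-one-out means."""
    v = np.asarray(values, dtype=float)
    n = v.size
    loo = (v.sum() - v) / (n - 1)
    d = loo.mean() - loo
    denom = (d**2).sum() ** 1.5
    if denom == 0.0:
        return 0.0
    return float((d**3).sum() / (6.0 * denom))


def bca_from_replicates(
    values: np.ndarray,
    replicates: np.ndarray,
    confidence: float = 0.95,
    z0: float | None = None,
    a: float | None = None,
) -> tuple[float, float]:
    """BCa interval from a precomputed bootstrap replicate stream.

    ``z0`` and ``a`` may be forced (e.g. both to 0, which reduces the
    interval to the plain percentile interval of the same replicates);
    when ``None`` they are estimated in the standard way: ``z0`` from the
    fraction of replicates strictly below the point estimate (clamped to
    ``[1/(B+1), B/(B+1)]`` before the normal quantile), ``a`` from the
    jackknife leave-one-out skewness.
    """
    v = np.asarray(values, dtype=float)
    reps = np.asarray(replicates, dtype=float)
    theta = v.mean()
    B = reps.size
    if z0 is None:
        prop = float((reps < theta).sum()) / B  # strict: ties not counted
        prop = min(max(prop, 1.0 / (B + 1)), B / (B + 1.0))
        z0 = float(norm.ppf(prop))
    if a is None:
        a = _jackknife_acceleration(v) if v.size > 1 else 0.0
    alpha = 1.0 - confidence
    lo_hi = []
    for z_tail in (norm.ppf(alpha / 2.0), norm.ppf(1.0 - alpha / 2.0)):
        zt = z0 + z_tail
        adj = z0 + zt / (1.0 - a * zt)
        lo_hi.append(float(norm.cdf(adj)))
    low = float(np.quantile(reps, lo_hi[0]))
    high = float(np.quantile(reps, lo_hi[1]))
    return min(low, high), max(low, high)


def bca_interval(
    values: np.ndarray | list,
    confidence: float = 0.95,
    B: int = 9999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval for the mean of ``values``.

    Deterministic given the generator (or integer seed) passed as ``rng``.
    Degenerate inputs — a single value, or all values identical — yield the
    zero-width interval ``(v, v)``; the single-value case additionally warns,
    since no resampling variability exists.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    if v.size == 1:
        warnings.warn(
            "BCa interval of a single value is degenerate", stacklevel=2
        )
        return float(v[0]), float(v[0])
    if np.ptp(v) == 0.0:
        return float(v[0]), float(v[0])
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    reps = bootstrap_means(v, B, rng)
    return bca_from_replicates(v, reps, confidence=confidence)


# ---------------------------------------------------------------------------
# Labels

def classify(ci_low: float, ci_high: float) -> str:
    """Specialist / tolerant / avoider from a confidence interval.

    Entirely positive interval -> specialist; entirely negative -> avoider;
    an interval overlapping zero (endpoints inclusive) -> tolerant.
    """
    if ci_low > ci_high:
        raise ValueError(f"ci_low {ci_low} > ci_high {ci_high}")
    if ci_low > 0.0:
        return "specialist"
    if ci_high < 0.0:
        return "avoider"
    return "tolerant"


@dataclass(frozen=True)
class AffinityResult:
    """Affinity of one taxon with one land-use type, with its BCa label."""

    taxon_id: str
    order: str
    frequency_class: str
    landuse: str
    A: float
    ci_low: float
    ci_high: float
    label: str
    K: int
    B: int
    unstable: bool


def classify_taxa(
    taxa: pd.DataFrame,
    observations: pd.DataFrame,
    index_table: pd.DataFrame,
    seed: int,
    confidence: float = 0.95,
    B: int = 9999,
    min_k: int = 3,
) -> pd.DataFrame:
    """Affinities, BCa intervals and labels for every taxon x land-use.

    Parameters
    ----------
    taxa
        Columns ``taxon_id, order, frequency_class``.
    observations
        Occurrence rows ``collection_id, taxon_id``; occurrences in
        collections absent from ``index_table`` are dropped.
    index_table
        Retained relative-index table with ``collection_id`` and the three
        ``M_*`` columns.
    min_k
        Taxa occupying fewer than this many collections get a degenerate
        interval, the label ``tolerant`` and an ``unstable`` flag rather
        than being excluded.

    Returns one row per taxon x land-use type with columns
    ``taxon_id, order, frequency_class, landuse, A, ci_low, ci_high, label,
    K, B, unstable``.
    """
    m = index_table.set_index("collection_id")[
        ["M_urban", "M_agri", "M_natural"]
    ]
    obs = observations[observations["collection_id"].isin(m.index)]
    occupied = obs.groupby("taxon_id")["collection_id"].agg(lambda s: sorted(set(s)))
    results: list[AffinityResult] = []
    for row in taxa.itertuples(index=False):
        cids = occupied.get(row.taxon_id, [])
        k = len(cids)
        for lu in LANDUSE_NAMES:
            if k == 0:
                continue  # never observed in a retained collection
            values = m.loc[cids, f"M_{lu}"].to_numpy(dtype=float)
            a_hat = affinity(values)
            unstable = k < min_k
            if unstable:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lo, hi = (a_hat, a_hat) if k == 1 else bca_interval(
                        values, confidence, B, taxon_rng(seed, row.taxon_id, lu)
                    )
                label = "tolerant"
            else:
                lo, hi = bca_interval(
                    values, confidence, B, taxon_rng(seed, row.taxon_id, lu)
                )
                label = classify(lo, hi)
            results.append(
                AffinityResult(
                    taxon_id=row.taxon_id,
                    order=row.order,
                    frequency_class=row.frequency_class,
                    landuse=lu,
                    A=a_hat,
                    ci_low=lo,
                    ci_high=hi,
                    label=label,
                    K=k,
                    B=B,
                    unstable=unstable,
                )
            )
    return pd.DataFrame([r.__dict__ for r in results])
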