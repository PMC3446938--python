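"""Synthetic landscapes, collections and occurrence data with ground truth.

The generator emulates the statistical structure of an opportunistic
flower-visitor monitoring scheme: a patchy categorical landscape dominated
by agricultural land with urban and natural patches and a little water;
volunteer sampling locations biased toward urban-dense surroundings; and
taxon occupancy that depends on local land-use composition through a
logistic model with planted, taxon-specific preference coefficients::

    P(taxon t present in collection c) = logistic(beta0_t + sum_l beta_{t,l} P_{c,l})

where ``P_{c,l}`` is the buffer composition around the collection — the
same covariate scale the analysis pipeline measures, so planted
preferences are recoverable as affinities.  Occupancy (presence), not
abundance, is simulated: picture counts are 1 per occurrence.

Everything is deterministic given the master seed; stages (landscape,
collections, observations) draw from independent substreams derived from
the master seed by fixed per-stage offsets, so any stage can be
regenerated on its own.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve
from scipy.special import expit

from .landuse import Category, LandUseMap, write_ascii_grid

__all__ = [
    "SimulationConfig",
    "default_taxa",
    "generate_landscape",
    "generate_collections",
    "generate_observations",
    "export_ground_truth",
    "generate_dataset",
]

_ORDERS = ("Coleoptera", "Diptera", "Hymenoptera", "Lepidoptera")

#: Raw level-1 code written to the ASCII grid for each generated category.
_RAW_CODE = {
    Category.URBAN: 1,
    Category.AGRICULTURAL: 2,
    Category.NATURAL: 3,
    Category.EXCLUDED: 5,
}

_STAGE_OFFSET = {"landscape": 1, "collections": 2, "observations": 3}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STAGE_OFFSET[stage]])
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the packaged synthetic scenario.

    Defaults describe the standard scenario: a 30 x 30 km landscape of
    100-m cells mixing 10% urban, 55% agricultural, 33% natural and 2%
    water at a 1.5-km patch scale; 2000 collections with urban sampling
    bias 2; and 160 taxa (40 frequent-tier, 120 infrequent-tier) across
    four insect orders with planted preference coefficients of +/-6.
    """

    n_rows: int = 300
    n_cols: int = 300
    cell_size: float = 100.0
    weights: tuple[float, float, float, float] = (0.10, 0.55, 0.33, 0.02)
    patch_scale: float = 1500.0
    n_collections: int = 2000
    urban_bias: float = 2.0
    taxa: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"mixing weights must be non-negative and sum to 1, got {self.weights}"
            )
        if self.n_collections < 1:
            raise ValueError("n_collections must be >= 1")
        if self.urban_bias < 0:
            raise ValueError("urban_bias must be >= 0")

    def resolved_taxa(self) -> pd.DataFrame:
        return self.taxa if self.taxa is not None else default_taxa()

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["taxa"] = "default" if self.taxa is None else "custom"
        d["weights"] = list(self.weights)
        return d


def default_taxa(
    n_frequent_per_order: int = 10,
    n_infrequent_per_order: int = 30,
    beta0_frequent: float = -2.0,
    beta0_infrequent_neutral: float = -5.0,
    beta0_infrequent_specialist: float = -10.5,
    effect: float = 6.0,
) -> pd.DataFrame:
    """The standard planted community: per order, a balanced preference pattern.

    Every block of 10 taxa holds one specialist and one avoider of each of
    the three land-use types (coefficient +/- ``effect`` on that type's
    buffer proportion, 0 elsewhere) plus four fully neutral taxa.  Frequent-
    tier taxa get a baseline logit giving roughly 10-25% occupancy.  The
    infrequent tier must stay below a 2% presence rate in *every* land-use
    type; a positive planted preference boosts occupancy by up to
    ``effect`` logits in near-pure buffers of the preferred type, so
    infrequent specialists need a baseline low enough to absorb that boost,
    while avoiders (boosted nowhere) share the neutral baseline.
    """
    pattern = [
        ("urban", +effect), ("urban", -effect),
        ("agri", +effect), ("agri", -effect),
        ("natural", +effect), ("natural", -effect),
        (None, 0.0), (None, 0.0), (None, 0.0), (None, 0.0),
    ]
    rows = []
    for order in _ORDERS:
        prefix = order[0]
        specs = ["F"] * n_frequent_per_order + ["I"] * n_infrequent_per_order
        for k, tier in enumerate(specs):
            axis, beta = pattern[k % len(pattern)]
            betas = {f"beta_{lu}": 0.0 for lu in ("urban", "agri", "natural")}
            if axis is not None:
                betas[f"beta_{axis}"] = beta
            if tier == "F":
                beta0 = beta0_frequent
            elif axis is not None and beta > 0:
                beta0 = beta0_infrequent_specialist
            else:
                beta0 = beta0_infrequent_neutral
            rows.append(
                {
                    "taxon_id": f"{prefix}{tier}{k + 1:03d}",
                    "order": order,
                    "beta0": beta0,
                    **betas,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Landscape

def generate_landscape(config: SimulationConfig, seed: int | None = None) -> LandUseMap:
    """Patchy categorical landscape matching the configured mixing weights.

    One smooth latent field per category (white noise smoothed at the patch
    scale) is rank-thresholded sequentially so realised category fractions
    match the weights to within rounding (a fraction of one cell).
    """
    rng = _stage_rng(config.seed if seed is None else seed, "landscape")
    shape = (config.n_rows, config.n_cols)
    sigma = config.patch_scale / config.cell_size
    cats_in_order = (
        Category.EXCLUDED,  # water first: carves lakes out of the latent field
        Category.URBAN,
        Category.AGRICULTURAL,
        Category.NATURAL,
    )
    w = dict(
        zip(
            (Category.URBAN, Category.AGRICULTURAL, Category.NATURAL, Category.EXCLUDED),
            config.weights,
        )
    )
    cells = np.full(shape, -1, dtype=np.int8)
    n_total = cells.size
    remaining = n_total
    for cat in cats_in_order[:-1]:
        target = int(round(w[cat] * n_total))
        target = min(target, remaining)
        if target > 0:
            latent = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
            latent = np.where(cells == -1, latent, -np.inf)
            idx = np.argpartition(latent.ravel(), -target)[-target:]
            cells.ravel()[idx] = cat
        remaining -= target
    cells[cells == -1] = cats_in_order[-1]
    return LandUseMap(origin_x=0.0, origin_y=0.0, cell_size=config.cell_size, cells=cells)


# ---------------------------------------------------------------------------
# Collections

def _urban_buffer_field(lmap: LandUseMap, radius: float) -> np.ndarray:
    """Urban buffer proportion at every cell centre, via disc convolution."""
    r_cells = radius / lmap.cell_size
    half = int(np.ceil(r_cells))
    ax = np.arange(-half, half + 1)
    disc = (ax[:, None] ** 2 + ax[None, :] ** 2) <= r_cells**2
    disc = disc.astype(float)
    urban = (lmap.cells == Category.URBAN).astype(float)
    num = fftconvolve(urban, disc, mode="same")
    den = fftconvolve(np.ones_like(urban), disc, mode="same")
    return np.clip(num / den, 0.0, 1.0)


def generate_collections(
    lmap: LandUseMap,
    n: int,
    urban_bias: float,
    seed: int,
    buffer_radius: float = 1000.0,
) -> pd.DataFrame:
    """Sampling locations biased toward urban-dense surroundings.

    Candidate points are uniform over non-excluded cells (a uniform offset
    within a uniformly chosen cell) and accepted with probability
    proportional to ``exp(urban_bias * u)`` where ``u`` is the urban
    proportion of the surrounding 1-km buffer; ``urban_bias = 0`` recovers
    uniform sampling.  Returns exactly ``n`` collections with deterministic
    ids, synthetic dates within one field season, and observer ids.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    valid = np.argwhere(lmap.cells != Category.EXCLUDED)
    if valid.size == 0:
        raise ValueError("map is entirely excluded (water): nowhere to sample")
    rng = _stage_rng(seed, "collections")
    u_field = _urban_buffer_field(lmap, buffer_radius)
    u_max = float(u_field[valid[:, 0], valid[:, 1]].max())
    xs, ys = [], []
    while len(xs) < n:
        batch = max(2 * (n - len(xs)), 64)
        pick = rng.integers(0, len(valid), size=batch)
        ij = valid[pick]
        accept = rng.random(batch) < np.exp(
            urban_bias * (u_field[ij[:, 0], ij[:, 1]] - u_max)
        )
        ij = ij[accept]
        off = rng.random((len(ij), 2))
        xs.extend(lmap.origin_x + (ij[:, 1] + off[:, 0]) * lmap.cell_size)
        ys.extend(lmap.origin_y + (ij[:, 0] + off[:, 1]) * lmap.cell_size)
    xs, ys = np.asarray(xs[:n]), np.asarray(ys[:n])
    day = rng.integers(0, 120, size=n)  # one May-August field season
    observer = rng.integers(1, max(2, n // 5), size=n)
    return pd.DataFrame(
        {
            "collection_id": [f"C{k + 1:05d}" for k in range(n)],
            "x": xs,
            "y": ys,
            "date": pd.to_datetime("2010-05-01")
            + pd.to_timedelta(day, unit="D"),
            "observer_id": [f"obs{o:04d}" for o in observer],
        }
    )


# ---------------------------------------------------------------------------
# Observations

def generate_observations(
    compositions: pd.DataFrame,
    taxa: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Bernoulli occupancy draws for every taxon x collection pair.

    ``compositions`` needs ``collection_id, P_urban, P_agri, P_natural``;
    ``taxa`` needs ``taxon_id, order, beta0, beta_urban, beta_agri,
    beta_natural``.  Presence is independent across pairs with probability
    ``logistic(beta0 + beta . P)``; one picture per occurrence.
    """
    required = {"beta0", "beta_urban", "beta_agri", "beta_natural"}
    if not required <= set(taxa.columns):
        raise ValueError(f"taxa table missing columns: {sorted(required - set(taxa.columns))}")
    rng = _stage_rng(seed, "observations")
    P = compositions[["P_urban", "P_agri", "P_natural"]].to_numpy(dtype=float)
    beta = taxa[["beta_urban", "beta_agri", "beta_natural"]].to_numpy(dtype=float)
    logits = taxa["beta0"].to_numpy(dtype=float)[:, None] + beta @ P.T
    present = rng.random(logits.shape) < expit(logits)
    t_idx, c_idx = np.nonzero(present)
    return pd.DataFrame(
        {
            "collection_id": compositions["collection_id"].to_numpy()[c_idx],
            "taxon_id": taxa["taxon_id"].to_numpy()[t_idx],
            "taxon_order": taxa["order"].to_numpy()[t_idx],
            "picture_count": 1,
        }
    )


# ---------------------------------------------------------------------------
# Ground truth

def export_ground_truth(taxa: pd.DataFrame, margin: float = 1.0) -> pd.DataFrame:
    """Expected label per taxon x land-use from the planted coefficients.

    A coefficient above ``margin`` plants a specialist of that land-use,
    below ``-margin`` an avoider, and within the margin no directional
    preference.  ``neutral_all`` flags taxa neutral on *all three* axes —
    the only taxa for which a tolerant label is expected everywhere, since
    a strong preference on one axis induces realised avoidance on the
    compositionally coupled ones.
    """
    if margin <= 0:
        raise ValueError("margin must be > 0")
    out = taxa[["taxon_id", "order", "beta0"]].copy()
    neutral = np.ones(len(taxa), dtype=bool)
    for lu in ("urban", "agri", "natural"):
        b = taxa[f"beta_{lu}"].to_numpy(dtype=float)
        out[f"expected_{lu}"] = np.select(
            [b > margin, b < -margin], ["specialist", "avoider"], "tolerant"
        )
        neutral &= np.abs(b) <= margin
    out["neutral_all"] = neutral
    return out


# ---------------------------------------------------------------------------
# Full dataset

def generate_dataset(
    config: SimulationConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Generate the full synthetic dataset, optionally writing it to disk.

    Returns a dict with keys ``map``, ``collections``, ``observations``,
    ``taxa``, ``ground_truth``.  When ``outdir`` is given, writes the exact
    text formats the pipeline reads: ``landscape.asc`` (raw level-1 codes),
    ``collections.csv``, ``observations.csv``, ``ground_truth.csv`` and a
    ``sim_config.json`` snapshot.  Byte-identical for identical config+seed.
    """
    config = config or SimulationConfig()
    lmap = generate_landscape(config)
    coll = generate_collections(
        lmap, config.n_collections, config.urban_bias, config.seed
    )
    # Buffer compositions for the occupancy model: cheap approximate field
    # lookup is NOT used here; the exact per-point buffer is what the
    # pipeline later measures, so the planted preferences live on that scale.
    from .landuse import buffer_proportions

    P = np.array(
        [
            buffer_proportions(lmap, r.x, r.y).as_array()
            for r in coll.itertuples(index=False)
        ]
    )
    comps = coll[["collection_id"]].copy()
    comps[["P_urban", "P_agri", "P_natural"]] = P
    taxa = config.resolved_taxa()
    obs = generate_observations(comps, taxa, config.seed)
    truth = export_ground_truth(taxa)
    bundle = {
        "map": lmap,
        "collections": coll,
        "observations": obs,
        "taxa": taxa,
        "ground_truth": truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        raw = np.vectorize(lambda c: _RAW_CODE[Category(int(c))])(lmap.cells)
        write_ascii_grid(
            outdir / "landscape.asc", raw, lmap.origin_x, lmap.origin_y, lmap.cell_size
        )
        coll_out = coll.copy()
        coll_out["date"] = coll_out["date"].dt.strftime("%Y-%m-%d")
        coll_out.to_csv(outdir / "collections.csv", index=False)
        obs.to_csv(outdir / "observations.csv", index=False)
        truth.to_csv(outdir / "ground_truth.csv", index=False)
        (outdir / "sim_config.json").write_text(
            json.dumps(config.snapshot(), indent=2, sort_keys=True, default=str) + "\n"
        )
    return bundle
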