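"""End-to-end orchestration: raster -> indexes -> affinities -> group tests.

A run is fully described by a :class:`RunConfig`; identical config + seed
produce byte-identical output bundles (no timestamps enter any output, and
the run id is a hash of the configuration).  Analyst-facing counts —
collections discarded by the minimum-neighbour rule, occurrences dropped
with them, taxa per frequency class — are logged at INFO and recorded in
the run metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .affinity import classify_taxa, frequency_table
from .group_stats import (
    RESPONSES,
    anova_type3_backward,
    build_occurrence_table,
    manova_type3,
    order_affinity_summary,
    tukey_letters,
)
from .io import read_collections, read_observations
from .landuse import Category, LandUseMap, landuse_at_point, read_ascii_grid
from .relative_index import compute_relative_indexes

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

_LU_OF_RESPONSE = dict(zip(RESPONSES, ("urban", "agri", "natural")))


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one analysis run.

    Defaults mirror the standard protocol: 1-km buffers, a 100-km regional
    radius with a minimum of 30 neighbouring collections, a 2% frequency
    threshold on per-land-use presence rates, 95% BCa intervals from 9999
    bootstrap replicates, and alpha 0.05 for the group tests.
    """

    landscape_path: str | Path
    collections_path: str | Path
    observations_path: str | Path
    output_dir: str | Path
    buffer_radius: float = 1000.0
    regional_radius: float = 100_000.0
    min_neighbours: int = 30
    frequency_threshold: float = 0.02
    confidence: float = 0.95
    bootstrap_B: int = 9999
    alpha: float = 0.05
    seed: int = 0
    include_focal: bool = True
    force: bool = False

    def __post_init__(self) -> None:
        if self.buffer_radius <= 0 or self.regional_radius <= 0:
            raise ValueError("radii must be > 0")
        if not 0 < self.frequency_threshold < 1:
            raise ValueError("frequency_threshold must be in (0, 1)")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("landscape_path", "collections_path", "observations_path", "output_dir"):
            d[k] = str(d[k])
        d.pop("force")  # overwrite permission is operational, not analytical
        return d

    @property
    def run_id(self) -> str:
        payload = json.dumps(self.snapshot(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s: starting", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("landuse")
def _load_inputs(config: RunConfig):
    lmap = read_ascii_grid(config.landscape_path)
    collections = read_collections(config.collections_path)
    observations = read_observations(config.observations_path)
    return lmap, collections, observations


@_stage("relative_index")
def _index_stage(config: RunConfig, lmap: LandUseMap, collections: pd.DataFrame):
    retained, discarded = compute_relative_indexes(
        collections,
        lmap,
        buffer_radius=config.buffer_radius,
        regional_radius=config.regional_radius,
        min_neighbours=config.min_neighbours,
        include_focal=config.include_focal,
    )
    logger.info(
        "stage relative_index: %d retained, %d discarded (R < %d)",
        len(retained), len(discarded), config.min_neighbours,
    )
    return retained, discarded


@_stage("affinity_classification")
def _affinity_stage(
    config: RunConfig,
    lmap: LandUseMap,
    retained: pd.DataFrame,
    observations: pd.DataFrame,
):
    if retained.empty:
        raise PipelineError(
            "stage 'affinity_classification' failed: no collections survived "
            f"the minimum-neighbour filter (min_neighbours={config.min_neighbours}); "
            "nothing to classify"
        )
    point_cat = pd.Series(
        {
            r.collection_id: landuse_at_point(lmap, r.x, r.y)
            for r in retained.itertuples(index=False)
        }
    )
    n_water = int((point_cat == Category.EXCLUDED).sum())
    if n_water:
        logger.info(
            "%d retained collection(s) sit on excluded (water) cells and do "
            "not count toward any land-use type's totals", n_water,
        )
    taxa = (
        observations[["taxon_id", "taxon_order"]]
        .drop_duplicates()
        .rename(columns={"taxon_order": "order"})
        .reset_index(drop=True)
    )
    taxa = frequency_table(
        taxa, observations, point_cat, threshold=config.frequency_threshold
    )
    counts = taxa["frequency_class"].value_counts().to_dict()
    logger.info("stage affinity_classification: taxa per class %s", counts)
    results = classify_taxa(
        taxa,
        observations,
        retained,
        seed=config.seed,
        confidence=config.confidence,
        B=config.bootstrap_B,
    )
    return taxa, results


@_stage("group_stats")
def _group_stage(
    config: RunConfig,
    observations: pd.DataFrame,
    retained: pd.DataFrame,
    discarded: pd.DataFrame,
    taxa: pd.DataFrame,
):
    occ = build_occurrence_table(
        observations, retained, taxa,
        discarded_ids=set(discarded["collection_id"].astype(str)),
    )
    # Degenerate designs (a factor with one observed level) keep whatever
    # terms remain testable rather than aborting the run.
    terms = ["order", "frequency_class", "order:frequency_class"]
    if occ["frequency_class"].nunique() < 2:
        terms = ["order"]
    if occ["order"].nunique() < 2:
        terms = [t for t in terms if t != "order" and ":" not in t]
    manova_rows = [
        {
            "term": t.term, "df_num": t.df_num, "df_den": t.df_den,
            "F": t.F, "p": t.p,
        }
        for t in manova_type3(occ, terms=terms)
    ]
    table2_rows = []
    fig2 = order_affinity_summary(occ)
    fig2["letters"] = ""
    for resp in RESPONSES:
        if terms == ["order", "frequency_class", "order:frequency_class"]:
            model, results = anova_type3_backward(occ, resp, alpha=config.alpha)
        else:  # degenerate factorial: report the testable terms unreduced
            from .group_stats import _anova_type3  # noqa: PLC0415

            results = _anova_type3(occ, resp, terms) if terms else []
            model = None
        for t in results:
            table2_rows.append(
                {
                    "response": resp, "term": t.term, "df_num": t.df_num,
                    "df_den": t.df_den, "F": t.F, "p": t.p,
                    "retained": int(t.retained),
                }
            )
        if occ["order"].nunique() >= 2:
            letters = tukey_letters(
                occ, resp, factor="order", alpha=config.alpha, model=model
            )
            lu = _LU_OF_RESPONSE[resp]
            lmapper = dict(zip(letters["level"], letters["letters"]))
            sel = fig2["landuse"] == lu
            fig2.loc[sel, "letters"] = fig2.loc[sel, "order"].map(lmapper)
    return occ, pd.DataFrame(manova_rows), pd.DataFrame(table2_rows), fig2


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and write the output bundle.

    Outputs under ``config.output_dir``: ``relative_index.csv`` (all
    collections, discarded rows carry empty M values and retained=0),
    ``affinity.csv``, ``manova.csv``, ``anova_table.csv``,
    ``group_summary.csv`` and ``run_metadata.json``.  Refuses to overwrite
    an existing run unless ``force`` is set.  Returns the result bundle as
    a dict of DataFrames.
    """
    outdir = Path(config.output_dir)
    meta_path = outdir / "run_metadata.json"
    if meta_path.exists() and not config.force:
        raise PipelineError(
            f"output directory {outdir} already holds a run "
            f"(run_metadata.json present); pass force=True / --force to overwrite"
        )
    lmap, collections, observations = _load_inputs(config)
    retained, discarded = _index_stage(config, lmap, collections)
    taxa, affinities = _affinity_stage(config, lmap, retained, observations)
    occ, manova_df, table2, fig2 = _group_stage(
        config, observations, retained, discarded, taxa
    )

    outdir.mkdir(parents=True, exist_ok=True)
    full_index = pd.concat(
        [retained, discarded.assign(retained=0)], ignore_index=True
    )
    header = f"# run_id: {config.run_id}\n"
    for name, df in (
        ("relative_index.csv", full_index),
        ("affinity.csv", affinities),
        ("manova.csv", manova_df),
        ("anova_table.csv", table2),
        ("group_summary.csv", fig2),
    ):
        with (outdir / name).open("w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    metadata = {
        "run_id": config.run_id,
        "package_version": __version__,
        "config": config.snapshot(),
        "counts": {
            "collections_total": int(len(collections)),
            "collections_retained": int(len(retained)),
            "collections_discarded": int(len(discarded)),
            "occurrences": int(len(occ)),
            "taxa_frequent": int((taxa["frequency_class"] == "frequent").sum()),
            "taxa_infrequent": int((taxa["frequency_class"] == "infrequent").sum()),
        },
    }
    meta_path.write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    return {
        "relative_index": full_index,
        "retained": retained,
        "discarded": discarded,
        "taxa": taxa,
        "affinity": affinities,
        "occurrences": occ,
        "manova": manova_df,
        "anova_table": table2,
        "group_summary": fig2,
        "metadata": metadata,
    }
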