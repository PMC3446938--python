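# landuse-affinity

Quantify the affinity of flower-visiting insects with urban, agricultural
and natural land-use from opportunistic (citizen-science style) occurrence
records, and classify each taxon as a **specialist**, **tolerant** or
**avoider** of each land-use type.

Opportunistic monitoring schemes sample where volunteers live, i.e.
disproportionately in human-dense landscapes. Comparing a taxon's
surroundings to the *whole* study region would therefore confound taxon
preference with observer placement. This package implements the standard
fix: every sampling event ("collection") is characterised *relative to the
collections sampled around it*.

## The statistics

For collection *c* and land-use type *l* ∈ {urban, agricultural, natural},
with *P*<sub>c,l</sub> the proportion of type *l* in a 1-km buffer around
the collection, the **relative land-use index** is

> *M*<sub>c,l</sub> = *P*<sub>c,l</sub> − (1/R) Σ<sub>r∈N(c)</sub> *P*<sub>r,l</sub>

where *N(c)* are the *R* collections within 100 km of *c* (the focal
collection included). Collections with *R* < 30 are discarded. Land-use
categories come from a level-1 land-cover raster: artificial surfaces →
urban, agricultural areas → agricultural, forests/semi-natural areas and
wetlands → natural, water bodies excluded (they still count toward buffer
area, so the three proportions sum to < 1 near water; elsewhere the three
*M* values of a collection sum to 0).

The **affinity** of taxon *t* with type *l* is the mean index over the *K*
collections where the taxon was recorded:

> *A*<sub>t,l</sub> = (1/K) Σ<sub>c∈occupied(t)</sub> *M*<sub>c,l</sub>

Each affinity gets a 95% **BCa** (bias-corrected accelerated) bootstrap
confidence interval (default B = 9999 replicates, one deterministic RNG
substream per taxon × land-use). Interval entirely positive → specialist;
entirely negative → avoider; overlapping zero → tolerant. Taxa are also
classed **frequent**/**infrequent**: infrequent means present in < 2% of
the collections made in every land-use type (by the category at the
sampling point). Order-level differences are tested with a type-III MANOVA
(Pillai's trace) and three type-III ANOVAs on occurrence-level *M* values
under sum-to-zero contrasts, reduced by backward elimination, with Tukey
HSD letters among orders.

Because real schemes rarely deposit raw data, the package ships a
synthetic-data generator: a patchy categorical landscape, urban-biased
sampling locations, and logistic occupancy with planted taxon preferences
(±6 logits on a buffer proportion), so the whole pipeline is testable
against known ground truth.

## Worked example

```sh
landuse-affinity simulate --outdir demo/data --seed 42 \
    --n-collections 500 --grid-size 150
landuse-affinity run-all \
    --landscape demo/data/landscape.asc \
    --collections demo/data/collections.csv \
    --observations demo/data/observations.csv \
    --outdir demo/out --seed 42 --bootstrap-b 1999 --min-neighbours 5
```

prints the analyst-facing counts

```json
{
  "collections_discarded": 0,
  "collections_retained": 500,
  "collections_total": 500,
  "occurrences": 4200,
  "taxa_frequent": 48,
  "taxa_infrequent": 95
}
```

(nothing is discarded here: on a 15-km synthetic map every collection has
all 500 others within 100 km) and writes `relative_index.csv`,
`affinity.csv`, `manova.csv`, `anova_table.csv`, `group_summary.csv` and
`run_metadata.json`. The first classified taxon in `affinity.csv`:

```
taxon_id,order,frequency_class,landuse,A,ci_low,ci_high,label,K,B,unstable
CF001,Coleoptera,frequent,urban,0.3310,0.2798,0.3765,specialist,213,1999,False
CF001,Coleoptera,frequent,agri,-0.1925,-0.2313,-0.1453,avoider,213,1999,False
```

`CF001` was planted as an urban specialist: its occupied collections are on
average 33 percentage points richer in urban cover than their regional
context, the interval excludes zero → urban specialist (and, land-use
proportions being compositional, an agricultural avoider). Reruns with the
same config and seed are byte-identical; an existing run is never
overwritten without `--force`.

The same machinery is available as a library (`landuse_affinity.run_pipeline`,
or the stage functions `buffer_proportions`, `relative_index`,
`classify_taxa`, `anova_type3_backward`, ...).

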