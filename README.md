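# calciphile

Soil-niche analysis of georeferenced plant-occurrence records. The package
links specimen records to a gridded soil database (a mapping-unit raster plus
one attribute record per unit), summarizes topsoil/subsoil pH and CaCO₃
distributions, predicts lime-tolerant taxa with an upper-quartile threshold
rule (UQ pH > 7.2 **and** UQ CaCO₃ > 2 % weight), and validates the prediction
with a Yates-corrected chi-square contingency test. A first-class synthetic
data module generates landscapes, taxa with known ground-truth tolerance,
specimen records and gazetteers, so the whole pipeline is testable offline.

## Components

| module | what it does |
| --- | --- |
| `calciphile.synthetic` | soil landscapes (multimodal pH, CaCO₃ coupled to pH, excluded surface classes, missing subsoil), taxa with distinct niches, specimen placement, noisy gazetteers |
| `calciphile.geodesy` | exact-label gazetteer geocoding, iterative Vincenty inverse distance on WGS84, geocoding accuracy statistics |
| `calciphile.soil_link` | point→cell lookup (half-open cells), attribute join, cleaning rules with a removal ledger (out-of-region, excluded surface, missing subsoil) |
| `calciphile.soil_classes` | pH classes (<4.5, 4.5–5.5, 5.5–7.2, 7.2–8.5, >8.5) and CaCO₃ classes (<2, 2–5, 5–15, >15); cell/specimen/taxon distribution tables and per-value histograms |
| `calciphile.tolerance` | per-taxon quartiles (linear interpolation between order statistics, min 10 specimens), UQ threshold predictions, lime/non-lime contingency table, 2×2 chi-square, taxonomy summaries |
| `calciphile.density` | quartic-kernel density surface of occurrences, exported as an ASCII grid |
| `calciphile.pipeline` | end-to-end orchestration with a reconciling run manifest |

All intermediates are plain text: TSV tables and ESRI ASCII grids.

## CLI

Run the whole synthetic pipeline in one go:

```sh
calciphile run --out run_out --seed 1
```

or stage by stage:

```sh
calciphile simulate --out sim --seed 1
calciphile geocode  --specimens sim/specimens.tsv --gazetteer sim/gazetteer.tsv --out sim/geocoded.tsv
calciphile link     --specimens sim/geocoded.tsv --grid sim/landscape.asc \
                    --attributes sim/attributes.tsv --out sim/linked.tsv --ledger sim/ledger.tsv
calciphile summarize --linked sim/linked.tsv --grid sim/landscape.asc \
                    --attributes sim/attributes.tsv --out sim/tables
calciphile predict  --linked sim/linked.tsv --min-n 10 --ph-threshold 7.2 \
                    --caco3-threshold 2 --out sim/pred
calciphile validate --linked sim/linked.tsv --predictions sim/pred/predictions.tsv --out sim/chi.json
calciphile density  --linked sim/linked.tsv --resolution 0.05 --bandwidth 1.0 --out sim/density.asc
```

`calciphile geo-accuracy --pairs PAIRS.tsv --out STATS.tsv` summarizes
geocoded-vs-reference distances (mean, standard error, quartiles, in km).

## Conventions worth knowing

- Grid cells are half-open; a point on an interior boundary belongs to the
  higher row/column index. Cell (0, 0) has its top-left corner at the grid
  origin.
- Class bins are lower-inclusive (pH 4.5 → "4.5–5.5", CaCO₃ 2.0 → "2–5").
- Quartiles interpolate linearly between order statistics (order statistic k
  of n sits at probability (k−1)/(n−1)).
- The tolerance rule uses strict inequalities at both thresholds.
- Specimens of taxa below the minimum specimen count enter the contingency
  table in the non-tolerant row by default (`unpredicted_taxa="exclude"`
  drops them instead); specimens in mixed soils (one attribute above its
  threshold, the other not) are excluded and counted separately.
- Vincenty non-convergence (nearly antipodal points) raises an error rather
  than silently approximating.
- Fixed seeds give byte-identical outputs everywhere; stage seeds derive from
  one top-level seed by fixed offsets.
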