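# Data dictionary

Column documentation for every file the pipeline reads or writes in the run
directory. All coordinates are planar meters; years are calendar years;
exposure values are pounds of active ingredient per treated acre (lbs/acre).

## Simulated inputs (stage `simulate`)

### parcels.geojson
GeoJSON FeatureCollection of rectangular field parcels.
Feature properties: `parcel_id`, `acres`, `crop`; geometry: polygon ring in
planar meters.

### applications.csv
One row per pesticide application (a pesticide-use-report-like record).

| column | meaning |
| --- | --- |
| `year` | application year |
| `parcel_id` | parcel receiving the application |
| `pesticide` | active-ingredient identifier |
| `pounds` | pounds of active ingredient applied |
| `acres_treated` | treated acres (> 0) |
| `crop` | crop grown on the parcel |

### participants.csv
| column | meaning |
| --- | --- |
| `participant_id` | unique participant identifier |
| `wave` | recruitment wave (stratification factor) |
| `case` | 1 = case, 0 = control |
| `index_year` | diagnosis (cases) / interview (controls) year |
| `age`, `gender`, `smoker` | covariates (`gender` in {M, F}) |

### addresses.csv
Address history spells, one row per spell.

| column | meaning |
| --- | --- |
| `participant_id` | participant |
| `location` | `residential` or `workplace` |
| `x`, `y` | address coordinates (m) |
| `start_year`, `end_year` | inclusive spell years |
| `start_month`, `end_month` | optional; enable month-weighted same-year averaging |

### true_exposure.csv
Generator ground truth computed through the analytic overlap route.
Columns: `participant_id`, `location`, `pesticide`, `true_raw` (windowed mean
lbs/acre). Participant-locations with no covered window years are absent.

### annotations.csv
Long pesticide-group annotation table: `pesticide`, `group` (prefixed
`use:`, `class:` or `tox:`).

### wells.csv
Screen well metadata: `well_id`, `compound` (or `DMSO`/`water`/`rotenone`),
`dose` (µM; 0 for controls), `role` (`DMSO`, `water`, `positive`,
`treated`), `replicate`.

### objects.csv
Day-11 imaging detections: `well_id`, `field`, `area` (µm²), `roundness`
(0–1), `intensity` (a.u.).

### true_counts.csv
Generator truth for the screen: `well_id`, `timepoint` (`baseline`,
`day11`), `n_bright` (true reporter-positive count).

### ocr.csv
Oxygen-consumption-rate traces: `trace_id`, `segment` (`basal`,
`oligomycin`, `fccp`, `rot_aa`), `cycle` (1–12), `time_min`, `ocr`.

### ground_truth.json
Recorded simulation truth: `seed`, `causal_log_or` (pesticide → log-OR per
SD), `covariate_effects`, `coapplication_clusters` (lists of member lists),
`toxic_compounds`, `combination_effects` (`"a|b"` → survival multiplier),
`ocr_truth`, `extras`.

## Exposure assessment (stage `exposure`)

### exposure_raw.csv / exposure_z.csv
Long format: `participant_id`, `location`, `pesticide`, `raw` (windowed mean
lbs/acre) or `z` (log1p, centered, scaled within wave × location). Missing
`z` marks zero-variance strata.

### inclusion_mask.csv
`pesticide`, `n_exposed` (participants with raw > 0 at either location),
`included` (n_exposed ≥ 25).

## Association screen (stages `pwas`, `ora`)

### pwas_results.csv
One row per tested pesticide, sorted by `q`.

| column | meaning |
| --- | --- |
| `pesticide` | tested pesticide |
| `beta`, `se` | pooled log-OR per SD and its SE |
| `z`, `p` | pooled z-score and two-sided p-value |
| `or`, `ci_low`, `ci_high` | pooled OR per SD with 95% CI |
| `n_strata` | usable strata pooled |
| `n_exposed` | exposed participants |
| `beta[...]`, `se[...]` | per-stratum estimates (stratum = `wave:location`) |
| `q` | Benjamini–Hochberg q-value |
| `tier` | `fdr<=0.01`, `0.01<fdr<=0.05`, `0.05<fdr<0.1`, or `ns` |
| `implicated` | q < 0.10 |
| `associated` | q ≤ 0.05 (overrepresentation input set) |

### ora_results.csv
One row per annotation group, sorted by `p`: `group`, `a`/`b`/`c`/`d` (2×2
cells: a = associated ∩ group), `or` (conditional MLE), `ci_low`/`ci_high`
(exact 95% CI), `p` (two-sided Fisher exact), `pct_of_group_associated`,
`pct_of_universe`, `q`.

## Co-exposure (stage `network`/`cluster`)

### corr_matrix.csv
Pairwise-complete Pearson correlation matrix of standardized residential
exposures over the implicated pesticides (first column: pesticide id).

### edges.csv / network_nodes.csv / network_summary.json
Cross-layer network at R > 0.45. Edges: `source`, `target`, `r`. Nodes:
`pesticide`, `layer` (`mDA-toxic`/`other`), `degree`, `closeness`, `fdr`.
Summary: `n_toxic`, `n_other`, `frac_other_linked_to_toxic`.

### clusters.csv
`pesticide`, `cluster` (complete-linkage partition at height 0.55 on 1 − R;
labels numbered by decreasing cluster size).

### crop_share.csv
`pesticide`, `crop`, `share` (proportion of the pesticide's application
records on that crop), descending.

## Screen (stages `screen`, `combos`, `mito`)

### well_counts.csv
Well metadata plus `count`, the reporter-positive object count above the
control-referenced cutoff.

### toxicity_calls.csv
Per compound at the screening dose: `compound`, `mean_count`, `threshold`
(DMSO mean − 3 SD), `toxic`, `n_wells`.

### zprime.txt
The Z′ factor of the control arms (single number).

### dose_summary.csv
Per toxic compound and dose: `compound`, `dose`, `mean_count`,
`pct_decrease` vs DMSO, `ld50` (log-linear interpolation; empty when not
bracketed).

### combos.csv
One row per combination condition: `condition` (`+`-joined sorted compound
names, `DMSO` for none), `n_compounds`, `mean_count`, `pct_decrease`,
`n_replicates`, `enhanced_toxicity` (pair significantly lower than both
constituents at BH q < 0.05).

### combo_tests.csv
Pairwise t-tests: `condition`, `reference` (constituent or `DMSO`), `t`,
`p`, `lower` (condition mean below reference mean), `q`.

### mito_params.csv
Per trace: `trace_id`, `non_mito`, `basal`, `atp_linked`, `maximal`,
`spare`, `spare_pct`, `flagged` (non-positive basal).

## manifest.json
Run provenance: package `version`, `seed`, `config_digest` (stable hash of
the simulation configuration), and per-file row counts under `rows`.
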