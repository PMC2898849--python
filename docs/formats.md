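# File formats

All tabular files are UTF-8, comma-separated CSV with a header row;
years are integers (calendar years, both endpoints of ranges
inclusive).  Grid indexing is (layer, row, col), 0-based, layer 0 at
the top; x grows with column, y with row; z is elevation in feet
(positive up, land surface at the top of layer 0).  Units: feet, days,
ft³/day.

## subjects.csv
`subject_id,status,index_year,confounder,bottled_water_ever`
— `status` is `case` or `control`; `index_year` is the diagnosis year
for cases and the assigned reference year for controls.

## residences.csv
`subject_id,address_id,start_year,end_year,water_source,supplier_id,x,y`
— `water_source` ∈ `public`, `private_well`, `unknown`; `supplier_id`
names the distribution system for public residences; `x,y` locate
private residences (feet, model coordinates).  Occupancy intervals for
one subject must not overlap.

## wells.csv
`well_id,layer,row,col,rated_capacity,start_year,end_year,role`
— `role` ∈ `supply`, `effluent_source`.

## impact_schedule.csv
`scenario_id,well_id,first_impact_year` — empty year means never
reached.

## tracks_<scenario>.csv
`track_id,vertex_index,x,y,z,t_days,calendar_year,terminal_status,well_id`
— one row per track vertex; `terminal_status` ∈ `captured_by_well`,
`exited_domain`, `stagnant`, `time_exhausted`.

## exposure_records.csv
`subject_id,scenario_id,latency,ever_exposed,duration,first_exposed_year,n_exposed_addresses`

## analysis_grid.csv
One row per (scenario, latency, contrast) with the 2×2 counts, crude
OR, Woolf CI bounds, defined flag, formatted string, and (when
requested) the adjusted columns.

## Head exports
Flat CSV `layer,row,col,head` and, from the `flow` subcommand, one ESRI
ASCII grid (`.asc`) per layer: the standard 6-line header
(`ncols`, `nrows`, `xllcorner`, `yllcorner`, `cellsize`,
`NODATA_value`) followed by rows north-to-south.

## Pipeline config (YAML)
Keys: `scenarios`, `latencies`, `duration_mode`, `seed`,
`n_particles_per_cell`, `adjusted`, `covariates`, `aquifer` (overrides
for the synthetic aquifer), `cohort` (overrides for the synthetic
cohort).  Unknown keys are rejected.
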