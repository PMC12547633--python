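# Methods

This note documents the statistical procedures implemented in `cumex`,
the defaults and why they were chosen, what the synthetic data do and do
not emulate, and the numerical conventions that make the pipeline
deterministic.

## Event definition and climatology

A daily variable's extreme threshold is seasonally varying: for calendar
day *d* (on a 365-day calendar) the threshold is the 90th percentile of
all values falling within *d* ± 5 days (an 11-day window), pooled across
every year of the record, then smoothed with a centred 31-day moving
average that wraps across the year boundary. The seasonal mean is built
identically with the mean in place of the percentile. The baseline is
the full record and no detrending is applied, so a warming record
detects more events late in the record — deliberately, since the
products aim at impact, not at trend-free anomaly statistics.

Defaults `window_days=11`, `smooth_days=31` follow the marine-heatwave
convention; both are configurable, and the same machinery is applied to
the atmospheric variables (window widths there vary across the
literature; the width is a parameter rather than a hard-coded rule).
Percentiles use NumPy's linear-interpolation definition. Missing cells
(e.g. SST over land) stay missing through climatology, detection and
all downstream layers.

An extreme event is a maximal run of days *strictly* above the
calendar-day threshold, kept when its length is at least the
type-specific minimum: 5 days for the marine variable, 3 for
atmospheric variables. Strict inequality makes the constant-field case
unambiguous (a constant record has no events). The keep rule is ≥ by
default with a `strict_min` switch for the > reading; runs are never
joined across sub-threshold gaps by default (`join_gap=0`, with the
optional gap-joining exposed but off, since the event definition here
aggregates *consecutive* extreme days only). Event intensity is the
mean anomaly over event days relative to the seasonal mean; an
alternative reference (anomaly above the threshold) is a config switch.

## Cumulative stacking

Per environment and metric the participating event-type layers are
min–max rescaled over the environment's cells, summed with equal
weights, and min–max rescaled again, giving a [0, 1] field whose
maximum marks the most cumulatively affected pixel. A spread-free layer
(max = min) maps to all zeros with a logged warning rather than
failing — constant layers occur naturally in small synthetic runs, and
zero is the information-preserving choice (the layer then contributes
nothing to the stack). An alternative re-normalization dividing the
stacked field by its domain-wide sum is available
(`renormalization="sum_to_one"`); min–max is the default because it
preserves the per-pixel 0–1 scale of the final maps. A pixel missing in
every input layer stays missing; a layer missing at a pixel (no events
there) contributes nothing at that pixel.

Dominant-type attribution is the argmax over normalized layers, with
exact ties resolved by a fixed canonical order — MHW before extreme
winds at sea; heatwaves, then winds, then precipitation on land — so
categorical maps are deterministic. Cumulative values are classed low /
medium / high / very high on quartile bins, left-closed with the top
bin closed.

## Trends

Event catalogs are annualized by start year (an event crossing the
year boundary counts fully in its start year): per pixel-year, mean
event intensity and duration (missing in event-free years) and total
extreme-event days (zero in event-free years). Each series is fit by
OLS on the centred year index (centring is numerical conditioning only);
the slope's two-sided t-test p-value is reported. Pixels with fewer
than 10 non-missing years are not fit — rare-event pixels otherwise
produce meaningless intensity/duration fits. A perfectly constant
series gets slope 0, p = 1.

The filter keeps slope > 0 and p < α with α = 0.05 (configurable; the
significance level is a convention, and no multiple-testing correction
is applied across pixels by default — a Benjamini–Hochberg option
exists but is off, matching per-pixel significance reporting). The
p-values are plain OLS and do not correct for serial correlation of the
annual series; for annual aggregates of daily AR(1) noise the
year-to-year correlation is negligible, and the replicate study below
confirms the empirical type-I rate of the one-sided rule is close to
its nominal α/2.

Cumulative trend maps use the same normalize–sum–normalize workflow on
the retained slopes (each layer normalized over its own retained
pixels; non-retained pixels contribute zero), and attribution is the
per-pixel *set* of retained types, serialized as a bitmask with a CSV
legend. Area fractions count, over each environment's cells, the share
with ≥ 1 retained type, exactly one, ≥ 2, and each specific
combination; single + multi = total by construction, which the tests
assert against an exhaustive cell-count oracle.

## Hotspots and exposure

A grid cell belongs to a species' hotspot when the polygon overlaps it
with positive area (boundary contact excluded, so a polygon exactly
covering one cell selects exactly that cell); a centre-in-polygon rule
is available by config. The intersect rule is the default because small
coastal colonies near cell edges would vanish under the centre rule.
Mixed coastal cells are routed to both the sea-role and land-role
masks. Species with polygons below the grid resolution (an island
smaller than a cell, sitting inside a sea-classed cell) get an empty
land-role mask and missing land rows — reported, not an error, since
this is a real situation at 1° resolution.

Mean exposure per species, environment and event type is the mean
metric value over the masked cells; the cumulative value is the sum of
those means across event types, normalized across species by the group
maximum *per metric and environment* (the groups are per-metric,
per-side by design: each panel of the ranking has its own best-exposed
species at 1). Trend exposure averages the retained slopes inside the
mask and divides by the *total* mask size in that environment role —
not the retained-cell count — so species whose hotspots are barely
touched by increasing trends score low; a species with no retained cell
reports a zero cumulative trend and 0% coverage. Coverage is reported
per event type and as the union across types.

## Synthetic data

The generator produces what the statistics need and nothing more: a
sinusoidal seasonal cycle whose phase flips across the equator
(Southern-Hemisphere seasonality peaking mid-January is the reference),
stationary AR(1) daily noise with marginal standard deviation
`noise_sd`, an optional linear level trend, and injected discrete
episodes of known pixel, start, duration and amplitude (defined
relative to the noise-free seasonal expectation, which makes detection
ground truth unambiguous). The calendar has no leap days; real-data
ingestion drops February 29 so both paths share one climatology
convention. Default record length is 31 years, mirroring a three-decade
baseline.

Not emulated: spatial noise correlation, teleconnections, frontal
dynamics, realistic precipitation distributions (precipitation is
Gaussian here and may go negative; nothing downstream assumes
positivity). Passing tests therefore validate the *statistical
machinery* — thresholds, run detection, trend inference, masking and
normalization arithmetic — not geophysical realism of any particular
map.

The demo pipeline grid is a west land block, one mixed coastal column
and sea to the east; occurrence trends are injected into the southern
half of the domain (one episode per pixel-year whose duration grows by
0.5 days/year, amplitude 5× the variable's noise sd), giving trend maps
and species rankings a known spatial structure. Generated hotspots
always include one land+sea-spanning species, one strictly marine
species and (with ≥ 3 species) one sub-cell island species.

## Replicate studies and problem sizes

Three seeded studies validate the chain end to end (synthetic record →
climatology → detection → annualization → OLS), at sizes chosen to
resolve the quantities being estimated:

* **Episode recovery** — 100 replicates of a 20-year single-pixel
  record with one 10-day episode every other year at amplitude 4× the
  noise sd on AR(1) = 0.5 noise (1,000 episodes). Injection is kept
  sparse (~1.4% of days) because the climatology is estimated from the
  injected record, as in real use: dense injection inflates the pooled
  percentile itself, and the study would measure threshold
  contamination rather than detection skill. Measured: recall 1.0,
  95–96% of recovered durations within ±2 days.
* **Trend recovery** — 200 replicates of a 31-year record with one
  episode per year whose duration grows by 0.5 days/year; the truth is
  the OLS slope of the integer duration schedule. Measured mean
  recovered slope within ~4% of truth.
* **Null retention** — 200 trend-free replicates, each a 15×15 field of
  independent pixels (45,000 OLS fits), through the full path and the
  positive-and-significant filter. The nominal rate of the one-sided
  rule is 0.025; a rate this small needs tens of thousands of fits to
  estimate with useful precision, hence the field-sized replicates.
  Measured ≈ 0.025.

## Determinism and numerical conventions

Every source of randomness derives from a single integer seed
(per-variable and per-replicate seeds are drawn from one generator and
kept below 2³¹). Identical config + seed reproduces every CSV/NetCDF
product byte for byte; the run manifest records the config hash, seed
and package version and deliberately contains no timestamps. NetCDF
output uses the NetCDF3 format with numeric no-leap time axes; GeoJSON
is written with sorted keys. Climatology smoothing uses a
uniform moving-sum filter whose result agrees with the explicit moving
average to well below the 1e-9 test tolerance.

## Known limitations

* Trend p-values assume independent annual residuals; strongly
  autocorrelated *annual* series (beyond what daily AR(1) noise
  induces) would inflate the type-I rate of the filter.
* Event severity categories, sub-daily events and temporal compounding
  of different event types are out of scope.
* Bilinear regridding propagates missing values conservatively (no
  coastal extrapolation), so regridded coastal pixels may lose data
  relative to nearest-neighbour schemes.
* The longitude convention is [−180, 180); inputs on [0, 360) must be
  normalized upstream.
* The IUCN status attached to hotspots is a pass-through label only.
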