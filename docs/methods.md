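# Methods

## Scope and model

`occurate` treats the curation of species-occurrence records as an explicit,
parameterised pipeline whose downstream scientific quantity — the latitudinal
position of the species-richness peak — can be recomputed under alternative
curation choices. The pipeline assumes records are independent rows of a
Darwin-Core-style table with WGS 84 decimal-degree coordinates, that record
count per grid cell is a usable proxy for survey effort, and that richness
within a cell can be summarised by individual-based rarefaction (records are
exchangeable within a cell; no abundance structure beyond per-species record
counts is used).

## Pre-processing rules

Each rule is a predicate on a single record, so the kept set of the full
chain is independent of rule order; every rule returns a partition
(kept ∪ removed = input) and a count report.

- **Fossil**: `basisOfRecord = FossilSpecimen` (format-insensitive match).
- **Illegitimate date**: a date that is present but not a calendar date
  (month > 12, day beyond the month's length) or in the future. Records with
  *no* date are kept at this stage; requiring a date is a curation decision,
  handled by the temporal filters.
- **Coordinates**: removed when latitude = longitude exactly, when either
  coordinate is 0 (a flag restricts this to the (0, 0) pair), when *both*
  coordinates are integral (the record carries no decimal precision), when
  coordinates are missing, or when latitude < 20° N (the study area is the
  temperate Northern Hemisphere). The integer rule requires both coordinates
  integral because a coordinate pair with one fractional member does carry
  decimal precision.
- **Country mismatch**: the point must fall inside the polygon of its
  declared `countryCode` buffered by 0.1° (~10 km, tolerating border and
  coastline digitisation error). Records with no country code skip the test
  (the rule targets contradictions, not missing metadata); unknown codes are
  kept and counted separately.
- **Gazetteer**: great-circle distance to each entry (country centroids,
  repository headquarters, institutions); default radius 1 km per entry —
  the radius at which coordinates were plainly filled in from the country
  field rather than measured.
- **Rank**: keep species, subspecies, variety, form. Missing rank is
  resolved by the name: binomial kept, uninomial removed.

## Grid, bands, regions

Records are projected with the EASE-Grid 2.0 Global projection (EPSG:6933,
ellipsoidal cylindrical equal-area, standard parallel 30° N), implemented
from the standard closed-form equations and unit-tested against the
published map extents (x ≤ 17 367 530.44 m, y ≤ 7 342 230.14 m). Cells are
100 km × 100 km half-open squares [low, high) in projected x/y (points on
the global upper edge belong to the last cell, making the tessellation a
total function). The cell row is the latitudinal band, numbered 1–49
northwards from y(20° N); 49 bands of 100 km reach the pole. Regions are
longitude intervals, by default split at −30° and 60° into NorthAmerica,
EuropeNAfrica and Asia; the split is configuration, not geometry.

## Taxonomy

Raw names are normalised to `Genus epithet` (authorship, infraspecific
epithets and rank markers stripped; case and whitespace canonical). Each of
five offline reference lookups maps normalised raw names to an accepted
binomial with a status (accepted / synonym / unresolved / no_match). Fuzzy
matching (edit distance ≤ 1, via edlib, ties unresolved) is available but
off by default — offline standardisation should be conservative, and
spelling tolerance is a property of individual services.

The consensus checklist contains every accepted binomial endorsed by at
least `min_votes` (default 3) of the 5 sources. Votes are counted on
accepted *binomials*: two sources reaching the same accepted name through
different synonym paths agree. Records are retained in the consensus
dataset when at least one source maps their raw name to a consensus member;
the final label is the member chosen by most sources, ties broken
lexicographically and flagged. Only names observed in the dataset can vote
— the checklist describes the data, not the sources' full contents.

## Cleaning filters and scenarios

Duplicates are records agreeing exactly on species name (standardised by
the scenario's taxonomy), coordinates, and collection date — optionally
also the collector string. Coordinates are compared as canonical decimal
strings without rounding (rounding would merge distinct localities
silently; a precision option exists). Any record missing a key component is
a singleton: a duplicate cannot be established on absent evidence. One
record per group survives, the first in stable input order.

The four standard scenarios (`date-TNRS`, `date-cons`, `date-specim`,
`date-1970`) combine a taxonomy source with the basis/temporal filters and
always deduplicate on name + coordinates + date. Stages run in the order
taxonomy → basis → temporal → dedupe; deduplicating last means duplicates
that differ only in an attribute the scenario discards (e.g. basis) are
still merged.

## Completeness

The per-cell accumulation curve is the analytic rarefaction expectation
E[S(m)] = S_obs − Σᵢ C(N−Nᵢ, m)/C(N, m), evaluated in log-gamma space
(cancellation-safe at large N) at up to 100 integer subsample sizes
spanning 1..N. Being an expectation, the curve is deterministic — no
permutation noise — and provably non-decreasing and concave.

True richness is estimated by the asymptote b/c of the rational model
S(m) = (a + b·m)/(1 + c·m). The fit is deterministic: Levenberg–Marquardt
from a geometric initial guess (initial slope of the curve; asymptote just
above the curve maximum), with the rearranged linear solve
S + c·m·S = a + b·m as an alternative start, keeping the converged solution
with lower SSE. The linearised solve alone is *not* reliable: on strongly
saturated curves it settles on negative-c solutions because the
rearrangement implicitly reweights the residuals. A flat curve is a
finished inventory (completeness 100 %); an asymptote below S_obs is capped
at 100 % and flagged; no admissible solution flags the cell unusable and
disqualifies it from well-sampled status.

Completeness = 100·S_obs/(b/c) uses the rational asymptote; the terminal
slope comes from the exact curve over the last 10 % of the m-range (at
least the final two points), in species per record. The split — asymptote
for completeness, exact curve for the slope — assigns each estimator the
quantity it measures directly; both the source curve and the tail fraction
are configurable.

Well-sampled thresholds (all inclusive): ≥ 100 records, completeness
≥ 70 %, records/richness ratio ≥ 5, terminal slope ≤ 0.1 (one new species
per ten further records). The per-cell count of criteria passed (0–4) and,
across several filtered datasets, the count of datasets under which the
cell qualifies, are both reported.

## Gradient

Band series are medians of observed richness (S_obs) and predicted richness
(rational asymptote) over well-sampled cells per band; bands without
well-sampled cells are omitted. The segmented model
y = β₀ + β₁x + β₂(x−ψ)·1[x>ψ] is fitted by profiling: candidate ψ on a
0.25-band grid over the interior of the x-range, ordinary least squares for
the remaining coefficients, global SSE minimum wins. Profiling is
deterministic and cannot be trapped by a poor initialisation, unlike
iterative linearisation; the model is identical. Fits with fewer than 5
distinct x values, or improving on a straight line by < 1e-9 relative SSE,
are flagged degenerate. The regression x is the band index; conversion to
degrees latitude is reporting-only (the fit is affine-equivariant in x).

A caveat established during verification and reflected in the test design:
like any changepoint estimator, breakpoint recovery under noise degrades
when ψ lies near the end of the series (at σ = 10 % of peak richness,
recovery within ±2 bands falls from ~98 % for a centred break to ~60 % for
a break 5 bands from the edge). The Monte-Carlo recovery check therefore
uses a centred break, where the estimator's behaviour — not the design's
identifiability — is being measured.

## Synthetic worlds

The generator emulates the documented pathologies of aggregated occurrence
data on a geography that makes every rule exactly checkable:

- **Community**: per-band true richness is exactly two-segment
  piecewise-linear in the band index (default base 6, slopes +2/−2 species
  per band, break at band 40 of 49, mirroring a temperate-zone richness
  peak near 60° N). Species occupy contiguous band ranges built by an
  active-set scan; extra neutral turnover tops the pool up to
  `n_species_per_region` (default 150). Abundances are log-normal.
- **Effort**: a fixed set of cells (2 per band per region) receives
  multinomial effort with log-normal weights (σ = 0.75) scaled by the
  band's pool size — richer cells attract more collecting, and the default
  budget of 120k base records (~147k with duplicate copies; a desk-scale
  stand-in for the multi-million-record reality) leaves a minority of
  cells well-sampled, as in real data.
- **Errors**: each class has a small default rate — 4 % undated records,
  0.5 % invalid dates, 1 % fossils, 1 % zero coordinates, 1 % integer
  pairs, 0.5 % latitude=longitude, 0.5 % centroid placements, 1 % country
  mismatches, 0.5 % genus-level names. The four classes that rewrite the
  same coordinate pair (zero / integer / lat=lon / centroid) are mutually
  exclusive by a single categorical draw, since two rewrites of the same
  coordinates cannot coexist on one record; all other classes apply
  independently, so a record may carry several labels. Country codes are
  reassigned from the *final* coordinates, so a coordinate error never
  masquerades as a country mismatch.
- **Duplicates**: 25 % of clean, dated records gain one copy identical in
  name, coordinates and date; 15 % of copies carry a different collector.
  The resulting removal fractions (~20 % under the date-only duplicate
  key, ~17 % with the collector included) match the proportions reported
  for real aggregated moss data. Copies are planted only on records with a
  complete duplicate key and no error labels, so duplicate accounting and
  error accounting stay exactly separable.
- **Names**: each species has a synonym (different binomial) and an
  orthographic variant (1-character edit); records use them at 10 % / 2 %
  rates, plus authorship strings (25 %) and infraspecific suffixes (5 %).
  Each reference source covers a species with probability 0.88–0.97 and
  then lists the accepted name and synonym (the typo half the time);
  uncovered species are unresolved or absent.
- **Geography**: nine rectangle countries tile the study area with
  non-integer centroids; the gazetteer lists those centroids plus one
  repository headquarters and one institution. Clean coordinates are
  nudged away from gazetteer radii so the centroid rule removes exactly
  the planted class.

Every record's labels, duplicate group, true species and intended cell go
into a ground-truth ledger; the test suite uses it as the oracle for exact
precision/recall of every filter.

What the generator does **not** emulate: real coastlines and political
borders (countries are rectangles), spatial autocorrelation of species
ranges beyond contiguous band intervals, temporal trends in collecting,
collector-name variability, or multi-repository overlap. Passing tests
therefore demonstrate that the *pipeline* recovers planted structure
exactly and that the estimators behave as designed — not that any
particular real dataset is clean.

The basis-contrast world (`generate_contrast_world`) plants
human-observation records on a rich community peaking at band 40 and
preserved-specimen records on a poor community peaking at band 29, sharing
the same sampled cells. The all-records analysis recovers a breakpoint just
south of 40 (the specimen component adds a secondary kink), the
specimen-only analysis recovers 29 — a shift of ~10.5 bands against the
planted offset of 11 — reproducing qualitatively the phenomenon where
restricting to preserved specimens relocates the apparent richness peak.

## Numerical and formatting choices

- Coordinates are parsed with Python's correctly-rounded `float()`;
  pandas' fast parser can be off by one ulp, which would break
  byte-identical round-trips of canonical CSVs.
- Generated coordinates carry 6 decimal places (~0.1 m), as served by real
  aggregators.
- All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; identical config + seed reproduce byte-identical outputs.
- Problem sizes in the test suite and the acceptance script (20k-record
  ledger worlds, 147k-record default worlds, 225k-record contrast worlds,
  200 Monte-Carlo replicates) were chosen to exercise every stage at
  realistic cell occupancies while keeping a full run in minutes on one
  CPU.

## Known limitations

- The country-mismatch test is polygon containment only; there is no
  coastline/sea test and no handling of coordinate-uncertainty radii.
- Only the two-parameter rational (Clench-type) richness estimator is
  implemented; Chao/jackknife-style estimators and sample-based rarefaction
  are out of scope.
- The segmented model fits a single breakpoint; genuinely multi-modal
  gradients will be summarised by their dominant change-point.
- Collector strings are compared verbatim in the duplicate key; no name
  disambiguation is attempted (real collector metadata is unstandardised,
  which is why the default duplicate key omits it).
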