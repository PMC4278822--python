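# Methods

This note documents the models, rules and numerical choices behind
`biocollate`, and what its synthetic fixtures do and do not emulate.

## Data model and assembly

Data are organised as Source → Study → Site. A Study is the unit of
methodological comparability: all its measurements share one sampling
method and one effort unit, and a study holds at least two sites (a
single site cannot support a comparison of human-impact levels).
Assembly (`assemble_database`) enforces only *structural* invariants —
resolvable foreign references, two-plus sites per study, one matrix per
study, a single metric type per study. Field-level defects (bad
coordinates, impossible dates, duplicated names) are deliberately left
representable in an assembled database, because the validation engine's
contract is to *report* them; internally sites and taxa are stored as
lists rather than id-keyed maps for exactly this reason.

**Blank cells.** Deposited site-by-taxon matrices often contain empty
cells. The rule is applied per incoming study matrix: if every filled
cell is non-zero the depositors evidently left absences blank, so
blanks become zeros; if any filled cell is zero they recorded absences
explicitly, so blanks mean the taxon was not looked for there and
become missing values. The operation is idempotent and never alters a
filled cell.

**Patch area** is a tri-state (known value in m² / unknown-but-large /
unknown). The −1 sentinel for "unknown but large" exists only in the
file dialect; inside the library the state is explicit, so no
arithmetic can accidentally consume the sentinel.

## Validation

Two tiers. Lower-level rules are local to a record: mandatory fields
(ids, coordinates, sampling dates, metric type, effort unit),
coordinate ranges, calendar validity of the as-entered date parts
against the proleptic Gregorian calendar (leap years included — "32nd
January" must fail because real calendars do), minutes/seconds < 60 in
angle literals, non-negative time since conversion, and duplicate
site/taxon names within a study (the same name in *different* studies
is legitimate). Higher-level rules need GIS context: the nearest
country polygon to each site must be a declared country ("Multiple
countries" passes anything), and annotated sites at non-zero distance
from every country polygon are flagged — review below a configurable
10 km threshold, warning above it. The threshold default is a design
choice: coastal/small-island sites legitimately fall a little outside
coarse global polygons, while tens of kilometres usually means a
coordinate error. For mismatches, `suggest_coordinate_fixes` evaluates
the four standard repairs (swap latitude/longitude; negate either or
both coordinates) and reports which land in a declared country; it is
advisory and never mutates data, because silently "fixing" coordinates
would be worse than rejecting them.

## Taxonomic names

Each taxon carries three names. The *name entered* is immutable
provenance. The *parsed name* is the putative binomial extracted by a
small grammar: token 1 is the genus; token 2 is kept iff it is
all-lowercase alphabetic and not an open-nomenclature qualifier
(sp., spp., cf., aff., gr., nr., indet.); authorities (capitalised
tokens), digits, parenthesised years and everything after a qualifier
are dropped. The grammar intentionally treats *every* input as a
scientific name — common names parse nonsensically and are caught by
the review queue, which is cheaper and safer than guessing name kinds
up front. The *query name* starts as the parsed name and is the only
name curation may change; every change records a reason and the full
history.

**Resolution.** A query is matched case-insensitively and
diacritic-folded against checklist names (scientific and common).
Results map to accepted records via their accepted-name pointers; all
non-accepted statuses (synonym, ambiguous synonym, misapplied, common
name) behave identically as pointers, since the checklist model gives
no basis for treating them differently. If exactly one accepted record
is reachable, it wins — the original identifiers are assumed
authoritative. If two or more distinct accepted records are reachable
(homonyms), the taxon resolves to the deepest rank of the *shared
classification prefix* of all results. The prefix semantics matter: two
homonym genus records agree on the genus string but diverge at family,
and the walk from kingdom downward stops at that divergence, placing
the taxon at the shared order. Classifications in different kingdoms
share no prefix; such a query is unmatched unless a kingdom constraint
is supplied. Clade constraints filter candidate records before the
rules apply and are the intended mechanism for homonym
disambiguation.

Fuzzy matching is deliberately absent: typographical errors are a
curation task, and the review queue surfaces them (unmatched names;
binomial or common-name entries resolving above species; one parsed
name linking to different records across studies; a study whose lowest
common taxon falls outside its declared expected clade).

**Bird codes.** Four-letter codes built from binomials expand as the
first two letters of genus plus epithet against a caller-supplied pool
(e.g. the birds of the study's country). Collisions resolve to the
lowest classification common to all matches. Codes derived from
North-American common names follow external construction rules and are
out of scope; a dictionary lookup covers them.

**Species counting.** Names resolved to species or infraspecies rank
count once per resolved name database-wide; anything coarser counts
once per name per study. The scheme knowingly inflates counts when two
studies report the same unnamed morphospecies — the ambiguity is
inherent in the deposited names and is documented rather than hidden.
Group roll-ups (Magnoliophyta = Magnoliopsida + Liliopsida; Gymnosperms
= Pinopsida + Gnetopsida; ferns and allies from five classes; Crustacea
= Malacostraca) exist only for comparison against described-species
estimates. Higher groups follow three ordered rules: order for Insecta
and Entognatha; class for the remaining Arthropoda, Chordata and
Tracheophyta; otherwise phylum. Entognatha is excluded from rule 2
symmetrically with Insecta. A study's reported "taxonomic group" is the
higher group of its lowest common taxon, falling back to that taxon's
own name when the shared classification stops above the rank the rules
need.

## Site attributes

Land use (six classes plus "Cannot decide", secondary vegetation
subdivided by stage), use intensity (minimal/light/intense/cannot
decide) and the five fragmentation layouts are controlled
enumerations; classifying free-text habitat descriptions into them is a
trained human task and out of scope. Near-miss relations, used for
partial credit in repeatability analyses, are fixed in advance:
primary vs mature secondary; adjacent secondary stages (on the order
young < intermediate < mature); indeterminate secondary vs any other
stage; "Cannot decide" vs anything; and for intensity, adjacent classes
or "Cannot decide" vs anything. Both relations are symmetric and
irreflexive, verified exhaustively.

Sampling dates are stored as the earliest possible start day and latest
possible end day at the stated resolution (day/month/year), so ordinary
date columns carry imprecise dates without losing precision
information. Time since conversion: ranges store midpoints; open-ended
reports ("at least N", "greater than N") store N × 1.25, a fixed
convention for turning a bound into a usable point value.

Maximum linear extent is the diameter of the sampling geometry: the
maximum pairwise great-circle distance over the supplied points
(transect ends, trap grid, vertices of a complex design); a single
point has extent 0.

## Geographic annotation and coverage

Distances use a spherical Earth of radius 6,371.0088 km (haversine).
Nearest-polygon matching returns the containing feature at distance 0
(boundary points count as inside) or else the feature minimising the
great-circle distance to its boundary, evaluated at the planar nearest
boundary point plus boundary vertices densified at 0.02° (≈2 km)
spacing; the documented tolerance is 0.5%, ample for review
thresholds in the hundreds of metres and above. Ties break
deterministically in feature order. Hotspot matching is exact with no
nearest fallback — a site slightly outside a hotspot is genuinely
outside it. Polygons crossing the antimeridian are rejected rather than
silently mishandled.

Coverage tables report the percentage of studies, sites and samples
(non-missing measurements) per category. A study contributes to every
category any of its sites touches, so the studies column can sum past
100% across categories — columns are independent percentages of their
own totals. Latitudinal bands are half-open [lower, upper) with the top
band closed; a study's latitude is the median of its sites' latitudes
(mean of the central two for even counts). Cell and band areas use the
exact spherical formula R²·Δλ·(sin φ₂ − sin φ₁), so summed cells
conserve total area to rounding. TNPP per region multiplies each cell's
mean daily NPP (g C m⁻² day⁻¹) by the days in each month and the cell's
terrestrial area in m², sums the twelve months (non-leap year
convention, matching the monthly-mean rasters), and sums member cells;
missing cells contribute zero and the terrestrial fraction defaults
to 1.

## Agreement statistics

Cohen's kappa is computed from exact category counts. The weighted
variant takes an arbitrary symmetric unit-diagonal credit function;
observed agreement is the mean credit over items and expected agreement
the credit-weighted product of the raters' marginals, so the
exact-match indicator reduces it bit-for-bit to the plain statistic.
The near-miss credit defaults to 0.5, injected from the site-attribute
near-miss relations. When both raters use a single category throughout,
chance agreement is 1 and kappa is undefined; both variants signal this
with a dedicated `UndefinedKappaError` rather than returning a
conventional value, keeping the reduction identity intact.

The representativeness test is a Pearson goodness-of-fit of observed
site counts per land-use × intensity combination against the
combinations' shares of terrestrial area. Combinations without an area
estimate are excluded from both sides and the remaining proportions
renormalised; df = k − 1 for the k included combinations (with six
land-use classes, three intensities and one excluded cell, df = 16).
P-values come from the χ² upper tail at double precision and are
reported as the bound "< 2.2e-16" below representable range. Secondary
stages are pooled into one land-use row by default; pooling is an
option. The published kappa and χ² values from the motivating
collation are not reproduction targets here: the underlying confusion
matrices and site tables are not published, so only the rules and their
properties are testable.

## Synthetic fixtures

The generators produce everything the machinery consumes, seeded and
reproducible: one pseudo-random stream per generator, derived from the
master seed by a stable label (CRC32), so adding a generator never
shifts existing output. The checklist generator emits ~100 entries
covering every resolution structure with recorded ground truth; the
survey generator emits 2 sources × 2 studies × 6 sites × 8 taxa by
default (scales that keep the full suite and the acceptance script in
seconds while exercising every code path), each study sampling one
focal phylum; the region generator emits nested rectangles (8
ecoregions, 4 biomes, 2 realms, 4 countries, 1 hotspot covering an
exact 25% of land) whose areas are available in closed form; the
ratings generator samples from an explicit joint distribution and
returns the analytic p_o, p_e and kappa alongside.

What the fixtures do **not** emulate: ecological community structure
(abundances are i.i.d. shifted-Poisson counts; no species-abundance
distribution, spatial autocorrelation or detection process), realistic
polygon shapes, and real nomenclatural mess beyond the structures
listed. Passing tests therefore demonstrate that the *machinery* is
correct — rules fire exactly where injected, resolutions match
engineered truth, statistics recover analytic values — not that any
ecological conclusion holds on real data.

## Numerical choices and limitations

- Name matching is case-insensitive and diacritic-folded but otherwise
  exact; no fuzzy matching.
- Great-circle distance tolerance 0.1% (extent) / 0.5% (boundary
  distance); boundary densification at 0.02°.
- Kappa degenerate case raises; χ² zero expected proportions raise with
  the offending cell named.
- Antimeridian-crossing polygons are unsupported by construction.
- Whether a species-richness study carries per-taxon rows or one
  per-site total is not constrained; both assemble, and the review
  workflow is the place to inspect them.
- The %-area column for hotspot coverage defines "terrestrial area"
  as the sum of the layer's polygon areas over the fixture land area;
  with real layers a land mask should be supplied instead.
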