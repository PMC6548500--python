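# Methods

## Scope and data model

The package operates on per-footprint measurement tables: up to five
digit-tip-to-heel-baseline lengths (Dt1–Dt5), ball/arch/heel baseline
lengths (mtm, mtl, ntu, mttu, ccm, ctul), three transverse widths, toe
declination, maximum foot length (max FL) and width (max FW), and the
arch angle (Aa). Units are fixed at centimetres and degrees; no unit
inference is attempted. Missing cells are first-class (empty CSV cells,
never sentinel numbers) and survive read/write round-trips. Decimal
commas are accepted on input — the transcribed source tables mix both
conventions — and always written back as decimal points.

The packaged reference tables are a hand-checked transcription of the
Bàsura cave footprint data: the qualitative shape descriptors with the
published five-morphotype labels (26 footprints), the full measurement
block with the printed foot-index/stature/mass/age cells retained as
`*_printed` columns, and the nine-variable matrix of the 23 best-preserved
prints used for the PCA. Internal inconsistencies of the source are
preserved as printed (SM26 recorded as a right foot in the measurement
block but left among the descriptors; one print spelt "CA10" in the
descriptors and "C10" elsewhere, harmonized through an explicit alias map
when labels are read off). The per-morphotype summary subsets were never
stated by the source and were recovered arithmetically; they are encoded
in the fixture (`in_summary` column), not guessed at run time:
morphotype 1 uses all four members, 2 uses SM5 and SM42, 3 uses CA8, C10,
SM15, SM11, SM6, SM1, 4 uses CA1, CA2, C61, C63, and 5 uses C60, C37,
C35b.

## Shape indices

The foot index is max FW / max FL, reported as a ratio (the convention of
the reference measurement table; a ×100 percentage form is a report
option). The arch angle is computed from three planar landmarks — the
most medial metatarsal point, a second point fixing the medial border
line, and the apex of the arch concavity — as the acute angle between the
border line and the metatarsal-to-apex line; it is invariant under rigid
motion and uniform scaling.

## Log transform, imputation, PCA

All multivariate analysis happens on natural logs of the measurements.
The log base is immaterial (PCA results are base-invariant up to uniform
scale), and log-shape space makes isometric size variation a single
direction.

Missing cells are completed by iterative PCA imputation: initialise
missing cells at their column means, then repeat {center, reconstruct
from the leading k components, overwrite the missing cells} until the
largest absolute change of any imputed cell falls below `tol` (default
1e-6) or `max_iter` (200) sweeps. Defaults: k = 3, covering the dominant
size axis plus two shape axes. Present cells are never modified, so the
operator is the identity on complete data, and the procedure is fully
deterministic. Preconditions: every column needs at least two observed
values and k < min(rows, columns).

PCA is an eigen-decomposition of the sample covariance matrix (n−1
denominator) of the column-centered log data. Covariance, not
correlation: the variables share units (log-cm), and covariance PCA keeps
the allometric interpretation of the loadings — on the reference matrix
the first component carries ~74% of the variance with all loadings
positive, i.e. a size axis. Components are ordered by decreasing
variance; the sign convention makes each loading column's
largest-magnitude entry positive. Degenerate inputs (constant matrix,
remaining missing cells, fewer than three rows) are rejected.

## Morphotype grouping and MNI

Footprints are grouped by average-linkage agglomerative clustering of the
log-measurement rows. The distance between two footprints is the
**median** absolute difference of their log measurements — a
relative-difference distance, invariant to uniform unit changes, chosen
over the mean-absolute variant because single badly preserved landmarks
(substrate collapse, partial digits) otherwise dominate the distance; the
median tolerates up to half the variables being distorted. Rows are
sorted lexicographically by footprint id before clustering, which fixes
tie-breaking and makes the output invariant to input row order. Groups
are renumbered 1..K by increasing mean size.

The source's stated grouping rule — overlap within 2% of the main
parameters — cannot literally reproduce its own published groups (the
within-morphotype max-FL ranges exceed 2%), so the dendrogram cut is a
calibrated configuration value instead: on the 23-print reference matrix
the five-cluster plateau spans cut heights ≈0.088–0.099, and the default
cut is frozen mid-plateau at **0.095**. The 2% figure is retained as a
per-group spread diagnostic (mean relative range per measurement column),
reported with every assignment. The MNI is the number of groups, under
the usual one-producer-per-morphotype reading.

## Biometric profiles

Per-footprint estimates are computed first and then summarized as
mean ± sample SD (n−1) — the source's order of operations; summaries are
taken over **unrounded** per-footprint values, which is the only order
that reproduces every printed summary cell (rounding first shifts e.g.
the smallest group's mean mass from 12.64 to 12.65). Report cells round
half-up to 2 decimals.

Mass-model routing is decided at group level from the mean stature of the
summarizing subset: below 147 cm the child exponential model (a); at or
above, the adult linear model (b), plus the child/adolescent linear model
(c) when the group mean is ≤ 152 cm (model c was calibrated on a cohort
averaging 147.44 cm, and this rule reproduces the published routing
without per-row exceptions).

Age bins for the interpolated point age: < 4.5 yr → `<3`, 4.5–7 → `5–6`,
7–12 → `8–11`, ≥ 12 → `>14 - adult`; adult-class morphology (a group
routed to the adult mass models) forces the adult bin. The bins bracket
every published class assignment; the 12-yr upper edge closes the gap a
strict reading of the published classes would leave between 12 and 13.5
years. Foot lengths outside the anchor range are clamped and flagged.
Above the 13-yr anchor the growth curve continues at half slope to a
plateau at age 16 (adult foot size ≈ 25.8 cm, i.e. stature ≈ 167 cm) — a
minimal juvenile-deceleration model, not a fitted curve.

Sex inference is deliberately a transparent rule table, and every call is
flagged low-confidence with its rationale attached: the largest
adult-class group with robust morphology (mean foot index ≥ 0.40, a
configurable threshold) → probable male; optionally
(`gracile_adult_female`) a gracile adult group → probable female;
everything else indeterminate. Foot-based sexing is population-dependent
and speculative; the package never emits a call without saying so.

## Synthetic trackways and recovery

The generator inverts the estimators. An individual gets an age (uniform
over a range, or specified), an expected foot length from the growth
reference, lognormal individual variation (CV 0.04 by default, inside the
printed anchor SD bands), and stature = FL / 0.1541; its true mass comes
from the mass model its stature routes to, so with zero noise the
pipeline recovers stature and mass exactly (generator/estimator
inversion). Footprints are a fixed nine-variable template — the mean
proportion profile of the reference matrix — scaled by foot length under
per-cell multiplicative lognormal noise (substrate plasticity distorts
positive lengths proportionally; the default CV of 0.02 keeps typical
cell errors under the ±0.5 cm landmark reliability bound). Cells go
missing at random at a configurable rate, mirroring the sparsity of the
real matrix. One master seed drives everything; replicate streams are
spawned from `numpy.random.SeedSequence(seed)`, so runs are bit-for-bit
reproducible.

What the generator does **not** emulate: between-individual shape
differences (all individuals share one template, so recovery tests probe
size-based grouping only), structured digit-block missingness,
left/right asymmetry, gait-dependent distortion, and substrate-specific
error correlation. Passing recovery tests therefore demonstrate that the
pipeline separates individuals by size at realistic noise, not that it
resolves same-sized individuals of different foot shape — which the MNI
concept does not promise anyway (with two near-identical adults the
recovered count honestly drops below the true count: a minimum).

Recovery experiments at the default configuration (five individuals with
≥10% pairwise foot-length separation, 3% measurement noise, 5% missing
cells, 100 replicates of 25 footprints) recover the true MNI in ≥95% of
replicates with group-stature RMSE around 2 cm; the noiseless limit is
exact. These problem sizes keep the full suite and the acceptance script
in the tens of seconds.

## Numerical choices and limitations

Half-up decimal rounding everywhere a table cell is printed (Python's
built-in banker's rounding disagrees on exact halves). Two printed mass
cells of the source (both FL 20.5 cm, model a) are off by one unit in the
last digit from the model value 30.3083 — the source truncated them while
rounding its other cells — and the tests treat exactly those two cells
with a one-digit tolerance. The clustering cut is calibrated to the
reference table and should be re-examined for assemblages with very
different preservation; the stature ratio, mass models and growth anchors
are population-specific calibrations carried in a swappable configuration,
not universal constants.
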