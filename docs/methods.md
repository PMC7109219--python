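# Methods

## Overview

`vitalink` implements a period-linked-file construction for infant
mortality surveillance: death registrations from a two-year calendar
window (2010–2011 by default) are linked against hospital birth records
spanning that window plus the preceding year, so infants born late in the
prior year remain linkable, while the live-birth denominator contains only
births dated inside the registration window. The package has three parts —
a synthetic registry generator with ground truth, the linkage engine, and
the rates/causes/comparison tables — described in pipeline order below.

## Synthetic registries

### What the generator emulates

Each live birth receives a birthweight bin and a gestational-age bin from
a joint distribution, exact values inside the bin, a birth date uniform
over the birth years, a region-coded hospital and Canadian-format postal
code (first letter keyed to region, FSA drawn from a finite per-region
pool so partial postal agreement between unrelated records is possible but
rare), demographic strata (maternal age band, parity, plurality, income
quintile, rural flag), and a unique encoded identifier. Stillbirth records
(default 0.6% of births — an arbitrary small value; the data source gives
no figure) and an orphan-record flag (2%) are added to the reference file
only.

The default birthweight-bin proportions and per-bin infant-mortality
probabilities reproduce the Ontario 2010–2011 birthweight-specific
mortality table (e.g. 12,153/280,924 births and mortality 0.0059 in the
2000–2499 g bin), and the gestational-age margins reproduce the
corresponding GA table. Because only the two margins are published, the
joint distribution is completed by iterative proportional fitting (IPF) of
a plausible support matrix (which birthweight bins can co-occur with which
GA bins) to both margins; the implied GA-specific mortality rates are then
strictly decreasing in gestational age, as they should be, and reasonably
close to the published GA-specific rates even though mortality is keyed to
the birthweight bin alone.

Deaths are assigned per live birth with its birthweight bin's mortality
probability. Age at death is a four-part mixture — within 24 h / 1–6 d /
7–27 d / 28–364 d with weights 660:167:181:303 (the registered-death
timing distribution) — uniform inside the neonatal buckets and
truncated-exponential (mean 80 d) post-neonatally. The underlying cause is
drawn from an ICD-10 mix calibrated so immaturity-related conditions lead
(~34% of deaths) and congenital anomalies come second (~23%). Day of birth
is day 0: a death on the birth date is age 0 ("within 24 h").

### Corruption and the unlinkable deaths

`corrupt_and_split` turns the true cohort into the two files the linkage
sees. Three mechanisms remove birth records from the reference file,
mirroring how a hospital discharge database misses births:

* **sub-threshold rule** — records with birthweight < 500 g AND
  gestational age < 20 weeks are dropped (the collection thresholds);
  the generator gives the < 25-week GA bin a 5% sub-20-week tail, making
  these ≈ 0.8% of registered deaths;
* **out-of-hospital / out-of-province births** — each live birth is
  dropped with probability 0.02 (≈ 2% of births occur outside hospitals),
  contributing ≈ 1.7–2% of deaths;
* **late terminations** — each death's birth record is dropped with
  probability 0.005.

Together these make ≈ 3.0% of registered deaths unlinkable by
construction; adding genuinely ambiguous pairs the probabilistic stage
declines to link, the observed unlinked share centres on ≈ 3.6%, matching
the surveillance target the defaults were calibrated to.

Field corruption forces the probabilistic pass: the encoded identifier is
blanked on 15% of death registrations (and on all deaths without a
hospital birth), postal codes get a typo in the non-FSA half with
probability 0.05, dates of birth shift by ±1 day with probability 0.02,
and sex is blanked with probability 0.01. Borderline-viability deaths
(< 1000 g) have their reference record flagged as a stillbirth with
probability 0.01, emulating live-birth/stillbirth misclassification.

### What the generator does **not** emulate

Strata (maternal age, income, region, …) are independent of mortality, so
stratified tables exercise the machinery but show no real gradients; cause
of death is independent of age at death; there is no real geography or
postal directory; unlinked deaths are a random subset apart from the
out-of-hospital place-of-death shift, so the linked-vs-unlinked timing
contrast is far weaker than in real registries. Passing tests therefore
demonstrate correctness of the algorithms and accounting, not realism of
every marginal association.

## Linkage

**Deterministic pass.** Exact join on the encoded identifier where present
on both sides; identifiers duplicated within a file or mapping to several
reference records are demoted to the probabilistic pass with a warning.

**Blocking.** Default `dob1`: candidate pairs share a birth date within
one day, which by construction always contains the true record under the
±1-day date corruption. `dob_year_fsa` (same birth year or same FSA) and
`none` are available; the union scheme never yields fewer candidates than
either key alone.

**Comparison vectors.** Four fields with multi-level agreement: date of
birth {exact, ±1 day, disagree, missing}; place (death's place-of-death
code vs birth hospital code) {agree, disagree, missing}; sex {agree,
disagree, missing}; postal code {exact, FSA-only, disagree, missing}.
Missing is distinct from disagreement; unparseable dates count as missing.

**EM.** Two-class latent mixture over the comparison vectors with
conditional independence of fields given class. Initialization: m puts 0.9
on each field's top agreement level, u equals the empirical level
frequencies over candidate pairs, λ = residual deaths / candidate pairs.
Missing levels are excluded from the field likelihood (equivalently
m = u), so a missing field contributes zero weight; an alternative that
models missingness as its own level is available behind a config flag.
The log-likelihood is non-decreasing by construction; parameters reaching
a boundary are clamped into [1e-6, 1 − 1e-6] with a warning (after
clamping, a probability vector may deviate from the exact simplex by a few
parts in 10⁶, which the likelihood tolerates). Convergence: maximum
absolute parameter change < 1e-6, up to 200 iterations by default (a few
full-scale runs stop at the iteration cap with no measurable effect on
classification).

**Decision rule.** Pair weight w = Σ log₂(m/u) at the observed levels.
Thresholds are expressed as posterior match probabilities under the fitted
prior — upper 0.9, lower 0.1 — translated to weights by
w* = log₂(odds(p*) / odds(λ)). Pairs at or above the upper threshold enter
a greedy one-to-one assignment by descending weight (ties broken by
death-id, birth-id lexicographic order); pairs between the thresholds, and
candidates skipped because either record was already assigned, are
reported as *possible* and counted as unlinked. No clerical review exists;
this reproducible rule replaces it.

**Stillbirth links.** Stillbirth records are linkable targets, but a link
to one is reported as a reclassification, never counted as a live-birth
link, and the death remains in every numerator.

**Accounting invariants.** Every registered death appears exactly once
(linked or unlinked); no record appears in two links; the deterministic
pass is never overridden. On synthetic data the evaluation reports
precision and recall per stage against the truth map: at full scale the
probabilistic stage shows precision 1.00 and recall ≈ 0.93–0.97 across
seeds — the missed pairs are true matches that disagree on place of death
and fall marginally below the upper threshold, a genuine ambiguity of a
four-field model rather than an estimation defect.

## Rates

Crude infant and neonatal rates put **all** registered deaths (linked and
unlinked) in the numerator over the live-birth denominator; the
post-neonatal denominator is the neonatal survivors (live births minus
neonatal deaths). Birthweight-, GA- and stratum-specific tables use linked
live-birth deaths only, report deaths lacking the attribute as an
exclusion count, and support restricted cumulative rows (≥ 500 g,
≥ 1000 g). Display rounding is one decimal per 1000; internal values stay
full-precision. Cells with numerator ≤ 5 are flagged suppressed but
retained, for auditability.

Two exact binomial intervals are implemented. The default, `midp`, inverts
the binomial tail sums with the boundary outcome at half weight; it is
what reproduces the published tables this package is calibrated against
(e.g. 363/1150 → 315.7 per 1000, CI 289.3–343.0). `clopper-pearson` is the
classical Beta-quantile inversion of the full tails — low = Beta(x,
n−x+1) α/2 quantile (0 at x = 0), high = Beta(x+1, n−x) 1−α/2 quantile
(1 at x = n) — and is verified in the tests against exhaustive tail-sum
inversion. Mid-p intervals are nested inside Clopper–Pearson by
construction. Zero-denominator bins are emitted flagged undefined, never
raised past the caller.

## Causes

ICD-10 codes map to ICE-style groups by longest-prefix match over
pairwise-disjoint prefix sets, with an `other/ill-defined` fallback for
valid unmatched codes and `unclassifiable` for malformed ones.
Disjointness makes the assignment independent of group order. The shipped
mapping (immaturity-related P05/P07/P22/P26–P28/P77; congenital anomalies
Q; asphyxia P03/P10/P15/P20–P21/P24; infection A/B/J/P23/P35–P39; SIDS
R95; external V/W/X/Y) is an approximation of the usual grouping: it is
reference data, replaceable via YAML, and no published cause-specific
numerator is asserted against it. Cause-specific rates use all registered
deaths per 1000 live births.

## Linked-vs-unlinked comparison

Categorical rows use Pearson chi-square with no continuity correction;
the age-at-death row uses Mann–Whitney with midrank ties and a two-sided
normal-approximation p-value with tie-corrected variance (no continuity
correction, no exact permutation p). Quartiles use linear interpolation on
sorted values — stated because IQR endpoints depend on the convention.
P-values below 0.001 display as "< 0.001". Empty groups produce the table
with tests skipped and a warning.

## Determinism and problem sizes

A single pipeline seed feeds named substreams per stage (generation,
corruption, …), so adding a stage never perturbs earlier streams;
identical config + seed gives byte-identical output files, verified by
checksummed manifests. The full-scale cohort is 421,386 births over three
years (≈ 281k denominator births, ≈ 1300 registered deaths) and runs the
whole pipeline in a few seconds; tests use 30k–100k cohorts for unit
properties and one full-scale run for the end-to-end checks.

## Known limitations

* The four linkage fields and the two-threshold Fellegi–Sunter rule are a
  documented default realization; real systems add clerical review and
  richer comparators (string distances, name fields) that are out of scope.
* The probabilistic pass's weights, thresholds and blocking are package
  choices, not reconstructions of any production system's settings.
* Income quintile, rurality and region arrive as already-attached
  attributes; no geographic or census linkage is modelled.
* The crude-rate denominator is the live-birth bin sum of the reference
  window, adopted and documented as such.
* No ICD-9 support and no multiple-cause-of-death analysis.
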