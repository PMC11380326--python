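# Methods

## The assessment model

The unit of observation is one *included comparison* ("study"): a primary
study contributing either a diseased-versus-control baseline comparison or
an experimental-treatment-versus-control comparison, in animals or humans.
A manuscript can contribute several studies, and a study included in both
review arms appears twice under distinct study ids — hence a default corpus
of 164 studies in 151 manuscripts.

Each study is assessed on a fixed, ordered instrument of 48 items merged
from four source checklists (ARRIVE, CONSORT, SYRCLE's RoB tool, Cochrane's
RoB tool). 38 items measure reporting quality (RQ, scored Y/N) and 10
measure risk of bias (RoB, scored L/U/H); items that can be inapplicable to
individual studies additionally admit I ("irrelevant"). The RoB block is
exactly S1–S10. Codes absorbed during the merge survive only in the
`merged_from` column of the bundled instrument CSV; each absorbed code is
assigned to exactly one surviving item. The five unnumbered rows of
Cochrane's tool carry synthetic codes CR1–CR5. The bundled instrument is a
reconstruction from the published operationalisation table (its version
string says so); users with the original extraction template can supply
their own CSV with the same columns.

Applicability is modelled at two levels, deliberately:

- **stratum-level** rules live in the instrument (one boolean per
  population × design stratum): animal-husbandry items (A15, A16a, A16c,
  S4) are never scored for human studies, intervention items (C8b, C10,
  S1) never for baseline designs, A12b not for human baseline studies, S3
  not for human baseline studies. The table normaliser materialises these
  cells as I so a corpus is always dense (48 × 164 = 7872 cells).
- **study-level** irrelevance (e.g. interim analyses for a
  single-measurement study) depends on study content no predicate can see;
  it is whatever the extractor recorded as I. A *missing* cell for an
  applicable item is a validation error, never silently I — this keeps the
  irrelevant bucket from inflating.

With the reconstructed applicability map the structural irrelevant count of
a default-sized corpus is 882 (592 RQ + 290 RoB). Study-level I scores come
on top of that in real extractions; the default synthetic preset draws
none, so generated corpora carry exactly 882.

## Summaries and the DIV statistic

Per item, irrelevant scores are counted and then removed; every percentage
is over the remaining *scored* assessments. For RQ items the distinctive
informative value is

    DIV = 50 − |%Y − 50|,

a tent function on [0, 100] with range [0, 50]: an element reported by
(almost) everyone or (almost) no one cannot discriminate between included
studies, one reported by half of them discriminates maximally. DIV is
computed from the unrounded percentage; display rounding is half-up to one
decimal (`round_half_up`), matching the convention of reporting e.g.
"26.6% of 5621". Items with zero scored assessments in a selection are
*not computable* (`None`/NaN downstream), never 0%. No DIV-like score is
defined for RoB items: with ten items at three levels a single scalar
hides more than it shows, so the RoB side is reported as L/U/H percentage
stacks instead.

Rankings sort descending on the requested key with ties broken by
instrument order (stable and reproducible); the ranked DIV table applies a
cut of 10 by default.

## Stratified comparisons

Per item, a contingency table of scored counts (rows: the two levels of
population or design; columns: Y/N or L/U/H) feeds a Pearson chi-square
test. The implementation replicates base R's `chisq.test`: expected counts
from the margins, and for 2×2 tables the Yates continuity correction with
the shift clamped at min(0.5, |O − E|) so the statistic cannot overshoot
zero (`correction="auto"`; `"on"`/`"off"` expose both behaviours, since for
2×2 tables the two conventions give different statistics and a reader
comparing against published values may need either). Items with an empty
stratum level (e.g. S4 across populations) are skipped with a logged
reason rather than failing the scan. The tests are explorative; no
multiplicity adjustment is applied unless Benjamini–Hochberg is requested
(`adjust="BH"`, via statsmodels). A small-expected-count warning is
attached when min E < 5.

The uncorrected statistic is verified against a brute-force
Σ(O−E)²/E oracle and scipy's `chi2_contingency`; the default behaviour is
verified against `Rscript -e 'chisq.test(...)'` itself. Null calibration
(empirical type-I error ≈ α) is checked for the uncorrected test, which is
the one with nominal asymptotic level; the Yates-corrected test is
conservative by design.

## Figures

Both figure builders are pure functions from per-stratum summaries to a
plot spec, and every rendered figure writes its data as CSV next to the
SVG/PNG. The reporting heatmap maps %reported through a diverging
green–yellow–red scale so *intermediate* shades flag high-DIV elements;
not-computable cells render grey, never as 0%. The RoB figure stacks L/U/H
percentages per item and stratum in the usual traffic-light colours
(green low, yellow unclear, red high). Heatmap rows default to instrument
order with an optional DIV sort (the published figure's ordering is not
specified, so the choice is exposed). SVG output is byte-stable
(fixed `svg.hashsalt`, no date metadata).

## Partial-assessment sampling

`recommend_plan` maps five interest levels to procedures: full RoB
analysis when review results will steer guidelines or future experiments;
high-DIV element subsets and/or random study subsets otherwise. The
sampling fraction anchors at 50% for reviews of ≤ 50 included papers (with
at least 25 studies assessed) and 5% at ≥ 1000 papers; between the anchors
the fraction interpolates log-linearly, clamped into the catalogue row's
range where a range is given (the interpolated point is returned alongside
the range endpoints, since no rule for choosing within a range exists).
Subset size is max(min_studies, ⌈f·N⌉) capped at N.

`evaluate_plan` measures what such a plan costs in estimation error:
replicate study subsets are drawn without replacement — by default
proportionally within the four strata (largest-remainder allocation, every
non-empty stratum keeps ≥ 1 study, so the 12 human-treatment studies are
never lost; `stratified=False` restores simple random sampling) — and the
per-item percentages are recomputed per replicate. Reported per item:
truth (full-corpus value), mean estimate, bias, MAE, per-replicate SD and
the empirical 95%-interval half-width. Replicates use independent
substreams spawned from one seed (`SeedSequence.spawn`), so results are
order-independent and byte-reproducible. For RQ items the estimated
quantity is %reported; for RoB items each of %L/%U/%H.

## The synthetic generator

Each applicable (study, item) cell is an independent Bernoulli (RQ) or
categorical (RoB) draw from a per-item, per-stratum distribution;
inapplicable cells are emitted as I. Stratum sizes default to
56/74/22/12. Year is uniform on 1981–2020 and used only as passthrough
metadata.

The `paper` preset sets each item's pooled rate to the published marginal
percentage where one is printed (e.g. ethics evaluation 64.6% reported,
selective outcome reporting 97.6% high RoB, animal-model relevance 74.4%
on its 90 applicable studies). The case study prints no percentage for 14
RQ items and parts of the RoB simplexes; those were fixed once at low
values (2–8% reported) chosen so that (a) their DIV stays below the
published table's cut of 10, (b) none undercuts the published bottom-five
list, and (c) the corpus-level expected reported fraction lands near the
published 26.6% — the preset metadata says the calibration is to pooled
marginals only. Identical rates across strata are used because only pooled
values are printed; the `paper-strata` preset additionally plants four
stratum splits (baseline values by population, adverse events by design,
and analogous splits on S2 and S5) that preserve the pooled marginals, for
power-testing the comparison module.

What the generator does *not* model, hence what passing tests do not show
about real data: between-item correlation (real studies that report badly
do so across many items at once), extractor disagreement, study-level
idiosyncratic I scores, and time trends. All analyses in this package are
marginal per item, so these omissions do not bias the quantities under
test, but corpus-level dispersion across studies is unrealistically
binomial.

`recover` is the parameter-recovery harness: across replicate corpora it
compares mean estimated percentages per item × stratum × level to the
generating probabilities, reporting deviations against the single-corpus
binomial standard error 100·√(p(1−p)/n) and the coverage of per-corpus
95% normal-approximation intervals (coverage is meaningful only away from
boundary probabilities, where the Wald interval degenerates).

## Numerical conventions and problem sizes

- Percentages: exact internally, half-up to 1 decimal for display.
- DIV from unrounded percentages; test tolerance ±0.05 on displayed values.
- Ranking tie-break: instrument order, always.
- Chi-square: `auto` = Yates for 2×2 only; p-values from the χ² survival
  function.
- Seeds: every stochastic routine takes an explicit seed; replicate
  substreams come from `numpy.random.SeedSequence`.
- Default simulation sizes, chosen to keep the full suite fast while
  leaving Monte-Carlo error well below the tolerances they are checked
  against: 200 corpora for recovery checks, 300–500 subsampling
  replicates, 1000 null replicates for test calibration.

## Known limitations

- The bundled instrument is reconstructed from a published summary table;
  a few letter-suffix codes of merged-away items are interpretation. The
  item *count* structure (48 = 38 + 10) and all applicability rules are
  verified by tests, the verbatim wording is approximate.
- The preset reproduces pooled printed percentages only; true per-stratum
  rates of the case study are unknown for most items.
- Structural irrelevance (882 cells) undercounts a real corpus's
  irrelevant total, which includes study-level I scores.
- The chi-square scan inherits the usual small-expected-count caveats;
  warnings are attached but tests are not switched to exact methods (the
  analysed design used the asymptotic test throughout).
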