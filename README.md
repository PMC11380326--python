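# robdiv

Tools for analysing the **informative value of risk-of-bias (RoB) and
reporting-quality (RQ) assessments** across the primary studies of a
systematic review.

Systematic reviews that include both animal and human studies assess each
included study against several instruments at once — ARRIVE and CONSORT for
reporting quality, SYRCLE's and Cochrane's tools for risk of bias. Scoring
all of them for every study is one of the most expensive steps of a review,
and much of the yield is "not reported" / "unclear". `robdiv` implements an
analysis pipeline for asking *how much discriminating information* those
assessments actually carry, and for designing cheaper partial assessments:

- a merged, machine-readable **48-item instrument** (38 RQ items scored
  Y/N, 10 RoB items scored L/U/H, with an "irrelevant" (I) option where an
  item can be inapplicable) with stratum-level applicability rules over
  population (animal/human) × design (baseline comparison/treatment trial);
- validated **score-table I/O** (long or wide CSV, token harmonisation,
  dense normalisation, project merging);
- irrelevant-aware **per-item summaries** and the **DIV statistic**

  $$\mathrm{DIV} = 50 - \lvert\,\%Y - 50\,\rvert,$$

  where %Y is the percentage of scored studies reporting the element: 0
  when reporting is universal or absent (scoring the item across studies
  discriminates nothing), 50 when exactly half the studies report it;
- **stratified comparisons**: per-item contingency tables and Pearson
  chi-square tests (replicating base R `chisq.test`, including the Yates
  continuity correction for 2×2 tables), with optional Benjamini–Hochberg
  adjustment;
- **figures**: a DIV-shaded reporting heatmap and stacked traffic-light RoB
  bars, each backed by an auditable CSV;
- **partial-assessment strategies**: a rule-based recommender (sample 50%
  of studies for reviews of ≤ 50 papers, floor of 25 studies, down to 5%
  at ≥ 1000 papers, log-linear in between) and a seeded Monte-Carlo
  evaluator of the estimation error any such plan incurs;
- a **synthetic-corpus generator** calibrated to the published marginal
  percentages of a 164-study cystic-fibrosis/nasal-potential-difference
  case study (56 animal-baseline, 74 human-baseline, 22 animal-treatment,
  12 human-treatment studies; 48 × 164 = 7872 assessed cells), so the whole
  pipeline is testable without any deposited data.

## Worked example

```python
from robdiv import (paper_preset, generate, summarise, div_table,
                    compare_all, percentage, load_instrument)

instrument = load_instrument()            # bundled 48-item list
config = paper_preset(instrument, seed=7) # calibrated generating rates
table = generate(config, instrument)      # one synthetic corpus
table.validate()

s = summarise(table)
rq = s.totals["RQ"]
print(table.n_studies, table.n_assessments)
print(rq["counts"]["Y"], rq["n_scored"],
      percentage(rq["counts"]["Y"], rq["n_scored"]))
print(div_table(s, min_div=10).head(5).to_string(index=False))
```

prints

```
164 7872
1518 5640 26.9
item_id                  text  pct_reported  div
   A21a Conflicts of interest          36.6 36.6
    A1b      Unit of analysis          31.7 31.7
    A14        Ethical review          68.9 31.1
   A17b           Limitations          30.5 30.5
    C15       Baseline values          28.0 28.0
```

164 studies yield 7872 assessed cells; after dropping irrelevant scores,
1518 of 5640 RQ cells (26.9%) are "reported", and the most *informative*
elements — those closest to 50% reporting, hence best at discriminating
between studies — are the conflicts-of-interest statement, the unit of
analysis, ethics evaluation, limitations and baseline values. A chi-square
scan between animal and human studies is one call away:

```python
res = compare_all(table, "population")
print(res[~res.skipped].nlargest(3, "statistic")[["item_id", "statistic", "p"]])
```

Everything is also exposed on a CLI:

```sh
robdiv synth --preset paper --seed 7 --out-scores scores.csv --out-studies studies.csv
robdiv validate  --scores scores.csv --studies studies.csv
robdiv summarise --scores scores.csv --studies studies.csv --out out/
robdiv compare   --scores scores.csv --studies studies.csv --by population
robdiv plot      --scores scores.csv --studies studies.csv --kind heatmap --out fig
robdiv recommend --n 1000 --interest all_aspects
robdiv sample-eval --scores scores.csv --studies studies.csv --fraction 0.5 --reps 500 --seed 1
```

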