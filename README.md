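# phv — pharmacovigilance signal detection on annotated forum corpora

Patients discuss medicines and their side effects on health web forums long
before — and sometimes instead of — reporting them to regulators. Once an NLP
annotation pipeline has turned such posts into rows of normalized drug
annotations (ATC level-5 codes) and adverse-drug-event annotations (MedDRA
preferred-term codes), the statistical question is the classic one of
pharmacovigilance: *which drug–event pairs are reported together more often
than chance would allow, and when did the reporting rate change?*

`phv` is the statistical back end for that question. It is written for
pharmacoepidemiologists and data scientists who have (or want to simulate)
per-post annotation tables and need, offline and scriptable:

- **Corpus management** — validated CSV I/O in a 12-column annotation schema
  (one row = one drug annotation, one ADE annotation, or one drug–ADE
  *couple* when the annotator asserted causality on the same row), plus
  filtering by forum, period, ATC codes/prefixes and MedDRA terms.
- **Descriptive statistics** — corpus summaries, ranked distributions with
  cumulative frequencies, monthly time series, and the precision/recall/F1
  helper used to score annotation quality.
- **Disproportionality analysis** — event-level 2×2 contingency tables and
  the two standard measures, with log-scale 95% Wald intervals:

  PRR = [a/(a+b)] / [c/(c+d)]   and   ROR = ad/bc,

  where `a` counts couple events (drug of interest, ADE of interest), `b`
  (drug of interest, other ADEs), `c` (other drugs, ADE of interest), `d`
  (other drugs, other ADEs). Both equal 1 under independence; a *signal* is
  declared when the lower bound of the 95% CI of ln(PRR) (or ln(ROR))
  exceeds 0. Cumulative monthly PRR series track how a signal emerges.
- **Class-imbalanced subsampling lasso** — the regression-based detector for
  an ADE of interest: over B = 250 resamples, draw n₁ case posts (with
  replacement) from S₁ and R = max(4·n₁, 4·N_m) non-case posts from S₀, fit
  an L1-penalized logistic regression of ADE presence on all N_m per-post
  drug indicators (at most 50 predictors per model), and retain the drugs
  whose q-th percentile (q ∈ {5, 10, 15}) of the coefficient distribution
  across draws is strictly positive.
- **Change-point analysis** — CUSUM segmentation of monthly count series:
  the drift statistic max(S) − min(S) of the cumulative deviations from the
  segment mean is compared with 1000 permutations of the segment; confident
  shifts are split at the largest |Sᵢ| and the procedure recurses.
- **A synthetic corpus generator** — every analysis is testable without any
  scraped data: configurable forum mixture, drug/ADE catalogs, designed
  drug→ADE odds multipliers (the generator's ADE stage *is* the logistic
  model the lasso assumes), and injected volume surges as ground-truth
  changepoints.

## Worked example

The packaged surge scenario simulates 50 months of a thyroid-community
corpus: one dominant forum, a levothyroxine-class drug (ATC `H03AA01`)
strongly associated with the "Tiredness" preferred term (`10016256`), and a
three-fold post-volume surge at month 24.

```python
from phv import (ChangepointConfig, build_contingency, detect_breakpoints,
                 monthly_series, prr, rank_by, scenario_levothyrox)

corpus, truth = scenario_levothyrox(seed=1)
top = rank_by(corpus, "forum_name").rows[0]
print(top.label, top.cumulative_pct)

est = prr(build_contingency(corpus, "H03AA01", "10016256"))
print(round(est.point, 2), round(est.log_ci_low, 3), est.is_signal)

series = monthly_series(corpus, unit="couples",
                        atc_selector="H03AA01", meddra_selector="10016256")
for bp in detect_breakpoints(series, ChangepointConfig(seed=1)):
    print(bp.index, str(bp.month), round(bp.confidence, 3),
          round(bp.mean_before, 1), round(bp.mean_after, 1))
```

Output:

```
Vivre sans thyroïde 81.9
1.66 0.391 True
24 2019-01 1.0 5.1 16.8
32 2019-09 0.962 20.0 15.4
```

The dominant forum carries 81.9% of the annotations; the drug–ADE pair has a
proportional reporting ratio of 1.66 whose log-scale 95% lower bound (0.391)
is above 0, so the pair is flagged as a signal; and the CUSUM segmentation
places its first breakpoint after month 24 (January 2019, the injected
surge) with full bootstrap confidence, the mean monthly couple count
stepping from 5.1 to 16.8. The second, weaker split at month 32 is a
recursion artifact of multiple testing at the 0.95 threshold — the generator
injected no shift there, a reminder that recursive segmentation trades some
family-wise error for sensitivity.

The same workflow is available from the shell:

```bash
phv simulate --config sim.yaml --seed 1 --out corpus.csv --truth truth.json
phv describe --input corpus.csv --out reports/
phv signal --input corpus.csv --drug H03AA01 --ade 10016256
phv lasso --input corpus.csv --ade 10016256 --q 10 --seed 1
phv changepoint --input corpus.csv --drug H03AA01 --ade 10016256 --seed 1
```

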