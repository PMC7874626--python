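# hacrp

Scoring engine and stability analysis for the CMS **Hospital-Acquired
Condition Reduction Program (HACRP)** under its FY2015–FY2018 rules.

Since October 2014 CMS has penalized the worst-performing quartile of
U.S. hospitals — those with a **total HAC score** above the 75th
percentile — with a 1% reduction of Medicare payments. The total score
combines two domains:

* **Domain 1** — the AHRQ PSI-90 composite, a weighted mean of
  risk-adjusted patient-safety-indicator component ratios
  (`Σᵢ wᵢ rᵢ / Σᵢ wᵢ`). The component weights changed with each AHRQ
  software release (4.5a → 5.0.1 → 6.0.2); all four published weight
  columns are shipped verbatim.
* **Domain 2** — CDC NHSN standardized infection ratios (CLABSI, CAUTI,
  SSI, MRSA bacteremia, CDI), a measure set that grew year over year and
  switched CLABSI/CAUTI from ICU-only to ICU+ward surveillance in FY2018.

Two scoring methods are implemented. FY2015–17 use **decile scoring**:
each measure maps to a 1–10 relative rank (`decile = ⌈10·r/n⌉` with
max-rank `r` under ties), Domain 2 is the mean of per-measure decile
points. FY2018 uses **winsorized z-scores**: each measure is capped at
its empirical 5th/95th percentiles (`p-th percentile` = order statistic
at `⌈p·n⌉`), standardized as `z = (clamp(x, p₅, p₉₅) − μ_w)/σ_w`, and
Domain 2 is the mean of per-measure z's. Domain weights are 35/65
(FY2015), 25/75 (FY2016) and 15/85 (FY2017–18) for Domain 1/Domain 2;
a hospital with only one domain gets 100% weight on it, and hospitals
with no Domain 2 data are either excused (HAI exception) or assigned the
maximum Domain 2 score.

Because the real inputs (HCUP state inpatient data, NHSN files) are
restricted, the package ships a seeded synthetic-cohort generator with
the study sample's structure (1704 hospitals, ~65% reporting at least
one Domain 2 measure, positively correlated lognormal measures, injected
ties), and a comparison module that scores one cohort under all four
methodologies and quantifies penalty-set overlap and rank churn.

Intended users: health-services and policy researchers studying
pay-for-performance programs, and anyone needing a reproducible,
testable implementation of the HACRP scoring arithmetic.

## Worked example

```python
from hacrp import builtin_methodologies, generate_worked_micro_cohort, score_methodology

cohort = generate_worked_micro_cohort()          # fixed 12-hospital cohort
scored = score_methodology(cohort, builtin_methodologies()[2016])
print(scored.table[["hospital_id", "domain1", "domain2", "total", "penalized"]]
      .to_string(index=False))
print(f"threshold (75th pct): {scored.threshold}")
print(f"penalized: {sorted(scored.penalty_set)}")
```

prints

```
hospital_id  domain1   domain2  total  penalized
        M01        1  2.333333  2.000      False
        M02        5  6.333333  6.000      False
        M03        6  5.000000  5.250      False
        M04        5  9.000000  8.000       True
        M05        9  5.000000  6.000      False
        M06        2  5.000000  4.250      False
        M07        3  2.500000  2.625      False
        M08        8  7.500000  7.625       True
        M09        7       NaN  7.000      False
        M10        4       NaN  4.000      False
        M11       10  5.666667  6.750      False
        M12       10 10.000000 10.000       True
threshold (75th pct): 7.0
penalized: ['M04', 'M08', 'M12']
```

Under the FY2016 rules each hospital's Domain 1 is the decile of its
PSI-90 composite (4.5a POA weights), Domain 2 the mean decile of its
reported infection ratios, and the total `0.25·D1 + 0.75·D2`. M09 and
M10 report no infection data, so 100% weight falls on Domain 1
(`domain2` is blank). The 75th-percentile cutoff of the twelve totals is
7.0, and the three hospitals strictly above it are penalized.

## Analysis pipeline

The full study-style analysis lives in `analysis/`, each script a thin
driver over the library:

```bash
python analysis/01_simulate_cohort.py      # default 1704-hospital cohort -> results/cohort.csv
python analysis/02_score_methodologies.py  # FY2015-18 x {exception, max_score} -> results/scored_*.csv
python analysis/03_compare_methodologies.py  # overlap matrix, rank shifts -> results/comparison_*.csv
```

The same operations are available from the shell via the `hacrp` CLI
(`hacrp simulate|score|compare`, see `--help`).

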