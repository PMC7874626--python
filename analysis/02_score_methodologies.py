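#!/usr/bin/env python
"""Score the cohort under all four fiscal-year methodologies.

Applies the FY2015-FY2018 scoring rules to the one cohort produced by
01_simulate_cohort.py ("retrospective" design: the data are held fixed
while the rules change), under both treatments of hospitals with no
Domain 2 data (HAI exception vs maximum-score imputation).

Writes results/scored_FY<year>_<mode>.csv and prints, per methodology,
the penalty threshold and the number of penalized hospitals.
"""

import logging
from pathlib import Path

from hacrp import builtin_methodologies, read_cohort, score_methodology, write_scored

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    cohort = read_cohort(RESULTS / "cohort.csv")
    for fy, config in builtin_methodologies().items():
        for mode in ("exception", "max_score"):
            scored = score_methodology(cohort.records, config.with_mode(mode))
            out = RESULTS / f"scored_FY{fy}_{mode}.csv"
            write_scored(scored, out)
            print(f"FY{fy} [{mode:>9}]  threshold={scored.threshold:8.4f}  "
                  f"penalized={int(scored.table['penalized'].sum()):4d}  "
                  f"skipped={len(scored.skipped)}  -> {out.name}")


if __name__ == "__main__":
    main()
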