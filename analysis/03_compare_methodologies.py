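#!/usr/bin/env python
"""Cross-methodology stability of the penalized quartile.

Scores the shared cohort under the four methodologies (HAI-exception
treatment of missing Domain 2 data), then reports the pairwise percent
overlap of the penalty sets, the percent of hospitals penalized under
every methodology, and pairwise rank-shift statistics.  A heatmap of
the overlap matrix goes to scratch/ (image output is auxiliary).

Writes results/comparison_{overlap,rank_shifts,summary}.csv.
"""

import logging
from pathlib import Path

from hacrp import builtin_methodologies, compare_all, read_cohort, write_comparison

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    cohort = read_cohort(RESULTS / "cohort.csv")
    configs = [builtin_methodologies()[fy] for fy in (2015, 2016, 2017, 2018)]
    result = compare_all(cohort.records, configs)
    paths = write_comparison(result, RESULTS / "comparison")

    print("pairwise % overlap of penalty sets:")
    print(result.overlap_matrix.round(1).to_string())
    print(f"\npenalized under all four methodologies: {result.all_years_pct:.1f}%")
    print("\nrank shifts (totals, same cohort):")
    for (a, b), s in sorted(result.pairwise_rank_stats.items()):
        print(f"  {a} vs {b}: Spearman={s.spearman:.3f}  "
              f"mean|shift|={s.mean_abs_percentile_shift:.2f} percentile pts  "
              f"threshold crossings={s.boundary_crossings}")
    for name, p in paths.items():
        print(f"{name}: {p}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        scratch = ROOT / "scratch"
        scratch.mkdir(exist_ok=True)
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(result.overlap_matrix.values, vmin=0, vmax=100, cmap="viridis")
        labels = list(result.methodologies)
        ax.set_xticks(range(len(labels)), labels)
        ax.set_yticks(range(len(labels)), labels)
        for i in range(len(labels)):
            for j in range(len(labels)):
                ax.text(j, i, f"{result.overlap_matrix.iat[i, j]:.0f}",
                        ha="center", va="center", color="white")
        fig.colorbar(im, label="% overlap of penalty sets")
        fig.tight_layout()
        fig.savefig(scratch / "overlap_heatmap.png", dpi=150)
        print(f"heatmap: {scratch / 'overlap_heatmap.png'}")
    except Exception as err:  # plotting is best-effort
        print(f"heatmap skipped: {err}")


if __name__ == "__main__":
    main()
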