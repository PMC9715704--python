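#!/usr/bin/env python
"""Capture-performance QC on the synthetic cohort: on-target proportions,
fold-increase, enrichment factors, windowed coverage homogeneity, and the
<4X / non-enriched sample filters."""

from pathlib import Path

import numpy as np

from ydna import io as yio
from ydna.qc import compute_capture_metrics, expected_window_count, filter_samples

COHORT = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    regions = yio.read_bed(COHORT / "regions.bed")
    counts = yio.read_counts_table(COHORT / "counts.tsv")
    depths = yio.read_depth_table(COHORT / "depths.tsv")

    metrics = compute_capture_metrics(counts, depths, regions)
    per = metrics.per_sample
    kept, discard = filter_samples(metrics, min_median_depth=4.0, min_fold_increase=5.0)

    per.to_csv(RESULTS / "qc_report.tsv", sep="\t", index=False)
    discard.to_csv(RESULTS / "qc_discards.tsv", sep="\t", index=False)
    with open(RESULTS / "qc_kept_samples.txt", "w") as fh:
        fh.write("\n".join(kept) + "\n")

    print(f"{len(per)} capture libraries over a {regions.total_length/1e6:.1f} Mb target")
    print(f"  windows tiled: {expected_window_count(regions)} x 10 kb")
    print(f"  median on-target proportion: {per['on_target_proportion'].median():.3f}")
    print(f"  mean enrichment factor: {per['enrichment_factor'].mean():.1f}")
    print(f"  median target depth: {per['median_depth'].median():.1f}X")
    print(f"  kept {len(kept)}, discarded {len(discard)}:")
    for _, row in discard.iterrows():
        print(f"    {row['sample_id']}: {row['reason']}")


if __name__ == "__main__":
    main()
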