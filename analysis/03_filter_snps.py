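#!/usr/bin/env python
"""SNP-level filters: capture-vs-WGS reference-bias screen (Fisher exact +
Benjamini-Hochberg, significant SNPs merged into fragments) followed by the
<5% missingness filter.  Writes the filtered matrix for the later stages."""

from pathlib import Path

import pandas as pd

from ydna import io as yio
from ydna.phylo import apply_bias_filter, reference_bias_screen, snp_missingness_filter

COHORT = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    matrix = yio.read_haploid_vcf(COHORT / "calls.vcf")
    meta = yio.read_sample_table(COHORT / "meta.tsv")
    platforms = pd.Series(meta["platform"].values, index=meta["sample_id"])

    n0 = matrix.n_snps
    bias = reference_bias_screen(matrix, platforms, merge_distance=5_000, q_threshold=0.01)
    matrix = apply_bias_filter(matrix, bias)
    matrix, removed = snp_missingness_filter(matrix, max_missing=0.05)

    bias.fragments.to_csv(RESULTS / "bias_fragments.tsv", sep="\t", index=False)
    yio.write_haploid_vcf(matrix, COHORT / "filtered.vcf")

    print(f"input matrix: {matrix.n_samples} samples x {n0} SNPs")
    print(
        f"  reference-bias screen: {bias.n_snps_removed} SNPs in "
        f"{len(bias.fragments)} fragments ({bias.bp_removed} bp) removed"
    )
    for _, f in bias.fragments.iterrows():
        print(f"    fragment {f['start']}-{f['end']}: {f['n_snps']} SNPs")
    print(f"  missingness <5% filter: {len(removed)} SNPs removed")
    print(f"  retained: {matrix.n_snps} SNPs -> {COHORT / 'filtered.vcf'}")


if __name__ == "__main__":
    main()
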