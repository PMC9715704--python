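#!/usr/bin/env python
"""Haplogroup and paragroup calls against the 22-haplogroup R1b-DF27 tree,
regional frequency tables, and a round-trip check against the generator's
planted assignments."""

import json
from pathlib import Path

from ydna import haplogroups as hg
from ydna import io as yio

COHORT = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    matrix = yio.read_haploid_vcf(COHORT / "filtered.vcf")
    tree = yio.read_tree_spec(COHORT / "tree.yaml")
    meta = yio.read_sample_table(COHORT / "meta.tsv")
    regions = yio.read_bed(COHORT / "regions.bed")
    truth = json.loads((COHORT / "truth.json").read_text())["sample_nodes"]

    calls = hg.assign_all(matrix, tree, region_set=regions)
    table = hg.calls_table(calls)
    table.to_csv(RESULTS / "haplogroup_calls.tsv", sep="\t", index=False)

    meta_g = meta[meta["sample_id"].isin(matrix.sample_ids)]
    freqs = hg.haplogroup_frequencies(calls, meta_g, denominator="all")
    freqs.to_csv(RESULTS / "haplogroup_frequencies.tsv", sep="\t", index=False)

    correct = sum(1 for c in calls if c.terminal == truth[c.sample_id])
    starred = sum(1 for c in calls if c.starred)
    para = sum(1 for c in calls if c.label == "DF27*")
    print(f"{len(calls)} samples assigned against {len(tree)} haplogroups")
    print(f"  terminal node matches planted truth: {correct}/{len(calls)}")
    print(f"  starred (paragroup) calls: {starred}; DF27*: {para} "
          f"({para / len(calls):.0%} of the cohort)")
    print("  most frequent calls per region:")
    for region, sub in freqs.groupby("region"):
        top = sub.sort_values("proportion", ascending=False).iloc[0]
        print(f"    {region}: {top['haplogroup']} ({top['proportion']:.0%})")


if __name__ == "__main__":
    main()
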