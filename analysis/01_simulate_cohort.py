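#!/usr/bin/env python
"""Build the synthetic study cohort every later stage analyses.

Emulates the study design at reduced scale: 120 capture libraries (9 planted
below the 4X coverage cutoff and 1 never enriched), 40 whole-genome samples
joining at genotyping, haplogroup composition varying across seven
geographical regions, ~35 private mutations per lineage over the 8.9 Mb
target (the mutational depth of a ~5,200-year-old star expansion), one
planted capture-biased fragment and a block of high-missingness SNPs.

Writes scratch/cohort/{calls.vcf,meta.tsv,regions.bed,counts.tsv,depths.tsv,
tree.yaml,truth.json}.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ydna import io as yio
from ydna.core import GenotypeMatrix, MISSING, default_region_set, make_sample_table
from ydna.simulate import simulate_capture_counts, simulate_from_tree
from ydna.tree import default_df27_tree

# per-region haplogroup composition (counts), loosely following the
# published regional pattern: paragroup lineages prevalent in the west,
# the M167/CTS4299 chain in Catalonia, Z220/M153 among Basques
COMPOSITION: dict[str, dict[str, int]] = {
    "Andalusia": {"DF27": 13, "Z220": 5, "L176.2": 2, "Z195": 1, "DF81": 1},
    "Asturias": {"DF27": 8, "DF81": 3, "Z220": 4, "M167": 1, "Z195": 1},
    "Catalonia": {"DF27": 3, "L176.2": 4, "M167": 3, "CTS4299": 5, "Z205": 2, "Z208": 2, "Z220": 4},
    "Central Spain": {"DF27": 10, "DF81": 1, "Z220": 5, "L176.2": 2, "CTS11567": 1},
    "Basque Country": {"DF27": 7, "Z220": 8, "M153": 4, "DF81": 5, "Z272": 3, "M167": 2},
    "Galicia": {"DF27": 13, "Z220": 6, "L176.2": 1, "Z222": 1},
    "NW Europe": {"DF27": 3, "L176.2": 8, "M167": 4, "CTS4299": 2, "CTS6519.1": 1, "Z195": 1},
}

N_GOOD_CAPTURE, N_LOW, N_NONENRICHED, N_WGS = 110, 9, 1, 40
PRIVATE_MUT_MEAN = 35.0


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20)
    ap.add_argument("--out", type=Path, default=Path("scratch/cohort"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    regions = default_region_set()
    tree = default_df27_tree()

    # --- capture read counts and windowed depths -------------------------
    good_c, good_d = simulate_capture_counts(
        N_GOOD_CAPTURE, 15_000_000, 30.0, regions, seed=args.seed, sample_prefix="CAP"
    )
    low_c, low_d = simulate_capture_counts(
        N_LOW, 3_500_000, 30.0, regions, seed=args.seed + 1, sample_prefix="LOW"
    )
    ne_c, ne_d = simulate_capture_counts(
        N_NONENRICHED, 15_000_000, 1.0, regions, seed=args.seed + 2, sample_prefix="NE"
    )
    counts = pd.concat([good_c, low_c, ne_c], ignore_index=True)
    depths = pd.concat([good_d, low_d, ne_d], ignore_index=True)

    # --- genotypes for QC-passing capture + WGS samples ------------------
    node_counts: dict[str, int] = {}
    assignments: list[tuple[str, str]] = []  # (node, region)
    for region, comp in COMPOSITION.items():
        for node, k in comp.items():
            node_counts[node] = node_counts.get(node, 0) + k
            assignments.extend([(node, region)] * k)
    n_geno = len(assignments)
    assert n_geno == N_GOOD_CAPTURE + N_WGS, n_geno

    matrix, truth = simulate_from_tree(
        tree, node_counts, PRIVATE_MUT_MEAN, seed=args.seed + 3, regions=regions
    )

    # samples are named <node>_<i>; map them onto cohort ids and regions
    per_node_regions: dict[str, list[str]] = {}
    for node, region in assignments:
        per_node_regions.setdefault(node, []).append(region)
    old_ids = list(matrix.sample_ids)
    wgs_slots = set(np.linspace(0, n_geno - 1, N_WGS).round().astype(int).tolist())
    assert len(wgs_slots) == N_WGS
    new_ids, sample_regions, platforms = [], [], []
    cap_i = wgs_i = 0
    for pos, old in enumerate(old_ids):
        node = old.rsplit("_", 1)[0]
        sample_regions.append(per_node_regions[node].pop())
        if pos in wgs_slots:
            new_ids.append(f"WGS{wgs_i:03d}")
            platforms.append("wgs")
            wgs_i += 1
        else:
            new_ids.append(f"CAP{cap_i:03d}")
            platforms.append("capture")
            cap_i += 1
    truth.sample_nodes = {
        new: old.rsplit("_", 1)[0] for new, old in zip(new_ids, old_ids)
    }
    matrix = GenotypeMatrix(
        new_ids, matrix.snp_names, matrix.positions, matrix.alleles, matrix.calls
    )

    # --- plant a capture-biased fragment ---------------------------------
    is_cap = np.array([p == "capture" for p in platforms])
    frag_start = regions.intervals[4][0] + 3_000
    bias_positions = sorted(
        int(p) for p in rng.choice(np.arange(frag_start, frag_start + 9_000), 12, replace=False)
    )
    existing = set(matrix.positions.tolist())
    bias_positions = [p for p in bias_positions if p + 1 not in existing]
    bias_calls = np.zeros((matrix.n_samples, len(bias_positions)), dtype=np.int8)
    for j in range(len(bias_positions)):
        derived = rng.random(matrix.n_samples) < 0.45
        bias_calls[derived & is_cap, j] = 1
    all_pos = np.concatenate([matrix.positions, np.array(bias_positions) + 1])
    all_names = matrix.snp_names + [f"bias{j}" for j in range(len(bias_positions))]
    all_alleles = matrix.alleles + [("A", "T")] * len(bias_positions)
    all_calls = np.hstack([matrix.calls, bias_calls])
    order = np.argsort(all_pos)
    matrix = GenotypeMatrix(
        matrix.sample_ids,
        [all_names[i] for i in order],
        all_pos[order],
        [all_alleles[i] for i in order],
        all_calls[:, order],
    )

    # --- plant high-missingness SNPs (private sites only) -----------------
    tree_snps = tree.all_snps()
    private_idx = [
        k for k, nm in enumerate(matrix.snp_names)
        if nm not in tree_snps and not nm.startswith("bias")
    ]
    n_degraded = 25
    degraded = rng.choice(private_idx, n_degraded, replace=False)
    for k in degraded:
        hit = rng.choice(matrix.n_samples, max(2, int(0.08 * matrix.n_samples)), replace=False)
        matrix.calls[hit, k] = MISSING

    # --- write the bundle -------------------------------------------------
    yio.write_haploid_vcf(matrix, out / "calls.vcf")
    yio.write_bed(regions, out / "regions.bed")
    all_ids = counts["sample_id"].tolist() + [s for s in new_ids if s.startswith("WGS")]
    meta_regions = {sid: reg for sid, reg in zip(new_ids, sample_regions)}
    meta = make_sample_table(
        all_ids,
        [meta_regions.get(s, "Central Spain") for s in all_ids],
        batches=["SEQ1" if i % 2 == 0 else "SEQ2" for i in range(len(all_ids))],
        platforms=["capture" if not s.startswith("WGS") else "wgs" for s in all_ids],
    )
    yio.write_sample_table(meta, out / "meta.tsv")
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    depths.to_csv(out / "depths.tsv", sep="\t", index=False)
    yio.write_tree_spec(tree, out / "tree.yaml")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": args.seed,
                "private_mut_mean": PRIVATE_MUT_MEAN,
                "implied_tmrca_years": PRIVATE_MUT_MEAN * 147.84,
                "n_planted_low_coverage": N_LOW,
                "n_planted_nonenriched": N_NONENRICHED,
                "n_bias_snps": len(bias_positions),
                "n_high_missing_snps": n_degraded,
                "sample_nodes": truth.sample_nodes,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    print(f"cohort: {matrix.n_samples} genotyped samples x {matrix.n_snps} SNPs")
    print(f"  {len(counts)} capture libraries ({N_LOW} low-coverage, {N_NONENRICHED} non-enriched planted)")
    print(f"  planted bias fragment: {len(bias_positions)} SNPs near {frag_start}")
    print(f"  planted high-missingness SNPs: {n_degraded}")
    print(f"written to {out}/")


if __name__ == "__main__":
    main()
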