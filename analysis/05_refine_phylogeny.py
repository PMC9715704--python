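#!/usr/bin/env python
"""Perfect-phylogeny census and bundle refinement on the filtered matrix:
how many branches stem directly from the DF27 base, how many are singleton
lineages, and where the uncertain-position ("~") SNP bundles fall."""

from pathlib import Path

from ydna import io as yio
from ydna.phylo import build_perfect_phylogeny, resolve_bundle
from ydna.tree import HaplogroupTree

COHORT = Path("scratch/cohort")
RESULTS = Path("results")

# the ISOGG 2019-2020 nine-SNP bundle below DF27 and the four-SNP chain
# bundle below M167, as they stood before refinement
NINE_SNP_BUNDLE = [
    "CTS6519.1", "S4247.1", "CTS11567", "Z2572", "DF79", "DF81", "DF83", "DF84",
    "S453", "Z224", "Z222", "S360", "Z223",
]
M167_BUNDLE = ["Z205", "Z208", "CTS8289", "CTS4299"]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    matrix = yio.read_haploid_vcf(COHORT / "filtered.vcf")
    tree = yio.read_tree_spec(COHORT / "tree.yaml")

    pp = build_perfect_phylogeny(matrix)
    stem = pp.stem()
    branches, singles = pp.branch_census(stem)
    (RESULTS / "phylogeny.nwk").write_text(pp.to_newick() + "\n")
    pp.quarantined.to_csv(RESULTS / "quarantined_sites.tsv", sep="\t", index=False)

    print(f"perfect phylogeny over {matrix.n_samples} samples x {matrix.n_snps} SNPs")
    print(f"  branches stemming from the {('|'.join(stem.snps) or 'root')} base: {branches}")
    print(f"  of which singleton lineages: {singles}")
    print(f"  quarantined sites: {len(pp.quarantined)}")

    for label, bundle, parent in (
        ("nine-SNP basal bundle", NINE_SNP_BUNDLE, tree.root),
        ("M167 chain bundle", M167_BUNDLE, "M167"),
    ):
        present = [s for s in bundle if s in matrix.snp_names]
        absent = [s for s in bundle if s not in matrix.snp_names]
        rep = resolve_bundle(present, matrix, tree, parent=parent)
        rep.to_csv(
            RESULTS / f"bundle_{label.split()[0]}.tsv", sep="\t", index=False
        )
        print(f"  {label}:")
        for _, row in rep.iterrows():
            print(f"    {row['snp']}: {row['classification']} "
                  f"({row['carrier_count']} carriers) {row['detail']}")
        for s in absent:
            print(f"    {s}: not observed in the callable matrix")


if __name__ == "__main__":
    main()
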