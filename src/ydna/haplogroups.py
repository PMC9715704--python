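"""Haplogroup assignment against a SNP-annotated tree.

A sample's terminal haplogroup is the deepest tree node supported by its
derived alleles; derived alleles off the chosen root-to-node path are
conflicts and flag the call.  A paragroup (starred call, e.g. DF27*) is a
sample derived at a node but confirmed ancestral at every known
child-defining SNP inside the target region — the lineages sitting on a
branch with no named substructure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, RegionSet
from .tree import HaplogroupTree


@dataclass
class HaplogroupCall:
    sample_id: str
    terminal: str
    starred: bool = False
    supporting: list[str] = field(default_factory=list)
    conflicting: list[str] = field(default_factory=list)
    missing_on_path: list[str] = field(default_factory=list)
    root_call: bool = False
    uncertain_paragroup: bool = False

    @property
    def label(self) -> str:
        return self.terminal + ("*" if self.starred else "")

    @property
    def flagged(self) -> bool:
        return self.root_call or bool(self.conflicting)


def _genotype_lookup(matrix: GenotypeMatrix, sample_idx: int) -> dict[str, int]:
    row = matrix.calls[sample_idx]
    return {name: int(row[k]) for k, name in enumerate(matrix.snp_names)}


def assign_haplogroup(
    genotypes: dict[str, int], tree: HaplogroupTree, sample_id: str = ""
) -> HaplogroupCall:
    """Assign the terminal haplogroup for one sample.

    ``genotypes`` maps SNP name -> 0/1/missing(-1); SNPs absent from the map
    are treated as missing.  The call is the deepest node maximising
    (supporting - conflicting) derived SNPs over its root-to-node path, ties
    broken toward the shallower node, so a clean genotype stops at the last
    node with derived evidence.  A missing path genotype never blocks
    descent when a deeper defining SNP is derived; such steps are recorded.
    """
    derived = {s for s, g in genotypes.items() if g == 1 and tree.node_of_snp(s)}
    scored: list[tuple[int, int, str]] = []  # (score, depth, name)
    for name in tree.nodes:
        path_snps = tree.path_snps(name)
        support = len(derived & path_snps)
        conflict = len(derived - path_snps)
        scored.append((support - conflict, tree.depth(name), name))
    best_score = max(s for s, _, _ in scored)
    candidates = [(d, nm) for s, d, nm in scored if s == best_score]
    depth, terminal = min(candidates)  # shallower wins ties, then name order
    path_snps = tree.path_snps(terminal)
    supporting = sorted(derived & path_snps)
    conflicting = sorted(derived - path_snps)
    missing_on_path = sorted(
        s for s in path_snps if genotypes.get(s, MISSING) == MISSING
    )
    return HaplogroupCall(
        sample_id=sample_id,
        terminal=terminal,
        supporting=supporting,
        conflicting=conflicting,
        missing_on_path=missing_on_path,
        root_call=(terminal == tree.root and not supporting),
    )


def call_paragroup(
    call: HaplogroupCall,
    genotypes: dict[str, int],
    tree: HaplogroupTree,
    region_set: RegionSet | None = None,
    snp_positions: dict[str, int] | None = None,
) -> HaplogroupCall:
    """Decide the star (paragroup) status of a terminal call.

    The star is appended iff the sample is confirmed ancestral (called, not
    missing) at every child-node defining SNP that maps inside the target
    region.  If every child SNP is missing the node is reported unstarred
    with an uncertainty flag.  Leaf nodes never star: a paragroup requires
    known child branches to be ancestral for.
    """
    node = call.terminal
    child_snps = tree.children_snps(node)
    if region_set is not None and snp_positions is not None:
        child_snps = {
            s for s in child_snps
            if s in snp_positions and region_set.contains(snp_positions[s])
        }
    if not tree.nodes[node].children:
        call.starred = False
        return call
    if not child_snps:
        # children exist but none of their SNPs are observable in the target
        call.starred = False
        call.uncertain_paragroup = True
        return call
    states = [genotypes.get(s, MISSING) for s in child_snps]
    if all(g == MISSING for g in states):
        call.starred = False
        call.uncertain_paragroup = True
    else:
        call.starred = all(g == 0 for g in states)
    return call


def assign_all(
    matrix: GenotypeMatrix,
    tree: HaplogroupTree,
    region_set: RegionSet | None = None,
) -> list[HaplogroupCall]:
    """Terminal + paragroup calls for every sample in the matrix."""
    snp_positions = {
        name: int(pos) for name, pos in zip(matrix.snp_names, matrix.positions)
    }
    calls = []
    for i, sid in enumerate(matrix.sample_ids):
        genotypes = _genotype_lookup(matrix, i)
        call = assign_haplogroup(genotypes, tree, sample_id=sid)
        call = call_paragroup(call, genotypes, tree, region_set, snp_positions)
        calls.append(call)
    return calls


def calls_table(calls: list[HaplogroupCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "haplogroup": [c.label for c in calls],
            "terminal": [c.terminal for c in calls],
            "starred": [c.starred for c in calls],
            "n_supporting": [len(c.supporting) for c in calls],
            "conflicting": [",".join(c.conflicting) for c in calls],
            "missing_on_path": [",".join(c.missing_on_path) for c in calls],
            "flagged": [c.flagged for c in calls],
        }
    )


def haplogroup_frequencies(
    calls: list[HaplogroupCall],
    metadata: pd.DataFrame,
    denominator: str = "all",
    tree: HaplogroupTree | None = None,
    focal: str | None = None,
) -> pd.DataFrame:
    """Haplogroup counts and proportions per region.

    ``denominator='all'`` divides by all samples in the region;
    ``denominator='within'`` restricts both numerator and denominator to
    calls at or below ``focal`` (e.g. proportions over DF27 chromosomes).
    """
    if denominator not in ("all", "within"):
        raise ValueError("denominator must be 'all' or 'within'")
    region_of = dict(zip(metadata["sample_id"], metadata["region"]))
    known = set(region_of)
    for c in calls:
        if c.sample_id not in known:
            raise ValueError(f"sample {c.sample_id!r} has no region label")
    rows = []
    use = calls
    if denominator == "within":
        if tree is None or focal is None:
            raise ValueError("within-haplogroup denominator needs tree and focal node")
        member = {focal} | tree.descendants(focal)
        use = [c for c in calls if c.terminal in member]
    df = pd.DataFrame(
        {
            "region": [region_of[c.sample_id] for c in use],
            "haplogroup": [c.label for c in use],
        }
    )
    for (region, hg), sub in df.groupby(["region", "haplogroup"]):
        rows.append((region, hg, len(sub)))
    out = pd.DataFrame(rows, columns=["region", "haplogroup", "count"])
    totals = out.groupby("region")["count"].transform("sum")
    out["proportion"] = out["count"] / totals
    out["denominator"] = denominator
    return out.sort_values(["region", "haplogroup"]).reset_index(drop=True)
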