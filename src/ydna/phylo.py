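"""Perfect-phylogeny construction and SNP-bundle refinement.

On an infinite-sites binary matrix rooted at the all-ancestral haplotype,
compatible SNPs have carrier sets that are nested or disjoint, so they tile
onto a unique rooted tree with each SNP labelling one edge.  Sites violating
compatibility (recurrent mutation, reference bias, genotyping error) are
quarantined, not fatal.  The same carrier-set relations drive the
classification of ISOGG "~" bundles — sets of SNPs whose position below a
parent node is unresolved — into same-branch groups, nested chains, or new
basal branches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .core import MISSING, GenotypeMatrix
from .tree import HaplogroupTree

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# compatibility


def four_gamete_test(site_i: int, site_j: int, matrix: GenotypeMatrix) -> str:
    """Classic unrooted four-gamete test over pairwise-complete observations.

    Returns ``"incompatible"`` iff all four gamete combinations 00, 01, 10,
    11 are observed among samples called at both sites, ``"indeterminate"``
    if no sample is called at both, else ``"compatible"``.
    """
    a = matrix.calls[:, site_i]
    b = matrix.calls[:, site_j]
    ok = (a != MISSING) & (b != MISSING)
    if not ok.any():
        return "indeterminate"
    combos = set(zip(a[ok].tolist(), b[ok].tolist()))
    if len(combos) == 4:
        return "incompatible"
    return "compatible"


def _rooted_incompatible(ci: frozenset, cj: frozenset, both_called: bool) -> bool:
    """Rooted (all-ancestral outgroup) criterion: carrier sets must be nested
    or disjoint.  The root supplies the 00 gamete, so overlap without
    nesting is already a conflict."""
    if not both_called:
        return False
    inter = ci & cj
    return bool(inter) and not (ci <= cj or cj <= ci)


# ---------------------------------------------------------------------------
# perfect phylogeny


@dataclass
class PhyloNode:
    clade: frozenset
    snps: list[str] = field(default_factory=list)
    children: list["PhyloNode"] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)  # leaves attached here


@dataclass
class PerfectPhylogeny:
    root: PhyloNode
    quarantined: pd.DataFrame  # snp, reason
    n_root_branches: int
    n_singleton_branches: int
    snp_edge: dict[str, frozenset]

    def stem(self) -> PhyloNode:
        """Deepest node through which every sample passes — the base of the
        in-group when all samples share a defining mutation."""
        node = self.root
        while len(node.children) == 1 and not node.samples:
            node = node.children[0]
        return node

    def branch_census(self, node: PhyloNode | None = None) -> tuple[int, int]:
        """(branches, singleton branches) stemming directly from ``node``."""
        node = node or self.root
        n_branches = len(node.children) + len(node.samples)
        singles = sum(1 for ch in node.children if len(ch.clade) == 1) + len(node.samples)
        return n_branches, singles

    def clades(self) -> set[frozenset]:
        out: set[frozenset] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node is not self.root:
                out.add(node.clade)
            stack.extend(node.children)
        return out

    def to_newick(self) -> str:
        def rec(node: PhyloNode) -> str:
            parts = [rec(c) for c in node.children] + list(node.samples)
            label = "|".join(node.snps)
            if not parts:
                return label or "anon"
            return "(" + ",".join(parts) + ")" + label

        return rec(self.root) + ";"


def build_perfect_phylogeny(matrix: GenotypeMatrix) -> PerfectPhylogeny:
    """Greedy rooted perfect phylogeny over the observed carrier sets.

    Sites are processed in order of decreasing carrier count; a site is
    retained if its carrier set is nested-or-disjoint with every retained
    set (checked over pairwise-complete observations); otherwise it is
    quarantined with a reason.  Monomorphic sites (no called carrier) are
    quarantined as uninformative.  Reports the root-branch census: the
    number of branches stemming directly from the root and how many of them
    are singleton lineages.
    """
    n = matrix.n_samples
    carriers = []
    called_idx = []
    for k in range(matrix.n_snps):
        col = matrix.calls[:, k]
        carriers.append(frozenset(np.flatnonzero(col == 1).tolist()))
        called_idx.append(frozenset(np.flatnonzero(col != MISSING).tolist()))
    order = sorted(range(matrix.n_snps), key=lambda k: (-len(carriers[k]), k))
    retained: list[int] = []
    quarantine: list[tuple[str, str]] = []
    membership: dict[int, set[int]] = {i: set() for i in range(n)}
    for k in order:
        ck = carriers[k]
        if not ck:
            quarantine.append((matrix.snp_names[k], "no derived carriers"))
            continue
        conflict = None
        # observed carrier sets that are nested or disjoint can never show
        # all four gametes, so laminarity over the intersecting retained
        # sets is the whole rooted compatibility check
        cand: set[int] = set()
        for i in ck:
            cand |= membership[i]
        for r in cand:
            if _rooted_incompatible(ck, carriers[r], True):
                conflict = (matrix.snp_names[r], "carrier sets overlap without nesting")
                break
        if conflict is None:
            # disjoint retained sites with no co-called sample cannot be
            # placed relative to this one (possible only under heavy
            # missingness: call sets must be disjoint too)
            for r in retained:
                if r in cand:
                    continue
                if len(called_idx[k]) + len(called_idx[r]) <= n and not (
                    called_idx[k] & called_idx[r]
                ):
                    conflict = (matrix.snp_names[r], "no overlapping calls")
                    break
        if conflict is not None:
            quarantine.append(
                (matrix.snp_names[k], f"incompatible with {conflict[0]}: {conflict[1]}")
            )
        else:
            retained.append(k)
            for i in ck:
                membership[i].add(k)

    # group retained sites by carrier set -> edges
    by_clade: dict[frozenset, list[str]] = {}
    for k in retained:
        by_clade.setdefault(carriers[k], []).append(matrix.snp_names[k])
    root = PhyloNode(clade=frozenset(range(n)))
    nodes = {root.clade: root}
    # attach bigger clades first so parents exist before children
    for clade in sorted(by_clade, key=len, reverse=True):
        # a full-sample carrier set is the stem edge below the all-ancestral
        # root and becomes an ordinary child node
        node = PhyloNode(clade=clade, snps=sorted(by_clade[clade]))
        parent = root
        changed = True
        while changed:
            changed = False
            for ch in parent.children:
                if clade <= ch.clade and clade != ch.clade:
                    parent = ch
                    changed = True
                    break
        parent.children.append(node)
        nodes[clade] = node
    # attach each sample as a leaf at its minimal containing node
    for i in range(n):
        parent = root
        changed = True
        while changed:
            changed = False
            for ch in parent.children:
                if i in ch.clade:
                    parent = ch
                    changed = True
                    break
        parent.samples.append(matrix.sample_ids[i])

    n_root = len(root.children) + len(root.samples)
    singles = sum(1 for ch in root.children if len(ch.clade) == 1) + len(root.samples)
    snp_edge = {
        matrix.snp_names[k]: carriers[k] for k in retained
    }
    return PerfectPhylogeny(
        root=root,
        quarantined=pd.DataFrame(quarantine, columns=["snp", "reason"]),
        n_root_branches=n_root,
        n_singleton_branches=singles,
        snp_edge=snp_edge,
    )


# ---------------------------------------------------------------------------
# bundle resolution


def resolve_bundle(
    bundle: set[str] | list[str],
    matrix: GenotypeMatrix,
    tree: HaplogroupTree,
    parent: str | None = None,
) -> pd.DataFrame:
    """Classify each SNP of an uncertain-position ("~") bundle.

    For every bundle SNP with at least one derived carrier the observed
    carrier sets decide its placement: identical carrier sets are the same
    branch; strictly nested sets form an ordered chain (position 1 is the
    outermost); a maximal set disjoint from the other bundle sets whose
    carriers are ancestral for every sibling-branch SNP is a new basal
    branch below the bundle's parent.  SNPs with no carriers — or carrier
    sets that overlap without nesting — stay unresolved.
    """
    bundle = [s for s in bundle]
    for s in bundle:
        if s not in matrix.snp_names:
            raise ValueError(f"bundle SNP {s!r} not in matrix")
    if parent is None:
        hosts = {tree.node_of_snp(s) for s in bundle if tree.node_of_snp(s)}
        parents = {tree.nodes[h].parent for h in hosts if h is not None}
        parents.discard(None)
        parent = sorted(parents, key=tree.depth)[0] if parents else tree.root
    child_sibling_idx = [
        matrix.snp_index(s)
        for s in (tree.children_snps(parent) - set(bundle))
        if s in matrix.snp_names
    ]

    carriers: dict[str, frozenset] = {}
    for s in bundle:
        col = matrix.calls[:, matrix.snp_index(s)]
        carriers[s] = frozenset(np.flatnonzero(col == 1).tolist())

    groups: dict[frozenset, list[str]] = {}
    for s in bundle:
        if carriers[s]:
            groups.setdefault(carriers[s], []).append(s)

    rows = []
    dsets = list(groups)
    for s in bundle:
        cs = carriers[s]
        if not cs:
            rows.append((s, "unresolved", 0, "no derived carriers"))
            continue
        partners = [t for t in groups[cs] if t != s]
        others = [d for d in dsets if d != cs]
        if any(cs & d and not (cs <= d or d <= cs) for d in others):
            rows.append((s, "unresolved", len(cs), "carrier sets overlap without nesting"))
            continue
        supersets = [d for d in others if cs < d]
        subsets = [d for d in others if d < cs]
        detail = f"same branch as {','.join(sorted(partners))}" if partners else ""
        if partners and not others:
            # a single shared carrier set: same branch, internal order unknown
            rows.append((s, "same-branch", len(cs), detail))
            continue
        if supersets:
            k = len(supersets) + 1
            cls = f"chain position {k}"
        elif subsets:
            cls = "chain position 1"
        else:
            # maximal, disjoint from every other bundle set: basal if the
            # carriers are ancestral at every sibling-branch SNP
            basal = True
            for idx in child_sibling_idx:
                col = matrix.calls[:, idx]
                if any(col[i] == 1 for i in cs):
                    basal = False
                    break
            cls = "new basal branch" if basal else "unresolved"
            if not basal:
                detail = "carriers derived at a sibling-branch SNP"
        if partners and not detail.startswith("same branch"):
            detail = f"same branch as {','.join(sorted(partners))}; {detail}"
        rows.append((s, cls, len(cs), detail))
    return pd.DataFrame(rows, columns=["snp", "classification", "carrier_count", "detail"])


# ---------------------------------------------------------------------------
# capture-vs-WGS reference-bias screen


@dataclass
class BiasReport:
    fragments: pd.DataFrame  # start, end (1-based inclusive span), n_snps, bp
    flagged_snps: list[str]
    per_snp: pd.DataFrame  # snp, pos, capture_rate, wgs_rate, p, q, flagged

    @property
    def n_snps_removed(self) -> int:
        return len(self.flagged_snps)

    @property
    def bp_removed(self) -> int:
        return int(self.fragments["bp"].sum()) if len(self.fragments) else 0


def reference_bias_screen(
    matrix: GenotypeMatrix,
    platforms: pd.Series | dict[str, str],
    merge_distance: int = 5_000,
    q_threshold: float = 0.01,
) -> BiasReport:
    """Flag genomic fragments where capture libraries show an excess or
    deficit of derived calls relative to whole-genome sequences.

    Per SNP a two-sided Fisher exact test compares derived/ancestral counts
    between platforms; Benjamini-Hochberg controls the FDR at ``q_threshold``
    and significant SNPs within ``merge_distance`` bp of each other merge
    into one flagged fragment.
    """
    if isinstance(platforms, dict):
        platforms = pd.Series(platforms)
    plat = np.array([platforms.get(s, "capture") for s in matrix.sample_ids])
    cap = plat == "capture"
    wgs = plat == "wgs"
    empty = pd.DataFrame(columns=["start", "end", "n_snps", "bp"])
    if not cap.any() or not wgs.any():
        logger.warning("reference-bias screen skipped: only one platform present")
        per = pd.DataFrame(
            columns=["snp", "pos", "capture_rate", "wgs_rate", "p", "q", "flagged"]
        )
        return BiasReport(fragments=empty, flagged_snps=[], per_snp=per)
    pvals, rows = [], []
    for k in range(matrix.n_snps):
        col = matrix.calls[:, k]
        c1 = int(((col == 1) & cap).sum())
        c0 = int(((col == 0) & cap).sum())
        w1 = int(((col == 1) & wgs).sum())
        w0 = int(((col == 0) & wgs).sum())
        _, p = fisher_exact([[c1, c0], [w1, w0]], alternative="two-sided")
        pvals.append(p)
        cr = c1 / (c1 + c0) if (c1 + c0) else np.nan
        wr = w1 / (w1 + w0) if (w1 + w0) else np.nan
        rows.append((matrix.snp_names[k], int(matrix.positions[k]), cr, wr, p))
    if rows:
        reject, qvals, _, _ = multipletests(pvals, alpha=q_threshold, method="fdr_bh")
    else:
        reject, qvals = np.array([], dtype=bool), np.array([])
    per = pd.DataFrame(rows, columns=["snp", "pos", "capture_rate", "wgs_rate", "p"])
    per["q"] = qvals
    per["flagged"] = reject
    flagged = per[per["flagged"]].sort_values("pos")
    frags = []
    if len(flagged):
        start = prev = None
        members = 0
        for pos in flagged["pos"]:
            if start is None:
                start, prev, members = pos, pos, 1
            elif pos - prev <= merge_distance:
                prev = pos
                members += 1
            else:
                frags.append((start, prev, members, prev - start + 1))
                start, prev, members = pos, pos, 1
        frags.append((start, prev, members, prev - start + 1))
    fragments = pd.DataFrame(frags, columns=["start", "end", "n_snps", "bp"])
    return BiasReport(
        fragments=fragments,
        flagged_snps=flagged["snp"].tolist(),
        per_snp=per,
    )


def apply_bias_filter(matrix: GenotypeMatrix, report: BiasReport) -> GenotypeMatrix:
    """Remove the flagged SNPs from the matrix."""
    drop = set(report.flagged_snps)
    keep = np.array([name not in drop for name in matrix.snp_names])
    return matrix.subset_snps(keep)


# ---------------------------------------------------------------------------
# missingness filter


def snp_missingness_filter(
    matrix: GenotypeMatrix, max_missing: float = 0.05
) -> tuple[GenotypeMatrix, list[str]]:
    """Retain SNPs whose missing-call fraction is strictly below the
    threshold; returns the filtered matrix and the removed SNP names."""
    frac = matrix.missing_mask.mean(axis=0) if matrix.n_samples else np.zeros(matrix.n_snps)
    keep = frac < max_missing
    removed = [name for name, k in zip(matrix.snp_names, keep) if not k]
    return matrix.subset_snps(keep), removed
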