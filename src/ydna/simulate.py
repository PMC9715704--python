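"""Synthetic-data generators with known ground truth.

The study's sequences are controlled-access, so every downstream stage is
exercised on simulated data whose generating parameters are stored in a
:class:`~ydna.core.SimTruth` record.  Four genealogy models are provided:

* a star genealogy (instantaneous radiation, private mutations only) — the
  regime inferred for the R1b-DF27 expansion and the regime in which the rho
  estimator is unbiased;
* a single-population Kingman coalescent with optional exponential growth,
  written in-package, which supplies the neutral null for Tajima's D;
* haplotypes generated down a SNP-annotated haplogroup tree, the round-trip
  oracle for haplogroup assignment;
* a two-level region-structured model (founder divergence + within-region
  star) with a computable expected phi_ST.

All models place mutations under infinite sites: positions are drawn without
replacement from the callable target, each site mutates once, time is in
years and the mutation rate is per site per year.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_GENOME_SIZE,
    GenotypeMatrix,
    MutationRateSpec,
    RegionSet,
    SimTruth,
    make_sample_table,
)
from .tree import HaplogroupTree

_BASES = np.array(list("ACGT"))


def _draw_positions(rng: np.random.Generator, span: int, k: int) -> np.ndarray:
    """k distinct 0-based offsets in [0, span), memory-light for k << span."""
    if k > span:
        raise ValueError(f"cannot place {k} distinct sites in {span} bp")
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if k > span // 2:
        return rng.permutation(span)[:k].astype(np.int64)
    chosen: set[int] = set()
    while len(chosen) < k:
        need = k - len(chosen)
        draw = rng.integers(0, span, size=int(need * 1.2) + 8)
        for v in draw:
            if len(chosen) == k:
                break
            chosen.add(int(v))
    out = np.fromiter(chosen, dtype=np.int64, count=k)
    return out


def _assemble_matrix(
    rng: np.random.Generator,
    sample_ids: list[str],
    offsets: np.ndarray,
    derived_rows: list[np.ndarray],
    regions: RegionSet | None,
    span: int,
    snp_names: list[str] | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from per-site offsets and per-site carrier rows."""
    order = np.argsort(offsets, kind="stable")
    offsets = offsets[order]
    if regions is not None:
        positions = regions.positions_from_offsets(offsets)
    else:
        positions = offsets + 1
    m = len(offsets)
    calls = np.zeros((len(sample_ids), m), dtype=np.int8)
    for new_j, old_j in enumerate(order):
        calls[derived_rows[old_j], new_j] = 1
    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    alleles = [
        (_BASES[ref_idx[j]], _BASES[(ref_idx[j] + alt_shift[j]) % 4]) for j in range(m)
    ]
    if snp_names is None:
        names = [f"s{p}" for p in positions]
    else:
        names = [snp_names[j] for j in order]
    return GenotypeMatrix(sample_ids, names, positions, alleles, calls)


# ---------------------------------------------------------------------------
# star genealogy


def simulate_star(
    n: int,
    tmrca_years: float,
    rate: MutationRateSpec,
    seed: int,
    regions: RegionSet | None = None,
    sample_prefix: str = "S",
) -> tuple[GenotypeMatrix, SimTruth]:
    """n lineages radiating simultaneously T years ago: each sample carries an
    independent Poisson(mu*L*T) set of private derived sites."""
    if n < 2:
        raise ValueError("n >= 2 required")
    if tmrca_years < 0:
        raise ValueError("TMRCA must be non-negative")
    span = regions.total_length if regions is not None else rate.length
    lam = rate.mu_point * rate.length * tmrca_years
    if lam > span:
        raise ValueError(
            f"expected mutations per lineage ({lam:.1f}) exceed callable length {span}"
        )
    rng = np.random.default_rng(seed)
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(n)]
    counts = rng.poisson(lam, size=n)
    total = int(counts.sum())
    offsets = _draw_positions(rng, span, total)
    derived_rows: list[np.ndarray] = []
    owner = np.repeat(np.arange(n), counts)
    for j in range(total):
        derived_rows.append(np.array([owner[j]]))
    matrix = _assemble_matrix(rng, sample_ids, offsets, derived_rows, regions, span)
    truth = SimTruth(
        genealogy="star",
        seed=seed,
        tmrca_years=tmrca_years,
        params={"n": n, "mu": rate.mu_point, "L": rate.length},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Kingman coalescent with exponential growth


def _coalescent_intervals(
    n: int, rng: np.random.Generator, growth_rate: float = 0.0
) -> list[float]:
    """Waiting times (coalescent units of the present-day size) while
    k = n..2 lineages remain, under N(t) = N0 * exp(-beta t) backward in time.

    The time change for an inhomogeneous rate k(k-1)/2 * exp(beta t) gives
    exp(beta t1) = exp(beta t0) + beta E / (k(k-1)/2) for E ~ Exp(1).
    """
    times = []
    t = 0.0
    for k in range(n, 1, -1):
        pair_rate = k * (k - 1) / 2.0
        e = rng.exponential()
        if growth_rate == 0.0:
            dt = e / pair_rate
        else:
            dt = (
                math.log(math.exp(growth_rate * t) + growth_rate * e / pair_rate)
                / growth_rate
                - t
            )
        times.append(dt)
        t += dt
    return times


def _coalescent_edges(
    n: int, rng: np.random.Generator, growth_rate: float = 0.0
) -> tuple[list[tuple[tuple[int, ...], float]], float]:
    """Simulate one genealogy; return edges as (descendant sample tuple,
    branch length) plus the total tree length, all in coalescent units."""
    lineages: list[list[int]] = [[i] for i in range(n)]
    lengths = [0.0] * n
    edges: list[tuple[tuple[int, ...], float]] = []
    for dt in _coalescent_intervals(n, rng, growth_rate):
        k = len(lineages)
        for i in range(k):
            lengths[i] += dt
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        edges.append((tuple(lineages[i]), lengths[i]))
        edges.append((tuple(lineages[j]), lengths[j]))
        merged = lineages[i] + lineages[j]
        lineages[i] = merged
        lengths[i] = 0.0
        del lineages[j], lengths[j]
    total = sum(le for _, le in edges)
    return edges, total


def simulate_growth_coalescent(
    n: int,
    theta: float,
    growth_rate: float,
    seed: int,
    regions: RegionSet | None = None,
    span: int | None = None,
    sample_prefix: str = "S",
) -> tuple[GenotypeMatrix, SimTruth]:
    """Neutral single-population coalescent sample under infinite sites.

    ``theta`` is the population-scaled mutation rate per locus: with no
    growth E[S] = theta * sum_{i=1}^{n-1} 1/i.  ``growth_rate`` is the
    exponential growth parameter in coalescent units; large values push the
    genealogy toward a star and Tajima's D strongly negative.
    """
    if n < 2:
        raise ValueError("n >= 2 required")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if growth_rate < 0:
        raise ValueError("growth_rate must be non-negative")
    rng = np.random.default_rng(seed)
    if span is None:
        span = regions.total_length if regions is not None else 1_000_000
    edges, total_len = _coalescent_edges(n, rng, growth_rate)
    n_mut = rng.poisson(theta * total_len / 2.0)
    n_mut = min(n_mut, span)  # infinite-sites cap
    edge_len = np.array([le for _, le in edges])
    which = rng.choice(len(edges), size=n_mut, p=edge_len / edge_len.sum()) if n_mut else []
    offsets = _draw_positions(rng, span, int(n_mut))
    derived_rows = [np.array(edges[w][0], dtype=np.int64) for w in which]
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(n)]
    matrix = _assemble_matrix(rng, sample_ids, offsets, derived_rows, regions, span)
    truth = SimTruth(
        genealogy="growth-coalescent",
        seed=seed,
        params={"n": n, "theta": theta, "growth_rate": growth_rate},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# haplogroup-tree-derived samples


def simulate_from_tree(
    tree: HaplogroupTree,
    counts: dict[str, int],
    private_mut_mean: float,
    seed: int,
    regions: RegionSet | None = None,
    span: int = 1_000_000,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Samples assigned to haplogroup nodes: derived exactly on the defining
    SNPs of the root-to-node path, ancestral at every other tree SNP, plus a
    Poisson number of private non-tree sites each."""
    for node in counts:
        if node not in tree.nodes:
            raise ValueError(f"node {node!r} not in tree")
    if private_mut_mean < 0:
        raise ValueError("private_mut_mean must be non-negative")
    rng = np.random.default_rng(seed)
    if regions is not None:
        span = regions.total_length
    tree_snps = sorted(tree.all_snps())
    sample_ids: list[str] = []
    sample_nodes: dict[str, str] = {}
    for node in sorted(counts):
        for i in range(counts[node]):
            sid = f"{node}_{i:02d}"
            sample_ids.append(sid)
            sample_nodes[sid] = node
    n = len(sample_ids)
    n_private = rng.poisson(private_mut_mean, size=n)
    total_sites = len(tree_snps) + int(n_private.sum())
    offsets = _draw_positions(rng, span, total_sites)
    derived_rows: list[np.ndarray] = []
    for snp in tree_snps:
        node_of = tree.node_of_snp(snp)
        carriers = [
            j for j, sid in enumerate(sample_ids)
            if snp in tree.path_snps(sample_nodes[sid])
        ]
        derived_rows.append(np.array(carriers, dtype=np.int64))
        del node_of
    names = list(tree_snps)
    p = 0
    for j in range(n):
        for _ in range(n_private[j]):
            derived_rows.append(np.array([j], dtype=np.int64))
            names.append(f"p{j}_{p}")
            p += 1
    matrix = _assemble_matrix(
        rng, sample_ids, offsets, derived_rows, regions, span, snp_names=names
    )
    truth = SimTruth(
        genealogy="tree-derived",
        seed=seed,
        sample_nodes=sample_nodes,
        params={"private_mut_mean": private_mut_mean},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# region-structured samples


def simulate_structured_regions(
    n_per_region: int,
    k_regions: int,
    divergence_years: float,
    within_years: float,
    rate: MutationRateSpec,
    seed: int,
    regions: RegionSet | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Two-level star model: region founders diverge from a common ancestor
    for ``divergence_years``, then samples radiate star-like within regions
    for ``within_years``.

    In the large-sample limit the expected phi_ST is
    divergence_years / (divergence_years + within_years): the expected
    between-region pairwise distance is 2 mu L (T_div + T_within) versus
    2 mu L T_within within regions.
    """
    if k_regions < 2:
        raise ValueError("k_regions >= 2 required")
    if n_per_region < 1:
        raise ValueError("n_per_region >= 1 required")
    rng = np.random.default_rng(seed)
    span = regions.total_length if regions is not None else rate.length
    lam_founder = rate.mu_point * rate.length * divergence_years
    lam_within = rate.mu_point * rate.length * within_years
    region_labels = [f"R{r + 1}" for r in range(k_regions)]
    sample_ids, sample_regions = [], []
    for r, lab in enumerate(region_labels):
        for i in range(n_per_region):
            sample_ids.append(f"{lab}_{i:03d}")
            sample_regions.append(lab)
    n = len(sample_ids)
    founder_counts = rng.poisson(lam_founder, size=k_regions)
    private_counts = rng.poisson(lam_within, size=n)
    total = int(founder_counts.sum() + private_counts.sum())
    offsets = _draw_positions(rng, span, total)
    derived_rows: list[np.ndarray] = []
    for r in range(k_regions):
        members = np.arange(r * n_per_region, (r + 1) * n_per_region)
        for _ in range(founder_counts[r]):
            derived_rows.append(members)
    for j in range(n):
        for _ in range(private_counts[j]):
            derived_rows.append(np.array([j], dtype=np.int64))
    matrix = _assemble_matrix(rng, sample_ids, offsets, derived_rows, regions, span)
    meta = make_sample_table(sample_ids, sample_regions)
    denom = divergence_years + within_years
    truth = SimTruth(
        genealogy="structured",
        seed=seed,
        target_phist=(divergence_years / denom) if denom > 0 else 0.0,
        params={
            "n_per_region": n_per_region,
            "k_regions": k_regions,
            "divergence_years": divergence_years,
            "within_years": within_years,
        },
    )
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# capture read counts and windowed coverage


def expected_on_target_proportion(enrichment: float, L: int, G: int = DEFAULT_GENOME_SIZE) -> float:
    """On-target read proportion implied by an enrichment level: reads are
    drawn from the target with odds multiplied by ``enrichment`` relative to
    the unenriched L/G share (enrichment=1 reduces to L/G)."""
    f = L / G
    return enrichment * f / (1 + (enrichment - 1) * f)


def enrichment_for_proportion(p: float, L: int, G: int = DEFAULT_GENOME_SIZE) -> float:
    """Inverse of :func:`expected_on_target_proportion`."""
    f = L / G
    return p * (1 - f) / (f * (1 - p))


def simulate_capture_counts(
    n_samples: int,
    total_reads: int,
    enrichment: float,
    regions: RegionSet,
    seed: int,
    window: int = 10_000,
    read_length: int = 150,
    duplicate_fraction: float = 0.11,
    sample_prefix: str = "C",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample read-count and windowed run-length depth tables.

    On-target counts are Binomial(total_reads, p) with p implied by the
    enrichment level; each 10-kb window's depth is Poisson around the mean
    depth implied by the on-target read mass, so windowed medians recover a
    homogeneous coverage profile.
    """
    if enrichment < 0:
        raise ValueError("enrichment must be non-negative")
    if total_reads < 0:
        raise ValueError("total_reads must be non-negative")
    rng = np.random.default_rng(seed)
    p = expected_on_target_proportion(enrichment, regions.total_length)
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(n_samples)]
    on_target = rng.binomial(total_reads, p, size=n_samples) if total_reads else np.zeros(n_samples, dtype=int)
    counts = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "total_reads": total_reads,
            "on_target_reads": on_target,
            "duplicate_fraction": np.round(
                rng.normal(duplicate_fraction, 0.01, size=n_samples).clip(0, 1), 4
            ),
        }
    )
    rows = []
    L = regions.total_length
    for j, sid in enumerate(sample_ids):
        mean_depth = on_target[j] * read_length / L if L else 0.0
        for (s, e) in regions.intervals:
            w0 = s
            while w0 < e:
                w1 = min(w0 + window, e)
                depth = rng.poisson(mean_depth) if mean_depth > 0 else 0
                rows.append((sid, w0, w1, depth))
                w0 = w1
    depths = pd.DataFrame(rows, columns=["sample_id", "start", "end", "depth"])
    return counts, depths
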