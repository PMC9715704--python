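"""Core domain types shared across the pipeline.

The package works on haploid binary Y-chromosome genotypes: each sample
carries, at each SNP, either the ancestral allele (0), the derived allele
(1), or a missing call.  Coordinates are 1-based GRCh37 positions on the Y
chromosome inside a declared callable target region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing haploid call in the int8 genotype matrix
MISSING: int = -1

#: GRCh37 defaults used throughout: callable target length and genome size
DEFAULT_TARGET_LENGTH: int = 8_900_000
DEFAULT_GENOME_SIZE: int = 6_000_000_000


@dataclass(frozen=True)
class MutationRateSpec:
    """Point estimate and 95% CI of the SNP mutation rate, per site per year.

    ``length`` is the number of callable sites the rate applies to; the
    product ``mu * length`` is the expected number of mutations per lineage
    per year, whose reciprocal is the years-per-mutation conversion used for
    rho dating.
    """

    mu_point: float = 0.76e-9
    mu_low: float = 0.67e-9
    mu_high: float = 0.86e-9
    length: int = DEFAULT_TARGET_LENGTH

    def __post_init__(self) -> None:
        if not (0 < self.mu_low <= self.mu_point <= self.mu_high):
            raise ValueError(
                f"require 0 < mu_low <= mu_point <= mu_high, got "
                f"({self.mu_low}, {self.mu_point}, {self.mu_high})"
            )
        if self.length <= 0:
            raise ValueError("target length must be positive")


class RegionSet:
    """Sorted, non-overlapping half-open 0-based intervals on chrY."""

    def __init__(self, intervals: Iterable[tuple[int, int]]):
        ivs = sorted((int(s), int(e)) for s, e in intervals)
        for (s, e) in ivs:
            if e <= s:
                raise ValueError(f"empty or inverted interval ({s}, {e})")
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError("overlapping intervals")
        self.intervals: list[tuple[int, int]] = ivs

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, pos_1based: int) -> bool:
        """Membership of a 1-based coordinate in the 0-based half-open set."""
        p = pos_1based - 1
        for s, e in self.intervals:
            if s <= p < e:
                return True
        return False

    def positions_from_offsets(self, offsets: np.ndarray) -> np.ndarray:
        """Map 0-based offsets within the concatenated region span to
        1-based chromosome coordinates."""
        offsets = np.asarray(offsets, dtype=np.int64)
        out = np.empty_like(offsets)
        lengths = np.array([e - s for s, e in self.intervals], dtype=np.int64)
        starts = np.array([s for s, _ in self.intervals], dtype=np.int64)
        bounds = np.concatenate([[0], np.cumsum(lengths)])
        if np.any(offsets < 0) or np.any(offsets >= bounds[-1]):
            raise ValueError("offset outside region span")
        idx = np.searchsorted(bounds, offsets, side="right") - 1
        out = starts[idx] + (offsets - bounds[idx]) + 1
        return out

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegionSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"RegionSet({len(self.intervals)} intervals, {self.total_length} bp)"


def default_region_set(n_regions: int = 9, total: int = DEFAULT_TARGET_LENGTH) -> RegionSet:
    """Synthetic stand-in for the unpublished GRCh37 capture target: nine
    disjoint intervals on chrY summing to the declared 8.9 Mb.  Interval
    lengths are deliberately non-multiples of 10 kb so that window tiling
    exercises partial terminal windows."""
    base = total // n_regions
    lengths = [base] * n_regions
    lengths[-1] += total - base * n_regions
    # stagger ends so most regions end mid-window
    for i in range(n_regions - 1):
        delta = (i + 1) * 1357
        lengths[i] -= delta
        lengths[-1] += delta
    intervals = []
    start = 2_650_000  # past the GRCh37 Y PAR1
    for ln in lengths:
        intervals.append((start, start + ln))
        start += ln + 50_000
    rs = RegionSet(intervals)
    assert rs.total_length == total
    return rs


class GenotypeMatrix:
    """Haploid sample x SNP matrix of ancestral/derived calls.

    ``calls`` is int8 with 0=ancestral, 1=derived, -1=missing.  Positions are
    1-based GRCh37 chrY coordinates, strictly increasing; SNP names unique.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        snp_names: Sequence[str],
        positions: Sequence[int],
        alleles: Sequence[tuple[str, str]],
        calls: np.ndarray,
    ):
        self.sample_ids = list(sample_ids)
        self.snp_names = list(snp_names)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.alleles = [(str(a), str(d)) for a, d in alleles]
        self.calls = np.asarray(calls, dtype=np.int8)
        self._validate()

    def _validate(self) -> None:
        n, m = len(self.sample_ids), len(self.snp_names)
        if self.calls.shape != (n, m):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{n} samples x {m} SNPs"
            )
        if len(self.positions) != m or len(self.alleles) != m:
            raise ValueError("positions/alleles length mismatch")
        if m > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if len(set(self.snp_names)) != m:
            raise ValueError("snp_names must be unique")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1 or missing (-1)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_names)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def snp_index(self, name: str) -> int:
        return self.snp_names.index(name)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.sample_ids,
            [self.snp_names[i] for i in keep],
            self.positions[keep],
            [self.alleles[i] for i in keep],
            self.calls[:, keep],
        )

    def subset_samples(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in keep],
            self.snp_names,
            self.positions,
            self.alleles,
            self.calls[keep, :],
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return self.subset_samples(np.asarray(idx))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.sample_ids == other.sample_ids
            and self.snp_names == other.snp_names
            and np.array_equal(self.positions, other.positions)
            and self.alleles == other.alleles
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_snps} SNPs)"


def make_sample_table(
    sample_ids: Sequence[str],
    regions: Sequence[str],
    batches: Sequence[str] | None = None,
    platforms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sample metadata table: id, geographic region, capture batch, platform.

    Platform is ``capture`` or ``wgs``; the reference-bias screen compares
    the two.
    """
    n = len(sample_ids)
    if len(set(sample_ids)) != n:
        raise ValueError("sample_id must be unique")
    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "region": list(regions),
            "batch": list(batches) if batches is not None else ["B1"] * n,
            "platform": list(platforms) if platforms is not None else ["capture"] * n,
        }
    )
    bad = ~df["platform"].isin(["capture", "wgs"])
    if bad.any():
        raise ValueError(f"platform must be capture|wgs, got {df.loc[bad, 'platform'].unique()}")
    return df


@dataclass
class SimTruth:
    """Ground truth stored alongside every simulated dataset."""

    genealogy: str  # star | growth-coalescent | tree-derived | structured
    seed: int
    tmrca_years: float | None = None
    sample_nodes: dict[str, str] = field(default_factory=dict)
    target_phist: float | None = None
    params: dict = field(default_factory=dict)
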