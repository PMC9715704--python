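"""Readers and writers for the pipeline's file formats.

Genotypes travel as haploid VCFv4.2 (the shape GATK HaplotypeCaller emits in
haploid mode: single-allele GT fields ``0``, ``1`` or ``.``), target regions
as 0-based half-open BED, sample metadata and reports as TSV, haplogroup
trees as structured YAML.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
import pysam

from .core import MISSING, GenotypeMatrix, RegionSet
from .tree import HaplogroupTree

logger = logging.getLogger(__name__)

DEFAULT_CONTIG = "Y"


class VcfFormatError(ValueError):
    pass


def read_haploid_vcf(path: str | os.PathLike, contig: str = DEFAULT_CONTIG) -> GenotypeMatrix:
    """Read a haploid single-sample-per-column VCF into a GenotypeMatrix.

    Haploid ``GT`` values 0/1/. map to ancestral/derived/missing.  A diploid
    GT is a hard error naming the sample and position; records on a contig
    other than ``contig`` are errors; records with more than one ALT allele
    are rejected (skipped with a log entry), as are non-SNP alleles.
    """
    vf = pysam.VariantFile(os.fspath(path))
    samples = list(vf.header.samples)
    names: list[str] = []
    positions: list[int] = []
    alleles: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    seen_names: set[str] = set()
    for rec in vf:
        if rec.chrom != contig:
            raise VcfFormatError(
                f"non-{contig} contig {rec.chrom!r} at position {rec.pos}"
            )
        alts = rec.alts or ()
        if len(alts) > 1:
            logger.warning("rejecting multi-allelic site at %s:%d", rec.chrom, rec.pos)
            continue
        alt = alts[0] if alts else "N"
        if len(rec.ref) != 1 or len(alt) != 1:
            logger.warning("rejecting non-SNP site at %s:%d", rec.chrom, rec.pos)
            continue
        row = np.empty(len(samples), dtype=np.int8)
        for j, s in enumerate(samples):
            gt = rec.samples[s]["GT"]
            if gt is None:
                gt = (None,)
            if len(gt) != 1:
                raise VcfFormatError(
                    f"diploid GT for sample {s!r} at {rec.chrom}:{rec.pos}"
                )
            a = gt[0]
            row[j] = MISSING if a is None else int(a)
        name = rec.id if rec.id not in (None, ".") else f"s{rec.pos}"
        if name in seen_names:
            raise VcfFormatError(f"duplicate SNP id {name!r}")
        seen_names.add(name)
        names.append(name)
        positions.append(rec.pos)
        alleles.append((rec.ref, alt))
        rows.append(row)
    vf.close()
    calls = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, names, positions, alleles, calls)


def write_haploid_vcf(
    matrix: GenotypeMatrix, path: str | os.PathLike, contig: str = DEFAULT_CONTIG,
    contig_length: int = 59_373_566,
) -> None:
    """Write a GenotypeMatrix as haploid VCFv4.2 (uncompressed text)."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in matrix.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for k in range(matrix.n_snps):
            anc, der = matrix.alleles[k]
            rec = out.new_record(
                contig=contig,
                start=int(matrix.positions[k]) - 1,
                stop=int(matrix.positions[k]),
                alleles=(anc, der),
                id=matrix.snp_names[k],
            )
            for j, s in enumerate(matrix.sample_ids):
                c = int(matrix.calls[j, k])
                rec.samples[s]["GT"] = (None,) if c == MISSING else (c,)
            out.write(rec)


def read_bed(path: str | os.PathLike, contig: str | None = None) -> RegionSet:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    if contig is not None:
        bad = df["chrom"] != contig
        if bad.any():
            raise ValueError(f"BED contains non-{contig} contigs: {df.loc[bad, 'chrom'].unique()}")
    return RegionSet(zip(df["start"], df["end"]))


def write_bed(regions: RegionSet, path: str | os.PathLike, contig: str = DEFAULT_CONTIG) -> None:
    with open(path, "w") as fh:
        for s, e in regions.intervals:
            fh.write(f"{contig}\t{s}\t{e}\n")


def read_sample_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "region", "batch", "platform"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata TSV missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return df


def write_sample_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tree_spec(path: str | os.PathLike) -> HaplogroupTree:
    """Parse a structured-text haplogroup tree (YAML node list)."""
    return HaplogroupTree.from_yaml(path)


def write_tree_spec(tree: HaplogroupTree, path: str | os.PathLike) -> None:
    tree.to_yaml(path)


def read_counts_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "total_reads", "on_target_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts TSV missing columns {sorted(missing)}")
    return df


def read_depth_table(path: str | os.PathLike) -> pd.DataFrame:
    """Run-length depth table: sample_id, start, end (0-based half-open), depth."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "start", "end", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"depth TSV missing columns {sorted(missing)}")
    return df
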