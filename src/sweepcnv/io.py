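"""Standard-format I/O: VCF, bedGraph-like coverage TSV, BED/GFF, metadata.

Variant data travel as VCF (via pysam): phased records load into a
:class:`~sweepcnv.containers.HaplotypeMatrix`, unphased records into a
:class:`~sweepcnv.containers.GenotypeMatrix` of per-site allele counts.
Coverage is a long-format TSV (chrom, start, end, sample, depth, gc);
gene spans come from BED (kept 0-based half-open) or GFF3 (converted);
sample metadata is a plain TSV. Region strings are 1-based inclusive and
converted at these boundaries only.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .containers import CoverageTrack, GeneSpan, GenotypeMatrix, HaplotypeMatrix, Region

__all__ = [
    "load_genotypes",
    "write_haplotype_vcf",
    "write_genotype_vcf",
    "read_coverage_tsv",
    "write_coverage_tsv",
    "load_gene_spans",
    "read_metadata",
    "write_metadata",
    "write_truth_json",
]

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "taxon", "location", "year", "insecticide", "phenotype"]

_ALLELES = ("A", "C", "G", "T")


def _iter_records(vf: pysam.VariantFile, region: Region | None):
    if region is None:
        yield from vf
        return
    try:
        yield from vf.fetch(region.contig, region.start - 1, region.end)
    except ValueError:
        # no index: fall back to a full scan with position filtering
        for rec in vf:
            if rec.chrom == region.contig and region.start <= rec.pos <= region.end:
                yield rec


def load_genotypes(
    path: str | Path, region: Region | None = None
) -> HaplotypeMatrix | GenotypeMatrix:
    """Load variants from a VCF over an optional 1-based inclusive region.

    Fully phased biallelic records yield a :class:`HaplotypeMatrix`
    (multiallelic sites are excluded with a logged count); unphased records
    yield a :class:`GenotypeMatrix` of allele counts with multiallelic sites
    (up to 4 alleles) retained. Missing genotypes are an error: filtering
    and imputation are upstream concerns.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise ValueError(f"{path} contains no samples")
        records = list(_iter_records(vf, region))

    if not records:
        warnings.warn(f"region {region} covers 0 variants in {path}", stacklevel=2)
        contig = region.contig if region else "NA"
        return GenotypeMatrix(
            np.zeros((0, len(samples), 4), dtype=np.int16),
            np.zeros(0, dtype=np.int64),
            samples,
            contig,
        )

    contigs = {r.chrom for r in records}
    if len(contigs) > 1:
        raise ValueError(f"records span multiple contigs: {sorted(contigs)}")
    contig = records[0].chrom

    phased = all(
        rec.samples[s].phased for rec in records for s in samples
    )
    if phased:
        positions, rows = [], []
        n_multi = 0
        for rec in records:
            if len(rec.alts or ()) != 1:
                n_multi += 1
                continue
            row = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or None in gt or len(gt) != 2:
                    raise ValueError(f"missing/non-diploid genotype at {rec.chrom}:{rec.pos}")
                row.extend(gt)
            positions.append(rec.pos)
            rows.append(row)
        if n_multi:
            logger.info("excluded %d multiallelic site(s) from haplotype data", n_multi)
        hap_ids = [f"{s}_{p}" for s in samples for p in ("a", "b")]
        return HaplotypeMatrix(
            np.asarray(rows, dtype=np.int8), np.asarray(positions, dtype=np.int64),
            hap_ids, contig,
        )

    positions, tensors = [], []
    for rec in records:
        n_alleles = 1 + len(rec.alts or ())
        if n_alleles > 4:
            raise ValueError(f"more than 4 alleles at {rec.chrom}:{rec.pos}")
        counts = np.zeros((len(samples), 4), dtype=np.int16)
        for i, s in enumerate(samples):
            gt = rec.samples[s]["GT"]
            if gt is None or None in gt or len(gt) != 2:
                raise ValueError(f"missing/non-diploid genotype at {rec.chrom}:{rec.pos}")
            for a in gt:
                counts[i, a] += 1
        positions.append(rec.pos)
        tensors.append(counts)
    return GenotypeMatrix(
        np.stack(tensors), np.asarray(positions, dtype=np.int64), samples, contig
    )


def _vcf_header(contig: str, length: int, samples: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)
    return header


def write_haplotype_vcf(haps: HaplotypeMatrix, path: str | Path) -> None:
    """Write phased biallelic haplotypes as an uncompressed VCF.

    Consecutive haplotype pairs become one diploid sample with a phased GT.
    """
    if haps.n_haplotypes % 2:
        raise ValueError("haplotype count must be even to emit diploid VCF records")
    samples = [hid.rsplit("_", 1)[0] for hid in haps.haplotype_ids[::2]]
    length = int(haps.positions[-1]) + 1 if haps.n_sites else 1
    header = _vcf_header(haps.contig, length, samples)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(haps.n_sites):
            rec = out.new_record(
                contig=haps.contig, start=int(haps.positions[i]) - 1,
                alleles=("A", "T"), filter="PASS",
            )
            for j, s in enumerate(samples):
                rec.samples[s]["GT"] = (
                    int(haps.alleles[i, 2 * j]), int(haps.alleles[i, 2 * j + 1])
                )
                rec.samples[s].phased = True
            out.write(rec)


def write_genotype_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write unphased allele-count genotypes as an uncompressed VCF."""
    length = int(gm.positions[-1]) + 1 if gm.n_sites else 1
    header = _vcf_header(gm.contig, length, gm.sample_ids)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(gm.n_sites):
            used = np.flatnonzero(gm.allele_counts[i].sum(axis=0) > 0)
            n_alleles = max(2, (int(used.max()) + 1) if used.size else 2)
            rec = out.new_record(
                contig=gm.contig, start=int(gm.positions[i]) - 1,
                alleles=_ALLELES[:n_alleles], filter="PASS",
            )
            for j, s in enumerate(gm.sample_ids):
                gt = []
                for a in range(4):
                    gt.extend([a] * int(gm.allele_counts[i, j, a]))
                rec.samples[s]["GT"] = tuple(gt)
                rec.samples[s].phased = False
            out.write(rec)


def write_coverage_tsv(track: CoverageTrack, path: str | Path) -> None:
    """Write a long-format bedGraph-like coverage TSV
    (chrom, start, end, sample, depth, gc)."""
    frames = []
    for j, s in enumerate(track.sample_ids):
        frames.append(
            pd.DataFrame(
                {
                    "chrom": track.contig,
                    "start": track.starts,
                    "end": track.ends,
                    "sample": s,
                    "depth": track.depth[:, j],
                    "gc": track.gc,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path: str | Path) -> CoverageTrack:
    """Read a coverage TSV written by :func:`write_coverage_tsv`."""
    df = pd.read_csv(path, sep="\t")
    needed = {"chrom", "start", "end", "sample", "depth", "gc"}
    if not needed.issubset(df.columns):
        raise ValueError(f"coverage TSV lacks columns: {sorted(needed - set(df.columns))}")
    contigs = df["chrom"].unique()
    if contigs.size != 1:
        raise ValueError(f"coverage TSV spans multiple contigs: {list(contigs)}")
    wide = df.pivot_table(index=["start", "end", "gc"], columns="sample",
                          values="depth", sort=True)
    idx = wide.index.to_frame(index=False)
    return CoverageTrack(
        str(contigs[0]),
        idx["start"].to_numpy(),
        idx["end"].to_numpy(),
        idx["gc"].to_numpy(),
        wide.to_numpy(),
        [str(c) for c in wide.columns],
    )


def load_gene_spans(path: str | Path) -> list[GeneSpan]:
    """Load gene spans from BED (0-based half-open, kept as-is) or GFF3
    (1-based inclusive ``gene`` features, converted)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["contig", "source", "type", "start", "end",
                   "score", "strand", "frame", "attributes"],
        )
        df = df[df["type"] == "gene"]
        spans = []
        for _, row in df.iterrows():
            attrs = dict(
                kv.split("=", 1) for kv in str(row["attributes"]).split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", f"{row['contig']}:{row['start']}")
            spans.append(GeneSpan(gene_id, row["contig"], int(row["start"]) - 1, int(row["end"])))
        return spans
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 4:
        raise ValueError("BED file needs at least 4 columns (chrom, start, end, name)")
    return [
        GeneSpan(str(r[3]), str(r[0]), int(r[1]), int(r[2]))
        for r in df.itertuples(index=False)
    ]


def assign_cohorts(
    metadata: pd.DataFrame,
    early: tuple[int, int] = (2012, 2015),
    late: tuple[int, int] = (2017, 2018),
) -> pd.DataFrame:
    """Add ``period`` and ``cohort`` columns (taxon / location / period).

    Collection years inside the ``early`` or ``late`` inclusive ranges get
    the matching period label; other years are labelled ``other``. Cohorts
    are disjoint by construction (each sample has one taxon, location and
    year).
    """
    out = metadata.copy()
    year = out["year"].astype(int)
    out["period"] = np.select(
        [year.between(*early), year.between(*late)], ["early", "late"], default="other"
    )
    out["cohort"] = (
        out["taxon"].astype(str) + "/" + out["location"].astype(str) + "/" + out["period"]
    )
    return out


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata lacks columns: {missing}")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_truth_json(truth_dict: Mapping, path: str | Path) -> None:
    """Serialize simulation ground truth (sets become sorted lists)."""

    def default(obj):
        if isinstance(obj, set):
            return sorted(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"cannot serialize {type(obj)}")

    Path(path).write_text(json.dumps(truth_dict, indent=2, sort_keys=True, default=default))
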