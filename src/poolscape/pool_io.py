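"""Reading/writing pooled variant data and the SNP coverage/MAF filters.

Two interchange formats are supported: VCF with per-sample allelic depths
(``AD``), one sample per pooled stand, and the tab-separated sync format
(``chr pos ref A:T:C:G:N:del`` count strings per pool) common in pool-seq
work.  Both round-trip exactly through the writers in this module.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .containers import FilterReport, FrequencyMatrix, PoolCounts

logger = logging.getLogger(__name__)

__all__ = [
    "read_pool_vcf",
    "write_pool_vcf",
    "read_sync",
    "write_sync",
    "filter_snps",
    "estimate_frequencies",
]

_HAPLOID_HEADER = "##poolscape_haploid_sizes="


def read_pool_vcf(path, haploid_sizes: Sequence[int] | None = None) -> PoolCounts:
    """Read a pooled VCF (one sample per stand, AD per sample) into PoolCounts.

    Only biallelic SNP records are retained; multiallelic records and indels
    are dropped with a logged count.  Pool haploid sizes are taken from the
    ``##poolscape_haploid_sizes`` header line if present, otherwise they must
    be supplied.  A record without allelic depths raises a ValueError naming
    the record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    stand_ids = list(vcf.samples)
    if haploid_sizes is None:
        for line in vcf.raw_header.splitlines():
            if line.startswith(_HAPLOID_HEADER):
                haploid_sizes = [int(x) for x in line[len(_HAPLOID_HEADER):].split(",")]
                break
    if haploid_sizes is None:
        raise ValueError(
            "haploid pool sizes not found in VCF header; pass haploid_sizes="
        )
    if len(haploid_sizes) != len(stand_ids):
        raise ValueError("haploid_sizes length does not match VCF sample count")

    snp_ids, contig, pos, ref_a, alt_a, refd, altd = [], [], [], [], [], [], []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise ValueError(
                f"record {var.CHROM}:{var.POS} has no AD (allelic depth) field"
            )
        ad = np.asarray(ad)
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        contig.append(var.CHROM)
        pos.append(var.POS)
        ref_a.append(var.REF)
        alt_a.append(var.ALT[0])
        refd.append(np.clip(ad[:, 0], 0, None))
        altd.append(np.clip(ad[:, 1], 0, None))
    if n_dropped:
        logger.info("read_pool_vcf: dropped %d multiallelic/indel records", n_dropped)
    if not snp_ids:
        raise ValueError(f"no biallelic SNP records in {path}")
    return PoolCounts(
        snp_ids=np.array(snp_ids, dtype=object),
        contig=np.array(contig, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref_allele=np.array(ref_a, dtype=object),
        alt_allele=np.array(alt_a, dtype=object),
        ref_depth=np.vstack(refd),
        alt_depth=np.vstack(altd),
        stand_ids=stand_ids,
        haploid_size=np.asarray(haploid_sizes),
    )


def write_pool_vcf(pc: PoolCounts, path) -> None:
    """Write PoolCounts as a minimal VCF with GT:AD per pooled sample."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(_HAPLOID_HEADER + ",".join(str(int(n)) for n in pc.haploid_size) + "\n")
        for c in sorted(set(pc.contig.tolist())):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Read depth for ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(pc.stand_ids)
            + "\n"
        )
        for l in range(pc.n_snps):
            samples = "\t".join(
                f"./.:{pc.ref_depth[l, s]},{pc.alt_depth[l, s]}"
                for s in range(pc.n_stands)
            )
            fh.write(
                f"{pc.contig[l]}\t{pc.pos[l]}\t{pc.snp_ids[l]}\t{pc.ref_allele[l]}\t"
                f"{pc.alt_allele[l]}\t.\tPASS\t.\tGT:AD\t{samples}\n"
            )


_NUC_ORDER = "ATCGN"  # sync column order is A:T:C:G:N:del


def read_sync(path, haploid_sizes: Sequence[int], stand_ids: Sequence[str] | None = None) -> PoolCounts:
    """Read sync-format allele counts.

    The two most frequent nucleotides summed across pools define the
    reference/alternate pair (ref = the more frequent).  Malformed count
    strings raise a ValueError with the offending line number.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected at least 4 columns")
            chrom, pos, ref = parts[0], parts[1], parts[2]
            counts = []
            for field in parts[3:]:
                bits = field.split(":")
                if len(bits) != 6:
                    raise ValueError(
                        f"{path}:{lineno}: malformed count string {field!r}"
                    )
                try:
                    counts.append([int(b) for b in bits])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed count string {field!r}"
                    ) from exc
            rows.append((chrom, int(pos), ref, np.array(counts)))
    if not rows:
        raise ValueError(f"no records in {path}")
    n_pools = rows[0][3].shape[0]
    if any(r[3].shape[0] != n_pools for r in rows):
        raise ValueError("inconsistent pool count across sync lines")
    if len(haploid_sizes) != n_pools:
        raise ValueError("haploid_sizes length does not match pool count")
    if stand_ids is None:
        stand_ids = [f"pool{i + 1}" for i in range(n_pools)]

    contig, pos, ref_a, alt_a, refd, altd, snp_ids = [], [], [], [], [], [], []
    for chrom, p, ref, counts in rows:
        nuc_tot = counts[:, :4].sum(axis=0)  # A,T,C,G totals across pools
        order = np.argsort(nuc_tot)[::-1]
        i_ref, i_alt = int(order[0]), int(order[1])
        # honour the stated reference base when it is one of the top two
        stated = _NUC_ORDER.find(ref.upper())
        if stated == i_alt:
            i_ref, i_alt = i_alt, i_ref
        contig.append(chrom)
        pos.append(p)
        ref_a.append(_NUC_ORDER[i_ref])
        alt_a.append(_NUC_ORDER[i_alt])
        refd.append(counts[:, i_ref])
        altd.append(counts[:, i_alt])
        snp_ids.append(f"{chrom}:{p}")
    return PoolCounts(
        snp_ids=np.array(snp_ids, dtype=object),
        contig=np.array(contig, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref_allele=np.array(ref_a, dtype=object),
        alt_allele=np.array(alt_a, dtype=object),
        ref_depth=np.vstack(refd),
        alt_depth=np.vstack(altd),
        stand_ids=list(stand_ids),
        haploid_size=np.asarray(haploid_sizes),
    )


def write_sync(pc: PoolCounts, path) -> None:
    """Write PoolCounts in sync format (A:T:C:G:N:del per pool)."""
    path = Path(path)
    with path.open("w") as fh:
        for l in range(pc.n_snps):
            cols = np.zeros((pc.n_stands, 6), dtype=np.int64)
            i_ref = _NUC_ORDER.find(str(pc.ref_allele[l]).upper())
            i_alt = _NUC_ORDER.find(str(pc.alt_allele[l]).upper())
            cols[:, i_ref] = pc.ref_depth[l]
            cols[:, i_alt] = pc.alt_depth[l]
            fields = "\t".join(":".join(str(x) for x in row) for row in cols)
            fh.write(f"{pc.contig[l]}\t{pc.pos[l]}\t{pc.ref_allele[l]}\t{fields}\n")


def filter_snps(
    pc: PoolCounts,
    min_cov: int = 60,
    cov_quantile_lo: float = 0.001,
    cov_quantile_hi: float = 0.999,
    maf_min: float = 0.008,
    maf_mode: str = "global",
) -> tuple[PoolCounts, FilterReport]:
    """Apply the three SNP retention rules in order.

    (a) every pool's total depth >= ``min_cov`` (1x per haplotype for pools of
    60); (b) every pool's total depth within that pool's
    [``cov_quantile_lo``, ``cov_quantile_hi``] depth quantiles, computed per
    pool across the SNPs surviving (a); (c) minor-allele frequency >=
    ``maf_min``, computed depth-weighted across all pools jointly
    (``maf_mode="global"``, the default: 0.008 is about one read in a
    60-haplotype pool) or within every pool (``maf_mode="per_pool"``).

    Quantile bounds use order statistics (the "lower"/"higher" quantile
    methods) so the bounds are observed depths and the interval is
    inclusive; depths being integers, this keeps the filter stable when
    re-applied to its own output.

    Returns the retained PoolCounts and a per-rule removal report.
    """
    if pc.n_snps == 0:
        raise ValueError("empty PoolCounts")
    depth = pc.total_depth  # (L, S)

    keep_a = (depth >= min_cov).all(axis=1)
    n_a = int((~keep_a).sum())

    depth_a = depth[keep_a]
    if len(depth_a):
        lo = np.quantile(depth_a, cov_quantile_lo, axis=0, method="lower")
        hi = np.quantile(depth_a, cov_quantile_hi, axis=0, method="higher")
        keep_b_sub = ((depth_a >= lo) & (depth_a <= hi)).all(axis=1)
    else:
        lo = np.zeros(pc.n_stands)
        hi = np.zeros(pc.n_stands)
        keep_b_sub = np.zeros(0, dtype=bool)
    n_b = int((~keep_b_sub).sum())

    idx_ab = np.flatnonzero(keep_a)[keep_b_sub]
    alt = pc.alt_depth[idx_ab]
    tot = depth[idx_ab]
    if maf_mode == "global":
        p = alt.sum(axis=1) / np.maximum(tot.sum(axis=1), 1)
        maf = np.minimum(p, 1.0 - p)
        keep_c_sub = maf >= maf_min
    elif maf_mode == "per_pool":
        with np.errstate(invalid="ignore"):
            p = alt / np.maximum(tot, 1)
        maf = np.minimum(p, 1.0 - p)
        keep_c_sub = (maf >= maf_min).all(axis=1)
    else:
        raise ValueError("maf_mode must be 'global' or 'per_pool'")
    n_c = int((~keep_c_sub).sum())

    idx = idx_ab[keep_c_sub]
    report = FilterReport(
        n_input=pc.n_snps,
        removed_min_cov=n_a,
        removed_cov_quantile=n_b,
        removed_maf=n_c,
        n_retained=len(idx),
        cov_quantile_bounds={
            s: (float(lo[i]), float(hi[i])) for i, s in enumerate(pc.stand_ids)
        },
    )
    if len(idx) == 0:
        warnings.warn("all SNPs removed by filters", stacklevel=2)
    logger.info(
        "filter_snps: %d -> %d SNPs (min_cov removed %d, quantile %d, maf %d)",
        pc.n_snps, len(idx), n_a, n_b, n_c,
    )
    return pc.subset_snps(idx), report


def estimate_frequencies(pc: PoolCounts) -> FrequencyMatrix:
    """Alternate-allele read proportion per SNP and stand.

    The raw read proportion alt/(ref+alt) is the standard pool-seq frequency
    estimate; the coverage filters guarantee positive depth everywhere.
    """
    depth = pc.total_depth
    if (depth == 0).any():
        bad = np.argwhere(depth == 0)[0]
        raise ValueError(
            f"zero depth at SNP {pc.snp_ids[bad[0]]} in stand "
            f"{pc.stand_ids[bad[1]]}; apply filter_snps first"
        )
    values = (pc.alt_depth / depth).T  # stands x snps
    return FrequencyMatrix(values, list(pc.stand_ids), pc.snp_ids.copy())
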