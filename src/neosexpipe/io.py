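"""File-format interfaces: VCF, GFF3, BED, sex tables.

VCF records are read with cyvcf2 and carried as the package's site
dataclasses; the strand/placement supports the variant filters need
(SAF, SAR, RPL, RPR) are taken from INFO.  Coordinates follow each
format's native convention (VCF/GFF3 1-based, BED 0-based half-open)
and are converted at the boundary.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .phasing import SampleGenotype, SiteGenotypes
from .popgen import GenotypeCall, VariantSite

logger = logging.getLogger(__name__)


def read_sexes_tsv(path: str) -> dict[str, str]:
    """Two-column TSV: sample_id, sex (M/F)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["sample_id", "sex"], dtype=str)
    bad = df[~df.sex.isin(["M", "F"])]
    if len(bad):
        raise ValueError(f"{path}: invalid sex labels {bad.sex.tolist()}")
    return dict(zip(df.sample_id, df.sex))


def _int_info(variant, key: str, path: str) -> int:
    val = variant.INFO.get(key)
    if val is None:
        raise ValueError(f"{path}: record {variant.CHROM}:{variant.POS} "
                         f"lacks INFO field {key}")
    if isinstance(val, (tuple, list)):
        val = val[0]
    return int(val)


def read_variant_sites(path: str, sexes: dict[str, str]) -> list[VariantSite]:
    """Load VCF records as :class:`~neosexpipe.popgen.VariantSite`."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in sexes]
    if missing:
        raise ValueError(f"{path}: samples without sex label: {missing}")
    sites = []
    for v in vcf:
        depths = v.format("DP")
        genotypes = []
        for i, sid in enumerate(samples):
            alleles = tuple(a for a in v.genotypes[i][:-1])
            depth = int(depths[i][0]) if depths is not None else 0
            genotypes.append(GenotypeCall(sid, sexes[sid], alleles, depth))
        sites.append(VariantSite(
            v.CHROM, v.POS, v.REF, tuple(v.ALT), float(v.QUAL or 0.0),
            _int_info(v, "SAF", path), _int_info(v, "SAR", path),
            _int_info(v, "RPL", path), _int_info(v, "RPR", path), genotypes))
    return sites


def read_site_genotypes(path: str, sexes: dict[str, str]) -> list[SiteGenotypes]:
    """Load VCF records with nucleotide genotypes for phasing."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in sexes]
    if missing:
        raise ValueError(f"{path}: samples without sex label: {missing}")
    sites = []
    for v in vcf:
        alleles_by_idx = [v.REF] + list(v.ALT)
        depths = v.format("DP")
        entries = []
        for i, sid in enumerate(samples):
            gt = v.genotypes[i][:-1]
            nts = tuple(alleles_by_idx[a] if a >= 0 else None for a in gt)
            depth = int(depths[i][0]) if depths is not None else 0
            entries.append(SampleGenotype(sid, sexes[sid], nts, depth))
        sites.append(SiteGenotypes(v.CHROM, v.POS, v.REF, tuple(v.ALT),
                                   float(v.QUAL or 0.0), entries))
    return sites


def write_vcf(path: str, sites: Sequence[VariantSite]) -> None:
    """Write sites as a minimal uncompressed VCF with SAF/SAR/RPL/RPR in
    INFO and GT:DP per sample."""
    if not sites:
        raise ValueError("no sites to write")
    samples = [g.sample_id for g in sites[0].genotypes]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for key in ("SAF", "SAR", "RPL", "RPR"):
            fh.write(f'##INFO=<ID={key},Number=1,Type=Integer,'
                     f'Description="{key} read count">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        scaffolds = {s.scaffold for s in sites}
        for scaf in sorted(scaffolds):
            fh.write(f"##contig=<ID={scaf}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for s in sorted(sites, key=lambda x: (x.scaffold, x.pos)):
            info = f"SAF={s.saf};SAR={s.sar};RPL={s.rpl};RPR={s.rpr}"
            cols = [s.scaffold, str(s.pos), ".", s.ref, ",".join(s.alts),
                    f"{s.qual:g}", "PASS", info, "GT:DP"]
            for g in s.genotypes:
                gt = "/".join("." if a < 0 else str(a) for a in g.alleles)
                cols.append(f"{gt}:{g.depth}")
            fh.write("\t".join(cols) + "\n")


def read_cds_intervals(path: str) -> dict[str, dict]:
    """CDS structure per gene from GFF3 (via gffutils, in-memory DB).

    Returns {gene_id: {"scaffold": str, "strand": "+"/"-",
    "intervals": [(start0, end0), ...]}} with 0-based half-open
    intervals in genomic order."""
    import gffutils

    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds)) or [cds]
        gene_id = parents[-1].id
        rec = genes.setdefault(gene_id, {
            "scaffold": cds.seqid, "strand": cds.strand, "intervals": []})
        rec["intervals"].append((cds.start - 1, cds.end))
    for rec in genes.values():
        rec["intervals"].sort()
    return genes


def write_tsv(path: str, df: pd.DataFrame, header_comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
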