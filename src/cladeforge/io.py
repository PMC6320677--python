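"""VCF and GFF3 input/output.

Variant records travel through the package as pandas DataFrames with one
single-base-or-allele-string column per sample (haploid calls: each
sample carries exactly one allele).  VCF files are written and read with
pysam; genotypes are haploid GT fields.  Gene models are read with
gffutils and written as plain GFF3 lines.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import gffutils
import pandas as pd
import pysam

from .indels import GeneModel


def write_vcf(
    records: list[dict],
    samples: list[str],
    chromosome_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write variant records (dicts with chrom/pos/ref/alt + per-sample
    allele strings) as a haploid-GT VCF."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom, length in chromosome_lengths.items():
        header.contigs.add(chrom, length=int(length) + 1000)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec in records:
            alleles = (rec["ref"], rec["alt"])
            r = vf.new_record(
                contig=rec["chrom"],
                start=rec["pos"] - 1,
                alleles=alleles,
            )
            for s in samples:
                allele = rec[s]
                r.samples[s]["GT"] = (alleles.index(allele),) if allele in alleles else (None,)
            vf.write(r)


def read_vcf(path: str | Path, samples: list[str] | None = None) -> pd.DataFrame:
    """Read a haploid-GT VCF into the package's variant DataFrame."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        names = samples or list(vf.header.samples)
        for rec in vf:
            alleles = rec.alleles
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": ",".join(rec.alts) if rec.alts else ".",
            }
            for s in names:
                gt = rec.samples[s]["GT"]
                idx = gt[0] if gt and gt[0] is not None else None
                row[s] = alleles[idx] if idx is not None else "."
            rows.append(row)
    return pd.DataFrame(rows)


def write_gff3(gene_models: list[dict], path: str | Path) -> None:
    """Write toy gene models (dicts with gene_id/chrom/start/end/strand/
    exons) as GFF3 gene -> mRNA -> exon/CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in gene_models:
            gid = g["gene_id"]
            fh.write(
                f"{g['chrom']}\tcladeforge\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={gid}\n"
            )
            fh.write(
                f"{g['chrom']}\tcladeforge\tmRNA\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={gid}.t1;Parent={gid}\n"
            )
            for i, (s, e) in enumerate(sorted(g["exons"])):
                fh.write(
                    f"{g['chrom']}\tcladeforge\texon\t{s}\t{e}\t.\t{g['strand']}\t.\t"
                    f"ID={gid}.e{i + 1};Parent={gid}.t1\n"
                )
                fh.write(
                    f"{g['chrom']}\tcladeforge\tCDS\t{s}\t{e}\t.\t{g['strand']}\t0\t"
                    f"ID={gid}.c{i + 1};Parent={gid}.t1\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + CDS/exon children) via gffutils."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = []
        cds = []
        for child in db.children(gene.id, level=None):
            if child.featuretype == "exon":
                exons.append((child.start, child.end))
            elif child.featuretype == "CDS":
                cds.append((child.start, child.end))
        if not exons:
            exons = [(gene.start, gene.end)]
        if not cds:
            cds = list(exons)
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=tuple(sorted(exons)),
                cds=tuple(sorted(cds)),
            )
        )
    return models


def gene_intervals_frame(models: list[GeneModel]) -> pd.DataFrame:
    """Half-open [start, end) gene intervals for the genic SNP partition."""
    return pd.DataFrame(
        [
            {"chrom": m.chrom, "start": m.start, "end": m.end + 1, "gene_id": m.gene_id}
            for m in models
        ]
    )
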