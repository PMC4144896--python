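"""Readers and writers for the on-disk formats.

All coordinates are 0-based half-open internally.  BED shares that
convention on disk; GFF3 (1-based inclusive) is converted at this
boundary.  Every writer emits ``#`` comment headers carrying the seed
and configuration digest so intermediate artifacts are diffable and
traceable; readers skip them.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import BindingRegion, GeneModel, ReadSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    genome: dict[str, str] = {}
    lowercase_seen = False
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate sequence name {record.id!r} in {path}")
        seq = str(record.seq)
        if not seq.isupper():
            lowercase_seen = True
        genome[record.id] = seq.upper()
    if not genome:
        logger.warning("FASTA file %s contains no sequences", path)
    if lowercase_seen:
        logger.info("lowercase bases in %s uppercased on read", path)
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ----------------------------------------------------------- gene models

def _header_lines(header: str | None) -> list[str]:
    return [f"# {line}" for line in header.splitlines()] if header else []


def write_gff3(genes: list[GeneModel], path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in _header_lines(header):
            fh.write(line + "\n")
        for g in genes:
            fh.write("\t".join([
                g.chrom, "chiptarget", "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", f"ID={g.gene_id}",
            ]) + "\n")


def write_bed12(genes: list[GeneModel], path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(header):
            fh.write(line + "\n")
        for g in genes:
            size = g.end - g.start
            fh.write("\t".join([
                g.chrom, str(g.start), str(g.end), g.gene_id, "0", g.strand,
                str(g.start), str(g.end), "0", "1", f"{size},", "0,",
            ]) + "\n")


def read_gene_models(path: str | Path, dialect: str | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 (``gene`` features) or BED12.

    The dialect is inferred from the extension unless given explicitly
    as ``"gff3"`` or ``"bed12"``.  Strand is mandatory in both.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = "gff3" if suffix in (".gff", ".gff3") else "bed12"
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "gff3":
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
                if fields[2] != "gene":
                    continue
                chrom, start, end, strand = fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
                attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
                gene_id = attrs.get("ID", f"gene_at_{chrom}_{start}")
            else:
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: BED12 needs >= 6 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                gene_id, strand = fields[3], fields[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            genes.append(GeneModel(gene_id, chrom, start, end, strand))
    return genes


# ----------------------------------------------------------------- reads

def write_bed6(reads: ReadSet, path: str | Path, header: str | None = None,
               name_prefix: str = "read") -> None:
    starts = reads.starts
    ends = reads.starts + reads.lengths
    strands = reads.strands
    with open(path, "w") as fh:
        for line in _header_lines(header):
            fh.write(line + "\n")
        for i in range(len(reads)):
            fh.write(f"{reads.chroms[i]}\t{starts[i]}\t{ends[i]}\t"
                     f"{name_prefix}{i}\t0\t{strands[i]}\n")


def read_reads(path: str | Path, fmt: str | None = None) -> ReadSet:
    """Read mapped reads from BED6 or minimal SAM.

    For SAM, only mapped primary records are kept (skips are counted
    and logged); the read occupies [pos, pos + aligned length).
    """
    path = Path(path)
    if fmt is None:
        fmt = "sam" if path.suffix.lower() == ".sam" else "bed"
    if fmt == "sam":
        chroms, starts, lengths, rev = [], [], [], []
        skipped = 0
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    skipped += 1
                    continue
                chroms.append(rec.reference_name)
                starts.append(rec.reference_start)
                lengths.append(rec.reference_length or rec.query_length)
                rev.append(rec.is_reverse)
        if skipped:
            logger.info("skipped %d unmapped/secondary records in %s", skipped, path)
        return ReadSet(chroms, np.array(starts, dtype=np.int64),
                       np.array(lengths, dtype=np.int64), np.array(rev, dtype=bool))
    chroms, starts, lengths, rev = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
            chroms.append(fields[0])
            start, end = int(fields[1]), int(fields[2])
            starts.append(start)
            lengths.append(end - start)
            rev.append(fields[5] == "-")
    return ReadSet(chroms, np.array(starts, dtype=np.int64),
                   np.array(lengths, dtype=np.int64), np.array(rev, dtype=bool))


# --------------------------------------------------------------- regions

REGION_COLUMNS = ["chrom", "start", "end", "condition", "q_peak", "q_input",
                  "strand_sep_q", "strand_sep_bp", "support_rep1", "support_rep2"]


def write_regions(regions: list[BindingRegion], path: str | Path,
                  header: str | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(header):
            fh.write(line + "\n")
        fh.write("\t".join(REGION_COLUMNS) + "\n")
        for r in regions:
            fh.write("\t".join([
                r.chrom, str(r.start), str(r.end), r.condition,
                f"{r.q_peak:.6g}", f"{r.q_input:.6g}", f"{r.strand_sep_q:.6g}",
                f"{r.strand_sep_bp:.6g}", str(int(r.support[0])), str(int(r.support[1])),
            ]) + "\n")


def read_regions(path: str | Path) -> list[BindingRegion]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in df.itertuples(index=False):
        out.append(BindingRegion(
            chrom=str(row.chrom), start=int(row.start), end=int(row.end),
            condition=str(row.condition), q_peak=float(row.q_peak),
            q_input=float(row.q_input), strand_sep_q=float(row.strand_sep_q),
            strand_sep_bp=float(row.strand_sep_bp),
            support=(bool(row.support_rep1), bool(row.support_rep2)),
        ))
    return out


# ------------------------------------------------------------ expression

def write_expression(values: pd.DataFrame, path: str | Path,
                     header: str | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(header):
            fh.write(line + "\n")
        values.round(6).to_csv(fh, sep="\t", index_label="gene_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")


# ----------------------------------------------------------- ground truth

def write_ground_truth(truth, path_sites: str | Path, path_genes: str | Path,
                       conditions: tuple[str, ...], header: str | None = None) -> None:
    with open(path_sites, "w") as fh:
        for line in _header_lines(header):
            fh.write(line + "\n")
        cond_cols = [f"active_{c}" for c in conditions]
        fh.write("\t".join(["chrom", "position"] + cond_cols + ["word_starts"]) + "\n")
        for s in truth.sites:
            fh.write("\t".join(
                [s.chrom, str(s.position)]
                + [str(int(a)) for a in s.active]
                + [",".join(map(str, s.word_starts))]
            ) + "\n")
    with open(path_genes, "w") as fh:
        for line in _header_lines(header):
            fh.write(line + "\n")
        fh.write("gene_id\tbound\tde_direction\n")
        gene_ids = sorted(set(truth.bound_genes) | set(truth.de_genes))
        for gid in gene_ids:
            fh.write(f"{gid}\t{int(gid in truth.bound_genes)}\t"
                     f"{truth.de_genes.get(gid, 'none')}\n")


def read_category_map(path: str | Path) -> dict[str, str]:
    """TSV gene_id -> functional category."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene_id", "category"])
    return dict(zip(df["gene_id"].astype(str), df["category"].astype(str)))
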