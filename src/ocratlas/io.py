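"""Readers and writers for the plain-text formats the pipeline exchanges.

BED / narrowPeak round-trip losslessly on canonical records.  GFF3 uses
1-based closed coordinates on disk and is converted to the package's
0-based half-open convention at this boundary (and back on write).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomeAnnotation, IntervalSet, PeakSet, ValidationError

__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gff3",
    "write_gff3",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "read_jaspar_pfm",
]


class ParseError(ValueError):
    """Malformed input line; the message names the file and line number."""


def _fail(path, lineno, msg):
    raise ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------


def read_bed(path, chrom_sizes: Mapping[str, int] | None = None) -> IntervalSet:
    """Read BED3/BED6 into an IntervalSet (extra columns ignored)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                _fail(path, lineno, f"expected >= 3 tab-separated fields, got {len(f)}")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates {f[1]!r}, {f[2]!r}")
            name = f[3] if len(f) > 3 else ""
            try:
                score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            except ValueError:
                _fail(path, lineno, f"non-numeric score {f[4]!r}")
            strand = f[5] if len(f) > 5 else "."
            if strand not in ("+", "-", "."):
                _fail(path, lineno, f"invalid strand {strand!r}")
            rows.append((f[0], start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    try:
        return IntervalSet(df, chrom_sizes)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e


def write_bed(intervals: IntervalSet, path, bed3: bool = False) -> None:
    df = intervals.df
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            if bed3:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            else:
                score = int(r.score) if float(r.score).is_integer() else r.score
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n")


def read_narrowpeak(path, chrom_sizes: Mapping[str, int] | None = None) -> PeakSet:
    """Read a 10-column ENCODE narrowPeak file.

    Column 10 (summit offset from start) uses -1 as the "undefined" sentinel;
    it is kept as -1, never coerced to position 0.
    """
    rows, summits = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 10:
                _fail(path, lineno, f"narrowPeak requires 10 fields, got {len(f)}")
            try:
                start, end, summit = int(f[1]), int(f[2]), int(f[9])
            except ValueError:
                _fail(path, lineno, "non-integer coordinate or summit field")
            rows.append((f[0], start, end, f[3], float(f[6]), f[5]))
            summits.append(summit)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return PeakSet(IntervalSet(df, chrom_sizes), np.asarray(summits, dtype=np.int64))


def write_narrowpeak(peaks: PeakSet, path) -> None:
    df = peaks.intervals.df
    so = peaks.summit_offset
    with open(path, "w") as fh:
        for i, r in enumerate(df.itertuples(index=False)):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}"
                f"\t{r.score:g}\t-1\t-1\t{so[i]}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_TYPES = {"gene", "exon", "five_prime_UTR", "three_prime_UTR"}


def read_gff3(path, chrom_sizes: Mapping[str, int] | None = None) -> GenomeAnnotation:
    """Read gene/exon/UTR records from GFF3 into a GenomeAnnotation.

    GFF3 is 1-based closed; internally start becomes ``start-1`` and end is
    kept, yielding 0-based half-open intervals.  Gene records must carry an
    explicit +/- strand.
    """
    genes, exons, utr5, utr3 = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                _fail(path, lineno, f"GFF3 requires 9 fields, got {len(f)}")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = f
            if ftype not in _GFF_TYPES:
                continue
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates {start1!r}, {end1!r}")
            tags = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    tags[k.strip()] = v.strip()
            if ftype == "gene":
                if strand not in ("+", "-"):
                    _fail(path, lineno, f"gene record requires +/- strand, got {strand!r}")
                gid = tags.get("ID")
                if gid is None:
                    _fail(path, lineno, "gene record lacks ID attribute")
                tss = start if strand == "+" else end - 1
                genes.append((gid, chrom, strand, start, end, tss))
            else:
                parent = tags.get("Parent", tags.get("ID", ""))
                rec = (parent, chrom, start, end)
                {"exon": exons, "five_prime_UTR": utr5, "three_prime_UTR": utr3}[
                    ftype
                ].append(rec)
    gdf = pd.DataFrame(genes, columns=["gene_id", "chrom", "strand", "start", "end", "tss"])
    sub_cols = ["gene_id", "chrom", "start", "end"]
    return GenomeAnnotation(
        genes=gdf,
        exons=pd.DataFrame(exons, columns=sub_cols),
        five_prime_utr=pd.DataFrame(utr5, columns=sub_cols),
        three_prime_utr=pd.DataFrame(utr3, columns=sub_cols),
        chrom_sizes=dict(chrom_sizes) if chrom_sizes else {},
    )


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Write the annotation back out as GFF3 (1-based closed on disk)."""
    strands = dict(zip(annotation.genes["gene_id"], annotation.genes["strand"]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in annotation.genes.itertuples(index=False):
            fh.write(
                f"{r.chrom}\tocratlas\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t"
                f"ID={r.gene_id}\n"
            )
        for ftype, df in (
            ("exon", annotation.exons),
            ("five_prime_UTR", annotation.five_prime_utr),
            ("three_prime_UTR", annotation.three_prime_utr),
        ):
            for r in df.itertuples(index=False):
                fh.write(
                    f"{r.chrom}\tocratlas\t{ftype}\t{r.start + 1}\t{r.end}\t.\t"
                    f"{strands.get(r.gene_id, '+')}\t.\tParent={r.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# chrom.sizes / FASTA / GMT / JASPAR
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> dict:
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 2:
                _fail(path, lineno, f"chrom.sizes requires 2 fields, got {len(f)}")
            try:
                sizes[f[0]] = int(f[1])
            except ValueError:
                _fail(path, lineno, f"non-integer size {f[1]!r}")
    return sizes


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")


def read_fasta(path) -> dict:
    """Read FASTA into an ordered dict of name -> uppercase sequence string."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gmt(path) -> dict:
    """Read GMT gene sets: name -> list of gene ids (description dropped)."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                _fail(path, lineno, f"GMT requires >= 3 fields, got {len(f)}")
            sets[f[0]] = [g for g in f[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, list], path) -> None:
    with open(path, "w") as fh:
        for name in gene_sets:
            genes = "\t".join(gene_sets[name])
            fh.write(f"{name}\tna\t{genes}\n")


def read_jaspar_pfm(path) -> list:
    """Read JASPAR-format position frequency matrices.

    Returns a list of :class:`ocratlas.motifs.PFM` in file order.
    """
    from Bio import motifs as bio_motifs

    from .motifs import PFM

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array(
                [m.counts[b] for b in "ACGT"], dtype=float
            )  # 4 x L, ACGT order
            name = m.name or m.matrix_id or f"motif_{len(out)}"
            out.append(PFM(matrix_id=m.matrix_id or name, name=name, counts=counts))
    return out
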