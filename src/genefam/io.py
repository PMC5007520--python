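"""Readers/writers for the formats the pipeline touches, and the domain types.

Coordinate convention: 1-based, inclusive at every public surface (the GFF3
convention), because the positional rules of the analysis (e.g. the 200-kb
tandem window) are stated in genomic base pairs. BED output converts to
0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("genefam")

STOP_CODONS = {"TAA", "TAG", "TGA"}


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input parsed but violates a domain invariant."""


def log_filter(stage: str, n_in: int, n_out: int, threshold) -> None:
    """Log a filter stage so 'X of Y' style summaries are reconstructible."""
    logger.info("%s: %d of %d survive (threshold=%r)", stage, n_out, n_in, threshold)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene's chromosomal placement, exon structure, and coding sequence.

    Coordinates are 1-based inclusive; ``exons`` is sorted by start and
    pairwise non-overlapping; ``cds_sequence`` is the in-frame sense-strand
    CDS (5'->3' of the coding strand), empty when no genome was available.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_sequence: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if self.end < self.start:
            raise ValidationError(f"{self.gene_id}: end {self.end} < start {self.start}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if b < a:
                raise ValidationError(f"{self.gene_id}: exon ({a},{b}) has end < start")
            if a < self.start or b > self.end:
                raise ValidationError(f"{self.gene_id}: exon ({a},{b}) outside gene span")
            if prev_end is not None and a <= prev_end:
                raise ValidationError(f"{self.gene_id}: overlapping exons at ({a},{b})")
            prev_end = b
        if self.cds_sequence:
            self.cds_sequence = self.cds_sequence.upper()
            if len(self.cds_sequence) % 3 != 0:
                raise ValidationError(
                    f"{self.gene_id}: CDS length {len(self.cds_sequence)} not a multiple of 3"
                )
            for i in range(0, len(self.cds_sequence) - 3, 3):
                if self.cds_sequence[i : i + 3] in STOP_CODONS:
                    raise ValidationError(f"{self.gene_id}: internal stop codon at {i + 1}")

    @property
    def intron_count(self) -> int:
        return max(len(self.exons) - 1, 0)

    def translate(self) -> str:
        """Translate the CDS (without a trailing stop) to protein."""
        cds = self.cds_sequence
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        return str(Seq(cds).translate())


@dataclass
class ProteinRecord:
    """A protein with length, molecular weight (Da) and isoelectric point."""

    protein_id: str
    sequence: str
    length: int = 0
    molecular_weight: float = 0.0
    isoelectric_point: float = 0.0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"{self.protein_id}: empty sequence")
        if self.length == 0:
            self.length = len(self.sequence)
        if self.length != len(self.sequence):
            raise ValidationError(f"{self.protein_id}: length field mismatches sequence")


@dataclass
class ExpressionMatrix:
    """Gene x condition grid of FPKM values (non-negative reals)."""

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValidationError("expression grid shape mismatches labels")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in expression matrix")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValidationError("duplicate condition ids in expression matrix")
        if np.isnan(self.values).any():
            raise ValidationError("missing cells in expression matrix")
        if (self.values < 0).any():
            g, c = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative FPKM at gene {self.gene_ids[g]!r}, condition {self.condition_ids[c]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.condition_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercased sequence) pairs in file order.

    Duplicate ids raise :class:`FormatError`; an empty file returns an empty
    list with a warning.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def write_fasta(records, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_gff3(path: str | Path, genome_fasta: str | Path | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon/CDS features).

    One :class:`GeneModel` per gene, using the first mRNA when several are
    present. ``cds_sequence`` is stitched from the CDS features in
    transcription order (reverse-complemented on the minus strand) when a
    genome FASTA is supplied, and left empty otherwise.
    """
    genome: dict[str, str] = {}
    if genome_fasta is not None:
        genome = dict(read_fasta(genome_fasta))

    genes: dict[str, dict] = {}
    gene_order: list[str] = []
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"GFF3 line does not have 9 columns: {line!r}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            start, end = int(start), int(end)
            attributes = _parse_attributes(attrs)
            if ftype == "gene":
                gid = attributes.get("ID")
                if gid is None:
                    raise FormatError(f"gene feature without ID: {line!r}")
                genes[gid] = {
                    "chromosome": chrom, "start": start, "end": end, "strand": strand,
                    "mrnas": [], "exons": {}, "cds": {},
                }
                gene_order.append(gid)
            elif ftype == "mRNA":
                mid = attributes.get("ID")
                parent = attributes.get("Parent")
                if parent in genes and mid is not None:
                    genes[parent]["mrnas"].append(mid)
                    mrna_to_gene[mid] = parent
            elif ftype in ("exon", "CDS"):
                parent = attributes.get("Parent")
                gid = mrna_to_gene.get(parent, parent)
                if gid not in genes:
                    continue
                store = genes[gid]["exons" if ftype == "exon" else "cds"]
                store.setdefault(parent, []).append((start, end))

    models = []
    for gid in gene_order:
        info = genes[gid]
        mrna = info["mrnas"][0] if info["mrnas"] else gid
        exons = sorted(info["exons"].get(mrna, []))
        cds_parts = sorted(info["cds"].get(mrna, []))
        cds_seq = ""
        if cds_parts and info["chromosome"] in genome:
            chrom_seq = genome[info["chromosome"]]
            cds_seq = "".join(chrom_seq[a - 1 : b] for a, b in cds_parts)
            if info["strand"] == "-":
                cds_seq = str(Seq(cds_seq).reverse_complement())
        models.append(GeneModel(
            gene_id=gid, chromosome=info["chromosome"], start=info["start"],
            end=info["end"], strand=info["strand"], exons=exons, cds_sequence=cds_seq,
        ))
    return models


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    """Write gene models in the same single-isoform GFF3 dialect read_gff3 reads."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            base = f"{g.chromosome}\tgenefam\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(f"{base}gene\t{g.start}\t{g.end}{tail}.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{base}mRNA\t{g.start}\t{g.end}{tail}.\tID={mrna};Parent={g.gene_id}\n")
            for a, b in g.exons:
                fh.write(f"{base}exon\t{a}\t{b}{tail}.\tParent={mrna}\n")
                fh.write(f"{base}CDS\t{a}\t{b}{tail}0\tParent={mrna}\n")


# ---------------------------------------------------------------------------
# Expression / Ct tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV FPKM table (first column gene id, header of condition ids)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"duplicated gene id {dup!r} in {path}")
    values = np.empty(frame.shape, dtype=float)
    for i, gene in enumerate(frame.index):
        for j, cond in enumerate(frame.columns):
            cell = frame.iat[i, j]
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric cell {cell!r} at gene {gene!r}, condition {cond!r}"
                ) from None
    return ExpressionMatrix(list(frame.index), list(frame.columns), values)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


CT_COLUMNS = ["gene", "condition", "replicate", "Ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format qPCR Ct table (gene, condition, replicate, Ct)."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"Ct table {path} missing columns {missing}")
    frame["Ct"] = pd.to_numeric(frame["Ct"], errors="raise")
    return frame[CT_COLUMNS]


def write_ct_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame[CT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED output (0-based half-open per the BED standard)
# ---------------------------------------------------------------------------

def write_bed(intervals: list[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (chromosome, start_1based, end_1based, name) intervals as BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# Count summaries
# ---------------------------------------------------------------------------

def summarize_counts(part: int, whole: int) -> float:
    """Percentage 100*part/whole, rounded half-up to one decimal.

    Matches the printed "(82 of 94; 87.2%)" style of family summaries.
    """
    if whole <= 0:
        raise ValueError(f"whole must be > 0, got {whole}")
    if not 0 <= part <= whole:
        raise ValueError(f"part must be in [0, whole], got part={part}, whole={whole}")
    pct = Decimal(100 * part) / Decimal(whole)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
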