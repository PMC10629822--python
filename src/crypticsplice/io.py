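"""Readers and writers for the files the pipeline touches.

Junction tables (STAR ``SJ.out.tab`` dialect or a documented ``simple_tsv``
dialect), GTF gene annotation, FASTA reference sequence, TSV sample sheets
and TSV PSI matrices.

Coordinate convention: all intron coordinates are 1-based inclusive
``[intron_start, intron_end]`` — the first and last intronic base — matching
STAR's SJ.out.tab. Conversion to 0-based slices happens only at
sequence-extraction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("crypticsplice")


class ParseError(ValueError):
    """A malformed line or attribute in an input file."""


class ConfigurationError(ValueError):
    """An invalid option, dialect or parameter value."""


class IntegrityError(ValueError):
    """Structurally inconsistent data (duplicates, non-rectangular tables)."""


STRAND_UNDEFINED = "."
_SJ_STRAND_CODES = {"0": STRAND_UNDEFINED, "1": "+", "2": "-"}

SIMPLE_TSV_COLUMNS = ("chrom", "intron_start", "intron_end", "strand", "unique_reads")


@dataclass(frozen=True)
class SpliceJunction:
    """One intron observed in one sample, with its unique-read support."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    unique_reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.intron_start <= 0 or self.intron_end <= 0:
            raise IntegrityError(
                f"junction coordinates must be positive: {self.intron_start}-{self.intron_end}"
            )
        if self.intron_start > self.intron_end:
            raise IntegrityError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if self.unique_reads < 0:
            raise IntegrityError(f"unique_reads must be >= 0, got {self.unique_reads}")
        if self.strand not in ("+", "-", STRAND_UNDEFINED):
            raise IntegrityError(f"strand must be one of '+', '-', '.': {self.strand!r}")

    @property
    def coords(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.intron_start, self.intron_end)


@dataclass(frozen=True)
class GeneModel:
    """One transcript of one gene: ordered exons and an optional CDS.

    ``exons`` and ``cds`` are tuples of 1-based inclusive ``(start, end)``
    intervals sorted in genomic order. The CDS reading frame is taken to
    start at frame 0 at the transcript-sense 5' end of the CDS.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise IntegrityError(f"gene strand must be '+' or '-': {self.strand!r}")
        if not self.exons:
            raise IntegrityError(f"{self.transcript_id}: transcript has no exons")
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise IntegrityError(
                    f"{self.transcript_id}: exons overlap or are unsorted at {s}-{e}"
                )
            if s > e:
                raise IntegrityError(f"{self.transcript_id}: exon {s}-{e} inverted")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic-order 1-based inclusive intron intervals."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def acceptor_of(self, intron: tuple[int, int]) -> int:
        """Transcript-sense 3' splice-site coordinate (last intronic base)."""
        return intron[1] if self.strand == "+" else intron[0]

    def donor_of(self, intron: tuple[int, int]) -> int:
        """Transcript-sense 5' splice-site coordinate (first intronic base)."""
        return intron[0] if self.strand == "+" else intron[1]

    @property
    def acceptors(self) -> frozenset[int]:
        return frozenset(self.acceptor_of(i) for i in self.introns)

    @property
    def donors(self) -> frozenset[int]:
        return frozenset(self.donor_of(i) for i in self.introns)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    group: str
    path: str

    def __post_init__(self) -> None:
        if self.group not in ("WT", "MUT"):
            raise IntegrityError(f"group must be 'WT' or 'MUT', got {self.group!r}")


@dataclass(frozen=True)
class SampleSheet:
    """Sample-to-genotype mapping for the two-group contrast."""

    samples: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise IntegrityError("sample_ids in sample sheet are not unique")

    def require_both_groups(self) -> None:
        if not self.group_ids("WT") or not self.group_ids("MUT"):
            raise IntegrityError(
                "differential testing requires both WT and MUT samples"
            )

    def group_ids(self, group: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.group == group]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def groups(self) -> dict[str, str]:
        return {s.sample_id: s.group for s in self.samples}


# ---------------------------------------------------------------------------
# junction tables
# ---------------------------------------------------------------------------


def read_junction_table(
    source: str | Path, dialect: str = "simple_tsv", sample_id: str | None = None
) -> list[SpliceJunction]:
    """Read one per-sample junction table.

    ``sj_tab`` is STAR's 9-column SJ.out.tab (no header): chrom, intron
    start, intron end, strand code (0 undefined / 1 + / 2 −), motif,
    annotated, unique reads, multimapped reads, max overhang. Multimapped
    reads are ignored. ``simple_tsv`` is a headered 5-column TSV
    (chrom, intron_start, intron_end, strand, unique_reads).

    ``sample_id`` defaults to the file's stem.
    """
    source = Path(source)
    if sample_id is None:
        sample_id = source.stem
    if dialect not in ("sj_tab", "simple_tsv"):
        raise ConfigurationError(f"unknown junction-table dialect: {dialect!r}")

    junctions: list[SpliceJunction] = []
    with open(source) as fh:
        lines = fh.read().splitlines()
    start_line = 0
    if dialect == "simple_tsv":
        if not lines:
            raise ParseError(f"{source}: empty simple_tsv table (header required)")
        header = tuple(lines[0].rstrip("\n").split("\t"))
        if header != SIMPLE_TSV_COLUMNS:
            raise ParseError(
                f"{source}: line 1: bad simple_tsv header {header!r}, "
                f"expected {SIMPLE_TSV_COLUMNS!r}"
            )
        start_line = 1

    for lineno, line in enumerate(lines[start_line:], start=start_line + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            if dialect == "sj_tab":
                if len(fields) != 9:
                    raise ValueError(f"expected 9 columns, got {len(fields)}")
                chrom, start, end, strand_code = fields[0], fields[1], fields[2], fields[3]
                strand = _SJ_STRAND_CODES[strand_code]
                unique_reads = int(fields[6])
            else:
                if len(fields) != 5:
                    raise ValueError(f"expected 5 columns, got {len(fields)}")
                chrom, start, end, strand = fields[0], fields[1], fields[2], fields[3]
                unique_reads = int(fields[4])
            junction = SpliceJunction(
                chrom=chrom,
                intron_start=int(start),
                intron_end=int(end),
                strand=strand,
                unique_reads=unique_reads,
                sample_id=sample_id,
            )
        except (ValueError, KeyError, IndexError) as exc:
            raise ParseError(f"{source}: line {lineno}: {exc}") from exc
        junctions.append(junction)
    return junctions


def write_junction_table(
    junctions: Iterable[SpliceJunction], sink: str | Path, dialect: str = "simple_tsv"
) -> None:
    """Write a per-sample junction table in the given dialect."""
    if dialect not in ("sj_tab", "simple_tsv"):
        raise ConfigurationError(f"unknown junction-table dialect: {dialect!r}")
    strand_to_code = {v: k for k, v in _SJ_STRAND_CODES.items()}
    with open(sink, "w") as fh:
        if dialect == "simple_tsv":
            fh.write("\t".join(SIMPLE_TSV_COLUMNS) + "\n")
            for j in junctions:
                fh.write(
                    f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\t{j.strand}\t{j.unique_reads}\n"
                )
        else:
            for j in junctions:
                code = strand_to_code[j.strand]
                fh.write(
                    f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\t{code}\t0\t0\t{j.unique_reads}\t0\t0\n"
                )


# ---------------------------------------------------------------------------
# annotation (GTF)
# ---------------------------------------------------------------------------


class EmptyAnnotationError(ParseError):
    """GTF contained no exon features."""


def read_annotation(source: str | Path) -> list[GeneModel]:
    """Read a GTF into per-transcript gene models (exons + optional CDS)."""
    try:
        db = gffutils.create_db(
            str(source),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises several parse-level types
        raise ParseError(f"{source}: failed to parse GTF: {exc}") from exc

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    n_exons = 0
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            gene_id = feat.attributes["gene_id"][0]
            transcript_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise ParseError(
                f"{source}: {feat.featuretype} at {feat.seqid}:{feat.start}-{feat.end} "
                f"missing {exc} attribute"
            ) from exc
        meta.setdefault(transcript_id, (gene_id, feat.seqid, feat.strand))
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(transcript_id, []).append((feat.start, feat.end))
        if feat.featuretype == "exon":
            n_exons += 1
    if n_exons == 0:
        raise EmptyAnnotationError(f"{source}: annotation contains no exon features")

    models = []
    for transcript_id in sorted(exons):
        gene_id, chrom, strand = meta[transcript_id]
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=transcript_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons[transcript_id])),
                cds=tuple(sorted(cds[transcript_id])) if transcript_id in cds else None,
            )
        )
    return models


def write_annotation(genes: Sequence[GeneModel], sink: str | Path) -> None:
    """Write gene models as GTF (gene, transcript, exon and CDS features)."""
    with open(sink, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}";'
            span = g.span
            for feature, intervals in (
                ("gene", [span]),
                ("transcript", [span]),
                ("exon", list(g.exons)),
                ("CDS", list(g.cds) if g.cds else []),
            ):
                for s, e in intervals:
                    fh.write(
                        f"{g.chrom}\tcrypticsplice\t{feature}\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# reference sequence (FASTA)
# ---------------------------------------------------------------------------


def read_fasta(source: str | Path) -> dict[str, str]:
    """Load a reference FASTA as a contig -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")}


def write_fasta(genome: Mapping[str, str], sink: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(sink, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


def read_sample_sheet(source: str | Path, require_both_groups: bool = True) -> SampleSheet:
    """Read the TSV sample sheet (columns sample_id, group, path)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    expected = ["sample_id", "group", "path"]
    if list(df.columns) != expected:
        raise ParseError(f"{source}: sample sheet columns must be {expected}, got {list(df.columns)}")
    sheet = SampleSheet(
        samples=tuple(
            SampleRecord(row.sample_id, row.group, row.path) for row in df.itertuples()
        )
    )
    if require_both_groups:
        sheet.require_both_groups()
    return sheet


def write_sample_sheet(sheet: SampleSheet, sink: str | Path) -> None:
    with open(sink, "w") as fh:
        fh.write("sample_id\tgroup\tpath\n")
        for s in sheet.samples:
            fh.write(f"{s.sample_id}\t{s.group}\t{s.path}\n")


# ---------------------------------------------------------------------------
# PSI matrices
# ---------------------------------------------------------------------------


def write_psi_matrix(matrix: pd.DataFrame, sink: str | Path) -> None:
    """Write an events × samples PSI matrix as TSV, missing encoded as NA."""
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise IntegrityError(f"duplicate event identifiers: {dupes}")
    matrix.to_csv(sink, sep="\t", na_rep="NA", index_label="event_id", float_format="%.6f")


def read_psi_matrix(source: str | Path) -> pd.DataFrame:
    """Read a TSV PSI matrix written by :func:`write_psi_matrix`."""
    try:
        df = pd.read_csv(
            source, sep="\t", index_col="event_id", na_values=["NA"], keep_default_na=False
        )
    except pd.errors.ParserError as exc:
        raise IntegrityError(f"{source}: non-rectangular PSI matrix: {exc}") from exc
    except ValueError as exc:
        raise ParseError(f"{source}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise IntegrityError(f"{source}: duplicate event identifiers: {dupes}")
    n_fields = {len(line.split("\t")) for line in Path(source).read_text().splitlines() if line}
    if len(n_fields) > 1:
        raise IntegrityError(f"{source}: non-rectangular PSI matrix (ragged rows)")
    return df.astype(float) if not df.empty else df
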