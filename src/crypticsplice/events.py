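"""Alternative-splicing event calling and PSI quantification.

Events are built by intersecting observed splice junctions (pooled over all
samples) with annotated gene models:

* **A3SS** — two junctions share a donor; one acceptor is annotated
  (canonical), the other is not (alternative). This is the event class that
  carries the SF3B1-mutant cryptic 3'ss signal.
* **A5SS** — mirror image on a shared annotated acceptor.
* **exon_skip** — a junction exactly bridging the two annotated introns that
  flank an annotated internal exon.

PSI for an event in a sample is the bounded two-way ratio
``alt_reads / (alt_reads + canonical_reads)``, missing when total support is
below ``min_coverage``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, IntegrityError, SpliceJunction, STRAND_UNDEFINED

logger = logging.getLogger("crypticsplice")

EVENT_TYPES = ("A3SS", "A5SS", "exon_skip")

JunctionCounts = Mapping[tuple[str, str, int, int], int]


def make_event_id(
    gene_id: str, event_type: str, canonical: int | None, alternative: int | None,
    skipped_exon: tuple[int, int] | None = None,
) -> str:
    """Deterministic event identifier from gene and coordinates."""
    if event_type == "exon_skip":
        s, e = skipped_exon  # type: ignore[misc]
        return f"{gene_id}:exon_skip:{s}-{e}"
    return f"{gene_id}:{event_type}:{canonical}>{alternative}"


@dataclass(frozen=True)
class AltSpliceEvent:
    """A canonical/alternative splice-site pair anchored to one gene.

    ``shared_site`` is the donor for A3SS and the acceptor for A5SS.
    ``canonical``/``alternative`` are the annotated and unannotated
    coordinates of the varying site. ``canonical_introns``/``alt_introns``
    hold the 1-based inclusive intron intervals whose junction reads
    support each isoform (two inclusion introns for exon_skip).
    """

    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    shared_site: int | None
    canonical: int | None
    alternative: int | None
    canonical_introns: tuple[tuple[int, int], ...]
    alt_introns: tuple[tuple[int, int], ...]
    skipped_exon: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise IntegrityError(f"unknown event type {self.event_type!r}")
        if self.event_type != "exon_skip" and self.canonical == self.alternative:
            raise IntegrityError(
                f"{self.event_id}: canonical and alternative sites coincide"
            )


def _intron(donor: int, acceptor: int, strand: str) -> tuple[int, int]:
    """Intron interval from transcript-sense donor/acceptor coordinates."""
    return (donor, acceptor) if strand == "+" else (acceptor, donor)


def a3ss_event(
    gene_id: str, chrom: str, strand: str, donor: int, canonical_acceptor: int,
    alt_acceptor: int,
) -> AltSpliceEvent:
    return AltSpliceEvent(
        event_id=make_event_id(gene_id, "A3SS", canonical_acceptor, alt_acceptor),
        gene_id=gene_id,
        event_type="A3SS",
        chrom=chrom,
        strand=strand,
        shared_site=donor,
        canonical=canonical_acceptor,
        alternative=alt_acceptor,
        canonical_introns=(_intron(donor, canonical_acceptor, strand),),
        alt_introns=(_intron(donor, alt_acceptor, strand),),
    )


def a5ss_event(
    gene_id: str, chrom: str, strand: str, acceptor: int, canonical_donor: int,
    alt_donor: int,
) -> AltSpliceEvent:
    return AltSpliceEvent(
        event_id=make_event_id(gene_id, "A5SS", canonical_donor, alt_donor),
        gene_id=gene_id,
        event_type="A5SS",
        chrom=chrom,
        strand=strand,
        shared_site=acceptor,
        canonical=canonical_donor,
        alternative=alt_donor,
        canonical_introns=(_intron(canonical_donor, acceptor, strand),),
        alt_introns=(_intron(alt_donor, acceptor, strand),),
    )


def exon_skip_event(
    gene_id: str, chrom: str, strand: str, upstream_intron: tuple[int, int],
    downstream_intron: tuple[int, int], skipped_exon: tuple[int, int],
) -> AltSpliceEvent:
    skip_intron = (upstream_intron[0], downstream_intron[1])
    return AltSpliceEvent(
        event_id=make_event_id(gene_id, "exon_skip", None, None, skipped_exon),
        gene_id=gene_id,
        event_type="exon_skip",
        chrom=chrom,
        strand=strand,
        shared_site=None,
        canonical=None,
        alternative=None,
        canonical_introns=(upstream_intron, downstream_intron),
        alt_introns=(skip_intron,),
        skipped_exon=skipped_exon,
    )


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _canonical_site(
    transcripts: Sequence[GeneModel], shared: int, role: str, strand: str
) -> int:
    """Annotated coordinate paired with ``shared``, preferring the longest
    transcript; ties break to the most-upstream site in transcript sense."""
    candidates: list[tuple[int, int]] = []  # (transcript length, site)
    for t in transcripts:
        for intron in t.introns:
            donor, acceptor = t.donor_of(intron), t.acceptor_of(intron)
            if role == "acceptor" and donor == shared:
                candidates.append((t.length, acceptor))
            elif role == "donor" and acceptor == shared:
                candidates.append((t.length, donor))
    best_len = max(length for length, _ in candidates)
    sites = [site for length, site in candidates if length == best_len]
    # transcript-sense upstream = genomically smaller on +, larger on -
    return min(sites) if strand == "+" else max(sites)


def detect_events(
    junctions: Iterable[SpliceJunction],
    genes: Sequence[GeneModel],
    min_reads: int = 1,
) -> list[AltSpliceEvent]:
    """Call A3SS / A5SS / exon_skip events from pooled junction evidence.

    Junctions with undefined strand are dropped (3'ss identity is
    strand-dependent); junctions outside every gene span are counted and
    logged, never an error. Events are deduplicated across samples and
    transcripts; identifiers are deterministic functions of gene and
    coordinates.
    """
    observed: dict[tuple[str, str], set[tuple[int, int]]] = {}
    n_undefined = 0
    all_junctions: list[SpliceJunction] = []
    for j in junctions:
        if j.strand == STRAND_UNDEFINED:
            n_undefined += 1
            continue
        all_junctions.append(j)
        if j.unique_reads >= min_reads:
            observed.setdefault((j.chrom, j.strand), set()).add(
                (j.intron_start, j.intron_end)
            )
    if n_undefined:
        logger.info("dropped %d junction records with undefined strand", n_undefined)

    by_gene: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_gene.setdefault(g.gene_id, []).append(g)

    events: dict[str, AltSpliceEvent] = {}
    for gene_id in sorted(by_gene):
        transcripts = by_gene[gene_id]
        chrom, strand = transcripts[0].chrom, transcripts[0].strand
        obs = observed.get((chrom, strand), set())
        if not obs:
            continue
        annotated_introns = {i for t in transcripts for i in t.introns}
        acceptor_set = {t.acceptor_of(i) for t in transcripts for i in t.introns}
        donor_set = {t.donor_of(i) for t in transcripts for i in t.introns}
        lo = min(t.span[0] for t in transcripts)
        hi = max(t.span[1] for t in transcripts)
        gene_obs = sorted(j for j in obs if lo <= j[0] and j[1] <= hi)

        for start, end in gene_obs:
            donor = start if strand == "+" else end
            acceptor = end if strand == "+" else start
            if (start, end) in annotated_introns:
                continue
            if donor in donor_set and acceptor not in acceptor_set:
                canonical = _canonical_site(transcripts, donor, "acceptor", strand)
                ev = a3ss_event(gene_id, chrom, strand, donor, canonical, acceptor)
                events.setdefault(ev.event_id, ev)
            if acceptor in acceptor_set and donor not in donor_set:
                canonical = _canonical_site(transcripts, acceptor, "donor", strand)
                ev = a5ss_event(gene_id, chrom, strand, acceptor, canonical, donor)
                events.setdefault(ev.event_id, ev)

        for t in transcripts:
            introns = t.introns
            for i in range(1, len(t.exons) - 1):
                up, down = introns[i - 1], introns[i]
                if (up[0], down[1]) in obs:
                    ev = exon_skip_event(gene_id, chrom, strand, up, down, t.exons[i])
                    events.setdefault(ev.event_id, ev)

    n_unassigned = _count_unassigned(all_junctions, genes)
    if n_unassigned:
        logger.info("%d junctions fall outside every gene span", n_unassigned)
    return [events[k] for k in sorted(events)]


def _count_unassigned(junctions: Sequence[SpliceJunction], genes: Sequence[GeneModel]) -> int:
    spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for g in genes:
        spans.setdefault((g.chrom, g.strand), []).append(g.span)
    n = 0
    for j in junctions:
        gene_spans = spans.get((j.chrom, j.strand), [])
        if not any(lo <= j.intron_start and j.intron_end <= hi for lo, hi in gene_spans):
            n += 1
    return n


# ---------------------------------------------------------------------------
# PSI quantification
# ---------------------------------------------------------------------------


def _support(event: AltSpliceEvent, counts: JunctionCounts) -> tuple[float, float]:
    """(alt_reads, canonical_reads) for one event in one sample.

    For exon_skip the canonical (inclusion) support is the mean of the two
    flanking-junction counts, since one inclusion read pair spans both.
    """
    def count_of(intron: tuple[int, int]) -> int:
        c = counts.get((event.chrom, event.strand, intron[0], intron[1]), 0)
        if c < 0:
            raise IntegrityError(f"{event.event_id}: negative junction count {c}")
        return c

    alt = float(sum(count_of(i) for i in event.alt_introns))
    canonical_counts = [count_of(i) for i in event.canonical_introns]
    canonical = float(np.mean(canonical_counts)) if canonical_counts else 0.0
    return alt, canonical


def compute_psi(
    event: AltSpliceEvent, counts: JunctionCounts, min_coverage: int = 10
) -> tuple[float | None, float]:
    """Bounded PSI ``alt / (alt + canonical)`` and the total support.

    Returns ``(None, total)`` when total support < ``min_coverage``.
    """
    alt, canonical = _support(event, counts)
    total = alt + canonical
    if total < min_coverage or total == 0:
        return None, total
    return alt / total, total


def compute_literal_ratio(event: AltSpliceEvent, counts: JunctionCounts) -> float:
    """Unbounded ``alt / canonical`` read ratio (NaN when canonical is 0).

    Provided alongside the bounded PSI for comparison; the pipeline's
    statistics always use the bounded form.
    """
    alt, canonical = _support(event, counts)
    return alt / canonical if canonical > 0 else float("nan")


@dataclass
class PsiMatrix:
    """Events × samples PSI values plus the per-cell total read support."""

    psi: pd.DataFrame
    totals: pd.DataFrame

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            vals = self.psi.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise IntegrityError("PSI values outside [0, 1]")


def counts_by_sample(
    junctions: Iterable[SpliceJunction],
) -> dict[str, dict[tuple[str, str, int, int], int]]:
    """Index junction read counts as sample_id -> coords -> unique reads."""
    out: dict[str, dict[tuple[str, str, int, int], int]] = {}
    for j in junctions:
        per_sample = out.setdefault(j.sample_id, {})
        per_sample[j.coords] = per_sample.get(j.coords, 0) + j.unique_reads
    return out


def build_psi_matrix(
    events: Sequence[AltSpliceEvent],
    junctions: Iterable[SpliceJunction],
    sample_ids: Sequence[str],
    min_coverage: int = 10,
) -> PsiMatrix:
    """Quantify PSI for every event in every sample."""
    counts = counts_by_sample(junctions)
    psi = pd.DataFrame(
        index=pd.Index([e.event_id for e in events], name="event_id"),
        columns=list(sample_ids),
        dtype=float,
    )
    totals = psi.copy()
    for e in events:
        for s in sample_ids:
            value, total = compute_psi(e, counts.get(s, {}), min_coverage)
            psi.loc[e.event_id, s] = np.nan if value is None else value
            totals.loc[e.event_id, s] = total
    return PsiMatrix(psi=psi, totals=totals)


def summarize_event_types(
    events: Sequence[AltSpliceEvent], significant_ids: Iterable[str] | None = None
) -> pd.DataFrame:
    """Count events per class, overall and among significant calls."""
    sig = set(significant_ids) if significant_ids is not None else set()
    rows = []
    for etype in EVENT_TYPES:
        of_type = [e for e in events if e.event_type == etype]
        rows.append(
            {
                "event_type": etype,
                "n_total": len(of_type),
                "n_significant": sum(e.event_id in sig for e in of_type),
            }
        )
    return pd.DataFrame(rows).set_index("event_type")


def plurality_class(summary: pd.DataFrame, column: str = "n_significant") -> str | None:
    """Event class with the most events in ``column`` (None if all zero)."""
    if summary[column].sum() == 0:
        return None
    return summary[column].idxmax()


def events_to_frame(events: Sequence[AltSpliceEvent]) -> pd.DataFrame:
    """Tabular view of events for the events TSV."""
    rows = []
    for e in events:
        rows.append(
            {
                "event_id": e.event_id,
                "gene_id": e.gene_id,
                "type": e.event_type,
                "chrom": e.chrom,
                "strand": e.strand,
                "shared_site": e.shared_site,
                "canonical": e.canonical,
                "alternative": e.alternative,
                "skipped_exon_start": e.skipped_exon[0] if e.skipped_exon else None,
                "skipped_exon_end": e.skipped_exon[1] if e.skipped_exon else None,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "event_id", "gene_id", "type", "chrom", "strand", "shared_site",
            "canonical", "alternative", "skipped_exon_start", "skipped_exon_end",
        ],
    )
    return df.set_index("event_id")
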