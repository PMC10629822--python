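"""Sequence characterization of cryptic 3' splice sites.

Offset convention (transcript sense, used throughout): intronic positions
are negative and exonic positions positive relative to the 3' splice site;
``-1`` is the last intronic base (the G of the acceptor AG), ``-2`` the A,
and ``+1`` the first exonic base. There is no offset 0.

Default windows:

* motif window ``(-30, +9)`` — 39 nt spanning the acceptor;
* polypyrimidine tract (PPT) ``(-20, -5)`` — 16 intronic nt;
* branchpoint ``(-40, -10)`` — 31 intronic nt where U2/SF3B1 reads the
  adenosine of the branch site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .io import GeneModel, IntegrityError
from .events import AltSpliceEvent

logger = logging.getLogger("crypticsplice")

SS_WINDOW = (-30, 9)
PPT_WINDOW = (-20, -5)
BRANCHPOINT_WINDOW = (-40, -10)

BASES = ("A", "C", "G", "T")
PYRIMIDINES = frozenset("CT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def window_offsets(window: tuple[int, int]) -> list[int]:
    """All offsets in ``window`` inclusive, skipping the nonexistent 0."""
    lo, hi = window
    if lo > hi:
        raise IntegrityError(f"window {window} is inverted")
    return [k for k in range(lo, hi + 1) if k != 0]


def window_interval(site: int, strand: str, window: tuple[int, int]) -> tuple[int, int]:
    """Genomic 1-based inclusive interval covered by ``window`` at a 3'ss.

    On '+' offset -k maps to ``site - k + 1`` and +j to ``site + j``; on '-'
    the mapping mirrors.
    """
    lo, hi = window
    if lo > hi or lo == 0 or hi == 0:
        raise IntegrityError(f"bad window {window}: bounds are nonzero offsets, lo <= hi")
    if strand == "+":
        start = site + lo + 1 if lo < 0 else site + lo
        end = site + hi + 1 if hi < 0 else site + hi
    else:
        start = site - hi - 1 if hi < 0 else site - hi
        end = site - lo - 1 if lo < 0 else site - lo
    return (start, end)


def extract_window(
    genome: Mapping[str, str], chrom: str, site: int, strand: str,
    window: tuple[int, int],
) -> str | None:
    """Transcript-sense sequence of ``window`` at a 3'ss, or None if the
    window runs off the contig (logged, per-event skip)."""
    start, end = window_interval(site, strand, window)
    contig = genome[chrom]
    if start < 1 or end > len(contig):
        logger.warning(
            "window %s at %s:%d(%s) off contig; skipped", window, chrom, site, strand
        )
        return None
    seq = contig[start - 1 : end]
    return seq if strand == "+" else reverse_complement(seq)


def extract_ss_windows(
    events: Sequence[AltSpliceEvent],
    site_class: str,
    genome: Mapping[str, str],
    window: tuple[int, int] = SS_WINDOW,
) -> dict[str, str]:
    """One transcript-sense acceptor-window sequence per A3SS event.

    ``site_class`` selects the canonical or the cryptic (alternative)
    acceptor of each event.
    """
    if site_class not in ("canonical", "cryptic"):
        raise IntegrityError(f"site_class must be 'canonical' or 'cryptic': {site_class!r}")
    out: dict[str, str] = {}
    for e in events:
        if e.event_type != "A3SS":
            raise TypeError(f"{e.event_id}: acceptor windows require A3SS events")
        site = e.canonical if site_class == "canonical" else e.alternative
        seq = extract_window(genome, e.chrom, site, e.strand, window)
        if seq is not None:
            out[e.event_id] = seq
    return out


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def cryptic_distance(event: AltSpliceEvent) -> int:
    """Signed cryptic-to-canonical acceptor distance in nt.

    Positive = cryptic upstream of the canonical acceptor (intron-internal);
    equals the length of the intronic sequence included in the mRNA.
    """
    if event.event_type != "A3SS":
        raise TypeError(f"{event.event_id}: cryptic distance requires an A3SS event")
    if event.strand == "+":
        return event.canonical - event.alternative
    return event.alternative - event.canonical


@dataclass
class DistanceHistogram:
    """Counts of cryptic distances in log2 bins ``[2^k, 2^(k+1))``."""

    table: pd.DataFrame           # columns bin_lo, bin_hi, count (positive d)
    negative_table: pd.DataFrame  # same binning on |d| for downstream shifts
    mode_bin: tuple[int, int] | None


def _log2_bin_table(values: Sequence[int]) -> pd.DataFrame:
    rows = []
    if values:
        ks = np.floor(np.log2(np.asarray(values))).astype(int)
        for k in range(0, int(ks.max()) + 1):
            rows.append({"bin_lo": 2 ** k, "bin_hi": 2 ** (k + 1), "count": int((ks == k).sum())})
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "count"])


def distance_histogram(distances: Iterable[int]) -> DistanceHistogram:
    """Histogram of signed cryptic distances on a log2 scale.

    Positive (upstream) distances fill the main table; negative distances
    (downstream shifts) are tabulated separately on their magnitude. Empty
    input yields empty tables, not an error.
    """
    ds = list(distances)
    pos = [d for d in ds if d >= 1]
    neg = [-d for d in ds if d <= -1]
    table = _log2_bin_table(pos)
    mode_bin = None
    if len(table) and table["count"].sum() > 0:
        best = table.loc[table["count"].idxmax()]
        mode_bin = (int(best["bin_lo"]), int(best["bin_hi"]))
    return DistanceHistogram(
        table=table, negative_table=_log2_bin_table(neg), mode_bin=mode_bin
    )


# ---------------------------------------------------------------------------
# motif profiles
# ---------------------------------------------------------------------------


@dataclass
class MotifProfile:
    """Per-position base counts, frequencies and information content.

    ``info_content`` is ``2 - H(p)`` bits per position (Shannon entropy in
    log2); 0 for a uniform column, 2 for an invariant one.
    """

    offsets: tuple[int, ...]
    counts: pd.DataFrame
    frequencies: pd.DataFrame
    info_content: pd.Series
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.columns = [f"count_{b}" for b in BASES]
        for b in BASES:
            out[f"freq_{b}"] = self.frequencies[b]
        out["info_content"] = self.info_content
        out.index.name = "offset"
        return out


def motif_profile(
    sequences: Iterable[str],
    offsets: Sequence[int] | None = None,
    small_sample_correction: bool = False,
) -> MotifProfile:
    """Position frequency matrix and information content of aligned windows.

    Sequences must be equal length over {A,C,G,T,N}; N is excluded per
    position. The small-sample correction subtracts the asymptotic bias
    ``3 / (2 ln2 · n)`` from the information content (off by default).
    """
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise IntegrityError("motif_profile requires at least one sequence")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise IntegrityError("motif_profile requires equal-length sequences")
    if offsets is None:
        offsets = tuple(range(1, length + 1))
    else:
        offsets = tuple(offsets)
        if len(offsets) != length:
            raise IntegrityError(
                f"{len(offsets)} offsets for sequences of length {length}"
            )

    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), length)
    counts = pd.DataFrame(
        {b: (arr == b.encode()).sum(axis=0) for b in BASES},
        index=pd.Index(offsets, name="offset"),
    )
    unknown = (~np.isin(arr, [b.encode() for b in BASES + ("N",)])).sum()
    if unknown:
        raise IntegrityError("sequences contain characters outside {A,C,G,T,N}")

    totals = counts.sum(axis=1)
    freqs = counts.div(totals.replace(0, np.nan), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = freqs * np.log2(freqs)
    entropy = -plogp.fillna(0.0).sum(axis=1)
    ic = 2.0 - entropy
    if small_sample_correction:
        n_eff = totals.replace(0, np.nan)
        ic = ic - 3.0 / (2.0 * np.log(2) * n_eff)
    ic = ic.clip(lower=0.0, upper=2.0)
    ic[totals == 0] = np.nan
    return MotifProfile(
        offsets=offsets,
        counts=counts,
        frequencies=freqs,
        info_content=ic,
        n_sequences=len(seqs),
    )


def plot_motif(profile: MotifProfile, ax=None):
    """Minimal stacked-bar rendering of a motif profile (matplotlib hook)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.25 * len(profile.offsets) + 1, 2.5))
    bottom = np.zeros(len(profile.offsets))
    x = np.arange(len(profile.offsets))
    heights = profile.frequencies.mul(profile.info_content, axis=0)
    for base, color in zip(BASES, ("#109648", "#255C99", "#F7B32B", "#D62839")):
        h = heights[base].to_numpy()
        ax.bar(x, h, bottom=bottom, color=color, label=base, width=0.85)
        bottom += np.nan_to_num(h)
    ax.set_xticks(x[::5])
    ax.set_xticklabels([profile.offsets[i] for i in range(0, len(x), 5)])
    ax.set_ylabel("bits")
    ax.set_xlabel("offset from 3'ss")
    ax.legend(ncol=4, fontsize="small")
    return ax


# ---------------------------------------------------------------------------
# PPT / branchpoint scores
# ---------------------------------------------------------------------------


def ppt_score(window_sequence: str) -> float | None:
    """Pyrimidine (C/T) fraction among non-N bases; None for empty windows."""
    bases = [b for b in window_sequence.upper() if b != "N"]
    if not bases:
        return None
    return sum(b in PYRIMIDINES for b in bases) / len(bases)


def branchpoint_a_fraction(window_sequence: str) -> float | None:
    """Adenosine fraction among non-N bases; None for empty windows."""
    bases = [b for b in window_sequence.upper() if b != "N"]
    if not bases:
        return None
    return sum(b == "A" for b in bases) / len(bases)


# ---------------------------------------------------------------------------
# NMD-proneness
# ---------------------------------------------------------------------------


def included_sequence(event: AltSpliceEvent, genome: Mapping[str, str]) -> str:
    """Transcript-sense intronic sequence a cryptic acceptor adds to the mRNA."""
    d = cryptic_distance(event)
    if d < 1:
        raise IntegrityError(
            f"{event.event_id}: no included sequence for downstream shift (d={d})"
        )
    contig = genome[event.chrom]
    if event.strand == "+":
        seq = contig[event.alternative : event.canonical]
    else:
        seq = reverse_complement(contig[event.canonical - 1 : event.alternative - 1])
    return seq


def _upstream_cds_sequence(
    gene: GeneModel, acceptor: int, genome: Mapping[str, str]
) -> str:
    """Transcript-sense CDS sequence upstream of the canonical acceptor."""
    assert gene.cds is not None
    contig = genome[gene.chrom]
    parts = []
    for s, e in gene.cds:
        if gene.strand == "+":
            s2, e2 = s, min(e, acceptor)
        else:
            s2, e2 = max(s, acceptor), e
        if s2 <= e2:
            parts.append(contig[s2 - 1 : e2])
    seq = "".join(parts)
    return seq if gene.strand == "+" else reverse_complement(seq)


def flag_nmd(
    event: AltSpliceEvent, gene: GeneModel | None, genome: Mapping[str, str]
) -> str:
    """Classify the NMD-proneness of a cryptic-acceptor inclusion.

    ``frameshift`` when the included length is not a multiple of 3;
    otherwise the inclusion is translated in the annotated reading frame and
    flagged ``ptc_in_frame`` if it introduces an in-frame stop, ``none`` if
    not, and ``unknown_frame`` when no CDS annotation is available.
    """
    d = cryptic_distance(event)
    if d < 1:
        raise IntegrityError(f"{event.event_id}: NMD flag requires positive d")
    if d % 3 != 0:
        return "frameshift"
    if gene is None or gene.cds is None:
        return "unknown_frame"
    upstream = _upstream_cds_sequence(gene, event.canonical, genome)
    r = len(upstream) % 3
    phase_prefix = upstream[-r:] if r else ""
    s = phase_prefix + included_sequence(event, genome)
    for i in range(0, len(s) - len(s) % 3, 3):
        if s[i : i + 3] in STOP_CODONS:
            return "ptc_in_frame"
    return "none"


# ---------------------------------------------------------------------------
# per-event annotation
# ---------------------------------------------------------------------------


def characterize_events(
    events: Sequence[AltSpliceEvent],
    genome: Mapping[str, str],
    gene_models: Sequence[GeneModel] | None = None,
    ppt_window: tuple[int, int] = PPT_WINDOW,
    branchpoint_window: tuple[int, int] = BRANCHPOINT_WINDOW,
) -> pd.DataFrame:
    """Per-event site annotation for A3SS events with upstream cryptic sites.

    Columns: cryptic distance, included intronic sequence, canonical and
    cryptic PPT pyrimidine fractions, canonical and cryptic
    branchpoint-window A fractions, NMD flag.
    """
    by_gene: dict[str, GeneModel] = {}
    for g in gene_models or []:
        if g.gene_id not in by_gene or (by_gene[g.gene_id].cds is None and g.cds):
            by_gene[g.gene_id] = g
    rows = []
    for e in events:
        if e.event_type != "A3SS":
            continue
        d = cryptic_distance(e)
        row: dict = {"event_id": e.event_id, "gene_id": e.gene_id, "distance": d}
        if d >= 1:
            row["included_sequence"] = included_sequence(e, genome)
            row["nmd_flag"] = flag_nmd(e, by_gene.get(e.gene_id), genome)
        else:
            row["included_sequence"] = ""
            row["nmd_flag"] = "none"
        for label, site in (("canonical", e.canonical), ("cryptic", e.alternative)):
            ppt_seq = extract_window(genome, e.chrom, site, e.strand, ppt_window)
            bp_seq = extract_window(genome, e.chrom, site, e.strand, branchpoint_window)
            row[f"ppt_{label}"] = ppt_score(ppt_seq) if ppt_seq else np.nan
            row[f"bp_a_{label}"] = branchpoint_a_fraction(bp_seq) if bp_seq else np.nan
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "gene_id", "distance", "included_sequence", "nmd_flag",
            "ppt_canonical", "ppt_cryptic", "bp_a_canonical", "bp_a_cryptic",
        ],
    ).set_index("event_id")
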