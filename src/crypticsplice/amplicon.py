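"""Targeted amplicon quantification of a two-isoform splice locus.

Models the RT-PCR / amplicon-sequencing readout of a cryptic-3'ss locus
such as Map3k7 exon 4-5: a canonical template, a non-canonical template
carrying the included intronic insertion at the exon junction, and exact
diagnostic k-mers spanning each isoform's junction. Reads matching exactly
one diagnostic string (in either orientation) are assigned to that isoform;
the misspliced fraction is non_canonical / (canonical + non_canonical).

The bundled fixtures are synthetic sequences reproducing the published
amplicon geometries — human cell lines 94 bp canonical / 114 bp
non-canonical (20 nt insertion) and murine pancreas 114 / 137 bp (23 nt
insertion); the murine sorted-cell assay shares the 94/114 geometry. The
real primer sequences are not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import reverse_complement

from .io import ConfigurationError, IntegrityError


class AssayError(ValueError):
    """Assay invariants violated (primers, insertion, diagnostics)."""


DEFAULT_K = 16
_PRIMER_LEN = 20


@dataclass(frozen=True)
class AmpliconAssay:
    """Canonical / non-canonical templates with primers and diagnostics.

    ``diagnostic_canonical`` spans the exon-exon junction of the canonical
    isoform; ``diagnostic_noncanonical`` spans the exon-intron junction
    created by the cryptic acceptor. Each must occur in its own template
    and be absent (both orientations) from the other.
    """

    name: str
    canonical_template: str
    noncanonical_template: str
    forward_primer: str
    reverse_primer: str
    diagnostic_canonical: str
    diagnostic_noncanonical: str

    def __post_init__(self) -> None:
        for label, template in (
            ("canonical", self.canonical_template),
            ("noncanonical", self.noncanonical_template),
        ):
            for pname, primer in (
                ("forward", self.forward_primer),
                ("reverse", reverse_complement(self.reverse_primer)),
            ):
                n = template.count(primer)
                if n != 1:
                    raise AssayError(
                        f"{self.name}: {pname} primer occurs {n} times in the "
                        f"{label} template (must be exactly once)"
                    )
        if self.insertion_length <= 0:
            raise AssayError(
                f"{self.name}: non-canonical template must be longer than the "
                f"canonical one (insertion length {self.insertion_length})"
            )
        for diag, own, other in (
            (self.diagnostic_canonical, self.canonical_template, self.noncanonical_template),
            (self.diagnostic_noncanonical, self.noncanonical_template, self.canonical_template),
        ):
            if diag not in own:
                raise AssayError(f"{self.name}: diagnostic {diag} absent from its template")
            if diag in other or reverse_complement(diag) in other:
                raise AssayError(
                    f"{self.name}: diagnostic {diag} is not unique to its isoform"
                )

    @property
    def insertion_length(self) -> int:
        return len(self.noncanonical_template) - len(self.canonical_template)


def predict_amplicons(assay: AmpliconAssay) -> tuple[int, int]:
    """Amplicon lengths (canonical, non-canonical) in bp.

    Measured from the forward primer's 5' end to the reverse primer's 5'
    end inclusive on each template.
    """
    lengths = []
    rc_rev = reverse_complement(assay.reverse_primer)
    for template in (assay.canonical_template, assay.noncanonical_template):
        fwd_start = template.index(assay.forward_primer)
        rev_end = template.index(rc_rev) + len(rc_rev)  # 5' end of the reverse primer
        if rev_end <= fwd_start:
            raise AssayError(f"{assay.name}: primers are not convergent")
        lengths.append(rev_end - fwd_start)
    return (lengths[0], lengths[1])


@dataclass(frozen=True)
class IsoformCallSummary:
    """Read-classification counts and the misspliced fraction."""

    canonical: int
    non_canonical: int
    unassigned: int

    def __post_init__(self) -> None:
        if min(self.canonical, self.non_canonical, self.unassigned) < 0:
            raise IntegrityError("negative read counts")

    @property
    def total(self) -> int:
        return self.canonical + self.non_canonical + self.unassigned

    @property
    def misspliced_fraction(self) -> float:
        assigned = self.canonical + self.non_canonical
        return self.non_canonical / assigned if assigned else float("nan")


def classify_reads(reads, assay: AmpliconAssay) -> IsoformCallSummary:
    """Assign each read by exact diagnostic-string matching.

    A read containing (in either orientation) exactly one isoform's
    diagnostic k-mer goes to that isoform; matching both or neither leaves
    it unassigned. No alignment and no error tolerance.
    """
    diag_c = assay.diagnostic_canonical
    diag_n = assay.diagnostic_noncanonical
    rc_c = reverse_complement(diag_c)
    rc_n = reverse_complement(diag_n)
    n_can = n_non = n_un = 0
    for read in reads:
        read = read.upper()
        hit_c = diag_c in read or rc_c in read
        hit_n = diag_n in read or rc_n in read
        if hit_c and not hit_n:
            n_can += 1
        elif hit_n and not hit_c:
            n_non += 1
        else:
            n_un += 1
    return IsoformCallSummary(canonical=n_can, non_canonical=n_non, unassigned=n_un)


def simulate_amplicon_reads(
    assay: AmpliconAssay,
    n_reads: int,
    noncanonical_fraction: float,
    seed: int = 0,
) -> list[str]:
    """Error-free synthetic amplicon reads at a true isoform mixture.

    Each read is a full-length template copy in random orientation, i.e.
    the merged-pair readout of an error-free sequencing run.
    """
    if not 0 <= noncanonical_fraction <= 1:
        raise ConfigurationError("noncanonical_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    is_non = rng.random(n_reads) < noncanonical_fraction
    flip = rng.random(n_reads) < 0.5
    reads = []
    for non, fl in zip(is_non, flip):
        t = assay.noncanonical_template if non else assay.canonical_template
        reads.append(reverse_complement(t) if fl else t)
    return reads


# ---------------------------------------------------------------------------
# synthetic fixtures with the published amplicon geometries
# ---------------------------------------------------------------------------


def build_assay(
    name: str,
    canonical_length: int,
    insertion_length: int,
    seed: int,
    k: int = DEFAULT_K,
    primer_length: int = _PRIMER_LEN,
) -> AmpliconAssay:
    """Construct a synthetic two-isoform assay with the given geometry.

    The canonical template *is* the amplicon (primers at its ends); the
    exon junction sits mid-amplicon and the non-canonical template inserts
    ``insertion_length`` intronic bases there, preceded by the acceptor AG.
    Sequences are drawn deterministically from ``seed`` and redrawn until
    all assay invariants (unique primers, isoform-specific diagnostics)
    hold.
    """
    if canonical_length < 2 * primer_length + k:
        raise AssayError("canonical amplicon too short for primers and diagnostics")
    if insertion_length < 3:
        raise AssayError("insertion must be >= 3 nt (cryptic AG plus included sequence)")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    half = k // 2
    junction = canonical_length // 2
    for _ in range(100):
        exon_up = rng.choice(bases, size=junction).tobytes().decode()
        exon_down = rng.choice(bases, size=canonical_length - junction).tobytes().decode()
        insertion = rng.choice(bases, size=insertion_length).tobytes().decode()
        insertion = insertion[:-2] + "AG"  # cryptic acceptor AG at the 3' end
        canonical = exon_up + exon_down
        noncanonical = exon_up + insertion + exon_down
        try:
            return AmpliconAssay(
                name=name,
                canonical_template=canonical,
                noncanonical_template=noncanonical,
                forward_primer=canonical[:primer_length],
                reverse_primer=reverse_complement(canonical[-primer_length:]),
                diagnostic_canonical=exon_up[-half:] + exon_down[:half],
                diagnostic_noncanonical=exon_up[-half:] + insertion[:half],
            )
        except AssayError:
            continue
    raise AssayError(f"{name}: could not build a valid assay in 100 attempts")


def human_cell_line_fixture() -> AmpliconAssay:
    """94 bp canonical / 114 bp non-canonical (20 nt insertion) geometry."""
    return build_assay("MAP3K7_human_like", canonical_length=94, insertion_length=20, seed=2718)


def murine_pancreas_fixture() -> AmpliconAssay:
    """114 bp canonical / 137 bp non-canonical (23 nt insertion) geometry."""
    return build_assay("Map3k7_murine_like", canonical_length=114, insertion_length=23, seed=3141)
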