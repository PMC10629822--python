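"""Synthetic cohorts carrying an SF3B1-mutant cryptic-3'ss signature.

The generator emulates the statistical structure of a two-genotype
junction-count study: a small cohort (default 3 wild-type vs 4 mutant
replicates), mostly alternative-3'ss events whose cryptic acceptors sit a
log-normal-distributed distance (mode inside 8-14 nt) upstream of the
canonical acceptor, a weakened polypyrimidine tract and upstream adenosine
enrichment at cryptic sites, and overdispersed junction coverage with
low-coverage missingness.

Count model (the generator's own choice; standard for junction data):
per event and sample, total support is negative binomial with configurable
mean and dispersion, and cryptic-junction reads are binomial within it at
the sample's true PSI. A truth table records every planted event.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .io import (
    ConfigurationError,
    GeneModel,
    SampleRecord,
    SampleSheet,
    SpliceJunction,
    write_annotation,
    write_fasta,
    write_junction_table,
    write_sample_sheet,
)
from .events import (
    AltSpliceEvent,
    a3ss_event,
    a5ss_event,
    exon_skip_event,
)
from .sites import BRANCHPOINT_WINDOW, PPT_WINDOW

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_PY = np.frombuffer(b"CT", dtype="S1")
_PU = np.frombuffer(b"AG", dtype="S1")
_MAX_DISTANCE_RETRIES = 100


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults encode the reference design: 3 WT vs 4 MUT replicates, 80%
    A3SS events among the planted classes, cryptic acceptors at log-normal
    distances with mode 11 nt, canonical/cryptic PPT pyrimidine fractions
    0.85/0.55, branchpoint-window adenosine enrichment at cryptic sites,
    and negative-binomial junction coverage (mean 50, dispersion 10).
    """

    n_genes: int = 200
    intron_length_range: tuple[int, int] = (150, 400)
    exon_length_range: tuple[int, int] = (80, 150)
    n_wt: int = 3
    n_mut: int = 4
    fraction_responsive: float = 0.5
    delta_psi_effect: float = 0.3
    baseline_psi_wt: float = 0.05
    coverage_mean: float = 50.0
    coverage_dispersion: float = 10.0
    cryptic_distance_mode: int = 11
    cryptic_distance_sigma: float = 0.35
    canonical_ppt_pyrimidine_fraction: float = 0.85
    cryptic_ppt_pyrimidine_fraction: float = 0.55
    branchpoint_a_enrichment: float = 0.2
    background_event_mix: dict = field(
        default_factory=lambda: {"A5SS": 0.1, "exon_skip": 0.1}
    )
    missing_min_coverage: int = 10
    mutant_allele_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "fraction_responsive": self.fraction_responsive,
            "baseline_psi_wt": self.baseline_psi_wt,
            "canonical_ppt_pyrimidine_fraction": self.canonical_ppt_pyrimidine_fraction,
            "cryptic_ppt_pyrimidine_fraction": self.cryptic_ppt_pyrimidine_fraction,
            **{f"background_event_mix[{k}]": v for k, v in self.background_event_mix.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 <= self.delta_psi_effect < 1.0:
            raise ConfigurationError("delta_psi_effect must be in [0, 1)")
        if self.n_wt < 2 or self.n_mut < 2:
            raise ConfigurationError("n_wt and n_mut must both be >= 2")
        if self.delta_psi_effect + self.baseline_psi_wt > 1.0:
            raise ConfigurationError("delta_psi_effect + baseline_psi_wt must be <= 1")
        if not 8 <= self.cryptic_distance_mode <= 14:
            raise ConfigurationError("cryptic_distance_mode must lie in [8, 14]")
        if sum(self.background_event_mix.values()) >= 1.0:
            raise ConfigurationError("background_event_mix proportions must sum to < 1")
        if self.mutant_allele_fraction is not None and not 0 < self.mutant_allele_fraction <= 1:
            raise ConfigurationError("mutant_allele_fraction must be in (0, 1] or None")
        self.intron_length_range = tuple(self.intron_length_range)
        self.exon_length_range = tuple(self.exon_length_range)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["intron_length_range"] = list(self.intron_length_range)
        d["exon_length_range"] = list(self.exon_length_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted event."""

    event_id: str
    gene_id: str
    event_type: str
    cryptic_distance: int | None
    true_delta_psi: float
    responsive: bool

    def __post_init__(self) -> None:
        if not self.responsive and self.true_delta_psi != 0.0:
            raise ConfigurationError(f"{self.event_id}: non-responsive event with effect")


@dataclass
class SimulatedGenome:
    """Reference, annotation, truth and the planted event objects."""

    genome: dict[str, str]
    genes: list[GeneModel]
    truth: list[TruthRecord]
    events: list[AltSpliceEvent]

    @property
    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {t.event_id: t for t in self.truth}


class SizingError(ConfigurationError):
    """Intron too short to host the sampled cryptic geometry."""


def sample_cryptic_distance(
    rng: np.random.Generator, mode: int, sigma: float, max_distance: int | None = None
) -> int:
    """Discretized log-normal cryptic distance, truncated at >= 3 nt.

    The underlying normal has ``mu = ln(mode) + sigma^2`` so that the
    continuous density peaks at ``mode``. Resamples (bounded) when the draw
    exceeds ``max_distance``; raises :class:`SizingError` on exhaustion.
    """
    mu = math.log(mode) + sigma**2
    for _ in range(_MAX_DISTANCE_RETRIES):
        d = int(round(math.exp(rng.normal(mu, sigma))))
        if d < 3:
            continue
        if max_distance is None or d <= max_distance:
            return d
    raise SizingError(
        f"could not place a cryptic acceptor within {max_distance} nt "
        f"after {_MAX_DISTANCE_RETRIES} draws"
    )


def _paint_exact_pyrimidine(
    seq: np.ndarray,
    locked: np.ndarray,
    window: tuple[int, int],
    target_fraction: float,
    rng: np.random.Generator,
) -> None:
    """Paint a window so its realized pyrimidine fraction tracks the target.

    ``window`` is a 0-based half-open slice. Locked positions (splice-site
    dinucleotides, previously painted windows) keep their bases; the free
    positions are set so the whole window's C/T count is as close as
    possible to ``round(target * width)``.
    """
    lo, hi = window
    idx = np.arange(lo, hi)
    free = idx[~locked[lo:hi]]
    width = hi - lo
    locked_py = int(np.isin(seq[idx[locked[lo:hi]]], _PY).sum())
    desired = int(round(target_fraction * width))
    n_py = int(np.clip(desired - locked_py, 0, free.size))
    py_pos = rng.permutation(free)[:n_py]
    pu_pos = np.setdiff1d(free, py_pos)
    seq[py_pos] = rng.choice(_PY, size=py_pos.size)
    seq[pu_pos] = rng.choice(_PU, size=pu_pos.size)
    locked[lo:hi] = True


def _paint_a_enriched(
    seq: np.ndarray,
    locked: np.ndarray,
    window: tuple[int, int],
    enrichment: float,
    rng: np.random.Generator,
) -> None:
    """Adenosine-enriched fill of the still-free positions of a window."""
    lo, hi = window
    idx = np.arange(lo, hi)
    free = idx[~locked[lo:hi]]
    p_a = min(0.9, 0.25 + enrichment)
    rest = (1.0 - p_a) / 3.0
    seq[free] = rng.choice(_BASES, size=free.size, p=[p_a, rest, rest, 1 - p_a - 2 * rest])
    locked[lo:hi] = True


def _window_slice(site_1based: int, window: tuple[int, int]) -> tuple[int, int]:
    """0-based half-open slice of an offset window at a transcript-sense 3'ss.

    Offset -k maps to 1-based position ``site - k + 1`` (no offset 0).
    """
    lo, hi = window
    start = site_1based + lo if lo < 0 else site_1based + lo - 1
    end = site_1based + hi if hi < 0 else site_1based + hi - 1
    return (start, end + 1)


@dataclass
class _GenePlan:
    gene_id: str
    chrom: str
    strand: str
    event_type: str
    responsive: bool
    distance: int | None  # A3SS cryptic distance; A5SS donor shift


def _assign_gene_plans(config: SimulationConfig, rng: np.random.Generator) -> list[_GenePlan]:
    n = config.n_genes
    n_a5 = int(round(config.background_event_mix.get("A5SS", 0.0) * n))
    n_es = int(round(config.background_event_mix.get("exon_skip", 0.0) * n))
    n_a3 = n - n_a5 - n_es
    n_resp = int(round(config.fraction_responsive * n_a3))
    plans = []
    for i in range(n):
        if i < n_a3:
            etype, responsive = "A3SS", i < n_resp
        elif i < n_a3 + n_a5:
            etype, responsive = "A5SS", False
        else:
            etype, responsive = "exon_skip", False
        plans.append(
            _GenePlan(
                gene_id=f"gene{i:04d}",
                chrom=f"ctg{i:04d}",
                strand=str(rng.choice(["+", "-"])),
                event_type=etype,
                responsive=responsive,
                distance=None,
            )
        )
    return plans


def _build_intron(
    length: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    cryptic_distance: int | None,
    cryptic_signature: bool,
) -> np.ndarray:
    """Transcript-sense intron sequence with donor GT, acceptor AG, painted
    canonical PPT and (optionally) a cryptic acceptor with its signature."""
    seq = rng.choice(_BASES, size=length)
    locked = np.zeros(length, dtype=bool)
    seq[0:2] = np.frombuffer(b"GT", dtype="S1")
    locked[0:2] = True
    a = length  # canonical acceptor, 1-based within the intron
    seq[a - 2 : a] = np.frombuffer(b"AG", dtype="S1")
    locked[a - 2 : a] = True

    c = None
    if cryptic_distance is not None:
        c = a - cryptic_distance
        if c - 40 < 2:
            raise SizingError(
                f"intron of {length} nt cannot host cryptic distance {cryptic_distance}"
            )
        seq[c - 2 : c] = np.frombuffer(b"AG", dtype="S1")
        locked[c - 2 : c] = True

    _paint_exact_pyrimidine(
        seq, locked, _window_slice(a, PPT_WINDOW),
        float(np.clip(rng.normal(config.canonical_ppt_pyrimidine_fraction, 0.02), 0.05, 0.98)),
        rng,
    )
    if c is not None and cryptic_signature:
        _paint_exact_pyrimidine(
            seq, locked, _window_slice(c, PPT_WINDOW),
            float(np.clip(rng.normal(config.cryptic_ppt_pyrimidine_fraction, 0.02), 0.05, 0.98)),
            rng,
        )
        _paint_a_enriched(
            seq, locked, _window_slice(c, BRANCHPOINT_WINDOW),
            config.branchpoint_a_enrichment, rng,
        )
    return seq


_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp_bytes(arr: np.ndarray) -> np.ndarray:
    return np.frombuffer(arr.tobytes().translate(_COMPLEMENT), dtype="S1")[::-1].copy()


def simulate_genome(config: SimulationConfig, seed: int | None = None) -> SimulatedGenome:
    """Generate the toy reference, annotation, truth table and event set.

    Every gene hosts exactly one planted event on its own contig. All A3SS
    genes carry a cryptic AG at the sampled distance upstream of the
    canonical acceptor; only responsive genes get the weak-PPT /
    branchpoint-adenosine signature around it. Deterministic given
    (config, seed).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    plans = _assign_gene_plans(config, rng)

    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    truth: list[TruthRecord] = []
    events: list[AltSpliceEvent] = []
    flank = 30

    for plan in plans:
        e_lo, e_hi = config.exon_length_range
        i_lo, i_hi = config.intron_length_range
        exon_lens = [int(rng.integers(e_lo, e_hi + 1)) for _ in range(3)]
        intron_lens = [int(rng.integers(i_lo, i_hi + 1)) for _ in range(2)]

        if plan.event_type == "exon_skip":
            n_exons = 3
        else:
            n_exons = 2
        exon_lens = exon_lens[:n_exons]
        intron_lens = intron_lens[: n_exons - 1]

        d = None
        shift = None
        if plan.event_type == "A3SS":
            d = sample_cryptic_distance(
                rng, config.cryptic_distance_mode, config.cryptic_distance_sigma,
                max_distance=intron_lens[0] - 42,
            )
            plan.distance = d
        elif plan.event_type == "A5SS":
            shift = int(rng.integers(6, 31))
            plan.distance = shift

        # transcript-sense assembly
        parts = [rng.choice(_BASES, size=flank)]
        exon_starts_ts: list[int] = []
        pos = flank
        intron_spans_ts: list[tuple[int, int]] = []
        for k, elen in enumerate(exon_lens):
            exon_starts_ts.append(pos + 1)
            parts.append(rng.choice(_BASES, size=elen))
            pos += elen
            if k < len(intron_lens):
                ilen = intron_lens[k]
                intron = _build_intron(
                    ilen, config, rng,
                    cryptic_distance=d if (plan.event_type == "A3SS" and k == 0) else None,
                    cryptic_signature=plan.responsive,
                )
                if plan.event_type == "A5SS" and k == 0:
                    # unannotated downstream-shifted donor GT inside the intron
                    intron[shift : shift + 2] = np.frombuffer(b"GT", dtype="S1")
                intron_spans_ts.append((pos + 1, pos + ilen))
                parts.append(intron)
                pos += ilen
        parts.append(rng.choice(_BASES, size=flank))
        pos += flank
        seq_ts = np.concatenate(parts)
        total = pos

        exons_ts = [
            (start, start + elen - 1) for start, elen in zip(exon_starts_ts, exon_lens)
        ]

        if plan.strand == "+":
            genome[plan.chrom] = seq_ts.tobytes().decode()
            to_genomic = lambda iv: iv  # noqa: E731
        else:
            genome[plan.chrom] = _revcomp_bytes(seq_ts).tobytes().decode()
            to_genomic = lambda iv: (total - iv[1] + 1, total - iv[0] + 1)  # noqa: E731

        exons_g = tuple(sorted(to_genomic(iv) for iv in exons_ts))
        model = GeneModel(
            gene_id=plan.gene_id,
            transcript_id=f"{plan.gene_id}.t1",
            chrom=plan.chrom,
            strand=plan.strand,
            exons=exons_g,
            cds=exons_g,
        )
        genes.append(model)

        introns_g = [tuple(sorted(to_genomic(iv))) for iv in intron_spans_ts]
        if plan.event_type == "A3SS":
            intron_g = introns_g[0]
            donor = model.donor_of(intron_g)
            canonical = model.acceptor_of(intron_g)
            alternative = canonical - d if plan.strand == "+" else canonical + d
            ev = a3ss_event(
                plan.gene_id, plan.chrom, plan.strand, donor, canonical, alternative
            )
        elif plan.event_type == "A5SS":
            intron_g = introns_g[0]
            acceptor = model.acceptor_of(intron_g)
            canonical = model.donor_of(intron_g)
            alternative = canonical + shift if plan.strand == "+" else canonical - shift
            ev = a5ss_event(
                plan.gene_id, plan.chrom, plan.strand, acceptor, canonical, alternative
            )
        else:
            left, right = sorted(introns_g)
            ev = exon_skip_event(
                plan.gene_id, plan.chrom, plan.strand, left, right, model.exons[1]
            )
        events.append(ev)
        truth.append(
            TruthRecord(
                event_id=ev.event_id,
                gene_id=plan.gene_id,
                event_type=plan.event_type,
                cryptic_distance=d if plan.event_type == "A3SS" else None,
                true_delta_psi=config.delta_psi_effect if plan.responsive else 0.0,
                responsive=plan.responsive,
            )
        )
    return SimulatedGenome(genome=genome, genes=genes, truth=truth, events=events)


# ---------------------------------------------------------------------------
# junction counts
# ---------------------------------------------------------------------------


def _negative_binomial(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """NB draws parameterized by mean m and dispersion theta
    (variance m + m^2/theta)."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_junction_counts(
    sim: SimulatedGenome, config: SimulationConfig, seed: int | None = None
) -> tuple[list[SpliceJunction], SampleSheet]:
    """Draw per-sample junction read counts for every planted event.

    WT samples splice at ``baseline_psi_wt``; MUT samples at baseline plus
    the event's true ΔPSI (scaled by ``mutant_allele_fraction`` when that
    partial-penetrance knob is set). Zero-count junction records are not
    emitted, so low negative-binomial draws become missing PSI downstream.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    sample_ids = [f"WT_{i + 1}" for i in range(config.n_wt)] + [
        f"MUT_{i + 1}" for i in range(config.n_mut)
    ]
    groups = ["WT"] * config.n_wt + ["MUT"] * config.n_mut
    truth_by_id = sim.truth_by_id
    scale = config.mutant_allele_fraction or 1.0

    junctions: list[SpliceJunction] = []
    for ev in sim.events:
        t = truth_by_id[ev.event_id]
        for sid, group in zip(sample_ids, groups):
            psi_true = config.baseline_psi_wt
            if group == "MUT":
                psi_true += t.true_delta_psi * scale
            n = int(_negative_binomial(rng, config.coverage_mean, config.coverage_dispersion, 1)[0])
            alt = int(rng.binomial(n, psi_true)) if n > 0 else 0
            canonical = n - alt
            emitted = [(iv, alt) for iv in ev.alt_introns]
            emitted += [(iv, canonical) for iv in ev.canonical_introns]
            for (start, end), reads in emitted:
                if reads > 0:
                    junctions.append(
                        SpliceJunction(
                            chrom=ev.chrom,
                            intron_start=start,
                            intron_end=end,
                            strand=ev.strand,
                            unique_reads=reads,
                            sample_id=sid,
                        )
                    )
    sheet = SampleSheet(
        samples=tuple(
            SampleRecord(sid, group, f"junctions/{sid}.tsv")
            for sid, group in zip(sample_ids, groups)
        )
    )
    return junctions, sheet


# ---------------------------------------------------------------------------
# cohort bundle
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """A fully simulated cohort ready to analyse or write to disk."""

    config: SimulationConfig
    sim: SimulatedGenome
    junctions: list[SpliceJunction]
    sample_sheet: SampleSheet


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """Genome + annotation + counts in one call, deterministic in seed."""
    sim = simulate_genome(config, seed)
    junctions, sheet = simulate_junction_counts(sim, config, seed)
    return Cohort(config=config, sim=sim, junctions=junctions, sample_sheet=sheet)


def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(t) for t in truth])
    return df.set_index("event_id")


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="event_id", na_values=["NA"], keep_default_na=False)
    df["responsive"] = df["responsive"].astype(bool)
    return df


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write FASTA, GTF, per-sample junction tables, sample sheet, truth
    table and the generating config; everything re-readable by the readers
    in :mod:`crypticsplice.io`."""
    directory = Path(directory)
    (directory / "junctions").mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": directory / "genome.fa",
        "annotation": directory / "annotation.gtf",
        "sample_sheet": directory / "sample_sheet.tsv",
        "truth": directory / "truth.tsv",
        "config": directory / "sim_config.yaml",
    }
    write_fasta(cohort.sim.genome, paths["genome"])
    write_annotation(cohort.sim.genes, paths["annotation"])
    write_sample_sheet(cohort.sample_sheet, paths["sample_sheet"])
    truth_to_frame(cohort.sim.truth).to_csv(paths["truth"], sep="\t", na_rep="NA")
    cohort.config.to_yaml(paths["config"])
    by_sample: dict[str, list[SpliceJunction]] = {
        s.sample_id: [] for s in cohort.sample_sheet.samples
    }
    for j in cohort.junctions:
        by_sample[j.sample_id].append(j)
    for s in cohort.sample_sheet.samples:
        path = directory / s.path
        write_junction_table(by_sample[s.sample_id], path)
        paths[f"junctions/{s.sample_id}"] = path
    return paths
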