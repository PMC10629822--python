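import numpy as np
import pytest

from crypticsplice import (
    ConfigurationError,
    SimulationConfig,
    build_psi_matrix,
    compute_psi,
    counts_by_sample,
    ppt_score,
    read_junction_table,
    sample_cryptic_distance,
    simulate_cohort,
    simulate_genome,
    simulate_junction_counts,
    write_cohort,
)
from crypticsplice.sites import PPT_WINDOW, extract_window


def test_defaults_encode_reference_design():
    cfg = SimulationConfig()
    assert (cfg.n_wt, cfg.n_mut) == (3, 4)
    assert 8 <= cfg.cryptic_distance_mode <= 14


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_wt": 1},
        {"delta_psi_effect": 1.2},
        {"baseline_psi_wt": 0.9, "delta_psi_effect": 0.3},
        {"cryptic_distance_mode": 25},
        {"fraction_responsive": -0.1},
        {"background_event_mix": {"A5SS": 0.6, "exon_skip": 0.5}},
        {"mutant_allele_fraction": 0.0},
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ConfigurationError):
        SimulationConfig(**kwargs)


def test_genome_is_deterministic(tmp_path):
    cfg = SimulationConfig(n_genes=12)
    a = write_cohort(simulate_cohort(cfg, 3), tmp_path / "a")
    b = write_cohort(simulate_cohort(cfg, 3), tmp_path / "b")
    for key in ("genome", "annotation", "truth"):
        assert a[key].read_bytes() == b[key].read_bytes()


def test_two_seeds_differ_but_share_schema(tmp_path):
    cfg = SimulationConfig(n_genes=12)
    a = write_cohort(simulate_cohort(cfg, 1), tmp_path / "a")
    b = write_cohort(simulate_cohort(cfg, 2), tmp_path / "b")
    assert a["genome"].read_bytes() != b["genome"].read_bytes()
    assert sorted(p.name for p in a.values()) == sorted(p.name for p in b.values())


def test_no_responsive_records_when_fraction_zero():
    sim = simulate_genome(SimulationConfig(n_genes=10, fraction_responsive=0.0), 1)
    assert not any(t.responsive for t in sim.truth)
    assert all(t.true_delta_psi == 0.0 for t in sim.truth)


def test_distance_mode_within_configured_range():
    """Monte-Carlo check of the generator's own distance distribution."""
    rng = np.random.default_rng(0)
    ds = [sample_cryptic_distance(rng, 11, 0.35) for _ in range(2000)]
    assert min(ds) >= 3
    values, counts = np.unique(ds, return_counts=True)
    assert 8 <= values[np.argmax(counts)] <= 14


def test_default_cohort_has_seven_junction_tables(cohort_dir, small_cohort):
    tables = sorted((cohort_dir / "junctions").glob("*.tsv"))
    assert len(tables) == 7  # 3 WT + 4 MUT replicates
    assert len(small_cohort.sample_sheet.group_ids("WT")) == 3
    assert len(small_cohort.sample_sheet.group_ids("MUT")) == 4


def test_written_counts_round_trip(cohort_dir, small_cohort):
    for s in small_cohort.sample_sheet.samples:
        back = read_junction_table(cohort_dir / s.path, sample_id=s.sample_id)
        original = [j for j in small_cohort.junctions if j.sample_id == s.sample_id]
        assert sorted(back, key=repr) == sorted(original, key=repr)


def test_null_effect_gives_balanced_groups():
    cfg = SimulationConfig(n_genes=60, fraction_responsive=0.0, coverage_mean=200,
                           background_event_mix={"A5SS": 0.0, "exon_skip": 0.0})
    cohort = simulate_cohort(cfg, 4)
    m = build_psi_matrix(
        cohort.sim.events, cohort.junctions, cohort.sample_sheet.sample_ids
    )
    wt = m.psi[cohort.sample_sheet.group_ids("WT")].mean(axis=1)
    mut = m.psi[cohort.sample_sheet.group_ids("MUT")].mean(axis=1)
    assert abs((mut - wt).mean()) < 0.01


def test_zero_coverage_means_all_missing():
    cfg = SimulationConfig(n_genes=5, coverage_mean=0.0)
    cohort = simulate_cohort(cfg, 1)
    assert cohort.junctions == []
    counts = counts_by_sample(cohort.junctions)
    for e in cohort.sim.events:
        psi, total = compute_psi(e, counts.get("WT_1", {}), min_coverage=10)
        assert psi is None and total == 0


def test_psi_converges_to_truth_at_high_coverage():
    """Generator self-consistency: empirical PSI -> configured psi_true."""
    cfg = SimulationConfig(
        n_genes=60, coverage_mean=1e4, coverage_dispersion=50.0,
        baseline_psi_wt=0.05, delta_psi_effect=0.3, fraction_responsive=1.0,
        background_event_mix={"A5SS": 0.0, "exon_skip": 0.0},
    )
    cohort = simulate_cohort(cfg, 9)
    m = build_psi_matrix(
        cohort.sim.events, cohort.junctions, cohort.sample_sheet.sample_ids
    )
    wt_mean = m.psi[cohort.sample_sheet.group_ids("WT")].mean().mean()
    mut_mean = m.psi[cohort.sample_sheet.group_ids("MUT")].mean().mean()
    assert abs(wt_mean - 0.05) < 0.005
    assert abs(mut_mean - 0.35) < 0.005


def test_mut_mean_psi_matches_binomial_expectation():
    """baseline 0.02 + effect 0.30 at coverage 100, 8v8, 500 responsive."""
    cfg = SimulationConfig(
        n_genes=500, n_wt=8, n_mut=8, coverage_mean=100,
        baseline_psi_wt=0.02, delta_psi_effect=0.30, fraction_responsive=1.0,
        background_event_mix={"A5SS": 0.0, "exon_skip": 0.0},
    )
    cohort = simulate_cohort(cfg, 2)
    m = build_psi_matrix(
        cohort.sim.events, cohort.junctions, cohort.sample_sheet.sample_ids
    )
    mut_mean = m.psi[cohort.sample_sheet.group_ids("MUT")].mean().mean()
    assert abs(mut_mean - 0.32) < 0.02


def test_partial_penetrance_attenuates_counts_not_truth():
    cfg = SimulationConfig(
        n_genes=80, coverage_mean=2000, fraction_responsive=1.0,
        mutant_allele_fraction=0.5,
        background_event_mix={"A5SS": 0.0, "exon_skip": 0.0},
    )
    cohort = simulate_cohort(cfg, 6)
    assert all(t.true_delta_psi == cfg.delta_psi_effect for t in cohort.sim.truth)
    m = build_psi_matrix(
        cohort.sim.events, cohort.junctions, cohort.sample_sheet.sample_ids
    )
    mut_mean = m.psi[cohort.sample_sheet.group_ids("MUT")].mean().mean()
    assert abs(mut_mean - (0.05 + 0.5 * 0.3)) < 0.01


def test_ppt_signature_in_generated_sequence(small_cohort):
    """Realized pyrimidine fractions track the configured canonical/cryptic
    targets whenever cryptic < canonical is configured."""
    genome = small_cohort.sim.genome
    truth = small_cohort.sim.truth_by_id
    can, cry = [], []
    for e in small_cohort.sim.events:
        t = truth[e.event_id]
        if e.event_type != "A3SS" or not t.responsive:
            continue
        can.append(ppt_score(extract_window(genome, e.chrom, e.canonical, e.strand, PPT_WINDOW)))
        cry.append(ppt_score(extract_window(genome, e.chrom, e.alternative, e.strand, PPT_WINDOW)))
    assert np.mean(cry) < np.mean(can)
    assert abs(np.mean(can) - 0.85) < 0.05
    assert abs(np.mean(cry) - 0.55) < 0.08


def test_every_intron_ends_in_ag(small_cohort):
    genome = small_cohort.sim.genome
    for g in small_cohort.sim.genes:
        for intron in g.introns:
            acceptor = g.acceptor_of(intron)
            window = extract_window(genome, g.chrom, acceptor, g.strand, (-2, -1))
            assert window == "AG"
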