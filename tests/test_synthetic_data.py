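"""Codon-alignment simulator and gene-set generator."""

import numpy as np
import pytest
from scipy import stats

from caverelax.codon_evolution import (
    BRANCH_NAMES,
    CODON_INDEX,
    N_SENSE,
    STOP_CODONS,
    ka_ks_ng86,
    ng86_branch_estimates,
)
from caverelax.synthetic_data import (
    MixedBranchScenario,
    SimulationConfig,
    default_regimes,
    generate_gene_sets,
    simulate_codon_alignment,
    simulate_mixed_branch_alignment,
)
from caverelax.codon_evolution import branch_length_from_time


def _config(n_codons=200, seed=0, omegas=None, lengths=None, **kw):
    return SimulationConfig(
        n_codons=n_codons,
        branch_omegas=omegas or {"cave": 0.5, "surface": 0.2, "outgroup": 1.0},
        branch_lengths=lengths or {"cave": 0.1, "surface": 0.1, "outgroup": 0.5},
        seed=seed,
        **kw,
    )


def test_identical_config_and_seed_give_identical_output():
    a = simulate_codon_alignment(_config(seed=42))
    b = simulate_codon_alignment(_config(seed=42))
    assert a.sites == b.sites
    c = simulate_codon_alignment(_config(seed=43))
    assert c.sites != a.sites


def test_simulated_alignments_contain_no_stops_or_gaps():
    aln = simulate_codon_alignment(_config(n_codons=500, seed=3))
    for taxon in aln.taxa:
        seq = aln.sequence(taxon)
        assert len(seq) == 1500
        assert set(seq) <= set("ACGT")
        for k in range(0, len(seq), 3):
            assert seq[k : k + 3] not in STOP_CODONS


def test_zero_codons_yield_empty_alignment():
    aln = simulate_codon_alignment(_config(n_codons=0))
    assert aln.n_codons == 0
    assert all(aln.sequence(t) == "" for t in aln.taxa)


def test_zero_branch_lengths_give_identical_sequences_from_freqs():
    cfg = _config(
        n_codons=50_000,
        seed=17,
        lengths={b: 0.0 for b in BRANCH_NAMES},
    )
    aln = simulate_codon_alignment(cfg)
    seqs = {t: aln.sequence(t) for t in aln.taxa}
    assert len(set(seqs.values())) == 1
    # empirical codon distribution consistent with the configured freqs
    counts = np.bincount(
        [CODON_INDEX[seqs["cave"][k : k + 3]] for k in range(0, len(seqs["cave"]), 3)],
        minlength=N_SENSE,
    )
    expected = cfg.codon_freqs * cfg.n_codons
    chi2 = ((counts - expected) ** 2 / expected).sum()
    p = stats.chi2.sf(chi2, df=N_SENSE - 1)
    assert p > 0.01


def test_unknown_branch_name_rejected():
    with pytest.raises(ValueError, match="unknown branch"):
        SimulationConfig(
            n_codons=10,
            branch_omegas={"cave": 1.0, "surface": 1.0, "root": 1.0},
            branch_lengths={"cave": 0.1, "surface": 0.1, "root": 0.1},
        )


def test_codon_freqs_must_sum_to_one():
    with pytest.raises(ValueError, match="sum to 1"):
        _config(codon_freqs=np.full(N_SENSE, 0.9 / N_SENSE))


def test_neutral_regime_pairwise_ng86_omega_near_one():
    # all branches neutral: every branch-spanning pair should estimate ω ≈ 1
    for seed in range(1, 6):
        cfg = _config(
            n_codons=20_000,
            seed=seed,
            omegas={b: 1.0 for b in BRANCH_NAMES},
            lengths={b: 0.25 for b in BRANCH_NAMES},
            kappa=1.0,  # NG86 site counting assumes no transition bias
        )
        aln = simulate_codon_alignment(cfg)
        est = ka_ks_ng86(aln.sequence("cave"), aln.sequence("surface"))
        assert 0.9 <= est.omega <= 1.1, seed


def test_nonsynonymous_divergence_increases_with_cave_omega():
    # raising cave ω must not decrease nonsynonymous divergence (mean over seeds)
    def mean_ka(omega):
        kas = []
        for seed in range(4):
            cfg = _config(
                n_codons=3000,
                seed=seed,
                omegas={"cave": omega, "surface": 0.2, "outgroup": 0.2},
                lengths={"cave": 0.3, "surface": 0.1, "outgroup": 0.3},
            )
            aln = simulate_codon_alignment(cfg)
            kas.append(ng86_branch_estimates(aln)["cave"].ka)
        return np.mean(kas)

    values = [mean_ka(w) for w in (0.1, 0.5, 1.0)]
    assert values[0] < values[1] < values[2]


# -- mixed branch ----------------------------------------------------------


def test_degenerate_mixture_t_zero_equals_plain_simulation():
    scen = MixedBranchScenario(T=21.3, t=0.0, omega_f=0.215)
    cfg = _config(n_codons=400, seed=9, omegas={
        "cave": 0.215, "surface": 0.215, "outgroup": 0.3,
    })
    mixed = simulate_mixed_branch_alignment(scen, cfg)
    # same law: plain simulation with the cave length the clock implies
    cave_len = branch_length_from_time(
        21.3, 0.215, scen.clock_rate, cfg.kappa, cfg.codon_freqs
    )
    lengths = dict(cfg.branch_lengths, cave=cave_len)
    plain = simulate_codon_alignment(
        SimulationConfig(
            n_codons=400, seed=9,
            branch_omegas=dict(cfg.branch_omegas),
            branch_lengths=lengths,
        )
    )
    assert mixed.sites == plain.sites


def test_fully_relaxed_mixture_gives_neutral_cave_branch():
    scen = MixedBranchScenario(T=21.3, t=21.3, omega_f=0.215)
    cfg = _config(
        n_codons=20_000,
        seed=5,
        omegas={"cave": 0.215, "surface": 0.215, "outgroup": 0.3},
        lengths={"cave": 0.0, "surface": 0.11, "outgroup": 0.9},
    )
    aln = simulate_mixed_branch_alignment(scen, cfg)
    omega_cave = ng86_branch_estimates(aln)["cave"].omega
    assert omega_cave == pytest.approx(1.0, abs=0.2)


def test_invalid_scenarios_rejected():
    with pytest.raises(ValueError):
        MixedBranchScenario(T=10.0, t=11.0, omega_f=0.2)
    with pytest.raises(ValueError):
        MixedBranchScenario(T=10.0, t=1.0, omega_f=0.2, clock_rate=-1.0)
    with pytest.raises(ValueError):
        MixedBranchScenario(T=10.0, t=1.0, omega_f=0.5, omega_n=0.2)


# -- gene sets -------------------------------------------------------------


def test_gene_set_sizes_match_requested_partition():
    records = generate_gene_sets(
        21, 94, 0, regimes=default_regimes(n_codons=5), seed=1
    )
    assert len(records) == 115
    assert sum(r.label == "specific" for r in records) == 21
    assert sum(r.label == "related" for r in records) == 94
    ids = [r.gene_id for r in records]
    assert len(set(ids)) == len(ids)


def test_empty_gene_set_request_gives_empty_list():
    assert generate_gene_sets(0, 0, 0, seed=1) == []


def test_missing_regime_rejected():
    regimes = default_regimes(n_codons=5)
    regimes.pop("related")
    with pytest.raises(ValueError, match="missing regime"):
        generate_gene_sets(1, 1, 1, regimes=regimes, seed=1)


def test_gene_sets_reproducible_for_fixed_seed():
    a = generate_gene_sets(2, 2, 2, regimes=default_regimes(n_codons=20), seed=4)
    b = generate_gene_sets(2, 2, 2, regimes=default_regimes(n_codons=20), seed=4)
    assert [r.alignment.sites for r in a] == [r.alignment.sites for r in b]
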