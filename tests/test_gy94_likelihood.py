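"""GY94 rate-matrix structure and the pruning likelihood on the star tree."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.linalg import expm

from caverelax.codon_evolution import (
    BRANCH_NAMES,
    N_SENSE,
    SENSE_CODONS,
    CodonAlignment,
    GY94Params,
    TreeSpec,
    gy94_rate_matrix,
    log_likelihood,
    transition_matrix,
)


def _params(kappa=2.0, omega=0.4, freqs=None):
    rng = np.random.default_rng(5)
    if freqs is None:
        freqs = np.full(N_SENSE, 1.0 / N_SENSE)
    return GY94Params(kappa=kappa, omegas={"w": omega}, codon_freqs=freqs)


def _random_freqs(rng):
    f = rng.dirichlet(np.full(N_SENSE, 5.0))
    return f / f.sum()


def test_uniform_neutral_matrix_has_equal_permitted_entries():
    Q = gy94_rate_matrix(_params(kappa=1.0, omega=1.0), "w")
    off = Q[~np.eye(N_SENSE, dtype=bool)]
    permitted = off[off > 0]
    assert permitted.size > 0
    assert np.allclose(permitted, permitted[0])


def test_rows_sum_to_zero_and_mean_rate_is_one():
    rng = np.random.default_rng(7)
    for _ in range(5):
        pi = _random_freqs(rng)
        params = GY94Params(
            kappa=rng.uniform(0.5, 10),
            omegas={"w": rng.uniform(0.05, 3)},
            codon_freqs=pi,
        )
        Q = gy94_rate_matrix(params, "w")
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert pi @ (-np.diag(Q)) == pytest.approx(1.0, abs=1e-10)


def test_detailed_balance_under_random_parameters():
    rng = np.random.default_rng(13)
    for _ in range(5):
        pi = _random_freqs(rng)
        params = GY94Params(
            kappa=rng.uniform(0.5, 10),
            omegas={"w": rng.uniform(0.05, 3)},
            codon_freqs=pi,
        )
        Q = gy94_rate_matrix(params, "w")
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)


@pytest.mark.parametrize("t", [0.0, 0.01, 0.5, 2.0, 10.0])
def test_transition_matrices_are_stochastic(t):
    params = _params(omega=0.3)
    Q = gy94_rate_matrix(params, "w")
    P = transition_matrix(Q, t, params.codon_freqs)
    assert np.all(P >= 0.0)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)


def test_transition_matrix_agrees_with_scipy_expm():
    params = _params(kappa=3.3, omega=0.7)
    Q = gy94_rate_matrix(params, "w")
    P = transition_matrix(Q, 0.37, params.codon_freqs)
    assert np.allclose(P, expm(Q * 0.37), atol=1e-10)


def _alignment_from_indices(idx):
    sites = tuple(
        tuple(SENSE_CODONS[idx[t, k]] for t in range(3))
        for k in range(idx.shape[1])
    )
    return CodonAlignment(taxa=BRANCH_NAMES, sites=sites)


def brute_force_lnl(alignment, tree, params):
    """Sum over all 61 internal-node states per site, no pruning, no reuse.

    Transition matrices via scipy expm on a naively rebuilt generator
    (Biopython translation, explicit python loops).
    """
    pi = np.asarray(params.codon_freqs)
    mats = {}
    for branch in BRANCH_NAMES:
        omega = params.omegas[tree.branch_labels[branch]]
        Q = np.zeros((61, 61))
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                if i == j:
                    continue
                diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diffs) != 1:
                    continue
                rate = pi[j]
                if diffs[0] in (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")):
                    rate *= params.kappa
                if str(Seq(ci).translate()) != str(Seq(cj).translate()):
                    rate *= omega
                Q[i, j] = rate
            Q[i, i] = -Q[i].sum()
        scale = sum(pi[i] * -Q[i, i] for i in range(61))
        mats[branch] = expm(Q / scale * tree.branch_lengths[branch])
    taxa = alignment.taxa
    idx = alignment.indices()
    lnl = 0.0
    for k in range(idx.shape[1]):
        site = 0.0
        for x in range(61):
            term = pi[x]
            for b_i, branch in enumerate(BRANCH_NAMES):
                term *= mats[branch][x, idx[taxa.index(branch), k]]
            site += term
        lnl += np.log(site)
    return lnl


def test_pruning_equals_brute_force_enumeration_on_random_instances():
    rng = np.random.default_rng(99)
    for _ in range(5):
        n = int(rng.integers(1, 30))
        idx = rng.integers(0, 61, size=(3, n))
        aln = _alignment_from_indices(idx)
        tree = TreeSpec(
            branch_lengths={
                b: float(rng.uniform(0.01, 1.5)) for b in BRANCH_NAMES
            }
        )
        params = GY94Params(
            kappa=float(rng.uniform(0.5, 8)),
            omegas={b: float(rng.uniform(0.05, 2)) for b in BRANCH_NAMES},
            codon_freqs=_random_freqs(rng),
        )
        assert log_likelihood(aln, tree, params) == pytest.approx(
            brute_force_lnl(aln, tree, params), abs=1e-8
        )


def test_zero_branch_lengths_reduce_to_log_frequencies():
    rng = np.random.default_rng(3)
    pi = _random_freqs(rng)
    params = GY94Params(kappa=2.0, omegas={b: 0.5 for b in BRANCH_NAMES},
                        codon_freqs=pi)
    tree = TreeSpec(branch_lengths={b: 0.0 for b in BRANCH_NAMES})
    idx = rng.integers(0, 61, size=(1, 25)).repeat(3, axis=0)
    aln = _alignment_from_indices(idx)
    expected = sum(np.log(pi[i]) for i in idx[0])
    assert log_likelihood(aln, tree, params) == pytest.approx(expected)


def test_site_order_does_not_change_likelihood(small_alignment, star_tree):
    params = GY94Params(
        kappa=2.0,
        omegas={b: 0.5 for b in BRANCH_NAMES},
        codon_freqs=np.full(N_SENSE, 1.0 / N_SENSE),
    )
    base = log_likelihood(small_alignment, star_tree, params)
    rng = np.random.default_rng(0)
    perm = rng.permutation(small_alignment.n_codons)
    shuffled = CodonAlignment(
        taxa=small_alignment.taxa,
        sites=tuple(small_alignment.sites[i] for i in perm),
    )
    assert log_likelihood(shuffled, star_tree, params) == pytest.approx(base)
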