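"""Sequence-space sampler correctness, Landau surface, selection, profiles."""

import math

import numpy as np
import pytest
from scipy import stats

from caterpillar.design import (
    DesignTarget,
    Sequence,
    SequenceSample,
    design_run,
    hydropathy_profile,
    landau_surface,
    log_multinomial,
    mutation_step,
    select_sequences,
)
from caterpillar.energy import AA_ALPHABET, AA_INDEX, ModelParameters, total_energy
from caterpillar.fixtures import load_tables, toy_design_system


# ------------------------------------------------------------ toy machinery

def _toy_enumeration(chain, alphabet, params, lambda_het, temperature):
    """Exhaustive Boltzmann weights over every sequence of the toy system."""
    target = DesignTarget(chain, params)
    n = chain.n_res
    letters = list(alphabet)
    seqs, logw = [], []
    for code in range(len(letters) ** n):
        s, c = [], code
        for _ in range(n):
            s.append(letters[c % len(letters)])
            c //= len(letters)
        seq = Sequence("".join(s))
        e = target.total(seq.indices)
        logw.append(-e / temperature + lambda_het * log_multinomial(seq))
        seqs.append(seq.residues)
    logw = np.array(logw)
    w = np.exp(logw - logw.max())
    return seqs, w / w.sum()


# ------------------------------------------------------------- multinomial

@pytest.mark.parametrize("residues,expected", [
    ("AAAAAA", 0.0),
    ("ACDEF", math.log(120)),
    ("AAACC", math.log(10)),
])
def test_log_multinomial_examples(residues, expected):
    assert log_multinomial(Sequence(residues)) == pytest.approx(expected, abs=1e-12)


def test_log_multinomial_exact_vs_integer_factorials(rng):
    for _ in range(30):
        n = int(rng.integers(1, 11))
        seq = Sequence.random(n, rng)
        counts = seq.counts
        exact = math.factorial(n)
        for c in counts:
            exact //= math.factorial(int(c))
        assert log_multinomial(seq) == pytest.approx(math.log(exact), rel=1e-12)


def test_sequence_validation_and_counts():
    with pytest.raises(ValueError):
        Sequence("AXB")
    s = Sequence("AAC")
    assert s.counts[AA_INDEX["A"]] == 2
    assert s.counts.sum() == 3


# ---------------------------------------------------------- mutation moves

def test_mutation_step_neutral_always_accepted(params):
    chain, _ = toy_design_system()
    # uniform matrix: every mutation has dE = 0; single-letter pool of two
    # equally-counted types makes d lnNperm = 0 for A<->E swaps at balance
    p = ModelParameters(eps_matrix=np.zeros((20, 20)))
    target = DesignTarget(chain, p)
    seq = Sequence("AAAEEE")
    state = SequenceSample(seq, target.total(seq.indices),
                           log_multinomial(seq), 0, 0)
    rng = np.random.default_rng(0)
    accepted = 0
    cur = state
    for _ in range(200):
        new = mutation_step(cur, target, 1.0, 0.0, p, rng, alphabet="AE")
        accepted += new.sequence.residues != cur.sequence.residues
        cur = new
    assert accepted == 200  # lambda = 0 and dE = 0: acceptance probability 1


def test_incremental_delta_matches_full_recomputation(params, compact16, rng):
    target = DesignTarget(compact16, params, use_solvation=True)
    seq = Sequence.random(16, rng)
    idx = seq.indices
    for _ in range(1000):
        pos = int(rng.integers(16))
        new_type = int(rng.integers(20))
        if new_type == idx[pos]:
            continue
        de = target.mutation_delta(idx, pos, new_type)
        e_before = target.total(idx)
        idx2 = idx.copy()
        idx2[pos] = new_type
        e_after = target.total(idx2)
        assert de == pytest.approx(e_after - e_before, rel=1e-9, abs=1e-9)
        idx = idx2


def test_design_energy_consistent_with_total_energy(params, helix16, rng):
    target = DesignTarget(helix16, params, use_solvation=True)
    seq = Sequence.random(16, rng)
    assert target.total(seq.indices) == pytest.approx(
        total_energy(helix16, seq, params, use_solvation=True).e_total,
        rel=1e-9)


def test_design_target_rejects_overlapping_backbone(params):
    from conftest import random_chain

    rng = np.random.default_rng(2)
    for _ in range(300):
        ch = random_chain(8, rng)
        d = np.linalg.norm(ch.ca[:, None] - ch.ca[None, :], axis=-1)
        iu = np.triu_indices(8, 2)
        if d[iu].min() < params.hard_core_distance:
            with pytest.raises(ValueError, match="overlap"):
                DesignTarget(ch, params)
            return
    pytest.skip("no overlapping conformation found")


# --------------------------------------------- stationary distribution (toy)

def chi2_pvalue_vs_enumeration(sampled_seqs, seqs, p_exact):
    """Pearson chi-squared of observed sequence frequencies against the
    enumerated distribution, pooling states with expected count < 5."""
    counts = {}
    for s in sampled_seqs:
        counts[s] = counts.get(s, 0) + 1
    n_tot = sum(counts.values())
    obs, exp = [], []
    rest_o = rest_e = 0.0
    for s, pe in zip(seqs, p_exact):
        e = pe * n_tot
        o = counts.get(s, 0)
        if e >= 5:
            obs.append(o)
            exp.append(e)
        else:
            rest_o += o
            rest_e += e
    if rest_e > 0:
        obs.append(rest_o)
        exp.append(rest_e)
    obs, exp = np.array(obs, float), np.array(exp, float)
    exp *= obs.sum() / exp.sum()
    chi2 = ((obs - exp) ** 2 / exp).sum()
    return stats.chi2.sf(chi2, len(obs) - 1)


def test_toy_sampler_matches_enumeration_chi2():
    """Single-temperature design MC against exhaustive enumeration.

    Samples are thinned to ~independence before the chi-squared test (the
    test statistic assumes independent draws)."""
    chain, alphabet = toy_design_system()
    params = ModelParameters(pair_scale=1.0)  # toy: energy contrast matters
    t_design, lam = 0.5, 1.0
    seqs, p_exact = _toy_enumeration(chain, alphabet, params, lam, t_design)
    samples = design_run(chain, [t_design], 60_000, lam, params, rng=123,
                         alphabet=alphabet, sample_stride=20)
    sampled = [s.sequence.residues for s in samples[len(samples) // 10:]]
    assert chi2_pvalue_vs_enumeration(sampled, seqs, p_exact) > 0.01


def test_heterogeneity_increases_with_lambda():
    chain, alphabet = toy_design_system()
    params = ModelParameters(pair_scale=1.0)  # toy: energy contrast matters
    means = []
    for lam in (0.0, 2.0, 6.0):
        vals = []
        for seed in range(5):
            samples = design_run(chain, [0.5], 600, lam, params,
                                 rng=seed, alphabet=alphabet)
            vals.extend(s.ln_nperm for s in samples[100:])
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_replica_exchange_preserves_marginals():
    """Swap moves leave every per-temperature marginal on the enumerated
    stationary distribution (chi-squared per rung; the toy's energy levels
    are heavily degenerate, so two-sample KS on energies is not applicable).
    """
    chain, alphabet = toy_design_system()
    params = ModelParameters(pair_scale=1.0)  # toy: energy contrast matters
    lam = 1.0
    temps = [0.4, 0.8, 1.6]
    swapped = design_run(chain, temps, 40_000, lam, params, rng=5,
                         alphabet=alphabet, sample_stride=20)
    for ti, t in enumerate(temps):
        seqs, p_exact = _toy_enumeration(chain, alphabet, params, lam, t)
        sampled = [s.sequence.residues for s in swapped
                   if s.temp_index == ti and s.sweep > 4000]
        assert chi2_pvalue_vs_enumeration(sampled, seqs, p_exact) > 0.01


# ----------------------------------------------------------- Landau surface

def _mk_sample(e, lnn, seq="AAAAAA"):
    return SequenceSample(Sequence(seq), e, lnn, 0, 0)


def test_landau_single_bin():
    samples = [_mk_sample(1.0, 2.0) for _ in range(10)]
    surf = landau_surface(samples, 0.5, bins=4)
    occ = ~surf.free_energy.mask
    assert occ.sum() == 1
    assert surf.hist.sum() == pytest.approx(1.0, abs=1e-9)
    assert float(surf.free_energy[surf.argmin_bin]) == pytest.approx(0.0)


def test_landau_two_bin_ratio():
    t = 0.7
    c = 50
    samples = ([_mk_sample(0.0, 0.0)] * int(np.e**2 * c)
               + [_mk_sample(10.0, 5.0)] * c)
    surf = landau_surface(samples, t, bins=2)
    occ = np.argwhere(~surf.free_energy.mask)
    f = sorted(float(surf.free_energy[tuple(b)]) for b in occ)
    assert f[1] - f[0] == pytest.approx(2 * t, abs=1e-2)


def test_landau_matches_independent_histogram(rng):
    samples = [_mk_sample(float(e), float(l))
               for e, l in zip(rng.normal(0, 2, 500), rng.uniform(0, 9, 500))]
    surf = landau_surface(samples, 1.0, bins=8)
    h, _, _ = np.histogram2d([s.energy for s in samples],
                             [s.ln_nperm for s in samples], bins=8)
    h = h / h.sum()
    occ = h > 0
    assert np.allclose(surf.hist, h)
    assert np.allclose(surf.free_energy[occ], -np.log(h[occ]), atol=1e-12)
    with pytest.raises(ValueError):
        landau_surface([], 1.0)


def test_select_low_f_vs_low_e_contrast():
    # crafted cloud: a populous moderate-energy bin and a rare lower-energy bin
    pop = [_mk_sample(-5.0 + 0.01 * i, 6.0, "ACDEFG") for i in range(50)]
    rare = [_mk_sample(-20.0, 1.0, "AAAAAA")]
    samples = pop + rare
    surf = landau_surface(samples, 1.0, bins=5)
    low_f = select_sequences(surf, samples, 1, mode="lowF")
    low_e = select_sequences(surf, samples, 1, mode="lowE")
    assert low_f[0].sequence.residues == "ACDEFG"
    assert low_e[0].sequence.residues == "AAAAAA"
    with pytest.raises(ValueError):
        select_sequences(surf, samples, 5)  # only 2 distinct sequences


def test_select_ties_broken_by_energy_then_order():
    a = _mk_sample(-3.0, 2.0, "AAACCC")
    b = _mk_sample(-3.5, 2.0, "CCCAAA")
    samples = [a, b]
    surf = landau_surface(samples, 1.0, bins=1)
    picked = select_sequences(surf, samples, 2)
    assert picked[0].sequence.residues == "CCCAAA"  # lower E first


# ------------------------------------------------------- hydropathy profile

def test_hydropathy_profile_constant_and_mean():
    _, hyd = load_tables()
    prof = hydropathy_profile([Sequence("IIII")])
    assert np.allclose(prof[:, 1], hyd[AA_INDEX["I"]])
    assert np.array_equal(prof[:, 0], [1, 2, 3, 4])
    two = hydropathy_profile([Sequence("AI"), Sequence("VI")])
    assert two[0, 1] == pytest.approx(
        (hyd[AA_INDEX["A"]] + hyd[AA_INDEX["V"]]) / 2)


def test_hydropathy_profile_window_matches_direct(rng):
    seqs = [Sequence.random(12, rng) for _ in range(10)]
    prof = hydropathy_profile(seqs, window=3)
    raw = hydropathy_profile(seqs, window=1)[:, 1]
    for i in range(12):
        lo, hi = max(0, i - 1), min(12, i + 2)
        assert prof[i, 1] == pytest.approx(raw[lo:hi].mean(), rel=1e-12)
    with pytest.raises(ValueError):
        hydropathy_profile([Sequence("AA"), Sequence("AAA")])
    with pytest.raises(ValueError):
        hydropathy_profile(seqs, window=2)
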