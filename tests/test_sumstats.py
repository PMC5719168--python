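"""Diversity statistics and AMOVA PhiST against brute-force oracles."""

import itertools

import numpy as np
import pytest

from steppeabc import (
    Alignment,
    MutationParams,
    build_model,
    mutate,
    phi_st,
    simulate_genealogy,
    summarize,
    summary_layout,
    within_population_stats,
)
from steppeabc.demography import ParameterDraw
from steppeabc.sumstats import SumstatsError, impute_summary_table

from conftest import constant_size_draw, default_draw_values, single_region_model


# ---------------------------------------------------------------- oracles
def brute_force_pairwise_mean(seqs: list[str]) -> float:
    pairs = list(itertools.combinations(seqs, 2))
    return sum(
        sum(a != b for a, b in zip(x, y)) for x, y in pairs
    ) / len(pairs)


def brute_force_phist(seqs_a: list[str], seqs_b: list[str]) -> float:
    """Independent AMOVA: explicit SSD partition on Hamming distances."""

    def d(x, y):
        return sum(a != b for a, b in zip(x, y))

    both = seqs_a + seqs_b
    N, P = len(both), 2
    ssd_total = sum(d(x, y) for x, y in itertools.combinations(both, 2)) / N
    ssd_within = (
        sum(d(x, y) for x, y in itertools.combinations(seqs_a, 2)) / len(seqs_a)
        + sum(d(x, y) for x, y in itertools.combinations(seqs_b, 2)) / len(seqs_b)
    )
    ms_among = (ssd_total - ssd_within) / (P - 1)
    sigma_w = ssd_within / (N - P)
    n_eff = (N - (len(seqs_a) ** 2 + len(seqs_b) ** 2) / N) / (P - 1)
    sigma_a = (ms_among - sigma_w) / n_eff
    return sigma_a / (sigma_a + sigma_w)


def _aln(seqs_by_pop: dict[str, list[str]]) -> Alignment:
    seqs, pops = {}, {}
    for pop, ss in seqs_by_pop.items():
        for i, s in enumerate(ss):
            seqs[f"{pop}{i}"] = s
            pops[f"{pop}{i}"] = pop
    return Alignment.from_sequences(seqs, pops)


# ----------------------------------------------------- within-population
def test_monomorphic_population_statistics():
    aln = _aln({"A": ["ACGTACGTAC"] * 4})
    st = within_population_stats(aln, "A")
    assert st["S"] == 0 and st["K"] == 1 and st["H"] == 0 and st["pi"] == 0
    assert np.isnan(st["D"])  # undefined, not zero


def test_handwritten_alignment_matches_pair_enumeration():
    """4 length-10 sequences with exactly 3 polymorphic columns."""
    seqs = ["AAAAAAAAAA", "AAAAAAAAAC", "AAGAAAAAAC", "ATGAAAAAAA"]
    aln = _aln({"A": seqs})
    st = within_population_stats(aln, "A")
    assert st["S"] == 3
    assert st["Pi"] == pytest.approx(brute_force_pairwise_mean(seqs), abs=1e-12)
    assert st["pi"] == pytest.approx(st["Pi"] / 10, abs=1e-15)
    assert st["K"] == 4
    assert st["H"] == pytest.approx(4 / 3 * (1 - 4 * (1 / 4) ** 2))


def test_haplotype_diversity_with_repeats():
    seqs = ["AAAA", "AAAA", "AAAT", "AATT"]  # haplotype counts 2,1,1
    st = within_population_stats(_aln({"A": seqs}), "A")
    assert st["K"] == 3
    assert st["H"] == pytest.approx(4 / 3 * (1 - (0.5**2 + 0.25**2 + 0.25**2)))


def test_small_population_errors():
    aln = _aln({"A": ["ACGT"], "B": ["ACGT", "ACGA"]})
    with pytest.raises(SumstatsError, match="need >= 2"):
        within_population_stats(aln, "A")
    with pytest.raises(SumstatsError, match="absent"):
        within_population_stats(aln, "C")


# ------------------------------------------------------------------ PhiST
def test_phist_one_when_populations_fixed_for_distinct_haplotypes():
    aln = _aln({"A": ["AAAA"] * 3, "B": ["AATT"] * 3})
    assert phi_st(aln, "A", "B") == 1.0


def test_phist_exact_zero_when_mean_squares_coincide():
    """d(h2,h3) = d(h1,h2) + d(h1,h3) makes among- and within-population
    mean squares equal, so the variance decomposition gives exactly 0."""
    aln = _aln({"A": ["AA", "AC"], "B": ["AA", "GA"]})
    assert phi_st(aln, "A", "B") == 0.0


def test_phist_undefined_without_variation():
    aln = _aln({"A": ["AAAA"] * 3, "B": ["AAAA"] * 3})
    assert np.isnan(phi_st(aln, "A", "B"))


def test_identical_compositions_give_small_negative_phist():
    """Identical haplotype compositions have zero among-group SSD; the
    unbiased estimator then lands at -1/(n-1), never above zero."""
    seqs = ["AAAA", "AATT", "TTAA"]
    aln = _aln({"A": seqs * 2, "B": seqs * 2})
    val = phi_st(aln, "A", "B")
    assert val <= 0
    assert val == pytest.approx(-1 / (6 - 1), abs=1e-12)
    assert phi_st(aln, "A", "B", clamp=True) == 0.0


def test_phist_matches_brute_force_amova():
    """3+3 toy alignments agree with the explicit SSD oracle to 1e-12."""
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    for _ in range(20):
        sa = ["".join(rng.choice(bases, 8)) for _ in range(3)]
        sb = ["".join(rng.choice(bases, 8)) for _ in range(3)]
        aln = _aln({"A": sa, "B": sb})
        expected = brute_force_phist(sa, sb)
        if np.isnan(expected):
            assert np.isnan(phi_st(aln, "A", "B"))
        else:
            assert phi_st(aln, "A", "B") == pytest.approx(expected, abs=1e-12)


def test_phist_symmetric_under_relabelling():
    aln = _aln({"A": ["AAAA", "AATT", "ATTT"], "B": ["TTTT", "TTAA", "TAAA"]})
    assert phi_st(aln, "A", "B") == phi_st(aln, "B", "A")


def test_panmictic_split_has_no_among_population_variance():
    """An arbitrary 5/5 split of one panmictic sample over 1,000 simulated
    datasets: the among-population variance component is zero in
    expectation (within 3 SE), and mean PhiST itself sits near zero (the
    ratio carries only its small finite-sample Jensen bias)."""
    from steppeabc.sumstats import phi_st_components

    model = single_region_model(10)
    draw = constant_size_draw(model, 1000.0, mu=4e-8)
    params = MutationParams(mu_per_site=4e-8)
    rng = np.random.default_rng(31)
    sig_a, ratios = [], []
    for _ in range(1000):
        tree = simulate_genealogy(model, draw, rng)
        aln = mutate(tree, params, rng)
        pops = {sid: ("L" if k < 5 else "R") for k, sid in enumerate(aln.ids)}
        relabelled = Alignment(
            ids=aln.ids, populations=pops, length=aln.length,
            variant_positions=aln.variant_positions,
            variant_matrix=aln.variant_matrix, background=aln.background,
        )
        a, w = phi_st_components(relabelled, "L", "R")
        if np.isfinite(a):
            sig_a.append(a)
            if a + w > 0:
                ratios.append(a / (a + w))
    sig_a = np.array(sig_a)
    se = sig_a.std(ddof=1) / np.sqrt(len(sig_a))
    assert abs(sig_a.mean()) < 3 * se
    assert abs(np.mean(ratios)) < 0.05


def test_phist_decreases_with_pulse_strength(default_cfg):
    """Raising the event-2 proportion mixes Corded Ware ancestry into the
    Yamnaya lineage pool, so PhiST(CordedWare, Yamnaya) trends downward."""
    model = build_model("MIG2", default_cfg)
    params = MutationParams(mu_per_site=4e-8)
    means = []
    for m2 in (0.0, 0.4, 0.8):
        values = default_draw_values("MIG2")
        values["m2"] = m2
        draw = ParameterDraw(values, "MIG2")
        rng = np.random.default_rng(71)
        vals = []
        for _ in range(400):
            tree = simulate_genealogy(model, draw, rng)
            aln = mutate(tree, params, rng)
            v = phi_st(aln, "CordedWare", "Yamnaya")
            if np.isfinite(v):
                vals.append(v)
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]


# -------------------------------------------------------------- summarize
def test_summary_vector_layout_and_length(default_cfg):
    model = build_model("NOMIG", default_cfg)
    draw = ParameterDraw(default_draw_values("NOMIG"), "NOMIG")
    tree = simulate_genealogy(model, draw, 3)
    aln = mutate(tree, MutationParams(mu_per_site=4e-8), 4)
    pops = [p.name for p in model.populations]
    vec = summarize(aln, pops)
    layout = summary_layout(pops)
    assert list(vec.index) == layout
    assert len(vec) == 6 * 6 + 15 + 15 + 6  # per-pop, PhiST, dxy, pooled


def test_summary_invariant_to_sample_order(default_cfg):
    model = build_model("NOMIG", default_cfg)
    draw = ParameterDraw(default_draw_values("NOMIG"), "NOMIG")
    tree = simulate_genealogy(model, draw, 11)
    aln = mutate(tree, MutationParams(mu_per_site=4e-8), 12)
    pops = [p.name for p in model.populations]
    vec = summarize(aln, pops)
    perm = np.random.default_rng(1).permutation(aln.n_samples)
    shuffled = Alignment(
        ids=tuple(aln.ids[k] for k in perm),
        populations=aln.populations,
        length=aln.length,
        variant_positions=aln.variant_positions,
        variant_matrix=aln.variant_matrix[perm],
        background=aln.background,
    )
    vec2 = summarize(shuffled, pops)
    assert np.allclose(vec.to_numpy(), vec2.to_numpy(), equal_nan=True)


def test_monomorphic_population_encoded_as_null_then_imputed():
    # n = 4 in B: Tajima's variance constants vanish below n = 4
    aln = _aln({"A": ["AAAA"] * 3, "B": ["AATT", "ATTT", "TTTT", "TTTA"]})
    vec = summarize(aln, ["A", "B"])
    assert np.isnan(vec["D_A"])
    import pandas as pd

    table = impute_summary_table(vec.to_frame().T)
    assert table["D_A"].iloc[0] == 0.0
    assert table["D_A_def"].iloc[0] == 0.0
    assert table["D_B_def"].iloc[0] == 1.0
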