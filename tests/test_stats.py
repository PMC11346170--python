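"""Spearman correlograms, Mann-Whitney tests and score stratifications."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ivcm_dryeye.stats import (
    mann_whitney,
    spearman_matrix,
    spearman_pair,
    stratify_extreme_tivcm,
    stratify_icsc,
    compare_hla_by_icsc,
    within_group_correlations,
)


# --- independent oracles ---------------------------------------------------

def oracle_spearman(x, y):
    """Rank-then-Pearson with explicit midranks, written independently."""
    rx = pd.Series(x).rank(method="average").to_numpy()
    ry = pd.Series(y).rank(method="average").to_numpy()
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def oracle_mw_exact_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    mid = n1 * (len(b)) / 2
    dev_obs = abs(u_obs - mid)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = np.sum(ranks[list(combo)]) - n1 * (n1 + 1) / 2
        count += abs(u - mid) >= dev_obs - 1e-12
        total += 1
    return count / total


# --- Spearman --------------------------------------------------------------

def test_spearman_perfect_monotone():
    table = pd.DataFrame({"x": [1, 2, 3, 4], "y": [10, 20, 30, 40], "z": [8, 6, 4, 2]})
    res = spearman_matrix(table, variables=("x", "y", "z"))
    assert res.rho[0, 1] == pytest.approx(1.0)
    assert res.rho[0, 2] == pytest.approx(-1.0)


def test_spearman_matches_rank_pearson_oracle_to_1e12():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = rng.integers(15, 120)
        x = rng.integers(0, 6, n).astype(float)  # heavy ties
        y = rng.standard_normal(n) + 0.4 * x
        w = rng.integers(0, 3, n).astype(float)
        table = pd.DataFrame({"x": x, "y": y, "w": w})
        res = spearman_matrix(table, variables=("x", "y", "w"))
        for i, a in enumerate(("x", "y", "w")):
            for j, b in enumerate(("x", "y", "w")):
                if i < j:
                    assert res.rho[i, j] == pytest.approx(
                        oracle_spearman(table[a], table[b]), abs=1e-12
                    )


def test_spearman_exact_permutation_p_small_n():
    # n = 6 with ties: p must equal full enumeration over all 720 pairings
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 3.0, 5.0, 4.0, 4.0])
    _rho, p, n = spearman_pair(x, y)
    assert n == 6
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho_obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = total = 0
    for perm in itertools.permutations(ry):
        hits += abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= rho_obs - 1e-12
        total += 1
    assert p == pytest.approx(hits / total, abs=1e-12)


def test_spearman_constant_variable_reported_missing():
    table = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0] * 5, "c": [7.0] * 20})
    res = spearman_matrix(table, variables=("x", "c"))
    assert np.isnan(res.rho[0, 1])
    assert not res.mask[0, 1]


def test_spearman_pairwise_complete_deletion():
    x = [1.0, 2.0, 3.0, 4.0, np.nan] * 4
    y = [2.0, 4.0, 6.0, 8.0, 10.0] * 4
    table = pd.DataFrame({"x": x, "y": y})
    res = spearman_matrix(table, variables=("x", "y"))
    assert res.n_pairs[0, 1] == 16
    assert res.rho[0, 1] == pytest.approx(1.0)


def test_spearman_bh_adjustment_only_weakens_mask():
    rng = np.random.default_rng(3)
    table = pd.DataFrame(rng.standard_normal((40, 5)), columns=list("abcde"))
    raw = spearman_matrix(table, variables=tuple("abcde"))
    adj = spearman_matrix(table, variables=tuple("abcde"), adjust="bh")
    assert np.all(adj.p >= raw.p - 1e-12)
    assert np.all(~adj.mask | raw.mask)


# --- Mann-Whitney ----------------------------------------------------------

def test_mann_whitney_separated_groups_exact():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.u_statistic == 0.0
    assert res.p_value == pytest.approx(0.1, abs=1e-12)  # 2/C(6,3)


def test_mann_whitney_identical_samples_midpoint_u():
    a = [1.0, 2.0, 3.0, 4.0]
    res = mann_whitney(a, a)
    assert res.u_statistic == pytest.approx(len(a) * len(a) / 2)


@pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (3, 5), (5, 5), (4, 6)])
def test_mann_whitney_exact_matches_enumeration(n1, n2):
    rng = np.random.default_rng(n1 * 10 + n2)
    for _ in range(3):
        a = rng.standard_normal(n1)
        b = rng.standard_normal(n2) + 0.8
        res = mann_whitney(a, b)
        assert res.p_value == pytest.approx(oracle_mw_exact_p(a, b), abs=1e-12)


def test_mann_whitney_asymptotic_close_to_exact_at_n6():
    """The tie-corrected normal approximation tracks the enumeration oracle
    even at n1=n2=6, the smallest size where the asymptotic path can fire
    (it only does so in the presence of ties; untied samples this small
    always take the exact path)."""
    rng = np.random.default_rng(7)
    worst = 0.0
    for _ in range(10):
        a = rng.standard_normal(6)
        b = rng.standard_normal(6) + 0.5
        # force the asymptotic path through a duplicated value (a tie)
        a_tied = np.concatenate([a[:5], a[4:5]])
        res = mann_whitney(a_tied, b)
        worst = max(worst, abs(res.p_value - oracle_mw_exact_p(a_tied, b)))
    assert worst <= 0.05


def test_mann_whitney_empty_group_errors():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# --- stratifications -------------------------------------------------------

def test_stratify_icsc_partition():
    table = pd.DataFrame({"ic_sub": [0, 1, 2, 3, 3], "hla_dr_auf": range(5)})
    low, high = stratify_icsc(table)
    assert len(low) == 3 and len(high) == 2
    assert len(low) + len(high) == len(table)


def test_stratify_icsc_empty_high_flagged():
    table = pd.DataFrame({"ic_sub": [0, 0, 1], "hla_dr_auf": [1.0, 2.0, 3.0]})
    assert compare_hla_by_icsc(table) is None


def test_stratify_extreme_tivcm_partition():
    table = pd.DataFrame({"tivcm": [0, 1, 2, 3, 4, 5, 6]})
    low, high = stratify_extreme_tivcm(table)
    assert sorted(low["tivcm"]) == [0, 1, 2]
    assert sorted(high["tivcm"]) == [5, 6]
    middle = len(table) - len(low) - len(high)
    assert middle == 2


def test_stratify_extreme_tivcm_empty_and_invalid():
    empty = pd.DataFrame({"tivcm": []})
    low, high = stratify_extreme_tivcm(empty)
    assert len(low) == 0 and len(high) == 0
    with pytest.raises(ValueError):
        stratify_extreme_tivcm(empty, low_max=5, high_min=5)


def test_within_group_identical_records_no_edges():
    table = pd.DataFrame({"a": [1.0] * 10, "b": [2.0] * 10})
    _res, edges = within_group_correlations(table, variables=("a", "b"))
    assert len(edges) == 0


def test_within_group_too_small_errors():
    with pytest.raises(ValueError):
        within_group_correlations(pd.DataFrame({"a": [1.0, 2.0]}), variables=("a",))


def test_within_group_edges_subset_of_mask(single_cohort):
    res, edges = within_group_correlations(
        single_cohort, variables=("age", "schirmer_mm", "tbut_s", "tivcm", "hla_dr_auf")
    )
    names = {v: i for i, v in enumerate(res.variables)}
    for _, row in edges.iterrows():
        i, j = names[row["var_a"]], names[row["var_b"]]
        assert res.mask[i, j]
        assert np.sign(res.rho[i, j]) == (1 if row["sign"] == "+" else -1)


def test_planted_high_group_schirmer_tbut_edge_recovered(replicate_cohorts):
    """The Schirmer-TBUT association planted in the generator survives
    restriction to the severe (high total score) stratum."""
    hits = 0
    for frame in replicate_cohorts:
        _low, high = stratify_extreme_tivcm(frame)
        rho, p, _n = spearman_pair(high["schirmer_mm"], high["tbut_s"])
        hits += (rho > 0) and (p < 0.05)
    assert hits >= 12  # significant positive edge in a clear majority
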