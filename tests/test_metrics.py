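"""Agreement metrics against brute-force oracles and invariants."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from rfcell.metrics import (
    adjusted_rand_index,
    contingency,
    entropy,
    mutual_information,
    nmi,
    pair_counts,
    rand_index,
)

# ---------------------------------------------------------------------------
# Independent oracles: exhaustive pair enumeration and direct summation.
# ---------------------------------------------------------------------------

def enum_pair_counts(p1, p2):
    a = b = c = d = 0
    for i, j in itertools.combinations(range(len(p1)), 2):
        same1, same2 = p1[i] == p1[j], p2[i] == p2[j]
        if same1 and same2:
            a += 1
        elif not same1 and not same2:
            b += 1
        elif same1:
            c += 1
        else:
            d += 1
    return a, b, c, d


def direct_entropy(p):
    m = len(p)
    return -sum(
        (list(p).count(v) / m) * math.log(list(p).count(v) / m)
        for v in set(p)
    )


def direct_mi(p1, p2):
    m = len(p1)
    total = 0.0
    for u in set(p1):
        for v in set(p2):
            nij = sum(1 for a, b in zip(p1, p2) if a == u and b == v)
            if nij == 0:
                continue
            pi = list(p1).count(u) / m
            pj = list(p2).count(v) / m
            total += (nij / m) * math.log((nij / m) / (pi * pj))
    return total


def direct_ari(p1, p2):
    a, b, c, d = enum_pair_counts(p1, p2)
    m = len(p1)
    total = m * (m - 1) / 2
    same1, same2 = a + c, a + d
    expected = same1 * same2 / total
    maximum = 0.5 * (same1 + same2)
    if maximum == expected:
        return 1.0
    return (a - expected) / (maximum - expected)


partitions = st.integers(2, 25).flatmap(
    lambda m: st.tuples(
        st.lists(st.integers(0, 4), min_size=m, max_size=m),
        st.lists(st.integers(0, 4), min_size=m, max_size=m),
    )
)


def test_contingency_counts_direct():
    table = contingency([0, 0, 1, 1], [0, 1, 0, 1]).counts
    assert (table == np.ones((2, 2), dtype=int)).all()
    diag = contingency(["a", "b", "a"], ["x", "y", "x"]).counts
    assert sorted(diag.flatten()) == [0, 0, 1, 2]
    single = contingency([0, 0, 1], [7, 7, 7]).counts
    assert single.shape == (2, 1) and list(single[:, 0]) == [2, 1]
    with pytest.raises(ValueError):
        contingency([0, 1], [0, 1, 2])


@pytest.mark.parametrize(
    "p, expected",
    [
        ([1, 1, 1], 0.0),
        ([0, 0, 1, 1], math.log(2)),
        ([0, 0, 1, 2], -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))),
    ],
)
def test_entropy_closed_forms(p, expected):
    assert entropy(p) == pytest.approx(expected, abs=1e-12)


def test_mutual_information_special_cases():
    # independent uniform pair: joint equals product
    assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)
    # identical partitions: I = H
    p = [0, 0, 1, 2, 2]
    assert mutual_information(p, p) == pytest.approx(entropy(p), abs=1e-12)
    expected = direct_mi([0, 0, 1, 1], [0, 0, 1, 2])
    assert mutual_information([0, 0, 1, 1], [0, 0, 1, 2]) == pytest.approx(
        expected, abs=1e-12
    )


def test_nmi_special_cases():
    assert nmi([0, 1, 2], [2, 0, 1]) == 1.0
    assert nmi([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)
    i = direct_mi([0, 0, 1, 1], [0, 0, 1, 2])
    h1, h2 = direct_entropy([0, 0, 1, 1]), direct_entropy([0, 0, 1, 2])
    assert nmi([0, 0, 1, 1], [0, 0, 1, 2]) == pytest.approx(
        2 * i / (h1 + h2), abs=1e-12
    )


def test_pair_counts_enumeration_example():
    pc = pair_counts([0, 0, 1, 1], [0, 1, 0, 1])
    assert (pc.a, pc.b, pc.c, pc.d) == (0, 2, 2, 2)
    same = pair_counts([0, 0, 1], [5, 5, 6])
    assert same.c == same.d == 0
    with pytest.raises(ValueError):
        pair_counts([0], [0])


def test_rand_index_examples():
    assert rand_index([0, 0, 1], [0, 0, 1]) == 1.0
    assert rand_index([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(1 / 3)
    assert rand_index([0, 1], [0, 0]) == 0.0


def test_ari_spot_check():
    # all-ones 2x2 contingency: (0 - 2/3) / (2 - 2/3) = -0.5
    assert adjusted_rand_index([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)
    assert adjusted_rand_index([0, 1, 1, 2], [0, 1, 1, 2]) == 1.0


def test_degenerate_partition_conventions():
    # both single-cluster: identical up to relabeling -> 1
    assert nmi([7, 7, 7], [1, 1, 1]) == 1.0
    assert adjusted_rand_index([7, 7, 7], [1, 1, 1]) == 1.0
    # all singletons in both: trivially identical -> 1
    assert adjusted_rand_index([0, 1, 2], [5, 6, 7]) == 1.0
    # one trivial, one not: max(RI) != E(RI) path, chance-level result
    assert adjusted_rand_index([0, 0, 0, 0], [0, 0, 1, 1]) == 0.0
    # single-cluster vs singletons: both trivial but not identical -> 0
    assert adjusted_rand_index([0, 0, 0], [0, 1, 2]) == 0.0


def test_oracle_equivalence_random_pairs():
    """Contingency-identity RI/ARI/NMI match enumeration/summation oracles."""
    rng = np.random.default_rng(0)
    from conftest import random_partition_pair

    for _ in range(200):
        p1, p2 = random_partition_pair(rng)
        a, b, c, d = enum_pair_counts(p1, p2)
        pc = pair_counts(p1, p2)
        assert (pc.a, pc.b, pc.c, pc.d) == (a, b, c, d)
        m = len(p1)
        assert rand_index(p1, p2) == pytest.approx(
            (a + b) / (m * (m - 1) / 2), abs=1e-12
        )
        assert adjusted_rand_index(p1, p2) == pytest.approx(
            direct_ari(p1, p2), abs=1e-12
        )
        h1, h2 = direct_entropy(p1), direct_entropy(p2)
        if h1 + h2 > 0:
            assert nmi(p1, p2) == pytest.approx(
                min(max(2 * direct_mi(p1, p2) / (h1 + h2), 0.0), 1.0), abs=1e-12
            )


def test_agreement_with_library_reference():
    """Independent cross-check against sklearn's implementations."""
    rng = np.random.default_rng(3)
    from conftest import random_partition_pair

    for _ in range(50):
        p1, p2 = random_partition_pair(rng)
        assert adjusted_rand_index(p1, p2) == pytest.approx(
            adjusted_rand_score(p1, p2), abs=1e-10
        )
        if len(set(p1)) > 1 or len(set(p2)) > 1:
            assert nmi(p1, p2) == pytest.approx(
                normalized_mutual_info_score(p1, p2, average_method="arithmetic"),
                abs=1e-10,
            )


@settings(derandomize=True, max_examples=100)
@given(partitions, st.integers(0, 2**31 - 1))
def test_relabel_invariance_and_symmetry(pair, seed):
    p1, p2 = pair
    rng = np.random.default_rng(seed)
    relabel = {v: f"L{k}" for k, v in enumerate(rng.permutation(5))}
    p1r = [relabel[v] for v in p1]
    for metric in (nmi, rand_index, adjusted_rand_index):
        assert metric(p1, p2) == pytest.approx(metric(p1r, p2), abs=1e-12)
        assert metric(p1, p2) == pytest.approx(metric(p2, p1), abs=1e-12)


@settings(derandomize=True, max_examples=100)
@given(partitions)
def test_bounds_and_pair_total(pair):
    p1, p2 = pair
    m = len(p1)
    pc = pair_counts(p1, p2)
    assert pc.a + pc.b + pc.c + pc.d == m * (m - 1) // 2
    assert 0.0 <= nmi(p1, p2) <= 1.0
    assert 0.0 <= rand_index(p1, p2) <= 1.0
    assert adjusted_rand_index(p1, p2) <= 1.0
    assert mutual_information(p1, p2) >= -1e-12


def test_random_partition_ari_near_zero():
    """Mean ARI of independent uniform partitions is chance-corrected to ~0."""
    rng = np.random.default_rng(5)
    vals = [
        adjusted_rand_index(rng.integers(0, 4, 100), rng.integers(0, 4, 100))
        for _ in range(1000)
    ]
    assert abs(np.mean(vals)) < 0.02
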