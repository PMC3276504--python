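import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from reversig import overlap as ovl
from reversig.io_formats import DrugAnnotation
from reversig.overlap import Direction
from reversig.ranking import RankedList, Window

from conftest import make_ranked


def oracle_tail(x, k, n):
    """Independent enumeration of P(X >= x) for the k/k overlap over n genes."""
    total = math.comb(n, k)
    return sum(math.comb(k, j) * math.comb(n - k, k - j) for j in range(x, k + 1)) / total


# ---------------------------------------------------------------------------
# overlap_pvalue
# ---------------------------------------------------------------------------


def test_pvalue_at_zero_is_one():
    for k, n in [(1, 2), (3, 20), (10, 100)]:
        assert ovl.overlap_pvalue(0, k, n) == pytest.approx(1.0)


def test_pvalue_full_overlap_example():
    assert ovl.overlap_pvalue(3, 3, 20) == pytest.approx(1 / 1140, rel=1e-12)


def test_pvalue_partial_overlap_example():
    assert ovl.overlap_pvalue(1, 2, 10) == pytest.approx(17 / 45, rel=1e-12)


def test_pvalue_matches_enumeration_small():
    for n in (6, 11, 20):
        for k in range(1, n // 2 + 1):
            for x in range(k + 1):
                assert ovl.overlap_pvalue(x, k, n) == pytest.approx(
                    oracle_tail(x, k, n), abs=1e-12
                )


def test_pvalue_monotone_in_x():
    k, n = 8, 50
    ps = [ovl.overlap_pvalue(x, k, n) for x in range(k + 1)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_pvalue_window_exhausts_background():
    with pytest.raises(ValueError, match="background"):
        ovl.overlap_pvalue(1, 6, 10)


def test_pvalue_infeasible_x():
    with pytest.raises(ValueError, match="infeasible"):
        ovl.overlap_pvalue(4, 3, 20)


# ---------------------------------------------------------------------------
# bh_adjust
# ---------------------------------------------------------------------------


def bh_oracle(p):
    """Independent step-up implementation."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p[i] * m / (pos + 1))
        q[i] = min(running, 1.0)
    return q


def test_bh_all_equal():
    q = ovl.bh_adjust([0.2, 0.2, 0.2])
    np.testing.assert_allclose(q, [0.2, 0.2, 0.2])


def test_bh_worked_example():
    q = ovl.bh_adjust([0.01, 0.02, 0.03])
    np.testing.assert_allclose(q, [0.03, 0.03, 0.03])


def test_bh_single_and_empty():
    assert ovl.bh_adjust([0.7])[0] == pytest.approx(0.7)
    assert ovl.bh_adjust([]).size == 0


def test_bh_matches_oracle_random():
    rng = np.random.default_rng(0)
    for _ in range(50):
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
        np.testing.assert_allclose(ovl.bh_adjust(p), bh_oracle(p), atol=1e-12)


def test_bh_rejects_bad_p():
    with pytest.raises(ValueError):
        ovl.bh_adjust([0.0, 0.5])
    with pytest.raises(ValueError):
        ovl.bh_adjust([1.5])


# ---------------------------------------------------------------------------
# test_all_compounds
# ---------------------------------------------------------------------------


def _genes(n):
    return [f"g{i:03d}" for i in range(n)]


def test_identical_list_no_reversal():
    genes = _genes(20)
    disease = make_ranked(genes)
    same = make_ranked(genes)
    tests = ovl.test_all_compounds(disease, {"c": same}, Window(5), Window(5))
    ucdb = [t for t in tests if t.direction is Direction.UC_DB][0]
    assert ucdb.overlap == 0
    assert ucdb.p_value == pytest.approx(1.0)
    assert not ucdb.significant


def test_reversed_list_full_overlap():
    genes = _genes(20)
    disease = make_ranked(genes)
    rev = make_ranked(list(reversed(genes)))
    tests = ovl.test_all_compounds(disease, {"c": rev}, Window(5), Window(5))
    for t in tests:
        assert t.overlap == 5
        assert t.p_value == pytest.approx(1 / math.comb(20, 5), rel=1e-9)


def test_universe_mismatch_errors():
    disease = make_ranked(_genes(10))
    other = make_ranked([f"x{i}" for i in range(10)])
    with pytest.raises(ValueError, match="different gene universe"):
        ovl.test_all_compounds(disease, {"c": other}, Window(2), Window(2))


def test_bh_is_per_direction():
    genes = _genes(40)
    disease = make_ranked(genes)
    rng = np.random.default_rng(1)
    compounds = {
        f"c{i}": make_ranked(list(rng.permutation(genes))) for i in range(6)
    }
    tests = ovl.test_all_compounds(disease, compounds, Window(10), Window(10))
    for direction in Direction:
        sub = [t for t in tests if t.direction is direction]
        expected_q = ovl.bh_adjust([t.p_value for t in sub])
        np.testing.assert_allclose([t.q_value for t in sub], expected_q)


# ---------------------------------------------------------------------------
# merge_candidates
# ---------------------------------------------------------------------------


def _fake_test(compound, direction, significant, q=0.001):
    return ovl.OverlapTest(
        compound=compound,
        direction=direction,
        k=2,
        overlap=2 if significant else 0,
        background=10,
        p_value=q,
        q_value=q if significant else 1.0,
        significant=significant,
    )


def test_merge_simple_duality():
    tests = [
        _fake_test("A", Direction.UC_DB, True),
        _fake_test("B", Direction.UC_DB, True),
        _fake_test("B", Direction.DC_UB, True),
        _fake_test("C", Direction.DC_UB, True),
        _fake_test("D", Direction.UC_DB, False),
    ]
    table = ovl.merge_candidates(tests)
    s = table.summary()
    assert s["n_distinct"] == 3
    assert s["n_duality"] == 1
    assert [r.compound for r in table.rows if r.duality] == ["B"]


@pytest.mark.parametrize(
    "n_ucdb, n_dcub, n_dual, expected_distinct",
    [(28, 62, 10, 80), (89, 26, 19, 96)],
)
def test_merge_counting_arithmetic(n_ucdb, n_dcub, n_dual, expected_distinct):
    # Direction calls with a fixed overlap reproduce the distinct/duality bookkeeping.
    ucdb = [f"u{i}" for i in range(n_ucdb - n_dual)] + [f"d{i}" for i in range(n_dual)]
    dcub = [f"v{i}" for i in range(n_dcub - n_dual)] + [f"d{i}" for i in range(n_dual)]
    tests = [_fake_test(c, Direction.UC_DB, True) for c in ucdb]
    tests += [_fake_test(c, Direction.DC_UB, True) for c in dcub]
    s = ovl.merge_candidates(tests).summary()
    assert s["n_UC_DB"] == n_ucdb
    assert s["n_DC_UB"] == n_dcub
    assert s["n_distinct"] == expected_distinct
    assert s["n_duality"] == n_dual


def test_merge_attaches_annotations_and_recovery():
    tests = [_fake_test("fulvestrant", Direction.UC_DB, True)]
    anns = {
        "fulvestrant": DrugAnnotation(
            "fulvestrant", fda_approved=True, approved_indications={"breast cancer"}
        )
    }
    table = ovl.merge_candidates(tests, anns)
    s = table.summary(target_disease="breast cancer")
    assert s["n_fda_approved"] == 1
    assert s["recovered_drugs"] == ["fulvestrant"]


# ---------------------------------------------------------------------------
# null calibration / planted recovery (light versions; full runs in acceptance)
# ---------------------------------------------------------------------------


def _random_compound_lists(rng, genes, n_compounds):
    return {f"c{i:03d}": make_ranked(list(rng.permutation(genes))) for i in range(n_compounds)}


def test_null_rejection_rate_matches_discrete_tail():
    # For the exact test the null P(p < 0.05) equals the largest attainable
    # tail probability below 0.05, not 0.05 itself.
    n, k = 2000, 100
    genes = _genes(n)
    disease = make_ranked(genes)
    rng = np.random.default_rng(7)
    n_tests = 0
    n_reject = 0
    n_disc = 0
    for _ in range(5):
        compounds = _random_compound_lists(rng, genes, 100)
        tests = ovl.test_all_compounds(disease, compounds, Window(k), Window(k))
        n_tests += len(tests)
        n_reject += sum(t.p_value < 0.05 for t in tests)
        n_disc += sum(t.significant for t in tests)
    xs = np.arange(0, k + 1)
    tails = hypergeom.sf(xs - 1, n, k, k)
    expected = tails[tails < 0.05].max()
    frac = n_reject / n_tests
    # binomial 4-sigma band around the discrete expectation
    sigma = math.sqrt(expected * (1 - expected) / n_tests)
    assert abs(frac - expected) < 4 * sigma + 1e-9
    assert n_disc / 5 < 0.5  # FDR-0.01 discoveries are rare under the null


def test_planted_reversal_recovered_with_duality():
    n, k = 2000, 100
    genes = _genes(n)
    rng = np.random.default_rng(8)
    hits = 0
    for _ in range(5):
        disease = make_ranked(list(rng.permutation(genes)))
        compounds = _random_compound_lists(rng, genes, 50)
        rev = list(reversed(disease.ordered_gene_ids))
        pos = rng.choice(n, size=n // 10, replace=False)
        vals = [rev[i] for i in pos]
        for i, j in zip(pos, rng.permutation(len(pos))):
            rev[i] = vals[j]
        compounds["planted"] = make_ranked(rev)
        tests = ovl.test_all_compounds(disease, compounds, Window(k), Window(k))
        planted = [t for t in tests if t.compound == "planted"]
        if all(t.significant for t in planted):
            hits += 1
    assert hits == 5


def test_overlap_gene_sets_collects_union():
    genes = _genes(20)
    disease = make_ranked(genes)
    rev = make_ranked(list(reversed(genes)))
    tests = ovl.test_all_compounds(disease, {"c": rev}, Window(5), Window(5))
    sets = ovl.overlap_gene_sets(tests)
    assert sets["c"] == frozenset(genes[:5]) | frozenset(genes[-5:])
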