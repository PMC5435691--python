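"""Agreement statistics against hand-computed values and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkdvol.stats import (PairedTKV, bland_altman, ccc, cov_repeated,
                          crossval_partition, dice, error_metrics,
                          evaluate_cohort, spearman, wilcoxon_signed_rank)

# ---------------------------------------------------------------- brute force


def dice_bruteforce(a, b):
    a = np.asarray(a).astype(bool).ravel()
    b = np.asarray(b).astype(bool).ravel()
    inter = sum(1 for x, y in zip(a, b) if x and y)
    na, nb = int(a.sum()), int(b.sum())
    return 1.0 if na + nb == 0 else 2.0 * inter / (na + nb)


def ccc_bruteforce(x, y):
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    vx = sum((v - mx) ** 2 for v in x) / n
    vy = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (vx + vy + (mx - my) ** 2)


def spearman_bruteforce(x, y):
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(list(x)), ranks(list(y))
    return np.corrcoef(rx, ry)[0, 1]


def pairs_from(true_vals, auto_vals):
    return [PairedTKV(f"c{i}", t, a)
            for i, (t, a) in enumerate(zip(true_vals, auto_vals))]


# ------------------------------------------------------------------ dice


def test_dice_hand_values():
    a = np.zeros(10, dtype=bool)
    b = np.zeros(10, dtype=bool)
    a[:4] = True
    b[2:6] = True          # |A|=4, |B|=4, overlap 2
    assert dice(a, b) == pytest.approx(0.5)
    assert dice(a, a) == 1.0
    assert dice(a, ~a) == 0.0
    assert dice(np.zeros(5, bool), np.zeros(5, bool)) == 1.0


@given(st.integers(0, 2**20 - 1))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_dice_matches_bruteforce_and_is_symmetric(seed):
    r = np.random.default_rng(seed)
    a = r.random((8, 8)) > 0.6
    b = r.random((8, 8)) > 0.6
    assert dice(a, b) == pytest.approx(dice_bruteforce(a, b), abs=1e-12)
    assert dice(a, b) == pytest.approx(dice(b, a), abs=1e-15)


def test_dice_shape_mismatch_raises():
    with pytest.raises(ValueError):
        dice(np.zeros((2, 2)), np.zeros((3, 3)))


# ------------------------------------------------------------------- ccc


def test_ccc_hand_value_and_limits():
    c, _ = ccc([1, 2, 3], [2, 3, 4])
    assert c == pytest.approx(4 / 7, abs=1e-12)
    x = np.array([-2.0, 0.0, 2.0, 1.0, -1.0])
    assert ccc(x, x)[0] == pytest.approx(1.0)
    assert ccc(x, -x)[0] == pytest.approx(-1.0)


def test_ccc_ci_brackets_estimate():
    rng = np.random.default_rng(5)
    x = rng.uniform(100, 5000, 30)
    y = x * rng.normal(1.0, 0.08, 30)
    c, (lo, hi) = ccc(x, y)
    assert lo < c < hi
    assert -1 <= lo and hi <= 1


def test_ccc_never_exceeds_pearson_magnitude():
    rng = np.random.default_rng(11)
    for _ in range(20):
        x = rng.normal(size=15)
        y = 2 * x + rng.normal(size=15) + 1.0
        c, _ = ccc(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(c) <= abs(r) + 1e-12


# ----------------------------------------------------------- bland-altman


def test_bland_altman_hand_values():
    m, (lo, hi) = bland_altman(pairs_from([100, 100], [99, 101]))
    assert m == pytest.approx(0.0)
    assert lo == pytest.approx(-1.96 * np.sqrt(2), abs=1e-9)
    assert hi == pytest.approx(+1.96 * np.sqrt(2), abs=1e-9)

    m, _ = bland_altman(pairs_from([100], [110]) + pairs_from([100], [110]),
                        mode="percentage")
    assert m == pytest.approx(100 * 10 / 105, abs=1e-9)

    m, (lo, hi) = bland_altman(pairs_from([50, 70], [50, 70]))
    assert (m, lo, hi) == (0.0, 0.0, 0.0)


def test_bland_altman_percentage_scale_invariant():
    t = [100.0, 220.0, 515.0, 90.0]
    a = [110.0, 200.0, 560.0, 85.0]
    m1, loa1 = bland_altman(pairs_from(t, a), mode="percentage")
    k = 3.7
    m2, loa2 = bland_altman(pairs_from([v * k for v in t],
                                       [v * k for v in a]), mode="percentage")
    assert m1 == pytest.approx(m2, abs=1e-9)
    assert loa1 == pytest.approx(loa2, abs=1e-9)


# -------------------------------------------------------------------- cov


def test_cov_repeated_hand_value_and_scale_invariance():
    assert cov_repeated(pairs_from([90], [110])) == pytest.approx(
        100 * np.sqrt(200.0) / 100.0, abs=1e-9)
    assert cov_repeated(pairs_from([100, 200], [100, 200])) == 0.0
    p1 = pairs_from([100, 300], [120, 280])
    p2 = pairs_from([500, 1500], [600, 1400])
    assert cov_repeated(p1) == pytest.approx(cov_repeated(p2), abs=1e-9)


# ---------------------------------------------------------- error metrics


def test_error_metrics_hand_values():
    e = error_metrics(pairs_from([100, 100], [110, 90]))
    assert e["mpe"] == pytest.approx(0.0)
    assert e["mape"] == pytest.approx(10.0)
    assert e["rmse"] == pytest.approx(10.0)
    assert e["rmspe"] == pytest.approx(10.0)
    perfect = error_metrics(pairs_from([100, 250], [100, 250]))
    assert all(v == 0.0 for v in perfect.values())


@given(st.integers(0, 2**20 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_mape_dominates_mpe(seed):
    r = np.random.default_rng(seed)
    t = r.uniform(100, 5000, 12)
    a = t * r.normal(1.0, 0.2, 12)
    e = error_metrics(pairs_from(t, a))
    assert e["mape"] >= abs(e["mpe"]) - 1e-12


def test_error_metrics_rejects_zero_truth():
    with pytest.raises(ValueError):
        error_metrics(pairs_from([0.0, 100.0], [10.0, 100.0]))


# --------------------------------------------------- spearman / wilcoxon


def test_spearman_hand_value_and_monotone_limits():
    rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert rho == pytest.approx(0.8, abs=1e-12)
    assert spearman([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
    assert spearman([1, 2, 3], [5, 4, 3])[0] == pytest.approx(-1.0)


def test_wilcoxon_paired_behaviour():
    rng = np.random.default_rng(3)
    x = rng.uniform(100, 1000, 15)
    p_same = wilcoxon_signed_rank(x + rng.normal(0, 1, 15), x)
    assert 0 <= p_same <= 1
    p_shift = wilcoxon_signed_rank(x + 50.0, x)
    assert p_shift < 0.01
    assert np.isnan(wilcoxon_signed_rank(x, x))


# ------------------------------------------- oracle sweep over cohorts


def test_statistics_match_bruteforce_on_random_cohorts():
    """Full battery vs independent brute force on 50 random 20-case cohorts."""
    rng = np.random.default_rng(99)
    for _ in range(50):
        t = rng.uniform(300, 8000, 20)
        a = t * rng.normal(1.0, 0.15, 20)
        pairs = pairs_from(t, a)
        assert ccc(t, a)[0] == pytest.approx(ccc_bruteforce(t, a), abs=1e-9)
        d = a - t
        m, (lo, hi) = bland_altman(pairs)
        sd = np.sqrt(sum((v - d.mean()) ** 2 for v in d) / (len(d) - 1))
        assert m == pytest.approx(d.mean(), abs=1e-9)
        assert lo == pytest.approx(d.mean() - 1.96 * sd, abs=1e-9)
        assert hi == pytest.approx(d.mean() + 1.96 * sd, abs=1e-9)
        assert cov_repeated(pairs) == pytest.approx(
            100 * np.sqrt(np.mean((a - t) ** 2 / 2))
            / np.concatenate([a, t]).mean(), abs=1e-9)
        pe = 100 * (a - t) / t
        e = error_metrics(pairs)
        assert e["mpe"] == pytest.approx(pe.mean(), abs=1e-9)
        assert e["mape"] == pytest.approx(np.abs(pe).mean(), abs=1e-9)
        assert e["rmse"] == pytest.approx(np.sqrt((d ** 2).mean()), abs=1e-9)
        assert e["rmspe"] == pytest.approx(np.sqrt((pe ** 2).mean()), abs=1e-9)
        assert spearman(t, a)[0] == pytest.approx(
            spearman_bruteforce(t, a), abs=1e-9)


# --------------------------------------------------------- evaluate_cohort


class _Case:
    def __init__(self, cid, mask, tkv):
        self.case_id, self.mask, self.tkv_ml = cid, mask, tkv


def _mock_cohort(rng, n=6, bias=1.0):
    refs, preds = [], []
    for i in range(n):
        m = rng.random((4, 16, 16)) > 0.7
        tkv = float(rng.uniform(500, 3000))
        refs.append(_Case(f"c{i}", m, tkv))
        pm = m.copy()
        pm[0] ^= rng.random((16, 16)) > 0.95
        preds.append(_Case(f"c{i}", pm, tkv * bias))
    return preds, refs


def test_evaluate_cohort_identity_is_perfect(rng):
    preds, refs = _mock_cohort(rng)
    report = evaluate_cohort(refs, refs)
    assert report.dsc_mean == 1.0
    assert report.ccc == pytest.approx(1.0)
    assert report.mape_pct == 0.0
    assert report.ba_loa_pct == (0.0, 0.0)


def test_evaluate_cohort_recovers_injected_bias(rng):
    preds, refs = _mock_cohort(rng, n=10, bias=1.10)
    report = evaluate_cohort(preds, refs)
    assert report.mpe_pct == pytest.approx(10.0, abs=1e-9)
    assert report.mape_pct == pytest.approx(10.0, abs=1e-9)
    assert len(report.per_case) == 10


def test_evaluate_cohort_unmatched_ids_raise(rng):
    preds, refs = _mock_cohort(rng)
    preds[0].case_id = "zzz"
    with pytest.raises(ValueError, match="zzz"):
        evaluate_cohort(preds, refs)


# ------------------------------------------------------ crossval partition


def test_crossval_fold_sizes_for_242_cases():
    rng = np.random.default_rng(1)
    tkvs = {f"p{i}": float(v) for i, v in
            enumerate(rng.uniform(321.2, 14670.7, 242))}
    folds = crossval_partition(tkvs, k=3, seed=4)
    assert sorted(len(f) for f in folds) == [80, 81, 81]
    flat = [c for f in folds for c in f]
    assert sorted(flat) == sorted(tkvs)


def test_crossval_stratifies_by_tkv_tercile():
    tkvs = {f"p{i}": float(100 * (i + 1)) for i in range(9)}
    folds = crossval_partition(tkvs, k=3, seed=0)
    ordered = sorted(tkvs, key=tkvs.get)
    terciles = [set(ordered[0:3]), set(ordered[3:6]), set(ordered[6:9])]
    for f in folds:
        assert len(f) == 3
        assert all(len(set(f) & t) == 1 for t in terciles)


def test_crossval_rejects_bad_k():
    with pytest.raises(ValueError):
        crossval_partition({"a": 1.0, "b": 2.0}, k=1)
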