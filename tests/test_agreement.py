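import numpy as np
import pytest

from ihcquant.agreement import (
    DegenerateAgreementError,
    agreement_report,
    cohens_kappa,
    contingency_table,
    format_report,
    landis_koch,
    quadratic_weighted_kappa,
    spearman,
)


def pairs_from_table(table):
    a, b = [], []
    for i, row in enumerate(table):
        for j, count in enumerate(row):
            a += [i] * count
            b += [j] * count
    return np.array(a), np.array(b)


# -- independent brute-force oracles ---------------------------------------

def brute_kappa(a, b, cats):
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    pe = sum(
        (sum(x == c for x in a) / n) * (sum(y == c for y in b) / n) for c in cats
    )
    return (po - pe) / (1 - pe)


def brute_weighted_kappa(a, b, cats):
    k = len(cats)
    n = len(a)
    idx = {c: i for i, c in enumerate(cats)}
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = 1 - (i - j) ** 2 / (k - 1) ** 2
            o = sum(1 for x, y in zip(a, b) if idx[x] == i and idx[y] == j)
            e = (
                sum(1 for x in a if idx[x] == i)
                * sum(1 for y in b if idx[y] == j)
                / n
            )
            num += w * (o - e)
            den += w * e
    return num / (n - den)


def brute_spearman(a, b):
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return np.array(r)

    ra, rb = ranks(list(a)), ranks(list(b))
    return float(np.corrcoef(ra, rb)[0, 1])


class TestCohensKappa:
    def test_perfect_diagonal(self):
        a, b = pairs_from_table([[10, 0], [0, 10]])
        kappa, se, ci = cohens_kappa(a, b)
        assert kappa == pytest.approx(1.0)

    def test_chance_level(self):
        a, b = pairs_from_table([[25, 25], [25, 25]])
        assert cohens_kappa(a, b)[0] == pytest.approx(0.0)

    def test_worked_example(self):
        # table [[20,5],[10,15]]: p_o = 0.7, p_e = 0.5 -> kappa 0.4
        a, b = pairs_from_table([[20, 5], [10, 15]])
        assert cohens_kappa(a, b)[0] == pytest.approx(0.4)

    def test_degenerate_identical_constant(self):
        assert cohens_kappa([2] * 5, [2] * 5)[0] == 1.0

    def test_constant_raters_on_different_categories(self):
        # marginals are point masses on different categories: p_e = 0, kappa = 0
        assert cohens_kappa([0] * 5, [1] * 5)[0] == pytest.approx(0.0)

    def test_ci_brackets_kappa(self, rng):
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 3, 60)
        kappa, se, (lo, hi) = cohens_kappa(a, b, categories=[0, 1, 2])
        assert lo <= kappa <= hi
        assert se > 0


class TestWeightedKappa:
    def test_identical_ratings(self):
        a = np.arange(9) % 9
        assert quadratic_weighted_kappa(a, a, categories=list(range(9)))[0] == pytest.approx(1.0)

    def test_zero_weight_at_maximal_disagreement(self):
        k = 9
        i, j = 0, 8
        w = 1 - (i - j) ** 2 / (k - 1) ** 2
        assert w == 0.0

    def test_matches_brute_force(self, rng):
        cats = list(range(9))
        a = rng.integers(0, 9, 50)
        b = rng.integers(0, 9, 50)
        ours = quadratic_weighted_kappa(a, b, cats)[0]
        assert ours == pytest.approx(brute_weighted_kappa(a, b, cats), abs=1e-12)

    def test_binary_equals_unweighted(self, rng):
        a = rng.integers(0, 2, 80)
        b = rng.integers(0, 2, 80)
        kw = quadratic_weighted_kappa(a, b, [0, 1])[0]
        k = cohens_kappa(a, b, [0, 1])[0]
        assert kw == pytest.approx(k, abs=1e-12)

    def test_se_matches_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        a = rng.integers(0, 5, 60)
        b = rng.integers(0, 5, 60)
        table, _ = contingency_table(a, b, list(range(5)))
        res = sm_kappa(table, wt="quadratic", return_results=True)
        kw, se = quadratic_weighted_kappa(a, b, list(range(5)))
        assert kw == pytest.approx(res.kappa, abs=1e-12)
        assert se == pytest.approx(np.sqrt(res.var_kappa), abs=1e-10)

    def test_degenerate_single_category(self):
        with pytest.raises(DegenerateAgreementError):
            quadratic_weighted_kappa([0, 0], [0, 0], categories=[0])


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10)
        assert spearman(x, x * 2 + 1)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_brute_force(self, rng):
        a = rng.integers(0, 4, 30)
        b = rng.integers(0, 4, 30)
        rho, p, ci = spearman(a, b)
        assert rho == pytest.approx(brute_spearman(a, b), abs=1e-12)

    def test_matches_scipy(self, rng):
        from scipy.stats import spearmanr

        a = rng.integers(0, 9, 40)
        b = rng.integers(0, 9, 40)
        rho, p, _ = spearman(a, b)
        ref = spearmanr(a, b)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateAgreementError):
            spearman([1, 1, 1], [0, 1, 2])


class TestLandisKoch:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (-0.5, "poor"),
            (0.138, "slight"),
            (0.3, "fair"),
            (0.485, "moderate"),
            (0.7, "substantial"),
            (0.859, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_bands(self, kappa, label):
        assert landis_koch(kappa) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            landis_koch(1.5)


class TestSymmetry:
    def test_swapping_raters_preserves_kappas(self, rng):
        a = rng.integers(0, 5, 40)
        b = rng.integers(0, 5, 40)
        cats = list(range(5))
        assert cohens_kappa(a, b, cats)[0] == pytest.approx(cohens_kappa(b, a, cats)[0], abs=1e-12)
        assert quadratic_weighted_kappa(a, b, cats)[0] == pytest.approx(
            quadratic_weighted_kappa(b, a, cats)[0], abs=1e-12
        )


def test_report_assembly_and_formatting(rng):
    a = rng.integers(0, 9, 50)
    b = np.where(rng.random(50) < 0.8, a, rng.integers(0, 9, 50))
    report = agreement_report(a, b, categories=list(range(9)))
    assert -1 <= report.kappa <= 1
    assert report.ci95[0] <= report.kappa <= report.ci95[1]
    text = format_report(report)
    assert "Cohen's kappa" in text and "weighted kappa" in text and "rho" in text


def test_small_p_floored_in_text():
    x = np.arange(20)
    report = agreement_report(x, x, categories=list(range(20)))
    assert "< 0.0001" in format_report(report)
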