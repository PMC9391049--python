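import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fenflux import (
    LefseEffectSize,
    MarkerEvidence,
    bray_curtis,
    identify_stimulated,
    kruskal_wallis,
    ra_ratio,
    root_abundance_screen,
    shared_phylotype_match,
    stimulation_call,
    wilcoxon_one_sided,
)
from fenflux.community import CommunityError, ra_ratios

from conftest import make_phylotype_table


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_constant_groups(self):
        h, p = kruskal_wallis([[3, 3, 3], [3, 3, 3]])
        assert h == 0.0 and p == 1.0

    def test_fully_separated_triplicates(self):
        """H from the rank-sum formula by hand: perfect separation of 3 vs 3
        gives H = 12/42*(6^2/3+15^2/3) - 21 = 27/7; chi-square p ~ 0.0495."""
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27.0 / 7.0, rel=1e-12)
        assert p == pytest.approx(0.0495, abs=5e-4)

    def test_exact_permutation_mode(self):
        """All 20 assignments of 6 ranks into two triples: the observed H is
        attained by 2 of them (the two perfect separations), so p = 0.1."""
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]], exact=True)
        assert h == pytest.approx(27.0 / 7.0)
        assert p == pytest.approx(2.0 / 20.0)

    def test_rank_invariance_within_groups(self):
        h1, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        h2, _ = kruskal_wallis([[3, 1, 2], [6, 4, 5]])
        assert h1 == h2

    def test_monotone_transform_invariance(self):
        h1, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        h2, _ = kruskal_wallis([[10, 400, 90000], [1e6, 2e6, 3e6]])
        assert h1 == pytest.approx(h2)

    def test_empty_group_rejected(self):
        with pytest.raises(CommunityError):
            kruskal_wallis([[1, 2], []])

    def test_exact_mode_two_groups_only(self):
        with pytest.raises(NotImplementedError):
            kruskal_wallis([[1], [2], [3]], exact=True)

    def test_matches_scipy_on_tied_data(self):
        from scipy import stats

        g1, g2 = [1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 3.0, 9.0]
        h, p = kruskal_wallis([g1, g2])
        ref = stats.kruskal(g1, g2)
        assert h == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


# ---------------------------------------------------------------------------
# LEfSe-style effect size
# ---------------------------------------------------------------------------

def reference_lefse(X, y, positive, n_boot=30, frac=2 / 3, alpha=0.05, seed=0):
    """Straight-line reference implementation of the pinned effect-size
    recipe: KW screen, bootstrap subsampling, Fisher direction via explicit
    matrix inverse, effect = mean(|raw diff|, |w_i| * projected gap)."""
    from scipy import stats

    X = np.asarray(X, dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    X = X / totals * 1e6
    y = np.asarray(y)
    classes = np.unique(y)
    neg = classes[classes != positive][0]
    ip = np.flatnonzero(y == positive)
    ineg = np.flatnonzero(y == neg)
    n_feat = X.shape[1]
    keep = []
    for j in range(n_feat):
        a, b = X[ip, j], X[ineg, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = stats.kruskal(a, b).pvalue
        if p <= alpha:
            keep.append(j)
    scores = np.full(n_feat, np.nan)
    if not keep:
        return scores
    keep = np.array(keep)
    rng = np.random.default_rng(seed)
    npos = max(2, math.ceil(frac * ip.size))
    nneg = max(2, math.ceil(frac * ineg.size))
    acc = np.zeros(keep.size)
    for _ in range(n_boot):
        sp = rng.choice(ip, size=npos, replace=False)
        sn = rng.choice(ineg, size=nneg, replace=False)
        xp, xn = X[sp][:, keep], X[sn][:, keep]
        m1, m2 = xp.mean(axis=0), xn.mean(axis=0)
        gm = np.abs(m1 - m2)
        cen = np.vstack([xp - m1, xn - m2])
        sw = cen.T @ cen / max(1, cen.shape[0] - 2)
        ridge = 1e-6 * (np.trace(sw) / sw.shape[0] + 1.0)
        w = np.linalg.inv(sw + ridge * np.eye(sw.shape[0])) @ (m1 - m2)
        if np.linalg.norm(w) == 0:
            acc += gm / 2
            continue
        wu = w / np.linalg.norm(w)
        ld = abs(wu @ (m1 - m2))
        acc += (gm + np.abs(wu) * ld) / 2
    mean_eff = acc / n_boot
    sign = np.sign(X[ip][:, keep].mean(axis=0) - X[ineg][:, keep].mean(axis=0))
    sign[sign == 0] = 1.0
    scores[keep] = sign * np.log10(1 + np.abs(mean_eff))
    return scores


class TestLefseEffectSize:
    def _fit(self, X, y, **kw):
        kw.setdefault("random_state", 7)
        kw.setdefault("positive_class", "h2")
        return LefseEffectSize(**kw).fit(X, y)

    def test_spiked_feature_scores_above_three(self):
        # 1% vs 10% of a 1e6-scaled community, noise-free elsewhere
        X = np.array(
            [[10_000, 990_000], [10_000, 990_000], [10_100, 989_900],
             [100_000, 900_000], [100_000, 900_000], [100_100, 899_900]],
            dtype=float,
        )
        y = np.array(["un", "un", "un", "h2", "h2", "h2"])
        est = self._fit(X, y)
        assert est.lda_score_[0] >= 3.0
        assert est.lda_score_[1] < 0  # complement is depleted in the h2 class

    def test_flat_feature_fails_the_screen(self):
        # already on the analysis scale; feature 0 identical in both classes
        X = np.array(
            [[5.0, 100.0], [5.0, 110.0], [5.0, 90.0],
             [5.0, 500.0], [5.0, 520.0], [5.0, 480.0]]
        )
        y = np.array(["un"] * 3 + ["h2"] * 3)
        est = self._fit(X, y, scale=None)
        assert math.isnan(est.lda_score_[0])

    def test_deterministic_given_seed(self, two_class_table):
        ra = two_class_table.relative_abundance().T.to_numpy()
        y = np.array(["un"] * 3 + ["h2"] * 3)
        s1 = self._fit(ra, y, random_state=11).lda_score_
        s2 = self._fit(ra, y, random_state=11).lda_score_
        np.testing.assert_array_equal(s1, s2)

    def test_stable_across_seeds_for_separated_features(self, two_class_table):
        ra = two_class_table.relative_abundance().T.to_numpy()
        y = np.array(["un"] * 3 + ["h2"] * 3)
        s1 = self._fit(ra, y, random_state=1).lda_score_[0]
        s2 = self._fit(ra, y, random_state=2).lda_score_[0]
        assert abs(s1 - s2) < 0.1

    def test_matches_reference_implementation_on_random_tables(self):
        """20 random 3v3 tables, scores equal the independently coded recipe."""
        rng = np.random.default_rng(123)
        for trial in range(20):
            X = rng.lognormal(3.0, 1.5, size=(6, 12))
            spike = rng.integers(0, 12)
            X[3:, spike] *= rng.uniform(3.0, 20.0)
            y = np.array(["un"] * 3 + ["h2"] * 3)
            est = self._fit(X, y, random_state=trial)
            ref = reference_lefse(X, y, positive="h2", seed=trial)
            np.testing.assert_allclose(est.lda_score_, ref, rtol=1e-8, equal_nan=True)

    def test_effect_scales_with_feature_magnitude(self):
        """Doubling one feature's abundance in both classes doubles its
        (pre-log) effect size when per-sample rescaling is disabled."""
        X = np.array(
            [[100.0, 50.0], [110.0, 55.0], [90.0, 45.0],
             [400.0, 48.0], [420.0, 52.0], [380.0, 50.0]]
        )
        y = np.array(["un"] * 3 + ["h2"] * 3)
        base = self._fit(X, y, scale=None, random_state=5).effect_size_[0]
        X2 = X.copy()
        X2[:, 0] *= 2.0
        doubled = self._fit(X2, y, scale=None, random_state=5).effect_size_[0]
        assert doubled == pytest.approx(2.0 * base, rel=1e-6)

    def test_requires_two_samples_per_class(self):
        X = np.ones((3, 4))
        with pytest.raises(CommunityError):
            self._fit(X, np.array(["a", "b", "b"]), positive_class="b")

    def test_seed_is_required(self):
        X = np.ones((4, 2))
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(CommunityError, match="random_state"):
            LefseEffectSize(positive_class="b").fit(X, y)

    def test_sklearn_params_round_trip(self):
        est = LefseEffectSize(n_boot=10, random_state=3)
        assert est.get_params()["n_boot"] == 10
        est.set_params(n_boot=50)
        assert est.n_boot == 50


# ---------------------------------------------------------------------------
# Ratios and the stimulation rule
# ---------------------------------------------------------------------------

class TestRaRatio:
    def _table(self, su, sh):
        counts = {
            "SU1": [su, 1000 - su], "SU2": [su, 1000 - su], "SU3": [su, 1000 - su],
            "SH1": [sh, 1000 - sh], "SH2": [sh, 1000 - sh], "SH3": [sh, 1000 - sh],
        }
        treatments = {s: s[:2] for s in counts}
        return make_phylotype_table(counts, treatments)

    def test_twofold(self):
        assert ra_ratio(self._table(10, 20), "PT0", "rRNA", ["SH"], ["SU"]) == (
            pytest.approx(2.0)
        )

    def test_equal_means(self):
        assert ra_ratio(self._table(10, 10), "PT0", "rRNA", ["SH"], ["SU"]) == (
            pytest.approx(1.0)
        )

    def test_absent_in_control_is_infinite(self):
        assert math.isinf(ra_ratio(self._table(0, 5), "PT0", "rRNA", ["SH"], ["SU"]))

    def test_absent_everywhere_is_undefined(self):
        assert math.isnan(ra_ratio(self._table(0, 0), "PT0", "rRNA", ["SH"], ["SU"]))

    def test_vectorised_matches_scalar(self):
        t = self._table(10, 30)
        series = ra_ratios(t, "rRNA", ["SH"], ["SU"])
        assert series["PT0"] == ra_ratio(t, "PT0", "rRNA", ["SH"], ["SU"])


class TestStimulationCall:
    def test_passes_on_one_marker_only(self):
        """An rRNA-level hit with a failing gene-level ratio still counts."""
        rec = stimulation_call(
            "C21",
            {
                "rRNA": MarkerEvidence(kw_p=0.04, lda_score=3.09, ra_ratio=2.3),
                "rRNA_gene": MarkerEvidence(kw_p=1.0, lda_score=None, ra_ratio=0.9),
            },
        )
        assert rec.stimulated
        assert rec.passes == {"rRNA": True, "rRNA_gene": False}

    def test_ratio_criterion_vetoes_discriminant_hit(self):
        """High LDA score with a ratio below 2 is not 'stimulated'."""
        rec = stimulation_call(
            "C15",
            {
                "rRNA": MarkerEvidence(kw_p=0.04, lda_score=3.76, ra_ratio=1.3),
                "rRNA_gene": MarkerEvidence(kw_p=1.0, lda_score=None, ra_ratio=1.0),
            },
        )
        assert not rec.stimulated

    def test_boundaries_are_inclusive(self):
        rec = stimulation_call(
            "X", {"rRNA": MarkerEvidence(kw_p=0.05, lda_score=3.0, ra_ratio=2.0)}
        )
        assert rec.stimulated

    def test_infinite_ratio_passes(self):
        rec = stimulation_call(
            "C186",
            {"rRNA_gene": MarkerEvidence(kw_p=0.03, lda_score=3.18,
                                         ra_ratio=math.inf)},
        )
        assert rec.stimulated

    def test_criteria_must_align_within_a_marker(self):
        """A gene-level ratio cannot rescue an rRNA-level discriminant hit."""
        rec = stimulation_call(
            "X",
            {
                "rRNA": MarkerEvidence(kw_p=0.01, lda_score=4.0, ra_ratio=1.2),
                "rRNA_gene": MarkerEvidence(kw_p=0.8, lda_score=None, ra_ratio=9.0),
            },
        )
        assert not rec.stimulated

    def test_empty_evidence_rejected(self):
        with pytest.raises(CommunityError):
            stimulation_call("X", {})


class TestIdentifyStimulated:
    def test_spiked_feature_flagged(self, two_class_table):
        out = identify_stimulated(two_class_table, ["SH"], ["SU"], seed=5)
        assert bool(out.loc["PT0", "stimulated"])
        assert out["stimulated"].sum() == 1


class TestRootScreen:
    def test_disjunctive_thresholds(self):
        counts = {
            "RUC1_rna": [94, 9906], "RUC1_gene": [40, 9960],
            "RHM1_rna": [936, 9064], "RHM1_gene": [50, 9950],
        }
        markers = {
            "RUC1_rna": "rRNA", "RHM1_rna": "rRNA",
            "RUC1_gene": "rRNA_gene", "RHM1_gene": "rRNA_gene",
        }
        treatments = {"RUC1_rna": "RUC", "RUC1_gene": "RUC",
                      "RHM1_rna": "RHM", "RHM1_gene": "RHM"}
        t = make_phylotype_table(counts, treatments, markers)
        # PT0: 9.36% rRNA in one RHM replicate -> retained
        assert "PT0" in root_abundance_screen(t, ["RUC", "RHM"])
        # restricted to RUC only: max 0.94% rRNA (<1%) and 0.4% gene -> excluded
        assert "PT0" not in root_abundance_screen(t, ["RUC"])

    def test_gene_boundary_inclusive(self):
        counts = {"R1_gene": [5, 995]}
        t = make_phylotype_table(
            counts, {"R1_gene": "RUM"}, {"R1_gene": "rRNA_gene"}
        )
        assert "PT0" in root_abundance_screen(t, ["RUM"])

    def test_no_samples_rejected(self):
        counts = {"S1": [1, 2]}
        t = make_phylotype_table(counts, {"S1": "SU"})
        with pytest.raises(CommunityError):
            root_abundance_screen(t, ["RUM"])


# ---------------------------------------------------------------------------
# Wilcoxon rank sum
# ---------------------------------------------------------------------------

def enumerate_one_sided_p(x, y):
    """Brute-force enumeration oracle with midranks."""
    from scipy import stats

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[: len(x)].sum()
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), len(x)):
        total += 1
        if ranks[list(combo)].sum() >= w_obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxonOneSided:
    def test_perfect_separation_is_one_twentieth(self):
        assert wilcoxon_one_sided([4, 5, 6], [1, 2, 3]) == pytest.approx(0.05)

    def test_identical_samples_not_significant(self):
        assert wilcoxon_one_sided([1, 2, 3], [1, 2, 3]) >= 0.5

    def test_all_tied_returns_one(self):
        assert wilcoxon_one_sided([2, 2], [2, 2]) == 1.0

    @pytest.mark.parametrize(
        "x,y",
        [([3, 9, 4], [2, 8, 1]), ([1.5, 2.5], [1.5, 3.5]),
         ([5, 5, 7, 1], [4, 5, 2])],
    )
    def test_matches_enumeration_oracle(self, x, y):
        assert wilcoxon_one_sided(x, y) == pytest.approx(
            enumerate_one_sided_p(np.array(x, float), np.array(y, float))
        )

    def test_reversed_alternative_consistency(self):
        """p(x>y) + p(y>x) = 1 + P(tie of the rank sum), checked against the
        enumeration on tie-free data."""
        x, y = [3.0, 9.0, 4.0], [2.0, 8.0, 1.0]
        p_fwd = wilcoxon_one_sided(x, y)
        p_rev = wilcoxon_one_sided(y, x)
        # point mass at the observed rank sum, from the same enumeration
        from scipy import stats

        ranks = stats.rankdata(np.concatenate([x, y]))
        w_obs = ranks[:3].sum()
        mass = sum(
            1
            for c in itertools.combinations(range(6), 3)
            if abs(ranks[list(c)].sum() - w_obs) < 1e-12
        ) / 20
        assert p_fwd + p_rev == pytest.approx(1.0 + mass)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 1.0, 12)
        y = rng.normal(0.0, 1.0, 12)
        p = wilcoxon_one_sided(x, y)
        assert 0.0 < p < 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(CommunityError):
            wilcoxon_one_sided([], [1.0])


# ---------------------------------------------------------------------------
# Bray-Curtis and sequence matching
# ---------------------------------------------------------------------------

class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        m = pd.DataFrame([[0.2, 0.8], [0.2, 0.8]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == 0.0

    def test_disjoint_supports_distance_one(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        m = pd.DataFrame([[2.0, 2.0], [1.0, 3.0]], index=["a", "b"])
        # sum|x-y| / sum(x+y) = (1+1)/8 = 0.25
        assert bray_curtis(m).loc["a", "b"] == pytest.approx(0.25)

    def test_metric_properties_on_random_input(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.uniform(0, 1, size=(6, 20)))
        d = bray_curtis(m)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d.to_numpy() >= 0) & (d.to_numpy() <= 1)).all()

    def test_all_zero_sample_flagged(self):
        m = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["a", "b"])
        with pytest.warns(UserWarning, match="all-zero"):
            d = bray_curtis(m)
        assert math.isnan(d.loc["a", "b"])

    def test_negative_input_rejected(self):
        with pytest.raises(CommunityError):
            bray_curtis(pd.DataFrame([[-1.0, 1.0]]))


class TestSharedPhylotypeMatch:
    def test_exact_and_case_insensitive_matches(self):
        pairs = shared_phylotype_match(
            {"C50": "ACGTACGT", "C15": "ACGTACGA"},
            {"M7": "acgtacgt", "M44": "TTTTACGT"},
        )
        assert pairs == [("C50", "M7")]

    def test_single_substitution_breaks_match(self):
        assert shared_phylotype_match({"a": "ACGT"}, {"b": "ACGA"}) == []

    def test_length_mismatch_breaks_match(self):
        assert shared_phylotype_match({"a": "ACGT"}, {"b": "ACGTA"}) == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(CommunityError, match="empty"):
            shared_phylotype_match({"a": ""}, {"b": "ACGT"})
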