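"""F/M expression ratios, the two-fold max-expression-tissue rule, and
pseudogene:functional ratios with bootstrap CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neopseudo.events import Category
from neopseudo.expression import (TissueProfile, compare_fm_by_category,
                                  fm_ratio, max_expression_tissue,
                                  pseudo_functional_ratio_by_tissue,
                                  upper_quartile_normalizer)
from neopseudo.io import ExpressionMatrix

from conftest import make_expr


def profile(gene_id="g1", **samples):
    """TissueProfile from tissue_sex=fpkm kwargs, e.g. head_F=10."""
    fpkm = {}
    for key, v in samples.items():
        tissue, sex = key.rsplit("_", 1)
        fpkm[(tissue, sex)] = v
    per_tissue = {}
    for (t, _s), v in fpkm.items():
        per_tissue.setdefault(t, []).append(v)
    cfpkm = {t: float(np.mean(vs)) for t, vs in per_tissue.items()}
    return TissueProfile(gene_id, fpkm, cfpkm)


class TestFmRatio:
    def test_simple_ratio(self):
        assert fm_ratio(profile(head_F=10, head_M=5), "head") == 2.0

    def test_silent_gene_excluded(self):
        assert fm_ratio(profile(head_F=0, head_M=0), "head") is None

    def test_pseudocount(self):
        p = profile(head_F=0, head_M=8)
        assert fm_ratio(p, "head", pseudocount=0.1) == pytest.approx(0.1 / 8.1)

    def test_gonad_pairs_ovary_with_testis(self):
        p = profile(ovary_F=30, testis_M=10)
        assert fm_ratio(p, "gonad") == 3.0

    def test_missing_tissue_errors(self):
        with pytest.raises(ValueError, match="thorax"):
            fm_ratio(profile(head_F=1, head_M=1), "thorax")

    def test_floor_uses_the_larger_sex(self):
        assert fm_ratio(profile(head_F=0.2, head_M=4), "head") == 0.05
        assert fm_ratio(profile(head_F=0.2, head_M=0.9), "head") is None


class TestMaxExpressionTissue:
    def test_twofold_argmax(self):
        assert max_expression_tissue({"testis": 10, "head": 4, "ovary": 1}) == "testis"

    def test_below_twofold_is_none(self):
        assert max_expression_tissue({"testis": 10, "head": 6}) is None

    def test_all_zero_is_none(self):
        assert max_expression_tissue({"testis": 0, "head": 0}) is None

    def test_scale_invariance(self):
        vals = {"testis": 8.0, "head": 3.0, "ovary": 1.0}
        scaled = {t: 7.3 * v for t, v in vals.items()}
        assert max_expression_tissue(vals) == max_expression_tissue(scaled)

    def test_single_tissue_errors(self):
        with pytest.raises(ValueError):
            max_expression_tissue({"head": 5})

    @given(st.dictionaries(st.sampled_from(["a", "b", "c", "d"]),
                           st.floats(0, 100), min_size=2),
           st.floats(0.01, 1000))
    @settings(derandomize=True, max_examples=60)
    def test_scale_invariance_property(self, cfpkm, k):
        scaled = {t: k * v for t, v in cfpkm.items()}
        assert max_expression_tissue(cfpkm) == max_expression_tissue(scaled)


class TestCompareFmByCategory:
    def _inputs(self, male_biased_cat=Category.XP_YF, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        profiles, categories = {}, {}
        for i, cat in enumerate([Category.XF_YF, Category.XF_YP,
                                 Category.XP_YF, Category.XP_YP] * 30):
            gid = f"g{i}"
            f, m = 10 * rng.lognormal(0, 0.3), 10 * rng.lognormal(0, 0.3)
            if cat is male_biased_cat:
                f /= 8
            profiles[gid] = profile(gid, ovary_F=f, testis_M=m)
            categories[gid] = cat
        return profiles, categories

    def test_planted_male_bias_gives_lowest_median(self):
        profiles, categories = self._inputs()
        res = compare_fm_by_category(profiles, categories, "gonad",
                                     reps=200, seed=1)
        medians = {c: s["median"] for c, s in res["summary"].items()}
        assert min(medians, key=medians.get) is Category.XP_YF
        key = tuple(sorted([Category.XP_YF, Category.XF_YF],
                           key=lambda c: c.value))
        assert res["pairwise_p"][key] <= 0.05

    def test_identical_expression_equal_medians(self):
        profiles = {f"g{i}": profile(f"g{i}", ovary_F=10, testis_M=10)
                    for i in range(40)}
        categories = {f"g{i}": list(Category)[i % 4] for i in range(40)}
        res = compare_fm_by_category(profiles, categories, "gonad",
                                     reps=200, seed=1)
        assert all(s["median"] == 1.0 for s in res["summary"].values())
        assert all(p > 0.5 for p in res["pairwise_p"].values())

    def test_order_invariance_with_fixed_seed(self):
        profiles, categories = self._inputs()
        res1 = compare_fm_by_category(profiles, categories, "gonad",
                                      reps=200, seed=9)
        rev_p = dict(reversed(list(profiles.items())))
        res2 = compare_fm_by_category(rev_p, categories, "gonad",
                                      reps=200, seed=9)
        assert res1["pairwise_p"] == res2["pairwise_p"]

    def test_unassigned_genes_dropped(self):
        profiles = {"g1": profile("g1", ovary_F=5, testis_M=5)}
        res = compare_fm_by_category(profiles, {"g1": Category.UNASSIGNED},
                                     "gonad")
        assert res["summary"] == {}


class TestPseudoFunctionalRatio:
    def test_point_ratio(self):
        is_pseudo = {f"p{i}": True for i in range(10)}
        is_pseudo.update({f"f{i}": False for i in range(40)})
        tissue = {g: "testis" for g in is_pseudo}
        res = pseudo_functional_ratio_by_tissue(is_pseudo, tissue, reps=200,
                                                seed=1)
        assert res["testis"]["ratio"] == 0.25
        assert res["testis"]["ci_low"] <= 0.25 <= res["testis"]["ci_high"]

    def test_zero_pseudo(self):
        is_pseudo = {f"f{i}": False for i in range(5)}
        res = pseudo_functional_ratio_by_tissue(
            is_pseudo, {g: "head" for g in is_pseudo}, reps=100, seed=1)
        assert res["head"]["ratio"] == 0 and res["head"]["ci_low"] == 0

    def test_zero_functional_reports_inf_without_ci(self):
        is_pseudo = {"p1": True, "p2": True}
        res = pseudo_functional_ratio_by_tissue(
            is_pseudo, {"p1": "head", "p2": "head"}, reps=100, seed=1)
        assert res["head"]["ratio"] == float("inf")
        assert res["head"]["ci_low"] is None

    def test_none_tissue_genes_excluded(self):
        is_pseudo = {"a": True, "b": False}
        res = pseudo_functional_ratio_by_tissue(
            is_pseudo, {"a": None, "b": "head"}, reps=100, seed=1)
        assert "head" in res and res["head"]["n_pseudo"] == 0

    def test_planted_testis_effect_recovered(self):
        rng = np.random.default_rng(8)
        is_pseudo, tissue = {}, {}
        for i in range(200):
            gid = f"g{i}"
            t = "testis" if i % 2 else "head"
            p_pseudo = 0.6 if t == "testis" else 0.1
            is_pseudo[gid] = bool(rng.random() < p_pseudo)
            tissue[gid] = t
        res = pseudo_functional_ratio_by_tissue(is_pseudo, tissue, reps=200,
                                                seed=2)
        assert res["testis"]["ratio"] > res["head"]["ratio"]

    def test_ci_coverage_of_true_ratio_under_null(self):
        """Percentile CIs contain the generating ratio in >=95% of null
        datasets (conservative bootstrap coverage at n = 200)."""
        rng = np.random.default_rng(42)
        true_p = 0.2
        covered = 0
        n_trials = 60
        for trial in range(n_trials):
            flags = rng.random(200) < true_p
            is_pseudo = {f"g{i}": bool(f) for i, f in enumerate(flags)}
            tissue = {g: "head" for g in is_pseudo}
            res = pseudo_functional_ratio_by_tissue(is_pseudo, tissue,
                                                    reps=300, seed=trial)
            true_ratio = true_p / (1 - true_p)
            if res["head"]["ci_low"] <= true_ratio <= res["head"]["ci_high"]:
                covered += 1
        assert covered / n_trials >= 0.9


def test_upper_quartile_normalizer_preserves_argmax():
    expr = ExpressionMatrix()
    rng = np.random.default_rng(0)
    for i in range(50):
        for t in ("head", "testis"):
            expr.add(f"g{i}", t, "M", float(rng.lognormal(1, 0.5)))
    norm = upper_quartile_normalizer(expr)
    assert norm("head", 10.0) > 0
    # within-tissue scaling leaves within-tissue ordering intact
    assert norm("head", 10.0) > norm("head", 5.0)
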