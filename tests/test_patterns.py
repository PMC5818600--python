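import dataclasses
from collections import Counter

import numpy as np
import pytest
from scipy import stats

import metabomoa as mm
from metabomoa.core_data import ValidationError
from metabomoa.patterns import Pattern, ProfileDatabase, _youden

from conftest import make_profile

MIDS = [f"met_{i:02d}" for i in range(1, 11)]


def _profile_from_t(treatment, t_values):
    p = make_profile(treatment, {}, MIDS[: len(t_values)])
    p.data["t_value"] = np.asarray(t_values, dtype=float)
    return p


class TestProfileSimilarity:
    def test_self_similarity_is_one(self):
        a = _profile_from_t("a", [1.0, -2.0, 3.0, 0.5])
        assert mm.profile_similarity(a, a).r == pytest.approx(1.0)

    def test_negated_profile_is_minus_one(self):
        a = _profile_from_t("a", [1.0, -2.0, 3.0, 0.5])
        b = _profile_from_t("b", [-1.0, 2.0, -3.0, -0.5])
        assert mm.profile_similarity(a, b).r == pytest.approx(-1.0)

    def test_against_pearson_oracle(self):
        ta, tb = [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 5.0, 9.0]
        r = mm.profile_similarity(_profile_from_t("a", ta), _profile_from_t("b", tb)).r
        r_oracle, _ = stats.pearsonr(ta, tb)
        assert r == pytest.approx(r_oracle, rel=1e-12)

    def test_too_few_shared_metabolites_is_an_error(self):
        a = _profile_from_t("a", [1.0, 2.0])
        b = _profile_from_t("b", [1.0, 2.0])
        with pytest.raises(ValidationError, match="shared"):
            mm.profile_similarity(a, b)

    def test_degenerate_metabolites_excluded(self):
        a = _profile_from_t("a", [1.0, 2.0, 3.0, 4.0, 5.0])
        b = _profile_from_t("b", [1.0, 2.0, 3.0, 4.0, -50.0])
        b.data.loc["met_05", "degenerate"] = True
        res = mm.profile_similarity(a, b)
        assert res.n_shared == 4
        assert res.r == pytest.approx(1.0)

    def test_metabolite_permutation_invariance(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=8)
        u = rng.normal(size=8)
        a, b = _profile_from_t("a", t), _profile_from_t("b", u)
        perm = rng.permutation(8)
        ap = _profile_from_t("a", t[perm])
        bp = _profile_from_t("b", u[perm])
        assert mm.profile_similarity(a, b).r == pytest.approx(
            mm.profile_similarity(ap, bp).r
        )


class TestPWCRank:
    def test_exact_copy_ranks_first_with_unit_r(self):
        rng = np.random.default_rng(1)
        query = _profile_from_t("query", rng.normal(size=10))
        twin = dataclasses.replace(query, treatment="twin", data=query.data.copy())
        others = [_profile_from_t(f"o{i}", rng.normal(size=10)) for i in range(5)]
        db = ProfileDatabase.from_profiles([query, twin] + others)
        ranking = mm.pwc_rank(query.key, db)
        key, r, rank = ranking.entries[0]
        assert key[0] == "twin" and rank == 1
        assert r == pytest.approx(1.0)

    def test_insertion_order_invariance(self):
        rng = np.random.default_rng(2)
        profs = [_profile_from_t(f"p{i}", rng.normal(size=10)) for i in range(6)]
        db_fwd = ProfileDatabase.from_profiles(profs)
        db_rev = ProfileDatabase.from_profiles(profs[::-1])
        r1 = mm.pwc_rank(profs[0].key, db_fwd)
        r2 = mm.pwc_rank(profs[0].key, db_rev)
        assert r1.entries == r2.entries

    def test_replicates_occupy_top_ranks(self):
        """Profiles of the same treatment re-measured in independent studies
        rank above unrelated treatments (scaled-down PWC reproducibility)."""
        cfg = mm.scenario_library("enzyme_inducers")
        profiles = []
        n_rep = 4
        for i, seed in enumerate(range(20, 20 + n_rep)):
            m, _ = mm.simulate_study(cfg, seed=seed)
            logged, _ = mm.normalize_pipeline(m)
            p = mm.welch_profile(logged, "inducer_ref_1", "HD")
            profiles.append(dataclasses.replace(p, treatment=f"rep_{i}"))
        m, _ = mm.simulate_study(cfg, seed=99)
        logged, _ = mm.normalize_pipeline(m)
        for t in ("proliferator_1", "untargeted_1"):
            profiles.append(mm.welch_profile(logged, t, "HD"))
        db = ProfileDatabase.from_profiles(profiles)
        ranking = mm.pwc_rank(profiles[0].key, db)
        top = [k[0] for k, _, _ in ranking.entries[: n_rep - 1]]
        assert all(t.startswith("rep_") for t in top)


class TestDeriveGeneralPattern:
    def test_concordant_everywhere_is_member(self):
        profs = [make_profile(f"t{i}", {"met_01": "up"}, MIDS) for i in range(4)]
        pattern = mm.derive_general_pattern(ProfileDatabase.from_profiles(profs))
        assert pattern.members == [("met_01", "up")]

    def test_discordant_directions_excluded(self):
        profs = [
            make_profile("t0", {"met_01": "up"}, MIDS),
            make_profile("t1", {"met_01": "up"}, MIDS),
            make_profile("t2", {"met_01": "down"}, MIDS),
            make_profile("t3", {"met_01": "down"}, MIDS),
        ]
        pattern = mm.derive_general_pattern(ProfileDatabase.from_profiles(profs))
        assert pattern.members == []

    def test_threshold_fraction_is_inclusive(self):
        profs = [
            make_profile(f"t{i}", {"met_01": "up"} if i < 3 else {}, MIDS) for i in range(4)
        ]
        db = ProfileDatabase.from_profiles(profs)
        assert mm.derive_general_pattern(db, min_fraction=0.75).members == [("met_01", "up")]
        assert mm.derive_general_pattern(db, min_fraction=0.80).members == []

    def test_recovers_planted_shared_signature(self):
        cfg = mm.scenario_library("general_toxicity")
        for seed in range(1, 6):
            m, truth = mm.simulate_study(cfg, seed=seed)
            logged, _ = mm.normalize_pipeline(m)
            db = ProfileDatabase.from_profiles(mm.profile_all(logged, doses=("HD",)))
            pattern = mm.derive_general_pattern(db)
            assert set(pattern.members) == truth.planted_set("general_toxicity")


class TestDeriveMoaPattern:
    def _db(self):
        sig = {"met_01": "up", "met_02": "down"}
        gen = {"met_09": "up"}
        profs = [
            make_profile(t, {**sig, **gen}, MIDS) for t in ("r1", "r2", "r3", "pos")
        ] + [make_profile("neg", gen, MIDS)]
        labels = {"r1": "moa", "r2": "moa", "r3": "moa", "pos": "moa", "neg": "other"}
        return ProfileDatabase.from_profiles(profs, moa_labels=labels)

    def test_intersection_of_references(self):
        general = Pattern("general_toxicity", "general_toxicity", [("met_09", "up")])
        pattern = mm.derive_moa_pattern(self._db(), ["r1", "r2", "r3"], general)
        assert pattern.members == [("met_01", "up"), ("met_02", "down")]
        assert pattern.moa_label == "moa"

    def test_general_members_excluded_even_if_concordant(self):
        general = Pattern("general_toxicity", "general_toxicity", [("met_09", "up")])
        pattern = mm.derive_moa_pattern(self._db(), ["r1", "r2", "r3"], general)
        assert "met_09" not in pattern.member_ids

    def test_without_general_subtraction_shared_member_included(self):
        pattern = mm.derive_moa_pattern(self._db(), ["r1", "r2", "r3"], general=None, refine=False)
        assert "met_09" in pattern.member_ids

    def test_fewer_than_three_references_rejected(self):
        with pytest.raises(ValidationError, match="3"):
            mm.derive_moa_pattern(self._db(), ["r1", "r2"], None)


class TestMatchPattern:
    def test_zero_matches_gives_p_one(self):
        pattern = Pattern("p", "moa", [(m, "up") for m in MIDS[:4]])
        prof = make_profile("t", {}, MIDS)
        res = mm.match_pattern(pattern, prof)
        assert res.k_matched == 0
        assert res.match_p == 1.0
        assert not res.matched

    def test_full_match_closed_form(self):
        pattern = Pattern("p", "moa", [(m, "up") for m in MIDS[:4]])
        prof = make_profile("t", {m: "up" for m in MIDS[:4]}, MIDS)
        res = mm.match_pattern(pattern, prof, p0=0.025)
        assert res.k_matched == 4
        assert res.match_p == pytest.approx(0.025**4, rel=1e-9)
        assert res.matched

    def test_wrong_direction_counts_as_unmatched(self):
        pattern = Pattern("p", "moa", [("met_01", "up")])
        prof = make_profile("t", {"met_01": "down"}, MIDS)
        assert mm.match_pattern(pattern, prof).k_matched == 0

    def test_p_nonincreasing_in_k(self):
        pattern_ids = MIDS[:6]
        pattern = Pattern("p", "moa", [(m, "up") for m in pattern_ids])
        last = 1.1
        for k in range(7):
            prof = make_profile("t", {m: "up" for m in pattern_ids[:k]}, MIDS)
            p = mm.match_pattern(pattern, prof).match_p
            assert p <= last
            last = p

    def test_adding_unmatched_member_never_decreases_p(self):
        prof = make_profile("t", {"met_01": "up", "met_02": "up"}, MIDS)
        members = [("met_01", "up"), ("met_02", "up")]
        p_small = mm.match_pattern(Pattern("p", "m", members), prof).match_p
        p_big = mm.match_pattern(
            Pattern("p", "m", members + [("met_07", "up")]), prof
        ).match_p
        assert p_big >= p_small

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            mm.match_pattern(Pattern("p", "m", []), make_profile("t", {}, MIDS))


class TestRefinePattern:
    def test_perfect_candidate_returned_unchanged(self):
        db = TestDeriveMoaPattern()._db()
        candidate = Pattern("p", "moa", [("met_01", "up"), ("met_02", "down")])
        refined = mm.refine_pattern(candidate, db, reference_treatments=["r1", "r2", "r3"])
        assert refined.members == candidate.members

    def test_noise_member_that_breaks_sensitivity_is_removed(self):
        """A pure-noise member dilutes a small pattern below the match
        threshold for a same-MoA compound; exhaustive J evaluation shows
        removal is the best move, and the hill-climb takes it."""
        profs = [
            make_profile("pos", {"met_01": "up"}, MIDS),
            make_profile("neg", {}, MIDS),
        ]
        db = ProfileDatabase.from_profiles(profs, moa_labels={"pos": "moa", "neg": "other"})
        candidate = Pattern("p", "moa", [("met_01", "up"), ("met_08", "up")])
        alpha = 0.03  # k=1 of m=2: p=0.049 fails; k=1 of m=1: p=0.025 passes
        assert _youden(candidate, [db.get(("pos", "HD", "intracellular"))],
                       [db.get(("neg", "HD", "intracellular"))], alpha) == 0.0
        refined = mm.refine_pattern(candidate, db, match_alpha=alpha)
        assert refined.members == [("met_01", "up")]

    def test_refinement_never_decreases_youden_j(self, ei_study):
        db = ei_study["db"]
        cfg = ei_study["cfg"]
        candidate = mm.derive_moa_pattern(
            db, cfg.reference_treatments, cfg.general_pattern(), refine=False
        )
        positives = [p for p in db.hd_profiles()
                     if db.moa_labels[p.treatment] == candidate.moa_label
                     and p.treatment not in cfg.reference_treatments]
        negatives = [p for p in db.hd_profiles()
                     if db.moa_labels[p.treatment] != candidate.moa_label]
        j_before = _youden(candidate, positives, negatives, 0.05)
        refined = mm.refine_pattern(
            candidate, db, reference_treatments=cfg.reference_treatments
        )
        j_after = _youden(refined, positives, negatives, 0.05)
        assert j_after >= j_before

    def test_db_insertion_order_invariance(self):
        db = TestDeriveMoaPattern()._db()
        db_rev = ProfileDatabase.from_profiles(
            list(db.profiles.values())[::-1], moa_labels=db.moa_labels
        )
        candidate = Pattern("p", "moa", [("met_01", "up"), ("met_02", "down")])
        a = mm.refine_pattern(candidate, db, reference_treatments=["r1", "r2", "r3"])
        b = mm.refine_pattern(candidate, db_rev, reference_treatments=["r1", "r2", "r3"])
        assert a.members == b.members

    def test_unscoreable_candidate_returned_with_warning(self):
        profs = [make_profile("r1", {"met_01": "up"}, MIDS)]
        db = ProfileDatabase.from_profiles(profs, moa_labels={"r1": "moa"})
        candidate = Pattern("p", "moa", [("met_01", "up")])
        with pytest.warns(UserWarning, match="refinement skipped"):
            out = mm.refine_pattern(candidate, db, reference_treatments=["r1"])
        assert out.members == candidate.members


class TestEndToEndSelectivity:
    @pytest.mark.parametrize("scenario, moa", [
        ("enzyme_inducers", "enzyme_inducer"),
        ("peroxisome_proliferators", "peroxisome_proliferator"),
    ])
    def test_pattern_matches_only_its_own_moa(self, scenario, moa):
        cfg = mm.scenario_library(scenario)
        hits = misses = 0
        n_seeds = 5
        for seed in range(1, n_seeds + 1):
            m, _ = mm.simulate_study(cfg, seed=seed)
            logged, _ = mm.normalize_pipeline(m)
            db = mm.ProfileDatabase.from_profiles(
                mm.profile_all(logged, doses=("HD",)), moa_labels=cfg.moa_labels
            )
            pattern = mm.derive_moa_pattern(
                db, cfg.reference_treatments, cfg.general_pattern()
            )
            for p in db.hd_profiles():
                res = mm.match_pattern(pattern, p)
                same_moa = cfg.moa_labels[p.treatment] == moa
                if res.matched == same_moa:
                    hits += 1
                else:
                    misses += 1
        assert hits / (hits + misses) >= 0.9


class TestPatternIO:
    def test_json_round_trip(self, tmp_path):
        pattern = Pattern("p", "moa", [("met_01", "up"), ("met_02", "down")])
        path = tmp_path / "pattern.json"
        pattern.to_json(path)
        back = Pattern.from_json(path)
        assert back.name == pattern.name
        assert back.moa_label == pattern.moa_label
        assert back.members == pattern.members

    def test_duplicate_members_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            Pattern("p", "m", [("met_01", "up"), ("met_01", "down")])


def test_similarity_matrix_symmetric_unit_diagonal(ei_study):
    db = ei_study["db"]
    mat = mm.similarity_matrix(db)
    np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T, atol=1e-12)
    np.testing.assert_allclose(np.diag(mat.to_numpy()), 1.0)
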