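"""Synthetic cohort generator: determinism, ground truth, group structure."""

import numpy as np
import pytest

from ktom.agents import MODEL_NAMES
from ktom.cohort import (
    AS_PROFILE,
    NT_PROFILE,
    CohortSpec,
    GroupProfile,
    SymptomModel,
    draw_participant,
    generate_cohort,
    participants_frame,
    true_phenotypes,
)

_M = {name: i for i, name in enumerate(MODEL_NAMES)}


def point_mass_profile(model="Inf"):
    rep = np.zeros(8)
    rep[_M[model]] = 1.0
    return GroupProfile(
        social_base=rep,
        nonsocial_base=rep,
        switch_rate_repetition=0.0,
        switch_rate_framing=0.0,
        dirichlet_concentration=1e6,
    )


class TestDrawParticipant:
    def test_repertoires_are_simplices(self, rng):
        spec = CohortSpec(n_per_group=2, seed=0)
        for group in ("AS", "NT"):
            p = draw_participant(spec, group, rng)
            p.validate()
            assert p.repertoire_social.sum() == pytest.approx(1.0)
            assert p.repertoire_nonsocial.sum() == pytest.approx(1.0)

    def test_as_dominated_by_influence_learning(self, rng):
        spec = CohortSpec(n_per_group=2, seed=0)
        reps = [draw_participant(spec, "AS", rng) for _ in range(40)]
        inf_soc = np.mean([p.repertoire_social[_M["Inf"]] for p in reps])
        inf_ns = np.mean([p.repertoire_nonsocial[_M["Inf"]] for p in reps])
        assert inf_soc > 0.4 and inf_ns > 0.6
        assert np.mean([p.switch_rate_framing for p in reps]) < 0.5

    def test_nt_social_repertoire_recruits_mentalizers(self, rng):
        spec = CohortSpec(n_per_group=2, seed=0)
        reps = [draw_participant(spec, "NT", rng) for _ in range(40)]
        tom_soc = np.mean(
            [p.repertoire_social[[_M["1-ToM"], _M["2-ToM"]]].sum() for p in reps]
        )
        tom_ns = np.mean(
            [p.repertoire_nonsocial[[_M["1-ToM"], _M["2-ToM"]]].sum() for p in reps]
        )
        assert tom_soc > tom_ns + 0.3

    def test_noiseless_symptoms_are_exact_linear_function(self, rng):
        sm = SymptomModel(noise_sd=0.0, stereotyped_sd=0.0)
        spec = CohortSpec(n_per_group=2, seed=0, symptom_model=sm)
        p = draw_participant(spec, "AS", rng)
        expected = 10.0 - 3.0 * p.true_delta_k - 5.0 * p.true_delta_f
        assert p.symptom_social == round(max(0.0, expected))

    def test_symptom_model_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            SymptomModel(noise_sd=-1.0)


class TestTruePhenotypes:
    def test_point_mass_no_switching_gives_zero_deltas(self, rng):
        spec = CohortSpec(
            n_per_group=2, seed=0, as_profile=point_mass_profile("Inf")
        )
        p = draw_participant(spec, "AS", rng)
        dk, df = true_phenotypes(p)
        assert dk == pytest.approx(0.0, abs=1e-3)
        assert df == pytest.approx(0.0, abs=1e-3)

    def test_full_framing_switch_between_disjoint_repertoires(self, rng):
        soc = np.zeros(8)
        soc[_M["1-ToM"]] = 1.0
        ns = np.zeros(8)
        ns[_M["RL"]] = 1.0
        prof = GroupProfile(
            social_base=soc, nonsocial_base=ns, switch_rate_repetition=0.0,
            switch_rate_framing=1.0, dirichlet_concentration=1e6,
        )
        spec = CohortSpec(n_per_group=2, seed=0, nt_profile=prof)
        p = draw_participant(spec, "NT", rng)
        dk, df = true_phenotypes(p)
        assert df == pytest.approx(1.0, abs=1e-2)  # always differ across framings
        assert dk == pytest.approx(1.0, abs=1e-2)  # 1-ToM socially, RL otherwise


class TestGenerateCohort:
    def test_shape_and_determinism(self):
        spec = CohortSpec(n_per_group=2, seed=5)
        parts1, sess1, truth1 = generate_cohort(spec)
        parts2, sess2, truth2 = generate_cohort(spec)
        assert len(parts1) == 4
        assert len(sess1) == 4 * 16
        assert truth1 == truth2
        for s1, s2 in zip(sess1, sess2):
            assert s1.subject_id == s2.subject_id
            assert np.array_equal(s1.a_self, s2.a_self)
            assert np.array_equal(s1.a_op, s2.a_op)
        for s in sess1:
            s.validate()

    def test_point_mass_truth_is_all_influence(self):
        spec = CohortSpec(
            n_per_group=2, seed=1, as_profile=point_mass_profile("Inf")
        )
        _, _, truth = generate_cohort(spec)
        as_truth = {k: v for k, v in truth.items() if k[0].startswith("AS")}
        assert set(as_truth.values()) == {"Inf"}

    def test_zero_switch_rate_keeps_strategy_across_repetitions(self):
        prof = GroupProfile(
            social_base=NT_PROFILE.social_base,
            nonsocial_base=NT_PROFILE.nonsocial_base,
            switch_rate_repetition=0.0,
            switch_rate_framing=1.0,
        )
        spec = CohortSpec(n_per_group=3, seed=2, nt_profile=prof)
        _, _, truth = generate_cohort(spec)
        for (sid, opp, fra, rep), strat in truth.items():
            if sid.startswith("NT") and rep == "2":
                assert truth[(sid, opp, fra, "1")] == strat

    def test_repertoire_frequencies_match_simplex(self):
        # empirical strategy frequencies across many draws ~ repertoire
        prof = GroupProfile(
            social_base=NT_PROFILE.social_base,
            nonsocial_base=NT_PROFILE.nonsocial_base,
            switch_rate_repetition=1.0,  # independent draws everywhere
            switch_rate_framing=1.0,
            dirichlet_concentration=1e6,  # no per-participant jitter
        )
        spec = CohortSpec(n_per_group=12, seed=3, nt_profile=prof, n_trials=60)
        _, _, truth = generate_cohort(spec)
        draws = [
            v for (sid, opp, fra, rep), v in truth.items()
            if sid.startswith("NT") and fra == "social"
        ]
        freq = np.array([draws.count(m) for m in MODEL_NAMES]) / len(draws)
        # binomial error band: 3 sd at n = 12*4*2
        n = len(draws)
        for f, p in zip(freq, NT_PROFILE.social_base):
            assert abs(f - p) < 3 * np.sqrt(p * (1 - p) / n) + 1e-9

    def test_invalid_group_size_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_per_group=1)


def test_participants_frame_columns():
    spec = CohortSpec(n_per_group=2, seed=0)
    parts, _, _ = generate_cohort(spec)
    df = participants_frame(parts)
    assert set(df.columns) >= {
        "subject_id", "group", "symptom_social", "symptom_stereotyped",
    }
    assert len(df) == 4
    assert (df.symptom_social >= 0).all()
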