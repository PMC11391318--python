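"""Colony generator: pedigree, housing, feature table, determinism."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from vocalkin import (
    EffectConfig,
    Individual,
    Pedigree,
    generate_colony,
    generate_housing,
    generate_pedigree,
    generate_trill_features,
    read_colony,
    write_colony,
)
from vocalkin.trill_signal import FEATURE_COLUMNS
from vocalkin.signature_stats import lda_loo, pca_kaiser
from vocalkin.dyad_scores import (
    acoustic_dissimilarity,
    individual_medians,
    social_contact_matrix,
)
from vocalkin.matrix_inference import mantel


class TestGeneratePedigree:
    def test_no_breeding_yields_only_founders(self):
        ped = generate_pedigree(4, 0, seed=1)
        assert len(ped) == 4
        assert all(i.sire_id is None and i.dam_id is None for i in ped.individuals)

    def test_every_non_founder_has_both_parents_in_pedigree(self):
        ped = generate_pedigree(4, 2, seed=1)
        ids = {i.id for i in ped.individuals}
        non_founders = [i for i in ped.individuals if i.sire_id is not None]
        assert non_founders, "two generations should produce offspring"
        for i in non_founders:
            assert i.sire_id in ids and i.dam_id in ids
            assert ped[i.sire_id].sex == "M" and ped[i.dam_id].sex == "F"
            assert i.birth_date > ped[i.sire_id].birth_date

    def test_same_seed_reproduces_identical_pedigree(self):
        a = generate_pedigree(6, 3, seed=42).to_frame()
        b = generate_pedigree(6, 3, seed=42).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_founders_rejected(self):
        with pytest.raises(ValueError):
            generate_pedigree(1, 2, seed=0)


class TestGenerateHousing:
    def _all_first_degree_females(self):
        d = dt.date
        mother = Individual("F0", "F", d(1990, 1, 1))
        daughters = [
            Individual(f"D{i}", "F", d(1995, i, 1), sire_id=None, dam_id="F0")
            for i in range(1, 6)
        ]
        return Pedigree([mother] + daughters)

    def test_full_kin_bias_houses_only_first_degree_female_dyads(self):
        ped = self._all_first_degree_females()
        intervals = generate_housing(ped, female_kin_bias=1.0, seed=3)
        from vocalkin.synth_colony import _first_degree

        by_cage: dict[str, list[str]] = {}
        for h in intervals:
            by_cage.setdefault(h.cage_id, []).append(h.individual_id)
        assert by_cage
        for members in by_cage.values():
            for a in members:
                for b in members:
                    if a != b:
                        assert _first_degree(ped, a, b)

    def test_cage_sizes_are_two_or_three(self):
        ped = generate_pedigree(10, 2, seed=5)
        intervals = generate_housing(ped, female_kin_bias=0.5, seed=5)
        counts = pd.DataFrame(
            [(h.cage_id, h.individual_id) for h in intervals],
            columns=["cage", "ind"],
        ).groupby("cage")["ind"].nunique()
        assert set(counts.unique()) <= {2, 3}

    def test_zero_bias_matches_random_assignment_kin_rate(self):
        # Monte-Carlo over assignments: the rate of first-degree female
        # cage dyads under bias=0 should match random cage formation.
        ped = generate_pedigree(8, 2, seed=9)
        from vocalkin.synth_colony import _first_degree

        def kin_rate(seed):
            dyads = kin = 0
            by_cage: dict[str, list[str]] = {}
            for h in generate_housing(ped, female_kin_bias=0.0, seed=seed):
                if ped[h.individual_id].sex == "F":
                    by_cage.setdefault(h.cage_id, []).append(h.individual_id)
            for members in by_cage.values():
                for i, a in enumerate(members):
                    for b in members[i + 1 :]:
                        dyads += 1
                        kin += _first_degree(ped, a, b)
            return kin, dyads

        kin, dyads = 0, 0
        for s in range(40):
            k, d = kin_rate(s)
            kin += k
            dyads += d
        # expected rate = population fraction of first-degree female pairs
        females = [i.id for i in ped.individuals if i.sex == "F"]
        pop_pairs = [(a, b) for i, a in enumerate(females) for b in females[i + 1 :]]
        expected = np.mean([_first_degree(ped, a, b) for a, b in pop_pairs])
        observed = kin / dyads
        se = np.sqrt(expected * (1 - expected) / dyads)
        assert abs(observed - expected) < 4 * se + 0.02


class TestGenerateTrillFeatures:
    def test_zero_noise_degenerate_case_gives_identical_calls(self):
        cfg = EffectConfig(
            sigma_individual=0.0,
            sigma_call=0.0,
            beta_sex=0.0,
            beta_kin=0.0,
            beta_contact=0.0,
            n_individuals_f=6,
            n_individuals_m=4,
            calls_per_individual=4,
            seed=2,
        )
        colony = generate_colony(cfg)
        vals = colony.features[list(FEATURE_COLUMNS)].to_numpy()
        assert np.allclose(vals, vals[0])

    def test_strong_signatures_give_near_perfect_loo_dfa(self):
        cfg = EffectConfig(
            sigma_individual=3.0,
            sigma_call=0.1,
            n_individuals_f=6,
            n_individuals_m=4,
            calls_per_individual=6,
            seed=4,
        )
        colony = generate_colony(cfg)
        _, scores = pca_kaiser(colony.features[list(FEATURE_COLUMNS)])
        _, loo = lda_loo(scores, colony.features["individual_id"])
        assert loo.accuracy_pct >= 95.0

    def test_strong_convergence_yields_negative_acoustic_contact_mantel_r(self):
        cfg = EffectConfig(beta_contact=-2.0, seed=6)
        colony = generate_colony(cfg)
        ids = sorted(colony.individuals[colony.individuals["sex"] == "F"]["id"])
        feats = colony.features[colony.features["individual_id"].isin(ids)]
        ac = acoustic_dissimilarity(individual_medians(feats, columns=list(FEATURE_COLUMNS)))
        rec = colony.recording_dates()
        ct = social_contact_matrix(
            colony.housing[colony.housing["individual_id"].isin(ids)],
            rec[rec.index.isin(ids)],
        ).subset(ac.ids)
        res = mantel(ac, ct, n_perm=99, seed=0)
        assert res.r < 0

    def test_empty_colony_rejected(self, small_colony):
        import dataclasses

        empty = dataclasses.replace(small_colony, recordings=pd.DataFrame(columns=["call_id", "individual_id", "date"]))
        with pytest.raises(ValueError):
            generate_trill_features(empty, EffectConfig())


def test_null_effect_colonies_give_uniform_mantel_p_values():
    """With beta_kin = beta_contact = 0 the acoustic-vs-contact Mantel p is
    uniform on (0, 1): KS test over 200 simulated colonies not rejecting at
    alpha = 0.01."""
    from scipy import stats
    from vocalkin import mantel

    ps = []
    for seed in range(200):
        cfg = EffectConfig(
            n_individuals_f=10,
            n_individuals_m=8,
            calls_per_individual=5,
            beta_kin=0.0,
            beta_contact=0.0,
            seed=seed,
        )
        colony = generate_colony(cfg)
        ids = sorted(colony.individuals[colony.individuals["sex"] == "F"]["id"])
        feats = colony.features[colony.features["individual_id"].isin(ids)]
        ac = acoustic_dissimilarity(individual_medians(feats, columns=list(FEATURE_COLUMNS)))
        rec = colony.recording_dates()
        ct = social_contact_matrix(
            colony.housing[colony.housing["individual_id"].isin(ids)],
            rec[rec.index.isin(ids)],
        ).subset(ac.ids)
        ps.append(mantel(ac, ct, n_perm=199, seed=1000 + seed).p_two_tailed)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestColonyDataset:
    def test_default_conditions(self, default_colony):
        sexes = default_colony.individuals["sex"].value_counts()
        assert sexes["F"] == 22 and sexes["M"] == 14
        assert len(default_colony.features) == 482
        lo, hi = EffectConfig().syllables_range
        assert default_colony.features["n_syllables"].between(lo, hi).all()

    def test_same_seed_gives_bit_identical_tables(self, small_effect_config, small_colony):
        other = generate_colony(small_effect_config)
        pd.testing.assert_frame_equal(other.features, small_colony.features)
        pd.testing.assert_frame_equal(other.housing, small_colony.housing)
        pd.testing.assert_frame_equal(other.weights, small_colony.weights)

    def test_recording_years_span_at_most_nine_years(self, default_colony):
        years = pd.to_datetime(default_colony.recordings["date"]).dt.year
        assert years.max() - years.min() <= 9

    def test_csv_round_trip(self, small_colony, small_effect_config, tmp_path):
        write_colony(small_colony, tmp_path, small_effect_config)
        back = read_colony(tmp_path)
        pd.testing.assert_frame_equal(
            back.features, small_colony.features, check_exact=False
        )
        assert len(back.pedigree) == len(small_colony.pedigree)


class TestEffectConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            EffectConfig(sigma_call=-1.0)
        with pytest.raises(ValueError):
            EffectConfig(syllables_range=(0, 10))
        with pytest.raises(ValueError):
            EffectConfig(syllables_range=(5, 31))
        with pytest.raises(ValueError):
            EffectConfig(beta_kin=1.5)

    def test_dict_round_trip_preserves_per_sex_contact(self):
        cfg = EffectConfig(beta_contact={"F": -1.0, "M": 0.5}, beta_sex=0.3)
        back = EffectConfig.from_dict(cfg.to_dict())
        assert back.contact_coefficient("F") == -1.0
        assert back.contact_coefficient("M") == 0.5
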