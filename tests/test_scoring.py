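"""Lysosomal-confidence scoring: point awards, totals, tiers."""

import pytest

from lysoquant import (
    assign_tier,
    compartments_points,
    criterion_points,
    gen_annotation_catalogs,
    score_dataset,
    score_protein,
)
from lysoquant.scoring import (
    DEFAULT_SCHEME,
    TIER_HC,
    TIER_LOW,
    TIER_MC,
    TIER_ORDER,
    TIER_VHC,
    ScoringScheme,
    enumerate_observation_combinations,
)

MAX_OBSERVATIONS = {
    "bovine": "SwissProt",
    "rat": "EL",
    "lgdb": True,
    "uniprot_kw": True,
    "compartments": 5.0,
    "hpa": True,
    "ncl": True,
}

# independent award table for the brute-force oracle
ORACLE_POINTS = {
    "bovine": {None: 0, "TrEMBL": 1, "SwissProt": 2},
    "rat": {None: 0, "Misc": 1, "EL": 2},
    "lgdb": {False: 0, True: 2},
    "uniprot_kw": {False: 0, True: 2},
    "compartments": {None: 0, 3.0: 1, 5.0: 2},
    "hpa": {False: 0, True: 2},
    "ncl": {False: 0, True: 2},
}


def oracle_total(obs):
    return sum(ORACLE_POINTS[c][v] for c, v in obs.items())


class TestCompartmentsBands:
    @pytest.mark.parametrize(
        "confidence,expected",
        [(0.0, 0), (2.0, 0), (2.001, 1), (3.0, 1), (3.999, 1), (4.0, 2), (5.0, 2)],
    )
    def test_band_awards(self, confidence, expected):
        assert compartments_points(confidence) == expected

    @pytest.mark.parametrize("bad", [-0.1, 5.1, 7.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError, match="outside"):
            compartments_points(bad)


class TestCriterionPoints:
    @pytest.mark.parametrize(
        "criterion,observation,expected",
        [
            ("bovine", "TrEMBL", 1),
            ("bovine", "SwissProt", 2),
            ("bovine", None, 0),
            ("rat", "Misc", 1),
            ("rat", "EL", 2),
            ("lgdb", True, 2),
            ("lgdb", False, 0),
            ("uniprot_kw", True, 2),
            ("hpa", True, 2),
            ("ncl", True, 2),
            ("compartments", 4.5, 2),
        ],
    )
    def test_awards(self, criterion, observation, expected):
        assert criterion_points(DEFAULT_SCHEME, criterion, observation) == expected

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError, match="unknown criterion"):
            criterion_points(DEFAULT_SCHEME, "mystery", True)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown category"):
            criterion_points(DEFAULT_SCHEME, "bovine", "Reviewed")

    def test_contradictory_categories_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            criterion_points(DEFAULT_SCHEME, "rat", {"Misc", "EL"})


class TestScoreProtein:
    def test_all_maxima_reach_ceiling(self):
        card = score_protein(DEFAULT_SCHEME, MAX_OBSERVATIONS)
        assert card.total == 14 == DEFAULT_SCHEME.max_total
        assert card.tier == TIER_VHC

    def test_no_observations_is_discarded(self):
        card = score_protein(DEFAULT_SCHEME, {})
        assert card.total == 0
        assert card.tier == TIER_LOW
        assert not card.retained

    def test_single_trembl_hit_is_medium_confidence(self):
        card = score_protein(DEFAULT_SCHEME, {"bovine": "TrEMBL"})
        assert card.total == 1
        assert card.tier == TIER_MC

    def test_unknown_criterion_in_observations_rejected(self):
        with pytest.raises(ValueError, match="unknown criteria"):
            score_protein(DEFAULT_SCHEME, {"bogus": True})

    def test_exhaustive_totals_match_brute_force_oracle(self):
        combos = list(enumerate_observation_combinations())
        assert len(combos) == 432
        totals = []
        for obs in combos:
            card = score_protein(DEFAULT_SCHEME, obs)
            assert card.total == oracle_total(obs)
            assert card.total == sum(card.points.values())
            assert card.tier == assign_tier(card.total)
            totals.append(card.total)
        assert max(totals) == 14
        assert min(totals) == 0

    def test_adding_evidence_never_lowers_score_or_tier(self):
        # upgrade each criterion from absent to its maximum, one at a time
        obs = {}
        prev_total, prev_rank = 0, 0
        for criterion, value in MAX_OBSERVATIONS.items():
            obs[criterion] = value
            card = score_protein(DEFAULT_SCHEME, obs)
            rank = TIER_ORDER.index(card.tier)
            assert card.total >= prev_total
            assert rank >= prev_rank
            prev_total, prev_rank = card.total, rank


class TestAssignTier:
    @pytest.mark.parametrize(
        "total,tier",
        [(0, TIER_LOW), (1, TIER_MC), (2, TIER_MC), (3, TIER_HC), (5, TIER_HC),
         (6, TIER_VHC), (14, TIER_VHC)],
    )
    def test_bands(self, total, tier):
        assert assign_tier(total) == tier

    def test_six_resolves_to_very_high(self):
        # the printed bands overlap at 6; the higher tier wins
        assert assign_tier(6) == TIER_VHC

    def test_monotone_nondecreasing(self):
        ranks = [TIER_ORDER.index(assign_tier(t)) for t in range(15)]
        assert ranks == sorted(ranks)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_tier(-1)


class TestSchemeConfig:
    def test_roundtrip(self):
        scheme = ScoringScheme.from_dict(DEFAULT_SCHEME.to_dict())
        assert scheme == DEFAULT_SCHEME

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ScoringScheme.from_dict({"vhc_min": 6, "bogus": 1})

    def test_alternative_points_change_ceiling(self):
        d = DEFAULT_SCHEME.to_dict()
        d["membership_points"]["uniprot_kw"] = 1
        assert ScoringScheme.from_dict(d).max_total == 13


class TestScoreDataset:
    def test_empty_input_gives_zero_counts(self):
        results = score_dataset([], [])
        assert sum(results.tier_counts.values()) == 0
        assert results.table.empty

    def test_tier_counts_partition_input(self):
        ids = [f"SYN{i:03d}" for i in range(60)]
        catalogs, _ = gen_annotation_catalogs(ids, seed=4)
        results = score_dataset(ids, catalogs)
        assert sum(results.tier_counts.values()) == len(ids)

    def test_perfect_catalogs_retain_exactly_the_lysosomal_fraction(self):
        ids = [f"SYN{i:04d}" for i in range(400)]
        catalogs, truth = gen_annotation_catalogs(
            ids, p_lyso=0.4, sensitivity_per_source=1.0, fpr_per_source=0.0, seed=9
        )
        results = score_dataset(ids, catalogs)
        n_lyso = sum(truth.lyso_labels.values())
        # non-lysosomal proteins still carry a Compartments confidence in
        # [0, 2], worth 0 points, so retention == latent lysosomal label
        assert len(results.retained) == n_lyso
        retained_ids = set(results.retained["accession"])
        assert all(truth.lyso_labels[i] for i in retained_ids)
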