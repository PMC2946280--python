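import dataclasses

import numpy as np
import pytest
from scipy import stats

from smallrna_libbias.annotation import annotate_reads, build_family_counts, Category
from smallrna_libbias.ess import ESSCategory, classify_ess
from smallrna_libbias.folding import fold_cached
from smallrna_libbias.io_formats import Protocol, RefClass
from smallrna_libbias.synthetic_data import (
    AbundanceProfile,
    NEUTRAL_LIGATION,
    NO_TRUNCATION,
    ProtocolBiasModel,
    default_models,
    make_reference_set,
    neutral_model,
    simulate_library,
    save_library,
    zipf_profile,
)


class TestMakeReferenceSet:
    def test_seed_determinism(self):
        a = make_reference_set(5, 1, 1, (20, 24), seed=7)
        b = make_reference_set(5, 1, 1, (20, 24), seed=7)
        assert a == b

    def test_empty_request_gives_empty_list(self):
        assert make_reference_set(0, 0, 0, (20, 24), seed=1) == []

    def test_pairwise_distance_enforced(self):
        refs = make_reference_set(20, 0, 0, (20, 20), seed=3)
        seqs = [r.sequence for r in refs]
        for i, a in enumerate(seqs):
            for b in seqs[i + 1 :]:
                assert sum(x != y for x, y in zip(a, b)) >= 5

    def test_overpacked_request_fails_after_retries(self):
        # at distance = length over a 4-letter alphabet no more than 4
        # mutually all-position-distinct sequences exist, so the fifth
        # draw must exhaust its retry budget
        with pytest.raises(RuntimeError, match="Hamming"):
            make_reference_set(8, 0, 0, (15, 15), seed=1, min_distance=15)

    def test_length_range_validated(self):
        with pytest.raises(ValueError, match="length range"):
            make_reference_set(3, 0, 0, (10, 24), seed=1)


class TestBiasModelValidation:
    def test_trunc_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            neutral = neutral_model(Protocol.ILLUMINA_GA, 10)
            dataclasses.replace(neutral, trunc3_probs={0: 0.5, 1: 0.1, 2: 0.0, 3: 0.0})

    def test_depth_must_be_positive(self):
        with pytest.raises(ValueError, match="depth"):
            neutral_model(Protocol.ILLUMINA_GA, 0)

    def test_model_roundtrips_through_dict(self):
        model = default_models()[Protocol.SOLID_CLONING]
        assert ProtocolBiasModel.from_dict(model.to_dict()) == model


class TestSimulateLibrary:
    def test_seed_reproducibility(self, mirna_refs, profile):
        model = dataclasses.replace(default_models()[Protocol.SOLID_CLONING], seed=5)
        a = simulate_library(mirna_refs, profile, model)
        b = simulate_library(mirna_refs, profile, model)
        assert [(r.read_id, r.sequence) for r in a] == [(r.read_id, r.sequence) for r in b]

    def test_exact_depth(self, mirna_refs, profile):
        model = dataclasses.replace(default_models()[Protocol.ILLUMINA_V15_CLONING], depth=137)
        assert len(simulate_library(mirna_refs, profile, model)) == 137

    def test_all_zero_ligation_rejected(self, mirna_refs, profile):
        model = dataclasses.replace(
            neutral_model(Protocol.ILLUMINA_GA, 10),
            ligation_success={c: 0.0 for c in ESSCategory},
        )
        with pytest.raises(ValueError, match="no read can ligate"):
            simulate_library(mirna_refs, profile, model)

    def test_blocked_category_absent_from_output(self, mirna_refs, profile):
        model = dataclasses.replace(
            neutral_model(Protocol.ILLUMINA_V1_CLONING, 400, seed=11),
            ligation_success={
                ESSCategory.NON_ESS: 1.0,
                ESSCategory.ESS5_ONLY: 1.0,
                ESSCategory.ESS3_ONLY: 0.0,
                ESSCategory.BOTH: 1.0,
            },
        )
        reads = simulate_library(mirna_refs, profile, model)
        calls = [classify_ess(fold_cached(r.sequence)) for r in reads]
        assert all(c.category != ESSCategory.ESS3_ONLY for c in calls)

    def test_truncation_fraction_within_binomial_bound(self):
        refs = make_reference_set(1, 0, 0, (24, 24), seed=8)
        profile = AbundanceProfile(families={refs[0].family: 1.0})
        model = ProtocolBiasModel(
            protocol=Protocol.SOLID_CLONING,
            length_sd=0.0,
            trunc3_probs={0: 0.2, 1: 0.0, 2: 0.8, 3: 0.0},
            var5_prob=0.0,
            ligation_success=NEUTRAL_LIGATION,
            nta_prob=0.0,
            depth=500,
            seed=13,
        )
        reads = simulate_library(refs, profile, model)
        frac_trunc2 = sum(len(r.sequence) == 22 for r in reads) / len(reads)
        assert abs(frac_trunc2 - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 500)

    def test_unknown_profile_family_rejected(self, mirna_refs):
        bad = AbundanceProfile(families={"not-a-family": 1.0})
        with pytest.raises(ValueError, match="absent"):
            simulate_library(mirna_refs, bad, neutral_model(Protocol.ILLUMINA_GA, 10))

    def test_neutral_frequencies_match_profile_chisquare(self, mirna_refs, profile):
        reads = simulate_library(
            mirna_refs, profile, neutral_model(Protocol.ILLUMINA_GA, 5000, seed=23)
        )
        annos = annotate_reads(reads, mirna_refs)
        counts = build_family_counts(annos, mirna_refs, [reads[0].library_id])
        observed = np.array(
            [counts.get(f, reads[0].library_id) for f in profile.families]
        )
        expected = np.array(list(profile.families.values())) * len(reads)
        p = stats.chisquare(observed, expected).pvalue
        assert p > 0.01

    def test_ligation_bias_ordering_recovered(self):
        # two protocols differing only in 3'-ESS ligation success (1.0 vs 0.1)
        # must show the same ordering in observed 3'-ESS read fractions
        refs = make_reference_set(8, 0, 0, (21, 23), seed=31)
        profile = zipf_profile([r.family for r in refs])
        base = neutral_model(Protocol.ILLUMINA_GA, 2000)
        permissive = dataclasses.replace(
            base,
            ligation_success={**NEUTRAL_LIGATION, ESSCategory.ESS3_ONLY: 1.0},
            seed=41,
        )
        restrictive = dataclasses.replace(
            base,
            ligation_success={**NEUTRAL_LIGATION, ESSCategory.ESS3_ONLY: 0.1},
            seed=41,
        )

        def ess3_fraction(reads):
            calls = [classify_ess(fold_cached(r.sequence)) for r in reads]
            return sum(c.category == ESSCategory.ESS3_ONLY for c in calls) / len(reads)

        f_perm = ess3_fraction(simulate_library(refs, profile, permissive))
        f_rest = ess3_fraction(simulate_library(refs, profile, restrictive))
        assert f_perm > f_rest

    def test_sidecar_roundtrip(self, tmp_path, mirna_refs, profile):
        model = dataclasses.replace(default_models()[Protocol.ILLUMINA_V1_CLONING], depth=30)
        reads = simulate_library(mirna_refs, profile, model)
        fasta = tmp_path / "lib.fasta"
        save_library(reads, model, fasta)
        assert fasta.exists()
        import json

        sidecar = json.loads((tmp_path / "lib.fasta.model.json").read_text())
        assert ProtocolBiasModel.from_dict(sidecar) == model


class TestDefaultModels:
    def test_four_protocols_present(self):
        models = default_models()
        assert set(models) == set(Protocol)
        for model in models.values():
            assert model.depth > 0

    def test_length_spread_ordering(self):
        m = default_models()
        assert (
            m[Protocol.SOLID_CLONING].length_sd
            > m[Protocol.ILLUMINA_V15_CLONING].length_sd
            > m[Protocol.ILLUMINA_V1_CLONING].length_sd
        )

    def test_3prime_ess_ligation_ordering(self):
        m = default_models()
        key = ESSCategory.ESS3_ONLY
        assert (
            m[Protocol.SOLID_CLONING].ligation_success[key]
            > m[Protocol.ILLUMINA_V15_CLONING].ligation_success[key]
            > m[Protocol.ILLUMINA_V1_CLONING].ligation_success[key]
        )

    def test_v1_blocks_3prime_ess_entirely(self):
        v1 = default_models()[Protocol.ILLUMINA_V1_CLONING]
        assert v1.ligation_success[ESSCategory.ESS3_ONLY] == 0.0
        assert v1.ligation_success[ESSCategory.BOTH] == 0.0
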