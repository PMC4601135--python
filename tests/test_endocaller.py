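"""Joint per-site caller: worked values, brute-force oracle equivalence,
fragment-endogeneity evidence and the simplified indel extension."""

import math

import numpy as np
import pytest

import paleomt as p
from paleomt.endocaller import (
    EndoPriors,
    FragmentLengthModel,
    call_consensus,
    consensus_sequence,
    count_mismatches,
    p_fragment_deam_posterior,
    p_fragment_endogenous,
    p_fragment_length_posterior,
    p_obs_given_pair,
    p_obs_given_template,
    site_indel_call,
    site_joint_posterior,
)
from paleomt.io import AlignedFragment, PileupColumn, ReferenceGenome
from paleomt.model import (
    BASES,
    BaseContext,
    DeaminationProfile,
    SubstitutionErrorModel,
    encode_sequence,
)

UNIFORM = SubstitutionErrorModel.uniform()


def profile_ct(rate, depth=3):
    end5 = np.zeros((depth, 4, 4))
    end5[0, 1, 3] = rate
    return DeaminationProfile(end5, np.zeros((depth, 4, 4)))


def make_column(bases, eps=1e-3, d5=5, d3=5, mismap=0.0, p_endo=None, ref_base="A",
                reverse=None):
    n = len(bases)
    return PileupColumn(
        ref_index=0, ref_base=ref_base,
        base=encode_sequence("".join(bases)),
        eps=np.full(n, eps) if np.isscalar(eps) else np.asarray(eps),
        dist5=np.full(n, d5, dtype=np.int32),
        dist3=np.full(n, d3, dtype=np.int32),
        reverse=np.zeros(n, dtype=bool) if reverse is None else np.asarray(reverse),
        mismap=np.full(n, mismap) if np.isscalar(mismap) else np.asarray(mismap),
        frag=np.arange(n, dtype=np.int32),
        p_endo=None if p_endo is None else (
            np.full(n, p_endo) if np.isscalar(p_endo) else np.asarray(p_endo)
        ),
    )


# ---------------------------------------------------------------------------
# independent oracle: direct Eq-by-Eq enumeration over all 16 pairs

def oracle_site_posterior(column, priors, err):
    joint = np.zeros((4, 4))
    for ie, b_e in enumerate(BASES):
        for ic, b_c in enumerate(BASES):
            logp = math.log(1.0 / 16.0)
            for k in range(column.coverage):
                ctx = BaseContext(
                    BASES[column.base[k]], float(column.eps[k]), "A",
                    int(column.dist5[k]), int(column.dist3[k]), bool(column.reverse[k]),
                )
                pe = (
                    column.p_endo[k]
                    if column.p_endo is not None
                    else 1.0 - priors.contamination
                )
                logp += math.log(
                    p_obs_given_pair(
                        ctx, b_e, b_c, float(pe), float(column.mismap[k]), priors, err
                    )
                )
            joint[ie, ic] = logp
    m = joint.max()
    post = np.exp(joint - m)
    return post / post.sum()


class TestObservationTerms:
    def test_match_no_error_no_damage(self):
        ctx = BaseContext("A", 0.0, "A")
        priors = EndoPriors(endo_profile=DeaminationProfile.zero())
        assert p_obs_given_template(ctx, "A", "endogenous", priors, UNIFORM) == 1.0

    def test_endogenous_branch_uses_endo_profile(self):
        ctx = BaseContext("T", 0.01, "C", dist5=0, dist3=9)
        priors = EndoPriors(endo_profile=profile_ct(0.3))
        val = p_obs_given_template(ctx, "C", "endogenous", priors, UNIFORM)
        assert val == pytest.approx(0.99 * 0.3 + 0.01 / 3)

    def test_contaminant_branch_zero_profile_is_error_only(self):
        ctx = BaseContext("T", 0.3, "C", dist5=0, dist3=9)
        priors = EndoPriors(endo_profile=profile_ct(0.3))
        assert p_obs_given_template(ctx, "C", "contaminant", priors, UNIFORM) == pytest.approx(0.1)

    def test_certain_mismap_gives_quarter_for_every_pair(self):
        ctx = BaseContext("G", 0.01, "A", dist5=2, dist3=2)
        priors = EndoPriors(endo_profile=profile_ct(0.3))
        for b_e in BASES:
            for b_c in BASES:
                assert p_obs_given_pair(ctx, b_e, b_c, 0.6, 1.0, priors, UNIFORM) == pytest.approx(0.25)

    def test_pure_endogenous_fragment(self):
        ctx = BaseContext("T", 0.02, "C", dist5=0, dist3=9)
        priors = EndoPriors(endo_profile=profile_ct(0.3))
        direct = p_obs_given_template(ctx, "C", "endogenous", priors, UNIFORM)
        assert p_obs_given_pair(ctx, "C", "G", 1.0, 0.0, priors, UNIFORM) == pytest.approx(direct)

    def test_half_endogenous_is_mean_of_templates(self):
        ctx = BaseContext("A", 0.05, "A", dist5=3, dist3=3)
        priors = EndoPriors(endo_profile=DeaminationProfile.zero())
        pe = p_obs_given_template(ctx, "C", "endogenous", priors, UNIFORM)
        pc = p_obs_given_template(ctx, "G", "contaminant", priors, UNIFORM)
        assert p_obs_given_pair(ctx, "C", "G", 0.5, 0.0, priors, UNIFORM) == pytest.approx(
            (pe + pc) / 2
        )


class TestSiteJointPosterior:
    def test_unanimous_column_confident_call(self):
        col = make_column(["A"] * 10, eps=1e-3, p_endo=1.0)
        priors = EndoPriors(endo_profile=DeaminationProfile.zero())
        call = site_joint_posterior(col, priors, UNIFORM)
        assert call.endo_base == "A"
        assert call.endo_error < 1e-20

    def test_empty_column_uniform(self):
        col = make_column([])
        call = site_joint_posterior(col, EndoPriors(), UNIFORM)
        assert call.endo_base == "N"
        assert call.endo_phred == 0.0
        assert np.allclose(call.endo_marginals, 0.25)

    def test_normalisation_and_error_identity(self):
        rng = np.random.default_rng(0)
        col = make_column(
            list(rng.choice(list(BASES), 8)), eps=rng.uniform(0.001, 0.1, 8),
            p_endo=rng.uniform(0, 1, 8), mismap=rng.uniform(0, 0.3, 8),
        )
        priors = EndoPriors(contamination=0.3, endo_profile=profile_ct(0.2))
        call = site_joint_posterior(col, priors, UNIFORM)
        assert np.exp(call.joint_log).sum() == pytest.approx(1.0, abs=1e-9)
        assert call.endo_marginals.sum() == pytest.approx(1.0, abs=1e-9)
        assert call.endo_error == pytest.approx(1.0 - call.endo_marginals.max(), abs=1e-12)
        assert call.cont_error == pytest.approx(1.0 - call.cont_marginals.max(), abs=1e-12)

    def test_all_mismapped_gives_uniform_posteriors(self):
        col = make_column(["A"] * 6 + ["G"] * 6, mismap=1.0)
        call = site_joint_posterior(col, EndoPriors(contamination=0.2), UNIFORM)
        assert np.allclose(call.endo_marginals, 0.25, atol=1e-12)
        assert np.allclose(call.cont_marginals, 0.25, atol=1e-12)
        assert call.endo_phred <= 1.25  # a flat 4-way posterior: error 3/4

    def test_oracle_equivalence_random_columns(self, err):
        """Optimised caller equals direct 16-pair enumeration on 200 random
        small columns (joint posterior to 1e-9)."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 6))
            col = make_column(
                list(rng.choice(list(BASES), n)),
                eps=rng.uniform(1e-4, 0.3, n),
                d5=int(rng.integers(0, 4)), d3=int(rng.integers(0, 4)),
                mismap=rng.uniform(0, 1, n),
                p_endo=rng.uniform(0, 1, n),
                reverse=rng.random(n) < 0.5,
            )
            end5 = rng.uniform(0, 0.25, (3, 4, 4)) * (1 - np.eye(4))
            end3 = rng.uniform(0, 0.25, (3, 4, 4)) * (1 - np.eye(4))
            cont5 = rng.uniform(0, 0.05, (3, 4, 4)) * (1 - np.eye(4))
            priors = EndoPriors(
                contamination=float(rng.uniform(0, 1)),
                endo_profile=DeaminationProfile(end5, end3),
                cont_profile=DeaminationProfile(cont5, np.zeros((3, 4, 4))),
            )
            call = site_joint_posterior(col, priors, err)
            expected = oracle_site_posterior(col, priors, err)
            assert np.allclose(np.exp(call.joint_log), expected, atol=1e-9)


class TestFragmentEvidence:
    def _calls(self, ref_seq):
        priors = EndoPriors(endo_profile=DeaminationProfile.zero())
        ref = ReferenceGenome("r", ref_seq)
        frags = [make_frag(ref_seq)]
        return call_consensus(frags, ref, priors, UNIFORM, two_pass=False, indels=False)

    def test_zero_prior_gives_certain_endogenous(self):
        calls = self._calls("ACGT")
        priors = EndoPriors(contamination=0.0, endo_profile=profile_ct(0.3))
        assert p_fragment_deam_posterior(make_frag("ACGT"), calls, priors, UNIFORM) == 1.0

    def test_zero_profile_reduces_to_prior(self):
        calls = self._calls("ACGT")
        priors = EndoPriors(contamination=0.35, endo_profile=DeaminationProfile.zero())
        val = p_fragment_deam_posterior(make_frag("ACGT"), calls, priors, UNIFORM)
        assert val == pytest.approx(0.65, abs=1e-9)

    def test_damaged_terminal_raises_posterior(self):
        # 1-base fragment showing C->T against a confident C consensus
        calls = self._calls("C")
        priors = EndoPriors(contamination=0.5, endo_profile=profile_ct(0.3))
        val = p_fragment_deam_posterior(make_frag("T"), calls, priors, UNIFORM)
        assert val > 0.5

    def test_length_posterior_density_value(self):
        model = FragmentLengthModel(mu_endo=math.log(50), sigma_endo=0.3,
                                    mu_cont=math.log(50), sigma_cont=0.3)
        pdf = FragmentLengthModel.lognormal_pdf(50, math.log(50), 0.3)
        assert pdf == pytest.approx(1 / (50 * math.sqrt(2 * math.pi) * 0.3), rel=1e-9)
        assert pdf == pytest.approx(0.026596, abs=1e-5)
        # identical endo/cont length models are uninformative
        assert p_fragment_length_posterior(37, model, 0.3) == pytest.approx(0.7)

    def test_length_posterior_monotone(self):
        model = FragmentLengthModel(mu_endo=math.log(45), sigma_endo=0.3,
                                    mu_cont=math.log(85), sigma_cont=0.3)
        vals = [p_fragment_length_posterior(l, model, 0.5) for l in (30, 50, 70, 90, 120)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_disabled_length_model_returns_prior_complement(self):
        assert p_fragment_length_posterior(55, FragmentLengthModel.disabled(), 0.2) == pytest.approx(0.8)

    def test_combined_reduces_to_deam_when_length_disabled(self):
        calls = self._calls("CCCC")
        priors = EndoPriors(contamination=0.4, endo_profile=profile_ct(0.3),
                            length_model=FragmentLengthModel.disabled())
        f = make_frag("TCCC")
        assert p_fragment_endogenous(f, calls, priors, UNIFORM) == pytest.approx(
            p_fragment_deam_posterior(f, calls, priors, UNIFORM)
        )

    def test_neutral_channels_give_prior_complement(self):
        calls = self._calls("AAAA")
        priors = EndoPriors(contamination=0.4, endo_profile=DeaminationProfile.zero(),
                            length_model=FragmentLengthModel(
                                mu_endo=3.8, sigma_endo=0.3, mu_cont=3.8, sigma_cont=0.3))
        assert p_fragment_endogenous(make_frag("AAAA"), calls, priors, UNIFORM) == pytest.approx(0.6)

    def test_short_damaged_beats_long_undamaged(self):
        calls = self._calls("C" * 120)
        priors = EndoPriors(contamination=0.5, endo_profile=profile_ct(0.3),
                            length_model=FragmentLengthModel())
        short_damaged = make_frag("T" + "C" * 29)
        long_clean = make_frag("C" * 110)
        assert p_fragment_endogenous(short_damaged, calls, priors, UNIFORM) > \
            p_fragment_endogenous(long_clean, calls, priors, UNIFORM)


def make_frag(seq, start=0, reverse=False, q=30, rid="f"):
    l = len(seq)
    idx = np.arange(l, dtype=np.int32)
    return AlignedFragment(
        read_id=rid, ref_start=start, mapq=60, reverse_strand=reverse, length=l,
        ref_pos=start + idx, read_idx=idx, base=encode_sequence(seq),
        qual=np.full(l, q, dtype=np.int16),
    )


class TestIndels:
    def test_no_insertion_observations_no_call(self):
        col = make_column(["A"] * 5, p_endo=1.0)
        assert site_indel_call(col, EndoPriors(), UNIFORM) is None

    def test_unanimous_deletion_called_endogenous(self):
        col = make_column([], ref_base="A")
        col.del_frag = np.arange(10, dtype=np.int32)
        col.del_eps = np.full(10, 1e-3)
        call = site_indel_call(col, EndoPriors(contamination=0.0), UNIFORM)
        assert call is not None and call.kind == "deletion"
        assert call.endo

    def test_split_deletion_follows_gap_carrying_class(self):
        # 5 base-carrying reads marked contaminant, 5 gap reads endogenous
        col = make_column(["A"] * 5, p_endo=0.0)
        col.frag = np.arange(5, dtype=np.int32)
        col.del_frag = np.arange(5, 10, dtype=np.int32)
        col.del_eps = np.full(5, 1e-3)
        call = site_indel_call(col, EndoPriors(contamination=0.5), UNIFORM)
        assert call is not None and call.kind == "deletion"
        assert call.endo and not call.cont

    def test_unanimous_insertion_called(self):
        col = make_column([], ref_base="A")
        col.insertion_observations = [(i, "GG", 1e-3) for i in range(8)]
        call = site_indel_call(col, EndoPriors(contamination=0.0), UNIFORM)
        assert call is not None and call.kind == "insertion"
        assert call.endo and call.endo_seq == "GG"


class TestConsensus:
    def test_matches_reference_on_clean_data(self):
        rng = np.random.default_rng(1)
        ref_seq = "".join(rng.choice(list(BASES), 60))
        ref = ReferenceGenome("r", ref_seq)
        frags = [
            make_frag(ref_seq[i : i + 20], start=i, rid=f"f{i}")
            for i in range(0, 40, 2)
        ]
        calls = call_consensus(frags, ref, EndoPriors(), UNIFORM)
        seq = consensus_sequence(calls)
        covered = seq[:59]  # the tail base may be uncovered
        for a, b in zip(covered, ref_seq):
            assert a in ("N", b)
        assert count_mismatches(calls, ref_seq) == 0
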