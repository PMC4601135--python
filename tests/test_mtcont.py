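"""Database-scan contamination estimation and the diagnostic-ratio helper."""

import math

import numpy as np
import pytest

import paleomt as p
from paleomt.endocaller import EndoPriors, call_consensus
from paleomt.io import PileupColumn
from paleomt.model import (
    BASES,
    BaseContext,
    DeaminationProfile,
    SubstitutionErrorModel,
    encode_sequence,
    p_deam,
    p_null,
)
from paleomt.mtcont import (
    NoInformativeSitesError,
    diagnostic_ratio,
    estimate_contamination,
    informative_sites,
    predicted_contaminant_sequence,
    site_rate_likelihood,
)
from .test_endocaller import make_column, make_frag

UNIFORM = SubstitutionErrorModel.uniform()


def simple_calls(seq, error=1e-6, coverage=10):
    from .test_io import make_call

    return [make_call(i, base=b, error=error, coverage=coverage, ref=b)
            for i, b in enumerate(seq)]


class TestInformativeSites:
    def test_identical_genomes_empty(self):
        calls = simple_calls("ACGT")
        assert len(informative_sites(calls, "ACGT")) == 0

    def test_counts_differing_positions(self):
        calls = simple_calls("ACGTACGT")
        sites = informative_sites(calls, "ACCTACGA")
        assert [pos for pos, _, _ in sites] == [2, 7]
        assert sites.sites[0] == (2, "G", "C")

    def test_iupac_code_containing_endo_base_not_informative(self):
        calls = simple_calls("A")
        assert len(informative_sites(calls, "R")) == 0  # A in {A, G}
        assert len(informative_sites(calls, "Y")) == 1  # A not in {C, T}

    def test_gaps_and_n_skipped(self):
        calls = simple_calls("ACGT")
        assert len(informative_sites(calls, "-NGT")) == 0


class TestSiteRateLikelihood:
    def test_closed_form_no_contamination(self):
        # 5 clean reads of A, endo marginal concentrated on A, c_r = 0
        col = make_column(["A"] * 5, eps=1e-3, mismap=0.0)
        marg = np.array([1.0, 0.0, 0.0, 0.0])
        priors = EndoPriors(endo_profile=DeaminationProfile.zero())
        lik = site_rate_likelihood(col, marg, "G", 0.0, priors, UNIFORM)
        assert lik == pytest.approx((1 - 1e-3) ** 5, rel=1e-9)

    def test_all_mismapped_quarter_per_read(self):
        col = make_column(["A", "C", "G"], mismap=1.0)
        marg = np.full(4, 0.25)
        priors = EndoPriors(endo_profile=DeaminationProfile.zero())
        for c_r in (0.0, 0.5, 1.0):
            assert site_rate_likelihood(col, marg, "T", c_r, priors, UNIFORM) == pytest.approx(0.25**3)

    def test_brute_force_oracle(self, err):
        """Module output equals explicit marginalisation over all 16
        (b_e, c) pairs on random columns, to 1e-9."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 6))
            col = make_column(
                list(rng.choice(list(BASES), n)),
                eps=rng.uniform(1e-4, 0.3, n),
                d5=int(rng.integers(0, 4)), d3=int(rng.integers(0, 4)),
                mismap=rng.uniform(0, 1, n),
                reverse=rng.random(n) < 0.5,
            )
            end5 = rng.uniform(0, 0.3, (3, 4, 4)) * (1 - np.eye(4))
            end3 = rng.uniform(0, 0.3, (3, 4, 4)) * (1 - np.eye(4))
            priors = EndoPriors(endo_profile=DeaminationProfile(end5, end3))
            marg = rng.dirichlet(np.ones(4))
            c_r = float(rng.uniform(0, 1))
            cont_base = str(rng.choice(list(BASES)))
            got = site_rate_likelihood(col, marg, cont_base, c_r, priors, err)

            expected = 1.0
            ic = BASES.index(cont_base)
            for k in range(n):
                per_obs = 0.0
                for ie, b_e in enumerate(BASES):
                    ctx = BaseContext(
                        BASES[col.base[k]], float(col.eps[k]), "A",
                        int(col.dist5[k]), int(col.dist3[k]), bool(col.reverse[k]),
                    )
                    pe_term = p_deam(
                        BaseContext(ctx.observed, ctx.eps, b_e, ctx.dist5, ctx.dist3, ctx.reverse),
                        priors.endo_profile, err,
                    )
                    for jc, c_base in enumerate(BASES):
                        pc_term = p_null(
                            BaseContext(ctx.observed, ctx.eps, c_base, ctx.dist5, ctx.dist3, ctx.reverse),
                            err,
                        )
                        mapped = (1 - c_r) * pe_term + c_r * pc_term
                        m = float(col.mismap[k])
                        prior = marg[ie] * (1.0 if jc == ic else 0.0)
                        per_obs += prior * ((1 - m) * mapped + m * 0.25)
                expected *= per_obs
            assert got == pytest.approx(expected, abs=1e-9, rel=1e-9)


@pytest.fixture(scope="module")
def scan_fixture():
    """200x library at 40 % contamination with consensus calls."""
    endo, cont = p.make_genome_pair(2000, 20, 1)
    cfg = p.SimulationConfig(endo_genome=endo, cont_genomes=[(cont, 0.4)],
                             n_fragments=8000, seed=13)
    res = p.simulate_dataset(cfg)
    frags = res.to_fragments()
    pile = p.Pileup(frags, res.reference)
    prof, _ = p.estimate_conditional_deamination(frags, res.reference, "single")
    priors = EndoPriors(contamination=0.4, endo_profile=prof)
    calls = call_consensus(pile, res.reference, priors, UNIFORM)
    return res, pile, calls, priors, endo, cont


class TestEstimateContamination:
    def test_recovers_per_nucleotide_rate(self, scan_fixture):
        res, pile, calls, priors, _endo, cont = scan_fixture
        est = estimate_contamination(
            pile, calls, [("truth", cont)], priors=priors, err=UNIFORM
        )
        assert abs(est.rate - res.per_nucleotide_contamination) <= 0.05
        assert est.ci_low <= est.rate <= est.ci_high
        curve_mass = None  # posterior normalisation checked via GenomeScan curves
        est2 = estimate_contamination(
            pile, calls, [("truth", cont)], priors=priors, err=UNIFORM, keep_curves=True
        )
        curve_mass = est2.table["truth"].curve.posterior.sum()
        assert curve_mass == pytest.approx(1.0, abs=1e-9)

    def test_identical_record_raises(self, scan_fixture):
        _res, pile, calls, priors, _endo, _cont = scan_fixture
        from paleomt.endocaller import consensus_sequence

        endo_consensus = consensus_sequence(calls, "endo")
        with pytest.raises(NoInformativeSitesError):
            estimate_contamination(
                pile, calls, [("self", endo_consensus)], priors=priors, err=UNIFORM
            )

    def test_true_contaminant_beats_decoys(self, genome_pair_10k):
        """With the true contaminant plus three decoys >=10 substitutions
        away, the true record wins the likelihood scan in >=95 % of 20
        seeded replicates (c = 0.4, 200x)."""
        endo, cont = p.make_genome_pair(2000, 20, 1)
        rng = np.random.default_rng(99)
        decoys = []
        for k in range(3):
            d = list(cont)
            for pos in rng.choice(len(d), 12, replace=False):
                d[pos] = [b for b in BASES if b != d[pos]][int(rng.integers(3))]
            decoys.append((f"decoy{k}", "".join(d)))
        db = [("truth", cont)] + decoys
        wins = 0
        for seed in range(20):
            cfg = p.SimulationConfig(endo_genome=endo, cont_genomes=[(cont, 0.4)],
                                     n_fragments=8000, seed=100 + seed)
            res = p.simulate_dataset(cfg)
            frags = res.to_fragments()
            pile = p.Pileup(frags, res.reference)
            prof, _ = p.estimate_conditional_deamination(frags, res.reference, "single")
            priors = EndoPriors(contamination=0.4, endo_profile=prof)
            calls = call_consensus(pile, res.reference, priors, UNIFORM)
            est = estimate_contamination(pile, calls, db, priors=priors, err=UNIFORM)
            wins += est.best_contaminant == "truth"
        assert wins >= 19

    def test_divergent_database_underestimates(self, scan_fixture):
        """Replacing the true contaminant with a 30-substitution-divergent
        record lowers the MAP (directional, database-divergence effect)."""
        res, pile, calls, priors, _endo, cont = scan_fixture
        rng = np.random.default_rng(5)
        div = list(cont)
        for pos in rng.choice(len(div), 30, replace=False):
            div[pos] = [b for b in BASES if b != div[pos]][int(rng.integers(3))]
        est_true = estimate_contamination(pile, calls, [("truth", cont)],
                                          priors=priors, err=UNIFORM)
        est_div = estimate_contamination(pile, calls, [("divergent", "".join(div))],
                                         priors=priors, err=UNIFORM)
        assert est_div.rate < est_true.rate

    def test_predicted_contaminant_masks_low_quality(self, scan_fixture):
        _res, _pile, calls, _priors, _endo, cont = scan_fixture
        seq = predicted_contaminant_sequence(calls, quality_threshold=200.0)
        assert len(seq) == len(calls)
        keep = [i for i, ch in enumerate(seq) if ch != "N"]
        assert keep, "high contamination should leave confident contaminant calls"
        for i in keep:
            assert calls[i].cont_phred >= 200.0


class TestDiagnosticRatio:
    def test_reported_mezmaiskaya_style_counts(self):
        # per-nucleotide contamination from diagnostic-position base counts
        assert 100 * diagnostic_ratio(2_443_418, 1_989_785) == pytest.approx(44.9, abs=0.05)

    def test_extremes(self):
        assert diagnostic_ratio(500, 0) == 0.0
        assert diagnostic_ratio(0, 500) == 1.0

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_ratio(0, 0)
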