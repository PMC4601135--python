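"""Joint per-site inference of the endogenous and contaminant base.

At each reference position the data are the aligned bases of all overlapping
fragments.  A fragment contributes through a mixture: with probability
P[R_j in E] its base reflects the endogenous nucleotide b_e (deamination
allowed, at the endogenous rates), otherwise the contaminant nucleotide b_c
(deamination at the typically much lower contaminant rates); mismapped
fragments (probability m_Rj = 10^(-MAPQ/10)) contribute a flat 1/4.  The joint
posterior over the 16 (b_e, b_c) pairs under a flat prior yields, by
marginalisation, both consensus bases with PHRED-scaled error estimates.

P[R_j in E] itself combines two evidence channels -- the fragment's
deamination pattern scored against the current per-site base posteriors, and
its length under two log-normal distributions -- as a naive-Bayes product with
the contamination prior c_c applied once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .io import AlignedFragment, Pileup, PileupColumn, ReferenceGenome
from .model import (
    BaseContext,
    DeaminationProfile,
    SubstitutionErrorModel,
    decode_base,
    null_likelihoods,
    prob_to_phred,
    template_likelihoods,
)

PHRED_CAP = 9999.0


@dataclass
class FragmentLengthModel:
    """Log-normal fragment-length models for the two populations.

    Parameters are on the natural-log scale.  When ``enabled`` is False the
    length channel is uninformative.
    """

    mu_endo: float = math.log(45.0)
    sigma_endo: float = 0.35
    mu_cont: float = math.log(85.0)
    sigma_cont: float = 0.35
    enabled: bool = True

    def __post_init__(self):
        if self.enabled and (self.sigma_endo <= 0 or self.sigma_cont <= 0):
            raise ValueError("sigma must be positive when the model is enabled")

    @staticmethod
    def lognormal_pdf(l, mu, sigma):
        l = np.asarray(l, dtype=float)
        return np.exp(-((np.log(l) - mu) ** 2) / (2 * sigma**2)) / (
            l * math.sqrt(2 * math.pi) * sigma
        )

    @classmethod
    def disabled(cls) -> "FragmentLengthModel":
        return cls(enabled=False)


@dataclass
class EndoPriors:
    """Inputs fixed during one consensus call: the contamination prior c_c,
    both deamination profiles and the fragment-length model."""

    contamination: float = 0.0
    endo_profile: DeaminationProfile = field(default_factory=DeaminationProfile.zero)
    cont_profile: DeaminationProfile = field(default_factory=DeaminationProfile.zero)
    length_model: FragmentLengthModel = field(default_factory=FragmentLengthModel.disabled)

    def __post_init__(self):
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination prior must lie in [0, 1]")


@dataclass
class IndelCall:
    kind: str  # "deletion" | "insertion"
    endo: bool = False
    cont: bool = False
    endo_seq: str = ""
    cont_seq: str = ""
    endo_phred: float = 0.0
    cont_phred: float = 0.0


@dataclass
class SiteCall:
    """Joint call at one reference position, with both marginal tracks."""

    ref_index: int
    ref_base: str
    joint_log: np.ndarray  # (4, 4) normalised log posterior over (b_e, b_c)
    endo_base: str
    endo_error: float
    endo_phred: float
    cont_base: str
    cont_error: float
    cont_phred: float
    coverage: int
    endo_marginals: np.ndarray
    cont_marginals: np.ndarray
    indel: IndelCall | None = None


# ---------------------------------------------------------------------------
# observation-level terms

def p_obs_given_template(
    ctx: BaseContext,
    template: str,
    which: str,
    priors: EndoPriors,
    err: SubstitutionErrorModel,
) -> float:
    """P[r_i | template, correctly mapped] for one class of fragment.

    The endogenous branch uses the endogenous deamination profile, the
    contaminant branch the (usually near-zero) contaminant profile.
    """
    profile = priors.endo_profile if which == "endogenous" else priors.cont_profile
    ctx2 = BaseContext(ctx.observed, ctx.eps, template, ctx.dist5, ctx.dist3, ctx.reverse)
    from .model import p_deam

    return p_deam(ctx2, profile, err)


def p_obs_given_pair(
    ctx: BaseContext,
    b_e: str,
    b_c: str,
    p_endo_fragment: float,
    m_rj: float,
    priors: EndoPriors,
    err: SubstitutionErrorModel,
) -> float:
    """P[r_i | b_e, b_c]: class mixture wrapped with the mapping term."""
    pe = p_obs_given_template(ctx, b_e, "endogenous", priors, err)
    pc = p_obs_given_template(ctx, b_c, "contaminant", priors, err)
    mapped = p_endo_fragment * pe + (1.0 - p_endo_fragment) * pc
    return (1.0 - m_rj) * mapped + m_rj * 0.25


# ---------------------------------------------------------------------------
# per-site joint posterior

def _joint_log_from_likelihoods(Pe, Pc, p_endo, mismap) -> np.ndarray:
    """Unnormalised (4, 4) joint log-likelihood from per-observation terms."""
    mix = (
        p_endo[:, None, None] * Pe[:, :, None]
        + (1.0 - p_endo)[:, None, None] * Pc[:, None, :]
    )
    term = (1.0 - mismap)[:, None, None] * mix + (mismap[:, None, None] * 0.25)
    return np.log(np.clip(term, 1e-300, None)).sum(axis=0)


def _finalise_call(ref_index, ref_base, joint_log, coverage, indel=None) -> SiteCall:
    m = joint_log.max()
    p = np.exp(joint_log - m)
    total = p.sum()
    joint_log = joint_log - (m + math.log(total))
    marg_e = p.sum(axis=1)
    marg_c = p.sum(axis=0)

    def track(marg):
        best = int(np.argmax(marg))
        # summing the alternatives directly keeps tiny error probabilities
        # exact where 1 - max would lose them to cancellation
        alt = float(marg.sum() - marg[best]) if marg[best] < 0.5 * total else float(
            sum(marg[k] for k in range(4) if k != best)
        )
        error = alt / total
        return decode_base(best), error, float(prob_to_phred(error, PHRED_CAP))

    eb, ee, ep = track(marg_e)
    cb, ce, cp = track(marg_c)
    marg_e = marg_e / total
    marg_c = marg_c / total
    return SiteCall(
        ref_index=ref_index,
        ref_base=ref_base,
        joint_log=joint_log,
        endo_base=eb,
        endo_error=ee,
        endo_phred=ep,
        cont_base=cb,
        cont_error=ce,
        cont_phred=cp,
        coverage=coverage,
        endo_marginals=marg_e,
        cont_marginals=marg_c,
        indel=indel,
    )


def _uniform_call(ref_index, ref_base) -> SiteCall:
    joint = np.full((4, 4), math.log(1.0 / 16.0))
    return SiteCall(
        ref_index=ref_index,
        ref_base=ref_base,
        joint_log=joint,
        endo_base="N",
        endo_error=0.75,
        endo_phred=0.0,
        cont_base="N",
        cont_error=0.75,
        cont_phred=0.0,
        coverage=0,
        endo_marginals=np.full(4, 0.25),
        cont_marginals=np.full(4, 0.25),
    )


def site_joint_posterior(
    column: PileupColumn,
    priors: EndoPriors,
    err: SubstitutionErrorModel | None = None,
) -> SiteCall:
    """Joint posterior over the 16 (b_e, b_c) pairs at one position.

    Per-observation endogeneity probabilities are taken from the column if
    set, else the neutral prior 1 - c_c is used.  An empty column yields a
    uniform joint, 'N' calls and PHRED 0.
    """
    err = err or SubstitutionErrorModel.uniform()
    n = column.coverage
    if n == 0:
        return _uniform_call(column.ref_index, column.ref_base)
    Pe = template_likelihoods(
        column.base, column.eps, column.dist5, column.dist3, column.reverse,
        priors.endo_profile, err,
    )
    Pc = template_likelihoods(
        column.base, column.eps, column.dist5, column.dist3, column.reverse,
        priors.cont_profile, err,
    )
    p_endo = (
        column.p_endo
        if column.p_endo is not None
        else np.full(n, 1.0 - priors.contamination)
    )
    joint = _joint_log_from_likelihoods(Pe, Pc, p_endo, column.mismap)
    # flat prior 1/16 is constant over pairs and cancels in the normalisation
    return _finalise_call(column.ref_index, column.ref_base, joint, n)


# ---------------------------------------------------------------------------
# fragment endogeneity (deamination + length evidence)

def _site_weights(endo_calls) -> np.ndarray:
    return np.stack([c.endo_marginals for c in endo_calls])


def fragment_endogenous_posteriors(
    pileup: Pileup,
    endo_calls,
    priors: EndoPriors,
    err: SubstitutionErrorModel | None = None,
    return_parts: bool = False,
    Pd: np.ndarray | None = None,
):
    """P[R_j in E] for every fragment in the pileup (vectorised).

    Deamination channel: each base is scored under the deaminated endogenous
    model and the error-only model, both marginalised over the current
    per-site endogenous base posteriors.  Length channel: log-normal
    likelihoods.  Channels multiply; the prior (1 - c_c) enters once.
    """
    err = err or SubstitutionErrorModel.uniform()
    c = priors.contamination
    W = _site_weights(endo_calls)  # (L, 4)
    if Pd is None:
        Pd = template_likelihoods(
            pileup.base, pileup.eps, pileup.dist5, pileup.dist3, pileup.reverse,
            priors.endo_profile, err,
        )
    Pn = null_likelihoods(pileup.base, pileup.eps, err)
    w_obs = W[pileup.site]
    pd_mix = np.clip((w_obs * Pd).sum(axis=1), 1e-300, None)
    pn_mix = np.clip((w_obs * Pn).sum(axis=1), 1e-300, None)
    n_frag = len(pileup.fragments)
    Ld = np.bincount(pileup.frag, weights=np.log(pd_mix), minlength=n_frag)
    Ln = np.bincount(pileup.frag, weights=np.log(pn_mix), minlength=n_frag)

    lm = priors.length_model
    if lm is not None and lm.enabled:
        lengths = np.array([fr.length for fr in pileup.fragments], dtype=float)
        ll_e = np.log(
            np.clip(FragmentLengthModel.lognormal_pdf(lengths, lm.mu_endo, lm.sigma_endo), 1e-300, None)
        )
        ll_c = np.log(
            np.clip(FragmentLengthModel.lognormal_pdf(lengths, lm.mu_cont, lm.sigma_cont), 1e-300, None)
        )
    else:
        ll_e = ll_c = np.zeros(n_frag)

    if c <= 0.0:
        p = np.ones(n_frag)
    elif c >= 1.0:
        p = np.zeros(n_frag)
    else:
        num = math.log(1.0 - c) + Ld + ll_e
        alt = math.log(c) + Ln + ll_c
        p = np.exp(num - np.logaddexp(num, alt))
    if return_parts:
        return p, (Ld, Ln, ll_e, ll_c)
    return p


def p_fragment_deam_posterior(
    fragment: AlignedFragment,
    endo_calls,
    priors: EndoPriors,
    err: SubstitutionErrorModel | None = None,
) -> float:
    """Deamination-only posterior that one fragment is endogenous."""
    err = err or SubstitutionErrorModel.uniform()
    W = _site_weights(endo_calls)
    keep = (fragment.base < 4) & (fragment.ref_pos >= 0) & (fragment.ref_pos < len(endo_calls))
    base, eps = fragment.base[keep], fragment.eps[keep]
    d5, d3 = fragment.dist5[keep], fragment.dist3[keep]
    rev = np.full(len(base), fragment.reverse_strand)
    Pd = template_likelihoods(base, eps, d5, d3, rev, priors.endo_profile, err)
    Pn = null_likelihoods(base, eps, err)
    w = W[fragment.ref_pos[keep]]
    Ld = float(np.log(np.clip((w * Pd).sum(axis=1), 1e-300, None)).sum())
    Ln = float(np.log(np.clip((w * Pn).sum(axis=1), 1e-300, None)).sum())
    c = priors.contamination
    if c <= 0.0:
        return 1.0
    if c >= 1.0:
        return 0.0
    num = math.log(1.0 - c) + Ld
    return float(math.exp(num - np.logaddexp(num, math.log(c) + Ln)))


def p_fragment_length_posterior(l: float, model: FragmentLengthModel, c_c: float) -> float:
    """Length-only posterior that a fragment of length ``l`` is endogenous."""
    if model is None or not model.enabled:
        return 1.0 - c_c
    pe = FragmentLengthModel.lognormal_pdf(l, model.mu_endo, model.sigma_endo)
    pc = FragmentLengthModel.lognormal_pdf(l, model.mu_cont, model.sigma_cont)
    num = (1.0 - c_c) * pe
    den = num + c_c * pc
    if den == 0.0:
        return 1.0 - c_c
    return float(num / den)


def p_fragment_endogenous(
    fragment: AlignedFragment,
    endo_calls,
    priors: EndoPriors,
    err: SubstitutionErrorModel | None = None,
) -> float:
    """Combined P[R_j in E]: deamination and length likelihoods multiplied,
    the contamination prior applied once."""
    err = err or SubstitutionErrorModel.uniform()
    c = priors.contamination
    if c <= 0.0:
        return 1.0
    if c >= 1.0:
        return 0.0
    W = _site_weights(endo_calls)
    keep = (fragment.base < 4) & (fragment.ref_pos >= 0) & (fragment.ref_pos < len(endo_calls))
    base, eps = fragment.base[keep], fragment.eps[keep]
    rev = np.full(len(base), fragment.reverse_strand)
    Pd = template_likelihoods(
        base, eps, fragment.dist5[keep], fragment.dist3[keep], rev, priors.endo_profile, err
    )
    Pn = null_likelihoods(base, eps, err)
    w = W[fragment.ref_pos[keep]]
    Ld = float(np.log(np.clip((w * Pd).sum(axis=1), 1e-300, None)).sum())
    Ln = float(np.log(np.clip((w * Pn).sum(axis=1), 1e-300, None)).sum())
    lm = priors.length_model
    if lm is not None and lm.enabled:
        Ld += float(np.log(np.clip(FragmentLengthModel.lognormal_pdf(fragment.length, lm.mu_endo, lm.sigma_endo), 1e-300, None)))
        Ln += float(np.log(np.clip(FragmentLengthModel.lognormal_pdf(fragment.length, lm.mu_cont, lm.sigma_cont), 1e-300, None)))
    num = math.log(1.0 - c) + Ld
    return float(math.exp(num - np.logaddexp(num, math.log(c) + Ln)))


# ---------------------------------------------------------------------------
# indels (simplified 5-symbol extension)

def site_indel_call(
    column: PileupColumn,
    priors: EndoPriors,
    err: SubstitutionErrorModel | None = None,
) -> IndelCall | None:
    """Simplified insertion/deletion call at one column.

    Deletions extend the per-site symbol set with a gap symbol whose
    observation likelihood uses per-read gap/non-gap evidence with error
    probabilities from neighbouring base qualities.  Insertions are called
    when the posterior of a specific inserted string (flat prior over the
    observed strings plus "no insertion") exceeds the no-insertion posterior.
    """
    err = err or SubstitutionErrorModel.uniform()
    del_call = _deletion_call(column, priors, err) if len(column.del_frag) else None
    ins_call = _insertion_call(column, priors, err) if column.insertion_observations else None
    if del_call is not None and (del_call.endo or del_call.cont):
        return del_call
    if ins_call is not None and (ins_call.endo or ins_call.cont):
        return ins_call
    return None


def _p_endo_for(column, frag_ids, priors):
    if column.p_endo is not None and column.coverage:
        lookup = {int(f): float(p) for f, p in zip(column.frag, column.p_endo)}
        return np.array([lookup.get(int(f), 1.0 - priors.contamination) for f in frag_ids])
    return np.full(len(frag_ids), 1.0 - priors.contamination)


def _deletion_call(column, priors, err) -> IndelCall:
    n = column.coverage
    nd = len(column.del_frag)
    # base observations: 5-symbol template likelihoods
    Pe = template_likelihoods(
        column.base, column.eps, column.dist5, column.dist3, column.reverse,
        priors.endo_profile, err,
    )
    Pc = template_likelihoods(
        column.base, column.eps, column.dist5, column.dist3, column.reverse,
        priors.cont_profile, err,
    )
    Pe5 = np.concatenate([Pe, (column.eps * 0.25)[:, None]], axis=1)
    Pc5 = np.concatenate([Pc, (column.eps * 0.25)[:, None]], axis=1)
    # deletion observations: gap seen with confidence 1 - eps_del
    de = column.del_eps
    Pe5_del = np.concatenate([np.tile(de[:, None], (1, 4)), (1.0 - de)[:, None]], axis=1)
    Pe5 = np.concatenate([Pe5, Pe5_del], axis=0)
    Pc5 = np.concatenate([Pc5, Pe5_del], axis=0)
    p_endo_base = (
        column.p_endo if column.p_endo is not None else np.full(n, 1.0 - priors.contamination)
    )
    p_endo = np.concatenate([p_endo_base, _p_endo_for(column, column.del_frag, priors)])
    mismap = np.concatenate([column.mismap, np.full(nd, 0.0)])
    mix = (
        p_endo[:, None, None] * Pe5[:, :, None]
        + (1.0 - p_endo)[:, None, None] * Pc5[:, None, :]
    )
    term = (1.0 - mismap)[:, None, None] * mix + (mismap[:, None, None] * 0.25)
    joint = np.log(np.clip(term, 1e-300, None)).sum(axis=0)
    joint -= logsumexp(joint)
    marg_e = logsumexp(joint, axis=1)
    marg_c = logsumexp(joint, axis=0)
    endo_del = int(np.argmax(marg_e)) == 4
    cont_del = int(np.argmax(marg_c)) == 4
    ep = float(prob_to_phred(1.0 - math.exp(marg_e[4]), PHRED_CAP))
    cp = float(prob_to_phred(1.0 - math.exp(marg_c[4]), PHRED_CAP))
    return IndelCall(
        kind="deletion", endo=endo_del, cont=cont_del,
        endo_seq="-" if endo_del else "", cont_seq="-" if cont_del else "",
        endo_phred=ep if endo_del else 0.0, cont_phred=cp if cont_del else 0.0,
    )


def _insertion_call(column, priors, err) -> IndelCall | None:
    obs = list(column.insertion_observations)  # (frag, seq, eps)
    if column._pileup is not None:
        span_frags, span_eps = column._pileup.insertion_support(column.ref_index)
        obs += [(int(f), "", float(e)) for f, e in zip(span_frags, span_eps)]
    strings = sorted({seq for _, seq, _ in obs if seq})
    if not strings:
        return None
    cands = [""] + strings
    k = len(cands)
    frag_ids = np.array([f for f, _, _ in obs])
    eps = np.array([max(e, 1e-4) for _, _, e in obs])
    observed = [seq for _, seq, _ in obs]
    lik = np.empty((len(obs), k))
    for j, cand in enumerate(cands):
        same = np.array([o == cand for o in observed])
        lik[:, j] = np.where(same, 1.0 - eps, eps / max(k - 1, 1))
    p_endo = _p_endo_for(column, frag_ids, priors)
    mismap = np.zeros(len(obs))
    mix = (
        p_endo[:, None, None] * lik[:, :, None]
        + (1.0 - p_endo)[:, None, None] * lik[:, None, :]
    )
    term = (1.0 - mismap)[:, None, None] * mix + (mismap[:, None, None] / k)
    joint = np.log(np.clip(term, 1e-300, None)).sum(axis=0)
    joint -= logsumexp(joint)
    marg_e = logsumexp(joint, axis=1)
    marg_c = logsumexp(joint, axis=0)
    ei, ci = int(np.argmax(marg_e)), int(np.argmax(marg_c))
    if ei == 0 and ci == 0:
        return None
    return IndelCall(
        kind="insertion",
        endo=ei != 0,
        cont=ci != 0,
        endo_seq=cands[ei],
        cont_seq=cands[ci],
        endo_phred=float(prob_to_phred(1.0 - math.exp(marg_e[ei]), PHRED_CAP)),
        cont_phred=float(prob_to_phred(1.0 - math.exp(marg_c[ci]), PHRED_CAP)),
    )


# ---------------------------------------------------------------------------
# whole-genome consensus

def _pass_calls(pileup: Pileup, Pe, Pc, p_endo_obs) -> list:
    """One calling pass over every column, from precomputed likelihoods.

    Produces exactly what :func:`site_joint_posterior` produces column by
    column; the shared `_joint_log_from_likelihoods` / `_finalise_call` core
    guarantees the two paths agree.
    """
    seq = pileup.reference.sequence
    starts = pileup.starts
    mism = pileup.mismap
    calls = []
    for i in range(pileup.n_sites):
        lo, hi = int(starts[i]), int(starts[i + 1])
        if hi == lo:
            calls.append(_uniform_call(i, seq[i]))
            continue
        joint = _joint_log_from_likelihoods(
            Pe[lo:hi], Pc[lo:hi], p_endo_obs[lo:hi], mism[lo:hi]
        )
        calls.append(_finalise_call(i, seq[i], joint, hi - lo))
    return calls


def call_consensus(
    fragments,
    reference: ReferenceGenome,
    priors: EndoPriors,
    err: SubstitutionErrorModel | None = None,
    two_pass: bool = True,
    indels: bool = True,
) -> list[SiteCall]:
    """Call both consensus genomes over the whole reference.

    Pass 1 scores every site with the neutral fragment prior 1 - c_c; the
    resulting per-site posteriors let each fragment's endogeneity probability
    be computed (deamination + length evidence), and pass 2 re-scores every
    site with those per-fragment probabilities.  Each returned SiteCall
    carries both the endogenous and the contaminant track.
    """
    err = err or SubstitutionErrorModel.uniform()
    pileup = fragments if isinstance(fragments, Pileup) else Pileup(fragments, reference)
    pileup.clear_fragment_endogenous_prob()
    # the per-observation template likelihoods depend only on the profiles,
    # so they are computed once and shared by both passes
    Pe = template_likelihoods(
        pileup.base, pileup.eps, pileup.dist5, pileup.dist3, pileup.reverse,
        priors.endo_profile, err,
    )
    Pc = template_likelihoods(
        pileup.base, pileup.eps, pileup.dist5, pileup.dist3, pileup.reverse,
        priors.cont_profile, err,
    )
    p_obs = np.full(pileup.total_observations, 1.0 - priors.contamination)
    calls = _pass_calls(pileup, Pe, Pc, p_obs)
    if two_pass and priors.contamination > 0.0:
        p_frag = fragment_endogenous_posteriors(pileup, calls, priors, err, Pd=Pe)
        pileup.set_fragment_endogenous_prob(p_frag)
        calls = _pass_calls(pileup, Pe, Pc, pileup.p_endo)
    if indels:
        for i in list(pileup.insertions.keys()):
            calls[i].indel = site_indel_call(pileup.column(i), priors, err)
        if len(pileup.del_site):
            for i in np.unique(pileup.del_site):
                ic = site_indel_call(pileup.column(int(i)), priors, err)
                if ic is not None:
                    calls[int(i)].indel = ic
    return calls


def consensus_sequence(calls, which: str = "endo", quality_filter: float | None = None) -> str:
    """Consensus string ('N' for zero coverage / below the quality filter)."""
    out = []
    for c in calls:
        base = c.endo_base if which == "endo" else c.cont_base
        phred = c.endo_phred if which == "endo" else c.cont_phred
        if c.coverage == 0 or (quality_filter is not None and phred < quality_filter):
            out.append("N")
        else:
            out.append(base)
    return "".join(out)


def count_mismatches(calls, truth: str, which: str = "endo", skip_n: bool = True) -> int:
    """Mismatches between the called track and a truth sequence."""
    seq = consensus_sequence(calls, which=which)
    n = 0
    for a, b in zip(seq, truth.upper()):
        if skip_n and (a == "N" or b == "N"):
            continue
        if a != b:
            n += 1
    return n
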