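"""Initial contamination prior from deamination patterns.

Endogenous (ancient) fragments carry terminal cytosine deamination while
present-day contaminant fragments are essentially undamaged.  Two things are
estimated here:

1. the endogenous deamination profile, by *end conditioning*: a fragment whose
   3' terminal base shows the protocol's deamination substitution is almost
   certainly endogenous, so the 5'-end rates measured within that subset are
   the endogenous rates (and symmetrically for the other end);
2. the mixture proportion c_d that best explains why the unconditional
   deamination rate over all fragments is diluted relative to the endogenous
   rate, via a gridded posterior with a uniform prior.

The mapping reference serves as the endogenous template throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .io import AlignedFragment, Pileup, ReferenceGenome
from .model import (
    BASE_INDEX,
    DeaminationProfile,
    SubstitutionErrorModel,
    null_likelihoods,
    template_likelihoods,
)

_C, _G, _T, _A = BASE_INDEX["C"], BASE_INDEX["G"], BASE_INDEX["T"], BASE_INDEX["A"]


class NoConditioningFragmentsError(RuntimeError):
    """No fragment shows the conditioning terminal deamination substitution."""


@dataclass
class PosteriorCurve:
    """Gridded posterior over a contamination rate in [0, 1]."""

    grid: np.ndarray
    log_posterior: np.ndarray
    map_rate: float
    ci_low: float
    ci_high: float
    flat: bool = False  # likelihood carried no information about the rate

    @property
    def posterior(self) -> np.ndarray:
        """Normalised posterior mass per grid point (sums to 1)."""
        return np.exp(self.log_posterior - logsumexp(self.log_posterior))


def hpd_interval(grid: np.ndarray, posterior: np.ndarray, mass: float = 0.95):
    """Smallest highest-posterior-density set on the grid covering ``mass``."""
    order = np.argsort(posterior)[::-1]
    cum = np.cumsum(posterior[order])
    k = int(np.searchsorted(cum, mass)) + 1
    chosen = grid[order[:k]]
    return float(chosen.min()), float(chosen.max())


def curve_from_loglik(grid: np.ndarray, loglik: np.ndarray, flat: bool = False) -> PosteriorCurve:
    logpost = loglik - logsumexp(loglik)
    post = np.exp(logpost)
    if flat:
        return PosteriorCurve(grid, logpost, float("nan"), float(grid[0]), float(grid[-1]), True)
    map_rate = float(grid[int(np.argmax(logpost))])
    lo, hi = hpd_interval(grid, post)
    return PosteriorCurve(grid, logpost, map_rate, lo, hi, False)


# ---------------------------------------------------------------------------
# conditional deamination estimation

def _molecule_view(fragment: AlignedFragment, reference: ReferenceGenome):
    """Template and observed codes in original-molecule orientation."""
    ref_codes = reference.codes[fragment.ref_pos]
    obs = fragment.base
    if fragment.reverse_strand:
        ref_codes = np.where(ref_codes < 4, 3 - ref_codes, ref_codes)
        obs = np.where(obs < 4, 3 - obs, obs)
    return ref_codes, obs, fragment.dist5, fragment.dist3


def _is_deaminated_at(template, obs, dist, window, sub):
    """Any position with dist < window showing substitution ``sub`` (t, o)."""
    t, o = sub
    m = (dist < window) & (template == t) & (obs == o)
    return bool(m.any())


# deamination chemistry only produces C->T (and, seen from the opposite
# strand, G->A); estimated profiles are restricted to these cells so that
# sampling noise in the other ten substitution types cannot masquerade as
# damage rates
DEAMINATION_MASK = np.zeros((4, 4), dtype=bool)
DEAMINATION_MASK[_C, _T] = True
DEAMINATION_MASK[_G, _A] = True


def _rates(subs: np.ndarray, tot: np.ndarray) -> np.ndarray:
    """Counts -> rates restricted to the deamination substitution cells."""
    out = np.where(tot[..., None] > 0, subs / np.maximum(tot[..., None], 1), 0.0)
    return np.where(DEAMINATION_MASK, out, 0.0)


def _assemble_profile(end5, end3, interior) -> DeaminationProfile:
    """Combine per-end excess rates with a pooled interior baseline.

    Per-end measured rates include the fragment-wide interior rate, which the
    additive two-end lookup would otherwise count twice; the interior rate,
    estimated precisely from all positions far from both ends, is subtracted
    from the 3' table and appended to the 5' table as the fallback row, so
    the lookup reproduces it exactly once everywhere.
    """
    end5 = np.clip(np.vstack([end5, interior[None]]), 0.0, 1.0)
    end3 = np.vstack([np.clip(end3 - interior[None], 0.0, 1.0), np.zeros((1, 4, 4))])
    return DeaminationProfile(end5, end3)


def estimate_conditional_deamination(
    fragments: list[AlignedFragment],
    reference: ReferenceGenome,
    protocol: str = "single",
    max_depth: int = 15,
    window: int = 1,
) -> tuple[DeaminationProfile, dict]:
    """Endogenous deamination profile via opposite-end conditioning.

    For the 5'-end rates, only fragments whose 3' terminal base (within
    ``window`` positions) shows the protocol's 3' deamination substitution
    (C->T single-stranded, G->A double-stranded) are counted, and vice versa.
    Rates are (# substitutions x->y) / (# template-x sites) per position from
    the end; the conditioning end itself is excluded from measurement.

    Returns the profile and the conditioning fragment counts per end.
    """
    if protocol not in ("single", "double"):
        raise ValueError("protocol must be 'single' or 'double'")
    sub5 = (_C, _T)
    sub3 = (_C, _T) if protocol == "single" else (_G, _A)

    subs5 = np.zeros((max_depth, 4, 4))
    tot5 = np.zeros((max_depth, 4))
    subs3 = np.zeros((max_depth, 4, 4))
    tot3 = np.zeros((max_depth, 4))
    subs_int = np.zeros((4, 4))
    tot_int = np.zeros(4)
    n_cond5 = 0  # fragments conditioning the 5'-end measurement (3' deaminated)
    n_cond3 = 0

    for fr in fragments:
        template, obs, d5, d3 = _molecule_view(fr, reference)
        valid = (template < 4) & (obs < 4)
        cond5 = _is_deaminated_at(template, obs, d3, window, sub3)
        cond3 = _is_deaminated_at(template, obs, d5, window, sub5)
        if cond5:
            n_cond5 += 1
            sel = valid & (d5 < max_depth) & (d3 >= window)
            np.add.at(tot5, (d5[sel], template[sel]), 1)
            np.add.at(subs5, (d5[sel], template[sel], obs[sel]), 1)
        if cond3:
            n_cond3 += 1
            sel = valid & (d3 < max_depth) & (d5 >= window)
            np.add.at(tot3, (d3[sel], template[sel]), 1)
            np.add.at(subs3, (d3[sel], template[sel], obs[sel]), 1)
        if cond5 or cond3:
            sel = valid & (d5 >= max_depth) & (d3 >= max_depth)
            np.add.at(tot_int, template[sel], 1)
            np.add.at(subs_int, (template[sel], obs[sel]), 1)

    if n_cond5 == 0 and n_cond3 == 0:
        raise NoConditioningFragmentsError(
            "no fragment shows terminal deamination at either end; "
            "supply a deamination profile instead of estimating one"
        )

    profile = _assemble_profile(
        _rates(subs5, tot5), _rates(subs3, tot3), _rates(subs_int, tot_int)
    )
    return profile, {"5p": n_cond5, "3p": n_cond3}


def measure_deamination(
    fragments: list[AlignedFragment],
    reference: ReferenceGenome,
    max_depth: int = 15,
) -> DeaminationProfile:
    """Unconditional substitution-rate profile against a template sequence."""
    subs5 = np.zeros((max_depth, 4, 4))
    tot5 = np.zeros((max_depth, 4))
    subs3 = np.zeros((max_depth, 4, 4))
    tot3 = np.zeros((max_depth, 4))
    subs_int = np.zeros((4, 4))
    tot_int = np.zeros(4)
    for fr in fragments:
        template, obs, d5, d3 = _molecule_view(fr, reference)
        valid = (template < 4) & (obs < 4)
        sel = valid & (d5 < max_depth)
        np.add.at(tot5, (d5[sel], template[sel]), 1)
        np.add.at(subs5, (d5[sel], template[sel], obs[sel]), 1)
        sel = valid & (d3 < max_depth)
        np.add.at(tot3, (d3[sel], template[sel]), 1)
        np.add.at(subs3, (d3[sel], template[sel], obs[sel]), 1)
        sel = valid & (d5 >= max_depth) & (d3 >= max_depth)
        np.add.at(tot_int, template[sel], 1)
        np.add.at(subs_int, (template[sel], obs[sel]), 1)
    return _assemble_profile(
        _rates(subs5, tot5), _rates(subs3, tot3), _rates(subs_int, tot_int)
    )


# ---------------------------------------------------------------------------
# fragment likelihoods and the contamination posterior

def _fragment_logliks(
    fragments, reference, profile, err
) -> tuple[np.ndarray, np.ndarray]:
    """(log P[R_j | deaminated endogenous], log P[R_j | error-only]) per fragment."""
    pile = fragments if isinstance(fragments, Pileup) else Pileup(fragments, reference)
    ref_codes = pile.reference.codes[pile.site]
    valid = ref_codes < 4
    n_frag = len(pile.fragments)
    Pd = template_likelihoods(
        pile.base, pile.eps, pile.dist5, pile.dist3, pile.reverse, profile, err
    )
    Pn = null_likelihoods(pile.base, pile.eps, err)
    idx = np.arange(len(pile.site))
    t = np.where(valid, ref_codes, 0)
    ld_obs = np.where(valid, np.log(np.clip(Pd[idx, t], 1e-300, None)), 0.0)
    ln_obs = np.where(valid, np.log(np.clip(Pn[idx, t], 1e-300, None)), 0.0)
    Ld = np.bincount(pile.frag, weights=ld_obs, minlength=n_frag)
    Ln = np.bincount(pile.frag, weights=ln_obs, minlength=n_frag)
    return Ld, Ln


def fragment_loglik_deam(
    fragment: AlignedFragment,
    reference: ReferenceGenome,
    profile: DeaminationProfile,
    err: SubstitutionErrorModel,
) -> float:
    """Log-likelihood of the fragment under the deaminated-endogenous model."""
    Ld, _ = _fragment_logliks([fragment], reference, profile, err)
    return float(Ld[0])


def fragment_loglik_null(
    fragment: AlignedFragment,
    reference: ReferenceGenome,
    err: SubstitutionErrorModel,
) -> float:
    """Log-likelihood of the fragment under the error-only model."""
    _, Ln = _fragment_logliks([fragment], reference, DeaminationProfile.zero(), err)
    return float(Ln[0])


def contamination_posterior(
    fragments,
    reference: ReferenceGenome,
    profile: DeaminationProfile,
    err: SubstitutionErrorModel | None = None,
    grid_step: float = 0.005,
) -> PosteriorCurve:
    """Posterior over the contamination rate c_d on a uniform grid.

    Each fragment contributes log[(1-c) * P[R_j|deam] + c * P[R_j|null]];
    the mixture is evaluated in log space for numerical safety.  When no
    fragment distinguishes the two models the posterior is flat and the MAP
    is flagged undefined with a full-range interval.
    """
    if not (0 < grid_step <= 0.1):
        raise ValueError("grid_step must lie in (0, 0.1]")
    err = err or SubstitutionErrorModel.uniform()
    Ld, Ln = _fragment_logliks(fragments, reference, profile, err)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    flat = bool(np.allclose(Ld, Ln, atol=1e-12))
    with np.errstate(divide="ignore"):
        log1mc = np.log(np.clip(1.0 - grid, 0.0, None))[:, None]
        logc = np.log(np.clip(grid, 0.0, None))[:, None]
    loglik = np.logaddexp(log1mc + Ld[None, :], logc + Ln[None, :]).sum(axis=1)
    return curve_from_loglik(grid, loglik, flat=flat)
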