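"""Partition fragments by the consensus they support, then re-estimate the
deamination profiles and fragment-length models for each population.

At positions where the endogenous and contaminant consensus calls differ
(both confidently), each overlapping fragment votes with its observed base;
majority assigns it to one population, ties and non-overlapping fragments
stay unassigned.  Damage rates and log-normal length parameters re-fit on the
separated sets feed the next consensus-calling iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contdeam import measure_deamination
from .endocaller import FragmentLengthModel, SiteCall, consensus_sequence
from .io import AlignedFragment, ReferenceGenome
from .model import BASE_INDEX, DeaminationProfile

logger = logging.getLogger(__name__)

MIN_FRAGMENTS = 30
SIGMA_FLOOR = 0.01


@dataclass
class Partition:
    endo: list
    cont: list
    unassigned: list
    differing_sites: list  # (position, endo base, cont base)


def differing_call_sites(
    endo_calls: list[SiteCall],
    cont_calls: list[SiteCall] | None = None,
    quality_threshold: float = 50.0,
) -> list:
    """Sites where the two consensus tracks confidently disagree.

    ``cont_calls`` defaults to the same joint records (each SiteCall carries
    both tracks).
    """
    cont_calls = cont_calls if cont_calls is not None else endo_calls
    out = []
    for ec, cc in zip(endo_calls, cont_calls):
        if ec.coverage == 0:
            continue
        if ec.endo_base not in "ACGT" or cc.cont_base not in "ACGT":
            continue
        if ec.endo_base == cc.cont_base:
            continue
        if ec.endo_phred >= quality_threshold and cc.cont_phred >= quality_threshold:
            out.append((ec.ref_index, ec.endo_base, cc.cont_base))
    return out


def partition_fragments(
    fragments: list[AlignedFragment],
    endo_calls: list[SiteCall],
    cont_calls: list[SiteCall] | None = None,
    quality_threshold: float = 50.0,
) -> Partition:
    """Assign each fragment by majority vote over the differing sites it covers."""
    sites = differing_call_sites(endo_calls, cont_calls, quality_threshold)
    endo_at = {p: BASE_INDEX[e] for p, e, _ in sites}
    cont_at = {p: BASE_INDEX[c] for p, _, c in sites}
    if not sites:
        return Partition([], [], list(fragments), [])
    positions = np.array(sorted(endo_at), dtype=np.int64)
    endo_set, cont_set, unassigned = [], [], []
    for fr in fragments:
        mask = np.isin(fr.ref_pos, positions)
        if not mask.any():
            unassigned.append(fr)
            continue
        votes_e = votes_c = 0
        for pos, b in zip(fr.ref_pos[mask], fr.base[mask]):
            if b == endo_at[int(pos)]:
                votes_e += 1
            elif b == cont_at[int(pos)]:
                votes_c += 1
        if votes_e > votes_c:
            endo_set.append(fr)
        elif votes_c > votes_e:
            cont_set.append(fr)
        else:
            unassigned.append(fr)
    return Partition(endo_set, cont_set, unassigned, sites)


def refit_deamination(
    fragment_set: list[AlignedFragment],
    template,
    max_depth: int = 15,
    min_fragments: int = MIN_FRAGMENTS,
    previous: DeaminationProfile | None = None,
) -> DeaminationProfile:
    """Unconditional substitution-rate profile of an already-separated set.

    ``template`` is the sequence the substitutions are measured against --
    normally the population's own inferred consensus (a ReferenceGenome, a
    raw string, or a list of SiteCall records), falling back to the mapping
    reference when requested.  Too-small sets keep the previous profile.
    """
    if len(fragment_set) < min_fragments:
        logger.warning(
            "deamination refit skipped: %d fragments < %d", len(fragment_set), min_fragments
        )
        return previous if previous is not None else DeaminationProfile.zero(max_depth)
    if isinstance(template, list):  # SiteCall records
        template = ReferenceGenome("consensus", consensus_sequence(template, "endo"))
    elif isinstance(template, str):
        template = ReferenceGenome("template", template)
    return measure_deamination(fragment_set, template, max_depth=max_depth)


def _lognormal_mle(lengths: np.ndarray) -> tuple[float, float]:
    logs = np.log(lengths.astype(float))
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    return mu, max(sigma, SIGMA_FLOOR)


def refit_length_model(
    endo_set: list[AlignedFragment],
    cont_set: list[AlignedFragment],
    previous: FragmentLengthModel | None = None,
    min_fragments: int = MIN_FRAGMENTS,
) -> FragmentLengthModel:
    """Closed-form log-normal MLE (mu = mean ln l, sigma = sd ln l) per set.

    A side with fewer than ``min_fragments`` keeps its previous parameters;
    the model is enabled only when both sides have usable parameters.
    """
    prev = previous if previous is not None else FragmentLengthModel()
    mu_e, s_e = prev.mu_endo, prev.sigma_endo
    mu_c, s_c = prev.mu_cont, prev.sigma_cont
    have_e = previous is not None and previous.enabled
    have_c = previous is not None and previous.enabled
    if len(endo_set) >= min_fragments:
        mu_e, s_e = _lognormal_mle(np.array([f.length for f in endo_set]))
        have_e = True
    else:
        logger.warning("length refit: endogenous side kept previous parameters")
    if len(cont_set) >= min_fragments:
        mu_c, s_c = _lognormal_mle(np.array([f.length for f in cont_set]))
        have_c = True
    else:
        logger.warning("length refit: contaminant side kept previous parameters")
    return FragmentLengthModel(
        mu_endo=mu_e, sigma_endo=s_e, mu_cont=mu_c, sigma_cont=s_c,
        enabled=bool(have_e and have_c),
    )
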