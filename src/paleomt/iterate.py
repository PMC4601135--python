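"""Full pipeline: deamination prior -> joint consensus -> database-scan
contamination -> fragment split/refit, cycled until the contamination
estimate stabilises.

Iteration 0 uses the end-conditioned deamination profile and the
deamination-based contamination prior, with an undamaged contaminant profile
and the length channel disabled (nothing is known yet about the two length
distributions).  Every later iteration feeds the database-scan rate and the
split-refit profiles/length model back into the consensus caller.  The loop
stops when the rate moves less than ``tol`` between iterations, or early --
with an "insufficient contaminant information" flag -- when the contaminant
consensus is too poor to separate fragments or to place informative sites,
in which case the deamination-based estimate is reported.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

from . import contdeam as cd
from . import io as pio
from . import mtcont as mc
from . import splitendo as se
from .endocaller import EndoPriors, FragmentLengthModel, call_consensus
from .io import Pileup, ReferenceGenome
from .model import DeaminationProfile, SubstitutionErrorModel

logger = logging.getLogger(__name__)

DEFAULT_TOL = 0.005
DEFAULT_MAX_ITER = 10


@dataclass
class IterationRecord:
    iteration: int
    c_in: float
    c_out: float | None
    informative_sites: int
    n_endo_assigned: int
    n_cont_assigned: int
    best_contaminant: str | None = None


@dataclass
class RunResult:
    calls: list  # final joint SiteCall records
    estimate: float  # final contamination rate (per nucleotide when iterated)
    ci_low: float
    ci_high: float
    contdeam_curve: cd.PosteriorCurve
    mtcont_estimate: mc.ContaminationEstimate | None
    trace: list = field(default_factory=list)
    converged: bool = False
    insufficient_contaminant_info: bool = False
    iterations: int = 0
    initial_calls: list | None = None  # iteration-0 calls, for before/after audits


def run_pipeline(
    fragments,
    reference: ReferenceGenome,
    db: list[tuple[str, str]] | None = None,
    protocol: str = "single",
    err: SubstitutionErrorModel | None = None,
    grid_step: float = 0.005,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    split_quality: float = 50.0,
    use_predicted_contaminant: bool = True,
    max_depth: int = 15,
    out_dir: str | None = None,
) -> RunResult:
    """Run the iterative joint inference to convergence.

    ``db`` is optional: without it the database scan relies entirely on the
    predicted contaminant consensus.  All randomness-free; identical inputs
    give identical outputs.
    """
    err = err or SubstitutionErrorModel.uniform()
    pileup = Pileup(fragments, reference)

    # iteration 0: deamination-based prior and end-conditioned profile
    endo_profile, _counts = cd.estimate_conditional_deamination(
        fragments, reference, protocol=protocol, max_depth=max_depth
    )
    prior_curve = cd.contamination_posterior(
        pileup, reference, endo_profile, err, grid_step=grid_step
    )
    c_current = prior_curve.map_rate if not prior_curve.flat else 0.0
    priors = EndoPriors(
        contamination=c_current,
        endo_profile=endo_profile,
        cont_profile=DeaminationProfile.zero(max_depth),
        length_model=FragmentLengthModel.disabled(),
    )
    calls = call_consensus(pileup, reference, priors, err)
    trace = [IterationRecord(0, c_current, None, 0, 0, 0)]
    _dump_iteration(out_dir, 0, reference, calls, priors, None)

    result = RunResult(
        calls=calls,
        estimate=c_current,
        ci_low=prior_curve.ci_low,
        ci_high=prior_curve.ci_high,
        contdeam_curve=prior_curve,
        mtcont_estimate=None,
        trace=trace,
        initial_calls=calls,
    )

    prev_rate = None
    for t in range(1, max_iter + 1):
        try:
            est = mc.estimate_contamination(
                pileup, calls, db,
                priors=priors, err=err, grid_step=grid_step,
                include_predicted_contaminant=use_predicted_contaminant,
                predicted_cont_calls=calls if use_predicted_contaminant else None,
            )
        except (mc.NoInformativeSitesError, ValueError) as exc:
            logger.info("iteration %d: stopping early (%s)", t, exc)
            result.insufficient_contaminant_info = True
            break

        part = se.partition_fragments(fragments, calls, quality_threshold=split_quality)
        if not part.differing_sites or (not part.endo and not part.cont):
            logger.info("iteration %d: no confidently differing sites; stopping early", t)
            result.insufficient_contaminant_info = True
            break

        endo_profile = se.refit_deamination(
            part.endo, calls, max_depth=max_depth, previous=priors.endo_profile
        )
        cont_template = ReferenceGenome(
            "cont_consensus",
            "".join(
                c.cont_base if c.cont_base in "ACGT" and c.coverage else "N" for c in calls
            ),
        )
        cont_profile = se.refit_deamination(
            part.cont, cont_template, max_depth=max_depth, previous=priors.cont_profile
        )
        length_model = se.refit_length_model(
            part.endo, part.cont, previous=priors.length_model
        )

        c_current = est.rate
        priors = EndoPriors(
            contamination=c_current,
            endo_profile=endo_profile,
            cont_profile=cont_profile,
            length_model=length_model,
        )
        calls = call_consensus(pileup, reference, priors, err)
        trace.append(
            IterationRecord(
                t, priors.contamination, est.rate, est.informative_site_count,
                len(part.endo), len(part.cont), est.best_contaminant,
            )
        )
        _dump_iteration(out_dir, t, reference, calls, priors, est)
        result.calls = calls
        result.estimate = est.rate
        result.ci_low, result.ci_high = est.ci_low, est.ci_high
        result.mtcont_estimate = est
        result.iterations = t
        if prev_rate is not None and abs(est.rate - prev_rate) < tol:
            result.converged = True
            break
        prev_rate = est.rate

    if result.insufficient_contaminant_info:
        # fall back to the deamination-based estimate, as the iterative one
        # has no contaminant signal to work with
        result.estimate = prior_curve.map_rate if not prior_curve.flat else 0.0
        result.ci_low = prior_curve.ci_low
        result.ci_high = prior_curve.ci_high
    return result


def _dump_iteration(out_dir, t, reference, calls, priors, est) -> None:
    if out_dir is None:
        return
    d = os.path.join(out_dir, f"iter_{t}")
    os.makedirs(d, exist_ok=True)
    pio.write_consensus(
        calls, os.path.join(d, "endo.fa"), os.path.join(d, "endo.log"),
        name=f"{reference.name}_endo", which="endo",
    )
    pio.write_consensus(
        calls, os.path.join(d, "cont.fa"), os.path.join(d, "cont.log"),
        name=f"{reference.name}_cont", which="cont",
    )
    pio.write_profile(priors.endo_profile.end5, os.path.join(d, "endo.5p.prof"))
    pio.write_profile(priors.endo_profile.end3, os.path.join(d, "endo.3p.prof"))
    summary = {
        "iteration": t,
        "contamination_prior": priors.contamination,
        "mtcont_rate": None if est is None else est.rate,
        "mtcont_ci": None if est is None else [est.ci_low, est.ci_high],
        "best_contaminant": None if est is None else est.best_contaminant,
    }
    with open(os.path.join(d, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
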