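"""Per-nucleotide contamination rate and contaminant identification.

Given the per-site endogenous base posteriors from the consensus caller and a
database of candidate contaminant genomes aligned to the reference coordinate
system, the likelihood of every contamination rate c_r on a grid is evaluated
at *informative* sites -- positions where the called endogenous base and the
candidate's base differ.  Each observed base there is explained as a mixture:
with probability 1 - c_r it reflects an endogenous base (deamination-aware
model, weighted by the endogenous base posterior), with probability c_r the
candidate's base (sequencing-error-only model).  The candidate with the
highest maximum likelihood is reported together with the MAP rate and a 95 %
highest-posterior-density interval.

Because the rate estimated here is per sampled base, not per fragment, it
exceeds the fragment-level rate whenever contaminant fragments are longer
than endogenous ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contdeam import PosteriorCurve, curve_from_loglik
from .endocaller import EndoPriors, SiteCall
from .io import IUPAC_SETS, Pileup, PileupColumn
from .model import (
    BASE_INDEX,
    SubstitutionErrorModel,
    null_likelihoods,
    template_likelihoods,
)


class NoInformativeSitesError(RuntimeError):
    """No candidate genome differs from the endogenous consensus anywhere."""


@dataclass
class DiagnosticSiteSet:
    """Sites where the endogenous and a contaminant genome disagree."""

    sites: list  # (position, endogenous allele, contaminant allele)

    def __len__(self):
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for p, _, _ in self.sites], dtype=np.int64)


@dataclass
class GenomeScan:
    name: str
    loglik_max: float
    map_rate: float
    ci_low: float
    ci_high: float
    n_sites: int
    curve: PosteriorCurve | None = None
    degenerate: bool = False


@dataclass
class ContaminationEstimate:
    rate: float
    ci_low: float
    ci_high: float
    best_contaminant: str
    table: dict = field(default_factory=dict)  # name -> GenomeScan
    informative_site_count: int = 0

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.rate <= self.ci_high <= 1.0):
            raise ValueError("require 0 <= ci_low <= rate <= ci_high <= 1")


def informative_sites(endo_calls: list[SiteCall], contaminant: str) -> DiagnosticSiteSet:
    """Positions where the MAP endogenous base and the candidate base differ.

    Gapped or N positions are skipped; an IUPAC code counts as differing only
    when the endogenous base lies outside the code's set.
    """
    sites = []
    for call in endo_calls:
        i = call.ref_index
        if i >= len(contaminant):
            break
        e = call.endo_base
        c = contaminant[i].upper()
        if call.coverage == 0 or e not in "ACGT" or c in "-N":
            continue
        allowed = IUPAC_SETS.get(c)
        if allowed is None:
            continue
        if e not in allowed:
            sites.append((i, e, c))
    return DiagnosticSiteSet(sites)


def _cont_prior_vector(code: str) -> np.ndarray:
    """P[c] over A/C/G/T: uniform over the IUPAC set of the database base."""
    allowed = IUPAC_SETS.get(code.upper(), set())
    v = np.zeros(4)
    for b in allowed:
        v[BASE_INDEX[b]] = 1.0
    s = v.sum()
    return v / s if s else v


def site_rate_likelihood(
    column: PileupColumn,
    endo_marginals: np.ndarray,
    cont_base: str,
    c_r: float,
    priors: EndoPriors,
    err: SubstitutionErrorModel | None = None,
    log: bool = False,
) -> float:
    """Likelihood of one column's observations at contamination rate c_r.

    Marginalises over (b_e, c) in Omega^2 with P[b_e, c] = P[b_e] P[c]; the
    endogenous branch uses the deamination-aware model, the contaminant
    branch sequencing errors only.  Mismapping contributes a flat 1/4.
    """
    err = err or SubstitutionErrorModel.uniform()
    if not 0.0 <= c_r <= 1.0:
        raise ValueError("c_r must lie in [0, 1]")
    Pe = template_likelihoods(
        column.base, column.eps, column.dist5, column.dist3, column.reverse,
        priors.endo_profile, err,
    )
    Pn = null_likelihoods(column.base, column.eps, err)
    w_e = np.asarray(endo_marginals, dtype=float)
    w_c = _cont_prior_vector(cont_base)
    # the mixture is bilinear in (b_e, c), so the Omega^2 marginalisation
    # collapses to two weighted template likelihoods per observation
    A = Pe @ w_e
    B = Pn @ w_c
    m = column.mismap
    per_obs = (1.0 - m) * ((1.0 - c_r) * A + c_r * B) + m * 0.25
    ll = float(np.log(np.clip(per_obs, 1e-300, None)).sum())
    return ll if log else float(np.exp(ll))


def _scan_genome(
    pileup: Pileup,
    endo_calls,
    sites: DiagnosticSiteSet,
    contaminant: str,
    grid: np.ndarray,
    priors: EndoPriors,
    err: SubstitutionErrorModel,
) -> tuple[np.ndarray, int]:
    """Log-likelihood over the rate grid, pooled over informative sites."""
    A_parts, B_parts, m_parts = [], [], []
    for pos, _e, c in sites:
        lo, hi = pileup.starts[pos], pileup.starts[pos + 1]
        if hi == lo:
            continue
        Pe = template_likelihoods(
            pileup.base[lo:hi], pileup.eps[lo:hi], pileup.dist5[lo:hi],
            pileup.dist3[lo:hi], pileup.reverse[lo:hi], priors.endo_profile, err,
        )
        Pn = null_likelihoods(pileup.base[lo:hi], pileup.eps[lo:hi], err)
        A_parts.append(Pe @ endo_calls[pos].endo_marginals)
        B_parts.append(Pn @ _cont_prior_vector(c))
        m_parts.append(pileup.mismap[lo:hi])
    if not A_parts:
        return np.full(len(grid), -np.inf), 0
    A = np.concatenate(A_parts)
    B = np.concatenate(B_parts)
    m = np.concatenate(m_parts)
    T = (1.0 - m) * A
    U = (1.0 - m) * B
    V = m * 0.25
    per = (1.0 - grid)[:, None] * T[None, :] + grid[:, None] * U[None, :] + V[None, :]
    loglik = np.log(np.clip(per, 1e-300, None)).sum(axis=1)
    return loglik, len(A)


def predicted_contaminant_sequence(cont_calls, quality_threshold: float = 200.0) -> str:
    """Contaminant consensus with low-confidence positions masked to N."""
    out = []
    for c in cont_calls:
        if c.coverage == 0 or c.cont_phred < quality_threshold or c.cont_base not in "ACGT":
            out.append("N")
        else:
            out.append(c.cont_base)
    return "".join(out)


def estimate_contamination(
    fragments,
    endo_calls,
    db: list[tuple[str, str]] | None,
    *,
    priors: EndoPriors,
    reference=None,
    err: SubstitutionErrorModel | None = None,
    grid_step: float = 0.005,
    include_predicted_contaminant: bool = False,
    predicted_cont_calls=None,
    keep_curves: bool = False,
) -> ContaminationEstimate:
    """MAP contamination rate and most likely contaminant source.

    ``db`` records must be aligned to the reference coordinate system.  With
    ``include_predicted_contaminant`` the caller's own contaminant consensus
    (PHRED >= 200 positions, others masked N) is appended as a database
    record, which sharpens the estimate once contamination is high enough for
    that consensus to be reliable.
    """
    err = err or SubstitutionErrorModel.uniform()
    pileup = fragments if isinstance(fragments, Pileup) else Pileup(fragments, reference)
    records = list(db) if db else []
    if include_predicted_contaminant:
        if predicted_cont_calls is None:
            raise ValueError("predicted_cont_calls required with include_predicted_contaminant")
        records.append(
            ("predicted_contaminant", predicted_contaminant_sequence(predicted_cont_calls))
        )
    if not records:
        raise ValueError("database empty and no predicted contaminant supplied")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    table: dict[str, GenomeScan] = {}
    best: GenomeScan | None = None
    for name, seq in records:
        sites = informative_sites(endo_calls, seq)
        if len(sites) == 0:
            table[name] = GenomeScan(name, -np.inf, float("nan"), 0.0, 1.0, 0, degenerate=True)
            continue
        loglik, n_obs = _scan_genome(pileup, endo_calls, sites, seq, grid, priors, err)
        if n_obs == 0:
            table[name] = GenomeScan(name, -np.inf, float("nan"), 0.0, 1.0, 0, degenerate=True)
            continue
        curve = curve_from_loglik(grid, loglik)
        scan = GenomeScan(
            name, float(loglik.max()), curve.map_rate, curve.ci_low, curve.ci_high,
            len(sites), curve=curve if keep_curves else None,
        )
        table[name] = scan
        if best is None or scan.loglik_max > best.loglik_max:
            best = scan
    if best is None:
        raise NoInformativeSitesError(
            "no informative sites: every candidate matches the endogenous consensus"
        )
    return ContaminationEstimate(
        rate=best.map_rate,
        ci_low=best.ci_low,
        ci_high=best.ci_high,
        best_contaminant=best.name,
        table=table,
        informative_site_count=best.n_sites,
    )


def diagnostic_ratio(base_counts_endo: int, base_counts_cont: int) -> float:
    """Contamination fraction from diagnostic-position base counts.

    Returns cont / (endo + cont); report as a percentage to one decimal for
    display.
    """
    if base_counts_endo < 0 or base_counts_cont < 0:
        raise ValueError("counts must be non-negative")
    total = base_counts_endo + base_counts_cont
    if total == 0:
        raise ValueError("counts must not both be zero")
    return base_counts_cont / total
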