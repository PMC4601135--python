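# Methods

`paleomt` jointly infers the endogenous mitochondrial consensus of an ancient
sample, the consensus of the present-day human DNA contaminating it, and the
contamination rate, from reads aligned to a mitochondrial reference. This
note describes the statistical model, the estimator design choices, what the
synthetic-data generator does and does not emulate, and the numerical
conventions.

## Observation model

Every aligned base r_i carries a base-caller error probability
eps_i = 10^(-Q/10) and belongs to a fragment with mismapping probability
m = 10^(-MAPQ/10). Two nested models describe how r_i arises from a template
base b:

- **error-only (null)**: P[r|b] = 1 - eps if r = b, else eps * P[b->r|E].
  The substitution-given-error term P[b->r|E] defaults to 1/3; an empirical
  4x4 matrix (rows normalised over the three mismatches) can be supplied as a
  TSV.
- **deamination-aware**: a position-dependent rate table
  rate(b->b', d5, d3) may additionally convert the template before
  sequencing. Match branch: (1-eps) * (1 - sum_b' rate(b->b')); mismatch
  branch: (1-eps) * rate(b->r) + eps * P[b->r|E]. The joint event
  "deamination and sequencing error at the same base" is second-order small
  and ignored; as a consequence the four observation probabilities sum to 1
  exactly only when the match-branch complement is computed from unclamped
  rates (asserted to 1e-9 in the tests).

Damage profiles are stored per end in *molecule orientation*: `end5[i]` and
`end3[i]` are 4x4 rate matrices at distance i from the 5'/3' end of the
original molecule. The rate at a base is `end5[d5] + end3[d3]`, clamped to
[0, 1] — terminal damage has near-disjoint support at the two ends, so
addition is the natural combination. Beyond the modelled depth (default 15
positions per end) the last row applies. For reverse-strand reads, stored
in reference-forward orientation, end distances are mirrored and the matrix
is complement-mirrored (a molecule C->T appears as G->A).

## Deamination-based contamination prior

Ancient molecules carry terminal cytosine deamination; present-day
contaminants essentially do not. The endogenous deamination profile is
estimated by **end conditioning**: for the 5'-end rates, only fragments whose
3'-terminal base shows the protocol's deamination substitution versus the
reference (C->T single-stranded, G->A double-stranded) are counted; the
conditioning end itself is excluded from measurement. The mapping reference
serves as the endogenous template.

Two estimator details matter in practice and are this package's own design:

- **Cell restriction.** Only the C->T and G->A cells of the counted tables
  are kept. The other ten substitution types are not produced by deamination;
  with a few hundred conditioning fragments their counted "rates" are pure
  sampling noise (one stray error in 200 observations reads as 0.005), and
  carrying them into the likelihood lets reference-contaminant divergence
  masquerade as damage, visibly biasing the mixture estimate.
- **Pooled interior baseline.** Each end's measured rates include the
  position-independent interior rate, which the additive two-end lookup would
  count twice. The interior rate is estimated once from all positions at
  least `max_depth` from both ends (a much larger count than any single row),
  appended to the 5' table as its fallback row, and subtracted from the 3'
  table. The lookup then reproduces the interior rate exactly once
  everywhere.

Given the profile, each fragment R_j is scored under the deaminated model
(L_deam, endogenous hypothesis) and the error-only model (L_null,
contaminant hypothesis), both against the reference, and the contamination
rate c_d gets the gridded posterior

    P[c_d | data] ∝ prod_j [ (1-c_d) e^{L_deam,j} + c_d e^{L_null,j} ]

with a uniform prior, evaluated in log space. The default grid step is 0.005
(matching the precision at which such estimates are conventionally
reported); the 95 % interval is the highest-posterior-density set on the
grid. If no fragment distinguishes the models the posterior is flat and the
MAP is flagged undefined.

Accuracy caveats, measured on synthetic data: the estimator needs a few
thousand conditioning fragments for the profile to support +-0.05 recovery
(with ~100 conditioning fragments the MAP scatters by ~+-0.1 even under the
generating profile), and unmodelled divergence between the contaminant and
the reference produces a mild shrinkage of extreme rates. A deaminated
contaminant biases the estimate downward, as expected from the model.

## Joint consensus calling

At each reference position the posterior over the 16 ordered pairs
(b_e, b_c) of endogenous and contaminant bases is

    P[b_e, b_c | R] ∝ prod_j [ (1-m_j) ( p_j P_e[r_j|b_e] + (1-p_j) P_c[r_j|b_c] ) + m_j/4 ] * 1/16

where p_j = P[R_j in E] is the fragment's endogeneity probability, P_e uses
the endogenous profile and P_c the (typically near-zero) contaminant
profile. A single contaminant base per site is assumed; multiple
simultaneous contaminants are a known limitation. Marginalising over one
coordinate gives each track's base posterior; the call is the argmax and its
error probability the summed alternatives, reported as PHRED (capped at
9999). The alternatives are summed directly rather than via 1 - max so that
errors far below machine epsilon (PHRED >> 160) remain exact. Zero-coverage
sites call 'N' at PHRED 0; an all-mismapped column yields uniform marginals
(error 3/4, i.e. PHRED 1.25).

**Fragment endogeneity.** p_j combines two evidence channels:

- *deamination*: the fragment is scored under the deaminated and error-only
  models, each marginalised over the current per-site endogenous base
  posteriors (so an uncertain consensus softens the evidence);
- *length*: log-normal densities for the endogenous and contaminant length
  distributions.

The two likelihoods multiply and the prior 1 - c_c enters once (chaining the
two channel posteriors would square the prior). Within one calling run the
per-site posteriors that the deamination channel needs are themselves the
caller's output; the run therefore makes two passes: pass 1 scores every
site with the neutral prior 1 - c_c per fragment, pass 2 re-scores with the
per-fragment posteriors computed from pass 1.

**Indels** are handled by a deliberately simplified extension: deletions
enlarge the per-site symbol set with a gap symbol (gap observations score
1 - eps under a gap template, with eps from flanking base qualities; base
observations score eps/4 under a gap template), and insertions are scored
over the observed strings plus "no insertion" with the same mixture
machinery. The generator does not simulate indel damage, so this path is
exercised only by constructed fixtures.

## Database-scan contamination estimate

Given the consensus call and a database of candidate contaminant genomes
aligned to the reference coordinates, the per-nucleotide rate c_r is
estimated at **informative sites** — positions where the called endogenous
base and the candidate base differ (IUPAC codes count as differing only when
the endogenous base is outside the code's set; gapped or N positions are
skipped). Each observation there is the mixture

    P[r] = (1-m) [ (1-c_r) sum_b P[b] P_e[r|b] + c_r sum_c P[c] P_n[r|c] ] + m/4

with P[b] the endogenous base posterior from the caller, P[c] an indicator
(uniform over an IUPAC set) of the database base, the endogenous branch
deamination-aware and the contaminant branch error-only. Because the
expression is bilinear in (b, c), the Omega^2 marginalisation collapses to
two weighted template likelihoods per observation; a brute-force enumeration
over all 16 pairs serves as the test oracle. The likelihood is evaluated on
the same 0.005 grid per candidate genome; the candidate with the highest
maximum likelihood is reported with its MAP rate and 95 % HPD interval.

The estimate is per sampled *base*: when contaminant fragments are longer
than endogenous ones, it exceeds the per-fragment mixing rate, and the
simulator records the per-nucleotide truth for exactly this reason.
Optionally the caller's own contaminant consensus (positions at PHRED >=
200, others masked to N) is appended as a database record; at high
contamination this record is accurate and sharpens the estimate, whereas a
database whose nearest record is tens of substitutions from the real
contaminant drives a marked underestimate.

## Fragment splitting and refits

At positions where the two consensus tracks confidently differ (both PHRED
>= 50 by default), each overlapping fragment votes with its observed base;
majority assigns it endogenous or contaminant, ties and non-overlapping
fragments stay unassigned. On the separated sets the damage profiles are
re-measured (against each population's own inferred consensus, not the
mapping reference, to avoid divergence masquerading as damage — the
reference-based variant is available) and the length models re-fit by the
closed-form log-normal MLE (mu = mean ln l, sigma = sd ln l, floored at
0.01). Sets smaller than 30 fragments keep their previous parameters.

## Iteration

Iteration 0 uses the end-conditioned profile and deamination-based prior,
with a zero contaminant profile and the length channel disabled (nothing is
known yet about the two length distributions). Each later iteration feeds
the database-scan rate and the refreshed profiles/length model back into the
caller, stopping when the rate moves less than 0.005 (the grid resolution)
or after 10 iterations. If the contaminant consensus is too poor to place
informative sites or to separate fragments — the typical situation near zero
contamination — the run stops early, flags "insufficient contaminant
information", and reports the deamination-based estimate. The pipeline is
deterministic: identical inputs give identical outputs and traces.

## Synthetic data

The generator emulates: log-normal fragment lengths (defaults ln 45 / 0.35
endogenous vs ln 85 / 0.35 contaminant — ancient shorter than modern),
uniform placement on a linear genome (no origin-spanning fragments), random
strand, protocol-specific terminal deamination with geometric positional
decay (rate(i) = baseline + terminal * decay^i; defaults 0.01 + 0.30 *
0.5^i), PHRED-consistent uniform sequencing errors at constant base quality
(Q30), constant MAPQ 60, and Bernoulli mixing of contaminant fragments at a
chosen fraction. Damage (terminal and baseline alike) applies to endogenous
molecules only unless a contaminant damage rate is explicitly set. The
geometric profile is a parametric stand-in with realistic terminal
behaviour; empirical profiles from real libraries decay similarly but not
exactly geometrically. Per-read truth labels and the realised per-nucleotide
contamination are recorded.

Not emulated: indel damage, paired-end artefacts, microbial background
reads, capture/ascertainment bias, quality-score miscalibration, multiple
simultaneous contaminants (supported by configuration but not a default
condition), and circular-genome wraparound. Passing tests on this generator
therefore demonstrate correctness of the inference under its stated model,
not robustness to those real-data features.

By default the mapping reference is the endogenous genome itself; real
analyses align to a community reference that diverges from both genomes, and
unmodelled reference divergence is one source of the residual bias noted
above.

## Numerical conventions and problem sizes

All likelihood products are accumulated in log space; probabilities are
floored at 1e-300 before logs. Grids run 0 to 1 inclusive at step 0.005.
Internal coordinates are 0-based half-open; all written logs are 1-based.
PHRED caps at 9999.

The test suite and the acceptance script run scaled-down analogues of the
method's validation experiments, as the package's own choice of problem
size: a 10 kb genome pair with 50 substitutions at up to 60,000 fragments
(~300x) for consensus accuracy and the 50 %-mixture estimates, a 5 kb pair
at 200x for the contamination-recovery sweep, and ~150x for the
58 %-contamination iteration audit. At these sizes every behaviour the
method claims — error-free endogenous consensus up to 50 % contamination,
per-nucleotide rate recovery within a few percent, divergent-database
underestimation, early stop without contaminant signal, and iteration
strictly improving a heavily contaminated consensus — reproduces.
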