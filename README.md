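# paleomt

Endogenous mitochondrial consensus calling and present-day human
contamination estimation for ancient DNA.

## The problem

DNA recovered from ancient remains is short (typically < 60 bp), carries
cytosine deamination — C→T substitutions enriched at fragment ends (read as
G→A at the 3′ end for double-stranded library protocols) — and is mixed with
present-day human DNA from excavation and handling. Contaminant fragments
align to the mitochondrial reference alongside the endogenous ones, so at
contamination rates above a few percent a naive consensus is wrong and every
downstream analysis (phylogenetics, population genetics, haplogroup calls)
inherits the errors. `paleomt` is for researchers reconstructing ancient
mitochondrial (or other small haploid) genomes who need both an accurate
endogenous consensus and a calibrated contamination estimate from a single
aligned library — without discarding the non-deaminated majority of reads.

## The model

Three linked Bayesian estimators are iterated until the contamination rate
stabilises:

1. **Deamination prior.** Endogenous damage rates are measured by
   conditioning on the opposite fragment end being deaminated; each fragment
   R_j is then scored under a deaminated model (L_deam) and an error-only
   model (L_null), and the fragment-level contamination rate c gets the grid
   posterior P[c | ℝ] ∝ ∏_j [(1−c) e^{L_deam,j} + c e^{L_null,j}].
2. **Joint consensus.** Per site, the posterior over endogenous/contaminant
   base pairs (b_e, b_c) ∈ Ω² is
   P[b_e, b_c | ℝ] ∝ ∏_j [(1−m_j)(p_j P_e[r_j|b_e] + (1−p_j) P_c[r_j|b_c]) + m_j/4],
   where p_j = P[R_j ∈ 𝔼] combines each fragment's deamination pattern and
   its length under two log-normal distributions, and m_j = 10^(−MAPQ/10) is
   the mismapping probability. Marginals give both consensus bases with
   PHRED-scaled qualities.
3. **Database scan.** At sites where the called endogenous base differs from
   a candidate contaminant genome, the per-nucleotide rate c_r is estimated
   from the mixture (1−c_r) P_e[r|b_e] + c_r P_c[r|c], scanned over a grid
   for every candidate; the best candidate and a 95 % HPD interval are
   reported. The caller's own contaminant consensus (PHRED ≥ 200 positions)
   can join the database, which sharpens the estimate at high contamination.

Between iterations, fragments are partitioned by the consensus they support
and the damage profiles and length models re-fit per population. A bundled
simulator generates synthetic libraries with known truth (log-normal
lengths, protocol-specific geometric-decay damage, PHRED-consistent errors,
chosen mixing rate), so the whole method is testable offline. See
`docs/methods.md` for the full model and design choices.

## Worked example

Simulate a single-stranded library at 40 % fragment contamination and run
the full pipeline:

```bash
cat > sim.json <<'EOF'
{"genome_length": 5000, "n_substitutions": 50, "contamination": 0.4,
 "n_fragments": 20000, "protocol": "single", "seed": 11}
EOF
paleomt simulate --config sim.json --out lib
paleomt run --ref lib.ref.fa --bam lib.sam --db lib.cont.fa \
            --protocol single --out run/ --seed 11
```

which prints

```
simulated 20000 fragments; per-nucleotide contamination 0.5548
final contamination 0.560 [0.550, 0.565] after 2 iterations
```

The simulator mixed 40 % contaminant *fragments*, but contaminant molecules
are longer, so 55.5 % of sampled *bases* are contaminant — that per-base
rate is what the database scan estimates, and 0.560 recovers it to half a
percent. The run directory holds one subdirectory per iteration with both
consensus FASTAs, per-site logs and profiles; `run/trace.tsv` records the
iteration history:

```
iteration  c_in    c_out   informative_sites  n_endo  n_cont  best
0          0.3100          0                  0       0
1          0.5600  0.5600  50                 4718    4904    cont0
2          0.5600  0.5600  50                 4718    4904    cont0
```

(iteration 0 is the deamination-based prior, on the fragment scale and
dragged down here by contaminant–reference divergence; the database scan
corrects it). Both final
consensus sequences match the simulated truth exactly (0 mismatches over
5,000 positions on each track). The classic diagnostic-position check is
also available directly:

```bash
$ paleomt diagratio --endo 2443418 --cont 1989785
44.9%
```

Each stage (`contdeam`, `endocaller`, `mtcont`, `splitendo`) is also a
standalone subcommand; `paleomt --help` lists them.

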