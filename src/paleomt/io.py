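"""Readers and writers for the external formats, and the internal
fragment/pileup model that every estimator consumes.

Coordinates are 0-based half-open internally; SAM input is converted on read
and all written logs are 1-based (the convention of mitochondrial position
reporting).  The reference is treated as linear: origin-spanning alignments
are not reconstructed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

from .model import (
    BASES,
    N_CODE,
    SUBSTITUTIONS,
    SubstitutionErrorModel,
    decode_base,
    encode_sequence,
    phred_to_prob,
)

__all__ = [
    "ReferenceGenome",
    "AlignedFragment",
    "Pileup",
    "PileupColumn",
    "SubstitutionErrorModel",
    "read_reference",
    "read_alignment",
    "read_contaminant_db",
    "read_profile",
    "write_profile",
    "read_error_model",
    "write_error_model",
    "write_consensus",
]

logger = logging.getLogger(__name__)

IUPAC_SETS = {code: set(vals) for code, vals in ambiguous_dna_values.items()}
IUPAC_SETS["N"] = set("ACGT")


@dataclass
class ReferenceGenome:
    """The mapping reference: name, uppercase sequence, circularity flag.

    Circularity is metadata only; alignments are treated as linear.
    """

    name: str
    sequence: str
    circular: bool = False

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError("reference sequence is empty")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("reference alphabet restricted to A/C/G/T/N")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        if not hasattr(self, "_codes"):
            self._codes = encode_sequence(self.sequence)
        return self._codes


def read_reference(path, name: str | None = None, circular: bool = False) -> ReferenceGenome:
    """Read a (single-record) FASTA reference; ``name`` selects a record."""
    for rec in SeqIO.parse(str(path), "fasta"):
        if name is None or rec.id == name:
            return ReferenceGenome(rec.id, str(rec.seq), circular=circular)
    raise ValueError(f"reference record {name!r} not found in {path}")


@dataclass
class AlignedFragment:
    """One mapped sequencing read (= one ancient-DNA molecule).

    Aligned (match) bases are stored as parallel arrays; insertions and
    deletions relative to the reference are kept separately.  ``length`` is
    the number of read bases excluding soft clips, so it equals the observed
    fragment length for merged aDNA reads.
    """

    read_id: str
    ref_start: int
    mapq: int
    reverse_strand: bool
    length: int
    ref_pos: np.ndarray  # int32, reference position of each matched base
    read_idx: np.ndarray  # int32, index of each matched base within the read
    base: np.ndarray  # int8 codes
    qual: np.ndarray  # int16 PHRED
    insertions: list = field(default_factory=list)  # (ref_pos, read_idx, seq, mean_qual)
    deletions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    del_qual: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def mismap(self) -> float:
        """Probability the fragment is mismapped, 10^(-MAPQ/10)."""
        return float(phred_to_prob(self.mapq))

    @property
    def eps(self) -> np.ndarray:
        return phred_to_prob(self.qual)

    @property
    def dist5(self) -> np.ndarray:
        """Distance of each matched base from the molecule's 5' end."""
        if self.reverse_strand:
            return (self.length - 1) - self.read_idx
        return self.read_idx

    @property
    def dist3(self) -> np.ndarray:
        if self.reverse_strand:
            return self.read_idx
        return (self.length - 1) - self.read_idx

    @property
    def pairs(self) -> list:
        """Ordered (read_index | None, ref_index | None, base, qual) tuples."""
        events = []
        for i in range(len(self.ref_pos)):
            events.append(
                (int(self.read_idx[i]), int(self.ref_pos[i]),
                 decode_base(int(self.base[i])), int(self.qual[i]))
            )
        for ref_pos, read_idx, seq, mq in self.insertions:
            for k, ch in enumerate(seq):
                events.append((read_idx + k, None, ch, mq))
        for j, d in enumerate(self.deletions):
            q = float(self.del_qual[j]) if len(self.del_qual) else None
            events.append((None, int(d), None, q))
        # order by reference progression, insertions anchored before the next
        # reference base, using the read index as tie-breaker
        def key(ev):
            ridx, refidx, _, _ = ev
            anchor = refidx if refidx is not None else self._ins_anchor(ridx)
            return (anchor, ridx if ridx is not None else -1)

        return sorted(events, key=key)

    def _ins_anchor(self, read_idx):
        for ref_pos, ridx, seq, _ in self.insertions:
            if ridx <= read_idx < ridx + len(seq):
                return ref_pos
        return self.ref_start


_MATCH_OPS = {0, 7, 8}  # M, =, X


def _fragment_from_read(read: pysam.AlignedSegment) -> AlignedFragment | None:
    seq = read.query_sequence
    quals = read.query_qualities
    if seq is None or quals is None:
        return None
    ref = read.reference_start
    q = 0
    ref_pos, read_idx, bases, bquals = [], [], [], []
    insertions = []
    deletions, del_quals = [], []
    n_clipped_lead = 0
    # read index below counts only non-soft-clipped bases
    aligned_i = 0
    for op, ln in read.cigartuples:
        if op in _MATCH_OPS:
            for k in range(ln):
                ref_pos.append(ref + k)
                read_idx.append(aligned_i + k)
                bases.append(seq[q + k])
                bquals.append(quals[q + k])
            ref += ln
            q += ln
            aligned_i += ln
        elif op == 1:  # insertion
            mq = float(np.mean(quals[q : q + ln]))
            insertions.append((ref, aligned_i, seq[q : q + ln], mq))
            q += ln
            aligned_i += ln
        elif op == 2:  # deletion
            flank = []
            if q > 0:
                flank.append(quals[q - 1])
            if q < len(quals):
                flank.append(quals[q])
            mq = float(np.mean(flank)) if flank else 20.0
            for k in range(ln):
                deletions.append(ref + k)
                del_quals.append(mq)
            ref += ln
        elif op == 4:  # soft clip: excluded
            q += ln
            if aligned_i == 0:
                n_clipped_lead += ln
        elif op == 3:  # N: skip reference
            ref += ln
        # H (5) and P (6): consume nothing we track
    length = aligned_i
    if length == 0:
        return None
    codes = encode_sequence("".join(bases)) if bases else np.empty(0, dtype=np.int8)
    return AlignedFragment(
        read_id=read.query_name,
        ref_start=read.reference_start,
        mapq=read.mapping_quality,
        reverse_strand=read.is_reverse,
        length=length,
        ref_pos=np.asarray(ref_pos, dtype=np.int32),
        read_idx=np.asarray(read_idx, dtype=np.int32),
        base=codes,
        qual=np.asarray(bquals, dtype=np.int16),
        insertions=insertions,
        deletions=np.asarray(deletions, dtype=np.int32),
        del_qual=np.asarray(del_quals),
    )


def read_alignment(path, reference_name: str) -> list[AlignedFragment]:
    """Read a SAM/BAM file into fragments aligned to ``reference_name``.

    Unmapped, secondary and supplementary records are skipped; soft-clipped
    bases are excluded; malformed records (CIGAR/sequence mismatch, missing
    qualities) are skipped with a logged warning count.
    """
    fragments = []
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        if reference_name not in af.references:
            raise ValueError(f"reference {reference_name!r} not in alignment header")
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != reference_name:
                continue
            try:
                frag = _fragment_from_read(read)
            except (ValueError, IndexError):
                frag = None
            if frag is None:
                skipped += 1
                continue
            fragments.append(frag)
    if skipped:
        logger.warning("skipped %d malformed alignment records", skipped)
    return fragments


def read_contaminant_db(path, expected_length: int | None = None) -> list[tuple[str, str]]:
    """Read a gapped multi-FASTA of candidate contaminant genomes.

    Every record must match the reference coordinate system length (alignment
    gaps '-' count).  IUPAC ambiguity codes and gaps are retained.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if expected_length is not None and len(seq) != expected_length:
            raise ValueError(
                f"contaminant record {rec.id!r} has length {len(seq)}, "
                f"expected {expected_length}"
            )
        records.append((rec.id, seq))
    if expected_length is None and records:
        L = len(records[0][1])
        for name, seq in records:
            if len(seq) != L:
                raise ValueError(f"contaminant record {name!r} has mismatched length")
    return records


# ---------------------------------------------------------------------------
# deamination-profile TSVs

_PROFILE_COLUMNS = [f"{x}>{y}" for x, y in SUBSTITUTIONS]


def write_profile(table: np.ndarray, path) -> None:
    """Write one end's (depth, 4, 4) rate table as a TSV."""
    depth = table.shape[0]
    data = {"pos": np.arange(depth)}
    for (x, y), col in zip(SUBSTITUTIONS, _PROFILE_COLUMNS):
        data[col] = table[:, BASES.index(x), BASES.index(y)]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_profile(path) -> np.ndarray:
    """Read one end's rate table written by :func:`write_profile`."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"profile file {path} is empty")
    depth = len(df)
    table = np.zeros((depth, 4, 4))
    for (x, y), col in zip(SUBSTITUTIONS, _PROFILE_COLUMNS):
        vals = df[col].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError(f"rate outside [0,1] in column {col} of {path}")
        table[:, BASES.index(x), BASES.index(y)] = vals
    return table


def write_error_model(err: SubstitutionErrorModel, path) -> None:
    pd.DataFrame(err.matrix, index=list(BASES), columns=list(BASES)).to_csv(
        path, sep="\t"
    )


def read_error_model(path) -> SubstitutionErrorModel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SubstitutionErrorModel(df.loc[list(BASES), list(BASES)].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# pileup

@dataclass
class PileupColumn:
    """Per-reference-position view of all observations (array slices)."""

    ref_index: int
    ref_base: str
    base: np.ndarray
    eps: np.ndarray
    dist5: np.ndarray
    dist3: np.ndarray
    reverse: np.ndarray
    mismap: np.ndarray
    frag: np.ndarray
    p_endo: np.ndarray | None = None
    insertion_observations: list = field(default_factory=list)  # (frag, seq, mean_eps)
    del_frag: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    del_eps: np.ndarray = field(default_factory=lambda: np.empty(0))
    _pileup: "Pileup | None" = None

    @property
    def coverage(self) -> int:
        return len(self.base)

    @property
    def observations(self) -> list:
        """Observation tuples (frag, base, eps, d5, d3, reverse, mismap, p_endo)."""
        pe = self.p_endo if self.p_endo is not None else [None] * self.coverage
        return [
            (int(self.frag[i]), decode_base(int(self.base[i])), float(self.eps[i]),
             int(self.dist5[i]), int(self.dist3[i]), bool(self.reverse[i]),
             float(self.mismap[i]), pe[i])
            for i in range(self.coverage)
        ]


class Pileup:
    """All observations of a fragment set, grouped by reference position.

    Construction is lossless for A/C/G/T read bases: every matched base lands
    in exactly one column and insertions are kept as per-junction records.
    Read bases called N carry no likelihood information and are dropped (the
    drop count is kept in ``n_dropped``).
    """

    def __init__(self, fragments: list[AlignedFragment], reference: ReferenceGenome):
        self.reference = reference
        self.fragments = fragments
        L = len(reference)
        sites, bases, quals, d5s, d3s, revs, mismaps, frags = [], [], [], [], [], [], [], []
        del_sites, del_frags, del_eps = [], [], []
        self.insertions: dict[int, list] = {}
        n_dropped = 0
        for fi, fr in enumerate(fragments):
            keep = (fr.base != N_CODE) & (fr.ref_pos >= 0) & (fr.ref_pos < L)
            n_dropped += int((~keep).sum())
            sites.append(fr.ref_pos[keep])
            bases.append(fr.base[keep])
            quals.append(fr.qual[keep])
            d5s.append(fr.dist5[keep])
            d3s.append(fr.dist3[keep])
            nk = int(keep.sum())
            revs.append(np.full(nk, fr.reverse_strand, dtype=bool))
            mismaps.append(np.full(nk, fr.mismap))
            frags.append(np.full(nk, fi, dtype=np.int32))
            for ref_pos, _ridx, seq, mq in fr.insertions:
                if 0 < ref_pos <= L:
                    self.insertions.setdefault(ref_pos - 1, []).append(
                        (fi, seq, float(phred_to_prob(mq)))
                    )
            if len(fr.deletions):
                ok = (fr.deletions >= 0) & (fr.deletions < L)
                del_sites.append(fr.deletions[ok])
                del_frags.append(np.full(int(ok.sum()), fi, dtype=np.int32))
                del_eps.append(phred_to_prob(fr.del_qual[ok]))
        self.n_dropped = n_dropped

        def cat(parts, dtype=None):
            if parts:
                out = np.concatenate(parts)
                return out.astype(dtype) if dtype is not None else out
            return np.empty(0, dtype=dtype or float)

        site = cat(sites, np.int32)
        order = np.argsort(site, kind="stable")
        self.site = site[order]
        self.base = cat(bases, np.int8)[order]
        self.eps = phred_to_prob(cat(quals, np.int16))
        self.eps = self.eps[order] if len(order) else self.eps
        self.dist5 = cat(d5s, np.int32)[order]
        self.dist3 = cat(d3s, np.int32)[order]
        self.reverse = cat(revs, bool)[order]
        self.mismap = cat(mismaps)[order]
        self.frag = cat(frags, np.int32)[order]
        self.starts = np.searchsorted(self.site, np.arange(L + 1))
        self.p_endo: np.ndarray | None = None

        dsite = cat(del_sites, np.int32)
        dorder = np.argsort(dsite, kind="stable")
        self.del_site = dsite[dorder]
        self.del_frag = cat(del_frags, np.int32)[dorder]
        self.del_eps = cat(del_eps)[dorder]
        self.del_starts = np.searchsorted(self.del_site, np.arange(L + 1))

    @property
    def n_sites(self) -> int:
        return len(self.reference)

    @property
    def total_observations(self) -> int:
        return len(self.site)

    def set_fragment_endogenous_prob(self, p_frag) -> None:
        """Attach per-fragment P[R_j in E]; broadcast to observations."""
        p_frag = np.asarray(p_frag, dtype=float)
        self.p_endo = p_frag[self.frag]

    def clear_fragment_endogenous_prob(self) -> None:
        self.p_endo = None

    def column(self, i: int) -> PileupColumn:
        lo, hi = self.starts[i], self.starts[i + 1]
        dlo, dhi = self.del_starts[i], self.del_starts[i + 1]
        return PileupColumn(
            ref_index=i,
            ref_base=self.reference.sequence[i],
            base=self.base[lo:hi],
            eps=self.eps[lo:hi],
            dist5=self.dist5[lo:hi],
            dist3=self.dist3[lo:hi],
            reverse=self.reverse[lo:hi],
            mismap=self.mismap[lo:hi],
            frag=self.frag[lo:hi],
            p_endo=None if self.p_endo is None else self.p_endo[lo:hi],
            insertion_observations=self.insertions.get(i, []),
            del_frag=self.del_frag[dlo:dhi],
            del_eps=self.del_eps[dlo:dhi],
            _pileup=self,
        )

    def columns(self):
        for i in range(self.n_sites):
            yield self.column(i)

    def insertion_support(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Fragments spanning the junction after site ``i`` with no insertion.

        Returns (fragment indices, mean eps) for reads that have a matched
        base at both ``i`` and ``i + 1`` and no recorded insertion there.
        """
        if i + 1 >= self.n_sites:
            return np.empty(0, dtype=np.int32), np.empty(0)
        lo, hi = self.starts[i], self.starts[i + 1]
        lo2, hi2 = self.starts[i + 1], self.starts[i + 2]
        here = {int(f): float(e) for f, e in zip(self.frag[lo:hi], self.eps[lo:hi])}
        with_ins = {fi for fi, _, _ in self.insertions.get(i, [])}
        frs, eps = [], []
        for f, e in zip(self.frag[lo2:hi2], self.eps[lo2:hi2]):
            f = int(f)
            if f in here and f not in with_ins:
                frs.append(f)
                eps.append((here[f] + float(e)) / 2.0)
        return np.asarray(frs, dtype=np.int32), np.asarray(eps)


# ---------------------------------------------------------------------------
# consensus output

def write_consensus(
    calls,
    fasta_path,
    log_path,
    name: str = "consensus",
    which: str = "endo",
    quality_filter: float | None = None,
) -> None:
    """Write a consensus FASTA plus a per-site TSV log.

    ``which`` selects the endogenous or contaminant track of the joint calls.
    Sites with zero coverage, or (when ``quality_filter`` is given) consensus
    quality below the threshold, are written as 'N'.  Called deletions are
    omitted from the FASTA (logged as '-'); called insertions are appended
    after the anchor base.
    """
    rows = []
    seq_parts = []
    for call in calls:
        base = call.endo_base if which == "endo" else call.cont_base
        phred = call.endo_phred if which == "endo" else call.cont_phred
        marg = call.endo_marginals if which == "endo" else call.cont_marginals
        out_base = base
        if call.coverage == 0:
            out_base = "N"
        elif quality_filter is not None and phred < quality_filter:
            out_base = "N"
        if out_base != "-":
            seq_parts.append(out_base)
        indel = getattr(call, "indel", None)
        if indel is not None and indel.kind == "insertion":
            ins_seq = indel.endo_seq if which == "endo" else indel.cont_seq
            if ins_seq:
                seq_parts.append(ins_seq)
        rows.append(
            (call.ref_index + 1, call.ref_base, out_base,
             round(float(phred), 2), call.coverage,
             *[round(float(p), 6) for p in marg])
        )
    with open(fasta_path, "w") as fh:
        fh.write(f">{name}\n")
        seq = "".join(seq_parts)
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    pd.DataFrame(
        rows, columns=["pos", "ref", "base", "phred", "coverage", "pA", "pC", "pG", "pT"]
    ).to_csv(log_path, sep="\t", index=False)


def read_consensus_log(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
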