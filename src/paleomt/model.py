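"""Per-base observation likelihoods shared by every estimator.

Two nested models describe how an aligned base arises from a template
nucleotide: a *null* model in which any mismatch is a sequencing error, and a
*deamination* model in which post-mortem cytosine deamination (C->T seen from
the 5' end of the molecule; its complementary-strand signature G->A at the 3'
end for double-stranded libraries) may additionally convert the template before
sequencing.  The joint event "deamination AND sequencing error at the same
base" is ignored: it is second-order in two small probabilities.

Bases are encoded A=0, C=1, G=2, T=3 so that the Watson-Crick complement of a
code ``b`` is ``3 - b``; anything else (N, IUPAC codes) maps to 4 and is
excluded from likelihood computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
N_CODE = 4
#: the 12 ordered substitutions, in the column order used by profile TSVs
SUBSTITUTIONS = [(x, y) for x in BASES for y in BASES if x != y]

_ENCODE_TABLE = np.full(256, N_CODE, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i


def encode_base(base: str) -> int:
    """Map a nucleotide character to its integer code (N/other -> 4)."""
    return int(_ENCODE_TABLE[ord(base)])


def encode_sequence(seq: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_base(code: int) -> str:
    return BASES[code] if 0 <= code < 4 else "N"


def complement_code(code):
    """Complement of an encoded base; N (4) stays N."""
    code = np.asarray(code)
    return np.where(code < 4, 3 - code, code)


def phred_to_prob(q):
    """PHRED score -> error probability, 10^(-q/10)."""
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def prob_to_phred(p, cap: float = 9999.0):
    """Error probability -> PHRED score, -10*log10(p), capped.

    A probability of 0 (or below the representable floor) maps to the cap.
    """
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        q = np.where(p > 0.0, -10.0 * np.log10(np.clip(p, 1e-323, None)), cap)
    return np.minimum(q, cap)


@dataclass(frozen=True)
class SubstitutionErrorModel:
    """Sequencing-error substitution probabilities P[x -> y | error].

    ``matrix[x, y]`` is the probability that a sequencing error on template
    ``x`` is read as ``y``; the diagonal is zero and each row sums to 1.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")
        if np.any(np.diag(m) != 0):
            raise ValueError("substitution matrix diagonal must be zero")
        rows = m.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("each row of the substitution matrix must sum to 1")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def uniform(cls) -> "SubstitutionErrorModel":
        """Every miscall equally likely: P[x->y|E] = 1/3 for y != x."""
        m = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(m, 0.0)
        return cls(m)

    @classmethod
    def from_counts(cls, counts) -> "SubstitutionErrorModel":
        """Build from empirical mismatch counts #x->y, normalised per row."""
        c = np.asarray(counts, dtype=float).copy()
        np.fill_diagonal(c, 0.0)
        rows = c.sum(axis=1, keepdims=True)
        if np.any(rows == 0):
            raise ValueError("every template base needs at least one observed mismatch")
        return cls(c / rows)

    def rate(self, template, observed) -> float:
        """P[template -> observed | error]; accepts characters or codes."""
        t = encode_base(template) if isinstance(template, str) else int(template)
        o = encode_base(observed) if isinstance(observed, str) else int(observed)
        return float(self.matrix[t, o])


@dataclass
class DeaminationProfile:
    """Position-from-end nucleotide substitution rates due to deamination.

    ``end5[i]`` and ``end3[i]`` are 4x4 matrices of per-substitution rates at
    distance ``i`` from the molecule's 5' / 3' end (molecule orientation, i.e.
    the orientation in which damage chemistry acts).  Positions beyond the
    modelled depth fall back to the last row.  The total rate at a base is the
    sum of both end contributions, clamped to [0, 1]: terminal damage has
    near-disjoint support at the two ends, so addition is the natural
    combination.
    """

    end5: np.ndarray
    end3: np.ndarray

    def __post_init__(self):
        self.end5 = np.asarray(self.end5, dtype=float)
        self.end3 = np.asarray(self.end3, dtype=float)
        for name, arr in (("end5", self.end5), ("end3", self.end3)):
            if arr.ndim != 3 or arr.shape[1:] != (4, 4) or arr.shape[0] < 1:
                raise ValueError(f"{name} must have shape (depth, 4, 4)")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} rates must lie in [0, 1]")

    @property
    def max_depth(self) -> int:
        return max(self.end5.shape[0], self.end3.shape[0])

    @classmethod
    def zero(cls, depth: int = 1) -> "DeaminationProfile":
        z = np.zeros((depth, 4, 4))
        return cls(z, z.copy())

    @classmethod
    def from_terminal_rates(
        cls,
        *,
        protocol: str = "single",
        terminal: float = 0.30,
        decay: float = 0.5,
        baseline: float = 0.0,
        depth: int = 15,
    ) -> "DeaminationProfile":
        """Geometric-decay profile: rate(i) = terminal * decay**i (+ baseline).

        Single-stranded libraries show C->T at both ends; double-stranded show
        C->T at the 5' end and G->A at the 3' end.  The baseline applies to the
        5' C->T rates only, so that the additive two-end lookup reproduces it
        exactly once at interior positions.
        """
        if protocol not in ("single", "double"):
            raise ValueError("protocol must be 'single' or 'double'")
        i = np.arange(depth)
        geom = terminal * decay ** i
        C, T, G, A = BASE_INDEX["C"], BASE_INDEX["T"], BASE_INDEX["G"], BASE_INDEX["A"]
        end5 = np.zeros((depth, 4, 4))
        end3 = np.zeros((depth, 4, 4))
        end5[:, C, T] = np.clip(geom + baseline, 0.0, 1.0)
        if protocol == "single":
            end3[:, C, T] = geom
        else:
            end3[:, G, A] = geom
        return cls(end5, end3)

    def rates_at(self, dist5: int, dist3: int, reverse: bool = False, clamp: bool = True) -> np.ndarray:
        """4x4 substitution-rate matrix for a base at the given end distances.

        For reverse-strand reads the stored observation is in reference-forward
        orientation while damage acts on the original molecule, so the matrix
        is complement-mirrored (C->T on the molecule is seen as G->A).
        """
        return self.rates_for(
            np.array([dist5]), np.array([dist3]), np.array([reverse]), clamp=clamp
        )[0]

    def rates_for(self, dist5, dist3, reverse, clamp: bool = True) -> np.ndarray:
        """Vectorised ``rates_at``: (n,) arrays -> (n, 4, 4) rate matrices."""
        i5 = np.minimum(np.asarray(dist5, dtype=np.int64), self.end5.shape[0] - 1)
        i3 = np.minimum(np.asarray(dist3, dtype=np.int64), self.end3.shape[0] - 1)
        m = self.end5[i5] + self.end3[i3]
        rev = np.asarray(reverse, dtype=bool)
        if rev.any():
            m[rev] = m[rev][:, ::-1, ::-1]
        if clamp:
            np.clip(m, 0.0, 1.0, out=m)
        return m


@dataclass
class BaseContext:
    """One aligned base observation: what was read, with what confidence,
    against which template, and where within the original molecule."""

    observed: str
    eps: float
    template: str
    dist5: int = 0
    dist3: int = 0
    reverse: bool = False

    obs_code: int = field(init=False)
    template_code: int = field(init=False)

    def __post_init__(self):
        self.obs_code = encode_base(self.observed)
        self.template_code = encode_base(self.template)


def p_null(ctx: BaseContext, err: SubstitutionErrorModel) -> float:
    """Likelihood of the observed base when mismatches are sequencing error only."""
    if ctx.template_code == ctx.obs_code:
        return 1.0 - ctx.eps
    return ctx.eps * err.matrix[ctx.template_code, ctx.obs_code]


def p_deam(
    ctx: BaseContext,
    profile: DeaminationProfile,
    err: SubstitutionErrorModel,
    clamp: bool = True,
) -> float:
    """Likelihood when deamination or sequencing error may explain a mismatch.

    Match branch: (1-eps) * (1 - sum of deamination rates away from the
    template).  Mismatch branch: (1-eps) * rate_deam(template->observed)
    + eps * P[template->observed|error].
    """
    rates = profile.rates_at(ctx.dist5, ctx.dist3, ctx.reverse, clamp=clamp)
    t, o = ctx.template_code, ctx.obs_code
    if t == o:
        stay = 1.0 - rates[t].sum()
        if clamp:
            stay = max(stay, 0.0)
        return (1.0 - ctx.eps) * stay
    return (1.0 - ctx.eps) * rates[t, o] + ctx.eps * err.matrix[t, o]


def position_rates(
    profile: DeaminationProfile,
    dist5: int,
    dist3: int,
    reverse: bool = False,
    clamp: bool = True,
) -> np.ndarray:
    """Per-substitution deamination rates at one base (additive two-end model)."""
    return profile.rates_at(dist5, dist3, reverse, clamp=clamp)


# ---------------------------------------------------------------------------
# vectorised observation likelihoods (shared fast path)

_CHUNK = 1 << 19


def template_likelihoods(
    base: np.ndarray,
    eps: np.ndarray,
    dist5: np.ndarray,
    dist3: np.ndarray,
    reverse: np.ndarray,
    profile: DeaminationProfile,
    err: SubstitutionErrorModel,
) -> np.ndarray:
    """P[r_i | template b] under the deamination model, for all four templates.

    Inputs are parallel (n,) arrays of observations; returns (n, 4).  This is
    the vectorised counterpart of :func:`p_deam` and agrees with it exactly.
    """
    n = base.shape[0]
    out = np.empty((n, 4))
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        b = base[lo:hi]
        e = eps[lo:hi]
        rates = profile.rates_for(dist5[lo:hi], dist3[lo:hi], reverse[lo:hi])
        stay = np.clip(1.0 - rates.sum(axis=2), 0.0, 1.0)  # (m,4)
        idx = np.arange(hi - lo)
        for t in range(4):
            mismatch = (1.0 - e) * rates[idx, t, b] + e * err.matrix[t, b]
            out[lo:hi, t] = np.where(b == t, (1.0 - e) * stay[:, t], mismatch)
    return out


def null_likelihoods(
    base: np.ndarray, eps: np.ndarray, err: SubstitutionErrorModel
) -> np.ndarray:
    """P[r_i | template b] under the error-only model; (n,) arrays -> (n, 4)."""
    n = base.shape[0]
    out = np.empty((n, 4))
    for t in range(4):
        out[:, t] = np.where(base == t, 1.0 - eps, eps * err.matrix[t, base])
    return out
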