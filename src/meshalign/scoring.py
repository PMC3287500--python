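"""Scoring schemes, matrix scale-up, and sum-of-pairs column scoring.

The DP meshes compute with unsigned unary numbers, so substitution matrices
with negative entries are *scaled up*: a constant ``beta`` is added to every
score (including the gap score) so the minimum becomes non-negative.  In
log-odds terms this multiplies every substitution probability by ``a**beta``
— it shifts each aligned column's contribution uniformly and can be undone
per alignment by re-scoring the traceback path against the original scheme.

Column-vs-column match scores for group alignment use the sum-of-pairs (SP)
function.  Because the residue alphabet is small, SP over the merged residue
pool of the two columns reduces to a counting problem over per-symbol
occurrence counts: with ``n_i`` the count of symbol ``i`` in the merged
pool,

    sp = sum_i C(n_i, 2) * s(i, i)  +  sum_{i<j} n_i * n_j * s(i, j)

whose cost is independent of the number of sequences.  The merged pool
deliberately counts within-column pairs as well as cross-column pairs; for
two single-residue columns it reduces to the plain substitution score.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .errors import InputError

__all__ = [
    "GAP",
    "SubstitutionMatrix",
    "ScoringScheme",
    "ScaleUpParams",
    "ProfileColumn",
    "scale_up",
    "rescore_original",
    "sp_pairs",
    "sum_of_pair",
    "read_ncbi_matrix",
]

#: the gap symbol used throughout (aligned FASTA convention)
GAP = "-"

DNA_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue-by-residue integer score table."""

    alphabet: str
    scores: Mapping  # (a, b) -> int, symmetric, both orders present

    @classmethod
    def from_pairs(cls, alphabet: str, pairs: Mapping) -> "SubstitutionMatrix":
        scores = {}
        for (a, b), v in pairs.items():
            scores[(a, b)] = int(v)
            scores[(b, a)] = int(v)
        return cls(alphabet, scores)

    @classmethod
    def match_mismatch(cls, alphabet: str, match: int, mismatch: int) -> "SubstitutionMatrix":
        scores = {
            (a, b): (match if a == b else mismatch)
            for a in alphabet
            for b in alphabet
        }
        return cls(alphabet, scores)

    def score(self, a: str, b: str) -> int:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise InputError(f"no score for residue pair ({a!r}, {b!r})")

    def min_score(self) -> int:
        return min(self.scores.values())

    def max_score(self) -> int:
        return max(self.scores.values())

    def shifted(self, beta: int) -> "SubstitutionMatrix":
        return SubstitutionMatrix(
            self.alphabet, {k: v + beta for k, v in self.scores.items()}
        )

    def is_symmetric(self) -> bool:
        return all(self.scores.get((b, a)) == v for (a, b), v in self.scores.items())


@dataclass(frozen=True)
class ScaleUpParams:
    """Additive scale-up: every score (and the gap) shifted by ``beta >= 0``."""

    beta: int


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores plus gap costs, with optional scale-up state.

    All step scores are *signed and additive*: a diagonal step contributes
    ``s(x_i, y_j)``, a gap step contributes ``gap`` (or, under affine
    costs, ``gap_open`` when the gap is opened and ``gap`` when extended;
    ``gap_open <= gap <= 0`` in unscaled form, so ``eps = gap - gap_open``
    is the extra opening charge).  ``gap_gap`` scores a gap-gap pair in
    sum-of-pairs columns.  A scheme is *mesh-safe* when every substitution
    score is non-negative; gap scores may stay negative, in which case the
    mesh subtracts their magnitude and a branch that would go negative
    carries the all-zero underflow pattern.
    """

    matrix: SubstitutionMatrix
    gap: int
    gap_open: int | None = None
    gap_gap: int = 0
    scaled: bool = False
    beta: int = 0

    def __post_init__(self):
        if self.gap_open is not None:
            if self.gap - self.gap_open < 0:
                raise InputError(
                    "affine costs need gap_open <= gap (opening at least as costly)"
                )
        if self.scaled:
            lo = min(self.matrix.min_score(), self.gap)
            if self.gap_open is not None:
                lo = min(lo, self.gap_open)
            if lo < 0:
                raise InputError("scaled scheme must have non-negative scores")

    # -- lookups -----------------------------------------------------------
    @property
    def alphabet(self) -> str:
        return self.matrix.alphabet

    @property
    def affine(self) -> bool:
        return self.gap_open is not None

    @property
    def eps(self) -> int:
        """Extra opening charge ``gap - gap_open`` (>= 0) under affine costs."""
        if self.gap_open is None:
            return 0
        return self.gap - self.gap_open

    def s(self, a: str, b: str) -> int:
        """Pair score with the gap symbol folded in as a residue type."""
        if a == GAP and b == GAP:
            return self.gap_gap
        if a == GAP or b == GAP:
            return self.gap
        return self.matrix.score(a, b)

    def is_mesh_safe(self) -> bool:
        return self.matrix.min_score() >= 0

    @classmethod
    def constant(cls, alphabet: str, match: int, mismatch: int, gap: int, **kw) -> "ScoringScheme":
        return cls(SubstitutionMatrix.match_mismatch(alphabet, match, mismatch), gap, **kw)


def scale_up(scheme: ScoringScheme) -> ScoringScheme:
    """Shift every score of ``scheme`` by ``beta`` so the minimum is >= 0.

    ``beta = max(0, -min(all substitution scores, gap[, gap_open]))``.  The
    antilog / multiply-by-``a**beta`` / log-odds round trip of integer
    log-odds scores is exactly this additive shift.  Idempotent on schemes
    that are already non-negative (``beta = 0``).
    """
    lo = min(scheme.matrix.min_score(), scheme.gap)
    if scheme.gap_open is not None:
        lo = min(lo, scheme.gap_open)
    beta = max(0, -lo)
    return replace(
        scheme,
        matrix=scheme.matrix.shifted(beta),
        gap=scheme.gap + beta,
        gap_open=None if scheme.gap_open is None else scheme.gap_open + beta,
        gap_gap=scheme.gap_gap + beta,
        scaled=True,
        beta=beta,
    )


def rescore_original(result, scheme_original: ScoringScheme) -> int:
    """Re-score a traceback path against the original (unscaled) scheme.

    Sums the original substitution score over diagonal steps and the
    original gap score over gap steps; steps along the zero-initialised
    first row/column (free end gaps) contribute nothing.  The sum is
    evaluated as the last element of a running prefix-sum over the path,
    mirroring the constant-time prefix-sum formulation.
    """
    contributions = []
    for step in result.steps():
        kind, i, j = step
        if i == 0 or j == 0:
            contributions.append(0)
        elif kind == "diag":
            contributions.append(scheme_original.s(result.x[i - 1], result.y[j - 1]))
        else:
            contributions.append(scheme_original.gap)
    if not contributions:
        return 0
    return int(np.cumsum(contributions)[-1])


# ---------------------------------------------------------------------------
# sum-of-pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileColumn:
    """Per-symbol occurrence counts for one column of an aligned group."""

    counts: Mapping  # symbol -> count

    @classmethod
    def from_residues(cls, residues: Iterable[str]) -> "ProfileColumn":
        return cls(dict(Counter(residues)))

    @property
    def m(self) -> int:
        return sum(self.counts.values())

    def merged(self, other: "ProfileColumn") -> Counter:
        out = Counter(self.counts)
        out.update(other.counts)
        return out


def sp_pairs(f: Iterable[str], g: Iterable[str]):
    """All unordered residue pairs of the merged columns, with multiplicity.

    Returns ``(Counter of sorted symbol pairs, total pair count)``; the
    total is always C(|f|+|g|, 2).
    """
    pool = list(f) + list(g)
    pairs = Counter()
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            pairs[tuple(sorted((pool[i], pool[j])))] += 1
    return pairs, sum(pairs.values())


def sum_of_pair(f: ProfileColumn, g: ProfileColumn, scheme: ScoringScheme) -> int:
    """Counting-form SP score of two profile columns.

    Evaluates the per-symbol-count form over the merged pool; equal to the
    brute-force enumeration of all merged residue pairs for every input.
    """
    merged = f.merged(g)
    symbols = sorted(merged)
    total = 0
    for i, a in enumerate(symbols):
        na = merged[a]
        total += na * (na - 1) // 2 * scheme.s(a, a)
        for b in symbols[i + 1:]:
            total += na * merged[b] * scheme.s(a, b)
    return total


# ---------------------------------------------------------------------------
# NCBI plain-text matrix format
# ---------------------------------------------------------------------------

def read_ncbi_matrix(path) -> SubstitutionMatrix:
    """Read a PAM/BLOSUM-style plain-text matrix.

    Format: ``#`` comment lines, then a header row of residue symbols, then
    one row per residue of integer scores.  Asymmetric entries are an input
    error.  ``*`` / ``X``-style wildcard columns are kept as ordinary
    symbols if present.
    """
    with open(path) as fh:
        lines = [ln.rstrip() for ln in fh]
    header: list[str] = []
    scores: dict = {}
    row_syms: list[str] = []
    for lineno, ln in enumerate(lines, start=1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        fields = ln.split()
        if not header:
            if any(len(f) != 1 or f.isdigit() for f in fields):
                raise InputError(f"line {lineno}: expected residue header row")
            header = fields
            continue
        sym = fields[0]
        vals = fields[1:]
        if len(sym) != 1 or len(vals) != len(header):
            raise InputError(
                f"line {lineno}: expected symbol + {len(header)} scores, got {ln!r}"
            )
        row_syms.append(sym)
        for col_sym, v in zip(header, vals):
            try:
                scores[(sym, col_sym)] = int(v)
            except ValueError:
                raise InputError(f"line {lineno}: non-integer score {v!r}")
    if not header:
        raise InputError("empty matrix file")
    if row_syms != header:
        raise InputError("matrix row symbols do not match header")
    mat = SubstitutionMatrix("".join(s for s in header if s != GAP), scores)
    if not mat.is_symmetric():
        raise InputError("matrix is not symmetric")
    return mat
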