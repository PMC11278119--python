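"""Pairwise sequence comparison primitives.

Local (Smith-Waterman) alignment with affine gap costs, Hamming distance,
overlapping motif counts, and the dot/dash difference-mask codec used to
publish repeat-unit haplotypes relative to a consensus sequence.

The default scoring (match +5, mismatch -4, gap open 10.0, gap extend 0.5)
follows the EMBOSS ``water`` convention in which a gap of length *L* costs
``open + L * extend``; percent identity is the number of identical columns
over *all* alignment columns, gap columns included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "AlignParams",
    "LocalAlignment",
    "DiffMask",
    "local_align",
    "global_align",
    "hamming",
    "count_motif",
    "decode_diff_mask",
    "encode_diff_mask",
]

_NEG = float("-inf")


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring parameters (EMBOSS water defaults)."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not (self.gap_open > self.gap_extend > 0):
            raise ValueError("require gap_open > gap_extend > 0")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")


@dataclass(frozen=True)
class LocalAlignment:
    """A gapped local alignment of two sequences."""

    aligned_a: str
    aligned_b: str
    score: float
    start_a: int  # 0-based start of the aligned substring in a
    end_a: int
    start_b: int
    end_b: int

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    @property
    def identities(self) -> int:
        return sum(
            x == y and x != "-" for x, y in zip(self.aligned_a, self.aligned_b)
        )

    @property
    def identity_pct(self) -> float:
        if self.columns == 0:
            return 0.0
        return 100.0 * self.identities / self.columns


def _clean(seq: str) -> str:
    # published consensus rows may carry alignment gap characters
    return seq.replace("-", "").upper()


def local_align(a: str, b: str, params: AlignParams | None = None) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Among co-optimal alignments the one ending at the smallest ``(i, j)``
    in row-major order is reported, and the traceback prefers diagonal
    over up (gap in ``b``) over left (gap in ``a``) moves, so the result
    is deterministic.
    """
    params = params or AlignParams()
    a, b = _clean(a), _clean(b)
    if not a or not b:
        raise ValueError("local_align requires two non-empty sequences")
    n, m = len(a), len(b)
    go = params.gap_open + params.gap_extend  # first gapped residue
    ge = params.gap_extend
    mt, mm = params.match, params.mismatch

    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (left)
    F = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (up)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] - go, Ei[j - 1] - ge)
            f = max(Hi1[j] - go, Fi1[j] - ge)
            s = mt if ai == b[j - 1] else mm
            h = Hi1[j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, bi, bj = h, i, j

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0.0:
                break
            s = mt if a[i - 1] == b[j - 1] else mm
            if h == H[i - 1][j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif h == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in b, consume a
            out_a.append(a[i - 1])
            out_b.append("-")
            from_h = F[i][j] == H[i - 1][j] - go
            i -= 1
            if from_h:
                state = "H"
        else:  # E: gap in a, consume b
            out_a.append("-")
            out_b.append(b[j - 1])
            from_h = E[i][j] == H[i][j - 1] - go
            j -= 1
            if from_h:
                state = "H"
    out_a.reverse()
    out_b.reverse()
    return LocalAlignment(
        aligned_a="".join(out_a),
        aligned_b="".join(out_b),
        score=best,
        start_a=i,
        end_a=bi,
        start_b=j,
        end_b=bj,
    )


def global_align(a: str, b: str, params: AlignParams | None = None) -> tuple[str, str, float]:
    """Needleman-Wunsch global alignment with the same affine gap costs.

    Used internally to place gaps when encoding a haplotype as a
    difference mask against a reference; terminal gaps are charged.
    """
    params = params or AlignParams()
    a, b = _clean(a), _clean(b)
    n, m = len(a), len(b)
    go = params.gap_open + params.gap_extend
    ge = params.gap_extend
    mt, mm = params.match, params.mismatch

    H = [[_NEG] * (m + 1) for _ in range(n + 1)]
    E = [[_NEG] * (m + 1) for _ in range(n + 1)]
    F = [[_NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = -go - (j - 1) * ge
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = -go - (i - 1) * ge
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            s = mt if ai == b[j - 1] else mm
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])

    out_a: list[str] = []
    out_b: list[str] = []
    i, j, state = n, m, "H"
    # ties prefer gap states so that score-equivalent gap runs land at
    # the alignment end (terminal truncations encode as trailing gaps)
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and H[i][j] == F[i][j]:
                state = "F"
                continue
            if j > 0 and H[i][j] == E[i][j]:
                state = "E"
                continue
            s = mt if a[i - 1] == b[j - 1] else mm
            assert H[i][j] == H[i - 1][j - 1] + s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == "F":
            out_a.append(a[i - 1])
            out_b.append("-")
            from_h = F[i][j] == H[i - 1][j] - go
            i -= 1
            if from_h:
                state = "H"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            from_h = E[i][j] == H[i][j - 1] - go
            j -= 1
            if from_h:
                state = "H"
    out_a.reverse()
    out_b.reverse()
    return "".join(out_a), "".join(out_b), H[n][m]


def hamming(a: str, b: str) -> int:
    """Number of differing positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def count_motif(seq: str, motif: str) -> int:
    """Count occurrences of ``motif`` in ``seq``; overlaps count."""
    if not motif:
        raise ValueError("motif must be non-empty")
    seq, motif = seq.upper(), motif.upper()
    return sum(seq.startswith(motif, i) for i in range(len(seq) - len(motif) + 1))


@dataclass(frozen=True)
class DiffMask:
    """A haplotype published as differences against a reference row.

    ``reference`` may contain ``-`` columns (insertion columns relative
    to the ungapped reference).  In ``mask``, ``.`` means identity to the
    reference column, ``-`` a deletion, and a base letter a substitution
    (or an insertion where the reference column is ``-``).  A mask
    shorter than the reference is padded with deletions, matching the
    convention for truncated final repeat units.
    """

    reference: str
    mask: str

    def __post_init__(self) -> None:
        if len(self.mask) > len(self.reference):
            raise ValueError("mask longer than reference row")


def decode_diff_mask(mask: DiffMask) -> str:
    """Materialize the concrete haplotype sequence (deletions removed)."""
    ref = mask.reference.upper()
    m = mask.mask.upper().ljust(len(ref), "-")
    out: list[str] = []
    for col, (r, c) in enumerate(zip(ref, m)):
        if c == ".":
            if r != "-":
                out.append(r)
        elif c == "-":
            continue
        else:
            if c == r:
                warnings.warn(
                    f"redundant substitution {c!r} at column {col}", stacklevel=2
                )
            out.append(c)
    return "".join(out)


def encode_diff_mask(
    reference: str, haplotype: str, params: AlignParams | None = None
) -> DiffMask:
    """Express ``haplotype`` as a dot/dash mask against ``reference``.

    Inverse of :func:`decode_diff_mask`:
    ``decode_diff_mask(encode_diff_mask(r, h)) == h``.
    """
    ref_aln, hap_aln, _ = global_align(reference, haplotype, params)
    mask_chars: list[str] = []
    for r, h in zip(ref_aln, hap_aln):
        if h == "-":
            mask_chars.append("-")
        elif r == h:
            mask_chars.append(".")
        else:  # substitution, or insertion where r == '-'
            mask_chars.append(h)
    return DiffMask(reference=ref_aln, mask="".join(mask_chars))
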