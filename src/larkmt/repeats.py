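"""Tandem-repeat detection and decomposition of a remnant control region.

A lark rCR2 decomposes into a 5' non-repeat region (5NR), a tandem
repeat array (TR) of near-identical units, and a 3' non-repeat region
(3NR).  This module finds the array, splits the region exactly
(``five_nr + units + three_nr`` reconstructs the input), derives unit
haplotypes and their column-majority consensus, computes pairwise
identity statistics, flags a divergent initial unit, detects a fused
two-subunit period (the H_1 + H_2 pattern), and scores unit foldability
by Watson-Crick base-pair maximization.

The detector is a re-implementation in the spirit of period-histogram
tools: candidate periods are proposed from the distance spectrum of
repeated k-mers, self-match segments at each period are refined against
the array consensus, and the best-scoring non-overlapping calls are
kept.  Unit phase is chosen to maximize first-unit identity to the
consensus (ties toward the smallest offset), and chance matches of the
flanks to the periodic continuation are trimmed when shorter than
``min_partial`` bases, so planted boundaries are recovered exactly with
high probability while genuinely truncated final units are retained.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import AlignParams, encode_diff_mask, hamming, local_align

__all__ = [
    "TandemRepeatCall",
    "CRDecomposition",
    "RepeatHaplotype",
    "RepeatUnitSet",
    "SimilarityStats",
    "FusionRecord",
    "FoldScore",
    "detect_tandem_repeats",
    "decompose_cr",
    "build_consensus",
    "build_repeat_unit_set",
    "unit_similarity_stats",
    "flag_divergent_initial_unit",
    "detect_subunit_fusion",
    "deletion_type",
    "fold_score",
]


@dataclass(frozen=True)
class TandemRepeatCall:
    start: int
    end: int  # 0-based half-open within the scanned sequence
    period: int
    copies: float
    unit_starts: tuple[int, ...]
    consensus: str
    score: float  # total bases matching the consensus tiling
    alt_periods: tuple[int, ...] = ()


@dataclass(frozen=True)
class CRDecomposition:
    five_nr: str
    units: tuple[str, ...]
    three_nr: str

    @property
    def sequence(self) -> str:
        return self.five_nr + "".join(self.units) + self.three_nr


@dataclass(frozen=True)
class RepeatHaplotype:
    name: str
    sequence: str
    multiplicity: int


@dataclass(frozen=True)
class FusionRecord:
    half_a: str
    half_b: str
    hamming: int


@dataclass(frozen=True)
class SimilarityStats:
    min_sim: float | None
    max_sim: float | None
    matrix: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class RepeatUnitSet:
    haplotypes: tuple[RepeatHaplotype, ...]
    consensus: str
    excluded: frozenset[str]  # names excluded from similarity statistics
    divergent_initial: bool
    fusion: FusionRecord | None


@dataclass(frozen=True)
class FoldScore:
    pairs: int
    structure: str  # dot-bracket


# ---------------------------------------------------------------------------
# consensus


def build_consensus(units: list[str]) -> str:
    """Column-majority consensus over full-length units.

    Full length is the modal unit length (ties toward the longest, so a
    lone truncated or divergent unit cannot define the frame); column
    ties break toward the base of the earliest contributing unit.
    """
    if not units:
        raise ValueError("need at least one unit")
    length_counts = Counter(len(u) for u in units)
    top = max(length_counts.values())
    modal_len = max(n for n, c in length_counts.items() if c == top)
    full = [u for u in units if len(u) == modal_len]
    out = []
    for col in range(modal_len):
        counts: dict[str, int] = {}
        first_seen: dict[str, int] = {}
        for idx, u in enumerate(full):
            b = u[col]
            counts[b] = counts.get(b, 0) + 1
            first_seen.setdefault(b, idx)
        best = max(counts.values())
        winner = min(
            (b for b, c in counts.items() if c == best), key=lambda b: first_seen[b]
        )
        out.append(winner)
    return "".join(out)


# ---------------------------------------------------------------------------
# tandem repeat detection


def _candidate_periods(seq: str, min_period: int, max_period: int, k: int = 8) -> list[int]:
    positions: dict[str, int] = {}
    dist_counts: Counter[int] = Counter()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in positions:
            d = i - positions[kmer]
            if min_period <= d <= max_period:
                dist_counts[d] += 1
        positions[kmer] = i
    ranked = sorted(dist_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [d for d, _ in ranked[:10]]


def _match_segments(m: list[int], thr: float) -> list[tuple[int, int]]:
    """Maximal segments of the 0/1 self-match track with mean >= thr."""
    segments = []
    cur = 0.0
    cur_start = 0
    best = 0.0
    best_span = None
    for i, v in enumerate(m):
        w = (1.0 - thr) if v else -thr
        if cur <= 0:
            cur = 0.0
            cur_start = i
        cur += w
        if cur > best:
            best = cur
            best_span = (cur_start, i + 1)
        if cur < 0 and best_span is not None:
            segments.append(best_span)
            best = 0.0
            best_span = None
            cur = 0.0
    if best_span is not None:
        segments.append(best_span)
    return segments


def _unit_identity(unit: str, cons_slice: str) -> float:
    if not unit or not cons_slice:
        return 0.0
    n = min(len(unit), len(cons_slice))
    matches = sum(unit[i] == cons_slice[i] for i in range(n))
    return 100.0 * matches / max(len(unit), len(cons_slice))


def _tile(seq: str, s: int, e: int, anchor: int, period: int) -> list[tuple[int, int]]:
    """Unit boundaries tiling [s, e) with boundaries == anchor (mod period)."""
    phase = anchor % period
    first_full = s + (phase - s) % period
    bounds = [s] if first_full != s else []
    bounds += list(range(first_full, e, period))
    intervals = []
    for i, a in enumerate(bounds):
        b = bounds[i + 1] if i + 1 < len(bounds) else e
        if b > a:
            intervals.append((a, b))
    return intervals


def _refine_call(
    seq: str,
    seg: tuple[int, int],
    period: int,
    min_copies: float,
    min_identity: float,
    min_partial: int,
) -> TandemRepeatCall | None:
    n = len(seq)
    s0, seg_end = seg
    e = min(n, seg_end + period)
    if (e - s0) // period < 1:
        return None
    units0 = [seq[a : a + period] for a in range(s0, e - period + 1, period)]
    if not units0:
        return None
    cons = build_consensus(units0)

    def match(i: int) -> bool:
        return seq[i] == cons[(i - s0) % period]

    s = s0
    while s > 0 and match(s - 1):
        s -= 1
    while e < n and match(e):
        e += 1
    lead = (s0 - s) % period
    if 0 < lead < min_partial:
        s += lead
    tail = (e - s0) % period
    if 0 < tail < min_partial:
        e -= tail
    if e - s < period:
        return None

    intervals = _tile(seq, s, e, s0, period)
    units = [seq[a:b] for a, b in intervals]
    full = [u for u in units if len(u) == period]
    if not full:
        return None
    cons = build_consensus(full)
    # identity of every unit to its consensus slice (partials vs prefix/suffix)
    idents = []
    score = 0.0
    for (a, b), u in zip(intervals, units):
        if len(u) == period:
            ref = cons
        elif a == s and (s0 - s) % period:  # leading partial: unit tail
            ref = cons[-len(u) :]
        else:  # trailing partial: unit head
            ref = cons[: len(u)]
        ident = _unit_identity(u, ref)
        idents.append(ident)
        score += sum(x == y for x, y in zip(u, ref))
    mean_full = sum(
        _unit_identity(u, cons) for u in full
    ) / len(full)
    copies = (e - s) / period
    if copies < min_copies or mean_full < min_identity:
        return None
    return TandemRepeatCall(
        start=s,
        end=e,
        period=period,
        copies=copies,
        unit_starts=tuple(a for a, _ in intervals),
        consensus=cons,
        score=score,
    )


def _alt_periods(
    seq: str, call: TandemRepeatCall, min_period: int, min_identity: float
) -> tuple[int, ...]:
    alts = []
    for d in range(min_period, call.period):
        if call.period % d:
            continue
        span = (call.end - call.start) // d * d
        units = [
            seq[a : a + d] for a in range(call.start, call.start + span - d + 1, d)
        ]
        if len(units) < 2:
            continue
        cons = build_consensus(units)
        mean_ident = sum(_unit_identity(u, cons) for u in units) / len(units)
        if mean_ident >= min_identity:
            alts.append(d)
    return tuple(alts)


def detect_tandem_repeats(
    seq: str,
    min_period: int = 10,
    min_copies: float = 1.9,
    min_identity: float = 80.0,
    min_partial: int = 5,
) -> list[TandemRepeatCall]:
    """Maximal non-overlapping tandem-repeat calls, sorted by start.

    ``min_identity`` is the mean percent identity of full units to the
    array consensus; ``min_partial`` is the shortest flank extension
    kept as a partial unit (shorter chance matches are trimmed).
    """
    seq = seq.upper()
    if len(seq) < 2 * min_period:
        raise ValueError("sequence shorter than two minimum periods")
    max_period = len(seq) // 2
    thr = min_identity / 100.0
    candidates: list[TandemRepeatCall] = []
    for p in _candidate_periods(seq, min_period, max_period):
        m = [1 if seq[i] == seq[i + p] else 0 for i in range(len(seq) - p)]
        for seg in _match_segments(m, thr):
            call = _refine_call(seq, seg, p, min_copies, min_identity, min_partial)
            if call is not None:
                candidates.append(call)
    # prefer higher coverage score, then smaller period, then leftmost
    candidates.sort(key=lambda c: (-c.score, c.period, c.start))
    selected: list[TandemRepeatCall] = []
    for c in candidates:
        if any(c.start < o.end and o.start < c.end for o in selected):
            continue
        selected.append(c)
    selected = [
        TandemRepeatCall(
            **{
                **c.__dict__,
                "alt_periods": _alt_periods(seq, c, min_period, min_identity),
            }
        )
        for c in selected
    ]
    return sorted(selected, key=lambda c: c.start)


def decompose_cr(cr: str, call: TandemRepeatCall) -> CRDecomposition:
    """Split a control region into 5NR / ordered units / 3NR.

    The concatenation of the three parts reconstructs ``cr`` exactly;
    a truncated final unit stays in ``units``.
    """
    cr = cr.upper()
    if not (0 <= call.start < call.end <= len(cr)):
        raise ValueError("repeat call lies outside the control region")
    bounds = list(call.unit_starts) + [call.end]
    units = tuple(cr[a:b] for a, b in zip(bounds, bounds[1:]))
    return CRDecomposition(five_nr=cr[: call.start], units=units, three_nr=cr[call.end :])


# ---------------------------------------------------------------------------
# haplotypes, similarity, divergence, fusion


def deletion_type(reference: str, haplotype: str, params: AlignParams | None = None) -> str:
    """Classify a haplotype's deletions against a reference.

    The haplotype is globally encoded against the reference (the
    aligner places score-equivalent gap runs at the alignment ends):
    gap runs touching an end are terminal truncations, any other run is
    an internal deletion.
    """
    mask = encode_diff_mask(reference, haplotype, params).mask
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(mask):
        if mask[i] == "-":
            j = i
            while j < len(mask) and mask[j] == "-":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return "none"
    if all(a == 0 or b == len(mask) for a, b in runs):
        return "terminal"
    return "internal"


def flag_divergent_initial_unit(units: list[str], threshold: float = 90.0) -> bool:
    """True iff the first unit diverges from the rest of the array.

    The first unit is flagged when its identity to the consensus of the
    remaining units is below ``threshold`` percent while every remaining
    full-length unit stays at or above it.
    """
    if len(units) < 2:
        raise ValueError("need at least two units")
    rest = units[1:]
    cons = build_consensus(list(rest))
    first_ident = local_align(units[0], cons).identity_pct
    if first_ident >= threshold:
        return False
    for u in rest:
        if len(u) == len(cons) and local_align(u, cons).identity_pct < threshold:
            return False
    return True


def detect_subunit_fusion(
    consensus: str, max_diff_frac: float = 0.35
) -> FusionRecord | None:
    """Split an even-length consensus into halves and test their kinship.

    Returns the (half_a, half_b, hamming) record when the halves differ
    at no more than ``max_diff_frac`` of their length — the signature of
    a repeat unit formed by fusing two smaller ancestral units.
    """
    if len(consensus) % 2:
        return None
    half = len(consensus) // 2
    a, b = consensus[:half], consensus[half:]
    d = hamming(a, b)
    if d <= max_diff_frac * half:
        return FusionRecord(half_a=a, half_b=b, hamming=d)
    return None


def build_repeat_unit_set(
    units: list[str],
    names: list[str] | None = None,
    divergent_threshold: float = 90.0,
    fusion_max_diff_frac: float = 0.35,
    params: AlignParams | None = None,
) -> RepeatUnitSet:
    """Assemble haplotypes, consensus and exclusion flags from array units.

    Haplotypes are distinct unit sequences in order of first occurrence.
    Excluded from similarity statistics are (a) the haplotype of a
    divergent initial unit and (b) haplotypes whose deletion against the
    consensus is internal; terminal truncations are retained because
    local alignment trims them naturally.
    """
    if not units:
        raise ValueError("empty unit list")
    order: list[str] = []
    mult: Counter[str] = Counter()
    for u in units:
        if u not in mult:
            order.append(u)
        mult[u] += 1
    if names is None:
        names = [f"U{i + 1}" for i in range(len(order))]
    haps = tuple(
        RepeatHaplotype(name=n, sequence=s, multiplicity=mult[s])
        for n, s in zip(names, order)
    )
    consensus = build_consensus(units)
    divergent = len(units) >= 2 and flag_divergent_initial_unit(
        units, divergent_threshold
    )
    excluded: set[str] = set()
    if divergent:
        first_hap = next(h.name for h in haps if h.sequence == units[0])
        excluded.add(first_hap)
    for h in haps:
        if h.name in excluded or len(h.sequence) >= len(consensus):
            continue
        if deletion_type(consensus, h.sequence, params) == "internal":
            excluded.add(h.name)
    fusion = detect_subunit_fusion(consensus, fusion_max_diff_frac)
    return RepeatUnitSet(
        haplotypes=haps,
        consensus=consensus,
        excluded=frozenset(excluded),
        divergent_initial=divergent,
        fusion=fusion,
    )


def unit_similarity_stats(
    unit_set: RepeatUnitSet, params: AlignParams | None = None
) -> SimilarityStats:
    """Pairwise local-alignment identity over non-excluded haplotypes."""
    usable = [h for h in unit_set.haplotypes if h.name not in unit_set.excluded]
    if len(usable) < 2:
        return SimilarityStats(min_sim=None, max_sim=None, matrix={})
    matrix: dict[tuple[str, str], float] = {}
    for i, h1 in enumerate(usable):
        for h2 in usable[i + 1 :]:
            matrix[(h1.name, h2.name)] = local_align(
                h1.sequence, h2.sequence, params
            ).identity_pct
    vals = list(matrix.values())
    return SimilarityStats(min_sim=min(vals), max_sim=max(vals), matrix=matrix)


# ---------------------------------------------------------------------------
# secondary-structure proxy

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def fold_score(seq: str, min_loop: int = 3) -> FoldScore:
    """Maximal Watson-Crick base-pair count with hairpin loops >= min_loop.

    A base-pair-maximization dynamic program (Nussinov-style) over
    nested structures; the count serves as a stability proxy for repeat
    units, and the structure is reported in dot-bracket notation.
    """
    seq = seq.upper()
    n = len(seq)
    if n == 0:
        return FoldScore(pairs=0, structure="")
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if (seq[i], seq[k]) in _PAIRS:
                    inner = dp[i + 1][k - 1] if k - 1 > i + 1 else 0
                    outer = dp[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + outer
                    if cand > best:
                        best = cand
            dp[i][j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i][j] == 0:
            continue
        if dp[i][j] == dp[i + 1][j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                inner = dp[i + 1][k - 1] if k - 1 > i + 1 else 0
                outer = dp[k + 1][j] if k + 1 <= j else 0
                if dp[i][j] == 1 + inner + outer:
                    structure[i], structure[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break
    return FoldScore(pairs=dp[0][n - 1] if n > 1 else 0, structure="".join(structure))
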