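"""Seven-pattern homology scan of rCR2-derived sequences against a mitogenome.

To ask where the pieces of a remnant CR2 came from, seven query patterns
are built from its decomposition — 5NR, TR unit (consensus), 3NR, and
their concatenations 5NR+TRunit, TRunit+3NR, 5NR+TRunit+3NR, 5NR+3NR —
and each is aligned locally against the whole circular genome (both
strands), with the source CR2 interval excluded so the trivial self-hit
is suppressed.  The known positive control is the lark observation of a
3NR aligning at 100% identity to the 5' end of rrnS.

The scan is deterministic seed-and-extend: exact 12-mer seed matches
nominate windows, each window is aligned with the affine Smith-Waterman
aligner, and hits passing the identity/length thresholds are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

from .align import AlignParams, local_align
from .core import Mitogenome
from .repeats import CRDecomposition

__all__ = ["HomologyHit", "build_patterns", "scan_genome"]

_SEED_K = 12
_MARGIN = 25

PATTERN_NAMES = (
    "5NR",
    "TRunit",
    "3NR",
    "5NR+TRunit",
    "TRunit+3NR",
    "5NR+TRunit+3NR",
    "5NR+3NR",
)


@dataclass(frozen=True)
class HomologyHit:
    pattern_name: str
    target_start: int  # genome coordinates, 0-based half-open (mod length)
    target_end: int
    strand: str  # '+' pattern matches H-strand sequence, '-' its reverse complement
    identity_pct: float
    columns: int
    aligned_pattern: str
    aligned_target: str
    overlapping_features: tuple[str, ...] = ()


def build_patterns(decomp: CRDecomposition, consensus: str | None = None) -> dict[str, str]:
    """The seven query patterns from one CR decomposition.

    ``consensus`` defaults to the first full-length unit's consensus
    source; pass the unit-set consensus explicitly when available.
    Empty components drop the patterns that would need them, with a
    warning.
    """
    from .repeats import build_consensus

    unit = consensus if consensus is not None else build_consensus(list(decomp.units))
    parts = {"5NR": decomp.five_nr, "TRunit": unit, "3NR": decomp.three_nr}
    if not any(parts.values()):
        raise ValueError("all decomposition components are empty")
    missing = [k for k, v in parts.items() if not v]
    patterns = {
        name: "".join(parts[c] for c in name.split("+")) for name in PATTERN_NAMES
    }
    patterns = {name: seq for name, seq in patterns.items() if seq}
    if missing:
        warnings.warn(
            f"empty decomposition component(s) {missing}; "
            f"{len(patterns)} patterns built",
            stacklevel=2,
        )
    return patterns


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _intervals_overlap(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def scan_genome(
    patterns: dict[str, str],
    genome: Mitogenome,
    params: AlignParams | None = None,
    min_identity: float = 85.0,
    min_length: int = 30,
    exclude: tuple[int, int] | None = None,
) -> list[HomologyHit]:
    """Scan every pattern against the circular genome, both strands.

    The genome is doubled so origin-spanning homology is found, and hits
    are deduplicated modulo genome length.  ``exclude`` is a genome
    interval (typically the source rCR2) whose hits are suppressed.
    Hits are sorted by identity then alignment length, descending.
    """
    L = genome.length
    doubled = genome.sequence * 2
    index = _kmer_index(doubled, _SEED_K)
    hits: list[HomologyHit] = []
    for name, pat in patterns.items():
        for strand in ("+", "-"):
            query = pat if strand == "+" else str(Seq(pat).reverse_complement())
            if len(query) < _SEED_K:
                continue
            window_starts: set[int] = set()
            for off in range(len(query) - _SEED_K + 1):
                for p in index.get(query[off : off + _SEED_K], ()):
                    if p - off >= L:  # same diagonal appears in first copy
                        continue
                    ws = max(0, p - off - _MARGIN)
                    window_starts.add(ws - ws % _MARGIN)  # cluster nearby seeds
            for ws in sorted(window_starts):
                window = doubled[ws : ws + len(query) + 2 * _MARGIN]
                if len(window) < min_length:
                    continue
                aln = local_align(query, window, params)
                if aln.columns < min_length or aln.identity_pct < min_identity:
                    continue
                t0, t1 = ws + aln.start_b, ws + aln.end_b
                if strand == "+":
                    a_pat, a_tgt = aln.aligned_a, aln.aligned_b
                else:
                    a_pat = str(Seq(aln.aligned_a).reverse_complement())
                    a_tgt = str(Seq(aln.aligned_b).reverse_complement())
                hits.append(
                    HomologyHit(
                        pattern_name=name,
                        target_start=t0 % L,
                        target_end=t0 % L + (t1 - t0),
                        strand=strand,
                        identity_pct=aln.identity_pct,
                        columns=aln.columns,
                        aligned_pattern=a_pat,
                        aligned_target=a_tgt,
                    )
                )
    # suppress the source interval
    if exclude is not None:
        x0, x1 = exclude
        hits = [
            h
            for h in hits
            if not (
                _intervals_overlap(h.target_start, h.target_end, x0, x1)
                or _intervals_overlap(h.target_start - L, h.target_end - L, x0, x1)
            )
        ]
    # deduplicate modulo length: keep the best hit per (pattern, strand, locus)
    best: dict[tuple[str, str, int], HomologyHit] = {}
    for h in hits:
        key = (h.pattern_name, h.strand, h.target_start % L // 10)
        prev = best.get(key)
        if prev is None or (h.identity_pct, h.columns) > (prev.identity_pct, prev.columns):
            best[key] = h
    out = []
    for h in best.values():
        feats = tuple(
            f.name
            for f in genome.features
            if _intervals_overlap(h.target_start, h.target_end, f.start, f.end)
            or _intervals_overlap(h.target_start - L, h.target_end - L, f.start, f.end)
        )
        out.append(
            HomologyHit(
                **{**h.__dict__, "overlapping_features": feats}
            )
        )
    out.sort(key=lambda h: (-h.identity_pct, -h.columns, h.pattern_name, h.target_start))
    return out
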