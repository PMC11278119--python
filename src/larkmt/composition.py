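"""Nucleotide composition, strand skew, RSCU and codon-end extraction.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C), computed on
the H-strand reading of a sequence; ambiguity codes are excluded from
the counts, and an undefined denominator yields ``None`` rather than 0.

RSCU (relative synonymous codon usage) is the observed count of a codon
divided by its expected count were all synonymous codons used equally;
the vertebrate mitochondrial genetic code (NCBI table 2) is the default,
which is what makes AGA/AGG stop codons in these genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Data import CodonTable

__all__ = [
    "SkewResult",
    "CodonEnds",
    "compute_skew",
    "compute_rscu",
    "rscu_families",
    "extract_start_stop",
]


@dataclass(frozen=True)
class SkewResult:
    at_skew: float | None
    gc_skew: float | None
    at_content: float  # percent


@dataclass(frozen=True)
class CodonEnds:
    start: str
    stop: str
    stop_incomplete: bool


def compute_skew(seq: str) -> SkewResult:
    """Strand skew and A+T content of one sequence (N excluded)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    a, c, g, t = (seq.count(b) for b in "ACGT")
    total = a + c + g + t
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return SkewResult(
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(g - c) / (g + c) if g + c else None,
        at_content=100.0 * (a + t) / total,
    )


def rscu_families(code: int = 2) -> dict[str, list[str]]:
    """Synonymous codon families (amino acid -> DNA codons), stops excluded."""
    table = CodonTable.unambiguous_dna_by_id[code]
    fams: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return fams


def compute_rscu(cds_list: list[str], code: int = 2) -> dict[str, float]:
    """RSCU per codon over a set of coding sequences.

    Each CDS is read 5'->3' on its coding strand; a trailing incomplete
    codon is trimmed.  Internal stop codons are counted but flagged with
    a warning.  Codons of a family with zero total usage get RSCU 0.
    """
    table = CodonTable.unambiguous_dna_by_id[code]
    stops = set(table.stop_codons)
    counts: dict[str, int] = {}
    for idx, cds in enumerate(cds_list):
        cds = cds.upper().replace("U", "T")
        usable = len(cds) - len(cds) % 3
        for pos in range(0, usable, 3):
            codon = cds[pos : pos + 3]
            if set(codon) - set("ACGT"):
                continue
            if codon in stops:
                if pos < usable - 3:
                    warnings.warn(
                        f"internal stop codon {codon} at nt {pos} of CDS {idx}",
                        stacklevel=2,
                    )
                continue  # terminal (and internal) stops excluded from RSCU
            counts[codon] = counts.get(codon, 0) + 1
    rscu: dict[str, float] = {}
    for fam in rscu_families(code).values():
        total = sum(counts.get(c, 0) for c in fam)
        for c in fam:
            rscu[c] = len(fam) * counts.get(c, 0) / total if total else 0.0
    return rscu


def extract_start_stop(cds: str, flag_incomplete: bool = True) -> CodonEnds:
    """Start codon and (possibly incomplete) stop codon of a CDS."""
    cds = cds.upper()
    if len(cds) < 6:
        raise ValueError("CDS shorter than 6 nt")
    tail = len(cds) % 3
    if tail and flag_incomplete:
        return CodonEnds(start=cds[:3], stop=cds[-tail:], stop_incomplete=True)
    usable = len(cds) - tail
    return CodonEnds(start=cds[:3], stop=cds[usable - 3 : usable], stop_incomplete=False)
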