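"""Circular mitogenome data model, I/O, and gene-order classification.

A :class:`Mitogenome` is a circular DNA sequence plus an ordered list of
:class:`GeneFeature` annotations (0-based half-open coordinates on the
forward/H strand orientation of the sequence).  Gene orders are circular
lists of (symbol, strand) tokens; two orders are equal iff one is a
rotation of the other (no reflection: mitochondrial strands are
annotated and not symmetric).

Order-type labels follow the avian control-region duplication
literature: ``A`` ancestral single-CR order, ``B`` two complete CRs,
``C`` one complete CR plus a remnant CR (rCR2), ``T1``-``T3``
transitional states still carrying duplicated protein/tRNA genes, and
``UN`` for anything else.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "Mitogenome",
    "GeneOrder",
    "PCG_SYMBOLS",
    "L_STRAND_GENES",
    "read_mitogenome",
    "write_mitogenome",
    "linearize",
    "extract_gene_order",
    "classify_gene_order",
]

PCG_SYMBOLS = frozenset(
    {
        "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
        "ND3", "ND4L", "ND4", "ND5", "ND6", "Cytb",
    }
)
CR_NAMES = frozenset({"CR", "CR1", "CR2", "rCR2", "rCR1"})
# ND6 and eight tRNAs are L-strand encoded in the avian mitogenome
L_STRAND_GENES = frozenset(
    {"ND6", "trnQ", "trnA", "trnN", "trnC", "trnY", "trnS2", "trnE", "trnP"}
)

_VALID_ALPHABET = set("ACGTN")
_COPY_SUFFIX = re.compile(r"_(\d+)$")


def gene_symbol(name: str) -> str:
    """Normalize a feature name to its gene symbol.

    Copy suffixes are stripped (``Cytb_2`` -> ``Cytb``) and all CR copy
    names map to the symbol ``CR``.
    """
    base = _COPY_SUFFIX.sub("", name)
    return "CR" if base in CR_NAMES else base


def _infer_kind(name: str) -> str:
    base = gene_symbol(name)
    if base == "CR":
        return "CR"
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    if base in PCG_SYMBOLS:
        return "PCG"
    warnings.warn(f"unknown gene symbol {name!r}; kind guessed by prefix", stacklevel=3)
    return "PCG"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: name, strand (H/L), 0-based half-open interval."""

    name: str
    strand: str
    start: int
    end: int
    kind: str = ""
    remnant: bool = False  # CR copies only: lacks the conserved boxes
    wraps: bool = False  # spans the circular origin; end may exceed length

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be H or L, got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end}) for {self.name}")
        if not self.kind:
            object.__setattr__(self, "kind", _infer_kind(self.name))

    @property
    def symbol(self) -> str:
        return gene_symbol(self.name)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Mitogenome:
    """A circular mitochondrial genome with ordered gene features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_ALPHABET
        if bad:
            raise ValueError(f"invalid sequence characters: {sorted(bad)}")
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique (suffix duplicates)")
        for f in self.features:
            limit = self.length + (self.length if f.wraps else 0)
            if f.end > limit:
                raise ValueError(
                    f"feature {f.name} [{f.start},{f.end}) exceeds genome "
                    f"length {self.length} (wraps={f.wraps})"
                )
        self.features.sort(key=lambda f: (f.start, f.end))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feature: GeneFeature) -> str:
        """Gene sequence 5'->3' on its coding strand."""
        if feature.end <= self.length:
            s = self.sequence[feature.start : feature.end]
        else:  # wraps the origin
            s = self.sequence[feature.start :] + self.sequence[: feature.end - self.length]
        if feature.strand == "L":
            s = str(Seq(s).reverse_complement())
        return s

    def get(self, symbol: str) -> list[GeneFeature]:
        return [f for f in self.features if f.symbol == gene_symbol(symbol)]


def _read_tsv_features(path: Path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None and parts[0] == "name":
                header = parts
                continue
            row = dict(zip(header or ["name", "strand", "start", "end"], parts))
            feats.append(
                GeneFeature(
                    name=row["name"],
                    strand=row["strand"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    kind=row.get("kind", ""),
                    remnant=row.get("remnant", "0") in ("1", "True", "true"),
                    wraps=row.get("wraps", "0") in ("1", "True", "true"),
                )
            )
    return feats


def _read_gff3_features(path: Path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or cols[2]
            feats.append(
                GeneFeature(
                    name=name,
                    strand="H" if cols[6] == "+" else "L",
                    start=int(cols[3]) - 1,  # GFF3 is 1-based inclusive
                    end=int(cols[4]),
                    remnant=attrs.get("remnant", "0") in ("1", "true", "True"),
                    wraps=attrs.get("wraps", "0") in ("1", "true", "True"),
                )
            )
    return feats


def read_mitogenome(fasta_path: str | Path, annotation_path: str | Path) -> Mitogenome:
    """Read a single-record FASTA plus a TSV or GFF3 annotation table."""
    fasta_path, annotation_path = Path(fasta_path), Path(annotation_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    if annotation_path.suffix.lower() in (".gff", ".gff3"):
        feats = _read_gff3_features(annotation_path)
    else:
        feats = _read_tsv_features(annotation_path)
    return Mitogenome(id=rec.id, sequence=str(rec.seq), features=feats)


def write_mitogenome(
    genome: Mitogenome, fasta_path: str | Path, annotation_path: str | Path
) -> None:
    """Write FASTA (70-column wrap) and the companion feature TSV."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    with open(fasta_path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    with open(annotation_path, "w") as fh:
        fh.write("name\tstrand\tstart\tend\tkind\tremnant\twraps\n")
        for f in genome.features:
            fh.write(
                f"{f.name}\t{f.strand}\t{f.start}\t{f.end}\t{f.kind}\t"
                f"{int(f.remnant)}\t{int(f.wraps)}\n"
            )


def linearize(genome: Mitogenome, anchor: str) -> Mitogenome:
    """Rotate the circular genome so that ``anchor``'s start is position 0."""
    hits = genome.get(anchor)
    if len(hits) != 1:
        raise ValueError(
            f"anchor {anchor!r} present {len(hits)} times; need exactly one"
        )
    shift = hits[0].start
    L = genome.length
    seq = genome.sequence[shift:] + genome.sequence[:shift]
    feats = []
    for f in genome.features:
        start = (f.start - shift) % L
        end = start + f.length
        feats.append(replace(f, start=start, end=end, wraps=end > L))
    return Mitogenome(id=genome.id, sequence=seq, features=feats)


@dataclass(frozen=True)
class GeneOrder:
    """A circular gene arrangement: (symbol, strand, cr_state) tokens.

    ``cr_state`` is ``None`` for non-CR genes, else ``"complete"`` or
    ``"remnant"``.  Equality is rotation-invariant but not
    reflection-invariant.
    """

    tokens: tuple[tuple[str, str, str | None], ...]

    @staticmethod
    def from_names(
        names: list[str],
        strands: list[str] | None = None,
        remnant: set[str] | None = None,
    ) -> "GeneOrder":
        """Build from feature-style names (``CR1``, ``rCR2``, ``Cytb_2``...).

        Strand defaults follow the avian H/L assignment; names in
        ``remnant`` (or starting with ``rCR``) become remnant CR copies.
        """
        remnant = remnant or set()
        toks = []
        for i, name in enumerate(names):
            sym = gene_symbol(name)
            strand = (
                strands[i]
                if strands is not None
                else ("L" if sym in L_STRAND_GENES else "H")
            )
            state = None
            if sym == "CR":
                state = (
                    "remnant"
                    if (name in remnant or name.startswith("rCR"))
                    else "complete"
                )
            toks.append((sym, strand, state))
        return GeneOrder(tuple(toks))

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.tokens)

    @property
    def cr_states(self) -> list[str]:
        return [t[2] for t in self.tokens if t[0] == "CR"]

    def rotate(self, k: int) -> "GeneOrder":
        n = len(self.tokens)
        k %= n
        return GeneOrder(self.tokens[k:] + self.tokens[:k])

    def canonical(self) -> tuple:
        n = len(self.tokens)
        return min(self.tokens[k:] + self.tokens[:k] for k in range(n))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def to_json(self) -> str:
        return json.dumps(
            [{"symbol": s, "strand": st, "cr_state": c} for s, st, c in self.tokens]
        )


def extract_gene_order(genome: Mitogenome) -> GeneOrder:
    """The circular (symbol, strand, cr_state) order of annotated genes."""
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    for a, b in zip(feats, feats[1:]):
        if a.kind == b.kind and b.start < a.end:
            warnings.warn(
                f"overlapping {a.kind} features {a.name}/{b.name}; kept start order",
                stacklevel=2,
            )
    toks = []
    for f in feats:
        state = None
        if f.symbol == "CR":
            state = "remnant" if (f.remnant or f.name.startswith("rCR")) else "complete"
        toks.append((f.symbol, f.strand, state))
    return GeneOrder(tuple(toks))


def classify_gene_order(order: GeneOrder) -> str:
    """Label a circular order as A, B, C, T1, T2, T3 or UN.

    T-states carry at least one duplicated non-CR gene (T1 keeps a
    duplicate Cytb, T2 a duplicate trnT but no Cytb, T3 duplicates
    within trnP-ND6-trnE only).  Without duplicated genes the label
    depends on CR copy number and completeness.
    """
    syms = order.symbols
    counts: dict[str, int] = {}
    for s in syms:
        counts[s] = counts.get(s, 0) + 1
    dup_non_cr = {s for s, c in counts.items() if c >= 2 and s != "CR"}
    if dup_non_cr:
        if "Cytb" in dup_non_cr:
            return "T1"
        if "trnT" in dup_non_cr:
            return "T2"
        if dup_non_cr & {"trnP", "ND6", "trnE"}:
            return "T3"
        return "UN"
    states = order.cr_states
    if len(states) == 1:
        return "A"
    if len(states) == 2:
        if states.count("complete") == 2:
            return "B"
        if sorted(states) == ["complete", "remnant"]:
            return "C"
    return "UN"
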