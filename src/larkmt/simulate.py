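"""Synthetic avian mitogenomes, control regions and trait trees with
known ground truth.

The generator emulates the structures this pipeline analyses without any
real sequence: a standard avian gene inventory (13 protein-coding genes,
22 tRNAs, 2 rRNAs) arranged per an order type; a CR1 carrying conserved
box motifs in domain order (ETAS1-2/CSB1-like in domain I, the F/E/D/C/
b/B boxes in domain II, an LSP/HSP stub, CSB1 and a poly-T in domain
III); and a remnant CR2 built as 5NR + tandem units + 3NR, optionally
with a divergent first unit and/or a period fused from two diverged
halves.  Optionally the 3' end of the 3NR is copied onto the 5' end of
rrnS, planting the homology event observed in *Alauda gulgula*.

Gene sequences are random DNA of plausible lengths (PCGs carry a
correct start/stop codon); the pipeline analyses the structure of these
regions, not their biology.  All randomness flows from one integer seed
(component sub-streams are derived from it), so regeneration with equal
seeds is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    GeneFeature,
    L_STRAND_GENES,
    Mitogenome,
    gene_symbol,
    write_mitogenome,
)

__all__ = [
    "CR2Spec",
    "SimConfig",
    "DEFAULT_CR1_BOXES",
    "simulate_cr2",
    "simulate_mitogenome",
    "simulate_traits_on_tree",
    "write_fixture",
]

_BASES = np.array(list("ACGT"))

# Fixed literal motifs planted in CR1; the pipeline only ever checks their
# presence or absence, so the letters just need to be stable and distinct.
DEFAULT_CR1_BOXES: dict[str, str] = {
    "ETAS1": "TACATTAAACTATTCTCTGGT",
    "ETAS2": "CCCCCTACCAAGTGTACAT",
    "CSB1like": "TTGGTTACGGGATAATA",
    "Fbox": "ATGTACGGGTTTAACTATA",
    "Ebox": "CCTGAAAACCAGGAACT",
    "Dbox": "CCCTTGACTTAAGCG",
    "Cbox": "ATGCTTGTAGGACATAA",
    "bbox": "TCTAGGCACCCCCC",
    "Bbox": "AAACCCCCCTACCCCC",
    "LSPHSP": "CACGTGACGTCACGTG",
    "CSB1_III": "TTAATGCTTGTTAGACATA",
}

# Avian ancestral gene order (type A), written from trnF; the circular
# order is what matters, not the starting gene.
_ORDER_A_CORE = [
    "trnF", "rrnS", "trnV", "rrnL", "trnL2", "ND1", "trnI", "trnQ", "trnM",
    "ND2", "trnW", "trnA", "trnN", "trnC", "trnY", "COX1", "trnS2", "trnD",
    "COX2", "trnK", "ATP8", "ATP6", "COX3", "trnG", "ND3", "trnR", "ND4L",
    "ND4", "trnH", "trnS1", "trnL1", "ND5",
]

_TAILS: dict[str, list[str]] = {
    "A": ["Cytb", "trnT", "trnP", "ND6", "trnE", "CR"],
    "B": ["Cytb", "trnT", "CR1", "trnP", "ND6", "trnE", "CR2"],
    "C": ["Cytb", "trnT", "CR1", "trnP", "ND6", "trnE", "rCR2"],
    "T1": ["Cytb", "trnT", "trnP", "ND6", "trnE", "CR1",
           "Cytb_2", "trnT_2", "trnP_2", "ND6_2", "trnE_2", "CR2"],
    "T2": ["Cytb", "trnT", "trnP", "ND6", "trnE", "CR1",
           "trnT_2", "trnP_2", "ND6_2", "trnE_2", "CR2"],
    "T3": ["Cytb", "trnT", "trnP", "ND6", "trnE", "CR1",
           "trnP_2", "ND6_2", "trnE_2", "CR2"],
}

_STOP_CODONS = {"TAA", "TAG", "AGA", "AGG"}  # vertebrate mitochondrial


@dataclass(frozen=True)
class CR2Spec:
    """Structure of the simulated remnant CR2.

    Defaults emulate a lark-like array: a 37-bp unit in four copies
    between a 60-bp 5NR and an 81-bp 3NR (81 bp being the length of the
    rrnS-homologous 3NR reported in *A. gulgula*).
    """

    five_nr_len: int = 60
    period: int = 37
    copies: float = 4.0
    per_unit_substitution_rate: float = 0.01
    divergent_first_unit: bool = False
    fused_halves: bool = False
    three_nr_len: int = 81

    def __post_init__(self) -> None:
        if not (0.0 <= self.per_unit_substitution_rate <= 0.2):
            raise ValueError("substitution rate must lie in [0, 0.2]")
        if self.period < 10:
            raise ValueError("period must be at least 10")
        if self.copies < 2:
            raise ValueError("need at least two copies")
        if self.fused_halves and self.period % 2:
            raise ValueError("fused_halves requires an even period")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    order_type: str = "C"
    genome_length_target: int = 17000
    cr1_boxes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CR1_BOXES))
    cr2: CR2Spec = field(default_factory=CR2Spec)
    plant_rrns_overlap: bool = False
    tree_tips: int = 8
    trait_change_branches: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.order_type not in _TAILS:
            raise ValueError(f"unknown order type {self.order_type!r}")


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[rng.integers(0, 3)]
    return "".join(out)


def simulate_cr2(spec: CR2Spec, seed: int) -> tuple[str, dict]:
    """A remnant CR2 string plus its ground-truth decomposition."""
    rng = np.random.default_rng([seed, 2])
    five_nr = _rand_dna(rng, spec.five_nr_len)
    if spec.fused_halves:
        half = spec.period // 2
        half_a = _rand_dna(rng, half)
        n_diff = max(1, int(round(0.28 * half)))
        pos = rng.choice(half, size=n_diff, replace=False)
        hb = list(half_a)
        for i in pos:
            alts = [b for b in "ACGT" if b != hb[i]]
            hb[i] = alts[rng.integers(0, 3)]
        half_b = "".join(hb)
        master = half_a + half_b
        fused_hamming = sum(x != y for x, y in zip(half_a, half_b))
    else:
        master = _rand_dna(rng, spec.period)
        fused_hamming = None
    n_full = int(spec.copies)
    partial_len = int(round((spec.copies - n_full) * spec.period))
    units: list[str] = []
    for k in range(n_full):
        rate = 0.30 if (spec.divergent_first_unit and k == 0) else spec.per_unit_substitution_rate
        units.append(_mutate(rng, master, rate))
    if partial_len:
        units.append(
            _mutate(rng, master[:partial_len], spec.per_unit_substitution_rate)
        )
    three_nr = _rand_dna(rng, spec.three_nr_len)
    cr2 = five_nr + "".join(units) + three_nr
    tr_start = len(five_nr)
    tr_end = tr_start + sum(len(u) for u in units)
    truth = {
        "five_nr": five_nr,
        "units": units,
        "three_nr": three_nr,
        "tr_start": tr_start,
        "tr_end": tr_end,
        "period": spec.period,
        "copies": (tr_end - tr_start) / spec.period,
        "master_unit": master,
        "fused_hamming": fused_hamming,
        "divergent_first_unit": spec.divergent_first_unit,
    }
    return cr2, truth


def _simulate_pcg(rng: np.random.Generator) -> str:
    n_codons = int(rng.integers(100, 500))  # 300-1500 nt; totals near 17 kb
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            c = _rand_dna(rng, 3)
            if c not in _STOP_CODONS:
                break
        codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _simulate_cr1(rng: np.random.Generator, boxes: dict[str, str]) -> str:
    # boxes planted in domain order with random spacers
    parts = []
    for motif in boxes.values():
        parts.append(_rand_dna(rng, int(rng.integers(30, 90))))
        parts.append(motif)
    parts.append(_rand_dna(rng, int(rng.integers(40, 120))))
    parts.append("T" * 10)  # the domain-III poly-T
    return "".join(parts)


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def simulate_mitogenome(config: SimConfig) -> tuple[Mitogenome, dict]:
    """A synthetic mitogenome arranged per ``config.order_type``.

    Returns the genome and a ground-truth record holding the planted
    feature coordinates, the CR2 decomposition, the order label, and the
    planted homology interval when ``plant_rrns_overlap`` is set.
    """
    rng = np.random.default_rng([config.seed, 1])
    names = _ORDER_A_CORE + _TAILS[config.order_type]
    segments: list[str] = []
    features: list[GeneFeature] = []
    cr2_truth: dict | None = None
    pos = 0
    for name in names:
        sym = gene_symbol(name)
        if sym == "CR":
            if name == "rCR2":
                seq, cr2_truth = simulate_cr2(config.cr2, config.seed)
            else:
                seq = _simulate_cr1(rng, config.cr1_boxes)
            strand = "H"
        elif name.startswith("trn"):
            seq = _rand_dna(rng, int(rng.integers(65, 76)))
            strand = "L" if sym in L_STRAND_GENES else "H"
        elif name.startswith("rrn"):
            length = int(rng.integers(950, 1000)) if name == "rrnS" else int(
                rng.integers(1550, 1650)
            )
            seq = _rand_dna(rng, length)
            strand = "H"
        else:  # PCG
            seq = _simulate_pcg(rng)
            strand = "L" if sym in L_STRAND_GENES else "H"
        if strand == "L":
            seq = _revcomp(seq)
        features.append(
            GeneFeature(
                name=name,
                strand=strand,
                start=pos,
                end=pos + len(seq),
                remnant=(sym == "CR" and name == "rCR2"),
            )
        )
        segments.append(seq)
        pos += len(seq)
    sequence = "".join(segments)

    truth: dict = {
        "order_type": config.order_type,
        "features": [
            {"name": f.name, "strand": f.strand, "start": f.start, "end": f.end}
            for f in features
        ],
        "cr2": cr2_truth,
        "planted_homology": None,
        "seed": config.seed,
    }
    if config.plant_rrns_overlap:
        if cr2_truth is None:
            raise ValueError("plant_rrns_overlap requires a remnant CR2 (order C)")
        rrns = next(f for f in features if f.name == "rrnS")
        insert = cr2_truth["three_nr"]
        sequence = (
            sequence[: rrns.start] + insert + sequence[rrns.start + len(insert) :]
        )
        truth["planted_homology"] = {
            "pattern": "3NR",
            "start": rrns.start,
            "end": rrns.start + len(insert),
            "feature": "rrnS",
        }
    genome = Mitogenome(id=f"sim{config.seed}_{config.order_type}", sequence=sequence,
                        features=features)
    return genome, truth


# ---------------------------------------------------------------------------
# trait trees


def _random_topology(rng: np.random.Generator, tips: int) -> str:
    """Random rooted binary topology as newick with labeled internals."""
    nodes = [f"T{i + 1}" for i in range(tips)]
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        counter += 1
        nodes.append(f"({a},{b})N{counter}")
    return nodes[0] + ";"


def simulate_traits_on_tree(
    tips: int, change_branches: list[str], seed: int
) -> tuple[str, dict[str, str], dict]:
    """A random labeled tree with a trait switched on chosen branches.

    The trait starts in state "0" at the root and switches to a fresh
    state on each branch named in ``change_branches`` (tip or internal
    labels of the generated topology).  Returns the newick string, the
    tip->state map, and the truth record (per-node states, change
    count).
    """
    import dendropy

    rng = np.random.default_rng([seed, 3])
    newick = _random_topology(rng, tips)
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=False
    )
    labels = set()
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            labels.add(node.taxon.label)
        elif node.label:
            labels.add(node.label)
    unknown = [b for b in change_branches if b not in labels]
    if unknown:
        raise ValueError(f"change branches not in topology: {unknown}")

    counter = [0]
    node_states: dict[str, str] = {}

    def label_of(node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        return node.label or "root"

    for node in tree.preorder_node_iter():
        lbl = label_of(node)
        parent = node.parent_node
        if parent is None:
            node_states[lbl] = "0"
            continue
        state = node_states[label_of(parent)]
        if lbl in change_branches:
            counter[0] += 1
            state = str(counter[0])
        node_states[lbl] = state
    tip_states = {
        label_of(lf): node_states[label_of(lf)] for lf in tree.leaf_node_iter()
    }
    truth = {
        "newick": newick,
        "node_states": node_states,
        "planted_changes": len(change_branches),
    }
    return newick, tip_states, truth


def write_fixture(config: SimConfig, out_dir: str | Path) -> dict:
    """Generate one full fixture set on disk.

    Writes ``genome.fasta``, ``annotation.tsv``, ``tree.nwk``,
    ``traits.tsv`` and ``truth.json``; returns the truth record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_mitogenome(config)
    write_mitogenome(genome, out / "genome.fasta", out / "annotation.tsv")
    newick, tip_states, tree_truth = simulate_traits_on_tree(
        config.tree_tips, list(config.trait_change_branches), config.seed
    )
    (out / "tree.nwk").write_text(newick + "\n")
    with open(out / "traits.tsv", "w") as fh:
        fh.write("tip\tstate\n")
        for tip, state in sorted(tip_states.items()):
            fh.write(f"{tip}\t{state}\n")
    truth = {**truth, "tree": tree_truth}
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
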