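"""Tandem-duplication random-loss (TDRL) scenarios between gene orders.

Under the TDRL model a rearranged mitochondrial gene order arises from
an ancestral one by tandem duplication of a contiguous gene block
followed by loss of one copy of each redundantly duplicated gene.  For
the avian control-region neighbourhood the relevant blocks end at the
control region: duplicating Cytb..CR, trnT..CR or trnP..CR from the
ancestral single-CR order (type A) and resolving the duplicate genes
all yield the two-CR order (type B), through transitional states T1, T2
and T3 respectively.  CR copies are never lost here — degradation of
CR2 to a remnant is a separate annotation step, not a gene loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .core import GeneOrder, classify_gene_order

__all__ = [
    "TDRLScenario",
    "EnumerationConstraints",
    "apply_tdrl",
    "enumerate_tdrl",
    "scenario_intermediates",
]


@dataclass(frozen=True)
class EnumerationConstraints:
    """Search window for duplicated blocks.

    Blocks start at or after ``window_start`` (a gene symbol), must
    contain and end at the CR, and a single duplication event is
    allowed.
    """

    window_start: str = "Cytb"
    block_end: str = "CR"
    max_duplications: int = 1


@dataclass(frozen=True)
class TDRLScenario:
    block: tuple[str, ...]  # symbols of the duplicated block, in order
    losses: frozenset[tuple[str, int]]  # (gene symbol, copy index 1|2)
    intermediate: GeneOrder  # after duplication, before loss
    result: GeneOrder

    @property
    def n_losses(self) -> int:
        return len(self.losses)


def _rotate_to(order: GeneOrder, symbol: str) -> tuple[int, GeneOrder]:
    """Rotate so that the first occurrence of ``symbol`` is at index 0."""
    for k, tok in enumerate(order.tokens):
        if tok[0] == symbol:
            return k, order.rotate(k)
    raise ValueError(f"gene {symbol!r} not in order")


def apply_tdrl(
    order: GeneOrder,
    block: tuple[int, int],
    losses: frozenset[tuple[str, int]] | set[tuple[str, int]] = frozenset(),
) -> GeneOrder:
    """Duplicate ``block`` (index interval, half-open) in tandem, then
    delete the requested copies.

    ``losses`` entries are (gene symbol, copy index) where copy 1/2 are
    the first/second occurrence of that gene inside the duplicated
    tandem region.  Losing a gene that was not duplicated, or both
    copies of a gene, is an error.
    """
    losses = frozenset(losses)
    i, j = block
    toks = order.tokens
    if not (0 <= i < j <= len(toks)):
        raise ValueError(f"block {block} outside order of length {len(toks)}")
    dup_syms = [t[0] for t in toks[i:j]]
    dup_counts = {s: dup_syms.count(s) for s in dup_syms}
    for sym, copy in losses:
        if sym not in dup_counts:
            raise ValueError(f"loss of non-duplicated gene {sym!r}")
        if copy not in (1, 2):
            raise ValueError(f"copy index must be 1 or 2, got {copy}")
        if (sym, 1) in losses and (sym, 2) in losses:
            raise ValueError(f"cannot lose both copies of {sym!r}")
    # tandem region: block followed by its copy
    tandem = list(toks[i:j]) + list(toks[i:j])
    kept = []
    seen: dict[str, int] = {}
    for tok in tandem:
        sym = tok[0]
        seen[sym] = seen.get(sym, 0) + 1
        if (sym, seen[sym]) in losses:
            continue
        kept.append(tok)
    new = list(toks[:i]) + kept + list(toks[j:])
    return GeneOrder(tuple(new))


def enumerate_tdrl(
    source: GeneOrder,
    target: GeneOrder,
    constraints: EnumerationConstraints | None = None,
) -> list[TDRLScenario]:
    """All single-duplication TDRL scenarios turning ``source`` into
    ``target`` up to rotation.

    One scenario is returned per (block, loss pattern); scenarios are
    ordered shortest block first, then by the loss set.  Every
    duplicated non-CR gene must lose exactly one copy; CR copies are
    always retained.  Returns an empty list when no scenario exists
    (including the degenerate ``source == target`` case).
    """
    constraints = constraints or EnumerationConstraints()
    if source == target:
        return []
    _, rot = _rotate_to(source, constraints.window_start)
    # CR position defining the block end (first CR at/after window start)
    cr_idx = next(
        (k for k, t in enumerate(rot.tokens) if t[0] == constraints.block_end), None
    )
    if cr_idx is None:
        return []
    scenarios: list[TDRLScenario] = []
    for start in range(cr_idx + 1):  # blocks [start, cr_idx]
        block = (start, cr_idx + 1)
        block_syms = tuple(t[0] for t in rot.tokens[start : cr_idx + 1])
        non_cr = [s for s in block_syms if s != constraints.block_end]
        if len(set(non_cr)) != len(non_cr) or block_syms.count(constraints.block_end) != 1:
            continue  # ambiguous copy indices; outside this model's scope
        intermediate = apply_tdrl(rot, block, frozenset())
        for choice in product((1, 2), repeat=len(non_cr)):
            losses = frozenset(zip(non_cr, choice))
            result = apply_tdrl(rot, block, losses)
            if result == target:
                scenarios.append(
                    TDRLScenario(
                        block=block_syms,
                        losses=losses,
                        intermediate=intermediate,
                        result=result,
                    )
                )
    scenarios.sort(key=lambda s: (len(s.block), sorted(s.losses)))
    return scenarios


def scenario_intermediates(scenario: TDRLScenario) -> list[tuple[str, GeneOrder]]:
    """The transitional states of a scenario with their order-type labels."""
    out = [(classify_gene_order(scenario.intermediate), scenario.intermediate)]
    if scenario.losses:
        out.append((classify_gene_order(scenario.result), scenario.result))
    return out
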