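#!/usr/bin/env python
"""Generate the synthetic lark-like mitogenome fixture used downstream.

Builds a type-C genome (one complete CR1 with conserved boxes, a remnant
CR2 of 5NR + 4 x 37 bp units + 81 bp 3NR) with the 3NR copied onto the
rrnS 5' end, plus a trait-annotated tree, and writes everything under
results/sim/ in plain text formats.
"""

from pathlib import Path

from larkmt.simulate import CR2Spec, SimConfig, write_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main(seed: int = 1) -> None:
    cfg = SimConfig(
        seed=seed,
        order_type="C",
        cr2=CR2Spec(per_unit_substitution_rate=0.0),
        plant_rrns_overlap=True,
        tree_tips=8,
        trait_change_branches=("N2",),
    )
    truth = write_fixture(cfg, OUT)
    n_feats = len(truth["features"])
    cr2 = truth["cr2"]
    print(f"wrote fixture to {OUT}")
    print(f"  genome: {n_feats} features, order type {truth['order_type']}")
    print(
        f"  rCR2: 5NR {len(cr2['five_nr'])} bp + "
        f"{len(cr2['units'])} x {cr2['period']} bp units + "
        f"3NR {len(cr2['three_nr'])} bp"
    )
    print(f"  planted homology: {truth['planted_homology']}")


if __name__ == "__main__":
    main()
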