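"""Published remnant-CR2 repeat-unit haplotypes of eight lark species.

Each species' tandem-repeat array is published as a consensus (or, for
*Melanocorypha mongolica*, the first unit type H_1) plus one dot/dash
difference mask per haplotype: dots mark identity to the reference row,
dashes mark gaps, letters mark substitutions.  These rows are the input
data for the repeat-unit similarity analysis; decode them with
:func:`larkmt.align.decode_diff_mask`.

The initial repeat units of *Alauda arvensis* (D_1), *Alauda razae*
(F_1) and *Calandrella cinerea* (G_1) diverge strongly from the rest of
their arrays and are excluded from within-species similarity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import DiffMask, decode_diff_mask

__all__ = ["SpeciesRepeatRecord", "REPEAT_UNIT_TABLE", "decoded_haplotypes"]


@dataclass(frozen=True)
class SpeciesRepeatRecord:
    species: str
    reference_name: str  # consensus row name, or the reference unit for masks
    reference: str  # may contain '-' insertion columns
    haplotype_masks: dict[str, str]  # name -> dot/dash mask
    divergent_initial: tuple[str, ...] = ()  # excluded from similarity stats
    notes: str = ""

    def haplotypes(self) -> dict[str, str]:
        """Decode every haplotype mask to a concrete sequence."""
        return {
            name: decode_diff_mask(DiffMask(self.reference, mask))
            for name, mask in self.haplotype_masks.items()
        }


REPEAT_UNIT_TABLE: dict[str, SpeciesRepeatRecord] = {
    "Eremophila alpestris": SpeciesRepeatRecord(
        species="Eremophila alpestris",
        reference_name="A_CS",
        reference="AACAAAAGAAATCAATCCCATTTCTTTCTTTATTATACATATAATAAAGAG",
        haplotype_masks={
            "A_1": "." * 51,
            "A_2": "." * 18 + "T" + "." * 32,
            "A_3": "." * 5 + "-" * 46,
        },
    ),
    "Alaudala cheleensis": SpeciesRepeatRecord(
        species="Alaudala cheleensis",
        reference_name="B_CS",
        reference="ACACACGTATAAATAAAGACAGGACACCTT-ACGTCTTCTTATACTATTCTTATACTATTATACACGT",
        haplotype_masks={
            "B_1": "." * 6 + "A" + "." * 5 + "G" + "." * 17 + "-" + "." * 37,
            "B_2": "." * 30 + "T" + "." * 37,
            "B_3": "." * 30 + "-" + "." * 37,
            "B_4": "." * 6 + "A" + "." * 5 + "G" + "." * 17 + "-" + "." * 26 + "G" + "." * 10,
            "B_5": "." * 30 + "-" + "." * 26 + "G" + "." * 10,
            "B_6": "." * 9 + "-" * 27 + "." * 32,
            "B_7": "." * 30 + "-" + "." * 11 + "-" * 26,
        },
        notes="B_6 carries an internal deletion, B_7 a 3' terminal deletion; "
        "the consensus row has one insertion column (occupied only by B_2).",
    ),
    "Alaudala heinei": SpeciesRepeatRecord(
        species="Alaudala heinei",
        reference_name="C_CS",
        reference="CACGTATAAGTAAAGAGAGGACACCTCACGTCTCCTTACTATTATACGTGTA",
        haplotype_masks={
            "C_1": "." * 52,
            "C_2": "." * 44 + "-" * 8,
        },
    ),
    "Alauda arvensis": SpeciesRepeatRecord(
        species="Alauda arvensis",
        reference_name="D_CS",
        reference="AAAGAAATCAATCCCATTGATTTCATTATATTAGTAT",
        haplotype_masks={
            "D_1": ".......C..G..ATA....C....C.G.....A..C",
            "D_2": "." * 37,
            "D_3": "." * 17 + "-" * 20,
        },
        divergent_initial=("D_1",),
    ),
    "Alauda gulgula": SpeciesRepeatRecord(
        species="Alauda gulgula",
        reference_name="E_CS",
        reference="AAAGAAATCAATCCCATTGATTTCATTATATTAGTAT",
        haplotype_masks={
            "E_1": "." * 37,
            "E_2": "....G........." + "-" * 23,
        },
    ),
    "Alauda razae": SpeciesRepeatRecord(
        species="Alauda razae",
        reference_name="F_CS",
        reference="AAAGAAATCAACCCTATTGACTTCATTATATTAGTAT",
        haplotype_masks={
            "F_1": "..CA..CCA.T...-......................",
            "F_2": "." * 37,
            "F_3": "." * 16 + "-" * 21,
        },
        divergent_initial=("F_1",),
    ),
    "Calandrella cinerea": SpeciesRepeatRecord(
        species="Calandrella cinerea",
        reference_name="G_CS",
        reference="AAAGAATAAGAGACCACTCTTACTCTTTATCATACACATAACTGTATATATATATATGTAT",
        haplotype_masks={
            "G_1": ".......---------.A..CTTA..C.T.ATC.T...C.TAAC.G..........TA...",
            "G_2": "." * 61,
            "G_3": "." * 44 + "----" + "." * 13,
            # truncated final unit: 26 retained columns, rest deleted
            "G_4": "." * 26,
        },
        divergent_initial=("G_1",),
    ),
    "Melanocorypha mongolica": SpeciesRepeatRecord(
        species="Melanocorypha mongolica",
        reference_name="H_1",
        reference="TCTTTACTTATTACATGTATATAAAGTAGAGA",
        haplotype_masks={
            "H_1": "." * 32,
            "H_2": "......TC.....T..ACG..C...AC.....",
            "H_3": "." * 22 + "-" * 10,
        },
        notes="The array tiles as a fused two-subunit period: H_1 and H_2 "
        "alternate, forming a combined 64-nt repeat unit H_1+H_2.",
    ),
}

# The fused repeat unit observed in M. mongolica (H_1 followed by H_2).
MONGOLICA_COMBINED_UNIT = (
    "TCTTTACTTATTACATGTATATAAAGTAGAGATCTTTATCTATTATATACGTACAAAACAGAGA"
)


def decoded_haplotypes(species: str) -> dict[str, str]:
    """Concrete haplotype sequences for one species, keyed by name."""
    return REPEAT_UNIT_TABLE[species].haplotypes()
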