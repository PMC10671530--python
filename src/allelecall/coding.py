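"""Codon bookkeeping: mapping alignment columns to reading-frame positions.

A :class:`CodingFrame` is built from a region map and one reference
haplotype: the concatenated exon columns are degapped on the reference and
read as consecutive codons under the standard genetic code.  Substitutions in
other sequences are then classified by swapping the altered base into the
reference codon and comparing translations.
"""

from __future__ import annotations

from Bio.Seq import Seq

from allelecall.errors import PreconditionError

STOP = "*"


def translate_codon(codon: str) -> str:
    """One-letter amino acid (or ``*``) for a codon; ``X`` if ambiguous."""
    if len(codon) != 3:
        raise PreconditionError(f"not a codon: {codon!r}")
    if set(codon) - set("ACGT"):
        return "X"
    return str(Seq(codon).translate())


class CodingFrame:
    """Reading frame of one locus anchored on a reference haplotype.

    Parameters
    ----------
    region_map : GeneRegionMap
        Supplies the exon columns.
    reference : AlignedHaplotype
        Sequence whose degapped exon concatenation defines codon positions.
        Its degapped coding length must be a multiple of 3.
    """

    def __init__(self, region_map, reference):
        self.reference = reference
        cols = region_map.exon_columns()
        self.col_to_pos: dict[int, int] = {}
        cds = []
        for c in cols:
            base = reference.sequence[c]
            if base != "-":
                self.col_to_pos[c] = len(cds)
                cds.append(base)
        self.cds = "".join(cds)
        if len(self.cds) % 3 != 0:
            raise PreconditionError(
                f"degapped coding length {len(self.cds)} of {reference.id} "
                "is not a multiple of 3"
            )

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def codon_at(self, column: int) -> tuple[str, int]:
        """(reference codon, within-codon position 0..2) covering ``column``."""
        pos = self.col_to_pos.get(column)
        if pos is None:
            raise PreconditionError(
                f"column {column} has no reference coding position"
            )
        i = pos // 3
        return self.cds[3 * i : 3 * i + 3], pos % 3

    def classify_substitution(self, column: int, alt_base: str) -> str:
        """Effect of substituting ``alt_base`` at ``column``: synonymous,
        nonsynonymous, or nonsense (premature stop)."""
        codon, offset = self.codon_at(column)
        mutant = codon[:offset] + alt_base + codon[offset + 1 :]
        ref_aa = translate_codon(codon)
        alt_aa = translate_codon(mutant)
        if alt_aa == ref_aa:
            return "synonymous"
        if alt_aa == STOP:
            return "nonsense"
        return "nonsynonymous"
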