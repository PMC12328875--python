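"""Mutant/wildtype peptide enumeration around somatic missense variants.

Every window of length 8-14 that contains the mutated residue is a candidate
MHC-I ligand; each window yields a mutant peptide and its matched wildtype
counterpart (differing at exactly the mutated position).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List

from .io import SomaticVariant

DEFAULT_LENGTHS = range(8, 15)


class ReferenceMismatchError(ValueError):
    """The variant's stated reference residue disagrees with the proteome."""


@dataclass(frozen=True)
class PeptidePair:
    """A matched mutant/wildtype k-mer spanning a missense variant."""

    variant: SomaticVariant
    length: int
    offset: int  # 1-based position of the mutated residue within the window
    mutant_seq: str
    wildtype_seq: str

    def __post_init__(self) -> None:
        k = self.length
        if not 8 <= k <= 14:
            raise ValueError(f"peptide length {k} outside 8-14")
        if len(self.mutant_seq) != k or len(self.wildtype_seq) != k:
            raise ValueError("sequence length disagrees with declared length")
        diffs = [i for i in range(k) if self.mutant_seq[i] != self.wildtype_seq[i]]
        if diffs != [self.offset - 1]:
            raise ValueError(
                "mutant and wildtype must differ exactly at the stated offset"
            )


def window_count(protein_length: int, position: int, k: int) -> int:
    """Number of k-windows of a length-L protein containing 1-based position p."""
    lo = max(1, position - k + 1)
    hi = min(position, protein_length - k + 1)
    return max(0, hi - lo + 1)


def enumerate_peptide_pairs(
    variant: SomaticVariant,
    proteome: Dict[str, str],
    lengths: Iterable[int] = DEFAULT_LENGTHS,
) -> List[PeptidePair]:
    """All mutant/wildtype windows of each length covering the variant.

    Windows are clipped to protein bounds; proteins shorter than a given
    length contribute no windows at that length (no padding).  Raises
    :class:`ReferenceMismatchError` if the proteome residue at the variant
    position is not the variant's reference amino acid.
    """
    if variant.gene not in proteome:
        raise KeyError(f"gene {variant.gene!r} absent from proteome")
    seq = proteome[variant.gene]
    L = len(seq)
    p = variant.protein_position
    if p > L:
        raise ValueError(
            f"{variant.gene}: position {p} beyond protein length {L}"
        )
    if seq[p - 1] != variant.ref_aa:
        raise ReferenceMismatchError(
            f"{variant.gene} position {p}: proteome has {seq[p - 1]!r}, "
            f"variant states {variant.ref_aa!r}"
        )
    mutated = seq[: p - 1] + variant.alt_aa + seq[p:]
    pairs: List[PeptidePair] = []
    for k in lengths:
        lo = max(1, p - k + 1)
        hi = min(p, L - k + 1)
        for start in range(lo, hi + 1):
            pairs.append(
                PeptidePair(
                    variant=variant,
                    length=k,
                    offset=p - start + 1,
                    mutant_seq=mutated[start - 1 : start - 1 + k],
                    wildtype_seq=seq[start - 1 : start - 1 + k],
                )
            )
    return pairs
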