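"""Per-peptide physicochemical properties.

Three quantities describe a peptide in this package:

* **PCL** -- peptide chain length, the residue count.
* **PMW** -- peptide molecular weight in Da, the sum of residue masses plus
  one water (the termini).
* **Pz** -- net charge at pH 7 in elementary charge units, computed from a
  fixed per-residue contribution table: Lys +1, Arg +1, His +0.1, Asp -1,
  Glu -1, Cys -0.07.  All other residues and both termini contribute zero
  (at neutral pH the terminal amine and carboxylate approximately cancel).

The charge model is deliberately not pH-parameterized: it is the fixed
pH-7 side-chain contribution model, not a Henderson--Hasselbalch titration.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AMINO_ACIDS",
    "MONOISOTOPIC_MASS",
    "AVERAGE_MASS",
    "WATER_MONOISOTOPIC",
    "WATER_AVERAGE",
    "CHARGE_PH7",
    "PropertyVector",
    "validate_sequence",
    "compute_pcl",
    "compute_pmw",
    "compute_pz",
    "compute_properties",
]

#: Monoisotopic residue masses (Da), IUPAC standard values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Average (isotope-abundance weighted) residue masses (Da).
AVERAGE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MONOISOTOPIC = 18.010565
WATER_AVERAGE = 18.01528

#: Side-chain charge contributions at pH 7 (elementary charge units).
CHARGE_PH7: dict[str, float] = {
    "K": 1.0, "R": 1.0, "H": 0.1, "D": -1.0, "E": -1.0, "C": -0.07,
}

AMINO_ACIDS: frozenset[str] = frozenset(MONOISOTOPIC_MASS)


@dataclass(frozen=True)
class PropertyVector:
    """PCL / PMW / Pz for one peptide."""

    pcl: int
    pmw: float
    pz: float


def validate_sequence(sequence: str) -> str:
    """Return the sequence if every character is a standard residue code.

    Raises ``ValueError`` naming the first offending character; empty
    sequences are rejected as well.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    for ch in sequence:
        if ch not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {ch!r} in sequence {sequence!r}")
    return sequence


def compute_pcl(sequence: str) -> int:
    """Peptide chain length (residue count)."""
    validate_sequence(sequence)
    return len(sequence)


def compute_pmw(sequence: str, monoisotopic: bool = True) -> float:
    """Peptide molecular weight in Da: residue masses plus one water.

    Monoisotopic masses are the default because upstream intensities come
    from high-resolution MS pipelines that report monoisotopic mass; set
    ``monoisotopic=False`` for average masses.
    """
    validate_sequence(sequence)
    if monoisotopic:
        table, water = MONOISOTOPIC_MASS, WATER_MONOISOTOPIC
    else:
        table, water = AVERAGE_MASS, WATER_AVERAGE
    return sum(table[ch] for ch in sequence) + water


def compute_pz(sequence: str) -> float:
    """Net charge at pH 7 from the fixed side-chain contribution table."""
    validate_sequence(sequence)
    return sum(CHARGE_PH7.get(ch, 0.0) for ch in sequence)


def compute_properties(sequence: str, monoisotopic: bool = True) -> PropertyVector:
    validate_sequence(sequence)
    return PropertyVector(
        pcl=len(sequence),
        pmw=compute_pmw(sequence, monoisotopic=monoisotopic),
        pz=compute_pz(sequence),
    )
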