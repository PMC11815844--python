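"""Sequence-level peptide descriptors: Kyte–Doolittle hydropathy (GRAVY) and
formal net charge, plus the bundled registry of the cell-penetrating peptides
used in the translocation experiment matrix.

The charge model is deliberately minimal: integer formal charges at neutral
pH (+1 for Lys/Arg, -1 for Asp/Glu, His neutral) with zwitterionic termini
whose +1/-1 cancel. pKa-based fractional charges are out of scope — the
integer model is the one that reproduces the declared charges of the study
peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

__all__ = [
    "KYTE_DOOLITTLE",
    "PeptideRecord",
    "gravy",
    "net_charge",
    "registry",
    "read_fasta",
]

#: Kyte & Doolittle hydropathy scale (dimensionless, per residue).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_POSITIVE = frozenset("KR")
_NEGATIVE = frozenset("DE")


def _validate(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty peptide sequence")
    bad = sorted(set(seq) - set(KYTE_DOOLITTLE))
    if bad:
        raise ValueError(f"non-standard residues in sequence: {''.join(bad)}")
    return seq


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value over residues.

    Negative values indicate hydrophilic peptides, positive hydrophobic.
    The full-precision mean is returned; round to 2 decimals for display.
    """
    seq = _validate(sequence)
    return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)


def net_charge(sequence: str, include_termini: bool = True) -> int:
    """Formal net charge (units of e) at neutral pH.

    +1 per Lys/Arg, -1 per Asp/Glu; His counted neutral. With
    ``include_termini`` the zwitterionic N-terminus (+1) and C-terminus (-1)
    are both counted and cancel, so the flag never changes the total for an
    unmodified peptide; it exists to make the convention explicit.
    """
    seq = _validate(sequence)
    charge = sum(+1 for aa in seq if aa in _POSITIVE)
    charge -= sum(1 for aa in seq if aa in _NEGATIVE)
    if include_termini:
        charge += 1 - 1  # N-terminal NH3+ and C-terminal COO- cancel
    return charge


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide of the experiment matrix with declared and derived fields."""

    name: str
    sequence: str
    declared_type: str
    declared_length: int
    declared_charge: int
    declared_gravy: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def net_charge(self) -> int:
        return net_charge(self.sequence)

    @property
    def gravy(self) -> float:
        return gravy(self.sequence)

    def consistency_flags(self) -> tuple[str, ...]:
        """Discrepancies between declared and recomputed descriptors."""
        flags = list(self.flags)
        if self.length != self.declared_length:
            flags.append(
                f"declared length {self.declared_length} != sequence length {self.length}"
            )
        if self.net_charge != self.declared_charge:
            flags.append(
                f"declared charge {self.declared_charge:+d} != computed {self.net_charge:+d}"
            )
        if round(self.gravy, 2) != round(self.declared_gravy, 2):
            flags.append(
                f"declared GRAVY {self.declared_gravy} != computed {self.gravy:.2f}"
            )
        return tuple(flags)


_REGISTRY: tuple[PeptideRecord, ...] = (
    PeptideRecord("Arg9", "RRRRRRRRR", "cationic", 9, +9, -4.5),
    PeptideRecord("MAP", "KLALKLALKALKAALKLA", "amphipathic", 18, +5, 0.99),
    PeptideRecord("TP10", "AGYLLGKINLKALAALAKKIL", "amphipathic", 21, +4, 0.93),
    PeptideRecord("TP2", "PLIYLRLLRGQWC", "hydrophobic", 13, +2, 0.42),
    # K-FGF is declared with length 17 but the published sequence has 16
    # residues; the printed sequence is stored verbatim and the mismatch is
    # surfaced via consistency_flags() rather than silently "fixed".
    PeptideRecord("K-FGF", "AAVALLPAVLLALLAP", "hydrophobic", 17, 0, 2.42),
)


def registry() -> list[PeptideRecord]:
    """Bundled records for the five study peptides (Arg9, MAP, TP10, TP2, K-FGF)."""
    return list(_REGISTRY)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(name, sequence)`` pairs from a FASTA file of peptides.

    Sequences are validated against the 20-residue alphabet.
    """
    name: str | None = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    yield name, _validate("".join(chunks))
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first FASTA header")
                chunks.append(line)
    if name is not None:
        yield name, _validate("".join(chunks))
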