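"""Monoisotopic mass bookkeeping for peptides and modifications.

Residue masses come from :mod:`pyteomics.mass`; this module adds the small
set of post-translational and diagenetic modifications relevant to ancient
milk proteins, and a peptide-mass routine that understands them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

from pyteomics import mass as _pmass

#: Monoisotopic residue masses (Da), standard 20-letter alphabet.
RESIDUE_MASS: dict[str, float] = dict(_pmass.std_aa_mass)

WATER: float = _pmass.calculate_mass(formula="H2O")
PROTON: float = 1.00727646688  # mass of H+ (Da)


@dataclass(frozen=True)
class ModificationSpec:
    """A mass modification applied to residues or a terminus.

    ``targets`` is a string of residue letters, or one of the designators
    ``"peptide-nterm-Q"`` (pyroglutamate) / ``"protein-nterm"`` (acetyl).
    ``mode`` is ``"fixed"`` (applied to every matching site) or
    ``"variable"`` (optional per site).
    """

    name: str
    targets: str
    delta_mass: float
    mode: str = "variable"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "variable"):
            raise ValueError(f"mode must be fixed|variable, got {self.mode!r}")
        if not (self.delta_mass == self.delta_mass and abs(self.delta_mass) < 1e6):
            raise ValueError("delta_mass must be finite")


# Fixed alkylation plus the degradation-aware variable set used for
# ancient-protein searches: deamidation of N/Q, N-terminal Gln cyclisation,
# Met oxidation, Pro hydroxylation, and protein N-terminal acetylation.
CARBAMIDOMETHYL = ModificationSpec("carbamidomethyl", "C", 57.02146, "fixed")
DEAMIDATION = ModificationSpec("deamidated", "NQ", 0.98402, "variable")
PYROGLUTAMATE = ModificationSpec("pyroglu", "peptide-nterm-Q", -17.02655, "variable")
OXIDATION_M = ModificationSpec("oxidation", "M", 15.99491, "variable")
HYDROXYLATION_P = ModificationSpec("hydroxyproline", "P", 15.99491, "variable")
ACETYL_NTERM = ModificationSpec("acetyl", "protein-nterm", 42.01057, "variable")

DEFAULT_MODIFICATIONS: tuple[ModificationSpec, ...] = (
    CARBAMIDOMETHYL,
    DEAMIDATION,
    PYROGLUTAMATE,
    OXIDATION_M,
    HYDROXYLATION_P,
    ACETYL_NTERM,
)


def peptide_mass(
    sequence: str,
    mods: Sequence[Tuple[int, ModificationSpec]] = (),
    x_mass: float | None = None,
) -> float:
    """Monoisotopic neutral mass of ``sequence`` with ``mods`` applied.

    ``mods`` is a list of ``(position, ModificationSpec)`` with 0-based
    positions into the peptide. ``X`` residues raise unless ``x_mass`` gives
    an explicit fallback mass (e.g. an average residue mass).
    """
    total = WATER
    for i, aa in enumerate(sequence):
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            if aa == "X" and x_mass is not None:
                total += x_mass
            else:
                raise ValueError(
                    f"unknown residue {aa!r} at position {i} in {sequence!r}"
                ) from None
    n = len(sequence)
    for pos, spec in mods:
        if not (0 <= pos < n):
            raise ValueError(f"modification position {pos} outside peptide of length {n}")
        total += spec.delta_mass
    return total


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a peptide ion of the given neutral mass and positive charge."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON) / charge


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def format_mods(mods: Iterable[Tuple[int, ModificationSpec]]) -> str:
    """Render a modification list as ``name@pos;...`` (stable order)."""
    return ";".join(f"{spec.name}@{pos}" for pos, spec in sorted(mods, key=lambda m: (m[0], m[1].name)))
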