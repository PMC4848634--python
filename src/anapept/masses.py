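"""Monoisotopic mass arithmetic for peptide residues and diagnostic ions.

Anabaenopeptin screening rests on a handful of low-mass diagnostic ions:
the Lys-derived marker at nominal m/z 84 (the lysine immonium ion after
ammonia loss), residue immonium ions such as Phe at m/z 120, and the
arginine-related ions at m/z 175 ([Arg + 2H]+, i.e. protonated free
arginine) and m/z 201. This module provides the residue mass table and the
arithmetic every other stage consumes.

All masses are monoisotopic (singly protonated positive-mode MS/MS
context); average-mass chemistry is deliberately not offered. Nominal
(integer) m/z values are obtained by rounding half away from zero, which
matches the reporting precision of fraction screening tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from pyteomics import mass as _pmass

__all__ = [
    "PROTON",
    "CO",
    "NH3",
    "H2O",
    "H2",
    "Residue",
    "ResidueTable",
    "UnknownResidueError",
    "default_table",
    "residue_mass",
    "immonium_mz",
    "lys_marker_mz",
    "arg_diagnostic_mzs",
    "protonate",
    "nominal",
]

# ---------------------------------------------------------------------------
# Constants (Da, monoisotopic)

PROTON: float = 1.00727646688
CO: float = _pmass.calculate_mass(formula="CO")
NH3: float = _pmass.calculate_mass(formula="NH3")
H2O: float = _pmass.calculate_mass(formula="H2O")
H2: float = _pmass.calculate_mass(formula="H2")

#: Empirical m/z of the carbamoyl-arginine-related diagnostic ion. The
#: bracket composition reported for this ion does not resolve to a single
#: elemental formula, so the observed value is stored rather than derived.
ARG_CARBAMOYL_MZ: float = 201.1


class UnknownResidueError(KeyError):
    """Raised when a residue code is absent from the residue table."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"unknown residue code: {self.code!r}"


@dataclass(frozen=True)
class Residue:
    """One residue entry: an amino acid (or modified residue) minus water.

    ``mono_mass`` is validated against the elemental ``formula`` on load.
    """

    code: str
    formula: str
    mono_mass: float


class ResidueTable:
    """Lookup table of residue monoisotopic masses, loadable from TSV."""

    def __init__(self, residues: list[Residue]):
        seen: dict[str, Residue] = {}
        for r in residues:
            if r.code in seen:
                raise ValueError(f"duplicate residue code: {r.code!r}")
            if r.mono_mass <= 0:
                raise ValueError(f"non-positive mass for {r.code!r}")
            formula_mass = _pmass.calculate_mass(formula=r.formula)
            if abs(formula_mass - r.mono_mass) > 1e-4:
                raise ValueError(
                    f"mass/formula mismatch for {r.code!r}: table says "
                    f"{r.mono_mass}, formula {r.formula} sums to {formula_mass:.5f}"
                )
            seen[r.code] = r
        self._residues = seen

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueTable":
        residues = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["code", "formula", "mono_mass"]:
                raise ValueError(f"unexpected residue table header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                code, formula, mono = line.rstrip("\n").split("\t")[:3]
                residues.append(Residue(code, formula, float(mono)))
        return cls(residues)

    def __contains__(self, code: str) -> bool:
        return code in self._residues

    def __getitem__(self, code: str) -> Residue:
        try:
            return self._residues[code]
        except KeyError:
            raise UnknownResidueError(code) from None

    def codes(self) -> list[str]:
        return list(self._residues)

    def mass(self, code: str) -> float:
        return self[code].mono_mass


_DEFAULT_TABLE: ResidueTable | None = None


def default_table() -> ResidueTable:
    """The built-in residue table (20 standard residues plus Hty, MeAla)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = resources.files("anapept").joinpath("data/residues.tsv")
        with resources.as_file(ref) as path:
            _DEFAULT_TABLE = ResidueTable.from_tsv(path)
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# Operations


def residue_mass(code: str, table: ResidueTable | None = None) -> float:
    """Monoisotopic residue mass (amino acid minus water), in Da."""
    table = table or default_table()
    return table.mass(code)


def immonium_mz(code: str, table: ResidueTable | None = None) -> float:
    """m/z of the singly charged immonium ion of a residue.

    Immonium ions (H2N+=CHR) sit at residue mass − CO + proton; they are
    the workhorse low-mass diagnostics of peptide MS/MS.
    """
    return residue_mass(code, table) - CO + PROTON


def lys_marker_mz(table: ResidueTable | None = None) -> float:
    """m/z of the Lys-specific gate ion at nominal m/z 84.

    The true Lys immonium ion lies at 101.107; the commonly reported Lys
    marker is its ammonia-loss product, which is what reproduces the
    printed nominal value 84.
    """
    return immonium_mz("K", table) - NH3


def arg_diagnostic_mzs(table: ResidueTable | None = None) -> tuple[float, float]:
    """The two arginine-related diagnostic ions: (175.119, 201.1).

    The first is protonated free arginine ([Arg + 2H]+ in screening
    shorthand); the second is the stored empirical carbamoyl-Arg value.
    """
    return (residue_mass("R", table) + H2O + PROTON, ARG_CARBAMOYL_MZ)


def protonate(neutral_mass: float) -> float:
    """m/z of the singly protonated species [M + H]+ of a neutral mass."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return neutral_mass + PROTON


def nominal(mz: float) -> int:
    """Nearest-integer m/z, rounding half away from zero."""
    if mz < 0:
        raise ValueError(f"m/z must be non-negative, got {mz}")
    return int(math.floor(mz + 0.5))
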