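"""Anabaenopeptin scaffold model, compound library and fragment prediction.

Anabaenopeptins (APs) are cyclic cyanobacterial hexapeptides: a ring of
five amino acid residues with a conserved Lys in the first position, plus
one exocyclic residue joined to the Lys side chain through an ureido
(-NH-CO-NH-) bond. Cyanopeptolins (CYPs) are cyclic depsipeptides carrying
a conserved 3-amino-6-hydroxy-2-piperidone (Ahp) residue; here they are
handled at the detection level only, via configurable diagnostic m/z
flags, because their depsipeptide assembly is out of scope.

Mass assembly rule
------------------
The neutral AP mass is

    sum(ring residue masses) + free exocyclic amino acid + CO − H2

i.e. the cyclic pentapeptide ring (no terminal water) joined to the free
exocyclic amino acid through the ureido carbonyl with loss of two
hydrogens. Collision-induced dissociation typically ejects the exocyclic
residue: for exocyclic Arg as [Arg + CO] (Δ 200.091 Da), leaving the bare
protonated ring; for exocyclic Tyr as free Tyr (Δ 181.074 Da), leaving the
ring still carrying the ureido carbonyl (an isocyanate-type ion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

from . import masses
from .masses import CO, H2, H2O, PROTON, ResidueTable, default_table, nominal, protonate

__all__ = [
    "APCompound",
    "PredictedSpectrum",
    "CYPTemplate",
    "DEFAULT_CYP_DIAGNOSTIC_MZS",
    "ap_neutral_mass",
    "ring_fragment_mz",
    "exocyclic_loss_mass",
    "loss_fragment_mz",
    "predict_fragments",
    "library_default",
    "load_library_tsv",
    "novel_name",
]

RING_LENGTH = 5

#: Residue codes treated as tyrosine for the exocyclic-loss rule.
_TYR_CODES = frozenset({"Y", "Tyr"})


@dataclass(frozen=True)
class APCompound:
    """A five-residue ring (first = Lys) plus an ureido-linked exocyclic residue."""

    name: str
    ring: tuple[str, ...]
    exocyclic: str
    source: Literal["literature", "novel"] = "literature"

    def __post_init__(self):
        object.__setattr__(self, "ring", tuple(self.ring))

    def validate(self, table: ResidueTable | None = None) -> None:
        table = table or default_table()
        if len(self.ring) != RING_LENGTH:
            raise ValueError(
                f"{self.name}: ring must have {RING_LENGTH} residues, got {len(self.ring)}"
            )
        if self.ring[0] != "K":
            raise ValueError(f"{self.name}: ring must start with the conserved Lys (K)")
        for code in (*self.ring, self.exocyclic):
            table[code]  # raises UnknownResidueError

    def contains_arg(self) -> bool:
        return "R" in self.ring or self.exocyclic == "R"


@dataclass(frozen=True)
class PredictedSpectrum:
    """In-silico fragment list for one compound, sorted by m/z.

    Labels: precursor, ring_ion, immonium, lys_marker, arg_diag, b_ion.
    Exactly one precursor and one ring_ion entry are present; the ring_ion
    is the charged product of the exocyclic loss.
    """

    compound: str
    entries: tuple[tuple[float, str], ...]

    def __post_init__(self):
        entries = tuple(sorted(self.entries))
        object.__setattr__(self, "entries", entries)
        if any(mz <= 0 for mz, _ in entries):
            raise ValueError("predicted m/z values must be positive")
        for required in ("precursor", "ring_ion"):
            if sum(1 for _, lab in entries if lab == required) != 1:
                raise ValueError(f"expected exactly one {required} entry")

    def mzs(self, label: str | None = None) -> list[float]:
        return [mz for mz, lab in self.entries if label is None or lab == label]

    @property
    def precursor_mz(self) -> float:
        return self.mzs("precursor")[0]


#: Ahp-related diagnostic ions commonly used to flag cyanopeptolin-like
#: spectra in the literature (protonated Ahp-adjacent fragment ions and
#: their water losses). Editable configuration, not a structural claim.
DEFAULT_CYP_DIAGNOSTIC_MZS: tuple[float, ...] = (215.1, 150.1, 134.1)


@dataclass(frozen=True)
class CYPTemplate:
    """Diagnostic m/z flags for cyanopeptolin-like spectra (detection only)."""

    name: str = "CYP-like"
    diagnostic_mzs: tuple[float, ...] = DEFAULT_CYP_DIAGNOSTIC_MZS

    def __post_init__(self):
        if not self.diagnostic_mzs:
            raise ValueError("CYP template requires at least one diagnostic m/z")


# ---------------------------------------------------------------------------
# Mass assembly


def ap_neutral_mass(c: APCompound, table: ResidueTable | None = None) -> float:
    """Neutral monoisotopic mass of an anabaenopeptin scaffold."""
    table = table or default_table()
    c.validate(table)
    ring = sum(table.mass(code) for code in c.ring)
    exo_free = table.mass(c.exocyclic) + H2O
    return ring + exo_free + CO - H2


def ring_fragment_mz(c: APCompound, table: ResidueTable | None = None) -> float:
    """m/z of the bare protonated cyclic pentapeptide ring."""
    table = table or default_table()
    c.validate(table)
    return sum(table.mass(code) for code in c.ring) + PROTON


def exocyclic_loss_mass(c: APCompound, table: ResidueTable | None = None) -> float:
    """Neutral mass ejected with the exocyclic residue under CID.

    Exocyclic Tyr leaves as the free amino acid (Δ 181.074, ring keeps the
    ureido CO); every other exocyclic residue follows the Arg-style rule,
    free amino acid + CO − H2 (Δ 200.091 for Arg), leaving the bare ring.
    """
    table = table or default_table()
    c.validate(table)
    exo_free = table.mass(c.exocyclic) + H2O
    if c.exocyclic in _TYR_CODES:
        return exo_free
    return exo_free + CO - H2


def loss_fragment_mz(c: APCompound, table: ResidueTable | None = None) -> float:
    """m/z of the charged fragment left after the exocyclic loss.

    Equals ``ring_fragment_mz`` for Arg-style losses and ring + CO + proton
    for Tyr; by construction [M+H]+ = loss_fragment + exocyclic_loss.
    """
    return protonate(ap_neutral_mass(c, table)) - exocyclic_loss_mass(c, table)


def predict_fragments(
    c: APCompound, table: ResidueTable | None = None
) -> PredictedSpectrum:
    """Deterministic in-silico fragment list for library matching.

    Includes: the [M+H]+ precursor; the exocyclic-loss ring ion; the Lys
    marker (84.081); the immonium ion of every distinct residue (ring and
    exocyclic); the two Arg diagnostics iff Arg occurs anywhere; and the
    b-ions of the canonical ring linearization (ring opened at the Lys
    α-amide, cumulative prefix sums + proton). Only one ring opening is
    generated to keep predicted spectra small and reproducible.
    """
    table = table or default_table()
    c.validate(table)
    entries: list[tuple[float, str]] = []
    entries.append((protonate(ap_neutral_mass(c, table)), "precursor"))
    entries.append((loss_fragment_mz(c, table), "ring_ion"))
    entries.append((masses.lys_marker_mz(table), "lys_marker"))
    seen: set[float] = set()
    for code in (*c.ring, c.exocyclic):
        mz = masses.immonium_mz(code, table)
        key = round(mz, 6)
        if key not in seen:
            seen.add(key)
            entries.append((mz, "immonium"))
    if c.contains_arg():
        for mz in masses.arg_diagnostic_mzs(table):
            entries.append((mz, "arg_diag"))
    # b2..b4 of the Lys-opened linear sequence; b1 is the Lys acylium
    # (uninformative) and b5 coincides with the full ring ion.
    prefix = 0.0
    for i, code in enumerate(c.ring[:4], start=1):
        prefix += table.mass(code)
        if i >= 2:
            entries.append((prefix + PROTON, "b_ion"))
    return PredictedSpectrum(compound=c.name, entries=tuple(entries))


# ---------------------------------------------------------------------------
# Library


def library_default() -> list[APCompound]:
    """The built-in anabaenopeptin library (AP A, AP B, AP F, OSC Y)."""
    ref = resources.files("anapept").joinpath("data/library.tsv")
    with resources.as_file(ref) as path:
        return load_library_tsv(path)


def load_library_tsv(path: str | Path) -> list[APCompound]:
    """Load a compound library TSV (name, comma-joined ring, exocyclic, source)."""
    table = default_table()
    compounds = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["name", "ring", "exocyclic", "source"]:
            raise ValueError(f"unexpected library header: {header}")
        for line in fh:
            if not line.strip():
                continue
            name, ring, exo, source = line.rstrip("\n").split("\t")[:4]
            c = APCompound(name, tuple(ring.split(",")), exo, source)  # type: ignore[arg-type]
            c.validate(table)
            compounds.append(c)
    return compounds


def novel_name(precursor_mz: float) -> str:
    """Name a novel analog by its nominal neutral molecular mass.

    A gated spectrum that matches no library compound is named "AP <M>"
    where M is the nominal neutral mass (precursor minus a proton, rounded).
    """
    if precursor_mz <= PROTON:
        raise ValueError(f"precursor m/z {precursor_mz} not above proton mass")
    return f"AP {nominal(precursor_mz - PROTON)}"
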