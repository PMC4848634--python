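"""Rule-based anabaenopeptin screening of MS/MS spectra.

The decision procedure mirrors how cyclic-peptide screeners read product-ion
spectra of SPE fractions:

1. **Gate** — the conserved Lys marker ion at m/z 84.081 must be present;
   no spectrum lacking it is ever called an anabaenopeptin.
2. **Evidence** — low-mass diagnostics are collected: the Lys marker, the
   Phe immonium ion (120.081) and the two Arg-related ions (175.119, 201.1).
3. **Exocyclic call** — the exocyclic residue is inferred from the neutral
   loss off the pseudomolecular ion: Δ 200.091 ([Arg + CO]) calls Arg,
   Δ 181.074 (free Tyr) calls Tyr.
4. **Library match** — the spectrum is scored against in-silico fragment
   predictions of known compounds; the best match above a threshold is
   reported under the library name.
5. **Novel analogs** — a gated spectrum with a determined exocyclic loss
   but no library match is named "AP <nominal neutral mass>".
6. **CYP flag** — remaining spectra carrying configured Ahp-related
   diagnostic ions are flagged cyanopeptolin-like; everything else is none.

Reports are Table-style rows (fraction, nominal m/z, proposed name); spectra
whose precursor coincides with a bare library ring ion are reported as
"AP fragment" rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from . import masses, scaffold
from .masses import nominal, protonate
from .scaffold import APCompound, predict_fragments
from .spectra import Spectrum, Tolerance, match_peak

__all__ = [
    "AP_FRAGMENT_LABEL",
    "ScreenConfig",
    "Assignment",
    "ScreenReport",
    "gate_lys",
    "collect_evidence",
    "infer_exocyclic",
    "score_library_match",
    "screen",
    "screen_fractions",
]

AP_FRAGMENT_LABEL = "AP fragment"

Verdict = Literal["named_ap", "novel_ap", "cyp_like", "none"]
ExocyclicCall = Literal["Arg", "Tyr", "undetermined"]


@dataclass(frozen=True)
class ScreenConfig:
    """Screening parameters.

    match_threshold is the minimum fraction of predicted library fragments
    (precursor excluded) that must be matched for a named call; 0.6 gives
    perfect separation on noiseless synthetic spectra while tolerating
    moderate fragment dropout.
    """

    tolerance: Tolerance = Tolerance(0.5, "da")
    match_threshold: float = 0.6
    cyp_diagnostic_mzs: tuple[float, ...] = scaffold.DEFAULT_CYP_DIAGNOSTIC_MZS
    novel_rule: bool = True

    def __post_init__(self):
        if not 0 < self.match_threshold <= 1:
            raise ValueError("match_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class Assignment:
    """Screening verdict for one spectrum, with the evidence behind it."""

    spectrum_id: str
    fraction: str
    precursor_nominal: int
    verdict: Verdict
    proposed_name: str = ""
    exocyclic: ExocyclicCall = "undetermined"
    evidence: frozenset[str] = frozenset()
    score: float = 0.0


def gate_lys(s: Spectrum, cfg: ScreenConfig) -> bool:
    """True iff the Lys marker ion (m/z 84.081) is present within tolerance."""
    return match_peak(s, masses.lys_marker_mz(), cfg.tolerance) is not None


_DIAGNOSTICS: tuple[tuple[str, str], ...] = (
    # (label, how to obtain the target m/z)
    ("lys_marker", "lys"),
    ("phe_immonium", "phe"),
    ("arg_175", "arg0"),
    ("arg_201", "arg1"),
)


def _diagnostic_mz(kind: str) -> float:
    if kind == "lys":
        return masses.lys_marker_mz()
    if kind == "phe":
        return masses.immonium_mz("F")
    arg = masses.arg_diagnostic_mzs()
    return arg[0] if kind == "arg0" else arg[1]


def collect_evidence(s: Spectrum, cfg: ScreenConfig) -> frozenset[str]:
    """Labels of the matched low-mass diagnostic ions."""
    found = set()
    for label, kind in _DIAGNOSTICS:
        if match_peak(s, _diagnostic_mz(kind), cfg.tolerance) is not None:
            found.add(label)
    return frozenset(found)


def _loss_targets() -> tuple[float, float]:
    """(Arg-style loss, Tyr loss) neutral masses in Da."""
    arg_loss = masses.residue_mass("R") + masses.H2O + masses.CO - masses.H2
    tyr_loss = masses.residue_mass("Y") + masses.H2O
    return arg_loss, tyr_loss


def infer_exocyclic(s: Spectrum, cfg: ScreenConfig) -> ExocyclicCall:
    """Call the exocyclic residue from the neutral loss off the precursor.

    If both loss peaks are present the more intense one wins.
    """
    arg_loss, tyr_loss = _loss_targets()
    arg_hit = match_peak(s, s.precursor_mz - arg_loss, cfg.tolerance)
    tyr_hit = match_peak(s, s.precursor_mz - tyr_loss, cfg.tolerance)
    if arg_hit and tyr_hit:
        return "Arg" if arg_hit[1] >= tyr_hit[1] else "Tyr"
    if arg_hit:
        return "Arg"
    if tyr_hit:
        return "Tyr"
    return "undetermined"


def score_library_match(s: Spectrum, c: APCompound, cfg: ScreenConfig) -> float:
    """Fraction of predicted fragments of ``c`` matched in ``s``.

    The precursor must agree within tolerance, otherwise the score is 0
    without evaluating fragments; the precursor entry itself is excluded
    from the fraction.
    """
    predicted = predict_fragments(c)
    if abs(s.precursor_mz - predicted.precursor_mz) > cfg.tolerance.window(
        predicted.precursor_mz
    ):
        return 0.0
    fragments = [mz for mz, label in predicted.entries if label != "precursor"]
    if not fragments:
        return 0.0
    matched = sum(1 for mz in fragments if match_peak(s, mz, cfg.tolerance))
    return matched / len(fragments)


def screen(
    s: Spectrum, library: Sequence[APCompound], cfg: ScreenConfig | None = None
) -> Assignment:
    """Run the full decision procedure on one spectrum."""
    cfg = cfg or ScreenConfig()
    evidence = collect_evidence(s, cfg)
    prec_nom = nominal(s.precursor_mz)
    gated = "lys_marker" in evidence

    if gated:
        scored: list[tuple[float, float, str, APCompound]] = []
        for c in library:
            score = score_library_match(s, c, cfg)
            delta = abs(s.precursor_mz - protonate(scaffold.ap_neutral_mass(c)))
            scored.append((score, delta, c.name, c))
        # best score; ties by smaller precursor error, then name
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        exo_call = infer_exocyclic(s, cfg)
        if scored and scored[0][0] >= cfg.match_threshold:
            best = scored[0]
            return Assignment(
                spectrum_id=s.id,
                fraction=s.fraction,
                precursor_nominal=prec_nom,
                verdict="named_ap",
                proposed_name=best[3].name,
                exocyclic=exo_call,
                evidence=evidence,
                score=best[0],
            )
        if cfg.novel_rule and exo_call != "undetermined":
            return Assignment(
                spectrum_id=s.id,
                fraction=s.fraction,
                precursor_nominal=prec_nom,
                verdict="novel_ap",
                proposed_name=scaffold.novel_name(s.precursor_mz),
                exocyclic=exo_call,
                evidence=evidence,
                score=scored[0][0] if scored else 0.0,
            )

    for mz in cfg.cyp_diagnostic_mzs:
        if match_peak(s, mz, cfg.tolerance) is not None:
            return Assignment(
                spectrum_id=s.id,
                fraction=s.fraction,
                precursor_nominal=prec_nom,
                verdict="cyp_like",
                evidence=evidence,
            )
    return Assignment(
        spectrum_id=s.id,
        fraction=s.fraction,
        precursor_nominal=prec_nom,
        verdict="none",
        evidence=evidence,
    )


@dataclass
class ScreenReport:
    """Fraction-level screening report.

    ``table`` has one deduplicated row per (fraction, nominal m/z, proposed
    name), sorted by fraction then m/z; summary counts cover distinct
    proposed anabaenopeptins (fragment rows excluded) and the fractions in
    which each compound occurs.
    """

    table: pd.DataFrame
    assignments: list[Assignment]
    distinct_aps: list[str]
    fractions_per_compound: dict[str, list[str]]

    @property
    def n_distinct_aps(self) -> int:
        return len(self.distinct_aps)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _fraction_sort_key(label: str) -> tuple[float, str]:
    digits = ""
    for ch in label:
        if ch.isdigit():
            digits += ch
        elif digits:
            break
    return (float(digits) if digits else float("inf"), label)


def screen_fractions(
    spectra: Iterable[Spectrum],
    library: Sequence[APCompound],
    cfg: ScreenConfig | None = None,
) -> ScreenReport:
    """Screen a batch of spectra and build the fraction report."""
    cfg = cfg or ScreenConfig()
    library = list(library)
    ring_mzs = {c.name: scaffold.ring_fragment_mz(c) for c in library}

    assignments: list[Assignment] = []
    rows: list[tuple[str, int, str]] = []
    for s in spectra:
        a = screen(s, library, cfg)
        assignments.append(a)
        name = a.proposed_name
        if a.verdict == "none":
            # bare ring ions of library compounds are reported as fragments
            for ring_mz in ring_mzs.values():
                if abs(s.precursor_mz - ring_mz) <= cfg.tolerance.window(ring_mz):
                    name = AP_FRAGMENT_LABEL
                    break
        if name:
            rows.append((a.fraction, a.precursor_nominal, name))

    unique = sorted(set(rows), key=lambda r: (_fraction_sort_key(r[0]), r[1], r[2]))
    table = pd.DataFrame(unique, columns=["fraction", "mz", "proposed_name"])

    ap_rows = [r for r in unique if r[2] != AP_FRAGMENT_LABEL]
    distinct = sorted({r[2] for r in ap_rows})
    per_compound: dict[str, list[str]] = {}
    for fraction, _, name in ap_rows:
        per_compound.setdefault(name, [])
        if fraction not in per_compound[name]:
            per_compound[name].append(fraction)
    for name in per_compound:
        per_compound[name].sort(key=_fraction_sort_key)

    return ScreenReport(
        table=table,
        assignments=assignments,
        distinct_aps=distinct,
        fractions_per_compound=per_compound,
    )
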