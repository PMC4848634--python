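"""Synthetic MS/MS spectra and inhibition plates for end-to-end testing.

No raw spectra or plate absorbances are distributed with the package, so
every pipeline stage is exercised on synthetic inputs generated here:

* anabaenopeptin spectra built from in-silico fragment predictions with
  m/z jitter, per-fragment dropout and uniform-random noise peaks over the
  50-1000 Da acquisition window;
* decoy spectra of pure noise, constructed to fail the Lys-marker gate;
* a fraction-screening fixture reproducing the published detection layout
  (which compounds appear in which methanol fractions);
* 96-well plates simulated from a known dose-response curve with Gaussian
  absorbance noise, duplicated sample wells, four zero-inhibitor wells and
  two negative controls.

All generators are pure functions of (parameters, seed): identical inputs
give identical outputs. Peak intensities are arbitrary lognormal units;
no instrument intensity model is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import masses, scaffold
from .inhibition import NEGATIVE_CONTROL, ZERO_SAMPLE, PlateMeasurement
from .scaffold import APCompound, library_default, predict_fragments
from .spectra import Spectrum

__all__ = [
    "SpectrumSimParams",
    "PlateSimParams",
    "TABLE1_LAYOUT",
    "simulate_spectrum",
    "simulate_decoy",
    "build_table1_fixture",
    "simulate_plate",
    "true_ic50",
]

#: Half-width (Da) of the window cleared around the Lys gate ion when
#: constructing decoys, matching the default screening tolerance.
GATE_EXCLUSION_DA = 0.5


@dataclass(frozen=True)
class SpectrumSimParams:
    """Noise model for simulated MS/MS spectra.

    mz_sigma is Gaussian m/z jitter (Da); dropout_p the independent
    per-fragment omission probability; noise peaks fall uniformly in
    noise_mz_range (the acquisition window). Intensities are
    lognormal(intensity_mu, intensity_sigma) in arbitrary units.
    Labels listed in always_keep are never dropped (the precursor is never
    dropped regardless).
    """

    mz_sigma: float = 0.01
    dropout_p: float = 0.05
    n_noise_peaks: int = 20
    noise_mz_range: tuple[float, float] = (50.0, 1000.0)
    intensity_mu: float = 10.0
    intensity_sigma: float = 1.0
    seed: int = 0
    always_keep: frozenset[str] = frozenset()

    def __post_init__(self):
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.mz_sigma < 0 or self.n_noise_peaks < 0:
            raise ValueError("mz_sigma and n_noise_peaks must be non-negative")


def _noise_peaks(
    rng: np.random.Generator,
    n: int,
    mz_range: tuple[float, float],
    params: SpectrumSimParams,
    exclude: Sequence[float] = (),
    exclusion_da: float = 0.6,
) -> list[tuple[float, float]]:
    """Uniform-random noise peaks avoiding windows around ``exclude`` m/z."""
    peaks: list[tuple[float, float]] = []
    kept = 0
    while kept < n:
        mz = float(rng.uniform(*mz_range))
        if any(abs(mz - x) <= exclusion_da for x in exclude):
            continue
        peaks.append((mz, float(rng.lognormal(params.intensity_mu, params.intensity_sigma))))
        kept += 1
    return peaks


def simulate_spectrum(
    c: APCompound,
    p: SpectrumSimParams,
    spectrum_id: str | None = None,
    fraction: str = "",
    rng: np.random.Generator | None = None,
    protected_mzs: Sequence[float] = (),
) -> Spectrum:
    """Simulate one spectrum of a compound from its predicted fragments.

    Each predicted fragment is kept with probability 1 - dropout_p (the
    precursor and any label in p.always_keep are always kept), jittered by
    N(0, mz_sigma) and assigned a lognormal intensity; n_noise_peaks random
    peaks are added, steered clear of ``protected_mzs`` windows so noise
    cannot forge a diagnostic ion.
    """
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    predicted = predict_fragments(c)
    peaks: list[tuple[float, float]] = []
    for mz, label in predicted.entries:
        keep = label == "precursor" or label in p.always_keep or rng.random() >= p.dropout_p
        if keep:
            jitter = rng.normal(0.0, p.mz_sigma) if p.mz_sigma > 0 else 0.0
            peaks.append(
                (mz + jitter, float(rng.lognormal(p.intensity_mu, p.intensity_sigma)))
            )
    peaks.extend(
        _noise_peaks(rng, p.n_noise_peaks, p.noise_mz_range, p, exclude=protected_mzs)
    )
    return Spectrum(
        id=spectrum_id or f"sim_{c.name.replace(' ', '_')}",
        precursor_mz=predicted.precursor_mz,
        peaks=tuple(peaks),
        fraction=fraction,
    )


def simulate_decoy(
    p: SpectrumSimParams,
    spectrum_id: str = "decoy",
    fraction: str = "",
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """A pure-noise spectrum guaranteed to fail the Lys-marker gate.

    Noise peaks are drawn uniformly and any peak within 0.5 Da of the gate
    ion (84.081) is removed, so the final peak count can be below
    n_noise_peaks.
    """
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    gate = masses.lys_marker_mz()
    raw = [
        (float(rng.uniform(*p.noise_mz_range)), float(rng.lognormal(p.intensity_mu, p.intensity_sigma)))
        for _ in range(p.n_noise_peaks)
    ]
    peaks = tuple(pk for pk in raw if abs(pk[0] - gate) > GATE_EXCLUSION_DA)
    precursor = float(rng.uniform(600.0, 900.0))
    return Spectrum(id=spectrum_id, precursor_mz=precursor, peaks=peaks, fraction=fraction)


# ---------------------------------------------------------------------------
# Fraction-screening fixture

#: Published detection layout: (fraction % MeOH, nominal m/z, proposed name).
#: Named entries refer to the built-in library; "AP 8xx" rows are putative
#: novel analogs whose ring compositions are unknown (their fixture spectra
#: claim no structure, only the gate ion and the Arg-style Δ200 loss);
#: "AP fragment" rows are bare ring ions or related fragments.
TABLE1_LAYOUT: tuple[tuple[int, int, str], ...] = (
    (20, 844, "AP A"),
    (30, 810, "AP 809"),
    (30, 844, "AP A"),
    (30, 858, "OSC Y"),
    (40, 803, "AP 802"),
    (40, 810, "AP 809"),
    (40, 828, "AP 827"),
    (40, 837, "AP B"),
    (40, 844, "AP A"),
    (40, 858, "OSC Y"),
    (50, 752, "AP fragment"),
    (50, 803, "AP 802"),
    (50, 837, "AP B"),
    (50, 844, "AP A"),
    (50, 858, "OSC Y"),
    (60, 752, "AP fragment"),
    (60, 803, "AP 802"),
    (60, 837, "AP B"),
    (60, 844, "AP A"),
    (60, 851, "AP F"),
    (70, 637, "AP fragment"),
    (80, 637, "AP fragment"),
    (90, 637, "AP fragment"),
    (100, 637, "AP fragment"),
)

#: Typical mass defect used for synthetic novel-analog precursors so that
#: nominal rounding lands on the intended integer.
_NOVEL_MASS_DEFECT = 0.455


def _diagnostic_exclusions(precursor_mz: float, cyp_mzs: Sequence[float]) -> list[float]:
    arg_loss = masses.residue_mass("R") + masses.H2O + masses.CO - masses.H2
    tyr_loss = masses.residue_mass("Y") + masses.H2O
    return [
        masses.lys_marker_mz(),
        precursor_mz - arg_loss,
        precursor_mz - tyr_loss,
        *cyp_mzs,
    ]


def build_table1_fixture(
    seed: int, params: SpectrumSimParams | None = None
) -> list[Spectrum]:
    """Simulated spectra reproducing the published fraction/compound layout.

    One spectrum per layout row. Library compounds are simulated from
    their predicted fragments with mild noise (mz_sigma 0.01, dropout 0.05);
    the gate ion and the exocyclic-loss ion are never dropped and noise
    peaks avoid all diagnostic windows, because the layout records ions
    that were observed — a fixture row without its defining evidence would
    describe a different experiment. Novel-analog and fragment spectra are
    built directly from their defining peaks (no structural claim).
    """
    p = params or SpectrumSimParams(mz_sigma=0.01, dropout_p=0.05)
    p = SpectrumSimParams(
        mz_sigma=p.mz_sigma,
        dropout_p=p.dropout_p,
        n_noise_peaks=p.n_noise_peaks,
        noise_mz_range=p.noise_mz_range,
        intensity_mu=p.intensity_mu,
        intensity_sigma=p.intensity_sigma,
        seed=seed,
        always_keep=frozenset({"lys_marker", "ring_ion"}),
    )
    rng = np.random.default_rng(seed)
    library = {c.name: c for c in library_default()}
    cyp_mzs = scaffold.DEFAULT_CYP_DIAGNOSTIC_MZS
    arg_loss = masses.residue_mass("R") + masses.H2O + masses.CO - masses.H2

    spectra: list[Spectrum] = []
    for i, (fraction_pct, mz, name) in enumerate(TABLE1_LAYOUT):
        fraction = f"{fraction_pct}% MeOH"
        sid = f"t1_{i:02d}_{fraction_pct}pct_{mz}"
        if name in library:
            spectra.append(
                simulate_spectrum(
                    library[name],
                    p,
                    spectrum_id=sid,
                    fraction=fraction,
                    rng=rng,
                    protected_mzs=_diagnostic_exclusions(
                        scaffold.protonate(scaffold.ap_neutral_mass(library[name])),
                        cyp_mzs,
                    ),
                )
            )
        elif name == "AP fragment":
            if mz == 637:
                precursor = scaffold.ring_fragment_mz(library["AP B"])
            else:
                precursor = mz + _NOVEL_MASS_DEFECT
            peaks = [
                (masses.lys_marker_mz() + rng.normal(0, p.mz_sigma),
                 float(rng.lognormal(p.intensity_mu, p.intensity_sigma))),
            ]
            peaks += _noise_peaks(
                rng, p.n_noise_peaks, p.noise_mz_range, p,
                exclude=_diagnostic_exclusions(precursor, cyp_mzs),
            )
            spectra.append(
                Spectrum(id=sid, precursor_mz=precursor, peaks=tuple(peaks), fraction=fraction)
            )
        else:  # putative novel analog: gate ion + Arg-style Δ200 loss
            precursor = mz + _NOVEL_MASS_DEFECT
            peaks = [
                (masses.lys_marker_mz() + rng.normal(0, p.mz_sigma),
                 float(rng.lognormal(p.intensity_mu, p.intensity_sigma))),
                (precursor - arg_loss + rng.normal(0, p.mz_sigma),
                 float(rng.lognormal(p.intensity_mu, p.intensity_sigma))),
            ]
            peaks += _noise_peaks(
                rng, p.n_noise_peaks, p.noise_mz_range, p,
                exclude=_diagnostic_exclusions(precursor, cyp_mzs),
            )
            spectra.append(
                Spectrum(id=sid, precursor_mz=precursor, peaks=tuple(peaks), fraction=fraction)
            )
    return spectra


# ---------------------------------------------------------------------------
# Plate simulation


@dataclass(frozen=True)
class PlateSimParams:
    """Ground truth and noise model for one simulated plate.

    The default dose series mirrors a six-point standard-inhibitor design
    (10-60 µg/mL in duplicate); each plate carries four zero-inhibitor
    wells and two negative controls. true_coefficients follow the polyfit
    convention (highest order first) on dose, or on log10 dose for the
    loglinear truth.
    """

    true_model: str = "linear"
    true_coefficients: tuple[float, ...] = (0.01, 0.0)
    dose_series: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    noise_sd: float = 0.02
    replicates: int = 2
    a0: float = 1.0
    n_zero_wells: int = 4
    n_negative_controls: int = 2
    negative_control_level: float = 0.05
    enzyme: str = "trypsin"
    sample: str = "standard"
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.true_model == "loglinear" and min(self.dose_series) <= 0:
            raise ValueError("loglinear truth requires positive doses")

    def true_inhibition(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        x = np.log10(dose) if self.true_model == "loglinear" else dose
        return np.polyval(self.true_coefficients, x)


def true_ic50(p: PlateSimParams) -> float:
    """Dose at which the generating curve crosses 50% inhibition."""
    if p.true_model in ("linear", "loglinear"):
        a, b = p.true_coefficients
        x = (0.5 - b) / a
        return 10.0**x if p.true_model == "loglinear" else x
    a2, a1, a0 = p.true_coefficients
    roots = np.roots([a2, a1, a0 - 0.5])
    real = sorted(
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-9 and min(p.dose_series) <= r.real <= max(p.dose_series)
    )
    if not real:
        raise ValueError("generating curve never crosses 50% in the dose range")
    return real[0]


def simulate_plate(p: PlateSimParams) -> list[PlateMeasurement]:
    """Simulate plate absorbances A = A0 (1 - inhibition(dose)) + N(0, sd).

    Absorbances are floored at zero (a photometer cannot report negative
    AU). Deterministic under the params' seed.
    """
    rng = np.random.default_rng(p.seed)
    wells: list[PlateMeasurement] = []

    def ab(mean: float) -> float:
        return max(0.0, float(mean + rng.normal(0.0, p.noise_sd)))

    for r in range(p.n_zero_wells):
        wells.append(PlateMeasurement(p.enzyme, ZERO_SAMPLE, 0.0, ab(p.a0), r))
    for r in range(p.n_negative_controls):
        wells.append(
            PlateMeasurement(p.enzyme, NEGATIVE_CONTROL, 0.0, ab(p.negative_control_level), r)
        )
    for dose in p.dose_series:
        mean = p.a0 * (1.0 - float(p.true_inhibition(dose)))
        for r in range(p.replicates):
            wells.append(PlateMeasurement(p.enzyme, p.sample, float(dose), ab(mean), r))
    return wells
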