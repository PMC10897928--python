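"""ECD band-shape construction and sign-pattern comparison.

Electronic circular dichroism resolves which enantiomer of an assigned
relative configuration is present: the two mirror images give exactly
sign-inverted spectra. Computed rotatory strengths (velocity or length
gauge, in 10^-40 cgs units) are broadened into a Delta-epsilon spectrum by
summing Gaussians in the energy domain,

    Δε(E) = 1/(2.296e-39 σ √π) Σ_j E_j R_j exp(-((E-E_j)/σ)^2)

the standard TDDFT post-processing convention (R_j in cgs, E in eV,
Δε in L mol^-1 cm^-1). Conformer spectra are combined with Boltzmann
weights, Cotton effects (signed band extrema) are extracted, and the
computed sign pattern is compared with the experimental spectrum; a fully
inverted pattern with strongly negative correlation calls the enantiomer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HC_EV_NM

__all__ = [
    "RotatoryStrengthSet",
    "Spectrum",
    "CottonEffect",
    "SignComparison",
    "default_grid",
    "broaden",
    "ensemble_spectrum",
    "cotton_effects",
    "sign_agreement",
]

# Δε amplitude prefactor for R in cgs units (10^-40 erg esu cm / Gauss)
_ROTATORY_PREFACTOR = 1.0 / 2.296e-39


def default_grid(start: float = 180.0, stop: float = 400.0, step: float = 0.1):
    """Wavelength grid (nm) matching a typical far-UV ECD acquisition."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


@dataclass(frozen=True)
class RotatoryStrengthSet:
    """Transitions of one conformer: (wavelength nm, R in 10^-40 cgs)."""

    conformer_label: str
    transitions: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if any(wl <= 0 for wl, _ in self.transitions):
            raise ValueError("transition wavelengths must be positive")


@dataclass
class Spectrum:
    wavelengths: np.ndarray  # nm, strictly ascending
    values: np.ndarray  # Delta-epsilon, L mol^-1 cm^-1

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.values = np.asarray(self.values, float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")

    def interpolated(self, grid: np.ndarray) -> "Spectrum":
        return Spectrum(grid, np.interp(grid, self.wavelengths, self.values))

    def __neg__(self) -> "Spectrum":
        return Spectrum(self.wavelengths.copy(), -self.values)


def broaden(
    strengths: RotatoryStrengthSet,
    sigma: float = 0.3,
    shift: float = 0.0,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Gaussian band-shape spectrum from rotatory strengths.

    ``sigma`` is the Gaussian width in eV (applied in the energy domain,
    then mapped onto the wavelength grid); ``shift`` is a uniform UV
    correction in nm added to every transition position. Linear in the
    strengths; an empty transition list yields a zero spectrum.
    """
    if sigma <= 0:
        raise ValueError("bandwidth sigma must be positive")
    if grid is None:
        grid = default_grid()
    energies = HC_EV_NM / np.asarray(grid, float)
    values = np.zeros_like(energies)
    for wl, strength in strengths.transitions:
        wl_eff = wl + shift
        if wl_eff <= 0:
            raise ValueError("UV shift moved a transition to non-positive nm")
        e0 = HC_EV_NM / wl_eff
        amp = _ROTATORY_PREFACTOR * e0 * strength * 1e-40 / (sigma * np.sqrt(np.pi))
        values += amp * np.exp(-(((energies - e0) / sigma) ** 2))
    return Spectrum(np.asarray(grid, float), values)


def ensemble_spectrum(spectra: list[Spectrum], weights) -> Spectrum:
    """Population-weighted pointwise sum of per-conformer spectra."""
    w = np.asarray(weights, float)
    if len(w) != len(spectra):
        raise ValueError("one weight per spectrum required")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != grid.shape or not np.allclose(
            s.wavelengths, grid
        ):
            raise ValueError("spectra must share a common wavelength grid")
    return Spectrum(grid, np.einsum("k,kn->n", w, [s.values for s in spectra]))


@dataclass(frozen=True)
class CottonEffect:
    wavelength: float  # nm
    delta_epsilon: float  # signed amplitude

    @property
    def sign(self) -> int:
        return 1 if self.delta_epsilon > 0 else -1


def cotton_effects(spectrum: Spectrum, min_abs: float = 1.0) -> list[CottonEffect]:
    """Signed local band extrema with |Δε| >= ``min_abs``, by wavelength."""
    v = spectrum.values
    wl = spectrum.wavelengths
    out = []
    for i in range(1, len(v) - 1):
        if abs(v[i]) < min_abs:
            continue
        if v[i] > 0 and v[i] >= v[i - 1] and v[i] > v[i + 1]:
            out.append(CottonEffect(float(wl[i]), float(v[i])))
        elif v[i] < 0 and v[i] <= v[i - 1] and v[i] < v[i + 1]:
            out.append(CottonEffect(float(wl[i]), float(v[i])))
    return out


@dataclass
class SignComparison:
    band_matches: list[tuple[float, bool]]  # (band nm, signs agree)
    correlation: float  # Pearson r on the overlapping grid
    verdict: str  # "match" | "enantiomer" | "ambiguous"


def _band_sign(spectrum: Spectrum, band: float, window: float) -> int:
    mask = (spectrum.wavelengths >= band - window) & (
        spectrum.wavelengths <= band + window
    )
    if not mask.any():
        raise ValueError(f"band {band} nm outside the spectrum grid")
    seg = spectrum.values[mask]
    return 1 if seg[np.argmax(np.abs(seg))] > 0 else -1


def sign_agreement(
    calc: Spectrum,
    exp: Spectrum,
    bands: list[float],
    window: float = 5.0,
) -> SignComparison:
    """Compare Cotton-effect signs of computed vs experimental spectra.

    For each band wavelength the signed dominant amplitude within
    ±``window`` nm is compared. All signs agreeing -> "match"; all signs
    inverted -> "enantiomer" (the mirror-image structure is indicated);
    otherwise "ambiguous". Correlation is Pearson r over the grid overlap.
    """
    lo = max(calc.wavelengths[0], exp.wavelengths[0])
    hi = min(calc.wavelengths[-1], exp.wavelengths[-1])
    if hi <= lo:
        raise ValueError("spectra do not overlap in wavelength")
    grid = np.linspace(lo, hi, 2048)
    c = calc.interpolated(grid).values
    e = exp.interpolated(grid).values
    denom = np.std(c) * np.std(e)
    corr = float(np.mean((c - c.mean()) * (e - e.mean())) / denom) if denom else 0.0
    matches = []
    for band in bands:
        matches.append(
            (band, _band_sign(calc, band, window) == _band_sign(exp, band, window))
        )
    agree = [m for _, m in matches]
    if all(agree):
        verdict = "match"
    elif not any(agree):
        verdict = "enantiomer"
    else:
        verdict = "ambiguous"
    return SignComparison(matches, corr, verdict)


def read_spectrum_csv(path) -> Spectrum:
    """Columns: wavelength_nm,delta_epsilon."""
    import pandas as pd

    tab = pd.read_csv(path)
    order = np.argsort(tab["wavelength_nm"].to_numpy())
    return Spectrum(
        tab["wavelength_nm"].to_numpy(float)[order],
        tab["delta_epsilon"].to_numpy(float)[order],
    )


def read_rotatory_csv(path) -> list[RotatoryStrengthSet]:
    """Columns: conformer_label,wavelength_nm,strength (10^-40 cgs)."""
    import pandas as pd

    tab = pd.read_csv(path)
    out = []
    for label, grp in tab.groupby("conformer_label", sort=True):
        out.append(
            RotatoryStrengthSet(
                str(label),
                tuple(
                    (float(r["wavelength_nm"]), float(r["strength"]))
                    for _, r in grp.iterrows()
                ),
            )
        )
    return out
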