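"""First-order simulation of 1D 1H spectra from predicted shift/coupling lists.

Each proton group is expanded into a first-order (weak-coupling) stick
multiplet — n equivalent spin-1/2 partners split a line into n+1 components
with binomial weights at spacings J/field ppm — and each stick deposits its
analytically integrated lineshape mass into the grid bins (the bins of a
binned spectrum hold integrals, not point samples, so this stays exact even
when the linewidth is narrower than the bin width).  No second-order
(strong-coupling) effects are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .spectra_io import (
    DEFAULT_N_POINTS,
    DEFAULT_PPM_MAX,
    DEFAULT_PPM_MIN,
    DegenerateSpectrumError,
    PredictionSet,
    ProtonGroup,
    Spectrum,
    normalize_total,
)

LINESHAPES = ("lorentzian", "gaussian")


@dataclass(frozen=True)
class SimulationParams:
    """Spectrometer and discretisation parameters for spectrum simulation.

    field:      spectrometer frequency in MHz (converts J in Hz to ppm)
    linewidth:  full width at half maximum of each line, in Hz
    lineshape:  'lorentzian' (default) or 'gaussian'
    grid:       (ppm_max, ppm_min, n_points) target window
    """

    field: float = 250.0
    linewidth: float = 1.0
    lineshape: str = "lorentzian"
    ppm_max: float = DEFAULT_PPM_MAX
    ppm_min: float = DEFAULT_PPM_MIN
    n_points: int = DEFAULT_N_POINTS

    def __post_init__(self) -> None:
        if self.field <= 0:
            raise ValueError("field must be positive (MHz)")
        if self.linewidth <= 0:
            raise ValueError("linewidth must be positive (Hz)")
        if self.lineshape not in LINESHAPES:
            raise ValueError(f"lineshape must be one of {LINESHAPES}")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not self.ppm_max > self.ppm_min:
            raise ValueError("ppm_max must exceed ppm_min")

    @property
    def fwhm_ppm(self) -> float:
        return self.linewidth / self.field


def multiplet_pattern(
    group: ProtonGroup, field: float
) -> list[tuple[float, float]]:
    """First-order stick pattern of a proton group as (offset_ppm, weight).

    A unit line is split iteratively by each coupling: ``n_partners``
    equivalent spin-1/2 partners yield ``n_partners + 1`` lines with binomial
    weights at spacing ``J / field`` ppm, symmetric about zero.  Weights sum
    to 1.
    """
    lines: list[tuple[float, float]] = [(0.0, 1.0)]
    for j_hz, n_partners in group.couplings:
        spacing = j_hz / field
        denom = 2.0 ** n_partners
        split = [
            ((k - n_partners / 2.0) * spacing, math.comb(n_partners, k) / denom)
            for k in range(n_partners + 1)
        ]
        lines = [(off + d_off, w * d_w) for off, w in lines for d_off, d_w in split]
    return lines


def _lineshape_bin_mass(
    edges: np.ndarray, x0: float, fwhm: float, kind: str
) -> np.ndarray:
    """Mass of a unit-area line integrated over consecutive bins.

    ``edges`` are the n+1 ascending bin edges; returns n bin masses from the
    analytic cumulative lineshape (atan for Lorentzian, erf for Gaussian).
    """
    if kind == "lorentzian":
        hw = fwhm / 2.0
        cdf = np.arctan((edges - x0) / hw) / math.pi
    else:  # gaussian
        sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        cdf = 0.5 * erf((edges - x0) / (sigma * math.sqrt(2.0)))
    return np.diff(cdf)


def simulate_spectrum(
    pred: PredictionSet, params: SimulationParams = SimulationParams()
) -> Spectrum:
    """Simulate a discretised spectrum from a prediction, unit total intensity.

    Each stick is weighted by the number of equivalent protons and by its
    multiplet weight, and deposits the analytic integral of its lineshape
    over every bin; the bins are centred on the grid points.  The result is
    normalised to unit total.  Sticks outside the window contribute only
    their in-window tails; if every stick is farther than 50 linewidths
    outside the window the spectrum would be indistinguishable from zero and
    a :class:`DegenerateSpectrumError` is raised.
    """
    delta = (params.ppm_max - params.ppm_min) / (params.n_points - 1)
    # ascending bin edges, bins centred on the descending grid points
    edges_asc = np.linspace(
        params.ppm_min - delta / 2.0, params.ppm_max + delta / 2.0, params.n_points + 1
    )
    fwhm = params.fwhm_ppm
    y_asc = np.zeros(params.n_points)
    margin = 50.0 * fwhm
    any_near = False
    for group in pred.groups:
        for offset, weight in multiplet_pattern(group, params.field):
            x0 = group.shift + offset
            if params.ppm_min - margin <= x0 <= params.ppm_max + margin:
                any_near = True
            y_asc += group.n_protons * weight * _lineshape_bin_mass(
                edges_asc, x0, fwhm, params.lineshape
            )
    y = y_asc[::-1].copy()  # descending-ppm convention
    if not any_near or y.sum() <= 0:
        raise DegenerateSpectrumError(
            f"'{pred.molecule_id}': all lines fall farther than 50 linewidths "
            "outside the observation window"
        )
    return normalize_total(Spectrum(pred.molecule_id, params.ppm_max, params.ppm_min, y))


def simulate_all(
    preds: list[PredictionSet], params: SimulationParams = SimulationParams()
) -> list[Spectrum]:
    """Simulate one spectrum per prediction set."""
    return [simulate_spectrum(p, params) for p in preds]
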