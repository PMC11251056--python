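"""Native-MS spectrum simulation, zero-charge reduction, and species assignment.

The measured quantity in a native mass spectrum of a protein–ligand
ensemble is a set of charge-state envelopes: each neutral species of mass
M appears at m/z = (M + z·m_H)/z for several charges z. This module

* simulates such spectra as Gaussian peaks whose width follows the
  instrument resolving power (FWHM = M / (z · resolution) in m/z),
* reduces a spectrum back to per-species intensities by non-negative
  least squares against the template of every candidate stoichiometry
  (a deliberately simple stand-in for full Bayesian deconvolution),
* assigns deconvolved zero-charge peaks to ligand stoichiometries by
  nearest mass within a tolerance, and
* converts assigned intensities to mole fractions, the quantity the
  binding analysis consumes.

Relative peak intensity is taken as proportional to species abundance,
the standard operating assumption when quantifying ligand binding from
native MS of a single protein under fixed transmission conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import numpy.typing as npt
from scipy.optimize import nnls

from .exceptions import (
    AmbiguousAssignmentError,
    ConfigurationError,
    InvalidInputError,
    UndefinedFractionError,
)

__all__ = [
    "PROTON_MASS",
    "LIGAND_MASSES",
    "SpeciesDefinition",
    "MassSpectrum",
    "DeconvolvedPeak",
    "SpeciesAssignment",
    "AssignmentResult",
    "DeconvolutionResult",
    "gaussian_charge_weights",
    "simulate_spectrum",
    "deconvolve_template",
    "assign_species",
    "intensities_to_mole_fractions",
]

PROTON_MASS = 1.00728  # Da

#: Average masses (Da) of the ligands used throughout: ATP and ADP from
#: their molecular formulas (C10H16N5O13P3, C10H15N5O10P2); Kdo2-lipid A
#: (KDL) and tetraoleoyl cardiolipin (TOCDL) from their published formulas.
LIGAND_MASSES: dict[str, float] = {
    "ATP": 507.18,
    "ADP": 427.20,
    "KDL": 2236.63,
    "TOCDL": 1457.05,
}

Stoichiometry = tuple[int, ...]


@dataclass(frozen=True)
class SpeciesDefinition:
    """Mass ladder of a protein with up to ``max_counts`` ligands per class.

    ``base_mass`` is the apo (homodimer) mass in Da; ligand order in
    ``ligand_masses`` fixes the ordering of stoichiometry tuples.
    """

    base_mass: float
    ligand_masses: dict[str, float]
    max_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.base_mass <= 0 or any(m <= 0 for m in self.ligand_masses.values()):
            raise InvalidInputError("all masses must be > 0")
        if set(self.max_counts) != set(self.ligand_masses):
            raise InvalidInputError("ligand_masses and max_counts keys must match")
        if any(c < 0 for c in self.max_counts.values()):
            raise InvalidInputError("max counts must be >= 0")

    @property
    def ligand_names(self) -> tuple[str, ...]:
        return tuple(self.ligand_masses)

    def stoichiometries(self) -> list[Stoichiometry]:
        """Every (count per ligand) combination, apo first."""
        ranges = [range(self.max_counts[n] + 1) for n in self.ligand_names]
        return list(product(*ranges))

    def mass(self, stoich: Stoichiometry) -> float:
        if len(stoich) != len(self.ligand_names):
            raise InvalidInputError("stoichiometry length mismatch")
        return self.base_mass + sum(
            c * self.ligand_masses[n] for c, n in zip(stoich, self.ligand_names))

    def label(self, stoich: Stoichiometry) -> str:
        return "_".join(f"{n}{c}" for n, c in zip(self.ligand_names, stoich))


@dataclass(frozen=True)
class MassSpectrum:
    """Raw m/z vs intensity trace (Th, arbitrary units)."""

    mz: npt.NDArray[np.float64]
    intensity: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise InvalidInputError("mz and intensity must be equal-length vectors")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise InvalidInputError("mz must be strictly increasing")
        if np.any(inten < 0):
            raise InvalidInputError("intensities must be >= 0")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class DeconvolvedPeak:
    """One zero-charge (neutral mass) peak."""

    neutral_mass: float  # Da
    intensity: float

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise InvalidInputError("neutral_mass must be > 0")
        if self.intensity < 0:
            raise InvalidInputError("intensity must be >= 0")


@dataclass(frozen=True)
class SpeciesAssignment:
    """A stoichiometry with its summed assigned intensity."""

    stoichiometry: Stoichiometry
    intensity: float
    mass_error: float  # Da, intensity-weighted mean observed − expected


@dataclass(frozen=True)
class AssignmentResult:
    assignments: list[SpeciesAssignment]
    unmatched: list[DeconvolvedPeak] = field(default_factory=list)


@dataclass(frozen=True)
class DeconvolutionResult:
    peaks: list[DeconvolvedPeak]
    residual_norm: float

    def __iter__(self):
        return iter(self.peaks)


def gaussian_charge_weights(center: float = 24.0, width: float = 2.0,
                            n_states: int = 7) -> dict[int, float]:
    """A Gaussian-weighted charge-state envelope around ``center``.

    Native MS of a ~129 kDa detergent-solubilized dimer typically spans a
    handful of charge states; the exact range is instrument-dependent, so
    the envelope is configurable and these defaults are placeholders.
    """
    zs = np.arange(round(center) - n_states // 2, round(center) + n_states // 2 + 1)
    zs = zs[zs >= 1]
    w = np.exp(-0.5 * ((zs - center) / width) ** 2)
    w /= w.sum()
    return {int(z): float(wi) for z, wi in zip(zs, w)}


def _peak_params(mass: float, z: int, resolution: float) -> tuple[float, float]:
    """(center m/z, sigma in m/z) of one charge state."""
    center = (mass + z * PROTON_MASS) / z
    sigma = mass / (z * resolution * 2.355)
    return center, sigma


def _profile(mz: npt.NDArray, species_masses: npt.NDArray, amounts: npt.NDArray,
             charges: dict[int, float], resolution: float) -> npt.NDArray:
    out = np.zeros_like(mz)
    for m, a in zip(species_masses, amounts):
        if a == 0:
            continue
        for z, w in charges.items():
            c, s = _peak_params(m, z, resolution)
            out += a * w / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((mz - c) / s) ** 2)
    return out


def simulate_spectrum(species: SpeciesDefinition,
                      abundances: dict[Stoichiometry, float],
                      charges: dict[int, float] | None = None,
                      resolution: float = 17_500.0,
                      noise_sd: float = 0.0,
                      seed: int | None = None,
                      points_per_sigma: float = 6.0) -> MassSpectrum:
    """Simulate a charge-state-resolved spectrum of the species ensemble.

    Each (species, charge) pair contributes a Gaussian whose area is
    proportional to abundance × charge weight; multiplicative Gaussian
    noise of relative SD ``noise_sd`` is then applied point-wise.
    Deterministic for a given ``seed``.
    """
    if not abundances:
        raise InvalidInputError("abundances must be non-empty")
    total = sum(abundances.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise InvalidInputError(f"abundances must sum to 1 (got {total})")
    if charges is None:
        charges = gaussian_charge_weights()
    if not np.isclose(sum(charges.values()), 1.0, atol=1e-6):
        raise InvalidInputError("charge weights must sum to 1")

    masses = np.array([species.mass(s) for s in abundances])
    amounts = np.array(list(abundances.values()), dtype=float)
    lo = min(_peak_params(m, z, resolution)[0] - 8 * _peak_params(m, z, resolution)[1]
             for m in masses for z in charges)
    hi = max(_peak_params(m, z, resolution)[0] + 8 * _peak_params(m, z, resolution)[1]
             for m in masses for z in charges)
    min_sigma = min(_peak_params(m, z, resolution)[1]
                    for m in masses for z in charges)
    n = int(np.ceil((hi - lo) / (min_sigma / points_per_sigma))) + 1
    mz = np.linspace(lo, hi, n)
    inten = _profile(mz, masses, amounts, charges, resolution)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        inten = np.clip(inten * (1.0 + rng.normal(0.0, noise_sd, inten.shape)), 0.0, None)
    return MassSpectrum(mz=mz, intensity=inten)


def deconvolve_template(spectrum: MassSpectrum, species: SpeciesDefinition,
                        charges: dict[int, float] | None = None,
                        resolution: float = 17_500.0) -> DeconvolutionResult:
    """Fit non-negative per-species intensities by template matching.

    Builds the unit-abundance profile of every candidate stoichiometry
    over the spectrum's m/z grid and solves the non-negative least-squares
    problem ``min ||A·x − intensity||, x ≥ 0``. One
    :class:`DeconvolvedPeak` per stoichiometry mass is returned together
    with the residual norm.
    """
    if spectrum.mz.size == 0:
        raise InvalidInputError("empty spectrum")
    if charges is None:
        charges = gaussian_charge_weights()
    stoichs = species.stoichiometries()
    templates = np.column_stack([
        _profile(spectrum.mz, np.array([species.mass(s)]), np.array([1.0]),
                 charges, resolution)
        for s in stoichs
    ])
    coef, resid = nnls(templates, spectrum.intensity)
    peaks = [DeconvolvedPeak(neutral_mass=species.mass(s), intensity=float(c))
             for s, c in zip(stoichs, coef)]
    return DeconvolutionResult(peaks=peaks, residual_norm=float(resid))


def assign_species(peaks: list[DeconvolvedPeak], species: SpeciesDefinition,
                   tolerance: float = 150.0) -> AssignmentResult:
    """Map neutral-mass peaks to the nearest candidate stoichiometry.

    ``tolerance`` (Da) must be positive and below half the smallest
    inter-species mass gap, so an in-tolerance match is always unique.
    The default of 150 Da sits well below the lightest ligand here
    (ADP, ~427 Da) while absorbing small adduct shifts. Peaks farther
    than the tolerance from every species are reported as unmatched;
    peaks exactly equidistant between two species raise rather than
    being assigned silently.
    """
    stoichs = species.stoichiometries()
    masses = np.array([species.mass(s) for s in stoichs])
    if tolerance <= 0:
        raise ConfigurationError("tolerance must be > 0")
    if len(masses) > 1:
        gaps = np.diff(np.sort(masses))
        min_gap = float(gaps[gaps > 0].min()) if np.any(gaps > 0) else 0.0
        if min_gap == 0.0 or tolerance >= min_gap / 2:
            raise ConfigurationError(
                f"tolerance {tolerance} Da must be < half the minimum "
                f"inter-species gap ({min_gap / 2:.1f} Da)")

    sums: dict[Stoichiometry, float] = {}
    werr: dict[Stoichiometry, float] = {}
    unmatched: list[DeconvolvedPeak] = []
    for pk in peaks:
        d = np.abs(masses - pk.neutral_mass)
        order = np.argsort(d)
        if len(masses) > 1 and d[order[0]] == d[order[1]]:
            raise AmbiguousAssignmentError(
                f"peak at {pk.neutral_mass:.2f} Da equidistant between "
                f"{species.label(stoichs[order[0]])} and {species.label(stoichs[order[1]])}")
        best = int(order[0])
        if d[best] > tolerance:
            unmatched.append(pk)
            continue
        s = stoichs[best]
        sums[s] = sums.get(s, 0.0) + pk.intensity
        werr[s] = werr.get(s, 0.0) + pk.intensity * (pk.neutral_mass - masses[best])
    assignments = [
        SpeciesAssignment(
            stoichiometry=s,
            intensity=inten,
            mass_error=(werr[s] / inten if inten > 0 else 0.0),
        )
        for s, inten in sums.items()
    ]
    return AssignmentResult(assignments=assignments, unmatched=unmatched)


def intensities_to_mole_fractions(
        assignments: list[SpeciesAssignment]) -> dict[Stoichiometry, float]:
    """Normalize assigned intensities to mole fractions, F(s) = I(s)/ΣI."""
    if not assignments:
        raise UndefinedFractionError("no assignments")
    total = sum(a.intensity for a in assignments)
    if total <= 0:
        raise UndefinedFractionError("all assigned intensities are zero")
    return {a.stoichiometry: a.intensity / total for a in assignments}
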