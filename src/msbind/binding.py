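"""Sequential ligand-binding model for a homodimeric protein.

A protein P (here the intact homodimer — species in native mass spectra are
dimer + n ligand masses) binds up to ``n_max`` copies of a ligand L in
sequential steps, each governed by a stepwise association constant

    P·L_{n-1} + L  <=>  P·L_n,     K_An = [PL_n] / ([PL_{n-1}][L])

so the mole fraction of the n-bound species at free ligand concentration
``x`` is

    F_n(x) = x^n Π_{j<=n} K_Aj / (1 + Σ_i x^i Π_{j<=i} K_Aj).

At micromolar protein concentrations the bound ligand is not negligible,
so the free concentration is obtained self-consistently from mass balance

    L_free + P_total · Σ_i i F_i(L_free) = L_total,

whose left side is strictly increasing in L_free: the root on
[0, L_total] is unique and is found here by bisection to double precision.

All concentrations are in µM and K_A in µM⁻¹; unit conversion belongs at
the I/O boundary, not here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import numpy.typing as npt

from .exceptions import InvalidInputError

__all__ = [
    "BindingModel",
    "EquilibriumState",
    "free_ligand_concentration",
    "mole_fractions",
    "mole_fractions_grid",
    "mean_occupancy",
    "joint_mole_fractions_independent",
]

_BISECT_ITER = 72  # halves [0, L_total] to ~2^-72, below double-precision spacing


@dataclass(frozen=True)
class BindingModel:
    """Stepwise association constants for one ligand class on the dimer.

    Parameters
    ----------
    k_a : array-like of float
        Per-step association constants ``K_A1..K_An`` in µM⁻¹, one entry
        per sequential site (2 for nucleotides, up to 4 for lipids).
        Entries must be finite and ≥ 0; a zero entry switches that step
        (and all later species) off.
    """

    k_a: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        k_a = np.atleast_1d(np.asarray(self.k_a, dtype=float))
        if k_a.ndim != 1 or k_a.size < 1:
            raise InvalidInputError("k_a must be a non-empty 1-D vector (n_max >= 1)")
        if not np.all(np.isfinite(k_a)) or np.any(k_a < 0):
            raise InvalidInputError("all K_A must be finite and >= 0")
        object.__setattr__(self, "k_a", k_a)

    @property
    def n_max(self) -> int:
        return self.k_a.size

    @property
    def k_d(self) -> npt.NDArray[np.float64]:
        """Stepwise dissociation constants K_D,j = 1/K_A,j in µM (inf for K_A=0)."""
        with np.errstate(divide="ignore"):
            return 1.0 / self.k_a

    @classmethod
    def from_kd(cls, k_d: npt.ArrayLike) -> "BindingModel":
        k_d = np.atleast_1d(np.asarray(k_d, dtype=float))
        if np.any(k_d <= 0):
            raise InvalidInputError("all K_D must be > 0 (use K_A = 0 for a dead step)")
        return cls(k_a=1.0 / k_d)

    # cumulative products beta_i = Π_{j<=i} K_Aj, with beta_0 = 1
    @property
    def _beta(self) -> npt.NDArray[np.float64]:
        return np.concatenate(([1.0], np.cumprod(self.k_a)))

    def to_dict(self) -> dict[str, float]:
        """Flat key-value form with explicit units, e.g. ``{"KD1_uM": 47.8}``."""
        return {f"KD{j + 1}_uM": float(kd) for j, kd in enumerate(self.k_d)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "BindingModel":
        keys = sorted((k for k in d if k.startswith("KD") and k.endswith("_uM")),
                      key=lambda k: int(k[2:-3]))
        if not keys:
            raise InvalidInputError("no KD<j>_uM keys found")
        return cls.from_kd([d[k] for k in keys])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BindingModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class EquilibriumState:
    """Solved binding equilibrium at one condition.

    ``fractions[n]`` is the mole fraction of the species carrying exactly
    ``n`` ligands; the vector has length ``n_max + 1`` and sums to 1.
    """

    p_total: float  # µM, dimer
    l_total: float  # µM
    l_free: float   # µM
    fractions: npt.NDArray[np.float64] = field(repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if min(self.p_total, self.l_total, self.l_free) < 0 or np.any(f < -1e-12):
            raise InvalidInputError("equilibrium state fields must be non-negative")

    @property
    def n_max(self) -> int:
        return self.fractions.size - 1


def _check_conc(p_total: float, l_total: float) -> None:
    if not (np.isfinite(p_total) and np.isfinite(l_total)):
        raise InvalidInputError("P_total and L_total must be finite")
    if p_total < 0 or l_total < 0:
        raise InvalidInputError("P_total and L_total must be >= 0")


def _fractions_at(beta: npt.NDArray, x: npt.NDArray) -> npt.NDArray:
    """F_n(x) for free-ligand array x; returns shape (len(x), n_max+1)."""
    n = np.arange(beta.size)
    w = beta * np.power.outer(np.asarray(x, dtype=float), n)
    return w / w.sum(axis=-1, keepdims=True)


def free_ligand_concentration(model: BindingModel, p_total: float, l_total: float) -> float:
    """Free ligand concentration (µM) at equilibrium, depletion included.

    Unique root of ``x + P_total·Σ i F_i(x) − L_total`` on ``[0, L_total]``.
    """
    _check_conc(p_total, l_total)
    return float(_free_ligand_grid(model, p_total, np.array([l_total]))[0])


def _free_ligand_grid(model: BindingModel, p_total: float,
                      l_total: npt.NDArray) -> npt.NDArray:
    """Vectorized bisection for L_free over an array of L_total values."""
    beta = model._beta
    n = beta.size - 1
    l_total = np.asarray(l_total, dtype=float)
    lo = np.zeros_like(l_total)
    hi = l_total.copy()
    for _ in range(_BISECT_ITER):
        mid = 0.5 * (lo + hi)
        # mean occupancy Σ i β_i x^i / Σ β_i x^i, powers built in place
        den = np.ones_like(mid)
        num = np.zeros_like(mid)
        xp = np.ones_like(mid)
        for i in range(1, n + 1):
            xp = xp * mid
            term = beta[i] * xp
            den += term
            num += i * term
        high = mid + p_total * (num / den) > l_total
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    root = 0.5 * (lo + hi)
    # residual is monotone; the bracket cannot fail for valid inputs
    assert np.all(root >= 0) and np.all(root <= l_total + 1e-9), "bracket lost"
    return root


def mole_fractions(model: BindingModel, p_total: float, l_total: float) -> EquilibriumState:
    """Solve the binding equilibrium at one condition.

    Returns an :class:`EquilibriumState` whose ``fractions`` follow the
    sequential-model mole-fraction formula evaluated at the
    self-consistent free ligand concentration.
    """
    _check_conc(p_total, l_total)
    x = free_ligand_concentration(model, p_total, l_total)
    f = _fractions_at(model._beta, np.array([x]))[0]
    return EquilibriumState(p_total=p_total, l_total=l_total, l_free=x, fractions=f)


def mole_fractions_grid(model: BindingModel, p_total: float,
                        l_total: npt.ArrayLike) -> npt.NDArray:
    """Mole fractions over a grid of total ligand concentrations.

    Vectorized form used by fitting; returns shape ``(len(L), n_max+1)``.
    """
    l_total = np.atleast_1d(np.asarray(l_total, dtype=float))
    if not np.all(np.isfinite(l_total)) or np.any(l_total < 0) or not np.isfinite(p_total):
        raise InvalidInputError("concentrations must be finite and >= 0")
    x = _free_ligand_grid(model, p_total, l_total)
    return _fractions_at(model._beta, x)


def mean_occupancy(state: EquilibriumState) -> float:
    """Average number of bound ligands per dimer, Σ i·F_i ∈ [0, n_max]."""
    return float(np.arange(state.n_max + 1) @ state.fractions)


def joint_mole_fractions_independent(nuc: BindingModel, lip: BindingModel,
                                     p_total: float, l_nuc_total: float,
                                     l_lip_total: float):
    """Joint (nucleotide i, lipid j) table under the independence null.

    Each ligand class is solved separately with its own depletion and the
    joint distribution is the outer product of the marginals — the null
    against which binding coupling is judged.
    """
    from .stoichiometry import StoichiometryTable  # avoid import cycle

    f_nuc = mole_fractions(nuc, p_total, l_nuc_total).fractions
    f_lip = mole_fractions(lip, p_total, l_lip_total).fractions
    return StoichiometryTable(ligands=("nucleotide", "lipid"),
                              fractions=np.outer(f_nuc, f_lip))
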