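"""Synthetic titrations, joint stoichiometry tables, and hydrolysis time courses.

Emulates the native-MS experiments the analysis consumes: a ~129 kDa
homodimeric transporter at 0.5 µM binding 0–2 nucleotides and 0–4 lipids,
titrated over micromolar nucleotide concentrations in biological
triplicate, with additive mole-fraction noise. Two phenomena seen in the
real data are reproduced with deliberately simple, single-parameter
mechanisms:

* lipid–nucleotide coupling — a bound lipid count j rescales the
  nucleotide stepwise K_D by exp(−α·j), so α > 0 makes high-lipid states
  favor nucleotide binding while α = 0 recovers exact independence;
* hydrolysis — the total ATP pool decays exponentially,
  ATP(t) = L₀·e^(−k_hyd·t), with ADP(t) = L₀ − ATP(t), and the bound-state
  distribution at each sampling time is the equilibrium for the current
  nucleotide totals (binding equilibrates much faster than turnover at
  the low temperature the time course emulates).

Noise is applied to mole fractions rather than raw intensities, because
that is the quantity the downstream analysis consumes; an intensity-level
path exists through :mod:`msbind.spectra`. One top-level seed determines
every output, with an independent substream per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import numpy.typing as npt

from .binding import BindingModel, _fractions_at, mole_fractions
from .exceptions import InvalidInputError
from .fitting import TitrationPoint, TitrationSeries
from .stoichiometry import StoichiometryTable

__all__ = [
    "GeneratorConfig",
    "JointCondition",
    "TimePointTables",
    "generate_titration",
    "joint_equilibrium_table",
    "generate_joint_dataset",
    "generate_timecourse",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters and experimental design for the generator.

    Defaults mirror the emulated experiments: 0.5 µM dimer; stepwise
    nucleotide K_Ds at the fitted ATP (47.8, 124.4 µM) and ADP
    (17.8, 62.3 µM) values; four sub-to-low-µM lipid sites (a tight
    binder at 1 µM total is strongly depleted); triplicates with 3%
    additive mole-fraction noise; and a 10 h time course sampled every
    2 h with 50 µM ATP and 1 µM lipid. ``k_hyd`` defaults to ln2/6 h⁻¹
    (half the ATP hydrolyzed by 6 h, the regime where ADP-bound states
    become prominent mid-course).
    """

    kd_nuc: tuple[float, ...] = (47.8, 124.4)   # µM, titrated nucleotide (ATP-like)
    kd_adp: tuple[float, ...] = (17.8, 62.3)    # µM, hydrolysis product
    kd_lip: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0)  # µM, sequential lipid sites
    p_total: float = 0.5                         # µM dimer
    l_grid: tuple[float, ...] | None = None      # µM; default spans 0.1×–4× max K_D
    l_lip_grid: tuple[float, ...] = (0.0, 1.0, 3.0)  # µM lipid conditions
    l_nuc_total: float = 50.0                    # µM, joint/time-course nucleotide
    l_lip_total: float = 1.0                     # µM, time-course lipid
    replicates: int = 3
    noise_sd: float = 0.03                       # additive, mole-fraction units
    alpha: float = 0.0                           # lipid→nucleotide coupling
    k_hyd: float = float(np.log(2) / 6.0)        # h⁻¹
    times: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)  # h
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")
        if self.k_hyd < 0:
            raise InvalidInputError("k_hyd must be >= 0")
        t = np.asarray(self.times)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be non-negative and increasing")
        if self.l_grid is None:
            hi = max(self.kd_nuc)
            grid = tuple(np.geomspace(0.1 * hi, 4.0 * hi, 8).round(3))
            object.__setattr__(self, "l_grid", grid)

    @property
    def nuc_model(self) -> BindingModel:
        return BindingModel.from_kd(self.kd_nuc)

    @property
    def adp_model(self) -> BindingModel:
        return BindingModel.from_kd(self.kd_adp)

    @property
    def lip_model(self) -> BindingModel:
        return BindingModel.from_kd(self.kd_lip)

    def _replicate_rngs(self) -> list[np.random.Generator]:
        seqs = np.random.SeedSequence(self.seed).spawn(self.replicates)
        return [np.random.default_rng(s) for s in seqs]


def _noisy_fractions(f: npt.NDArray, rng: np.random.Generator,
                     noise_sd: float) -> npt.NDArray:
    """Additive Gaussian noise, clipped at 0 and renormalized."""
    if noise_sd == 0:
        return f.copy()
    g = np.clip(f + rng.normal(0.0, noise_sd, size=f.shape), 0.0, None)
    total = g.sum()
    if total == 0:  # pathological draw; keep the noiseless truth
        return f.copy()
    return g / total


def generate_titration(config: GeneratorConfig) -> TitrationSeries:
    """Noisy triplicate titration of the nucleotide against the dimer."""
    model = config.nuc_model
    points: list[TitrationPoint] = []
    for r, rng in enumerate(config._replicate_rngs(), start=1):
        for l_total in config.l_grid:
            f_true = mole_fractions(model, config.p_total, float(l_total)).fractions
            f = _noisy_fractions(f_true, rng, config.noise_sd)
            points.append(TitrationPoint(p_total=config.p_total,
                                         l_total=float(l_total),
                                         f_obs=f, replicate=f"rep{r}"))
    return TitrationSeries(ligand="nucleotide", points=tuple(points),
                           n_max=model.n_max)


def _coupled_nuc_models(nuc: BindingModel, alpha: float,
                        n_lip: int) -> list[BindingModel]:
    """Nucleotide model conditional on each lipid count j: K_D scaled by e^(−αj)."""
    return [BindingModel(k_a=nuc.k_a * np.exp(alpha * j)) for j in range(n_lip + 1)]


def joint_equilibrium_table(nuc: BindingModel, lip: BindingModel,
                            p_total: float, l_nuc_total: float,
                            l_lip_total: float, alpha: float = 0.0,
                            ligands: tuple[str, str] = ("ATP", "KDL"),
                            ) -> StoichiometryTable:
    """Noise-free joint (nucleotide, lipid) equilibrium with coupling α.

    The lipid marginal is solved with its own depletion; conditional on a
    lipid count j the nucleotide stepwise K_Ds are scaled by exp(−α·j),
    and the free nucleotide concentration is solved self-consistently
    against the lipid-state mixture. α = 0 reduces exactly to the outer
    product of the independently solved marginals.
    """
    f_lip = mole_fractions(lip, p_total, l_lip_total).fractions
    cond_models = _coupled_nuc_models(nuc, alpha, lip.n_max)
    counts = np.arange(nuc.n_max + 1)

    def bound_nuc(x: float) -> float:
        return sum(
            fj * float(_fractions_at(m._beta, np.array([x]))[0] @ counts)
            for fj, m in zip(f_lip, cond_models))

    lo, hi = 0.0, l_nuc_total
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if mid + p_total * bound_nuc(mid) > l_nuc_total:
            hi = mid
        else:
            lo = mid
    x = 0.5 * (lo + hi)

    table = np.column_stack([
        fj * _fractions_at(m._beta, np.array([x]))[0]
        for fj, m in zip(f_lip, cond_models)])
    return StoichiometryTable(ligands=ligands, fractions=table / table.sum())


@dataclass(frozen=True)
class JointCondition:
    """One generated joint table with its lipid condition."""

    l_lip_total: float
    replicate: str
    table: StoichiometryTable


def generate_joint_dataset(config: GeneratorConfig) -> list[JointCondition]:
    """Joint nucleotide×lipid tables over the lipid-concentration grid."""
    out: list[JointCondition] = []
    for r, rng in enumerate(config._replicate_rngs(), start=1):
        for l_lip in config.l_lip_grid:
            truth = joint_equilibrium_table(
                config.nuc_model, config.lip_model, config.p_total,
                config.l_nuc_total, float(l_lip), alpha=config.alpha)
            f = _noisy_fractions(truth.fractions, rng, config.noise_sd)
            out.append(JointCondition(
                l_lip_total=float(l_lip), replicate=f"rep{r}",
                table=StoichiometryTable(ligands=truth.ligands,
                                         fractions=f / f.sum(),
                                         replicate=f"rep{r}")))
    return out


# ---------------------------------------------------------------------------
# hydrolysis time course: competitive ATP/ADP occupancy of the two sites
# ---------------------------------------------------------------------------

def _competitive_weights(k_atp: npt.NDArray, k_adp: npt.NDArray,
                         x_atp: float, x_adp: float) -> dict[tuple[int, int], float]:
    """Partition-function weights W(a, b) for a ATP + b ADP bound.

    Sites fill sequentially; a species' weight sums the per-step
    association constants over every binding order (path-summed
    sequential scheme). Reduces to the single-ligand sequential model
    when the other ligand's free concentration is zero.
    """
    n_max = k_atp.size
    weights: dict[tuple[int, int], float] = {(0, 0): 1.0}
    # sequences of ligand identities, one per filled step
    for n in range(1, n_max + 1):
        for seq in product((0, 1), repeat=n):
            w = 1.0
            for step, lig in enumerate(seq):
                w *= (k_atp[step] * x_atp) if lig == 0 else (k_adp[step] * x_adp)
            key = (n - sum(seq), sum(seq))  # (a ATP, b ADP)
            weights[key] = weights.get(key, 0.0) + w
    return weights


def _competitive_fractions(k_atp: npt.NDArray, k_adp: npt.NDArray,
                           x_atp: float, x_adp: float) -> dict[tuple[int, int], float]:
    w = _competitive_weights(k_atp, k_adp, x_atp, x_adp)
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def _solve_competitive(f_lip: npt.NDArray, k_atp_by_j: list[npt.NDArray],
                       k_adp: npt.NDArray, p_total: float,
                       atp_total: float, adp_total: float,
                       iters: int = 60) -> tuple[float, float]:
    """Free (ATP, ADP) concentrations by nested bisection on mass balance."""

    def bound(x_atp: float, x_adp: float) -> tuple[float, float]:
        b_atp = b_adp = 0.0
        for fj, k_atp in zip(f_lip, k_atp_by_j):
            frac = _competitive_fractions(k_atp, k_adp, x_atp, x_adp)
            b_atp += fj * sum(a * f for (a, _), f in frac.items())
            b_adp += fj * sum(b * f for (_, b), f in frac.items())
        return b_atp, b_adp

    def solve_adp(x_atp: float) -> float:
        lo, hi = 0.0, adp_total
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            if mid + p_total * bound(x_atp, mid)[1] > adp_total:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    lo, hi = 0.0, atp_total
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        x_adp = solve_adp(mid)
        if mid + p_total * bound(mid, x_adp)[0] > atp_total:
            hi = mid
        else:
            lo = mid
    x_atp = 0.5 * (lo + hi)
    return x_atp, solve_adp(x_atp)


@dataclass(frozen=True)
class TimePointTables:
    """Equilibrium snapshot of one replicate at one sampling time."""

    time_h: float
    replicate: str
    atp_table: StoichiometryTable   # (ATP count, lipid count), ADP marginalized
    adp_table: StoichiometryTable   # (ADP count, lipid count), ATP marginalized
    atp_total: float                # µM remaining ATP
    adp_total: float                # µM accumulated ADP


def generate_timecourse(config: GeneratorConfig) -> list[TimePointTables]:
    """Hydrolysis time course of joint stoichiometry tables.

    The ATP pool decays as L₀·e^(−k_hyd·t) and the released ADP competes
    for the same two sites (ADP binds tighter, matching the measured
    stepwise constants). Coupling α rescales the ATP stepwise K_Ds by
    lipid count, reproducing the lipid-driven ATP selectivity pattern;
    ADP affinity is left unmodulated. Returns one entry per
    (time, replicate), each holding the (nucleotide, lipid) table with
    the other nucleotide marginalized out.
    """
    lip = config.lip_model
    f_lip = mole_fractions(lip, config.p_total, config.l_lip_total).fractions
    k_atp_by_j = [m.k_a for m in
                  _coupled_nuc_models(config.nuc_model, config.alpha, lip.n_max)]
    k_adp = config.adp_model.k_a
    n_nuc = config.nuc_model.n_max
    l0 = config.l_nuc_total

    out: list[TimePointTables] = []
    for r, rng in enumerate(config._replicate_rngs(), start=1):
        for t in config.times:
            atp_t = l0 * float(np.exp(-config.k_hyd * t))
            adp_t = l0 - atp_t
            x_atp, x_adp = _solve_competitive(
                f_lip, k_atp_by_j, k_adp, config.p_total, atp_t, adp_t)
            # joint over (a ATP, b ADP, j lipid), then marginalize
            atp_tab = np.zeros((n_nuc + 1, lip.n_max + 1))
            adp_tab = np.zeros((n_nuc + 1, lip.n_max + 1))
            for j, fj in enumerate(f_lip):
                frac = _competitive_fractions(k_atp_by_j[j], k_adp, x_atp, x_adp)
                for (a, b), f in frac.items():
                    atp_tab[a, j] += fj * f
                    adp_tab[b, j] += fj * f
            atp_tab = _noisy_fractions(atp_tab, rng, config.noise_sd)
            adp_tab = _noisy_fractions(adp_tab, rng, config.noise_sd)
            out.append(TimePointTables(
                time_h=float(t), replicate=f"rep{r}",
                atp_table=StoichiometryTable(("ATP", "KDL"), atp_tab / atp_tab.sum(),
                                             time_h=float(t), replicate=f"rep{r}"),
                adp_table=StoichiometryTable(("ADP", "KDL"), adp_tab / adp_tab.sum(),
                                             time_h=float(t), replicate=f"rep{r}"),
                atp_total=atp_t, adp_total=adp_t))
    return out
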