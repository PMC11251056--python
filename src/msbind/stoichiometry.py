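"""Joint stoichiometry tables and time-course tracking.

A :class:`StoichiometryTable` is the joint distribution of the protein over
counts of two ligand classes — e.g. nucleotide count i = 0..2 against lipid
count j = 0..4 at one condition or time point. ``track_stoichiometry``
extracts mole-fraction traces for selected cells (``"ATP=2,KDL=*"``) across
a time series, and ``summarize_replicates`` reduces replicate traces to
mean ± SD, mirroring how replicate native-MS time courses are reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt
import pandas as pd

from .exceptions import AlignmentError, EmptySelectionError, InvalidInputError

__all__ = [
    "StoichiometryTable",
    "parse_selector",
    "track_stoichiometry",
    "summarize_replicates",
]

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class StoichiometryTable:
    """Joint mole fractions F(i, j) over two ligand-count axes.

    ``fractions[i, j]`` is the fraction of protein bound to i copies of
    ``ligands[0]`` and j copies of ``ligands[1]``; the table sums to 1.
    """

    ligands: tuple[str, str]
    fractions: npt.NDArray[np.float64] = field(repr=False)
    time_h: float | None = None
    replicate: str | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 2:
            raise InvalidInputError("fractions must be a 2-D (i, j) array")
        if np.any(f < -1e-12):
            raise InvalidInputError("mole fractions must be non-negative")
        if abs(f.sum() - 1.0) > _SUM_TOL:
            raise InvalidInputError(
                f"table must sum to 1 within {_SUM_TOL} (got {f.sum():.8f})")
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "ligands", tuple(self.ligands))

    @property
    def shape(self) -> tuple[int, int]:
        return self.fractions.shape

    def marginal(self, ligand: str) -> npt.NDArray[np.float64]:
        """Marginal count distribution of one ligand class."""
        axis = 1 - self._axis_of(ligand)
        return self.fractions.sum(axis=axis)

    def _axis_of(self, ligand: str) -> int:
        try:
            return self.ligands.index(ligand)
        except ValueError:
            raise EmptySelectionError(
                f"ligand {ligand!r} not in table axes {self.ligands}") from None

    def cell_label(self, i: int, j: int) -> str:
        return f"{self.ligands[0]}{i}_{self.ligands[1]}{j}"

    def to_frame(self) -> pd.DataFrame:
        """Rows = first-axis counts, columns = second-axis counts."""
        n_i, n_j = self.shape
        return pd.DataFrame(
            self.fractions,
            index=pd.Index(range(n_i), name=self.ligands[0]),
            columns=pd.Index(range(n_j), name=self.ligands[1]),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ligands: tuple[str, str],
                   time_h: float | None = None,
                   replicate: str | None = None) -> "StoichiometryTable":
        return cls(ligands=ligands, fractions=df.to_numpy(dtype=float),
                   time_h=time_h, replicate=replicate)


_SELECTOR_RE = re.compile(r"^\s*([A-Za-z][\w-]*)\s*=\s*(\*|\d+)\s*$")


def parse_selector(selector: str | dict[str, int | str]) -> dict[str, int | str]:
    """Parse ``"ATP=2,KDL=*"`` into ``{"ATP": 2, "KDL": "*"}``."""
    if isinstance(selector, dict):
        return {k: (v if v == "*" else int(v)) for k, v in selector.items()}
    out: dict[str, int | str] = {}
    for part in selector.split(","):
        m = _SELECTOR_RE.match(part)
        if m is None:
            raise InvalidInputError(
                f"bad selector clause {part!r}; expected LIGAND=k or LIGAND=*")
        out[m.group(1)] = "*" if m.group(2) == "*" else int(m.group(2))
    return out


def _matched_cells(table: StoichiometryTable,
                   sel: dict[str, int | str]) -> list[tuple[int, int]]:
    for lig in sel:
        table._axis_of(lig)  # validates ligand names
    n_i, n_j = table.shape
    cells = []
    for i in range(n_i):
        for j in range(n_j):
            counts = dict(zip(table.ligands, (i, j)))
            if all(v == "*" or counts[k] == v for k, v in sel.items()):
                cells.append((i, j))
    return cells


def track_stoichiometry(series: list[StoichiometryTable],
                        selector: str | dict[str, int | str]) -> pd.DataFrame:
    """Extract time traces for every table cell matching a selector.

    Returns a DataFrame indexed by time (h), one column per matched cell
    labelled ``<lig0><i>_<lig1><j>``. When a ligand class is omitted from
    the selector it is marginalized by summation, and the returned
    columns are labelled by the mentioned classes only. Time points absent
    from ``series`` are simply absent from the index (gaps, never zeros).
    """
    if not series:
        raise InvalidInputError("empty table series")
    axes = series[0].ligands
    if any(t.ligands != axes or t.shape != series[0].shape for t in series):
        raise AlignmentError("all tables must share ligand axes and shape")
    sel = parse_selector(selector)
    for lig in sel:
        series[0]._axis_of(lig)  # unknown ligand names fail here
    full_sel = {lig: sel.get(lig, "*") for lig in axes}
    cells = _matched_cells(series[0], full_sel)
    if not cells:
        raise EmptySelectionError(f"selector {selector!r} matched no cell")

    mentioned = [lig for lig in sel if lig in axes]  # selector order, axes-agnostic
    marginalized = [lig for lig in axes if lig not in sel]

    def label(i: int, j: int) -> str:
        counts = dict(zip(axes, (i, j)))
        return "_".join(f"{lig}{counts[lig]}" for lig in mentioned) or "total"

    rows: dict[float, dict[str, float]] = {}
    for t in series:
        key = t.time_h if t.time_h is not None else 0.0
        if key in rows:
            raise AlignmentError(
                f"duplicate time point {key} h; track one replicate at a time")
        row = rows[key] = {}
        for (i, j) in cells:
            lab = label(i, j)
            # summing duplicate labels marginalizes the unmentioned classes
            row[lab] = row.get(lab, 0.0) + t.fractions[i, j]
    if marginalized:
        labels = sorted({label(i, j) for (i, j) in cells})
    else:
        labels = [label(i, j) for (i, j) in cells]
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=labels)
    df.index.name = "time_h"
    return df.sort_index()


def summarize_replicates(traces: dict[str, pd.DataFrame]
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pointwise mean and sample SD (n−1) across replicate trace frames.

    Replicate frames must share identical time grids and columns; no
    interpolation is attempted — misalignment raises.
    """
    if len(traces) < 2:
        raise InvalidInputError("need >= 2 replicates to summarize")
    frames = list(traces.values())
    ref = frames[0]
    for name, df in traces.items():
        if not df.index.equals(ref.index) or list(df.columns) != list(ref.columns):
            raise AlignmentError(
                f"replicate {name!r} time grid/columns differ; exact alignment required")
    stack = np.stack([df.to_numpy(dtype=float) for df in frames])
    mean = pd.DataFrame(stack.mean(axis=0), index=ref.index, columns=ref.columns)
    sd = pd.DataFrame(stack.std(axis=0, ddof=1), index=ref.index, columns=ref.columns)
    return mean, sd
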