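"""CSV/JSON schemas and atomic, provenance-stamped file output.

Fixed schemas:

* titration CSV — columns ``replicate, P_total_uM, L_total_uM, F0..Fn``;
* joint-table CSV — rows = nucleotide count, columns = lipid count;
* time-course CSV — ``time_h, replicate`` plus one column per
  stoichiometry label (e.g. ``ATP2_KDL3``);
* spectrum — two-column whitespace/CSV text (m/z, intensity);
* species config and fit reports — JSON.

Every writer goes through a temp-file + rename so partial outputs are
never left behind, and prepends ``#``-comment header lines carrying the
seed and a config hash sufficient to regenerate the file. Readers skip
``#`` comments.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .fitting import FitResult, TitrationPoint, TitrationSeries
from .spectra import MassSpectrum, SpeciesDefinition
from .stoichiometry import StoichiometryTable

__all__ = [
    "config_hash",
    "atomic_write_text",
    "write_titration_csv",
    "read_titration_csv",
    "write_joint_table_csv",
    "read_joint_table_csv",
    "write_timecourse_csv",
    "read_timecourse_csv",
    "read_spectrum",
    "write_spectrum",
    "read_species_config",
    "write_species_config",
    "fit_report_dict",
    "write_fit_report",
]


def config_hash(obj: Any) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(meta: dict[str, Any] | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temporary file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# titration CSV
# ---------------------------------------------------------------------------

def titration_to_frame(series: TitrationSeries) -> pd.DataFrame:
    rows = []
    for p in series.points:
        row = {"replicate": p.replicate, "P_total_uM": p.p_total,
               "L_total_uM": p.l_total}
        row.update({f"F{i}": f for i, f in enumerate(p.f_obs)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_titration_csv(series: TitrationSeries, path: str | Path,
                        meta: dict[str, Any] | None = None) -> None:
    df = titration_to_frame(series)
    atomic_write_text(path, _header_lines(meta) + df.to_csv(index=False))


def read_titration_csv(path: str | Path, ligand: str = "ligand") -> TitrationSeries:
    df = pd.read_csv(path, comment="#")
    required = ["replicate", "P_total_uM", "L_total_uM"]
    missing = [c for c in required if c not in df.columns]
    f_cols = sorted((c for c in df.columns if c.startswith("F") and c[1:].isdigit()),
                    key=lambda c: int(c[1:]))
    expected_f = [f"F{i}" for i in range(len(f_cols))]
    if f_cols != expected_f or len(f_cols) < 2:
        missing.append("contiguous F0..Fn columns")
    if missing:
        raise SchemaError(f"{path}: missing/invalid columns: {', '.join(missing)}")
    points = []
    for idx, row in df.iterrows():
        try:
            points.append(TitrationPoint(
                p_total=float(row["P_total_uM"]),
                l_total=float(row["L_total_uM"]),
                f_obs=np.array([float(row[c]) for c in f_cols]),
                replicate=str(row["replicate"])))
        except (ValueError, TypeError) as err:
            raise SchemaError(f"{path}: row {idx + 1}: {err}") from err
    return TitrationSeries(ligand=ligand, points=tuple(points),
                           n_max=len(f_cols) - 1)


# ---------------------------------------------------------------------------
# joint stoichiometry table CSV (rows = first axis, columns = second axis)
# ---------------------------------------------------------------------------

def write_joint_table_csv(table: StoichiometryTable, path: str | Path,
                          meta: dict[str, Any] | None = None) -> None:
    meta = dict(meta or {})
    meta.setdefault("row_ligand", table.ligands[0])
    meta.setdefault("col_ligand", table.ligands[1])
    if table.time_h is not None:
        meta.setdefault("time_h", table.time_h)
    if table.replicate is not None:
        meta.setdefault("replicate", table.replicate)
    atomic_write_text(path, _header_lines(meta) + table.to_frame().to_csv())


def read_joint_table_csv(path: str | Path,
                         ligands: tuple[str, str] | None = None
                         ) -> StoichiometryTable:
    meta = _read_meta(path)
    if ligands is None:
        try:
            ligands = (meta["row_ligand"], meta["col_ligand"])
        except KeyError:
            raise SchemaError(
                f"{path}: ligand axis names absent from header; pass ligands=") from None
    df = pd.read_csv(path, comment="#", index_col=0)
    time_h = float(meta["time_h"]) if "time_h" in meta else None
    return StoichiometryTable(ligands=ligands, fractions=df.to_numpy(dtype=float),
                              time_h=time_h, replicate=meta.get("replicate"))


def _read_meta(path: str | Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


# ---------------------------------------------------------------------------
# time-course CSV
# ---------------------------------------------------------------------------

def write_timecourse_csv(tables: list[StoichiometryTable], path: str | Path,
                         meta: dict[str, Any] | None = None) -> None:
    """Flatten (time, replicate) tables into one row per time point."""
    if not tables:
        raise SchemaError("no tables to write")
    rows = []
    for t in tables:
        row: dict[str, Any] = {"time_h": t.time_h,
                               "replicate": t.replicate or "rep1"}
        n_i, n_j = t.shape
        for i in range(n_i):
            for j in range(n_j):
                row[t.cell_label(i, j)] = t.fractions[i, j]
        rows.append(row)
    df = pd.DataFrame(rows)
    atomic_write_text(path, _header_lines(meta) + df.to_csv(index=False))


def read_timecourse_csv(path: str | Path,
                        ligands: tuple[str, str]) -> list[StoichiometryTable]:
    df = pd.read_csv(path, comment="#")
    for col in ("time_h", "replicate"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    cells = []
    for c in df.columns:
        parts = c.split("_")
        if (len(parts) == 2 and parts[0].startswith(ligands[0])
                and parts[1].startswith(ligands[1])):
            cells.append((c, int(parts[0][len(ligands[0]):]),
                          int(parts[1][len(ligands[1]):])))
    if not cells:
        raise SchemaError(f"{path}: no {ligands[0]}i_{ligands[1]}j columns found")
    n_i = max(i for _, i, _ in cells) + 1
    n_j = max(j for _, _, j in cells) + 1
    out = []
    for _, row in df.iterrows():
        f = np.zeros((n_i, n_j))
        for c, i, j in cells:
            f[i, j] = float(row[c])
        out.append(StoichiometryTable(ligands=ligands, fractions=f,
                                      time_h=float(row["time_h"]),
                                      replicate=str(row["replicate"])))
    return out


# ---------------------------------------------------------------------------
# spectra and species config
# ---------------------------------------------------------------------------

def read_spectrum(path: str | Path) -> MassSpectrum:
    """Two-column (m/z, intensity) whitespace- or comma-delimited text.

    ``#`` comment lines and an optional one-line text header are skipped.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         header=None, skip_blank_lines=True)
    except (ValueError, pd.errors.ParserError) as err:
        raise SchemaError(f"{path}: cannot parse spectrum: {err}") from err
    first = df.iloc[0]
    if not np.issubdtype(np.asarray(first).dtype, np.number):
        df = df.iloc[1:]  # column-name header
    try:
        arr = df.to_numpy(dtype=float)
    except ValueError as err:
        raise SchemaError(f"{path}: non-numeric spectrum values: {err}") from err
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise SchemaError(f"{path}: expected two columns (m/z, intensity)")
    order = np.argsort(arr[:, 0])
    return MassSpectrum(mz=arr[order, 0], intensity=arr[order, 1])


def write_spectrum(spectrum: MassSpectrum, path: str | Path,
                   meta: dict[str, Any] | None = None) -> None:
    body = "\n".join(f"{mz:.6f},{i:.8g}"
                     for mz, i in zip(spectrum.mz, spectrum.intensity))
    atomic_write_text(path, _header_lines(meta) + "mz,intensity\n" + body + "\n")


def read_species_config(path: str | Path) -> SpeciesDefinition:
    """JSON with ``base_mass_Da`` and per-ligand ``mass_Da``/``max_count``."""
    cfg = json.loads(Path(path).read_text())
    try:
        ligands = cfg["ligands"]
        return SpeciesDefinition(
            base_mass=float(cfg["base_mass_Da"]),
            ligand_masses={n: float(v["mass_Da"]) for n, v in ligands.items()},
            max_counts={n: int(v["max_count"]) for n, v in ligands.items()})
    except (KeyError, TypeError, ValueError) as err:
        raise SchemaError(f"{path}: bad species config: {err}") from err


def write_species_config(species: SpeciesDefinition, path: str | Path) -> None:
    cfg = {"base_mass_Da": species.base_mass,
           "ligands": {n: {"mass_Da": species.ligand_masses[n],
                           "max_count": species.max_counts[n]}
                       for n in species.ligand_names}}
    atomic_write_text(path, json.dumps(cfg, indent=2) + "\n")


# ---------------------------------------------------------------------------
# fit reports
# ---------------------------------------------------------------------------

def fit_report_dict(result: FitResult, settings: dict[str, Any] | None = None
                    ) -> dict[str, Any]:
    rep = {
        "KD_uM": [float(x) for x in result.k_d],
        "KD_sd_uM": ([float(x) for x in result.k_d_sd]
                     if result.k_d_sd is not None else None),
        "per_replicate_KD_uM": {r: [float(x) for x in v]
                                for r, v in result.per_replicate.items()},
        "chi2": result.chi2,
        "converged": result.converged,
        "n_iter": result.n_iter,
        "mode": result.mode,
    }
    if settings:
        rep["settings"] = settings
    return rep


def write_fit_report(result: FitResult, path: str | Path,
                     settings: dict[str, Any] | None = None) -> None:
    atomic_write_text(path, json.dumps(fit_report_dict(result, settings),
                                       indent=2) + "\n")
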