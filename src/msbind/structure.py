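"""NBD-separation metric for ABC-transporter conformations.

The degree of opening of an ABC transporter's inward-facing conformation
is summarized by one number: the Cα–Cα distance of a marker residue in
the nucleotide-binding domain (NBD), measured across the two chains of
the homodimer (for MsbA, residue T561). Structures can then be ranked
from most open (largest separation) to most closed.

Coordinates are read with gemmi from mmCIF or legacy PDB files; author
residue numbering is used throughout, matching how marker residues are
quoted in the literature. Only the first model of multi-model files is
considered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, LookupFailure

__all__ = [
    "StructureModel",
    "load_structure",
    "residue_pair_distance",
    "rank_by_separation",
]


@dataclass(frozen=True)
class StructureModel:
    """A parsed coordinate file (first model only)."""

    label: str
    model: gemmi.Model

    @property
    def chain_names(self) -> list[str]:
        return [ch.name for ch in self.model]


def load_structure(path: str | Path, label: str | None = None) -> StructureModel:
    """Read an mmCIF or PDB file; the format is detected from the content."""
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise InvalidInputError(f"{path}: no models found")
    return StructureModel(label=label or path.stem, model=st[0])


def _find_atom(model: gemmi.Model, chain_name: str, residue_number: int,
               atom_name: str, label: str) -> np.ndarray:
    chain = model.find_chain(chain_name)
    if chain is None:
        raise LookupFailure(f"{label}: chain {chain_name!r} not found")
    residues = [r for r in chain if r.seqid.num == residue_number]
    if not residues:
        raise LookupFailure(
            f"{label}: residue {residue_number} not found in chain {chain_name!r}")
    atoms = [a for r in residues for a in r if a.name == atom_name]
    if not atoms:
        raise LookupFailure(
            f"{label}: atom {atom_name!r} not found in {chain_name}/{residue_number}")
    # altloc resolution: highest occupancy, ties broken toward altloc 'A'
    atom = min(atoms, key=lambda a: (-a.occ, a.altloc or "A"))
    pos = atom.pos
    xyz = np.array([pos.x, pos.y, pos.z])
    if not np.all(np.isfinite(xyz)):
        raise InvalidInputError(f"{label}: non-finite coordinates")
    return xyz


def _auto_chains(model: gemmi.Model, residue_number: int, atom_name: str,
                 label: str) -> tuple[str, str]:
    """The two chains of a C2-symmetric dimer carrying the marker residue."""
    hits = []
    for chain in model:
        if any(r.seqid.num == residue_number and any(a.name == atom_name for a in r)
               for r in chain):
            hits.append(chain.name)
    if len(hits) != 2:
        raise LookupFailure(
            f"{label}: expected the marker residue {residue_number}/{atom_name} "
            f"in exactly 2 chains, found it in {hits or 'none'}; "
            "pass explicit chain names")
    return hits[0], hits[1]


def residue_pair_distance(structure: StructureModel | str | Path,
                          residue_number: int,
                          atom_name: str = "CA",
                          chain_a: str | None = None,
                          chain_b: str | None = None) -> float:
    """Inter-chain distance (Å) between the named atoms of one residue.

    With no explicit chains, the two chains containing the residue are
    auto-detected (homodimer assumption). Symmetric in chain order.
    """
    if not isinstance(structure, StructureModel):
        structure = load_structure(structure)
    model, label = structure.model, structure.label
    if (chain_a is None) != (chain_b is None):
        raise InvalidInputError("pass both chain names or neither")
    if chain_a is None:
        chain_a, chain_b = _auto_chains(model, residue_number, atom_name, label)
    xyz_a = _find_atom(model, chain_a, residue_number, atom_name, label)
    xyz_b = _find_atom(model, chain_b, residue_number, atom_name, label)
    return float(np.linalg.norm(xyz_a - xyz_b))


def rank_by_separation(structures: list[StructureModel | str | Path],
                       residue_number: int,
                       atom_name: str = "CA") -> pd.DataFrame:
    """Rank structures by marker-residue separation, most open first.

    Returns a DataFrame with columns ``label``, ``distance_A`` and
    ``rank`` (1 = largest separation); ties keep input order. Lookup
    errors are re-raised annotated with the structure label.
    """
    if not structures:
        raise InvalidInputError("no structures given")
    rows = []
    for s in structures:
        sm = s if isinstance(s, StructureModel) else load_structure(s)
        try:
            d = residue_pair_distance(sm, residue_number, atom_name)
        except LookupFailure as err:
            raise LookupFailure(f"[{sm.label}] {err}") from err
        rows.append({"label": sm.label, "distance_A": d})
    df = pd.DataFrame(rows)
    # stable sort preserves input order on exact ties
    df = df.sort_values("distance_A", ascending=False, kind="stable")
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)
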