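"""Structural metrics: superposition RMSD, SASA, burial, distances.

These are the calculations used to interpret the tryptophan-probe
fluorescence in structural terms: how similar a probe-carrying mutant is to
the wild-type C1 ring (backbone RMSD after optimal superposition), how
solvent-exposed a tryptophan is in the monomer versus the hexamer
(Shrake-Rupley SASA and interface burial), and how far a probe site sits
from bound KaiB or from candidate quenchers (minimum atom distances).

Structures are parsed with biotite (PDB and mmCIF); author residue numbering
is preserved verbatim.  The Kabsch superposition itself is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io import pdbx

from .errors import StructureError, ValidationError

#: Backbone heavy atoms used for superposition by default.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Van der Waals radii (A) for SASA; single-atom radii (Bondi-style).
#: Unknown elements raise unless an override is supplied.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

DEFAULT_PROBE_RADIUS = 1.4  # A, water probe
DEFAULT_POINT_NUMBER = 960  # sphere sample points per atom

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class StructureModel:
    """Parsed atomic coordinates with chain/residue identity.

    Thin wrapper around a biotite ``AtomArray``; alternate locations are
    resolved to the highest-occupancy conformer at load time, waters are
    retained but flagged.
    """

    atoms: "struc.AtomArray"
    source: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.atoms.coord)):
            raise StructureError(f"non-finite coordinates in {self.source or 'structure'}")

    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.atoms.res_name, list(_WATER_NAMES))

    def chains(self) -> list[str]:
        seen = []
        for c in self.atoms.chain_id:
            if c not in seen:
                seen.append(c)
        return seen

    def subset(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(atoms=self.atoms[mask], source=self.source)

    def chain(self, chain_id: str) -> "StructureModel":
        mask = self.atoms.chain_id == chain_id
        if not mask.any():
            raise StructureError(
                f"chain {chain_id!r} not found in {self.source or 'structure'} "
                f"(available: {self.chains()})"
            )
        return self.subset(mask)


def load_structure(path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Format is inferred from the suffix (.pdb/.ent -> PDB, .cif/.mmcif ->
    mmCIF) unless given explicitly.  Only the first model is read; altlocs
    are resolved by occupancy.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in (".pdb", ".ent"):
            fmt = "PDB"
        elif suffix in (".cif", ".mmcif", ".pdbx"):
            fmt = "mmCIF"
        else:
            raise StructureError(
                f"cannot infer format from suffix {suffix!r}; pass fmt='PDB' or 'mmCIF'"
            )
    try:
        if fmt == "PDB":
            atoms = PDBFile.read(str(path)).get_structure(model=1, altloc="occupancy")
        elif fmt == "mmCIF":
            atoms = pdbx.get_structure(pdbx.CIFFile.read(str(path)), model=1, altloc="occupancy")
        else:
            raise StructureError(f"unknown format {fmt!r}; expected 'PDB' or 'mmCIF'")
    except StructureError:
        raise
    except Exception as exc:
        raise StructureError(f"failed to parse {path} as {fmt}: {exc}") from exc
    return StructureModel(atoms=atoms, source=str(path))


def write_structure(model: StructureModel, path) -> None:
    """Write to PDB or mmCIF, chosen by suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        f = PDBFile()
        f.set_structure(model.atoms)
        f.write(str(path))
    elif suffix in (".cif", ".mmcif"):
        f = pdbx.CIFFile()
        pdbx.set_structure(f, model.atoms)
        f.write(str(path))
    else:
        raise StructureError(f"cannot infer output format from suffix {suffix!r}")


def _atom_key_table(model: StructureModel, atom_names=None, chain_map=None):
    a = model.atoms
    keys = {}
    for i in range(a.array_length()):
        if atom_names is not None and a.atom_name[i] not in atom_names:
            continue
        chain = a.chain_id[i]
        if chain_map is not None:
            if chain not in chain_map:
                continue
            chain = chain_map[chain]
        ins = a.ins_code[i] if "ins_code" in a.get_annotation_categories() else ""
        keys[(chain, int(a.res_id[i]), str(ins), str(a.atom_name[i]))] = i
    return keys


def kabsch_superpose(P: np.ndarray, Q: np.ndarray):
    """Optimal rigid superposition of P onto Q (least-squares, SVD form).

    Returns (rotation 3x3, translation 3, rmsd).  The rotation is proper
    (det = +1); reflections are excluded by the usual sign correction.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] == 0:
        raise ValidationError("point sets must be nonempty (n, 3) arrays of equal shape")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (R @ P.T).T + t - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def kabsch_rmsd(
    a: StructureModel,
    b: StructureModel,
    atom_names=BACKBONE_ATOMS,
    chain_map: dict | None = None,
):
    """Backbone (or custom-selection) RMSD after optimal superposition.

    Atoms are paired by (chain, residue number, insertion code, atom name)
    over the residues common to both structures.  ``chain_map`` maps chains
    of ``a`` onto chains of ``b``; by default the first chain of each file is
    paired (the single-protomer comparison).
    """
    if chain_map is None:
        chain_map = {a.chains()[0]: b.chains()[0]}
    keys_a = _atom_key_table(a, atom_names, chain_map=chain_map)
    keys_b = _atom_key_table(b, atom_names, chain_map=None)
    common = sorted(set(keys_a) & set(keys_b))
    if not common:
        raise StructureError(
            f"no common atoms under chain mapping {chain_map} and selection "
            f"{tuple(atom_names) if atom_names else 'all atoms'}"
        )
    P = a.atoms.coord[[keys_a[k] for k in common]]
    Q = b.atoms.coord[[keys_b[k] for k in common]]
    return kabsch_superpose(P, Q)


@dataclass
class SASAResult:
    """Per-residue solvent-accessible surface area (A^2)."""

    table: pd.DataFrame  # chain_id, res_id, res_name, sasa_A2
    probe_radius: float
    point_number: int

    def residue(self, chain_id: str, res_id: int) -> float:
        m = (self.table.chain_id == chain_id) & (self.table.res_id == res_id)
        if not m.any():
            raise StructureError(f"residue {chain_id}:{res_id} not in SASA table")
        return float(self.table.loc[m, "sasa_A2"].iloc[0])

    @property
    def total(self) -> float:
        return float(self.table.sasa_A2.sum())


def _radii_for(atoms, overrides: dict | None):
    radii = np.empty(atoms.array_length())
    for i, el in enumerate(atoms.element):
        key = str(el).upper()
        if overrides and key in overrides:
            radii[i] = overrides[key]
        elif key in VDW_RADII:
            radii[i] = VDW_RADII[key]
        else:
            raise StructureError(
                f"no van der Waals radius for element {el!r}; supply "
                "radius_overrides={'EL': radius}"
            )
    return radii


def residue_sasa(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    include_het: bool = False,
    point_number: int = DEFAULT_POINT_NUMBER,
    radius_overrides: dict | None = None,
) -> SASAResult:
    """Shrake-Rupley SASA summed per residue.

    Waters are always excluded; other heteroatoms (bound nucleotide, ions)
    are excluded by default and switched on with ``include_het`` — both modes
    matter when validating published burial numbers, since papers rarely
    state whether ligands were included.  Each atomic sphere is sampled with
    ``point_number`` quadrature points.
    """
    atoms = model.atoms
    keep = ~np.isin(atoms.res_name, list(_WATER_NAMES))
    if not include_het:
        keep &= ~atoms.hetero
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise StructureError("no atoms left after water/het filtering")
    radii = _radii_for(atoms, radius_overrides)
    per_atom = struc.sasa(
        atoms,
        probe_radius=probe_radius,
        point_number=point_number,
        vdw_radii=radii,
        ignore_ions=False,
    )
    per_atom = np.nan_to_num(per_atom, nan=0.0)
    df = pd.DataFrame(
        {
            "chain_id": atoms.chain_id,
            "res_id": atoms.res_id,
            "res_name": atoms.res_name,
            "sasa_A2": per_atom,
        }
    )
    table = (
        df.groupby(["chain_id", "res_id", "res_name"], sort=False, as_index=False)
        .sasa_A2.sum()
    )
    return SASAResult(table=table, probe_radius=probe_radius, point_number=point_number)


def assembly_burial(
    assembly: StructureModel,
    chain_id: str,
    res_id: int,
    **sasa_kwargs,
):
    """SASA of one residue in the isolated chain vs the full assembly.

    Returns (sasa_isolated, sasa_assembly, delta) in A^2 with
    delta = isolated - assembly >= 0 up to quadrature noise; both
    computations use identical settings.
    """
    chain = assembly.chain(chain_id)
    if not np.any(chain.atoms.res_id == res_id):
        raise StructureError(f"residue {res_id} absent from chain {chain_id}")
    iso = residue_sasa(chain, **sasa_kwargs).residue(chain_id, res_id)
    asm = residue_sasa(assembly, **sasa_kwargs).residue(chain_id, res_id)
    return iso, asm, iso - asm


def min_distance(
    model: StructureModel,
    from_atom: tuple,
    to,
) -> float:
    """Minimum Euclidean distance (A) from one atom to a target selection.

    ``from_atom`` is (chain_id, res_id, atom_name); ``to`` is either a chain
    id (string) or a boolean mask over the structure's atoms.
    """
    chain_id, res_id, atom_name = from_atom
    a = model.atoms
    src = (a.chain_id == chain_id) & (a.res_id == res_id) & (a.atom_name == atom_name)
    if not src.any():
        raise StructureError(f"source atom {chain_id}:{res_id}:{atom_name} not found")
    p = a.coord[src][0]
    if isinstance(to, str):
        mask = a.chain_id == to
        if not mask.any():
            raise StructureError(f"target chain {to!r} not found (available: {model.chains()})")
    else:
        mask = np.asarray(to, dtype=bool)
        if mask.shape != (a.array_length(),):
            raise ValidationError("target mask must cover all atoms")
        if not mask.any():
            raise StructureError("target selection is empty")
    d = np.linalg.norm(a.coord[mask] - p, axis=1)
    return float(d.min())
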