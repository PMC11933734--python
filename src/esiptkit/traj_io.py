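"""Reading and writing conformational ensembles and tabular results.

Ensembles are exchanged as multi-model PDB (fixed-column ATOM/HETATM records,
frames delimited by MODEL/ENDMDL) or XYZ trajectory files (repeated
``n_atoms / comment / element x y z`` blocks).  Coordinates are Angstrom
everywhere; no unit auto-detection is attempted.  Per-conformation
state-energy tables are delimited text with columns
``conformation_id, dE1, dE2, dE3`` where a missing energy is an empty field
or an em-dash.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SelectionError, TopologyError, ValidationError

__all__ = [
    "AtomRecord",
    "Conformation",
    "Ensemble",
    "EnergyRecord",
    "read_ensemble",
    "write_ensemble",
    "read_energy_table",
]

EnsembleFormat = Literal["pdb_multimodel", "xyz_trajectory"]

#: markers accepted for an absent energy value (besides an empty field)
MISSING_MARKERS = {"", "—", "–", "nan", "NaN"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame: identity plus cartesian coordinates in Å."""

    name: str
    element: str
    residue_name: str
    residue_index: int
    coordinates: np.ndarray  # shape (3,)


class Conformation:
    """Labeled atom records with 3D coordinates for one ensemble frame.

    Atom identity arrays are shared across all frames of one ensemble; only
    ``coordinates`` varies per frame.
    """

    def __init__(
        self,
        frame_index: int,
        atom_names: Sequence[str],
        elements: Sequence[str],
        residue_names: Sequence[str],
        residue_indices: Sequence[int],
        coordinates: np.ndarray,
    ):
        self.frame_index = int(frame_index)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        coords = np.asarray(coordinates, dtype=float)
        if coords.shape != (len(self.atom_names), 3):
            raise ValidationError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atom_names)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates must be finite")
        self.coordinates = coords
        self._index = _build_atom_index(self.residue_indices, self.atom_names)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                name=self.atom_names[i],
                element=self.elements[i],
                residue_name=self.residue_names[i],
                residue_index=int(self.residue_indices[i]),
                coordinates=self.coordinates[i],
            )
            for i in range(self.n_atoms)
        ]

    def atom_position(self, residue_index: int, atom_name: str) -> np.ndarray:
        """Coordinates of the atom identified by (residue_index, atom_name)."""
        return self.coordinates[self.atom_index(residue_index, atom_name)]

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        key = (int(residue_index), atom_name)
        if key not in self._index:
            raise SelectionError(f"no atom {atom_name!r} in residue {residue_index}")
        return self._index[key]


def _build_atom_index(residue_indices, atom_names) -> dict:
    index: dict = {}
    for i, (res, name) in enumerate(zip(residue_indices, atom_names)):
        key = (int(res), str(name))
        if key in index:
            raise ValidationError(
                f"atom name {name!r} is not unique within residue {res}"
            )
        index[key] = i
    return index


class Ensemble:
    """An ordered collection of conformations sharing one atom ordering."""

    def __init__(
        self,
        atom_names: Sequence[str],
        elements: Sequence[str],
        residue_names: Sequence[str],
        residue_indices: Sequence[int],
        coordinates: np.ndarray,  # (n_frames, n_atoms, 3)
        provenance: str = "",
    ):
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        coords = np.asarray(coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[1] != len(self.atom_names) or coords.shape[2] != 3:
            raise ValidationError(f"coordinate array has shape {coords.shape}")
        if coords.shape[0] < 1:
            raise ValidationError("an ensemble needs at least one frame")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates must be finite")
        self.coordinates = coords
        self.provenance = provenance
        self._index = _build_atom_index(self.residue_indices, self.atom_names)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    @property
    def topology_hash(self) -> str:
        h = hashlib.sha1()
        for name, elem, rname, ridx in zip(
            self.atom_names, self.elements, self.residue_names, self.residue_indices
        ):
            h.update(f"{name}|{elem}|{rname}|{ridx};".encode())
        return h.hexdigest()

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        key = (int(residue_index), atom_name)
        if key not in self._index:
            raise SelectionError(f"no atom {atom_name!r} in residue {residue_index}")
        return self._index[key]

    def frame(self, i: int) -> Conformation:
        return Conformation(
            frame_index=i,
            atom_names=self.atom_names,
            elements=self.elements,
            residue_names=self.residue_names,
            residue_indices=self.residue_indices,
            coordinates=self.coordinates[i],
        )

    @property
    def frames(self) -> list[Conformation]:
        return [self.frame(i) for i in range(self.n_frames)]

    @classmethod
    def from_conformations(
        cls, conformations: Sequence[Conformation], provenance: str = ""
    ) -> "Ensemble":
        if len(conformations) == 0:
            raise ValidationError("an ensemble needs at least one frame")
        first = conformations[0]
        for i, conf in enumerate(conformations):
            if conf.n_atoms != first.n_atoms or not (
                np.array_equal(conf.atom_names, first.atom_names)
                and np.array_equal(conf.residue_indices, first.residue_indices)
            ):
                raise TopologyError(f"frame {i} does not share the ensemble topology")
        coords = np.stack([c.coordinates for c in conformations])
        return cls(
            atom_names=first.atom_names,
            elements=first.elements,
            residue_names=first.residue_names,
            residue_indices=first.residue_indices,
            coordinates=coords,
            provenance=provenance,
        )


# ---------------------------------------------------------------------------
# PDB (multi-model), backed by biotite
# ---------------------------------------------------------------------------


def _prescan_pdb(lines: list[str]) -> None:
    """Cheap line-level validation so parse errors can name the line number."""
    counts: list[int] = []
    current: Optional[int] = None
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            current = 0
        elif rec == "ENDMDL":
            if current is not None:
                counts.append(current)
            current = None
        elif rec in ("ATOM", "HETATM"):
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"line {lineno}: truncated {rec} record")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: malformed coordinate field {line[lo:hi]!r}"
                    ) from None
            if current is not None:
                current += 1
            else:
                # single-model file without MODEL records
                if not counts:
                    counts.append(0)
                counts[0] += 1
    if current is not None and current > 0:
        counts.append(current)
    if len(set(counts)) > 1:
        raise TopologyError(f"inconsistent atom count across MODELs: {sorted(set(counts))}")


def _read_pdb(path: Path) -> Ensemble:
    from biotite.structure.io.pdb import PDBFile

    text = path.read_text()
    _prescan_pdb(text.splitlines())
    try:
        pdb = PDBFile.read(io.StringIO(text))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises several ad-hoc types
        raise ParseError(f"{path}: {exc}") from exc
    return Ensemble(
        atom_names=stack.atom_name,
        elements=[e.capitalize() for e in stack.element],
        residue_names=stack.res_name,
        residue_indices=stack.res_id,
        coordinates=np.asarray(stack.coord, dtype=float),
        provenance=f"read from {path}",
    )


def _write_pdb(ensemble: Ensemble, path: Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_frames, n_atoms = ensemble.n_frames, ensemble.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = ensemble.coordinates.astype(np.float32)
    stack.set_annotation("atom_name", ensemble.atom_names.astype("U6"))
    stack.set_annotation("element", np.array([e.upper() for e in ensemble.elements], dtype="U2"))
    stack.set_annotation("res_name", ensemble.residue_names.astype("U5"))
    stack.set_annotation("res_id", ensemble.residue_indices)
    stack.set_annotation("chain_id", np.full(n_atoms, "A", dtype="U4"))
    stack.set_annotation("hetero", np.ones(n_atoms, dtype=bool))
    stack.set_annotation("occupancy", np.ones(n_atoms))
    stack.set_annotation("b_factor", np.zeros(n_atoms))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# XYZ trajectory
# ---------------------------------------------------------------------------


def _read_xyz(path: Path) -> Ensemble:
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    elements: list[str] = []
    i = 0
    lineno = 0
    n_atoms_ref: Optional[int] = None
    while i < len(lines):
        if lines[i].strip() == "" and all(l.strip() == "" for l in lines[i:]):
            break  # trailing blank lines
        lineno = i + 1
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {lineno}: expected atom count, got {lines[i]!r}") from None
        if n_atoms_ref is None:
            n_atoms_ref = n_atoms
        elif n_atoms != n_atoms_ref:
            raise TopologyError(
                f"line {lineno}: frame has {n_atoms} atoms, expected {n_atoms_ref}"
            )
        block = lines[i + 2 : i + 2 + n_atoms]
        if len(block) < n_atoms:
            raise TopologyError(
                f"line {lineno}: frame block ends after {len(block)} of {n_atoms} atoms"
            )
        coords = np.empty((n_atoms, 3))
        frame_elements = []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"line {i + 3 + j}: malformed XYZ atom line {line!r}")
            try:
                coords[j] = [float(x) for x in parts[1:4]]
            except ValueError:
                raise ParseError(f"line {i + 3 + j}: non-numeric coordinate in {line!r}") from None
            frame_elements.append(parts[0])
        if not frames:
            elements = frame_elements
        elif frame_elements != elements:
            raise TopologyError(f"line {lineno}: element order differs from first frame")
        frames.append(coords)
        i += 2 + n_atoms
    if not frames:
        raise ParseError(f"{path}: no frames found")
    names = [f"{el}{k + 1}" for k, el in enumerate(elements)]
    return Ensemble(
        atom_names=names,
        elements=[el.capitalize() for el in elements],
        residue_names=["MOL"] * len(elements),
        residue_indices=[1] * len(elements),
        coordinates=np.stack(frames),
        provenance=f"read from {path}",
    )


def _write_xyz(ensemble: Ensemble, path: Path) -> None:
    with open(path, "w") as fh:
        for i in range(ensemble.n_frames):
            fh.write(f"{ensemble.n_atoms}\n")
            fh.write(f"frame {i}\n")
            for el, xyz in zip(ensemble.elements, ensemble.coordinates[i]):
                fh.write(f"{el:<3s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}\n")


# ---------------------------------------------------------------------------
# Public ensemble I/O
# ---------------------------------------------------------------------------


def read_ensemble(path, format: EnsembleFormat = "pdb_multimodel") -> Ensemble:
    """Read a conformational ensemble from a multi-model PDB or XYZ trajectory.

    Frames are returned in file order; PDB MODEL records map one-to-one to
    frames.  Raises :class:`ParseError` (naming the offending line) on
    malformed records and :class:`TopologyError` if the atom count differs
    between frames.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "pdb_multimodel":
        return _read_pdb(path)
    if format == "xyz_trajectory":
        return _read_xyz(path)
    raise ValueError(f"unknown ensemble format {format!r}")


def write_ensemble(ensemble: Ensemble, path, format: EnsembleFormat = "pdb_multimodel") -> None:
    """Write an ensemble so that :func:`read_ensemble` recovers it.

    Round-trip is the identity up to format precision (PDB stores 3 decimals;
    XYZ keeps 6).  The XYZ dialect records only elements and coordinates, so
    atom/residue naming is regenerated on read.
    """
    if not isinstance(ensemble, Ensemble):
        raise ValidationError("write_ensemble expects an Ensemble")
    path = Path(path)
    if format == "pdb_multimodel":
        _write_pdb(ensemble, path)
    elif format == "xyz_trajectory":
        _write_xyz(ensemble, path)
    else:
        raise ValueError(f"unknown ensemble format {format!r}")


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyRecord:
    """State-energy differences for one conformation, in eV.

    ``dE1`` is the enol emission gap, ``dE2`` the keto-S1 minus enol-S1
    difference (negative favours the proton transfer), ``dE3`` the keto
    emission gap.  ``d_n_ho`` optionally carries the N···HO contact distance
    in Å when the table provides it.
    """

    conformation_id: str
    dE1: float
    dE2: Optional[float] = None
    dE3: Optional[float] = None
    d_n_ho: Optional[float] = None


def _parse_energy(raw, column: str, row_id: str) -> Optional[float]:
    if raw is None:
        return None
    text = str(raw).strip()
    if text in MISSING_MARKERS:
        return None
    # tolerate unicode minus as printed in typeset tables
    text = text.replace("−", "-")
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"row {row_id!r}: non-numeric value {raw!r} in column {column}"
        ) from None


def read_energy_table(path) -> list[EnergyRecord]:
    """Read a per-conformation state-energy table (CSV).

    Requires columns ``conformation_id, dE1, dE2, dE3`` (case-insensitive);
    an optional ``d_N_HO`` column is kept when present.  Missing dE2/dE3 are
    marked absent, never zero.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    colmap = {c.lower(): c for c in df.columns}
    required = ["conformation_id", "de1", "de2", "de3"]
    missing = [c for c in required if c not in colmap]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    records = []
    seen = set()
    for _, row in df.iterrows():
        cid = str(row[colmap["conformation_id"]]).strip()
        if cid in seen:
            raise ValidationError(f"duplicate conformation_id {cid!r}")
        seen.add(cid)
        dE1 = _parse_energy(row[colmap["de1"]], "dE1", cid)
        if dE1 is None:
            raise ValidationError(f"row {cid!r}: dE1 is required")
        dE2 = _parse_energy(row[colmap["de2"]], "dE2", cid)
        dE3 = _parse_energy(row[colmap["de3"]], "dE3", cid)
        d_n_ho = None
        if "d_n_ho" in colmap:
            d_n_ho = _parse_energy(row[colmap["d_n_ho"]], "d_N_HO", cid)
        records.append(EnergyRecord(cid, dE1, dE2, dE3, d_n_ho))
    return records
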