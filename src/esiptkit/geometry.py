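"""Core molecular geometry: torsions, distances, angles, circular statistics,
and optimal-superposition RMSD.

Torsions follow the IUPAC sign convention (cis = 0°, values in (−180°, 180°])
and are computed with the two-argument arctangent form, which is numerically
stable near 0° and 180°.  All operations act on coordinates in Å and are
invariant under a common rigid motion of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, SelectionError, ValidationError
from .traj_io import Ensemble

__all__ = [
    "DescriptorSpec",
    "DescriptorMatrix",
    "torsion",
    "distance",
    "angle",
    "kabsch_rmsd",
    "circular_mean",
    "circular_std",
    "wrap_degrees",
    "evaluate_descriptors",
]

DescriptorKind = Literal["torsion", "distance", "angle"]

_SELECTOR_COUNT = {"distance": 2, "angle": 3, "torsion": 4}


@dataclass(frozen=True)
class DescriptorSpec:
    """A named geometric descriptor defined by atom selectors.

    Each selector is a ``(residue_index, atom_name)`` pair; ``kind`` fixes the
    selector count (distance=2, angle=3, torsion=4).
    """

    name: str
    kind: DescriptorKind
    atom_selectors: tuple

    def __post_init__(self):
        if self.kind not in _SELECTOR_COUNT:
            raise ValidationError(f"unknown descriptor kind {self.kind!r}")
        if len(self.atom_selectors) != _SELECTOR_COUNT[self.kind]:
            raise ValidationError(
                f"descriptor {self.name!r}: kind {self.kind!r} needs "
                f"{_SELECTOR_COUNT[self.kind]} selectors, got {len(self.atom_selectors)}"
            )


@dataclass
class DescriptorMatrix:
    """Per-frame values of named descriptors.

    Torsions are degrees in (−180°, 180°], distances Å, angles degrees.
    """

    frame_indices: np.ndarray  # (n_frames,)
    descriptor_names: list[str]
    kinds: list[str]  # parallel to descriptor_names
    values: np.ndarray  # (n_frames, n_descriptors)

    def __post_init__(self):
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.frame_indices), len(self.descriptor_names)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.frame_indices)} frames x {len(self.descriptor_names)} descriptors"
            )
        if len(self.kinds) != len(self.descriptor_names):
            raise ValidationError("kinds must parallel descriptor_names")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("descriptor values must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.frame_indices)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.descriptor_names.index(name)
        except ValueError:
            raise SelectionError(f"no descriptor named {name!r}") from None
        return self.values[:, j]

    def kind_of(self, name: str) -> str:
        return self.kinds[self.descriptor_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        df.insert(0, "frame", self.frame_indices)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kinds: Optional[Sequence[str]] = None) -> "DescriptorMatrix":
        """Load a matrix written by :meth:`to_csv`.

        ``kinds`` may be given explicitly; otherwise columns named like
        ``dihedral_*`` are treated as torsions, ``d_*`` as distances, the
        rest as angles.
        """
        df = pd.read_csv(path)
        names = [c for c in df.columns if c != "frame"]
        if kinds is None:
            kinds = [
                "torsion" if n.startswith("dihedral") else
                "distance" if n.startswith("d_") else "angle"
                for n in names
            ]
        return cls(
            frame_indices=df["frame"].to_numpy(),
            descriptor_names=names,
            kinds=list(kinds),
            values=df[names].to_numpy(),
        )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def wrap_degrees(a):
    """Wrap angles in degrees to the interval (−180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -np.remainder(-a + 180.0, 360.0) + 180.0
    return wrapped if wrapped.ndim else float(wrapped)


def distance(p1, p2) -> float:
    """Euclidean distance in Å."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return float(np.linalg.norm(p2 - p1))


def angle(p1, p2, p3) -> float:
    """Bond angle p1–p2–p3 in degrees, in [0, 180]."""
    v1 = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    v2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise DegenerateGeometryError("coincident points in angle computation")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _torsion_batch(p1, p2, p3, p4) -> np.ndarray:
    """Vectorised signed dihedral (degrees in (−180, 180]) for (n, 3) inputs."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_n1 = np.linalg.norm(n1, axis=-1)
    norm_n2 = np.linalg.norm(n2, axis=-1)
    norm_b2 = np.linalg.norm(b2, axis=-1)
    scale = np.linalg.norm(b1, axis=-1) * norm_b2
    bad = (norm_n1 <= 1e-10 * np.maximum(scale, 1e-30)) | (
        norm_n2 <= 1e-10 * np.maximum(np.linalg.norm(b3, axis=-1) * norm_b2, 1e-30)
    ) | (norm_b2 <= 1e-12)
    if np.any(bad):
        raise DegenerateGeometryError(
            "collinear or coincident points make the torsion undefined"
        )
    m = np.cross(n1, n2)
    y = np.einsum("...i,...i->...", m, b2) / norm_b2
    x = np.einsum("...i,...i->...", n1, n2)
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


def torsion(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees in (−180°, 180°], IUPAC convention.

    The value is the angle from plane (p1,p2,p3) to plane (p2,p3,p4) measured
    about the p2→p3 axis.  Raises :class:`DegenerateGeometryError` when three
    consecutive points are collinear or consecutive points coincide.
    """
    pts = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    return float(_torsion_batch(*pts))


def circular_mean(angles_deg) -> float:
    """Mean direction (degrees in (−180°, 180°]) of angles on the circle.

    The result is the argument of the mean unit phasor; it is invariant under
    adding multiples of 360° to any input.  Raises
    :class:`DegenerateGeometryError` when the resultant length is ~0 (e.g.
    {0°, 180°}), where no mean direction exists.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValidationError("circular_mean of an empty list")
    s, c = np.mean(np.sin(a)), np.mean(np.cos(a))
    if np.hypot(s, c) < 1e-12:
        raise DegenerateGeometryError("resultant vector vanishes; circular mean undefined")
    return wrap_degrees(np.degrees(np.arctan2(s, c)))


def circular_std(angles_deg) -> float:
    """Standard deviation (degrees) of angles unwrapped about their circular mean."""
    a = np.asarray(angles_deg, dtype=float)
    center = circular_mean(a)
    dev = wrap_degrees(a - center)
    return float(np.std(dev))


def kabsch_rmsd(ref, mobile, selection: Optional[Sequence[int]] = None) -> float:
    """Minimum RMSD (Å) over all rigid rotations+translations.

    Uses the Kabsch solution of the optimal-superposition problem (via
    :func:`scipy.spatial.transform.Rotation.align_vectors`).  Returns 0 iff
    the two coordinate sets are congruent.
    """
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        ref = ref[sel]
        mobile = mobile[sel]
    if ref.shape != mobile.shape:
        raise ValidationError(f"shape mismatch: {ref.shape} vs {mobile.shape}")
    n = ref.shape[0]
    if n < 3:
        raise ValidationError("superposition needs at least 3 atoms")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mobile - mobile.mean(axis=0)
    _, rssd = Rotation.align_vectors(ref_c, mob_c)
    return float(rssd / np.sqrt(n))


# ---------------------------------------------------------------------------
# Descriptor evaluation over an ensemble
# ---------------------------------------------------------------------------


def evaluate_descriptors(ensemble: Ensemble, specs: Sequence[DescriptorSpec]) -> DescriptorMatrix:
    """Evaluate descriptors for every frame of an ensemble.

    Returns a matrix with one row per frame and one column per spec; torsions
    are wrapped to (−180°, 180°].  Raises :class:`SelectionError`, naming the
    spec, when a selector does not resolve in the topology.
    """
    n = ensemble.n_frames
    columns = []
    for spec in specs:
        try:
            idx = [ensemble.atom_index(res, name) for res, name in spec.atom_selectors]
        except SelectionError as exc:
            raise SelectionError(f"descriptor {spec.name!r}: {exc}") from None
        pts = [ensemble.coordinates[:, i, :] for i in idx]
        if spec.kind == "distance":
            col = np.linalg.norm(pts[1] - pts[0], axis=1)
        elif spec.kind == "angle":
            v1 = pts[0] - pts[1]
            v2 = pts[2] - pts[1]
            cosang = np.einsum("ij,ij->i", v1, v2) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            col = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        else:
            col = _torsion_batch(*pts)
        columns.append(col)
    values = np.column_stack(columns) if columns else np.empty((n, 0))
    return DescriptorMatrix(
        frame_indices=np.arange(n),
        descriptor_names=[s.name for s in specs],
        kinds=[s.kind for s in specs],
        values=values,
    )
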