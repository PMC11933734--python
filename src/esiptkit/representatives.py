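"""Selection of representative conformations and geometric ESIPT classification.

For each metastate, the representative is the frame of a reference
(equilibrium) ensemble whose descriptors are closest to the metastate's mean
descriptor values.  "Closest" is a standardized Euclidean distance: each
torsion contributes its wrapped angular difference in degrees, each
non-angular descriptor its absolute difference, and every term is divided by
that descriptor's reference-ensemble standard deviation (circular for
torsions).  Ties break to the lowest frame index.

A conformation is geometrically capable of excited-state intramolecular
proton transfer (ESIPT) when its N···HO contact distance is strictly below
the threshold (default 3.00 Å): the hydroxyl proton must sit within
hydrogen-bond reach of the acceptor nitrogen for the ultrafast transfer to
be possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, SelectionError, ValidationError
from .geometry import DescriptorMatrix, circular_std, wrap_degrees

__all__ = [
    "RepresentativeConformation",
    "select_representative",
    "select_representatives",
    "esipt_geometry_flag",
    "esipt_capable_fraction",
    "ESIPT_DISTANCE_THRESHOLD",
]

#: default N···HO cutoff (Å) below which the ESIPT geometry is considered intact
ESIPT_DISTANCE_THRESHOLD = 3.00


@dataclass(frozen=True)
class RepresentativeConformation:
    metastate_id: str
    frame_index: int
    descriptor_values: dict
    distance_to_mean: float  # standardized, dimensionless
    d_n_ho: Optional[float] = None
    esipt_geometry_ok: Optional[bool] = None
    from_reference: bool = True  # False when the biased-ensemble fallback fired


def _standardized_distances(
    targets: Mapping[str, float], reference: DescriptorMatrix
) -> np.ndarray:
    """Standardized distance of every reference frame to the target vector."""
    missing = [n for n in targets if n not in reference.descriptor_names]
    if missing:
        raise SelectionError(f"descriptor(s) {missing} not present in the reference matrix")
    total = np.zeros(reference.n_frames)
    for name, target in targets.items():
        col = reference.column(name)
        if reference.kind_of(name) == "torsion":
            diff = wrap_degrees(col - target)
            try:
                sd = circular_std(col)
            except DegenerateGeometryError:
                sd = float(np.std(col))  # no mean direction: fall back to linear spread
        else:
            diff = col - target
            sd = float(np.std(col))
        if sd < 1e-12:
            sd = 1.0  # constant column: unit weight keeps the term finite
        total += (diff / sd) ** 2
    return np.sqrt(total)


def select_representative(
    metastate_means: Mapping[str, float], reference: DescriptorMatrix
) -> int:
    """Frame index (in the reference ensemble) closest to the target means."""
    if reference.n_frames == 0:
        raise ValidationError("reference matrix is empty")
    dist = _standardized_distances(metastate_means, reference)
    pos = int(np.argmin(dist))  # np.argmin takes the first minimum: lowest frame index
    return int(reference.frame_indices[pos])


def select_representatives(
    metastate_means: Mapping[str, Mapping[str, float]],
    reference: DescriptorMatrix,
    biased: Optional[DescriptorMatrix] = None,
    distance_ceiling: Optional[float] = None,
    distance_descriptor: str = "d_N_HO",
    threshold: float = ESIPT_DISTANCE_THRESHOLD,
) -> list[RepresentativeConformation]:
    """Representatives for every metastate, with geometric ESIPT flags.

    When ``distance_ceiling`` is set and the best reference frame lies above
    it (the metastate was never visited at equilibrium), the nearest frame of
    the ``biased`` matrix is used instead and flagged via
    ``from_reference=False``.
    """
    reps = []
    for mid, targets in metastate_means.items():
        targets = {k: v for k, v in targets.items() if np.isfinite(v)}
        dist = _standardized_distances(targets, reference)
        pos = int(np.argmin(dist))
        best, matrix, from_ref = dist[pos], reference, True
        if distance_ceiling is not None and best > distance_ceiling and biased is not None:
            dist_b = _standardized_distances(targets, biased)
            pos = int(np.argmin(dist_b))
            best, matrix, from_ref = dist_b[pos], biased, False
        values = {n: float(matrix.values[pos, j]) for j, n in enumerate(matrix.descriptor_names)}
        d_n_ho = values.get(distance_descriptor)
        reps.append(
            RepresentativeConformation(
                metastate_id=str(mid),
                frame_index=int(matrix.frame_indices[pos]),
                descriptor_values=values,
                distance_to_mean=float(best),
                d_n_ho=d_n_ho,
                esipt_geometry_ok=(
                    esipt_geometry_flag(d_n_ho, threshold) if d_n_ho is not None else None
                ),
                from_reference=from_ref,
            )
        )
    return reps


def esipt_geometry_flag(d_n_ho: float, threshold: float = ESIPT_DISTANCE_THRESHOLD) -> bool:
    """True iff the N···HO distance is strictly below the threshold."""
    if d_n_ho < 0:
        raise ValidationError("a distance cannot be negative")
    return bool(d_n_ho < threshold)


def esipt_capable_fraction(
    flags_or_distances: Sequence,
    threshold: float = ESIPT_DISTANCE_THRESHOLD,
    labels: Optional[Sequence] = None,
):
    """Percent of frames with ESIPT-capable geometry.

    Accepts either booleans or N···HO distances (compared strictly against
    ``threshold``).  With per-frame metastate ``labels`` the per-metastate
    percents are returned as a second value.
    """
    arr = np.asarray(flags_or_distances)
    if arr.size == 0:
        raise ValidationError("no frames given")
    if arr.dtype == bool:
        flags = arr
    else:
        vals = arr.astype(float)
        if np.any(vals < 0):
            raise ValidationError("a distance cannot be negative")
        flags = vals < threshold
    overall = 100.0 * float(np.mean(flags))
    if labels is None:
        return overall
    labels = np.asarray(labels, dtype=object)
    per_state = {
        str(mid): 100.0 * float(np.mean(flags[labels == mid])) for mid in np.unique(labels)
    }
    return overall, per_state


def representatives_table(reps: Sequence[RepresentativeConformation]) -> pd.DataFrame:
    rows = []
    for r in reps:
        row = {
            "metastate": r.metastate_id,
            "frame": r.frame_index,
            "distance_to_mean": r.distance_to_mean,
            "d_N_HO": r.d_n_ho,
            "esipt_geometry_ok": r.esipt_geometry_ok,
            "from_reference": r.from_reference,
        }
        row.update(r.descriptor_values)
        rows.append(row)
    return pd.DataFrame(rows)
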