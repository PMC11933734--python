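"""Per-conformation ESIPT photophysics from state-energy differences.

The chromophore follows the classic four-state ESIPT cycle: enol S0 →
(absorption) enol S1 → (proton transfer) keto S1 → (emission) keto S0.
Three energy differences, in eV, summarise it per conformation:

- ``dE1``: enol vertical emission gap (enol S1 → enol S0),
- ``dE2``: keto S1 minus enol S1 (negative favours the transfer),
- ``dE3``: keto vertical emission gap (keto S1 → keto S0).

Emission wavelengths come from λ = hc/E with hc = 1239.84193 eV·nm, rounded
to 2 decimals; the Stokes shift of a conformation is the difference of its
rounded keto and enol wavelengths.  Whether ESIPT actually occurs is a
geometric on/off call: the keto pathway must exist (dE3 present) and the
N···HO contact must be below 3.00 Å.  dE2 enters only as a favourability
annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import DomainError, ValidationError
from .representatives import ESIPT_DISTANCE_THRESHOLD
from .traj_io import EnergyRecord

__all__ = [
    "HC_EV_NM",
    "PhotophysicalRecord",
    "EnsembleSummary",
    "ev_to_nm",
    "stokes_shift",
    "classify_record",
    "classify_table",
    "ensemble_summary",
    "from_state_energies",
    "reference_energy_table",
]

#: Planck constant times speed of light, eV·nm (CODATA)
HC_EV_NM = 1239.84193

#: wavelengths at or below this (nm) are labelled UVA, above it visible
#: (violet onset by the common convention; descriptive labels only)
UVA_VISIBLE_BOUNDARY_NM = 380.0


@dataclass(frozen=True)
class PhotophysicalRecord:
    """Spectroscopic quantities derived for one conformation."""

    conformation_id: str
    dE1: float
    dE2: Optional[float]
    dE3: Optional[float]
    lambda_enol: float  # nm
    lambda_keto: Optional[float]  # nm, only when ESIPT occurs
    stokes_shift: Optional[float]  # nm, only when ESIPT occurs
    esipt_occurs: bool
    dE2_favorable: Optional[bool]  # dE2 < 0, when dE2 is present
    enol_region: str  # "UVA" or "visible" (descriptive only)
    keto_region: Optional[str]
    d_n_ho: Optional[float] = None


@dataclass
class EnsembleSummary:
    """Ensemble-level ESIPT statistics."""

    esipt_capable_percent: float
    esipt_capable_display: int
    capable_metastates: list
    metastate_fractions: dict
    records: pd.DataFrame


def ev_to_nm(energy_ev: float) -> float:
    """Convert a transition energy (eV) to a wavelength (nm, 2 decimals)."""
    if not energy_ev > 0:
        raise DomainError(f"energy must be positive, got {energy_ev}")
    return round(HC_EV_NM / energy_ev, 2)


def stokes_shift(dE1: float, dE3: float) -> float:
    """Stokes shift (nm): rounded keto wavelength minus rounded enol wavelength.

    Computed from the two already-rounded wavelengths so that the printed
    wavelength and shift tables stay mutually consistent.
    """
    if not (dE1 > 0 and dE3 > 0):
        raise DomainError("both emission gaps must be positive")
    if dE3 >= dE1:
        warnings.warn(
            f"keto gap {dE3} eV is not below the enol gap {dE1} eV; "
            "Stokes shift will be non-positive",
            stacklevel=2,
        )
    return round(ev_to_nm(dE3) - ev_to_nm(dE1), 2)


def _region(lambda_nm: float) -> str:
    return "UVA" if lambda_nm <= UVA_VISIBLE_BOUNDARY_NM else "visible"


def classify_record(
    conformation_id: str,
    dE1: float,
    dE2: Optional[float] = None,
    dE3: Optional[float] = None,
    d_n_ho: Optional[float] = None,
    threshold: float = ESIPT_DISTANCE_THRESHOLD,
) -> PhotophysicalRecord:
    """Build the full photophysical record of one conformation.

    ESIPT occurs iff the keto emission gap is present AND the N···HO distance
    (when known) is strictly below the threshold.  The enol wavelength is
    always computed; keto wavelength and Stokes shift only when ESIPT occurs.
    """
    if dE1 is None:
        raise ValidationError(
            f"{conformation_id}: dE1 is required (dE3 without dE1 is invalid)"
        )
    lambda_enol = ev_to_nm(dE1)
    esipt = dE3 is not None and (d_n_ho is None or d_n_ho < threshold)
    lambda_keto = ev_to_nm(dE3) if esipt else None
    return PhotophysicalRecord(
        conformation_id=conformation_id,
        dE1=dE1,
        dE2=dE2,
        dE3=dE3,
        lambda_enol=lambda_enol,
        lambda_keto=lambda_keto,
        stokes_shift=stokes_shift(dE1, dE3) if esipt else None,
        esipt_occurs=esipt,
        dE2_favorable=(dE2 < 0) if dE2 is not None else None,
        enol_region=_region(lambda_enol),
        keto_region=_region(lambda_keto) if lambda_keto is not None else None,
        d_n_ho=d_n_ho,
    )


def classify_table(
    records: Sequence[EnergyRecord],
    distances: Optional[Mapping[str, float]] = None,
    threshold: float = ESIPT_DISTANCE_THRESHOLD,
) -> list[PhotophysicalRecord]:
    """Classify every row of an energy table.

    ``distances`` optionally maps conformation ids to N···HO distances,
    overriding any distance column carried by the table itself.
    """
    out = []
    for rec in records:
        d = rec.d_n_ho
        if distances is not None and rec.conformation_id in distances:
            d = distances[rec.conformation_id]
        out.append(
            classify_record(rec.conformation_id, rec.dE1, rec.dE2, rec.dE3, d, threshold)
        )
    return out


def records_frame(records: Sequence[PhotophysicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def ensemble_summary(
    records: Sequence[PhotophysicalRecord],
    metastate_fractions: Mapping[str, float],
    assignment: Mapping[str, str],
) -> EnsembleSummary:
    """Ensemble-level ESIPT capability from per-representative records.

    ``metastate_fractions`` gives the population percent of each metastate
    (must sum to 100 ± 0.1); ``assignment`` maps each record's conformation
    id to its metastate.  The capable percent is the summed fraction of the
    metastates whose representatives can perform ESIPT.
    """
    total = sum(metastate_fractions.values())
    if abs(total - 100.0) > 0.1:
        raise ValidationError(f"metastate fractions sum to {total}, expected 100")
    unknown = [r.conformation_id for r in records if r.conformation_id not in assignment]
    if unknown:
        raise ValidationError(f"records without metastate assignment: {unknown}")
    capable = set()
    for rec in records:
        if rec.esipt_occurs:
            capable.add(str(assignment[rec.conformation_id]))
    capable_ids = sorted(capable & set(map(str, metastate_fractions)))
    percent = sum(
        frac for mid, frac in metastate_fractions.items() if str(mid) in capable
    )
    return EnsembleSummary(
        esipt_capable_percent=percent,
        esipt_capable_display=int(round(percent)),
        capable_metastates=capable_ids,
        metastate_fractions=dict(metastate_fractions),
        records=records_frame(records),
    )


def from_state_energies(
    conformation_id: str,
    enol_s0: float,
    enol_s1: float,
    keto_s1: Optional[float] = None,
    keto_s0: Optional[float] = None,
    d_n_ho: Optional[float] = None,
    threshold: float = ESIPT_DISTANCE_THRESHOLD,
) -> PhotophysicalRecord:
    """Alternative input: absolute four-state energies (eV) instead of deltas.

    dE1 = enol S1 − enol S0; dE2 = keto S1 − enol S1; dE3 = keto S1 − keto S0.
    """
    dE1 = enol_s1 - enol_s0
    dE2 = keto_s1 - enol_s1 if keto_s1 is not None else None
    dE3 = keto_s1 - keto_s0 if (keto_s1 is not None and keto_s0 is not None) else None
    return classify_record(conformation_id, dE1, dE2, dE3, d_n_ho, threshold)


def reference_energy_records() -> list[EnergyRecord]:
    """The packaged reference TDDFT energy table for the seven representative
    conformations of the protein-environment system (deltas in eV, N···HO in Å)."""
    from .traj_io import read_energy_table

    with resources.as_file(
        resources.files("esiptkit.data").joinpath("state_energies_protein.csv")
    ) as path:
        return read_energy_table(path)


def reference_energy_table() -> pd.DataFrame:
    """The packaged reference table as a DataFrame (missing energies as NaN)."""
    return pd.DataFrame([r.__dict__ for r in reference_energy_records()])
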