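"""Geometric hydrogen-bond detection and per-pair occupancy over an ensemble.

A hydrogen bond is recorded when the donor–acceptor heavy-atom distance is at
most ``max_da_distance`` (default 3.0 Å) and the D–H···A angle deviates from
linearity (180°) by at most ``max_dha_deviation`` (default 30°) — the common
geometric criterion of trajectory-visualisation tools.  Boundaries are
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import angle, distance
from .traj_io import Conformation, Ensemble

__all__ = ["HBondCriterion", "HBondEvent", "detect_hbonds", "occupancy"]

AtomId = Tuple[int, str]  # (residue_index, atom_name)


@dataclass(frozen=True)
class HBondCriterion:
    """Distance/angle cutoffs of the geometric hydrogen-bond definition."""

    max_da_distance: float = 3.0  # Å, donor–acceptor heavy atoms
    max_dha_deviation: float = 30.0  # degrees away from a linear D–H···A

    def __post_init__(self):
        if self.max_da_distance <= 0 or self.max_dha_deviation <= 0:
            raise ValidationError("h-bond cutoffs must be strictly positive")


@dataclass(frozen=True)
class HBondEvent:
    frame_index: int
    donor: AtomId
    hydrogen: AtomId
    acceptor: AtomId
    da_distance: float
    dha_deviation: float


def detect_hbonds(
    frame: Conformation,
    donors: Sequence[Tuple[AtomId, AtomId]],
    acceptors: Sequence[AtomId],
    criterion: HBondCriterion = HBondCriterion(),
) -> list[HBondEvent]:
    """Detect hydrogen bonds in one frame.

    ``donors`` lists (donor, hydrogen) atom-id pairs — the hydrogen must be
    the one covalently bound to that donor, which is the caller's
    responsibility to guarantee.  An event is emitted iff
    d(D,A) ≤ max_da_distance and the deviation of D–H···A from 180° is
    ≤ max_dha_deviation, with donor ≠ acceptor.
    """
    events = []
    for donor_id, hydrogen_id in donors:
        d_pos = frame.atom_position(*donor_id)
        h_pos = frame.atom_position(*hydrogen_id)
        for acceptor_id in acceptors:
            if acceptor_id == donor_id:
                continue
            a_pos = frame.atom_position(*acceptor_id)
            da = distance(d_pos, a_pos)
            if da > criterion.max_da_distance:
                continue
            deviation = 180.0 - angle(d_pos, h_pos, a_pos)
            if deviation > criterion.max_dha_deviation:
                continue
            events.append(
                HBondEvent(
                    frame_index=frame.frame_index,
                    donor=donor_id,
                    hydrogen=hydrogen_id,
                    acceptor=acceptor_id,
                    da_distance=da,
                    dha_deviation=deviation,
                )
            )
    return events


def occupancy(
    ensemble: Ensemble,
    donors: Sequence[Tuple[AtomId, AtomId]],
    acceptors: Sequence[AtomId],
    criterion: HBondCriterion = HBondCriterion(),
) -> pd.DataFrame:
    """Per-pair hydrogen-bond occupancy over an ensemble.

    Returns one row per (donor, acceptor) pair with:

    - ``n_frames``: frames in which the pair bonds at least once,
    - ``fraction``: that count divided by the total frame count (in [0, 1]),
    - ``event_share``: the pair's percentage of all detected events (the
      "share of interactions" statistic; sums to 100 when any event exists).
    """
    pair_frames: dict = {}
    pair_events: dict = {}
    for i in range(ensemble.n_frames):
        frame = ensemble.frame(i)
        seen_this_frame = set()
        for ev in detect_hbonds(frame, donors, acceptors, criterion):
            pair = (ev.donor, ev.acceptor)
            pair_events[pair] = pair_events.get(pair, 0) + 1
            if pair not in seen_this_frame:
                pair_frames[pair] = pair_frames.get(pair, 0) + 1
                seen_this_frame.add(pair)
    total_events = sum(pair_events.values())
    all_pairs = [((d, a)) for d, _h in donors for a in acceptors if a != d]
    rows = []
    for pair in all_pairs:
        n = pair_frames.get(pair, 0)
        rows.append(
            {
                "donor": f"{pair[0][0]}:{pair[0][1]}",
                "acceptor": f"{pair[1][0]}:{pair[1][1]}",
                "n_frames": n,
                "fraction": n / ensemble.n_frames,
                "event_share": (
                    100.0 * pair_events.get(pair, 0) / total_events if total_events else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
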