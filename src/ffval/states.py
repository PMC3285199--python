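"""Helicity, dual-cutoff folding-state assignment, and melting curves.

The dual-cutoff scheme assigns each frame to folded/unfolded with hysteresis:
a folding event is triggered when the Calpha RMSD to the reference drops
below a strict fold threshold, an unfolding event when it rises above a
looser unfold threshold; in between, the previous state persists, which
suppresses spurious recrossings.  Multi-segment specifications (several
residue stretches with their own thresholds) require all segments to satisfy
the criterion simultaneously in the same frame.

Built-in presets carry the segment definitions and thresholds for the villin
headpiece (reference PDB 2F4K), the FiP35 WW domain (2F21) and the CLN025
beta-hairpin (single segment, 1.0 / 4.0 Angstrom).
"""

from __future__ import annotations


from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import ConformationalEnsemble, ResidueRange, backbone_dihedral
from .exceptions import FfvalError

__all__ = [
    "HelixAssignment",
    "DEFAULT_HELIX_BOX",
    "assign_helical",
    "helical_fraction",
    "State",
    "DualCutoffSpec",
    "PRESETS",
    "StateTrajectory",
    "dual_cutoff_states",
    "count_events",
    "fraction_folded",
    "melting_curve",
    "read_rmsd_traces",
    "write_rmsd_traces",
]


# -- helicity ---------------------------------------------------------------

#: (phi, psi) rectangle of the alpha-helical basin, degrees.
DEFAULT_HELIX_BOX = ((-100.0, -30.0), (-67.0, -7.0))


@dataclass
class HelixAssignment:
    """Boolean frame x residue matrix of per-residue helicity.

    Residues whose phi or psi is undefined (chain termini) are never helical
    and are excluded from fraction estimates via ``assignable``.
    """

    residues: list[int]
    matrix: np.ndarray           # (n_frames, n_residues) bool
    assignable: np.ndarray       # (n_residues,) bool

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        self.assignable = np.asarray(self.assignable, dtype=bool)
        if self.matrix.shape[1] != len(self.residues):
            raise ValueError("matrix width must equal number of residues")
        if self.matrix[:, ~self.assignable].any():
            raise ValueError("unassignable residues must never be helical")


def assign_helical(
    ensemble: ConformationalEnsemble,
    phi_psi_box: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_HELIX_BOX,
    min_run: int = 3,
) -> HelixAssignment:
    """Mark residues helical per frame from a (phi, psi) box plus run length.

    A residue is helical in a frame iff its (phi, psi) lies inside the box
    and it belongs to a run of at least ``min_run`` consecutive in-box
    residues — a nucleated helical segment, not an isolated dihedral.
    """
    residues = ensemble.residue_indices
    (phi_lo, phi_hi), (psi_lo, psi_hi) = phi_psi_box
    n_frames = ensemble.n_frames
    in_box = np.zeros((n_frames, len(residues)), dtype=bool)
    assignable = np.zeros(len(residues), dtype=bool)
    for j, r in enumerate(residues):
        try:
            phi = backbone_dihedral(ensemble, r, "phi")
            psi = backbone_dihedral(ensemble, r, "psi")
        except FfvalError:
            continue
        assignable[j] = True
        in_box[:, j] = (
            (phi >= phi_lo) & (phi <= phi_hi) & (psi >= psi_lo) & (psi <= psi_hi)
        )

    helical = np.zeros_like(in_box)
    # mark runs of >= min_run residues that are in-box AND consecutive in
    # author numbering
    consecutive = np.diff(residues) == 1
    n = len(residues)
    for f in range(n_frames):
        j = 0
        while j < n:
            if not in_box[f, j]:
                j += 1
                continue
            k = j
            while k + 1 < n and in_box[f, k + 1] and consecutive[k]:
                k += 1
            if k - j + 1 >= min_run:
                helical[f, j : k + 1] = True
            j = k + 1
    return HelixAssignment(residues=residues, matrix=helical, assignable=assignable)


def helical_fraction(assignment: HelixAssignment | np.ndarray) -> float:
    """Mean helicity over frames and assignable residues."""
    if isinstance(assignment, HelixAssignment):
        if not assignment.assignable.any():
            raise FfvalError("no assignable residues")
        m = assignment.matrix[:, assignment.assignable]
    else:
        m = np.asarray(assignment, dtype=bool)
    if m.size == 0:
        raise FfvalError("empty helix assignment")
    return float(np.mean(m))


# -- dual-cutoff state assignment ------------------------------------------

class State(Enum):
    UNDETERMINED = "undetermined"
    FOLDED = "folded"
    UNFOLDED = "unfolded"


@dataclass(frozen=True)
class DualCutoffSpec:
    """Per-segment fold/unfold RMSD thresholds against a reference structure."""

    segments: tuple[tuple[ResidueRange, float, float], ...]
    reference: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("spec needs at least one segment")
        for rng, fold, unfold in self.segments:
            if not fold < unfold:
                raise ValueError(
                    f"fold threshold ({fold}) must be below unfold threshold ({unfold}) "
                    f"for segment {rng.first}-{rng.last}"
                )

    @property
    def fold_thresholds(self) -> np.ndarray:
        return np.array([s[1] for s in self.segments])

    @property
    def unfold_thresholds(self) -> np.ndarray:
        return np.array([s[2] for s in self.segments])


#: Segment definitions and thresholds (Angstrom) for the benchmark systems.
PRESETS: dict[str, DualCutoffSpec] = {
    "villin-2F4K": DualCutoffSpec(
        segments=(
            (ResidueRange(3, 31), 1.2, 5.0),
            (ResidueRange(3, 18), 0.9, 4.6),
            (ResidueRange(14, 31), 0.9, 2.5),
        ),
        reference="2F4K",
    ),
    "ww-2F21": DualCutoffSpec(
        segments=(
            (ResidueRange(2, 33), 2.0, 7.0),
            (ResidueRange(8, 22), 1.1, 5.8),
            (ResidueRange(12, 18), 0.6, 1.8),
            (ResidueRange(19, 30), 0.9, 3.8),
        ),
        reference="2F21",
    ),
    "cln025": DualCutoffSpec(
        segments=((ResidueRange(1, 10), 1.0, 4.0),),
        reference="CLN025 NMR structure",
    ),
}


@dataclass
class StateTrajectory:
    """Per-frame folded/unfolded assignment plus fold/unfold events.

    Events record transitions between determined states only: the first
    threshold crossing out of the initial "undetermined" stretch establishes
    the state without counting as an event.  ``frame_index`` is the 0-based
    trigger frame.  Events alternate in kind and their counts differ by at
    most one.
    """

    states: list[State]
    events: list[tuple[int, str]]


def dual_cutoff_states(
    rmsd_series: np.ndarray | Sequence[Sequence[float]],
    spec: DualCutoffSpec,
) -> StateTrajectory:
    """Hysteresis state assignment from per-segment RMSD series.

    ``rmsd_series`` has shape ``(n_segments, n_frames)`` matching
    ``spec.segments``.  A frame triggers *fold* when every segment is below
    its fold threshold, *unfold* when every segment is above its unfold
    threshold; otherwise the previous state persists.
    """
    series = np.atleast_2d(np.asarray(rmsd_series, dtype=float))
    if series.shape[0] != len(spec.segments):
        raise ValueError(
            f"got {series.shape[0]} RMSD series for {len(spec.segments)} segments"
        )
    if series.shape[1] == 0:
        raise FfvalError("empty RMSD series")
    fold_trig = (series < spec.fold_thresholds[:, None]).all(axis=0)
    unfold_trig = (series > spec.unfold_thresholds[:, None]).all(axis=0)

    states: list[State] = []
    events: list[tuple[int, str]] = []
    current = State.UNDETERMINED
    for f in range(series.shape[1]):
        if fold_trig[f] and current is not State.FOLDED:
            if current is State.UNFOLDED:
                events.append((f, "fold"))
            current = State.FOLDED
        elif unfold_trig[f] and current is not State.UNFOLDED:
            if current is State.FOLDED:
                events.append((f, "unfold"))
            current = State.UNFOLDED
        states.append(current)
    return StateTrajectory(states=states, events=events)


def count_events(traj: StateTrajectory) -> tuple[int, int]:
    """(n_fold, n_unfold) event counts of a state trajectory."""
    kinds = [k for _, k in traj.events]
    return kinds.count("fold"), kinds.count("unfold")


def fraction_folded(traj: StateTrajectory) -> float:
    """Folded fraction over determined frames (undetermined frames excluded)."""
    determined = [s for s in traj.states if s is not State.UNDETERMINED]
    if not determined:
        raise FfvalError("all frames undetermined: no threshold crossing observed")
    return determined.count(State.FOLDED) / len(determined)


# -- melting curves ---------------------------------------------------------

def _block_sem(values: np.ndarray, n_blocks: int = 5) -> float:
    values = np.asarray(values, dtype=float)
    edges = np.linspace(0, values.size, n_blocks + 1, dtype=int)
    means = [values[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a]
    if len(means) < 2:
        return float("nan")
    return float(np.std(means, ddof=1) / np.sqrt(len(means)))


def melting_curve(
    per_temperature: Sequence[tuple[float, np.ndarray | Sequence[float]]],
    n_blocks: int = 5,
) -> pd.DataFrame:
    """Fraction (helical or folded) vs temperature with block-averaged SEM.

    ``per_temperature`` holds ``(temperature_K, per-frame indicator series)``
    pairs; indicators may be boolean or already fractional per frame (e.g.
    per-frame helicity).  Output rows are sorted by temperature.
    """
    if len(per_temperature) < 2:
        raise FfvalError("melting curve needs at least 2 temperatures")
    temps = [t for t, _ in per_temperature]
    if len(set(temps)) != len(temps):
        raise FfvalError(f"duplicate temperatures in melting-curve input: {sorted(temps)}")
    rows = []
    for t, series in per_temperature:
        v = np.asarray(series, dtype=float)
        if v.ndim == 2:  # frame x residue indicator matrix: average residues first
            v = v.mean(axis=1)
        if v.size == 0:
            raise FfvalError(f"empty indicator series at T={t} K")
        rows.append((float(t), float(v.mean()), _block_sem(v, n_blocks)))
    df = pd.DataFrame(rows, columns=["temperature_K", "fraction", "sem"])
    return df.sort_values("temperature_K", ignore_index=True)


# -- RMSD trace I/O ---------------------------------------------------------

def write_rmsd_traces(series: np.ndarray, path: str | Path, header_comment: str = "") -> None:
    """Write per-segment RMSD traces as CSV (columns frame, seg1..segN)."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    df = pd.DataFrame(
        {"frame": np.arange(series.shape[1]),
         **{f"seg{i + 1}": series[i] for i in range(series.shape[0])}}
    )
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_rmsd_traces(path: str | Path) -> np.ndarray:
    """Read per-segment RMSD traces written by :func:`write_rmsd_traces`."""
    df = pd.read_csv(path, comment="#")
    seg_cols = [c for c in df.columns if c.startswith("seg")]
    if not seg_cols:
        raise FfvalError(f"{path}: no segment columns (seg1..segN) found")
    return df[seg_cols].to_numpy().T
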