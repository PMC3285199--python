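"""Back-calculation of backbone NMR observables from conformational ensembles.

Three observable classes are supported, mirroring how folded-state ensembles
are usually validated against solution NMR:

* scalar (J) couplings from the Karplus relation
  ``J(phi) = A cos^2(phi + delta) + B cos(phi + delta) + C``, averaged over
  frames;
* residual dipolar couplings (RDCs) ``D = scale * b^T S b`` with a Saupe
  order tensor S fitted by linear least squares to the experimental values,
  summarised by the Q factor ``Q = rms(D_calc - D_exp) / rms(D_exp)``;
* Lipari-Szabo-type order parameters S^2, read off the internal orientational
  autocorrelation function ``C(t) = <P2(mu(tau) . mu(tau+t))>`` at lag times
  near the rotational correlation time tau_c (overall tumbling is removed by
  superposing every frame on a reference before extracting bond vectors).

Experimental tables are plain delimited text handled through pandas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import (
    BACKBONE_HEAVY,
    ConformationalEnsemble,
    backbone_dihedral,
    superpose_frames,
)
from .exceptions import FfvalError, MissingAtomError, UnderdeterminedError

__all__ = [
    "KarplusParameters",
    "DEFAULT_KARPLUS",
    "karplus_coupling",
    "calc_coupling_table",
    "CouplingAgreement",
    "coupling_agreement",
    "AlignmentTensor",
    "AlignmentTensorFit",
    "bond_dyadics",
    "fit_alignment_tensor",
    "back_calculate_rdc",
    "q_score",
    "CorrelationFunction",
    "internal_acf",
    "order_parameter",
    "order_parameter_table",
    "ExperimentalObservables",
    "observable_agreement_panel",
    "read_coupling_table",
    "read_rdc_table",
    "read_s2_table",
]

COUPLING_TYPES = ("HNHA", "HNCO", "HNCB", "HACO")


@dataclass(frozen=True)
class KarplusParameters:
    """Coefficients of ``J(phi) = A cos^2(phi+delta) + B cos(phi+delta) + C``.

    ``delta_deg`` is the phase offset relating phi to the dihedral spanned by
    the coupled nuclei (e.g. -60 deg for HN-HA).
    """

    A: float
    B: float
    C: float
    delta_deg: float
    coupling_type: str

    def __post_init__(self) -> None:
        if self.coupling_type not in COUPLING_TYPES:
            raise ValueError(
                f"coupling_type must be one of {COUPLING_TYPES}, got {self.coupling_type!r}"
            )
        for v in (self.A, self.B, self.C, self.delta_deg):
            if not np.isfinite(v):
                raise ValueError("Karplus parameters must be finite")


#: Default Karplus coefficient sets (Hz) for the four backbone couplings.
#: Transcribed from commonly used literature parameterisations of the
#: backbone Karplus curves; every report records the set actually used, and
#: they can be overridden in the pipeline config.
DEFAULT_KARPLUS: dict[str, KarplusParameters] = {
    "HNHA": KarplusParameters(7.97, -1.26, 0.63, -60.0, "HNHA"),
    "HNCO": KarplusParameters(4.29, -1.01, 0.00, 180.0, "HNCO"),
    "HNCB": KarplusParameters(3.06, -0.74, 0.13, 60.0, "HNCB"),
    "HACO": KarplusParameters(3.72, -2.18, 1.28, 120.0, "HACO"),
}


def karplus_coupling(phi_deg: np.ndarray | Sequence[float], params: KarplusParameters) -> float:
    """Ensemble-averaged scalar coupling (Hz) from a per-frame phi series."""
    phi = np.asarray(phi_deg, dtype=float)
    if phi.size == 0:
        raise ValueError("phi series is empty")
    c = np.cos(np.radians(phi + params.delta_deg))
    return float(np.mean(params.A * c * c + params.B * c + params.C))


def calc_coupling_table(
    ensemble: ConformationalEnsemble,
    params: Mapping[str, KarplusParameters] | None = None,
    residues: Sequence[int] | None = None,
    frame_slice: slice = slice(None),
) -> pd.DataFrame:
    """Back-calculated couplings for every residue with a defined phi.

    Returns a table with columns ``residue, type, value_hz``; residues whose
    phi is undefined (chain start) are silently omitted.
    """
    params = dict(params or DEFAULT_KARPLUS)
    if residues is None:
        residues = ensemble.residue_indices
    rows = []
    for r in residues:
        try:
            phi = backbone_dihedral(ensemble, r, "phi")[frame_slice]
        except MissingAtomError:
            continue
        for ctype, p in params.items():
            rows.append((r, ctype, karplus_coupling(phi, p)))
    return pd.DataFrame(rows, columns=["residue", "type", "value_hz"])


@dataclass
class CouplingAgreement:
    """RMS deviation between calculated and experimental couplings."""

    rmsd_hz: float
    n_matched: int
    unmatched_calc: list[tuple[int, str]]
    unmatched_exp: list[tuple[int, str]]


def coupling_agreement(calc: pd.DataFrame, exp: pd.DataFrame) -> CouplingAgreement:
    """Root-mean-square difference over matched (residue, type) rows.

    Rows present on only one side are reported in the result, never silently
    dropped.  An empty intersection is an error.
    """
    merged = calc.merge(exp, on=["residue", "type"], suffixes=("_calc", "_exp"))
    if merged.empty:
        raise FfvalError("no matching (residue, type) rows between calculated and experimental tables")
    keys_c = set(zip(calc["residue"], calc["type"]))
    keys_e = set(zip(exp["residue"], exp["type"]))
    diff = merged["value_hz_calc"].to_numpy() - merged["value_hz_exp"].to_numpy()
    return CouplingAgreement(
        rmsd_hz=float(np.sqrt(np.mean(diff**2))),
        n_matched=len(merged),
        unmatched_calc=sorted(keys_c - keys_e),
        unmatched_exp=sorted(keys_e - keys_c),
    )


# ---------------------------------------------------------------------------
# Residual dipolar couplings
# ---------------------------------------------------------------------------

@dataclass
class AlignmentTensor:
    """Traceless symmetric Saupe order tensor plus an overall coupling scale.

    ``D = scale * b^T S b`` for an internuclear unit vector b.  When fitted,
    the pair-specific maximal coupling is absorbed into the tensor and
    ``scale`` is 1 Hz.
    """

    saupe: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.saupe = np.asarray(self.saupe, dtype=float)
        if self.saupe.shape != (3, 3):
            raise ValueError("saupe must be 3x3")
        if not np.allclose(self.saupe, self.saupe.T, atol=1e-10):
            raise ValueError("saupe must be symmetric")
        if abs(np.trace(self.saupe)) > 1e-9 * max(1.0, np.abs(self.saupe).max()):
            raise ValueError("saupe must be traceless")


@dataclass
class AlignmentTensorFit:
    tensor: AlignmentTensor
    residuals_hz: np.ndarray
    rank: int


def bond_dyadics(
    ensemble: ConformationalEnsemble,
    pair: tuple[str, str] = ("N", "H"),
    residues: Sequence[int] | None = None,
    superpose: bool = True,
    superpose_selection: np.ndarray | None = None,
    frame_slice: slice = slice(None),
) -> tuple[list[tuple[int, str]], np.ndarray]:
    """Ensemble-averaged normalised bond dyadics ``<b b^T>`` per residue.

    Frames are first superposed on the first frame (backbone heavy atoms by
    default) so the average reflects internal structure, not tumbling.
    Returns ``(keys, dyadics)`` with keys ``(residue, "N-H")`` and dyadics of
    shape ``(n_pairs, 3, 3)``.
    """
    if residues is None:
        residues = [r for r in ensemble.residue_indices
                    if ensemble.has_atom(r, pair[0]) and ensemble.has_atom(r, pair[1])]
    else:
        for r in residues:
            if not (ensemble.has_atom(r, pair[0]) and ensemble.has_atom(r, pair[1])):
                raise MissingAtomError(f"residue {r} lacks atom pair {pair[0]}-{pair[1]}")
    if superpose:
        sel = superpose_selection
        if sel is None:
            sel = ensemble.select(BACKBONE_HEAVY)
        coords = superpose_frames(ensemble, ensemble.frames[0], sel)
    else:
        coords = ensemble.frames
    coords = coords[frame_slice]
    label = f"{pair[0]}-{pair[1]}"
    keys, dyads = [], []
    for r in residues:
        b = coords[:, ensemble.atom_index(r, pair[1]), :] - coords[:, ensemble.atom_index(r, pair[0]), :]
        b /= np.linalg.norm(b, axis=1, keepdims=True)
        dyads.append(np.einsum("fi,fj->ij", b, b) / b.shape[0])
        keys.append((r, label))
    return keys, np.asarray(dyads)


def _design_matrix(dyadics: np.ndarray) -> np.ndarray:
    """Map averaged dyadics to the 5 independent traceless-symmetric components."""
    m = np.asarray(dyadics, dtype=float)
    return np.column_stack(
        [
            m[:, 0, 0] - m[:, 2, 2],
            m[:, 1, 1] - m[:, 2, 2],
            2.0 * m[:, 0, 1],
            2.0 * m[:, 0, 2],
            2.0 * m[:, 1, 2],
        ]
    )


def fit_alignment_tensor(dyadics: np.ndarray, rdc_hz: np.ndarray | Sequence[float]) -> AlignmentTensorFit:
    """Least-squares Saupe tensor from averaged dyadics and measured RDCs.

    Solves ``D_i = tr(S <b_i b_i^T>)`` for the five independent components of
    the traceless symmetric S (in Hz; ``scale`` = 1).  Fewer than five
    couplings, or a rank-deficient design (degenerate bond directions),
    raises :class:`UnderdeterminedError`.
    """
    values = np.asarray(rdc_hz, dtype=float)
    dyadics = np.asarray(dyadics, dtype=float)
    if dyadics.shape[0] != values.shape[0]:
        raise ValueError("dyadics and RDC values differ in length")
    if values.shape[0] < 5:
        raise UnderdeterminedError(f"need >= 5 RDCs to fit a Saupe tensor, got {values.shape[0]}")
    a = _design_matrix(dyadics)
    sol, _, rank, _ = np.linalg.lstsq(a, values, rcond=None)
    if rank < 5:
        raise UnderdeterminedError(f"design matrix rank {rank} < 5: bond directions degenerate")
    sxx, syy, sxy, sxz, syz = sol
    saupe = np.array(
        [[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, -sxx - syy]]
    )
    tensor = AlignmentTensor(saupe=saupe, scale=1.0)
    residuals = a @ sol - values
    return AlignmentTensorFit(tensor=tensor, residuals_hz=residuals, rank=int(rank))


def back_calculate_rdc(
    dyadics: np.ndarray,
    tensor: AlignmentTensor,
    keys: Sequence[tuple[int, str]] | None = None,
) -> pd.DataFrame:
    """RDCs ``D = scale * tr(S <b b^T>)`` for each averaged dyadic."""
    dyadics = np.asarray(dyadics, dtype=float)
    values = tensor.scale * np.einsum("ij,nij->n", tensor.saupe, dyadics)
    if keys is None:
        keys = [(i + 1, "N-H") for i in range(len(values))]
    return pd.DataFrame(
        {"residue": [k[0] for k in keys], "pair": [k[1] for k in keys], "value_hz": values}
    )


def q_score(calc: pd.DataFrame | np.ndarray, exp: pd.DataFrame | np.ndarray) -> float:
    """Q factor ``sqrt(sum (Dc-De)^2 / sum De^2)`` over matched rows.

    DataFrame inputs are matched on (residue, pair); arrays are matched
    positionally.  Zero experimental RMS is an error.
    """
    if isinstance(calc, pd.DataFrame) and isinstance(exp, pd.DataFrame):
        merged = calc.merge(exp, on=["residue", "pair"], suffixes=("_calc", "_exp"))
        if merged.empty:
            raise FfvalError("no matching (residue, pair) rows for Q score")
        dc = merged["value_hz_calc"].to_numpy()
        de = merged["value_hz_exp"].to_numpy()
    else:
        dc = np.asarray(calc, dtype=float)
        de = np.asarray(exp, dtype=float)
        if dc.shape != de.shape or dc.size == 0:
            raise ValueError("calc and exp must be non-empty and equally shaped")
    denom = np.sum(de**2)
    if denom == 0:
        raise FfvalError("Q undefined: experimental RDCs have zero RMS")
    return float(np.sqrt(np.sum((dc - de) ** 2) / denom))


# ---------------------------------------------------------------------------
# Order parameters from internal autocorrelation functions
# ---------------------------------------------------------------------------

@dataclass
class CorrelationFunction:
    """Internal orientational autocorrelation ``C(t) = <P2(mu(0).mu(t))>``."""

    lags_ns: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lags_ns = np.asarray(self.lags_ns, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags_ns.shape != self.values.shape:
            raise ValueError("lags and values differ in shape")


def internal_acf(
    ensemble: ConformationalEnsemble,
    max_lag_ns: float | None = None,
    max_lag_frames: int | None = None,
    pair: tuple[str, str] = ("N", "H"),
    residues: Sequence[int] | None = None,
    superpose_selection: np.ndarray | None = None,
) -> dict[int, CorrelationFunction]:
    """Per-residue internal ACF of a bond vector (default backbone N-H).

    Every frame is superposed on the first frame over ``superpose_selection``
    (default: all backbone heavy atoms) to remove overall tumbling, then
    ``C(t) = <P2(mu(tau).mu(tau+t))>`` is estimated over all overlapping time
    origins.  ``max_lag`` may be given in ns (requires ``frame_interval_ns``)
    or directly in frames and must be shorter than the trajectory.
    """
    if max_lag_frames is None:
        if max_lag_ns is None:
            raise ValueError("give max_lag_ns or max_lag_frames")
        if ensemble.frame_interval_ns is None:
            raise ValueError("ensemble.frame_interval_ns is required for max_lag_ns")
        max_lag_frames = int(round(max_lag_ns / ensemble.frame_interval_ns))
    if max_lag_frames >= ensemble.n_frames:
        raise ValueError(
            f"max_lag ({max_lag_frames} frames) must be < trajectory length ({ensemble.n_frames})"
        )
    dt = ensemble.frame_interval_ns if ensemble.frame_interval_ns is not None else 1.0
    if residues is None:
        residues = [r for r in ensemble.residue_indices
                    if ensemble.has_atom(r, pair[0]) and ensemble.has_atom(r, pair[1])]
    else:
        for r in residues:
            if not (ensemble.has_atom(r, pair[0]) and ensemble.has_atom(r, pair[1])):
                raise MissingAtomError(f"residue {r} lacks atom pair {pair[0]}-{pair[1]}")
    sel = superpose_selection
    if sel is None:
        sel = ensemble.select(BACKBONE_HEAVY)
    coords = superpose_frames(ensemble, ensemble.frames[0], sel)

    lags = np.arange(max_lag_frames + 1)
    out: dict[int, CorrelationFunction] = {}
    for r in residues:
        b = coords[:, ensemble.atom_index(r, pair[1]), :] - coords[:, ensemble.atom_index(r, pair[0]), :]
        b /= np.linalg.norm(b, axis=1, keepdims=True)
        c = np.empty(max_lag_frames + 1)
        c[0] = 1.0
        for lag in range(1, max_lag_frames + 1):
            dots = np.einsum("ij,ij->i", b[:-lag], b[lag:])
            c[lag] = np.mean(1.5 * dots * dots - 0.5)
        out[r] = CorrelationFunction(lags_ns=lags * dt, values=c)
    return out


def order_parameter(acf: CorrelationFunction, tau_c_ns: float, window: float = 0.2) -> float:
    """S^2 read off the ACF plateau near the rotational correlation time.

    Averages C(t) over lags in ``[tau_c*(1-window), tau_c*(1+window)]`` and
    clips to [0, 1] with a warning if the estimate falls outside.
    """
    lo, hi = tau_c_ns * (1 - window), tau_c_ns * (1 + window)
    if hi > acf.lags_ns.max() + 1e-12:
        raise ValueError(
            f"lag window upper edge {hi:.3g} ns exceeds available lags (max {acf.lags_ns.max():.3g} ns)"
        )
    mask = (acf.lags_ns >= lo) & (acf.lags_ns <= hi)
    if not mask.any():
        raise ValueError(f"no ACF lags inside window [{lo:.3g}, {hi:.3g}] ns")
    s2 = float(np.mean(acf.values[mask]))
    if s2 < -1e-9 or s2 > 1.0 + 1e-9:
        warnings.warn(f"S^2 estimate {s2:.4f} outside [0, 1]; clipping", stacklevel=2)
    return min(max(s2, 0.0), 1.0)


def order_parameter_table(
    ensemble: ConformationalEnsemble,
    tau_c_ns: float,
    window: float = 0.2,
    pair: tuple[str, str] = ("N", "H"),
    residues: Sequence[int] | None = None,
    superpose_selection: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-residue S^2 table (columns ``residue, s2``) via :func:`internal_acf`."""
    acfs = internal_acf(
        ensemble,
        max_lag_ns=tau_c_ns * (1 + window),
        pair=pair,
        residues=residues,
        superpose_selection=superpose_selection,
    )
    rows = [(r, order_parameter(acf, tau_c_ns, window)) for r, acf in sorted(acfs.items())]
    return pd.DataFrame(rows, columns=["residue", "s2"])


# ---------------------------------------------------------------------------
# Aggregated agreement panel
# ---------------------------------------------------------------------------

@dataclass
class ExperimentalObservables:
    """Bundle of experimental tables for one protein (any subset may be set)."""

    couplings: pd.DataFrame | None = None
    rdcs: pd.DataFrame | None = None
    s2: pd.DataFrame | None = None
    karplus: Mapping[str, KarplusParameters] = field(default_factory=lambda: dict(DEFAULT_KARPLUS))
    tau_c_ns: float | None = None


def _block_slices(n_frames: int, n_blocks: int) -> list[slice]:
    edges = np.linspace(0, n_frames, n_blocks + 1, dtype=int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def _sem(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(np.std(v, ddof=1) / np.sqrt(v.size))


def observable_agreement_panel(
    ensemble: ConformationalEnsemble,
    experimental: ExperimentalObservables,
    n_blocks: int = 5,
    s2_window: float = 0.2,
    superpose_selection: np.ndarray | None = None,
) -> pd.DataFrame:
    """Point estimates and block-averaged SEMs for all configured observables.

    For each observable class present in ``experimental`` the agreement metric
    (coupling RMSD in Hz, RDC Q factor, S^2 RMSD) is computed on the full
    ensemble, and again on ``n_blocks`` contiguous frame blocks; the standard
    error of the mean across blocks is reported alongside.  Returns one row
    per observable with columns
    ``observable, metric, value, sem, n_matched, n_unmatched_exp``.
    """
    rows = []
    slices = _block_slices(ensemble.n_frames, n_blocks)

    if experimental.couplings is not None:
        exp = experimental.couplings
        full = coupling_agreement(calc_coupling_table(ensemble, experimental.karplus), exp)
        blocks = [
            coupling_agreement(
                calc_coupling_table(ensemble, experimental.karplus, frame_slice=s), exp
            ).rmsd_hz
            for s in slices
        ]
        rows.append(("couplings", "rmsd_hz", full.rmsd_hz, _sem(blocks),
                     full.n_matched, len(full.unmatched_exp)))

    if experimental.rdcs is not None:
        exp = experimental.rdcs

        def _q(frame_slice: slice) -> tuple[float, int, int]:
            keys, dy = bond_dyadics(
                ensemble, superpose_selection=superpose_selection, frame_slice=frame_slice
            )
            calc_keys = {k for k in keys}
            exp_keys = set(zip(exp["residue"], exp["pair"]))
            matched = [i for i, k in enumerate(keys) if k in exp_keys]
            if len(matched) < 5:
                raise UnderdeterminedError("fewer than 5 RDCs match the topology")
            order = {k: v for k, v in zip(zip(exp["residue"], exp["pair"]), exp["value_hz"])}
            vals = np.array([order[keys[i]] for i in matched])
            fit = fit_alignment_tensor(dy[matched], vals)
            calc = back_calculate_rdc(dy[matched], fit.tensor, [keys[i] for i in matched])
            return (
                q_score(calc["value_hz"].to_numpy(), vals),
                len(matched),
                len(exp_keys - calc_keys),
            )

        q_full, n_matched, n_unmatched = _q(slice(None))
        q_blocks = [_q(s)[0] for s in slices]
        rows.append(("rdcs", "q_score", q_full, _sem(q_blocks), n_matched, n_unmatched))

    if experimental.s2 is not None:
        if experimental.tau_c_ns is None:
            raise ValueError("tau_c_ns is required to compute order parameters")
        exp = experimental.s2

        def _s2_rmsd(sub: ConformationalEnsemble) -> tuple[float, int, int]:
            calc = order_parameter_table(
                sub, experimental.tau_c_ns, s2_window,
                superpose_selection=superpose_selection,
            )
            merged = calc.merge(exp, on="residue", suffixes=("_calc", "_exp"))
            if merged.empty:
                raise FfvalError("no matching residues between calculated and experimental S^2")
            d = merged["s2_calc"].to_numpy() - merged["s2_exp"].to_numpy()
            return (
                float(np.sqrt(np.mean(d**2))),
                len(merged),
                len(set(exp["residue"]) - set(calc["residue"])),
            )

        full_rmsd, n_matched, n_unmatched = _s2_rmsd(ensemble)
        blocks = []
        for s in slices:
            sub = ConformationalEnsemble(
                atoms=ensemble.atoms,
                frames=ensemble.frames[s],
                frame_interval_ns=ensemble.frame_interval_ns,
                temperature_K=ensemble.temperature_K,
            )
            blocks.append(_s2_rmsd(sub)[0])
        rows.append(("s2", "rmsd", full_rmsd, _sem(blocks), n_matched, n_unmatched))

    return pd.DataFrame(
        rows,
        columns=["observable", "metric", "value", "sem", "n_matched", "n_unmatched_exp"],
    )


# ---------------------------------------------------------------------------
# Experimental table readers (TSV/CSV with headers)
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"experimental table not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FfvalError(f"{path}: missing required columns {missing}")
    return df


def read_coupling_table(path: str | Path) -> pd.DataFrame:
    """Scalar couplings: columns ``residue, type, value_hz``."""
    return _read_table(path, ["residue", "type", "value_hz"])


def read_rdc_table(path: str | Path) -> pd.DataFrame:
    """RDCs: columns ``residue, pair, value_hz`` (optional ``medium``)."""
    return _read_table(path, ["residue", "pair", "value_hz"])


def read_s2_table(path: str | Path) -> pd.DataFrame:
    """Order parameters: columns ``residue, s2``."""
    return _read_table(path, ["residue", "s2"])
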