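"""Synthetic ensembles, traces and observable tables with known ground truth.

These generators emulate the statistical structure the analysis assumes —
not the physics that produces it — so every pipeline stage can be exercised
against an exact answer:

* two-state folding/unfolding traces: a continuous-time Markov chain with
  exponential dwell times, emitted as per-segment RMSD levels plus Gaussian
  noise, with the true transition list kept;
* helix-coil ensembles: a nucleation-propagation (Zimm-Bragg-type) chain
  sampled exactly by transfer-matrix conditional sampling, with the analytic
  mean helicity computed from the same matrix;
* diffusion-in-a-cone ensembles: per-residue N-H vectors resampled uniformly
  within a cone about their reference orientation, with the closed-form
  S^2 = [cos(t0) (1 + cos(t0)) / 2]^2 attached as metadata;
* RDC and scalar-coupling datasets generated from a known Saupe tensor /
  Karplus curve with additive noise.

Every generator consumes an explicit seed (or numpy Generator) and is
byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .ensemble import (
    AtomRecord,
    ConformationalEnsemble,
    reconstruct_amide_hydrogens,
)
from .observables import AlignmentTensor, KarplusParameters, karplus_coupling

__all__ = [
    "build_ideal_peptide",
    "TwoStateParams",
    "TwoStateTrace",
    "generate_two_state_trace",
    "generate_two_state_coordinate_ensemble",
    "HelixCoilParams",
    "zimm_bragg_helicity",
    "sample_helix_coil",
    "generate_helix_coil_ensemble",
    "ConeMotionParams",
    "cone_order_parameter",
    "generate_cone_ensemble",
    "random_unit_vectors",
    "random_alignment_tensor",
    "generate_rdc_dataset",
    "generate_coupling_dataset",
]

GAS_CONSTANT_KCAL = 1.987204e-3  # kcal / (mol K)


def _rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Ideal peptide geometry (reference structures for the generators)
# ---------------------------------------------------------------------------

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_peptide(
    n_res: int,
    phi_deg: float | Sequence[float] = -57.0,
    psi_deg: float | Sequence[float] = -47.0,
    omega_deg: float = 180.0,
    with_hydrogens: bool = True,
    residue_name: str = "ALA",
) -> ConformationalEnsemble:
    """Single-frame backbone (N, CA, C, O, optional amide H) from internal coordinates.

    Defaults build an ideal alpha-helix.  ``phi_deg``/``psi_deg`` may be
    scalars or per-residue sequences; amide hydrogens are reconstructed from
    ideal amide geometry (residue 1 has none).
    """
    phi = np.broadcast_to(np.asarray(phi_deg, dtype=float), (n_res,))
    psi = np.broadcast_to(np.asarray(psi_deg, dtype=float), (n_res,))
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []

    def add(name: str, res: int, xyz: np.ndarray, element: str | None = None) -> None:
        atoms.append(AtomRecord(name, res, residue_name, element or name[0]))
        coords.append(np.asarray(xyz, dtype=float))

    # first residue in a canonical frame
    n0 = np.zeros(3)
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = math.radians(_ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    add("N", 1, n0, "N")
    add("CA", 1, ca0)
    add("C", 1, c0)
    prev = {"N": n0, "CA": ca0, "C": c0}
    for i in range(2, n_res + 1):
        n_i = _nerf(prev["N"], prev["CA"], prev["C"],
                    _BOND["C-N"], _ANGLE["CA-C-N"], psi[i - 2])
        o_prev = _nerf(prev["N"], prev["CA"], prev["C"],
                       _BOND["C-O"], _ANGLE["CA-C-O"], psi[i - 2] + 180.0)
        ca_i = _nerf(prev["CA"], prev["C"], n_i,
                     _BOND["N-CA"], _ANGLE["C-N-CA"], omega_deg)
        c_i = _nerf(prev["C"], n_i, ca_i,
                    _BOND["CA-C"], _ANGLE["N-CA-C"], phi[i - 1])
        add("O", i - 1, o_prev, "O")
        add("N", i, n_i, "N")
        add("CA", i, ca_i)
        add("C", i, c_i)
        prev = {"N": n_i, "CA": ca_i, "C": c_i}
    # carbonyl O of the last residue, using its psi for a consistent plane
    o_last = _nerf(prev["N"], prev["CA"], prev["C"],
                   _BOND["C-O"], _ANGLE["CA-C-O"], psi[n_res - 1] + 180.0)
    add("O", n_res, o_last, "O")

    ens = ConformationalEnsemble(atoms=atoms, frames=np.stack(coords)[None, :, :])
    if with_hydrogens:
        ens = reconstruct_amide_hydrogens(ens)
    return ens


# ---------------------------------------------------------------------------
# Two-state folding/unfolding traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStateParams:
    """Kinetic and emission parameters of the two-state trace generator.

    Defaults describe the benchmark design point: equal folding and
    unfolding rates ``1/T`` with a simulation horizon of ``10 T`` (here
    T = 1 ns of nominal time), starting unfolded, with RMSD emission levels
    well separated from the CLN025-style 1.0 / 4.0 Angstrom cutoffs.
    """

    k_fold_per_ns: float = 1.0
    k_unfold_per_ns: float = 1.0
    duration_ns: float = 10.0
    frame_interval_ns: float = 0.01
    folded_levels: tuple[float, ...] = (0.5,)
    unfolded_levels: tuple[float, ...] = (6.0,)
    level_sd: float = 0.1
    start_folded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_fold_per_ns < 0 or self.k_unfold_per_ns < 0:
            raise ValueError("rates must be >= 0")
        if len(self.folded_levels) != len(self.unfolded_levels):
            raise ValueError("folded/unfolded level tuples must have equal length")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be > 0")


@dataclass
class TwoStateTrace:
    """Emitted RMSD traces plus the ground truth behind them.

    ``events`` lists transitions of the *frame-discretised* state sequence
    (0-based frame index, "fold"/"unfold") — dwells shorter than one frame
    interval are invisible at the emitted resolution and are likewise absent
    from the truth, so a perfect detector can match it exactly.
    """

    rmsd: np.ndarray            # (n_segments, n_frames)
    folded: np.ndarray          # (n_frames,) bool, true state per frame
    events: list[tuple[int, str]]


def generate_two_state_trace(
    params: TwoStateParams,
    rng: np.random.Generator | None = None,
) -> TwoStateTrace:
    """Sample a two-state Markov trace and emit noisy per-segment RMSD series."""
    rng = _rng(params.seed) if rng is None else rng
    n_frames = int(round(params.duration_ns / params.frame_interval_ns))
    n_seg = len(params.folded_levels)
    if n_frames == 0:
        return TwoStateTrace(
            rmsd=np.empty((n_seg, 0)), folded=np.empty(0, dtype=bool), events=[]
        )

    # continuous-time state path, then sample at frame times
    folded_state = params.start_folded
    t = 0.0
    times = np.arange(n_frames) * params.frame_interval_ns
    folded = np.empty(n_frames, dtype=bool)
    cursor = 0
    while cursor < n_frames:
        rate = params.k_unfold_per_ns if folded_state else params.k_fold_per_ns
        dwell = math.inf if rate == 0 else rng.exponential(1.0 / rate)
        t_next = t + dwell
        upto = np.searchsorted(times, t_next, side="left")
        folded[cursor:upto] = folded_state
        cursor = upto
        folded_state = not folded_state
        t = t_next

    events: list[tuple[int, str]] = []
    for f in range(1, n_frames):
        if folded[f] != folded[f - 1]:
            events.append((f, "fold" if folded[f] else "unfold"))

    levels = np.where(
        folded[None, :],
        np.asarray(params.folded_levels)[:, None],
        np.asarray(params.unfolded_levels)[:, None],
    )
    rmsd = levels + params.level_sd * rng.standard_normal((n_seg, n_frames))
    np.clip(rmsd, 0.0, None, out=rmsd)
    return TwoStateTrace(rmsd=rmsd, folded=folded, events=events)


def generate_two_state_coordinate_ensemble(
    params: TwoStateParams,
    reference: ConformationalEnsemble | None = None,
    coordinate_noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[ConformationalEnsemble, TwoStateTrace]:
    """Coordinate-emitting variant of the two-state generator.

    Folded frames are the reference structure plus small Gaussian jitter;
    unfolded frames interpolate towards an expanded decoy (the reference
    scaled about its centroid) so the Calpha RMSD is far above the unfold
    thresholds.  Intended for end-to-end pipeline tests; the RMSD levels of
    ``params`` are ignored, only its kinetics are used.
    """
    rng = _rng(params.seed) if rng is None else rng
    if reference is None:
        reference = build_ideal_peptide(10, with_hydrogens=False)
    trace = generate_two_state_trace(params, rng)
    ref = reference.frames[0]
    centroid = ref.mean(axis=0)
    decoy = centroid + 3.0 * (ref - centroid)  # ~2x atom spread => large RMSD
    n_frames = trace.folded.size
    frames = np.empty((n_frames, ref.shape[0], 3))
    for f in range(n_frames):
        base = ref if trace.folded[f] else decoy
        frames[f] = base + coordinate_noise_sd * rng.standard_normal(ref.shape)
    ens = ConformationalEnsemble(
        atoms=list(reference.atoms),
        frames=frames,
        frame_interval_ns=params.frame_interval_ns,
        metadata={"true_events": list(trace.events)},
    )
    return ens, trace


# ---------------------------------------------------------------------------
# Helix-coil (nucleation-propagation) ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixCoilParams:
    """Zimm-Bragg-type chain with van't Hoff temperature dependence.

    The per-residue propagation weight is
    ``w(T) = exp(-dH/R (1/T - 1/T_m))`` (so w = 1 at ``t_m_K`` and helix is
    favoured below it) and ``sigma`` multiplies the first residue of every
    helical run.  Defaults emulate a 15-mer alanine-rich peptide melting
    over 275-320 K: dH = -1.3 kcal/mol per residue, T_m = 305 K,
    sigma = 0.003 (typical nucleation penalties are 1e-3 to 1e-2).
    ``weights`` may override the van't Hoff curve with explicit per-
    temperature values.
    """

    n_res: int = 15
    sigma: float = 0.003
    temperatures_K: tuple[float, ...] = (275.0, 290.0, 300.0, 310.0, 320.0)
    n_frames: int = 10_000
    seed: int = 0
    dh_kcal_mol: float = -1.3
    t_m_K: float = 305.0
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.sigma <= 1:
            raise ValueError("sigma must be in (0, 1]")
        if self.weights is not None and len(self.weights) != len(self.temperatures_K):
            raise ValueError("weights must match temperatures in length")

    def weight(self, temperature_K: float) -> float:
        if self.weights is not None:
            return self.weights[self.temperatures_K.index(temperature_K)]
        return math.exp(
            -self.dh_kcal_mol / GAS_CONSTANT_KCAL * (1.0 / temperature_K - 1.0 / self.t_m_K)
        )


def _transfer_matrix(w: float, sigma: float) -> np.ndarray:
    # states (coil, helix); entry [prev, cur]; nucleation costs sigma*w
    return np.array([[1.0, sigma * w], [1.0, w]])


def zimm_bragg_helicity(n_res: int, w: float, sigma: float) -> float:
    """Exact mean helical fraction of the nucleation-propagation chain."""
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    m = _transfer_matrix(w, sigma)
    # forward vectors a_i = e_coil M^i, backward b_i = M^(n-i) 1
    a = np.zeros((n_res + 1, 2))
    a[0] = (1.0, 0.0)
    for i in range(1, n_res + 1):
        a[i] = a[i - 1] @ m
    b = np.zeros((n_res + 1, 2))
    b[n_res] = (1.0, 1.0)
    for i in range(n_res - 1, -1, -1):
        b[i] = m @ b[i + 1]
    z = a[0] @ b[0]
    p_helix = np.array([a[i][1] * b[i][1] / z for i in range(1, n_res + 1)])
    return float(p_helix.mean())


def sample_helix_coil(
    n_res: int, w: float, sigma: float, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact samples from the chain distribution, shape ``(n_frames, n_res)`` bool.

    Sequential conditional sampling: P(s_i | s_{i-1}) is proportional to
    M[s_{i-1}, s_i] times the backward partial sum, so draws are exact, not
    Markov-chain-Monte-Carlo approximations.
    """
    m = _transfer_matrix(w, sigma)
    b = np.zeros((n_res + 1, 2))
    b[n_res] = (1.0, 1.0)
    for i in range(n_res - 1, -1, -1):
        b[i] = m @ b[i + 1]
    states = np.zeros((n_frames, n_res), dtype=bool)
    u = rng.random((n_frames, n_res))
    prev = np.zeros(n_frames, dtype=int)  # virtual coil before residue 1
    for i in range(n_res):
        w_coil = m[prev, 0] * b[i + 1][0]
        w_helix = m[prev, 1] * b[i + 1][1]
        p_helix = w_helix / (w_coil + w_helix)
        cur = u[:, i] < p_helix
        states[:, i] = cur
        prev = cur.astype(int)
    return states


def generate_helix_coil_ensemble(
    params: HelixCoilParams,
) -> tuple[dict[float, np.ndarray], dict[float, float]]:
    """Per-temperature helicity indicator matrices plus analytic means.

    Returns ``(indicators, analytic)`` where ``indicators[T]`` is an
    ``(n_frames, n_res)`` boolean matrix and ``analytic[T]`` the exact
    transfer-matrix mean helicity at that temperature.
    """
    rng = _rng(params.seed)
    indicators: dict[float, np.ndarray] = {}
    analytic: dict[float, float] = {}
    for t in params.temperatures_K:
        w = params.weight(t)
        indicators[t] = sample_helix_coil(params.n_res, w, params.sigma, params.n_frames, rng)
        analytic[t] = zimm_bragg_helicity(params.n_res, w, params.sigma)
    return indicators, analytic


# ---------------------------------------------------------------------------
# Diffusion-in-a-cone ensembles (order-parameter test bed)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConeMotionParams:
    """Restricted-amplitude N-H motion: uniform resampling within a cone."""

    half_angle_deg: Mapping[int, float] | float = 20.0
    n_frames: int = 10_000
    seed: int = 0
    tumble: bool = True  # apply a random global rigid motion per frame

    def angle_for(self, residue: int) -> float | None:
        if isinstance(self.half_angle_deg, Mapping):
            return self.half_angle_deg.get(residue)
        return float(self.half_angle_deg)


def cone_order_parameter(half_angle_deg: float) -> float:
    """Closed-form S^2 of uniform diffusion in a cone of given half-angle."""
    c = math.cos(math.radians(half_angle_deg))
    return (c * (1.0 + c) / 2.0) ** 2


def _sample_in_cone(
    axis: np.ndarray, half_angle_deg: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit vectors uniform on the spherical cap of half-angle about ``axis``."""
    cos0 = math.cos(math.radians(half_angle_deg))
    cos_t = rng.uniform(cos0, 1.0, size=n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    # orthonormal frame around the axis
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return (
        sin_t[:, None] * np.cos(phi)[:, None] * e1
        + sin_t[:, None] * np.sin(phi)[:, None] * e2
        + cos_t[:, None] * a
    )


def generate_cone_ensemble(
    params: ConeMotionParams,
    reference: ConformationalEnsemble | None = None,
    frame_interval_ns: float = 0.01,
) -> ConformationalEnsemble:
    """Ensemble whose N-H vectors wobble in per-residue cones.

    Heavy atoms stay at their reference positions (internal geometry rigid);
    each frame the amide H of every configured residue is redrawn uniformly
    within its cone about the reference N-H direction, which makes
    successive frames orientationally independent — the internal ACF is flat
    at the cone's analytic S^2 for every positive lag.  With
    ``params.tumble`` a random global rotation + translation is applied per
    frame, to be removed again by the analysis superposition step.
    Ground-truth values are stored in ``metadata["true_s2"]``.
    """
    rng = _rng(params.seed)
    if reference is None:
        n_res = (
            max(params.half_angle_deg) if isinstance(params.half_angle_deg, Mapping) else 6
        )
        reference = build_ideal_peptide(max(int(n_res), 3))
    ref = reference.frames[0]
    frames = np.repeat(ref[None, :, :], params.n_frames, axis=0)

    true_s2: dict[int, float] = {}
    for r in reference.residue_indices:
        if not (reference.has_atom(r, "N") and reference.has_atom(r, "H")):
            continue
        theta0 = params.angle_for(r)
        if theta0 is None:
            continue
        i_n = reference.atom_index(r, "N")
        i_h = reference.atom_index(r, "H")
        nh = ref[i_h] - ref[i_n]
        length = np.linalg.norm(nh)
        if theta0 > 0:
            dirs = _sample_in_cone(nh, theta0, params.n_frames, rng)
            frames[:, i_h, :] = frames[:, i_n, :] + length * dirs
        true_s2[r] = cone_order_parameter(theta0)

    if params.tumble:
        rots = Rotation.random(params.n_frames, random_state=rng).as_matrix()
        shifts = rng.uniform(-20.0, 20.0, size=(params.n_frames, 3))
        frames = np.einsum("fij,faj->fai", rots, frames) + shifts[:, None, :]

    return ConformationalEnsemble(
        atoms=list(reference.atoms),
        frames=frames,
        frame_interval_ns=frame_interval_ns,
        metadata={"true_s2": true_s2},
    )


# ---------------------------------------------------------------------------
# RDC and scalar-coupling datasets
# ---------------------------------------------------------------------------

def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def random_alignment_tensor(rng: np.random.Generator, magnitude_hz: float = 10.0) -> AlignmentTensor:
    """Random traceless symmetric Saupe tensor with entries of order ``magnitude_hz``."""
    a = rng.standard_normal((3, 3))
    s = 0.5 * (a + a.T)
    s -= np.eye(3) * np.trace(s) / 3.0
    s *= magnitude_hz / max(np.abs(s).max(), 1e-12)
    return AlignmentTensor(saupe=s, scale=1.0)


def generate_rdc_dataset(
    bond_vectors: np.ndarray,
    tensor: AlignmentTensor,
    noise_sd_hz: float = 0.0,
    seed: int | np.random.Generator = 0,
    keys: Sequence[tuple[int, str]] | None = None,
) -> pd.DataFrame:
    """RDC table ``D = scale b^T S b + noise`` from known bond directions.

    ``bond_vectors`` is ``(n, 3)`` (normalised internally).  The generating
    tensor, noise level and noiseless values are recorded in ``attrs``.
    """
    rng = _rng(seed)
    b = np.asarray(bond_vectors, dtype=float)
    b = b / np.linalg.norm(b, axis=1, keepdims=True)
    clean = tensor.scale * np.einsum("ni,ij,nj->n", b, tensor.saupe, b)
    noisy = clean + noise_sd_hz * rng.standard_normal(clean.shape)
    if keys is None:
        keys = [(i + 1, "N-H") for i in range(len(clean))]
    df = pd.DataFrame(
        {"residue": [k[0] for k in keys], "pair": [k[1] for k in keys], "value_hz": noisy}
    )
    df.attrs["true_tensor"] = tensor
    df.attrs["true_values_hz"] = clean
    df.attrs["noise_sd_hz"] = noise_sd_hz
    return df


def generate_coupling_dataset(
    phi_samples_deg: Mapping[int, np.ndarray | Sequence[float]],
    params: KarplusParameters,
    noise_sd_hz: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scalar-coupling table from per-residue phi distributions.

    Returns ``(noisy, truth)`` tables; ``truth`` holds the exact ensemble
    means ``<J(phi)>`` without noise.
    """
    rng = _rng(seed)
    rows_true, rows_noisy = [], []
    for r in sorted(phi_samples_deg):
        j = karplus_coupling(np.asarray(phi_samples_deg[r], dtype=float), params)
        rows_true.append((r, params.coupling_type, j))
        rows_noisy.append((r, params.coupling_type, j + noise_sd_hz * rng.standard_normal()))
    cols = ["residue", "type", "value_hz"]
    return pd.DataFrame(rows_noisy, columns=cols), pd.DataFrame(rows_true, columns=cols)
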