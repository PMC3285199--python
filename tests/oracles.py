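"""Independent oracles used to cross-check the implementation.

These deliberately use different algorithms from the package: the quaternion
(Horn) eigenvalue method for superposition RMSD, a plane-normal formulation
for dihedrals, and brute-force state enumeration for the helix-coil chain.
"""

from __future__ import annotations

import itertools

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD via the largest eigenvalue of Horn's 4x4 key matrix."""
    x = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    y = np.asarray(reference, float) - np.mean(reference, axis=0)
    n = x.shape[0]
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    msd = max((np.sum(x**2) + np.sum(y**2) - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))


def dihedral_oracle(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees from plane normals plus a triple-product sign."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    # IUPAC: the angle defined above is measured from the cis (0) arrangement
    return float(ang if ang != -180.0 else 180.0)


def helicity_by_enumeration(n_res: int, w: float, sigma: float) -> float:
    """Exact mean helicity by summing over all 2**n chain configurations."""
    z = 0.0
    h_sum = 0.0
    for states in itertools.product((0, 1), repeat=n_res):
        weight = 1.0
        prev = 0
        for s in states:
            if s == 1:
                weight *= sigma * w if prev == 0 else w
            prev = s
        z += weight
        h_sum += weight * sum(states) / n_res
    return h_sum / z
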