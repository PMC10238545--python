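"""Low-level 3D geometry: internal-coordinate atom placement, torsions,
ideal-geometry hydrogen construction, and least-squares superposition."""

from __future__ import annotations

import numpy as np

# Ideal backbone geometry (lengths in Angstrom, angles in degrees).
BOND = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.521,
    ("N", "H"): 1.041,
    ("CA", "HA"): 1.117,
}
ANGLE = {
    ("N", "CA", "C"): 111.0,
    ("CA", "C", "N"): 116.2,
    ("C", "N", "CA"): 121.7,
    ("CA", "C", "O"): 120.8,
}


def normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given atoms A-B-C, the C-D bond length, the B-C-D angle
    and the A-B-C-D torsion (natural extension reference frame)."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = normalize(c - b)
    n = normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Torsion angle in degrees, IUPAC sign convention."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = n1 @ n2
    y = np.linalg.norm(b2) * (b1 @ n2)
    return float(np.degrees(np.arctan2(y, x)))


def build_amide_h(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray,
                  length: float = 1.041) -> np.ndarray:
    """Amide proton: in-plane on nitrogen, anti to the bisector of the
    C'(i-1)-N and CA-N directions."""
    d = -(normalize(c_prev - n) + normalize(ca - n))
    return n + length * normalize(d)


def build_ha(ca: np.ndarray, n: np.ndarray, c: np.ndarray, cb: np.ndarray,
             length: float = 1.117) -> np.ndarray:
    """Alpha proton by tetrahedral completion of the other three
    substituents on CA."""
    d = -(normalize(n - ca) + normalize(c - ca) + normalize(cb - ca))
    return ca + length * normalize(d)


def build_ha_gly(ca: np.ndarray, n: np.ndarray, c: np.ndarray,
                 length: float = 1.117) -> np.ndarray:
    """One of the two glycine alpha protons (HA2-like position)."""
    un, uc = normalize(n - ca), normalize(c - ca)
    bis = -(un + uc)
    perp = np.cross(un, uc)
    d = normalize(bis) * np.cos(np.deg2rad(54.75)) + \
        normalize(perp) * np.sin(np.deg2rad(54.75))
    return ca + length * normalize(d)


def build_cb(ca: np.ndarray, n: np.ndarray, c: np.ndarray,
             length: float = 1.521) -> np.ndarray:
    """Beta carbon at the L-configuration tetrahedral site."""
    un, uc = normalize(n - ca), normalize(c - ca)
    s = -(un + uc)
    p = np.cross(un, uc)
    # coefficients give N-CA-CB and C-CA-CB angles near 110.5 deg
    cos_t = np.cos(np.deg2rad(110.5))
    a = cos_t / (s @ un)
    rest = 1.0 - a * a * (s @ s)
    b = np.sqrt(max(rest, 0.0) / (p @ p))
    return ca + length * normalize(a * s - b * p)


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           allow_reflection: bool = False):
    """Optimal least-squares superposition of `mobile` onto `reference`.

    Returns (rotation, translation, rmsd) such that
    mobile @ rotation.T + translation approximates reference.
    Raises ValueError if the optimal transform requires a reflection and
    reflections are not allowed (chirality mismatch).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need >=3 paired atoms of identical shape")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d < 0 and not allow_reflection:
        u[:, -1] *= -1.0
    rot = vt.T @ u.T
    if np.linalg.det(rot) < 0:
        raise ValueError("superposition requires a reflection")
    moved = (mobile - mc) @ rot.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, rc - rot @ mc, rmsd


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about `axis` by `angle_deg` (Rodrigues)."""
    k = normalize(np.asarray(axis, dtype=float))
    t = np.deg2rad(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * kx + (1 - np.cos(t)) * (kx @ kx)
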