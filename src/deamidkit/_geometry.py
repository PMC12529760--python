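"""Low-level vector geometry shared by the descriptor modules.

All routines take coordinates in nm and are plain-numpy so they can be
applied frame-wise to small atom sets without trajectory-library overhead.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "minimum_image",
    "pairwise_min_image_distances",
    "dihedral",
    "kabsch_fit",
    "kabsch_rmsd",
]


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention.

    Parameters
    ----------
    d : (..., 3) displacement vectors in nm.
    box : (3,) or (..., 3) orthorhombic box lengths in nm.
    """
    d = np.asarray(d, dtype=float)
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def pairwise_min_image_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Distances |a_i - b_j| under the minimum image; returns (len(a), len(b))."""
    d = a[:, None, :] - b[None, :, :]
    d = minimum_image(d, box)
    return np.linalg.norm(d, axis=-1)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle (degrees, in (-180, 180]) for stacked points.

    Accepts (..., 3) arrays; the IUPAC sign convention (cis = 0) is used.
    """
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(b1 / np.linalg.norm(b1, axis=-1, keepdims=True), n1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is half-open as documented
    return np.where(ang <= -180.0, ang + 360.0, ang)


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` (N,3) onto ``reference`` (N,3).

    Returns the transformed mobile coordinates (optimal rotation after
    centroid removal, translated onto the reference centroid). Unweighted.
    """
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    rot = u @ d @ vt
    return mob_c @ rot + reference.mean(axis=0)


def kabsch_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD (nm) between two conformations after optimal superposition."""
    fitted = kabsch_fit(mobile, reference)
    return float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
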