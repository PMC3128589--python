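"""Backbone geometry of the caterpillar model.

The caterpillar representation keeps one interaction sphere per residue
centred on CA plus the explicit backbone atoms N, C', O and amide H needed
for directional hydrogen bonds.  The only degrees of freedom are the
(phi, psi) torsions; every bond length, bond angle and the peptide torsion
omega are fixed at standard values shared by all residues.

This module builds chains from torsions, inverts that construction, and
computes the structural order parameters used throughout (DRMSD, Kabsch
RMSD, contact counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from ._kernels import (
    rebuild_chain,
    drmsd_kernel,
    contact_counts_kernel,
    N_,
    CA_,
    C_,
    O_,
    H_,
)

__all__ = [
    "InternalCoordinates",
    "ChainGeometry",
    "build_backbone",
    "extract_torsions",
    "drmsd",
    "rmsd_kabsch",
    "contact_counts",
    "dihedral",
    "rigid_transform",
]

ATOM_NAMES = ("N", "CA", "C", "O", "H")


@dataclass(frozen=True)
class InternalCoordinates:
    """Fixed per-residue backbone geometry (lengths in Angstrom, angles in deg).

    The model is sequence-independent in its geometry: every residue shares
    these values.  Defaults are standard peptide-unit values; all are
    overridable through configuration.
    """

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    bond_n_h: float = 1.000
    angle_n_ca_c: float = 111.0
    angle_ca_c_n: float = 116.6
    angle_c_n_ca: float = 121.9
    omega: float = 180.0

    def __post_init__(self):
        for name in ("bond_n_ca", "bond_ca_c", "bond_c_n", "bond_c_o", "bond_n_h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"bond length {name} must be positive")
        for name in ("angle_n_ca_c", "angle_ca_c_n", "angle_c_n_ca", "omega"):
            v = getattr(self, name)
            if not (0.0 < v <= 180.0):
                raise ValueError(f"angle {name} must lie in (0, 180] degrees")

    def as_array(self) -> np.ndarray:
        """Kernel layout: 5 lengths then 4 angles in radians."""
        return np.array(
            [
                self.bond_n_ca,
                self.bond_ca_c,
                self.bond_c_n,
                self.bond_c_o,
                self.bond_n_h,
                np.deg2rad(self.angle_n_ca_c),
                np.deg2rad(self.angle_ca_c_n),
                np.deg2rad(self.angle_c_n_ca),
                np.deg2rad(self.omega),
            ]
        )


@dataclass
class ChainGeometry:
    """A caterpillar conformation: coordinates plus the torsions that built it.

    coords has shape (n_res, 5, 3) with atom order N, CA, C', O, H; the amide
    H of residue 0 does not exist and is stored as NaN.  torsions has shape
    (n_res, 2) = (phi, psi) in radians with NaN at the undefined terminal
    slots (phi of residue 0, psi of the last residue).
    """

    coords: np.ndarray
    torsions: np.ndarray
    internal: InternalCoordinates = field(default_factory=InternalCoordinates)

    @property
    def n_res(self) -> int:
        return self.coords.shape[0]

    @property
    def ca(self) -> np.ndarray:
        return self.coords[:, CA_, :]

    def copy(self) -> "ChainGeometry":
        return ChainGeometry(self.coords.copy(), self.torsions.copy(), self.internal)


def build_backbone(torsions, ic: InternalCoordinates | None = None) -> ChainGeometry:
    """Build a chain from (phi, psi) pairs by sequential atom placement.

    Undefined terminal torsions (phi[0], psi[-1]) may be given as NaN or any
    number; they are never used.  The first residue defines a canonical
    frame (N at the origin, CA on +x, C' in the xy-plane), so the result is
    deterministic given its inputs.
    """
    if ic is None:
        ic = InternalCoordinates()
    t = np.asarray(torsions, dtype=np.float64)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 1:
        raise ValueError("torsions must be an (n_res, 2) array with n_res >= 1")
    n = t.shape[0]
    interior = t.copy()
    interior[0, 0] = 0.0  # phi of residue 0: unused
    interior[n - 1, 1] = 0.0  # psi of last residue: unused
    if not np.all(np.isfinite(interior)):
        raise ValueError("non-finite torsion angle")
    phi = np.ascontiguousarray(interior[:, 0])
    psi = np.ascontiguousarray(interior[:, 1])
    coords = np.empty((n, 5, 3), dtype=np.float64)
    rebuild_chain(phi, psi, ic.as_array(), coords)
    stored = t.copy()
    stored[0, 0] = np.nan
    stored[n - 1, 1] = np.nan
    return ChainGeometry(coords, stored, ic)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in radians (IUPAC sign convention)."""
    b1 = np.asarray(p1, float) - np.asarray(p0, float)
    b2 = np.asarray(p2, float) - np.asarray(p1, float)
    b3 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate dihedral: colinear atom triplet")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


def extract_torsions(chain: ChainGeometry) -> np.ndarray:
    """Recover (phi, psi) from coordinates; NaN marks the undefined termini."""
    n = chain.n_res
    c = chain.coords
    out = np.full((n, 2), np.nan)
    for i in range(n):
        try:
            if i > 0:
                out[i, 0] = dihedral(c[i - 1, C_], c[i, N_], c[i, CA_], c[i, C_])
            if i < n - 1:
                out[i, 1] = dihedral(c[i, N_], c[i, CA_], c[i, C_], c[i + 1, N_])
        except ValueError as exc:
            raise ValueError(f"degenerate dihedral at residue {i}: {exc}") from exc
    return out


def drmsd(a: ChainGeometry, b: ChainGeometry) -> float:
    """Distance-RMSD over all CA pairs with |i-j| >= 2 (rigid-motion invariant)."""
    if a.n_res != b.n_res:
        raise ValueError(f"chain length mismatch: {a.n_res} vs {b.n_res}")
    return float(
        drmsd_kernel(np.ascontiguousarray(a.ca), np.ascontiguousarray(b.ca))
    )


def rmsd_kabsch(a: ChainGeometry, b: ChainGeometry) -> float:
    """Minimal CA RMSD over proper rigid superpositions (no reflections)."""
    if a.n_res != b.n_res:
        raise ValueError(f"chain length mismatch: {a.n_res} vs {b.n_res}")
    pa = a.ca - a.ca.mean(axis=0)
    pb = b.ca - b.ca.mean(axis=0)
    if pa.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    if np.linalg.matrix_rank(pa, tol=1e-8) < 2:
        raise ValueError("degenerate (colinear) point set")
    u, _, vt = np.linalg.svd(pa.T @ pb)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt  # proper rotation only
    return float(np.sqrt(np.mean(np.sum((pa - pb @ rot.T) ** 2, axis=1))))


def contact_counts(chain: ChainGeometry, r_cut: float) -> np.ndarray:
    """Per-residue number of non-consecutive CA neighbours within r_cut."""
    if not r_cut > 0:
        raise ValueError("r_cut must be positive")
    out = np.zeros(chain.n_res, dtype=np.int64)
    contact_counts_kernel(np.ascontiguousarray(chain.ca), float(r_cut), out)
    return out


def rigid_transform(chain: ChainGeometry, rotation=None, translation=None) -> ChainGeometry:
    """Apply a rigid motion; torsions are untouched (they are invariants)."""
    coords = chain.coords.copy()
    if rotation is not None:
        R = np.asarray(rotation, float)
        coords = coords @ R.T
    if translation is not None:
        coords = coords + np.asarray(translation, float)
    return replace(chain, coords=coords, torsions=chain.torsions.copy())
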