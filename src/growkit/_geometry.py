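"""Internal-coordinate construction helpers (NeRF) and hydrogen placement."""

from __future__ import annotations

import numpy as np


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise ValueError("zero-length vector in geometric construction")
    return v / n


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               dist: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom d given three reference atoms and internal coordinates
    (distance c–d, angle b–c–d, dihedral a–b–c–d), the standard NeRF build."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = dist * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(dihedral),
        np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    axis = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(_unit(v), axis)) > 0.9:
        axis = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, axis))


def hydrogens_tetra_1(x: np.ndarray, nbrs: list[np.ndarray], bl: float) -> list[np.ndarray]:
    """One H completing a tetrahedral centre with three heavy neighbours."""
    d = -sum(_unit(nb - x) for nb in nbrs)
    return [x + bl * _unit(d)]


def hydrogens_tetra_2(x: np.ndarray, nbrs: list[np.ndarray], bl: float) -> list[np.ndarray]:
    """Two H completing a tetrahedral centre with two heavy neighbours."""
    u1, u2 = _unit(nbrs[0] - x), _unit(nbrs[1] - x)
    bis = -_unit(u1 + u2)
    perp = _unit(np.cross(u1, u2))
    half = np.deg2rad(109.47 / 2.0)
    return [x + bl * _unit(bis * np.cos(half) + s * perp * np.sin(half))
            for s in (+1.0, -1.0)]


def hydrogens_planar_1(x: np.ndarray, nbrs: list[np.ndarray], bl: float) -> list[np.ndarray]:
    """One H on an sp2 centre with two heavy neighbours (in-plane bisector)."""
    u1, u2 = _unit(nbrs[0] - x), _unit(nbrs[1] - x)
    return [x + bl * -_unit(u1 + u2)]


def hydrogens_terminal(x: np.ndarray, nbr: np.ndarray, ref: np.ndarray | None,
                       n_h: int, bl: float, sp3: bool) -> list[np.ndarray]:
    """H atoms on an atom with a single heavy neighbour.

    ref is a heavy neighbour of nbr (defines the dihedral frame); sp3 picks
    tetrahedral staggered geometry, otherwise planar sp2 placement.
    """
    if ref is None:
        # no frame available: build one from an arbitrary perpendicular
        ref = nbr + _any_perpendicular(x - nbr)
    angle = 109.47 if sp3 else 120.0
    if n_h == 3:
        dihedrals = (180.0, 60.0, -60.0)
    elif n_h == 2:
        dihedrals = (60.0, -60.0) if sp3 else (0.0, 180.0)
    elif n_h == 1:
        dihedrals = (180.0,)
    else:
        raise ValueError("terminal centre supports 1-3 hydrogens")
    return [place_atom(ref, nbr, x, bl, angle, d) for d in dihedrals[:n_h]]


def hydrogens_water(o: np.ndarray, bl: float = 0.9572,
                    hoh_deg: float = 104.52) -> list[np.ndarray]:
    """Two H on an isolated water oxygen, deterministic fixed orientation."""
    half = np.deg2rad(hoh_deg / 2.0)
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([0.0, 1.0, 0.0])
    return [o + bl * (np.cos(half) * u + s * np.sin(half) * v) for s in (1.0, -1.0)]
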