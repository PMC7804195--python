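"""Molecular integration grids.

Per-atom spherical product grids (Gauss-Legendre radial points under the
Becke r = R(1+x)/(1-x) mapping; Gauss-Legendre in cos(theta) x uniform
trapezoid in phi for the angular part) combined with Becke fuzzy-cell
partitioning for multi-center integrands.  The angular product rule
integrates spherical harmonics exactly up to degree ~n_theta, which is ample
for the l <= 3 solid harmonics used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MolecularGeometry


@dataclass(frozen=True)
class GridSpec:
    """Resolution of the per-atom product grid."""

    n_radial: int = 35
    n_theta: int = 12
    n_phi: int = 24
    radial_scale: float = 1.0  # Becke mapping parameter R, Bohr

    def points_per_atom(self) -> int:
        return self.n_radial * self.n_theta * self.n_phi


def _radial_rule(spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(spec.n_radial)
    R = spec.radial_scale
    r = R * (1.0 + x) / (1.0 - x)
    # dr = 2R/(1-x)^2 dx; weight includes r^2 for the volume element
    wr = w * 2.0 * R / (1.0 - x) ** 2 * r**2
    return r, wr


def _angular_rule(spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    ct, wt = np.polynomial.legendre.leggauss(spec.n_theta)
    st = np.sqrt(1.0 - ct**2)
    phi = 2.0 * np.pi * np.arange(spec.n_phi) / spec.n_phi
    wphi = 2.0 * np.pi / spec.n_phi
    dirs = np.empty((spec.n_theta * spec.n_phi, 3))
    wang = np.empty(spec.n_theta * spec.n_phi)
    k = 0
    for i in range(spec.n_theta):
        for j in range(spec.n_phi):
            dirs[k] = (st[i] * np.cos(phi[j]), st[i] * np.sin(phi[j]), ct[i])
            wang[k] = wt[i] * wphi
            k += 1
    return dirs, wang


def atomic_grid(center: np.ndarray, spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Spherical product grid around one center; weights integrate d^3r."""
    r, wr = _radial_rule(spec)
    dirs, wang = _angular_rule(spec)
    pts = center[None, None, :] + r[:, None, None] * dirs[None, :, :]
    w = wr[:, None] * wang[None, :]
    return pts.reshape(-1, 3), w.reshape(-1)


def _becke_step(mu: np.ndarray, k: int = 3) -> np.ndarray:
    f = mu
    for _ in range(k):
        f = 1.5 * f - 0.5 * f**3
    return 0.5 * (1.0 - f)


def becke_weights(points: np.ndarray, centers: np.ndarray, host: int) -> np.ndarray:
    """Becke fuzzy-cell weight of atom ``host`` at each point."""
    n_at = centers.shape[0]
    if n_at == 1:
        return np.ones(points.shape[0])
    d = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)  # (npts, nat)
    rij = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    cell = np.ones((points.shape[0], n_at))
    for a in range(n_at):
        for b in range(n_at):
            if a == b:
                continue
            mu = (d[:, a] - d[:, b]) / rij[a, b]
            cell[:, a] *= _becke_step(mu)
    total = cell.sum(axis=1)
    return cell[:, host] / total


def molecular_grid(
    geometry: MolecularGeometry, spec: GridSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Becke-partitioned union of atomic grids; returns (points, weights)."""
    all_pts, all_w = [], []
    centers = geometry.positions
    for a in range(geometry.n_atoms):
        pts, w = atomic_grid(centers[a], spec)
        w = w * becke_weights(pts, centers, a)
        all_pts.append(pts)
        all_w.append(w)
    return np.concatenate(all_pts), np.concatenate(all_w)
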