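"""Density fitting: atom-centered expansion and atomic decomposition.

The electron density is expanded in atom-centered auxiliary functions,

    rho(r) ~= sum_A sum_Q C_Q^A phi_Q(r - r_A) = sum_A rho_A(r),

which decomposes the density unambiguously into per-atom contributions
rho_A.  The coefficients are obtained by a metric least-squares fit,
M C = b with M_PQ = <phi_P | w | phi_Q> and b_P = <phi_P | w | rho>, where
the metric weight w is either the overlap (w = 1, used on the synthetic
quadrature path) or the Coulomb kernel (standard RI-J practice, available
through an electronic-structure backend).

The quadrature path needs only a pointwise-evaluable density; no
electronic-structure engine is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np
import scipy.linalg

from .basis import AuxBasis
from .geometry import MolecularGeometry
from .grids import GridSpec, molecular_grid

logger = logging.getLogger(__name__)


class FitError(ValueError):
    """Raised on dimension mismatches or irrecoverably singular metrics."""


@dataclass
class DensityMatrix:
    """One-particle density matrix in an orbital basis (backend contract).

    Only carried through to a backend adapter; the quadrature path never
    builds one.
    """

    matrix: np.ndarray
    nbf: int
    n_electrons: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.nbf, self.nbf):
            raise FitError("density matrix shape disagrees with nbf")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise FitError("density matrix must be symmetric")


@dataclass
class AtomicDFCoefficients:
    """Per-atom DF expansion coefficients, ordered as the geometry's atoms.

    Carries the element symbols so downstream featurization can interpret
    each atom's coefficient layout without the geometry at hand.
    """

    per_atom: list[np.ndarray]
    elements: list[str]
    metric: str  # "overlap" or "coulomb"
    fit_residual: float
    basis_name: str = ""

    def __post_init__(self) -> None:
        self.per_atom = [np.asarray(c, dtype=float) for c in self.per_atom]
        if len(self.per_atom) != len(self.elements):
            raise FitError("per_atom and elements disagree in length")
        if self.metric not in ("overlap", "coulomb"):
            raise FitError(f"unknown metric {self.metric!r}")
        if self.fit_residual < 0:
            raise FitError("fit_residual must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.per_atom)

    def flat(self) -> np.ndarray:
        return np.concatenate(self.per_atom)


@runtime_checkable
class IntegralProvider(Protocol):
    """Supplies the metric matrix and density projection for a fit."""

    metric_name: str

    def metric(self, geometry: MolecularGeometry, aux_basis: AuxBasis) -> np.ndarray: ...

    def projection(
        self, geometry: MolecularGeometry, aux_basis: AuxBasis, density_source
    ) -> np.ndarray: ...

    def density_norm_sq(
        self, geometry: MolecularGeometry, aux_basis: AuxBasis, density_source
    ) -> float: ...


def aux_atom_slices(geometry: MolecularGeometry, aux_basis: AuxBasis) -> list[slice]:
    """Slice of the flat aux-function vector belonging to each atom."""
    slices, start = [], 0
    for el in geometry.elements:
        n = aux_basis.n_functions(el)
        slices.append(slice(start, start + n))
        start += n
    return slices


def evaluate_aux_functions(
    geometry: MolecularGeometry, aux_basis: AuxBasis, points: np.ndarray
) -> np.ndarray:
    """All aux functions of the molecule at the given points: (npts, naux)."""
    points = np.asarray(points, dtype=float)
    blocks = [
        aux_basis.evaluate_element(el, points - geometry.positions[a])
        for a, el in enumerate(geometry.elements)
    ]
    return np.concatenate(blocks, axis=1)


class QuadratureProvider:
    """Overlap-metric integrals by Becke-grid quadrature.

    ``density_source`` must be callable: ``rho(points) -> values`` with
    points in Bohr.  The molecular grid and basis-function matrix are cached
    per geometry (keyed by positions and grid spec), since a fit queries the
    provider three times.
    """

    metric_name = "overlap"

    def __init__(self, grid_spec: GridSpec | None = None):
        self.grid_spec = grid_spec or GridSpec()
        self._cache: dict[bytes, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _key(self, geometry: MolecularGeometry, aux_basis: AuxBasis) -> bytes:
        return (
            geometry.positions.tobytes()
            + "".join(geometry.elements).encode()
            + repr(self.grid_spec).encode()
            + aux_basis.fingerprint().encode()
        )

    def _grid_and_phi(self, geometry, aux_basis):
        key = self._key(geometry, aux_basis)
        if key not in self._cache:
            pts, w = molecular_grid(geometry, self.grid_spec)
            phi = evaluate_aux_functions(geometry, aux_basis, pts)
            if len(self._cache) > 8:
                self._cache.clear()
            self._cache[key] = (pts, w, phi)
        return self._cache[key]

    def metric(self, geometry, aux_basis) -> np.ndarray:
        _, w, phi = self._grid_and_phi(geometry, aux_basis)
        m = phi.T @ (phi * w[:, None])
        return 0.5 * (m + m.T)

    def projection(self, geometry, aux_basis, density_source) -> np.ndarray:
        pts, w, phi = self._grid_and_phi(geometry, aux_basis)
        rho = np.asarray(density_source(pts), dtype=float)
        return phi.T @ (w * rho)

    def density_norm_sq(self, geometry, aux_basis, density_source) -> float:
        pts, w, _ = self._grid_and_phi(geometry, aux_basis)
        rho = np.asarray(density_source(pts), dtype=float)
        return float(np.sum(w * rho * rho))

    def residual_norm(self, geometry, aux_basis, density_source, coeffs) -> float:
        """Pointwise metric-norm residual; avoids the cancellation of the
        algebraic expression for densities near the aux-basis span."""
        pts, w, phi = self._grid_and_phi(geometry, aux_basis)
        diff = np.asarray(density_source(pts), dtype=float) - phi @ coeffs
        return float(np.sqrt(max(np.sum(w * diff * diff), 0.0)))


def _floored_solve(
    metric: np.ndarray, b: np.ndarray, cond_floor: float
) -> tuple[np.ndarray, float]:
    """SPD solve with an eigenvalue floor against near-linear dependence."""
    evals, evecs = scipy.linalg.eigh(metric)
    emax = float(evals[-1])
    if emax <= 0:
        raise FitError("metric is not positive-definite; check the aux basis/grid")
    keep = evals > cond_floor * emax
    n_drop = int(np.sum(~keep))
    if n_drop:
        logger.warning(
            "metric eigenvalue floor triggered: dropped %d/%d modes "
            "(condition estimate %.2e)",
            n_drop,
            len(evals),
            emax / max(float(evals[0]), 1e-300),
        )
    bt = evecs.T @ b
    c = evecs[:, keep] @ (bt[keep] / evals[keep])
    return c, emax / float(evals[keep][0])


def fit_density(
    geometry: MolecularGeometry,
    aux_basis: AuxBasis,
    provider: IntegralProvider,
    density_source,
    cond_floor: float = 1e-10,
) -> AtomicDFCoefficients:
    """Fit ``density_source`` in the aux basis by a metric least-squares solve.

    Returns per-atom coefficient vectors and the metric-norm residual
    ``sqrt(<rho|rho> - 2 c.b + c.M.c)`` of the reconstruction.
    """
    metric = provider.metric(geometry, aux_basis)
    b = provider.projection(geometry, aux_basis, density_source)
    if metric.shape[0] != b.shape[0]:
        raise FitError(
            f"metric dimension {metric.shape[0]} vs projection length {b.shape[0]}"
        )
    coeffs, _cond = _floored_solve(metric, b, cond_floor)
    if hasattr(provider, "residual_norm"):
        residual = provider.residual_norm(geometry, aux_basis, density_source, coeffs)
    else:
        rho2 = provider.density_norm_sq(geometry, aux_basis, density_source)
        resid_sq = rho2 - 2.0 * coeffs @ b + coeffs @ metric @ coeffs
        residual = float(np.sqrt(max(resid_sq, 0.0)))
    per_atom = [coeffs[s] for s in aux_atom_slices(geometry, aux_basis)]
    return AtomicDFCoefficients(
        per_atom=per_atom,
        elements=list(geometry.elements),
        metric=provider.metric_name,
        fit_residual=residual,
        basis_name=aux_basis.name,
    )


def evaluate_df_density(
    coeffs: AtomicDFCoefficients,
    geometry: MolecularGeometry,
    aux_basis: AuxBasis,
    points: np.ndarray,
) -> np.ndarray:
    """Evaluate the fitted density sum_A sum_Q C_Q^A phi_Q(r - r_A) at points."""
    if coeffs.n_atoms != geometry.n_atoms:
        raise FitError("coefficient set and geometry disagree in atom count")
    points = np.asarray(points, dtype=float)
    out = np.zeros(points.shape[0])
    for a, el in enumerate(geometry.elements):
        c = coeffs.per_atom[a]
        if c.shape[0] != aux_basis.n_functions(el):
            raise FitError(f"atom {a} ({el}): coefficient length mismatch")
        phi = aux_basis.evaluate_element(el, points - geometry.positions[a])
        out += phi @ c
    return out


def electron_count(coeffs: AtomicDFCoefficients, aux_basis: AuxBasis) -> float:
    """Integral of the fitted density: only l=0 functions contribute."""
    total = 0.0
    for el, c in zip(coeffs.elements, coeffs.per_atom):
        total += float(c @ aux_basis.function_integrals(el))
    return total
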