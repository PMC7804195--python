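"""Electronic-structure backend adapter contract.

The training labels of a production functional are correlation energies
E_c = E(method) - E(HF) from a wavefunction code, and the fitted density is
the self-consistent HF density expanded in a literature auxiliary basis
with the Coulomb metric.  Those quantities enter this package only through
the :class:`BackendAdapter` protocol below; no electronic-structure method
is implemented here, and every core code path is equally served by the
synthetic quadrature fixtures.

A pyscf-based adapter is provided for users who have pyscf installed; it is
an optional extra (``pip install kdfa[backend]``) and nothing else in the
package imports it.
"""

from __future__ import annotations

import hashlib
from typing import Protocol, runtime_checkable

import numpy as np

from .density_fitting import AtomicDFCoefficients
from .geometry import MolecularGeometry


@runtime_checkable
class BackendAdapter(Protocol):
    """What an electronic-structure engine must supply."""

    def hf_energy(self, geometry: MolecularGeometry) -> float: ...

    def correlation_energy(self, geometry: MolecularGeometry, method: str) -> float:
        """E(method) - E(HF) in Hartree for method in {'MP2', 'CCSD(T)'}."""
        ...

    def df_coefficients(self, geometry: MolecularGeometry) -> AtomicDFCoefficients:
        """Coulomb-metric DF coefficients of the converged HF density."""
        ...


def geometry_hash(geometry: MolecularGeometry) -> str:
    h = hashlib.sha256()
    h.update("".join(geometry.elements).encode())
    h.update(np.round(geometry.positions, 10).tobytes())
    h.update(str(geometry.total_charge).encode())
    return h.hexdigest()[:16]


class CachingAdapter:
    """Wrap any adapter with a geometry-hash keyed in-memory cache."""

    def __init__(self, inner: BackendAdapter):
        self.inner = inner
        self._cache: dict[tuple[str, str], object] = {}

    def _memo(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    def hf_energy(self, geometry):
        return self._memo(("hf", geometry_hash(geometry)), lambda: self.inner.hf_energy(geometry))

    def correlation_energy(self, geometry, method):
        return self._memo(
            (f"corr:{method}", geometry_hash(geometry)),
            lambda: self.inner.correlation_energy(geometry, method),
        )

    def df_coefficients(self, geometry):
        return self._memo(
            ("df", geometry_hash(geometry)), lambda: self.inner.df_coefficients(geometry)
        )


class PyscfBackend:
    """Adapter over pyscf: RHF density, Coulomb-metric DF, MP2/CCSD(T) labels.

    Requires the optional ``pyscf`` dependency.
    """

    def __init__(self, basis: str = "def2-svp", aux_basis: str = "def2-universal-jfit"):
        try:
            import pyscf  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "PyscfBackend requires pyscf (pip install kdfa[backend])"
            ) from exc
        self.basis = basis
        self.aux_basis = aux_basis

    def _mol(self, geometry: MolecularGeometry):
        from pyscf import gto

        atom = [
            (el, tuple(xyz))
            for el, xyz in zip(geometry.elements, geometry.positions)
        ]
        return gto.M(
            atom=atom,
            unit="Bohr",
            basis=self.basis,
            charge=geometry.total_charge,
            verbose=0,
        )

    def _rhf(self, geometry):
        from pyscf import scf

        mf = scf.RHF(self._mol(geometry))
        mf.kernel()
        if not mf.converged:  # pragma: no cover
            raise RuntimeError(f"HF did not converge for {geometry.frame_id}")
        return mf

    def hf_energy(self, geometry):
        return float(self._rhf(geometry).e_tot)

    def correlation_energy(self, geometry, method="MP2"):
        mf = self._rhf(geometry)
        if method.upper() == "MP2":
            from pyscf import mp

            return float(mp.MP2(mf).kernel()[0])
        if method.upper() in ("CCSD(T)", "CCSDT"):
            from pyscf import cc

            mycc = cc.CCSD(mf)
            e_ccsd = mycc.kernel()[0]
            return float(e_ccsd + mycc.ccsd_t())
        raise ValueError(f"unknown reference method {method!r}")

    def df_coefficients(self, geometry) -> AtomicDFCoefficients:
        import numpy as np
        from pyscf import df, gto

        mol = self._mol(geometry)
        mf = self._rhf(geometry)
        dm = mf.make_rdm1()
        auxmol = df.addons.make_auxmol(mol, self.aux_basis)
        # Coulomb metric and 3-center projection of the density
        j2c = auxmol.intor("int2c2e")
        j3c = df.incore.aux_e2(mol, auxmol, intor="int3c2e")
        b = np.einsum("uvP,uv->P", j3c, dm)
        coeffs = np.linalg.solve(j2c, b)
        resid_sq = float(max(0.0, -coeffs @ b + coeffs @ j2c @ coeffs))
        per_atom, slices = [], auxmol.aoslice_by_atom()
        for a in range(mol.natm):
            per_atom.append(coeffs[slices[a, 2] : slices[a, 3]])
        return AtomicDFCoefficients(
            per_atom=per_atom,
            elements=list(geometry.elements),
            metric="coulomb",
            fit_residual=float(np.sqrt(resid_sq)),
            basis_name=self.aux_basis,
        )
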