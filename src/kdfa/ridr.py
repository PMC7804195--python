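"""Rotationally invariant density representation (RIDR).

Density-fitting coefficients transform under rotation like the real
spherical harmonics they multiply, so they are not directly usable as
features.  Contracting them pairwise over the magnetic quantum number,

    p_{n n' l} = s * sum_m c_{n l m} c_{n' l m},   n <= n',

yields a per-atom power spectrum that is exactly rotationally invariant
(each fixed-l block of coefficients rotates by an orthogonal Wigner matrix,
which the m-sum annihilates).  With the default off-diagonal scaling
s = sqrt(2) for n < n', the Euclidean dot product of two flattened spectra
equals the Frobenius inner product of the full (n, n') matrices, so the
normalized polynomial kernel built on these vectors is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import AuxBasis
from .density_fitting import AtomicDFCoefficients


class LayoutError(ValueError):
    """Coefficient vector does not match the declared shell structure."""


@dataclass(frozen=True)
class RIDRConfig:
    """Conventions of the power-spectrum contraction."""

    offdiag_scaling: float = float(np.sqrt(2.0))
    l_normalization: bool = False  # multiply each l block by 1/sqrt(2l+1)

    def __post_init__(self) -> None:
        if self.offdiag_scaling <= 0:
            raise ValueError("offdiag_scaling must be positive")


@dataclass
class RIDRVector:
    """Per-atom invariant feature vector, indexed by (n, n', l), n <= n'."""

    element: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise LayoutError("RIDR entries must be finite")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


def _coeffs_by_l(
    atom_coeffs: np.ndarray, aux_basis: AuxBasis, element: str
) -> dict[int, np.ndarray]:
    """Reshape a flat per-atom coefficient vector into {l: (N_l, 2l+1)}."""
    labels = aux_basis.function_labels(element)
    if atom_coeffs.shape[0] != len(labels):
        raise LayoutError(
            f"{element}: got {atom_coeffs.shape[0]} coefficients, "
            f"layout expects {len(labels)}"
        )
    channels = aux_basis.radial_channels(element)
    blocks = {l: np.zeros((nl, 2 * l + 1)) for l, nl in channels.items()}
    for c, lab in zip(atom_coeffs, labels):
        blocks[lab.l][lab.n, lab.m + lab.l] = c
    return blocks


def ridr_length(aux_basis: AuxBasis, element: str) -> int:
    """Feature-vector length: sum over l of N_l (N_l + 1) / 2."""
    return sum(nl * (nl + 1) // 2 for nl in aux_basis.radial_channels(element).values())


def power_spectrum(
    atom_coeffs: np.ndarray,
    aux_basis: AuxBasis,
    element: str,
    config: RIDRConfig | None = None,
) -> RIDRVector:
    """Contract one atom's DF coefficients into its invariant power spectrum."""
    config = config or RIDRConfig()
    blocks = _coeffs_by_l(np.asarray(atom_coeffs, dtype=float), aux_basis, element)
    out: list[float] = []
    for l in sorted(blocks):
        c = blocks[l]  # (N_l, 2l+1)
        gram = c @ c.T
        if config.l_normalization:
            gram = gram / np.sqrt(2 * l + 1)
        nl = gram.shape[0]
        for n in range(nl):
            for np_ in range(n, nl):
                s = 1.0 if n == np_ else config.offdiag_scaling
                out.append(s * gram[n, np_])
    return RIDRVector(element=element, values=np.array(out))


def featurize_molecule(
    coeffs: AtomicDFCoefficients,
    aux_basis: AuxBasis,
    config: RIDRConfig | None = None,
) -> list[RIDRVector]:
    """Per-atom RIDR vectors in the coefficient set's atom order."""
    config = config or RIDRConfig()
    return [
        power_spectrum(c, aux_basis, el, config)
        for el, c in zip(coeffs.elements, coeffs.per_atom)
    ]
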