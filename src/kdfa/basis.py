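"""Auxiliary Gaussian basis sets for density fitting.

A density-fitting (DF) basis is an element-specific list of solid-harmonic
Gaussian shells; a shell of angular momentum ``l`` contributes ``2l+1``
functions with real spherical harmonics in the standard m = -l..+l order.
Each basis function is normalized, ``<phi|phi> = 1``.

The package ships a compact even-tempered family, ``kdfa-light`` (H, C, N,
O; l <= 2), designed to span the smooth synthetic test densities.  External
sets (e.g. the def2 Coulomb-fitting families) can be loaded from the
Gaussian94 text interchange format via :func:`parse_gaussian94`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gamma

MAX_L = 3
_SHELL_LETTERS = {"S": 0, "P": 1, "D": 2, "F": 3}
_L_LETTERS = {v: k.lower() for k, v in _SHELL_LETTERS.items()}


class BasisError(ValueError):
    """Raised for invalid shells or malformed basis input."""


def _primitive_norm(alpha: float, l: int) -> float:
    # <phi|phi> = N^2 * Gamma(l+3/2) / (2 (2a)^(l+3/2)) for phi = N r^l Y_lm e^{-a r^2}
    return float(np.sqrt(2.0 * (2.0 * alpha) ** (l + 1.5) / gamma(l + 1.5)))


@dataclass(frozen=True)
class GaussianShell:
    """One contracted solid-harmonic Gaussian shell on a given element."""

    element: str
    l: int
    exponents: tuple[float, ...]
    contraction_coeffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.l < 0 or self.l > MAX_L:
            raise BasisError(f"angular momentum l={self.l} outside supported 0..{MAX_L}")
        if len(self.exponents) != len(self.contraction_coeffs):
            raise BasisError("exponent and contraction lists differ in length")
        if len(self.exponents) == 0:
            raise BasisError("shell must contain at least one primitive")
        if any(a <= 0 for a in self.exponents):
            raise BasisError("all exponents must be positive")

    @property
    def n_functions(self) -> int:
        return 2 * self.l + 1

    def normalized_coeffs(self) -> np.ndarray:
        """Contraction coefficients rescaled so the contracted function has unit norm."""
        alphas = np.asarray(self.exponents)
        coeffs = np.asarray(self.contraction_coeffs) * np.array(
            [_primitive_norm(a, self.l) for a in alphas]
        )
        # contracted self-overlap from the same-center radial integral
        aa = alphas[:, None] + alphas[None, :]
        s = gamma(self.l + 1.5) / (2.0 * aa ** (self.l + 1.5))
        norm2 = coeffs @ s @ coeffs
        return coeffs / np.sqrt(norm2)

    def radial(self, r: np.ndarray) -> np.ndarray:
        """Radial part r^l * sum_k c_k exp(-a_k r^2) with normalized contraction."""
        coeffs = self.normalized_coeffs()
        out = np.zeros_like(r, dtype=float)
        for a, c in zip(self.exponents, coeffs):
            out += c * np.exp(-a * r * r)
        return out * r**self.l

    def integral_s(self) -> float:
        """3-D integral of the contracted function; nonzero only for l = 0."""
        if self.l != 0:
            return 0.0
        coeffs = self.normalized_coeffs()
        # int phi d3r = sum_k c_k Y00^-1... phi = c_k Y00 e^{-a r^2}; int = c_k (1/sqrt(4pi)) (pi/a)^{3/2}
        val = 0.0
        for a, c in zip(self.exponents, coeffs):
            val += c * (np.pi / a) ** 1.5
        return float(val / np.sqrt(4.0 * np.pi))


def real_solid_harmonics(l: int, dxyz: np.ndarray) -> np.ndarray:
    """Real solid harmonics S_lm = r^l Y_lm(theta, phi) for m = -l..+l.

    ``dxyz`` has shape (..., 3); returns shape (2l+1, ...).  The Y_lm are the
    tesseral harmonics orthonormal on the unit sphere; as r^l Y_lm they are
    polynomials in (x, y, z), finite at the origin.
    """
    x, y, z = dxyz[..., 0], dxyz[..., 1], dxyz[..., 2]
    pi4 = 4.0 * np.pi
    if l == 0:
        return np.array([np.full(np.shape(x), 1.0 / np.sqrt(pi4))])
    if l == 1:
        c = np.sqrt(3.0 / pi4)
        return np.stack([c * y, c * z, c * x])
    r2 = x * x + y * y + z * z
    if l == 2:
        c15 = np.sqrt(15.0 / pi4)
        return np.stack(
            [
                c15 * x * y,
                c15 * y * z,
                np.sqrt(5.0 / (16.0 * np.pi)) * (3.0 * z * z - r2),
                c15 * x * z,
                np.sqrt(15.0 / (16.0 * np.pi)) * (x * x - y * y),
            ]
        )
    if l == 3:
        return np.stack(
            [
                np.sqrt(35.0 / (32.0 * np.pi)) * y * (3.0 * x * x - y * y),
                np.sqrt(105.0 / pi4) * x * y * z,
                np.sqrt(21.0 / (32.0 * np.pi)) * y * (5.0 * z * z - r2),
                np.sqrt(7.0 / (16.0 * np.pi)) * z * (5.0 * z * z - 3.0 * r2),
                np.sqrt(21.0 / (32.0 * np.pi)) * x * (5.0 * z * z - r2),
                np.sqrt(105.0 / (16.0 * np.pi)) * z * (x * x - y * y),
                np.sqrt(35.0 / (32.0 * np.pi)) * x * (x * x - 3.0 * y * y),
            ]
        )
    raise BasisError(f"l={l} not supported")


@dataclass(frozen=True)
class FunctionLabel:
    """Bookkeeping for one aux function: shell index, radial channel, l, m."""

    shell_index: int
    n: int  # radial channel index among shells of the same l
    l: int
    m: int


@dataclass
class AuxBasis:
    """Element-keyed collection of DF shells."""

    shells_by_element: dict[str, list[GaussianShell]]
    name: str = "custom"

    def shells(self, element: str) -> list[GaussianShell]:
        try:
            return self.shells_by_element[element]
        except KeyError as exc:
            raise BasisError(f"no aux shells defined for element {element!r}") from exc

    def n_functions(self, element: str) -> int:
        return sum(sh.n_functions for sh in self.shells(element))

    def function_labels(self, element: str) -> list[FunctionLabel]:
        """Per-function labels in shell order, m = -l..+l within each shell."""
        labels: list[FunctionLabel] = []
        per_l_counter: dict[int, int] = {}
        for i, sh in enumerate(self.shells(element)):
            n = per_l_counter.get(sh.l, 0)
            per_l_counter[sh.l] = n + 1
            for m in range(-sh.l, sh.l + 1):
                labels.append(FunctionLabel(i, n, sh.l, m))
        return labels

    def radial_channels(self, element: str) -> dict[int, int]:
        """Number of radial channels N_l for each angular momentum present."""
        counts: dict[int, int] = {}
        for sh in self.shells(element):
            counts[sh.l] = counts.get(sh.l, 0) + 1
        return counts

    def function_integrals(self, element: str) -> np.ndarray:
        """3-D integrals of each function (zero except l=0), in function order."""
        out = []
        for sh in self.shells(element):
            ints = [sh.integral_s()] if sh.l == 0 else [0.0] * sh.n_functions
            out.extend(ints)
        return np.array(out)

    def evaluate_element(self, element: str, dxyz: np.ndarray) -> np.ndarray:
        """Evaluate all functions of one element at displacements from its center.

        ``dxyz``: (n_points, 3) in Bohr. Returns (n_points, n_functions).
        """
        dxyz = np.asarray(dxyz, dtype=float)
        r = np.linalg.norm(dxyz, axis=-1)
        cols = []
        for sh in self.shells(element):
            coeffs = sh.normalized_coeffs()
            radial = np.zeros_like(r)
            for a, c in zip(sh.exponents, coeffs):
                radial += c * np.exp(-a * r * r)
            ang = real_solid_harmonics(sh.l, dxyz)  # (2l+1, n_points), includes r^l
            cols.append((ang * radial).T)
        return np.concatenate(cols, axis=1)

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for el in sorted(self.shells_by_element):
            for sh in self.shells_by_element[el]:
                h.update(
                    f"{el}:{sh.l}:{sh.exponents}:{sh.contraction_coeffs};".encode()
                )
        return h.hexdigest()[:16]


def parse_gaussian94(text: str, name: str = "custom") -> AuxBasis:
    """Parse a Gaussian94-format basis block (the Basis Set Exchange default).

    Element blocks are separated by ``****`` lines; each block starts with
    ``<El> 0`` followed by shells ``<letter> <nprim> <scale>`` and their
    exponent/coefficient lines.  ``SP`` shells are split into S and P.
    """
    shells: dict[str, list[GaussianShell]] = {}
    lines = [
        ln.split("!")[0].rstrip()
        for ln in text.splitlines()
        if ln.split("!")[0].strip()
    ]
    i = 0
    while i < len(lines):
        if lines[i].strip() == "****":
            i += 1
            continue
        head = lines[i].split()
        if len(head) < 1 or head[0].upper() in _SHELL_LETTERS:
            raise BasisError(f"expected an element header, got {lines[i]!r}")
        element = head[0].capitalize()
        shells.setdefault(element, [])
        i += 1
        while i < len(lines) and lines[i].strip() != "****":
            parts = lines[i].split()
            letter = parts[0].upper()
            if letter not in _SHELL_LETTERS and letter != "SP":
                raise BasisError(f"unknown shell type {parts[0]!r}")
            nprim = int(parts[1])
            prim_lines = lines[i + 1 : i + 1 + nprim]
            if len(prim_lines) < nprim:
                raise BasisError(f"shell {parts[0]!r} on {element}: missing primitives")
            rows = [[float(x.replace("D", "E").replace("d", "e")) for x in ln.split()] for ln in prim_lines]
            exps = tuple(row[0] for row in rows)
            if letter == "SP":
                shells[element].append(
                    GaussianShell(element, 0, exps, tuple(r[1] for r in rows))
                )
                shells[element].append(
                    GaussianShell(element, 1, exps, tuple(r[2] for r in rows))
                )
            else:
                shells[element].append(
                    GaussianShell(
                        element, _SHELL_LETTERS[letter], exps, tuple(r[1] for r in rows)
                    )
                )
            i += 1 + nprim
    if not shells:
        raise BasisError("no element blocks found")
    return AuxBasis(shells, name=name)


def load_basis(path: str | Path, name: str | None = None) -> AuxBasis:
    p = Path(path)
    return parse_gaussian94(p.read_text(), name=name or p.stem)


def _even_tempered(element: str, spec: dict[int, tuple[float, ...]]) -> list[GaussianShell]:
    return [
        GaussianShell(element, l, (a,), (1.0,))
        for l in sorted(spec)
        for a in spec[l]
    ]


def builtin_basis(name: str = "kdfa-light") -> AuxBasis:
    """The shipped auxiliary family.

    ``kdfa-light`` is a small uncontracted even-tempered set (s ranges chosen
    to bracket the widths of the synthetic atomic densities, plus p and d
    shells to capture off-center bond lobes).  It is this package's own set,
    not a literature basis.
    """
    if name != "kdfa-light":
        raise BasisError(f"unknown built-in basis {name!r}; load external sets from file")
    spec = {
        "H": {0: (0.12, 0.25, 0.52, 1.1, 2.3, 4.8), 1: (0.35, 0.85, 2.0)},
        "C": {0: (0.15, 0.31, 0.65, 1.36, 2.85, 6.0, 12.5), 1: (0.35, 0.9, 2.3), 2: (0.6, 1.5)},
        "N": {0: (0.16, 0.33, 0.7, 1.47, 3.1, 6.5, 13.6), 1: (0.38, 1.0, 2.6), 2: (0.65, 1.7)},
        "O": {0: (0.16, 0.34, 0.72, 1.5, 3.2, 6.7, 14.0), 1: (0.4, 1.05, 2.7), 2: (0.7, 1.8)},
    }
    return AuxBasis(
        {el: _even_tempered(el, sh) for el, sh in spec.items()}, name="kdfa-light"
    )
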