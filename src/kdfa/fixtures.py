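"""Synthetic inputs: geometries, densities, quadrature fits, surrogate labels.

Everything needed to exercise the full pipeline without an
electronic-structure engine:

* thermal-looking ensembles of water clusters, protonated water clusters,
  alkanes and the protonated water dimer (seeded Gaussian jitter of template
  coordinates, emulating decorrelated MD snapshots at ~350 K);
* smooth synthetic densities (atom- plus bond-midpoint-centered Gaussians
  whose integral is exactly the electron count; the off-center bond lobes
  force nonzero higher-angular-momentum fitting coefficients);
* overlap-metric quadrature fits of those densities into an aux basis;
* size-extensive surrogate correlation-energy labels built atomwise from
  the RIDR features, E_syn = sum_A [o_e(A) + a_e(A) tanh(b u_e(A).p_hat_A)],
  exactly additive over non-interacting fragments — the structure the KDFA
  is designed to exploit.

These fixtures validate code paths and statistical behavior; they are not
physically accurate densities or energies.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .basis import AuxBasis
from .density_fitting import (
    AtomicDFCoefficients,
    QuadratureProvider,
    electron_count,
    fit_density,
)
from .geometry import (
    ATOMIC_NUMBERS,
    COVALENT_RADII,
    MolecularGeometry,
    random_rotation,
)
from .grids import GridSpec
from .ridr import RIDRConfig, RIDRVector, featurize_molecule
from .units import BOHR_PER_ANGSTROM, MEV_TO_HARTREE


class FixtureError(ValueError):
    """Raised when generation constraints cannot be met."""


class UnderResolvedGridError(FixtureError):
    """Quadrature grid too coarse: fitted electron count off by > 1%."""


# ---------------------------------------------------------------- templates

_WATER = (
    ["O", "H", "H"],
    np.array([[0.0, 0.0, 0.0], [0.7572, 0.5865, 0.0], [-0.7572, 0.5865, 0.0]]),
)

_HYDRONIUM = (
    ["O", "H", "H", "H"],
    np.array(
        [
            [0.0, 0.0, 0.0],
            [0.924, 0.0, -0.327],
            [-0.462, 0.800, -0.327],
            [-0.462, -0.800, -0.327],
        ]
    ),
)

#: Protonated water dimer with the shared proton on the O-O midpoint,
#: r_OO = 2.45 Angstrom.
_ZUNDEL = (
    ["O", "O", "H", "H", "H", "H", "H"],
    np.array(
        [
            [0.0, 0.0, 0.0],
            [2.45, 0.0, 0.0],
            [1.225, 0.0, 0.0],
            [-0.33, 0.92, 0.0],
            [-0.33, -0.46, 0.80],
            [2.78, 0.92, 0.0],
            [2.78, -0.46, -0.80],
        ]
    ),
)


def _alkane_template(n_carbons: int) -> tuple[list[str], np.ndarray]:
    """Zig-zag C_nH_(2n+2) chain (methane for n=1)."""
    if n_carbons == 1:
        els = ["C", "H", "H", "H", "H"]
        d = 1.09 / np.sqrt(3.0)
        pos = np.array(
            [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]],
            dtype=float,
        )
        return els, pos
    els: list[str] = []
    pos: list[list[float]] = []
    for i in range(n_carbons):
        els.append("C")
        pos.append([i * 1.26, 0.44 * (-1) ** i, 0.0])
    for i in range(n_carbons):
        cx, cy, _ = pos[i]
        sign = (-1) ** i
        els += ["H", "H"]
        pos += [[cx, cy + 0.40 * sign, 0.92], [cx, cy + 0.40 * sign, -0.92]]
        if i == 0:
            els.append("H")
            pos.append([cx - 0.95, cy + 0.45 * sign, 0.0])
        if i == n_carbons - 1:
            els.append("H")
            pos.append([cx + 0.95, cy + 0.45 * sign, 0.0])
    return els, np.array(pos)


@dataclass
class SyntheticDensity:
    """Sum of isotropic Gaussians; pointwise evaluable, analytic integral."""

    centers: np.ndarray  # (n, 3) Bohr
    amplitudes: np.ndarray  # integrated charge of each lobe (electrons)
    widths: np.ndarray  # Gaussian widths (Bohr)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if np.any(self.amplitudes <= 0) or np.any(self.widths <= 0):
            raise FixtureError("amplitudes and widths must be positive")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        out = np.zeros(points.shape[0])
        for c, q, w in zip(self.centers, self.amplitudes, self.widths):
            d2 = np.sum((points - c) ** 2, axis=1)
            out += q / (2.0 * np.pi * w * w) ** 1.5 * np.exp(-d2 / (2.0 * w * w))
        return out

    def total_integral(self) -> float:
        return float(self.amplitudes.sum())

    def translated(self, shift_bohr) -> "SyntheticDensity":
        return SyntheticDensity(
            self.centers + np.asarray(shift_bohr), self.amplitudes, self.widths
        )

    def rotated(self, rotation: np.ndarray) -> "SyntheticDensity":
        return SyntheticDensity(
            self.centers @ np.asarray(rotation).T, self.amplitudes, self.widths
        )


@dataclass
class FixtureEnsemble:
    """Reproducible set of frames (plus labels once assigned)."""

    geometries: list[MolecularGeometry]
    labels: np.ndarray | None = None
    params: dict = field(default_factory=dict)


_TEMPLATES = {
    "water_cluster": _WATER,
    "protonated_water": _HYDRONIUM,
    "zundel": _ZUNDEL,
}


def _assemble(
    kind: str,
    n_monomers: int,
    rng: np.random.Generator,
    deterministic: bool = False,
) -> tuple[list[str], np.ndarray, int]:
    if kind == "zundel":
        if n_monomers != 2:
            raise FixtureError("the protonated water dimer has exactly 2 monomers")
        els, pos = _ZUNDEL
        return list(els), pos.copy(), 1
    if kind == "alkane":
        els, pos = _alkane_template(n_monomers)
        return list(els), pos.copy(), 0
    charge = 1 if kind == "protonated_water" else 0
    units = []
    if kind == "protonated_water":
        units.append(_HYDRONIUM)
        units += [_WATER] * (n_monomers - 1)
    else:
        units += [_WATER] * n_monomers
    # monomer centers on a jittered cubic lattice, random orientations
    side = max(1, int(np.ceil(n_monomers ** (1.0 / 3.0))))
    cells = [(i, j, k) for i in range(side) for j in range(side) for k in range(side)]
    if deterministic:
        order = np.arange(n_monomers)
    else:
        order = rng.permutation(len(cells))[:n_monomers]
    spacing = 3.1
    els: list[str] = []
    pos_list: list[np.ndarray] = []
    for u, ci in zip(units, order):
        cell = np.array(cells[ci], dtype=float)
        center = spacing * cell
        if not deterministic:
            center = center + rng.uniform(-0.35, 0.35, size=3)
        rot = np.eye(3) if deterministic else random_rotation(rng)
        tels, tpos = u
        els += list(tels)
        pos_list.append((tpos - tpos.mean(axis=0)) @ rot.T + center)
    return els, np.vstack(pos_list), charge


def _min_distance(pos: np.ndarray) -> float:
    if pos.shape[0] < 2:
        return np.inf
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    return float(d[np.triu_indices_from(d, k=1)].min())


def make_geometries(
    kind: str,
    n_monomers: int,
    n_frames: int,
    jitter_sigma: float = 0.05,
    seed: int = 0,
) -> FixtureEnsemble:
    """Seeded thermal-looking frames of a template system.

    ``jitter_sigma`` (Angstrom, default 0.05) is the per-coordinate Gaussian
    displacement emulating decorrelated snapshots at roughly 350 K.  Frames
    with atomic clashes (any pair closer than 0.7 Angstrom) are regenerated,
    with a bounded retry budget.
    """
    if kind not in ("water_cluster", "protonated_water", "alkane", "zundel"):
        raise FixtureError(f"unknown fixture kind {kind!r}")
    if n_monomers < 1:
        raise FixtureError("n_monomers must be >= 1")
    if jitter_sigma < 0:
        raise FixtureError("jitter_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    deterministic = jitter_sigma == 0.0  # frames must equal the template
    geoms: list[MolecularGeometry] = []
    for f in range(n_frames):
        for attempt in range(60):
            els, pos, charge = _assemble(kind, n_monomers, rng, deterministic)
            pos = pos + rng.normal(0.0, jitter_sigma, size=pos.shape)
            if _min_distance(pos) > 0.7:
                break
        else:
            raise FixtureError(
                f"could not place a clash-free frame (kind={kind}, "
                f"n_monomers={n_monomers}, seed={seed}, frame={f})"
            )
        geoms.append(
            MolecularGeometry.from_angstrom(
                els, pos, total_charge=charge, frame_id=f"{kind}-{n_monomers}-{seed}-{f}"
            )
        )
    return FixtureEnsemble(
        geometries=geoms,
        params={
            "kind": kind,
            "n_monomers": n_monomers,
            "n_frames": n_frames,
            "jitter_sigma": jitter_sigma,
            "seed": seed,
        },
    )


#: Gaussian widths of the synthetic atomic densities, Bohr.
_DENSITY_WIDTHS = {"H": 0.9, "C": 0.65, "N": 0.6, "O": 0.55}
_BOND_WIDTH = 0.7
#: electrons moved into each bond-midpoint lobe (half from each partner);
#: ~0.15 e is a typical covalent bond-density accumulation
_BOND_CHARGE = 0.15


def detect_bonds(geometry: MolecularGeometry, scale: float = 1.3) -> list[tuple[int, int]]:
    """Bonded pairs by covalent-radius cutoff: d < scale * (r_a + r_b)."""
    pos = geometry.positions_angstrom()
    bonds = []
    for a in range(geometry.n_atoms):
        for b in range(a + 1, geometry.n_atoms):
            cutoff = scale * (
                COVALENT_RADII[geometry.elements[a]] + COVALENT_RADII[geometry.elements[b]]
            )
            if np.linalg.norm(pos[a] - pos[b]) < cutoff:
                bonds.append((a, b))
    return bonds


def synthesize_density(geometry: MolecularGeometry) -> SyntheticDensity:
    """Smooth atom- plus bond-centered Gaussian density; integral = electron count."""
    n_elec = geometry.n_electrons
    z = np.array([ATOMIC_NUMBERS[e] for e in geometry.elements], dtype=float)
    q_atom = z * (n_elec / z.sum())  # absorb net charge proportionally
    bonds = detect_bonds(geometry)
    centers = [geometry.positions[a] for a in range(geometry.n_atoms)]
    widths = [_DENSITY_WIDTHS[e] for e in geometry.elements]
    amps = list(q_atom)
    for a, b in bonds:
        take = min(_BOND_CHARGE, 0.5 * min(amps[a], amps[b]))
        amps[a] -= 0.5 * take
        amps[b] -= 0.5 * take
        centers.append(0.5 * (geometry.positions[a] + geometry.positions[b]))
        widths.append(_BOND_WIDTH)
        amps.append(take)
    return SyntheticDensity(np.array(centers), np.array(amps), np.array(widths))


def quadrature_fit(
    density: SyntheticDensity,
    geometry: MolecularGeometry,
    aux_basis: AuxBasis,
    grid_spec: GridSpec | None = None,
    provider: QuadratureProvider | None = None,
    check_electrons: bool = True,
) -> AtomicDFCoefficients:
    """Overlap-metric DF fit of a synthetic density on a Becke quadrature grid.

    Raises :class:`UnderResolvedGridError` if the fitted electron count
    deviates from the analytic integral by more than 1%.
    """
    provider = provider or QuadratureProvider(grid_spec or GridSpec())
    coeffs = fit_density(geometry, aux_basis, provider, density)
    if check_electrons:
        n_fit = electron_count(coeffs, aux_basis)
        n_ref = density.total_integral()
        if abs(n_fit - n_ref) > 0.01 * abs(n_ref):
            raise UnderResolvedGridError(
                f"fitted electron count {n_fit:.4f} vs analytic {n_ref:.4f} "
                "(> 1% off): refine the grid or extend the aux basis"
            )
    return coeffs


def featurize_ensemble(
    ensemble: FixtureEnsemble,
    aux_basis: AuxBasis,
    grid_spec: GridSpec | None = None,
    ridr_config: RIDRConfig | None = None,
) -> list[list[RIDRVector]]:
    """Density synthesis + quadrature fit + RIDR for every frame."""
    provider = QuadratureProvider(grid_spec or GridSpec())
    out = []
    for geom in ensemble.geometries:
        rho = synthesize_density(geom)
        coeffs = quadrature_fit(rho, geom, aux_basis, provider=provider)
        out.append(featurize_molecule(coeffs, aux_basis, ridr_config))
    return out


# ------------------------------------------------------- surrogate labels

#: per-element mean correlation-energy offsets (meV) and fluctuation
#: amplitudes (meV) of the surrogate labels; the tanh gain scales the
#: thermal feature fluctuations (which are small relative deviations of the
#: normalized power spectrum) up to the ~100 meV molecular-label spread of
#: a thermal ensemble.
_LABEL_OFFSET_MEV = {"H": -800.0, "C": -4000.0, "N": -5500.0, "O": -7000.0}
_LABEL_AMP_MEV = {"H": 150.0, "C": 300.0, "N": 350.0, "O": 400.0}
_LABEL_GAIN = 40.0

#: template systems supplying one reference atomic environment per element
_REFERENCE_TEMPLATES = {"H": ("water_cluster", 1), "O": ("water_cluster", 1), "C": ("alkane", 1)}
_reference_cache: dict[str, np.ndarray] = {}


def _reference_environment(element: str, dim: int) -> np.ndarray | None:
    """Normalized template RIDR vector for the element, or None if the
    feature length does not match the default basis (custom aux sets)."""
    if element not in _reference_cache and element in _REFERENCE_TEMPLATES:
        from .basis import builtin_basis
        from .grids import GridSpec

        kind, n_mono = _REFERENCE_TEMPLATES[element]
        geom = make_geometries(kind, n_mono, 1, jitter_sigma=0.0, seed=0).geometries[0]
        coeffs = quadrature_fit(
            synthesize_density(geom), geom, builtin_basis(), GridSpec()
        )
        for p in featurize_molecule(coeffs, builtin_basis()):
            if p.element not in _reference_cache:
                _reference_cache[p.element] = p.values / p.norm
    ref = _reference_cache.get(element)
    if ref is None or ref.shape[0] != dim:
        return None
    return ref


def _element_direction(element: str, dim: int) -> np.ndarray:
    """Fixed unit vector per (element, feature length), orthogonalized
    against the template reference environment so the tanh argument
    measures the thermal deviation from it; process-independent."""
    seed = zlib.crc32(f"kdfa-label:{element}:{dim}".encode())
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(dim)
    ref = _reference_environment(element, dim)
    if ref is not None:
        u = u - (u @ ref) * ref
    return u / np.linalg.norm(u)


def synthetic_labels(
    features: list[list[RIDRVector]],
    noise_sigma: float = 1.0 * MEV_TO_HARTREE,
    seed: int = 0,
) -> np.ndarray:
    """Size-extensive surrogate correlation energies (Hartree).

    E_syn(mol) = sum_A [o_e + a_e tanh(g u_e . (p_hat_A - r_e))] + eps, with
    fixed per-element constants, fixed directions u_e orthogonal to the
    template reference environment r_e, unit-normalized features p_hat_A and
    Gaussian noise eps ~ N(0, noise_sigma).  Exactly additive over
    non-interacting fragments when noise_sigma = 0.
    """
    rng = np.random.default_rng(seed)
    labels = np.empty(len(features))
    for i, mol in enumerate(features):
        e_mev = 0.0
        for p in mol:
            u = _element_direction(p.element, p.values.shape[0])
            phat = p.values / p.norm
            ref = _reference_environment(p.element, phat.shape[0])
            arg = float(u @ (phat - ref)) if ref is not None else float(u @ phat)
            e_mev += _LABEL_OFFSET_MEV[p.element] + _LABEL_AMP_MEV[p.element] * np.tanh(
                _LABEL_GAIN * arg
            )
        labels[i] = e_mev * MEV_TO_HARTREE
    if noise_sigma > 0:
        labels = labels + rng.normal(0.0, noise_sigma, size=labels.shape)
    return labels


# ---------------------------------------------- protonated-dimer ensembles

#: harmonic surrogate force constants, meV / Angstrom^2
_K_ROO = 2600.0
_K_NU = 1150.0
_ROO_MIN = 2.45


def surrogate_zundel_energy(r_oo: float, nu: float) -> float:
    """Low-level surrogate energy (Hartree) of a protonated-dimer frame."""
    e_mev = 0.5 * _K_ROO * (r_oo - _ROO_MIN) ** 2 + 0.5 * _K_NU * nu**2
    return e_mev * MEV_TO_HARTREE


def make_zundel_ensemble(
    n_frames: int, temperature: float = 300.0, seed: int = 0
) -> tuple[list[MolecularGeometry], np.ndarray]:
    """Boltzmann sample of protonated-dimer frames from the harmonic surrogate.

    Draws (r_OO, nu) from the exact Gaussian Boltzmann distribution of
    :func:`surrogate_zundel_energy` at the given temperature, builds matching
    geometries (shared proton on the O-O axis, flanking hydrogens jittered),
    and returns (geometries, low-level energies in Hartree).
    """
    from .units import KB_MEV

    rng = np.random.default_rng(seed)
    kbt = KB_MEV * temperature
    sig_r = np.sqrt(kbt / _K_ROO)
    sig_nu = np.sqrt(kbt / _K_NU)
    els, tpos = _ZUNDEL
    geoms, e_low = [], np.empty(n_frames)
    for f in range(n_frames):
        r = _ROO_MIN + rng.normal(0.0, sig_r)
        nu = rng.normal(0.0, sig_nu)
        pos = tpos.copy()
        pos[1, 0] = r
        pos[2] = [(r + nu) / 2.0, 0.0, 0.0]  # nu = d(H,O1) - d(H,O2) on-axis
        pos[5:, 0] += r - _ROO_MIN
        pos[3:] += rng.normal(0.0, 0.03, size=pos[3:].shape)
        geoms.append(
            MolecularGeometry.from_angstrom(
                list(els), pos, total_charge=1, frame_id=f"zundel-{seed}-{f}"
            )
        )
        e_low[f] = surrogate_zundel_energy(r, nu)
    return geoms, e_low
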