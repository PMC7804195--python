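"""Ensemble reweighting to a high-level free-energy surface.

A long, cheap MD ensemble (low-level energies E_low) is turned into an
ensemble at a higher level of theory (E_high, e.g. Hartree-Fock plus the
KDFA correlation energy) by Monte Carlo resampling: each frame carries a
Boltzmann weight

    w_i  proportional to  exp(-(E_high,i - E_low,i) / kB T),

so frames the high-level method favors are up-weighted.  Free energies over
the proton-transfer coordinates of a protonated water dimer,

    r_OO = |O1 - O2|,
    nu   = d(H_shared, O1) - d(H_shared, O2),

follow from the weighted 2-D histogram as F = -kB T ln(P / max P), reported
in meV with the minimum at zero.  nu = 0 means the shared proton is
equidistant from both oxygens; the sign convention fixes O1 as the
lower-indexed oxygen atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import MolecularGeometry
from .units import HARTREE_TO_MEV, KB_MEV


class EnsembleError(ValueError):
    """Raised for malformed ensembles or coordinates."""


@dataclass
class EnsembleRecord:
    """One MD frame with its energies (Hartree) and reaction coordinates (Angstrom)."""

    frame_id: str
    e_low: float
    e_high: float
    r_oo: float
    nu: float
    geometry: MolecularGeometry | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.e_low) and np.isfinite(self.e_high)):
            raise EnsembleError(f"frame {self.frame_id}: non-finite energies")
        if self.r_oo <= 0:
            raise EnsembleError(f"frame {self.frame_id}: r_OO must be positive")


@dataclass
class FESGrid:
    """Binned 2-D free-energy surface over (r_OO, nu)."""

    r_oo_edges: np.ndarray
    nu_edges: np.ndarray
    probability: np.ndarray  # (n_r, n_nu), sums to 1 over occupied bins
    free_energy_mev: np.ndarray  # NaN on empty bins; min over occupied bins = 0
    temperature: float
    marginal_r_oo: np.ndarray = field(default=None)
    marginal_nu: np.ndarray = field(default=None)

    def minimum_location(self) -> tuple[float, float]:
        """Bin-center coordinates of the free-energy minimum."""
        idx = np.unravel_index(np.nanargmin(self.free_energy_mev), self.free_energy_mev.shape)
        rc = 0.5 * (self.r_oo_edges[idx[0]] + self.r_oo_edges[idx[0] + 1])
        nc = 0.5 * (self.nu_edges[idx[1]] + self.nu_edges[idx[1] + 1])
        return float(rc), float(nc)


def proton_coordinates(geometry: MolecularGeometry) -> tuple[float, float]:
    """Proton-transfer coordinates (r_OO, nu) of a protonated water dimer, in Angstrom.

    The shared proton is the hydrogen nearest the O-O midpoint.  O1 and O2
    are ordered by atom index, so nu < 0 means the proton sits closer to the
    lower-indexed oxygen.
    """
    ox = [i for i, e in enumerate(geometry.elements) if e == "O"]
    hy = [i for i, e in enumerate(geometry.elements) if e == "H"]
    if len(ox) != 2:
        raise EnsembleError(
            f"proton coordinates require exactly 2 oxygens, found {len(ox)}"
        )
    if not hy:
        raise EnsembleError("no hydrogen atoms present")
    pos = geometry.positions_angstrom()
    o1, o2 = pos[ox[0]], pos[ox[1]]
    r_oo = float(np.linalg.norm(o1 - o2))
    mid = 0.5 * (o1 + o2)
    shared = hy[int(np.argmin([np.linalg.norm(pos[h] - mid) for h in hy]))]
    nu = float(np.linalg.norm(pos[shared] - o1) - np.linalg.norm(pos[shared] - o2))
    return r_oo, nu


def rsm_weights(e_low: np.ndarray, e_high: np.ndarray, temperature: float) -> np.ndarray:
    """Normalized Boltzmann resampling weights from energy differences (Hartree).

    Invariant to adding any constant to either energy vector; the exponent is
    max-shifted for overflow safety.
    """
    e_low = np.asarray(e_low, dtype=float)
    e_high = np.asarray(e_high, dtype=float)
    if e_low.shape != e_high.shape:
        raise EnsembleError("energy vectors differ in length")
    if not (np.all(np.isfinite(e_low)) and np.all(np.isfinite(e_high))):
        raise EnsembleError("energies must be finite")
    if temperature <= 0:
        raise EnsembleError("temperature must be positive")
    kbt_hartree = KB_MEV * temperature / HARTREE_TO_MEV
    x = -(e_high - e_low) / kbt_hartree
    x -= x.max()
    w = np.exp(x)
    return w / w.sum()


def resample(weights: np.ndarray, n_draws: int, seed: int) -> np.ndarray:
    """Seeded multinomial draw of frame indices with replacement."""
    weights = np.asarray(weights, dtype=float)
    if n_draws < 1:
        raise EnsembleError("n_draws must be >= 1")
    if not np.isclose(weights.sum(), 1.0, atol=1e-8):
        raise EnsembleError("weights must be normalized")
    rng = np.random.default_rng(seed)
    return rng.choice(len(weights), size=n_draws, replace=True, p=weights / weights.sum())


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size 1 / sum(w_i^2); N for uniform, 1 for one-hot."""
    weights = np.asarray(weights, dtype=float)
    return float(1.0 / np.sum(weights**2))


def fes_2d(
    records: list[EnsembleRecord],
    weights: np.ndarray | None = None,
    temperature: float = 300.0,
    r_oo_bin_width: float = 0.02,
    nu_bin_width: float = 0.02,
    r_oo_range: tuple[float, float] | None = None,
    nu_range: tuple[float, float] | None = None,
) -> FESGrid:
    """Weighted 2-D free-energy surface over (r_OO, nu).

    F_bin = -kB T ln(P_bin / max P) in meV; empty bins are NaN (undefined),
    never zero.  Marginal distributions along both coordinates are attached.
    Default bin width 0.02 Angstrom in both coordinates.
    """
    if not records:
        raise EnsembleError("need at least one ensemble record")
    if temperature <= 0:
        raise EnsembleError("temperature must be positive")
    r = np.array([rec.r_oo for rec in records])
    v = np.array([rec.nu for rec in records])
    if weights is None:
        weights = np.full(len(records), 1.0 / len(records))
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != len(records):
        raise EnsembleError("one weight per record required")

    def _edges(vals, width, rng_):
        lo, hi = rng_ if rng_ is not None else (vals.min(), vals.max())
        n = max(1, int(np.ceil((hi - lo) / width - 1e-12)))
        return lo + width * np.arange(n + 1)

    r_edges = _edges(r, r_oo_bin_width, r_oo_range)
    v_edges = _edges(v, nu_bin_width, nu_range)
    hist, _, _ = np.histogram2d(r, v, bins=[r_edges, v_edges], weights=weights)
    total = hist.sum()
    if total <= 0:
        raise EnsembleError("all weight falls outside the requested ranges")
    if np.count_nonzero(hist) == 1 and hist.size > 1:
        import warnings

        warnings.warn("all weight concentrated in a single bin; check binning", stacklevel=2)
    prob = hist / total
    fes = np.full_like(prob, np.nan)
    occ = prob > 0
    fes[occ] = -KB_MEV * temperature * np.log(prob[occ] / prob.max())
    marg_r = prob.sum(axis=1)
    marg_v = prob.sum(axis=0)
    return FESGrid(
        r_oo_edges=r_edges,
        nu_edges=v_edges,
        probability=prob,
        free_energy_mev=fes,
        temperature=temperature,
        marginal_r_oo=marg_r,
        marginal_nu=marg_v,
    )
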