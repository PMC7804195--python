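"""Molecular geometries and XYZ I/O.

Geometries are stored in Bohr internally; XYZ files are read and written in
Angstrom, the universal convention for that format. Multi-frame XYZ
(concatenated blocks) is supported for trajectories; the comment line of each
frame is preserved as ``frame_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM

# Elements the shipped auxiliary family and fixture generators know about.
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "P": 15, "S": 16, "Cl": 17,
}

#: Covalent radii in Angstrom (Cordero et al. consensus values), used for
#: bond detection in the synthetic-density builder.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "S": 1.05, "Cl": 1.02, "P": 1.07,
}


class GeometryError(ValueError):
    """Raised for malformed geometries or XYZ input."""


@dataclass
class MolecularGeometry:
    """A finite molecule: element symbols plus Cartesian positions in Bohr."""

    elements: list[str]
    positions: np.ndarray  # (n_atoms, 3), Bohr
    total_charge: int = 0
    frame_id: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise GeometryError("positions must be an (n_atoms, 3) array")
        if len(self.elements) != self.positions.shape[0]:
            raise GeometryError("element list and positions disagree in length")
        if len(self.elements) == 0:
            raise GeometryError("geometry must contain at least one atom")
        if not np.all(np.isfinite(self.positions)):
            raise GeometryError("positions must be finite")
        bad = [e for e in self.elements if e not in ATOMIC_NUMBERS]
        if bad:
            raise GeometryError(f"unknown element symbols: {sorted(set(bad))}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_electrons(self) -> int:
        return sum(ATOMIC_NUMBERS[e] for e in self.elements) - self.total_charge

    def translated(self, shift_bohr: Sequence[float]) -> "MolecularGeometry":
        return replace(self, positions=self.positions + np.asarray(shift_bohr))

    def rotated(self, rotation: np.ndarray) -> "MolecularGeometry":
        """Apply a proper rotation matrix about the origin."""
        return replace(self, positions=self.positions @ np.asarray(rotation).T)

    def permuted(self, order: Sequence[int]) -> "MolecularGeometry":
        order = list(order)
        return replace(
            self,
            elements=[self.elements[i] for i in order],
            positions=self.positions[order],
        )

    @classmethod
    def from_angstrom(
        cls,
        elements: Sequence[str],
        positions_angstrom: np.ndarray,
        total_charge: int = 0,
        frame_id: str | None = None,
    ) -> "MolecularGeometry":
        pos = np.asarray(positions_angstrom, dtype=float) * BOHR_PER_ANGSTROM
        return cls(list(elements), pos, total_charge, frame_id)

    def positions_angstrom(self) -> np.ndarray:
        return self.positions * ANGSTROM_PER_BOHR


def read_xyz(path: str | Path) -> list[MolecularGeometry]:
    """Read a (possibly multi-frame) XYZ file; coordinates in Angstrom."""
    lines = Path(path).read_text().splitlines()
    frames: list[MolecularGeometry] = []
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise GeometryError(
                f"{path}, line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from exc
        comment = lines[i + 1].strip() if i + 1 < len(lines) else ""
        body = lines[i + 2 : i + 2 + n_atoms]
        if len(body) < n_atoms:
            raise GeometryError(
                f"{path}, frame starting at line {i + 1}: "
                f"expected {n_atoms} atom lines, found {len(body)}"
            )
        elements, coords = [], []
        for j, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise GeometryError(
                    f"{path}, line {i + 3 + j}: malformed atom line {line!r}"
                )
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        frames.append(
            MolecularGeometry.from_angstrom(
                elements, np.array(coords), frame_id=comment or f"frame{frame_no}"
            )
        )
        frame_no += 1
        i += 2 + n_atoms
    if not frames:
        raise GeometryError(f"{path}: no frames found")
    return frames


def write_xyz(path: str | Path, geometries: MolecularGeometry | Iterable[MolecularGeometry]) -> None:
    """Write one or more geometries as (multi-frame) XYZ in Angstrom."""
    if isinstance(geometries, MolecularGeometry):
        geometries = [geometries]
    out: list[str] = []
    for geom in geometries:
        out.append(str(geom.n_atoms))
        out.append(geom.frame_id or "")
        for el, xyz in zip(geom.elements, geom.positions_angstrom()):
            out.append(f"{el:<2s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}")
    Path(path).write_text("\n".join(out) + "\n")


def iter_frames(path: str | Path) -> Iterator[MolecularGeometry]:
    yield from read_xyz(path)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q
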