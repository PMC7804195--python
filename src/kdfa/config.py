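"""Run configuration: YAML round-trip plus a stable content hash."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Resolved settings of a pipeline run; serialized losslessly to YAML."""

    aux_basis: str = "kdfa-light"
    aux_basis_file: str | None = None
    kernel_exponent: int = 2
    element_blocked: bool = True
    ridge_lambda: float = 1e-8
    offdiag_scaling_sq: float = 2.0  # RIDR off-diagonal scaling squared
    l_normalization: bool = False
    seed: int = 0
    temperature: float = 300.0
    r_oo_bin_width: float = 0.02
    nu_bin_width: float = 0.02
    grid_n_radial: int = 35
    grid_n_theta: int = 12
    grid_n_phi: int = 24
    label_noise_mev: float = 1.0

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def grid_spec(self):
        from .grids import GridSpec

        return GridSpec(self.grid_n_radial, self.grid_n_theta, self.grid_n_phi)

    def kernel_config(self):
        from .model import KernelConfig

        return KernelConfig(
            exponent=self.kernel_exponent,
            element_blocked=self.element_blocked,
            ridge_lambda=self.ridge_lambda,
        )

    def ridr_config(self):
        import numpy as np

        from .ridr import RIDRConfig

        return RIDRConfig(
            offdiag_scaling=float(np.sqrt(self.offdiag_scaling_sq)),
            l_normalization=self.l_normalization,
        )

    def basis(self):
        from .basis import builtin_basis, load_basis

        if self.aux_basis_file:
            return load_basis(self.aux_basis_file, name=self.aux_basis)
        return builtin_basis(self.aux_basis)
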