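"""Persistence of features and trained models.

A single self-describing HDF5 container format (versioned) holds per-frame
RIDR feature sets and trained functionals.  Every file records the
aux-basis name and fingerprint plus the config hash that produced it, so
downstream stages can refuse mismatched inputs.  Tabular results (energies,
free-energy surfaces, learning curves) are plain text for diff-ability.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .model import KernelConfig, TrainedKDFA
from .ridr import RIDRVector

FORMAT_VERSION = 1


class StorageError(ValueError):
    """Raised on malformed or incompatible containers."""


def _write_header(f: h5py.File, kind: str, meta: dict) -> None:
    f.attrs["format"] = f"kdfa-{kind}"
    f.attrs["format_version"] = FORMAT_VERSION
    for k, v in meta.items():
        if v is not None:
            f.attrs[k] = v


def _check_header(f: h5py.File, kind: str) -> None:
    if f.attrs.get("format") != f"kdfa-{kind}":
        raise StorageError(
            f"not a kdfa {kind} container (format={f.attrs.get('format')!r})"
        )
    if int(f.attrs.get("format_version", -1)) > FORMAT_VERSION:
        raise StorageError("container written by a newer format version")


def _write_molecule(grp: h5py.Group, mol: list[RIDRVector]) -> None:
    grp.create_dataset(
        "elements", data=np.array([p.element for p in mol], dtype="S4")
    )
    for i, p in enumerate(mol):
        grp.create_dataset(f"atom{i:04d}", data=p.values)


def _read_molecule(grp: h5py.Group) -> list[RIDRVector]:
    elements = [e.decode() for e in grp["elements"][()]]
    return [
        RIDRVector(el, grp[f"atom{i:04d}"][()]) for i, el in enumerate(elements)
    ]


def save_features(
    path: str | Path,
    frame_ids: list[str],
    features: list[list[RIDRVector]],
    meta: dict | None = None,
) -> None:
    """Persist per-frame RIDR feature sets keyed by frame_id."""
    if len(frame_ids) != len(features):
        raise StorageError("one frame_id per feature set required")
    with h5py.File(path, "w") as f:
        _write_header(f, "features", meta or {})
        frames = f.create_group("frames")
        for fid, mol in zip(frame_ids, features):
            _write_molecule(frames.create_group(fid), mol)


def load_features(path: str | Path) -> tuple[list[str], list[list[RIDRVector]], dict]:
    with h5py.File(path, "r") as f:
        _check_header(f, "features")
        meta = dict(f.attrs)
        frame_ids = sorted(f["frames"].keys())
        feats = [_read_molecule(f["frames"][fid]) for fid in frame_ids]
    return frame_ids, feats, meta


def save_coefficients(
    path: str | Path,
    frame_ids: list[str],
    coefficient_sets: list,
    meta: dict | None = None,
) -> None:
    """Persist per-frame atomic DF coefficient sets keyed by frame_id.

    Each entry is an :class:`~kdfa.density_fitting.AtomicDFCoefficients`;
    the basis name, metric and fit residual are stored alongside.
    """
    if len(frame_ids) != len(coefficient_sets):
        raise StorageError("one frame_id per coefficient set required")
    with h5py.File(path, "w") as f:
        _write_header(f, "coefficients", meta or {})
        frames = f.create_group("frames")
        for fid, cs in zip(frame_ids, coefficient_sets):
            grp = frames.create_group(fid)
            grp.attrs["metric"] = cs.metric
            grp.attrs["fit_residual"] = cs.fit_residual
            grp.attrs["basis_name"] = cs.basis_name
            grp.create_dataset(
                "elements", data=np.array(cs.elements, dtype="S4")
            )
            for i, c in enumerate(cs.per_atom):
                grp.create_dataset(f"atom{i:04d}", data=c)


def load_coefficients(path: str | Path):
    """Load coefficient sets; returns (frame_ids, coefficient_sets, meta)."""
    from .density_fitting import AtomicDFCoefficients

    with h5py.File(path, "r") as f:
        _check_header(f, "coefficients")
        meta = dict(f.attrs)
        frame_ids = sorted(f["frames"].keys())
        sets = []
        for fid in frame_ids:
            grp = f["frames"][fid]
            elements = [e.decode() for e in grp["elements"][()]]
            per_atom = [grp[f"atom{i:04d}"][()] for i in range(len(elements))]
            sets.append(
                AtomicDFCoefficients(
                    per_atom=per_atom,
                    elements=elements,
                    metric=str(grp.attrs["metric"]),
                    fit_residual=float(grp.attrs["fit_residual"]),
                    basis_name=str(grp.attrs["basis_name"]),
                )
            )
    return frame_ids, sets, meta


def save_model(path: str | Path, model: TrainedKDFA, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        _write_header(f, "model", meta or {})
        f.attrs["kernel_exponent"] = model.kernel_config.exponent
        f.attrs["element_blocked"] = model.kernel_config.element_blocked
        f.attrs["ridge_lambda"] = model.kernel_config.ridge_lambda
        for k, v in model.provenance.items():
            if v is not None:
                f.attrs[f"prov_{k}"] = v
        f.create_dataset("alphas", data=model.alphas)
        systems = f.create_group("systems")
        for i, mol in enumerate(model.systems):
            _write_molecule(systems.create_group(f"sys{i:05d}"), mol)


def load_model(path: str | Path) -> TrainedKDFA:
    with h5py.File(path, "r") as f:
        _check_header(f, "model")
        config = KernelConfig(
            exponent=int(f.attrs["kernel_exponent"]),
            element_blocked=bool(f.attrs["element_blocked"]),
            ridge_lambda=float(f.attrs["ridge_lambda"]),
        )
        alphas = f["alphas"][()]
        keys = sorted(f["systems"].keys())
        systems = [_read_molecule(f["systems"][k]) for k in keys]
        provenance = {
            k[len("prov_") :]: v for k, v in f.attrs.items() if k.startswith("prov_")
        }
    return TrainedKDFA(systems, alphas, config, provenance)
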