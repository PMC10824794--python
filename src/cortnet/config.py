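"""Flat YAML run configuration, output writing and manifests.

One flat key space with explicit schema validation: unknown keys are
rejected by name, and ``load_config(write_config(cfg)) == cfg`` for all
fields.  Every run directory records the fully resolved configuration
and seed next to its outputs so published examples regenerate
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .kernels import KernelSpec
from .propagation import CascadeNetwork
from .specs import ColumnSpec, NetworkSpec, PopulationSpec, SimConfig

__all__ = ["RunConfig", "load_config", "write_config", "write_outputs"]


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration covering network, simulation and cascade blocks.

    ``omegas``/``s_mat``/``p_mat`` describe one column layout shared by
    all columns; the number of columns is the trailing dimension of
    ``h`` (1 when ``h`` is null).
    """

    omegas: tuple[float, ...] = (6.283185307179586,)
    s_mat: tuple[tuple[float, ...], ...] = ((0.0,),)
    p_mat: tuple[tuple[float, ...], ...] = ((1.0,),)
    eps: float = 0.0
    p_scale: float = 0.01
    s_gain: float = 1.0
    p_coeffs: tuple[float, float, float] = (1.0, 1.0, 0.2)
    h: tuple | None = None
    cascading: bool = False
    onset_node: int = 0
    dt: float = 1.0e-3
    t_end: float = 10.0
    noise_sigma: float = 0.0
    seed: int = 0
    record_stride: int = 1

    def kernel(self) -> KernelSpec:
        return KernelSpec(s_gain=self.s_gain, p_coeffs=tuple(self.p_coeffs))

    def network(self) -> NetworkSpec:
        col = ColumnSpec(
            populations=tuple(PopulationSpec(w) for w in self.omegas),
            s_mat=np.asarray(self.s_mat, dtype=float),
            p_mat=np.asarray(self.p_mat, dtype=float),
            eps=self.eps,
            p_scale=self.p_scale,
            kernel=self.kernel(),
        )
        if self.h is None:
            return NetworkSpec(columns=(col,), cascading=self.cascading)
        h = np.asarray(self.h, dtype=float)
        n_cols = h.shape[-1]
        return NetworkSpec(columns=(col,) * n_cols, h=h, cascading=self.cascading)

    def cascade(self) -> CascadeNetwork:
        if self.h is None:
            raise ValueError("cascade requires an h matrix in the config")
        h = np.asarray(self.h, dtype=float)
        if h.ndim == 3:
            if h.shape[0] != 1:
                raise ValueError("cascade networks are single-layer")
            h = h[0]
        return CascadeNetwork(h=h, onset_node=self.onset_node,
                              omega=self.omegas[0], p_scale=self.p_scale,
                              kernel=self.kernel())

    def sim_config(self) -> SimConfig:
        return SimConfig(dt=self.dt, t_end=self.t_end,
                         noise_sigma=self.noise_sigma, seed=self.seed,
                         record_stride=self.record_stride)


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def _to_plain(value):
    if isinstance(value, tuple):
        return [_to_plain(v) for v in value]
    return value


def _to_tuple(value):
    if isinstance(value, list):
        return tuple(_to_tuple(v) for v in value)
    return value


def load_config(path) -> RunConfig:
    """Read and validate a flat YAML config; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    kwargs = {k: _to_tuple(v) for k, v in raw.items()}
    return RunConfig(**kwargs)


def write_config(cfg: RunConfig, path) -> None:
    plain = {k: _to_plain(v) for k, v in dataclasses.asdict(cfg).items()}
    Path(path).write_text(yaml.safe_dump(plain, sort_keys=True))


def write_outputs(results: dict[str, "object"], out_dir) -> dict:
    """Write result tables/objects to ``out_dir`` and return a hash manifest.

    Values may be pandas DataFrames (written as TSV), numpy arrays
    (TSV), strings (verbatim) or RunConfig (YAML).  The manifest lists
    every file with its sha256 and is itself written as manifest.json.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, value in results.items():
        p = out / name
        if isinstance(value, RunConfig):
            write_config(value, p)
        elif isinstance(value, pd.DataFrame):
            value.to_csv(p, sep="\t", index=False, na_rep="")
        elif isinstance(value, np.ndarray):
            np.savetxt(p, np.atleast_2d(value), delimiter="\t", fmt="%.17g")
        elif isinstance(value, str):
            p.write_text(value)
        else:
            raise TypeError(f"cannot write result {name!r} of type {type(value).__name__}")
        manifest[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
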