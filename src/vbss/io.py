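"""Delimited-text and JSON I/O for data, model, prior and option records.

CSV dialect: comma separator, header row, UTF-8, '.' decimal; rows are time
samples and columns are channels.  Missing cells become excluded samples.
Model JSON references mappings by registered name (see
:data:`vbss.models.REGISTRY`); arbitrary code in config files is not
supported.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import (
    GammaPrior,
    GaussianPrior,
    InversionOptions,
    ModelSpec,
    PriorBundle,
    TimeSeriesData,
)
from .models import REGISTRY

__all__ = [
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_matrix_csv",
    "read_matrix_csv",
    "spec_to_json",
    "spec_from_json",
    "priors_to_json",
    "priors_from_json",
    "options_to_json",
    "options_from_json",
]

_PathLike = Union[str, Path]


def write_timeseries_csv(path: _PathLike, data: TimeSeriesData) -> None:
    y = np.where(data.exclusion_mask, np.nan, data.y)
    df = pd.DataFrame(y.T, columns=[f"y{i}" for i in range(data.p)])
    df.to_csv(path, index=False, float_format="%.17g")


def read_timeseries_csv(path: _PathLike, u: np.ndarray = None,
                        dt: float = None) -> TimeSeriesData:
    df = pd.read_csv(path)
    y = df.to_numpy(dtype=float).T
    return TimeSeriesData(y=y, u=u, dt=dt)


def write_matrix_csv(path: _PathLike, m: np.ndarray, prefix: str = "u") -> None:
    m = np.atleast_2d(np.asarray(m, dtype=float))
    df = pd.DataFrame(m.T, columns=[f"{prefix}{i}" for i in range(m.shape[0])])
    df.to_csv(path, index=False, float_format="%.17g")


def read_matrix_csv(path: _PathLike) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float).T


def _arr(x):
    return np.asarray(x, dtype=float).tolist() if x is not None else None


def spec_to_json(path: _PathLike, spec: ModelSpec, f_name: str, g_name: str) -> None:
    """Serialize a spec whose mappings are registered library entries."""
    for nm in (f_name, g_name):
        if nm is not None and nm not in REGISTRY:
            raise KeyError(f"mapping {nm!r} is not registered")
    doc = {
        "f": f_name,
        "g": g_name,
        "n": spec.n,
        "n_theta": spec.n_theta,
        "n_phi": spec.n_phi,
        "source": spec.source,
        "n_micro": spec.n_micro,
        "dt": spec.dt,
        "delay_matrix": _arr(spec.delay_matrix),
        "extras": {
            k: (_arr(v) if isinstance(v, np.ndarray) else v)
            for k, v in spec.extras.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def spec_from_json(path: _PathLike) -> ModelSpec:
    doc = json.loads(Path(path).read_text())
    for key in ("g", "n", "n_theta", "n_phi"):
        if key not in doc:
            raise ValueError(f"model JSON missing required field {key!r}")
    f = REGISTRY[doc["f"]] if doc.get("f") else None
    g = REGISTRY[doc["g"]]
    dm = doc.get("delay_matrix")
    extras = {
        k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
        for k, v in doc.get("extras", {}).items()
    }
    return ModelSpec(
        f=f,
        g=g,
        n=int(doc["n"]),
        n_theta=int(doc["n_theta"]),
        n_phi=int(doc["n_phi"]),
        source=doc.get("source", "continuous"),
        n_micro=int(doc.get("n_micro", 1)),
        dt=float(doc.get("dt", 1.0)),
        delay_matrix=np.asarray(dm, dtype=int) if dm is not None else None,
        extras=extras,
    )


def _gauss_doc(g: GaussianPrior) -> dict:
    return {"mean": _arr(g.mean), "covariance": _arr(g.covariance)}


def _gauss_from(doc: dict) -> GaussianPrior:
    return GaussianPrior(
        np.asarray(doc["mean"], dtype=float),
        np.asarray(doc["covariance"], dtype=float),
    )


def priors_to_json(path: _PathLike, priors: PriorBundle) -> None:
    doc = {
        "theta": _gauss_doc(priors.theta),
        "phi": _gauss_doc(priors.phi),
        "x0": _gauss_doc(priors.x0),
        "state_precision": {"a": priors.state_precision.a, "b": priors.state_precision.b},
        "noise_precision": {"a": priors.noise_precision.a, "b": priors.noise_precision.b},
        "state_noise_cov_structure": _arr(priors.state_noise_cov_structure),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def priors_from_json(path: _PathLike) -> PriorBundle:
    doc = json.loads(Path(path).read_text())
    Q = doc.get("state_noise_cov_structure")
    return PriorBundle(
        theta=_gauss_from(doc["theta"]),
        phi=_gauss_from(doc["phi"]),
        x0=_gauss_from(doc["x0"]),
        state_precision=GammaPrior(**doc["state_precision"]),
        noise_precision=GammaPrior(**doc["noise_precision"]),
        state_noise_cov_structure=np.asarray(Q, dtype=float) if Q is not None else None,
    )


def options_to_json(path: _PathLike, options: InversionOptions) -> None:
    doc = {
        "lag_k": options.lag_k,
        "max_iter": options.max_iter,
        "tol_dF": options.tol_dF,
        "seed": options.seed,
        "deterministic_limit": options.deterministic_limit,
        "verbose": options.verbose,
        "fixed_noise_precision": options.fixed_noise_precision,
        "fixed_state_precision": options.fixed_state_precision,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def options_from_json(path: _PathLike) -> InversionOptions:
    return InversionOptions(**json.loads(Path(path).read_text()))
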