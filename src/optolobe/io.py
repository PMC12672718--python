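"""Plain-text file formats: catalogs, connectivity, tensors, fit results.

All files are delimited text (CSV) or JSON/YAML with a ``#`` provenance
comment line carrying the package version, seed and configuration hash, so
every output can be traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .network_model import CellTypeCatalog, SignedConnectome
from .parameters import GainParameters, GateParams, ModelParameters
from .protocol import ResponseTensor
from .target_data import TargetSet

__all__ = [
    "write_catalog",
    "read_catalog",
    "write_connectivity",
    "read_connectivity",
    "read_connectome",
    "write_response_tensor",
    "read_response_tensor",
    "read_target_set",
    "write_params",
    "read_params",
    "write_fit_result",
    "read_fit_result",
    "load_config",
    "dump_config",
]


def provenance_line(seed: int | None = None, config: dict | None = None) -> str:
    parts = [f"optolobe v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        parts.append(f"config_sha={digest}")
    return "# " + " ".join(parts)


def _write_csv(df: pd.DataFrame, path, seed=None, config=None, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(seed, config) + "\n")
        df.to_csv(fh, index=index)


def write_catalog(catalog: CellTypeCatalog, path, seed=None) -> None:
    _write_csv(catalog.to_frame(), path, seed)


def read_catalog(path) -> CellTypeCatalog:
    return CellTypeCatalog.from_frame(pd.read_csv(path, comment="#", keep_default_na=False, na_values=[]))


def write_connectivity(matrix: np.ndarray, names, path, seed=None) -> None:
    df = pd.DataFrame(np.asarray(matrix, int), index=list(names), columns=list(names))
    _write_csv(df, path, seed, index=True)


def read_connectivity(path, names=None) -> np.ndarray:
    df = pd.read_csv(path, comment="#", index_col=0)
    if names is not None:
        expected = list(names)
        if list(df.index) != expected or list(df.columns) != expected:
            raise ValueError(f"connectivity file {path} does not match the catalog order")
    return df.to_numpy(dtype=float)


def read_connectome(catalog_path, intra_path, inter_path) -> SignedConnectome:
    catalog = read_catalog(catalog_path)
    intra = read_connectivity(intra_path, catalog.names)
    inter = read_connectivity(inter_path, catalog.names)
    return SignedConnectome(intra=intra, inter=inter, catalog=catalog)


def write_response_tensor(tensor: ResponseTensor, path, seed=None) -> None:
    df = tensor.to_long_frame()
    with open(path, "w") as fh:
        fh.write(provenance_line(seed) + "\n")
        fh.write(f"# onset_index={tensor.onset_index}\n")
        df.to_csv(fh, index=False)


def read_response_tensor(path) -> ResponseTensor:
    onset = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "onset_index=" in line:
                onset = int(line.split("onset_index=")[1])
    if onset is None:
        raise ValueError(f"{path} is missing its onset_index header record")
    df = pd.read_csv(path, comment="#")
    return ResponseTensor.from_long_frame(df, onset_index=onset)


def read_target_set(path) -> TargetSet:
    return TargetSet(tensor=read_response_tensor(path))


def _params_dict(params: ModelParameters) -> dict:
    d = {
        "inp_gain": params.gains.inp_gain.tolist(),
        "out_gain": params.gains.out_gain.tolist(),
        "gate": None,
    }
    if params.gate is not None:
        g = params.gate
        d["gate"] = {
            "g_max": g.g_max.tolist(),
            "v_mid": g.v_mid,
            "slope": g.slope,
            "tau_midv": g.tau_midv,
            "e_rev": g.e_rev,
        }
    return d


def _params_from_dict(d: dict) -> ModelParameters:
    gate = None
    if d.get("gate") is not None:
        g = d["gate"]
        gate = GateParams(
            g_max=np.asarray(g["g_max"], float),
            v_mid=g["v_mid"],
            slope=g["slope"],
            tau_midv=g["tau_midv"],
            e_rev=g.get("e_rev", -30.0),
        )
    gains = GainParameters(
        inp_gain=np.asarray(d["inp_gain"], float),
        out_gain=np.asarray(d["out_gain"], float),
    )
    return ModelParameters(gains=gains, gate=gate)


def _atomic_json(obj: dict, path) -> None:
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=1)
    os.replace(tmp, path)  # atomic per-file write


def write_params(params: ModelParameters, path, seed=None) -> None:
    _atomic_json({"provenance": provenance_line(seed), "params": _params_dict(params)}, path)


def read_params(path) -> ModelParameters:
    with open(path) as fh:
        return _params_from_dict(json.load(fh)["params"])


def write_fit_result(result, path, seed=None, config: dict | None = None) -> None:
    obj = {
        "provenance": provenance_line(seed, config),
        "final_cost": result.final_cost,
        "seed": result.seed,
        "restart_index": result.restart_index,
        "failed": result.failed,
        "message": result.message,
        "cost_trajectory": np.asarray(result.cost_trajectory).tolist(),
        "params": None if result.params is None else _params_dict(result.params),
    }
    _atomic_json(obj, path)


def read_fit_result(path):
    from .fitting import FitResult

    with open(path) as fh:
        d = json.load(fh)
    return FitResult(
        params=None if d["params"] is None else _params_from_dict(d["params"]),
        final_cost=d["final_cost"],
        cost_trajectory=np.asarray(d["cost_trajectory"], float).reshape(-1, 2),
        seed=d["seed"],
        restart_index=d["restart_index"],
        failed=d["failed"],
        message=d.get("message", ""),
    )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(config=cfg) + "\n")
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_synth_spec(spec, path) -> None:
    dump_config(asdict(spec), path)
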