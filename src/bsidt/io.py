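"""Readers and writers for raw stacks, volumes, transfer functions and spectra.

Formats: multi-page TIFF + YAML sidecar for raw camera frames (interchange
with Fiji/ImageJ), HDF5 containers for volumes / transfer functions /
hyperspectral stacks, two-column CSV for spectra, YAML for configuration.
Integer raw frames round-trip bit-exactly; float data are stored at
float64 unless stated otherwise.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import tifffile
import yaml

from .forward import STATES, IntensityStack
from .inverse import ChemicalRecord
from .optics import OpticalConfig
from .photothermal import PumpProbeTiming, Spectrum
from .transfer import IlluminationSet, TransferFunctionSet

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "save_config",
    "load_config",
    "write_stack",
    "read_stack",
    "write_volumes",
    "read_volumes",
    "write_tfs",
    "read_tfs",
    "write_spectrum",
    "read_spectrum",
    "write_hyperstack",
    "read_hyperstack",
]

SCHEMA_VERSION = "1"


class SchemaError(IOError):
    """Raised when a sidecar or container does not match the expected schema."""


# -- configuration -----------------------------------------------------------


def save_config(path: str | Path, config: OpticalConfig) -> None:
    doc = {"schema_version": SCHEMA_VERSION, "optical_config": config.to_dict()}
    Path(path).write_text(
        "# bsidt optical configuration; lengths in µm, frequencies in cycles/µm\n"
        + yaml.safe_dump(doc, sort_keys=False)
    )


def load_config(path: str | Path) -> OpticalConfig:
    doc = yaml.safe_load(Path(path).read_text())
    _check_schema(doc)
    return OpticalConfig.from_dict(doc["optical_config"])


def _check_schema(doc: object) -> None:
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise SchemaError("missing schema_version field")
    if str(doc["schema_version"]) != SCHEMA_VERSION:
        raise SchemaError(
            f"schema version mismatch: file has {doc['schema_version']!r}, expected {SCHEMA_VERSION!r}"
        )


# -- raw stacks --------------------------------------------------------------


def write_stack(path: str | Path, stack: IntensityStack) -> None:
    """Multi-page TIFF (source-major, hot/cold, repetition order) plus a
    ``<stem>.yaml`` sidecar carrying per-page metadata."""
    path = Path(path)
    n_src, n_states, n_rep, ny, nx = stack.frames.shape
    pages = stack.frames.reshape(n_src * n_states * n_rep, ny, nx)
    if np.allclose(pages, np.round(pages)) and pages.max() < 2**16 and pages.min() >= 0:
        tifffile.imwrite(path, pages.astype(np.uint16))
    else:
        tifffile.imwrite(path, pages.astype(np.float32))
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "shape": [n_src, n_states, n_rep, ny, nx],
        "states": list(STATES),
        "wavenumber": stack.wavenumber,
        "pump_power": stack.pump_power,
        "timing": stack.timing.to_dict() if isinstance(stack.timing, PumpProbeTiming) else None,
        "backgrounds": stack.backgrounds.ravel().tolist(),
        "metadata": _jsonable(stack.metadata),
        "pages": [
            {"source": s, "state": STATES[st], "repetition": r}
            for s in range(n_src)
            for st in range(n_states)
            for r in range(n_rep)
        ],
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_stack(path: str | Path) -> IntensityStack:
    path = Path(path)
    sidecar_path = path.with_suffix(".yaml")
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar {sidecar_path}")
    sidecar = yaml.safe_load(sidecar_path.read_text())
    _check_schema(sidecar)
    pages = tifffile.imread(path)
    shape = tuple(sidecar["shape"])
    frames = np.asarray(pages, dtype=float).reshape(shape)
    backgrounds = np.asarray(sidecar["backgrounds"], dtype=float).reshape(shape[:3])
    timing = PumpProbeTiming(**sidecar["timing"]) if sidecar.get("timing") else None
    return IntensityStack(
        frames=frames,
        backgrounds=backgrounds,
        wavenumber=sidecar.get("wavenumber"),
        pump_power=sidecar.get("pump_power", 0.0),
        timing=timing,
        metadata=sidecar.get("metadata", {}),
    )


def _jsonable(d: dict) -> dict:
    return json.loads(json.dumps(d, default=lambda o: float(o) if np.isscalar(o) else str(o)))


# -- reconstructed volumes ---------------------------------------------------


def write_volumes(path: str | Path, record: ChemicalRecord, config: OpticalConfig | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("cold_ri", data=record.cold_ri)
        f.create_dataset("hot_ri", data=record.hot_ri)
        f.create_dataset("delta_ri", data=record.delta_ri)
        if record.wavenumber is not None:
            f.attrs["wavenumber"] = record.wavenumber
        f.attrs["pump_power"] = record.pump_power
        if record.delay_time is not None:
            f.attrs["delay_time"] = record.delay_time
        f.attrs["metadata"] = json.dumps(_jsonable(record.metadata))
        if config is not None:
            f.attrs["optical_config"] = json.dumps(config.to_dict())


def read_volumes(path: str | Path) -> tuple[ChemicalRecord, OpticalConfig | None]:
    with h5py.File(path, "r") as f:
        if str(f.attrs.get("schema_version", "")) != SCHEMA_VERSION:
            raise SchemaError("volume container schema mismatch")
        record = ChemicalRecord(
            cold_ri=f["cold_ri"][...],
            hot_ri=f["hot_ri"][...],
            delta_ri=f["delta_ri"][...],
            wavenumber=float(f.attrs["wavenumber"]) if "wavenumber" in f.attrs else None,
            pump_power=float(f.attrs.get("pump_power", 0.0)),
            delay_time=float(f.attrs["delay_time"]) if "delay_time" in f.attrs else None,
            metadata=json.loads(f.attrs.get("metadata", "{}")),
        )
        config = None
        if "optical_config" in f.attrs:
            config = OpticalConfig.from_dict(json.loads(f.attrs["optical_config"]))
    return record, config


# -- transfer functions ------------------------------------------------------


def write_tfs(path: str | Path, tfs: TransferFunctionSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("H_re", data=tfs.H_re)
        f.create_dataset("H_im", data=tfs.H_im)
        f.create_dataset("illumination/nu", data=tfs.illumination.nu)
        f.create_dataset("illumination/amplitudes", data=tfs.illumination.amplitudes)
        f.attrs["optical_config"] = json.dumps(tfs.config.to_dict())


def read_tfs(path: str | Path) -> TransferFunctionSet:
    with h5py.File(path, "r") as f:
        if str(f.attrs.get("schema_version", "")) != SCHEMA_VERSION:
            raise SchemaError("transfer-function container schema mismatch")
        config = OpticalConfig.from_dict(json.loads(f.attrs["optical_config"]))
        illum = IlluminationSet(nu=f["illumination/nu"][...], amplitudes=f["illumination/amplitudes"][...])
        return TransferFunctionSet(H_re=f["H_re"][...], H_im=f["H_im"][...], config=config, illumination=illum)


# -- spectra -----------------------------------------------------------------


def write_spectrum(path: str | Path, spectrum: Spectrum) -> None:
    header = (
        "bsidt extracted spectrum\n"
        f"provenance: {json.dumps(_jsonable(spectrum.provenance))}\n"
        "wavenumber_cm-1,delta_ri"
    )
    np.savetxt(
        path,
        np.column_stack([spectrum.wavenumbers, spectrum.values]),
        delimiter=",",
        header=header,
    )


def read_spectrum(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, delimiter=",")
    return data[:, 0], data[:, 1]


# -- hyperspectral container -------------------------------------------------


def write_hyperstack(
    path: str | Path,
    records: Sequence[ChemicalRecord],
    ir_power: np.ndarray,
    config: OpticalConfig | None = None,
) -> None:
    order = np.argsort([r.wavenumber for r in records])
    records = [records[i] for i in order]
    wn = np.asarray([r.wavenumber for r in records], dtype=float)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("wavenumbers", data=wn)
        f.create_dataset("ir_power", data=np.asarray(ir_power, dtype=float)[order])
        f.create_dataset("delta_ri", data=np.stack([r.delta_ri for r in records], axis=0))
        f.create_dataset("cold_ri", data=np.stack([r.cold_ri for r in records], axis=0))
        f.create_dataset("hot_ri", data=np.stack([r.hot_ri for r in records], axis=0))
        if config is not None:
            f.attrs["optical_config"] = json.dumps(config.to_dict())


def read_hyperstack(path: str | Path) -> tuple[list[ChemicalRecord], np.ndarray]:
    with h5py.File(path, "r") as f:
        if str(f.attrs.get("schema_version", "")) != SCHEMA_VERSION:
            raise SchemaError("hyperspectral container schema mismatch")
        wn = f["wavenumbers"][...]
        power = f["ir_power"][...]
        records = [
            ChemicalRecord(
                cold_ri=f["cold_ri"][w],
                hot_ri=f["hot_ri"][w],
                delta_ri=f["delta_ri"][w],
                wavenumber=float(wn[w]),
            )
            for w in range(wn.size)
        ]
    return records, power
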