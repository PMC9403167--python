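"""Serialization: tabular measurement/perturbation files, corpus and model artifacts.

Tabular exports are plain CSV; corpora go to HDF5 (one group per split
with stacked input/target matrices plus JSON scene metadata); trained
models go to a single ``.npz`` whose JSON header carries the layer
widths, the normalization anchors, the initialization seed, and a
schema version.  Every reader checks the schema version and fails
loudly on mismatch rather than misparsing.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .ann import MLPModel, ModelSpec
from .geometry import FDMeasurement, ProbeGeometry
from .perturbation import COMMON_MAX_LOGAMP, COMMON_MIN_PHASE, Perturbation
from .synthdata import Corpus, Scene

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    pass


def measurement_frame(meas: FDMeasurement, geometry: ProbeGeometry) -> pd.DataFrame:
    s, d = geometry.pair_index()
    return pd.DataFrame(
        {
            "wavelength": meas.wavelength,
            "source_id": s,
            "detector_id": d,
            "rho": meas.rho,
            "amplitude": meas.amplitude,
            "phase": np.angle(meas.U),
        }
    )


def write_measurement(path, meas: FDMeasurement, geometry: ProbeGeometry) -> None:
    frame = measurement_frame(meas, geometry)
    with open(path, "w") as fh:
        fh.write(f"# dotdiff measurement schema={SCHEMA_VERSION}\n")
        frame.to_csv(fh, index=False)


def read_measurement(path, geometry: ProbeGeometry) -> FDMeasurement:
    with open(path) as fh:
        header = fh.readline()
        if "dotdiff measurement" not in header:
            raise SchemaError(f"not a measurement file: {path}")
        version = int(header.rsplit("schema=", 1)[1])
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported measurement schema {version}")
        frame = pd.read_csv(fh)
    expected = {"wavelength", "source_id", "detector_id", "rho", "amplitude", "phase"}
    if set(frame.columns) != expected:
        raise SchemaError(f"unexpected columns {sorted(frame.columns)}")
    frame = frame.sort_values(["source_id", "detector_id"], kind="stable")
    U = frame["amplitude"].to_numpy() * np.exp(1j * frame["phase"].to_numpy())
    return FDMeasurement(
        U=U,
        rho=frame["rho"].to_numpy(),
        wavelength=float(frame["wavelength"].iloc[0]),
        geometry=geometry,
    )


def write_perturbation(path, pert: Perturbation, geometry: ProbeGeometry) -> None:
    s, d = geometry.pair_index()
    frame = pd.DataFrame(
        {
            "source_id": s,
            "detector_id": d,
            "real": pert.values.real,
            "imag": pert.values.imag,
            "provenance": pert.provenance,
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# dotdiff perturbation schema={SCHEMA_VERSION} wavelength={pert.wavelength}\n"
        )
        frame.to_csv(fh, index=False)


def read_perturbation(path) -> Perturbation:
    with open(path) as fh:
        header = fh.readline()
        if "dotdiff perturbation" not in header:
            raise SchemaError(f"not a perturbation file: {path}")
        fields = dict(
            kv.split("=") for kv in header.split("schema=", 1)[1].split() if "=" in kv
        )
        version = int(header.split("schema=", 1)[1].split()[0])
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported perturbation schema {version}")
        wavelength = float(fields.get("wavelength", 0.0))
        frame = pd.read_csv(fh)
    frame = frame.sort_values(["source_id", "detector_id"], kind="stable")
    return Perturbation(
        values=frame["real"].to_numpy() + 1j * frame["imag"].to_numpy(),
        wavelength=wavelength,
        provenance=str(frame["provenance"].iloc[0]),
    )


def save_corpus(path, train: Corpus, val: Corpus, manifest: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["manifest"] = json.dumps(manifest or {})
        for name, corpus in (("train", train), ("validation", val)):
            g = f.create_group(name)
            g.create_dataset("X", data=corpus.X, compression="gzip")
            g.create_dataset("Y", data=corpus.Y, compression="gzip")
            g.create_dataset("seeds", data=corpus.seeds)
            g.create_dataset(
                "scenes",
                data=np.array(
                    [json.dumps(s.to_dict()) for s in corpus.scenes], dtype=object
                ),
                dtype=h5py.string_dtype(),
            )


def load_corpus(path) -> tuple[Corpus, Corpus, dict]:
    with h5py.File(path, "r") as f:
        if int(f.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
            raise SchemaError(f"unsupported corpus schema in {path}")
        manifest = json.loads(f.attrs["manifest"])
        out = []
        for name in ("train", "validation"):
            g = f[name]
            scenes = [Scene.from_dict(json.loads(s)) for s in g["scenes"].asstr()[()]]
            out.append(
                Corpus(X=g["X"][()], Y=g["Y"][()], scenes=scenes, seeds=g["seeds"][()])
            )
    return out[0], out[1], manifest


def save_model(path, model: MLPModel, extra_meta: dict | None = None) -> None:
    meta = {
        "schema_version": SCHEMA_VERSION,
        "layer_widths": list(model.spec.layer_widths),
        "seed": model.seed,
        "common_max_logamp": COMMON_MAX_LOGAMP,
        "common_min_phase": COMMON_MIN_PHASE,
        "input_layout": "logamp_then_phase",
        "output_layout": "real_then_imag",
        **(extra_meta or {}),
    }
    arrays = {f"W{i}": w for i, w in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> tuple[MLPModel, dict]:
    with np.load(path) as data:
        try:
            meta = json.loads(bytes(data["meta"]).decode())
        except Exception as exc:  # noqa: BLE001 - any parse failure is a schema error
            raise SchemaError(f"corrupt model artifact {path}") from exc
        if meta.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(f"unsupported model schema in {path}")
        widths = tuple(meta["layer_widths"])
        n_layers = len(widths) - 1
        weights = [data[f"W{i}"] for i in range(n_layers)]
        biases = [data[f"b{i}"] for i in range(n_layers)]
    model = MLPModel(
        spec=ModelSpec(layer_widths=widths),
        weights=weights,
        biases=biases,
        seed=int(meta.get("seed", 0)),
    )
    return model, meta
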