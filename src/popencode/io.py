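"""Dataset and model serialization.

Datasets live in a single HDF5 container (arrays + metadata, language
portable); model specs are JSON and fitted parameter vectors are ``.npy``
(explicitly little-endian, so round-trips are byte-stable across
platforms).  Score tables are CSV (written by the CLI).
"""

from __future__ import annotations

import json
import pathlib

import h5py
import numpy as np

from .frontend import Spectrogram, TrialRaster
from .models import ModelSpec, ParameterSet, build_network
from .synthetic import SyntheticDataset

__all__ = ["read_dataset", "write_dataset", "save_model", "load_model",
           "SCHEMA_VERSION"]

SCHEMA_VERSION = "popencode-dataset-1"


class SchemaError(ValueError):
    """Raised when a container does not match the expected schema."""


def _write_stim(group, stim: Spectrogram):
    group.create_dataset("values", data=stim.values)
    group.create_dataset("center_freqs", data=stim.center_freqs)
    group.create_dataset("seg_lens", data=stim.seg_lens)
    group.attrs["bin_size"] = stim.bin_size


def _read_stim(group) -> Spectrogram:
    return Spectrogram(group["values"][()], group["center_freqs"][()],
                       float(group.attrs["bin_size"]),
                       seg_lens=group["seg_lens"][()])


def write_dataset(dataset: SyntheticDataset, path):
    """Write a dataset container; the file is overwritten atomically."""
    _validate(dataset)
    path = pathlib.Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["meta"] = json.dumps(dataset.meta, default=str)
        for split, stim, resp in (("est", dataset.est_stim, dataset.est_resp),
                                  ("val", dataset.val_stim, dataset.val_resp)):
            _write_stim(f.create_group(f"stimulus/{split}"), stim)
            g = f.create_group(f"response/{split}")
            g.create_dataset("rates", data=resp.rates)
        f.create_dataset("response/neuron_ids",
                         data=np.asarray(dataset.neuron_ids, dtype="int64"))
        f.create_dataset("response/site_ids",
                         data=np.asarray(dataset.site_ids, dtype="int64"))


def read_dataset(path) -> SyntheticDataset:
    """Read a dataset container, validating schema and axis alignment."""
    path = pathlib.Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise SchemaError(f"cannot open {path}: not a valid container ({e})")
    with f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version mismatch: file has {version!r}, "
                f"reader expects {SCHEMA_VERSION!r}")
        try:
            neuron_ids = f["response/neuron_ids"][()]
            site_ids = f["response/site_ids"][()]
            parts = {}
            for split in ("est", "val"):
                stim = _read_stim(f[f"stimulus/{split}"])
                rates = f[f"response/{split}/rates"][()]
                parts[split] = (stim, TrialRaster(rates, stim.bin_size,
                                                  neuron_ids, site_ids))
            meta = json.loads(f.attrs.get("meta", "{}"))
        except KeyError as e:
            raise SchemaError(f"container missing group: {e}")
    ds = SyntheticDataset(parts["est"][0], parts["est"][1],
                          parts["val"][0], parts["val"][1], meta=meta)
    _validate(ds)
    return ds


def _validate(ds: SyntheticDataset):
    for split, stim, resp in (("est", ds.est_stim, ds.est_resp),
                              ("val", ds.val_stim, ds.val_resp)):
        if stim.T != resp.rates.shape[1]:
            raise SchemaError(
                f"time-axis mismatch in split {split!r}: stimulus has "
                f"{stim.T} bins, response has {resp.rates.shape[1]}")
    if len(set(np.asarray(ds.neuron_ids).tolist())) != ds.n_neurons:
        raise SchemaError("neuron_ids are not unique")


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def save_model(spec: ModelSpec, params: ParameterSet, path):
    """Write ``<path>.json`` (spec) and ``<path>.npy`` (parameter vector)."""
    net = build_network(spec)
    if len(params) != net.n_params:
        raise ValueError("parameter set does not match the model spec")
    path = pathlib.Path(path)
    path.with_suffix(".json").write_text(spec.to_json())
    vec = np.ascontiguousarray(params.vector, dtype="<f8")
    np.save(path.with_suffix(".npy"), vec)


def load_model(path):
    """Load a (ModelSpec, ParameterSet) pair written by :func:`save_model`.

    Raises ValueError if the parameter vector length does not match the
    spec (e.g. a hand-edited layer size)."""
    path = pathlib.Path(path)
    spec = ModelSpec.from_json(path.with_suffix(".json").read_text())
    vec = np.load(path.with_suffix(".npy")).astype(float)
    net = build_network(spec)
    if vec.size != net.n_params:
        raise ValueError(
            f"integrity error: spec implies {net.n_params} parameters "
            f"but the file holds {vec.size}")
    labels = [(i, name, v.shape) for i, name, v in net.param_items()]
    return spec, ParameterSet(vec, labels)
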