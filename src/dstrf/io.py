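"""HDF5 persistence for datasets, model checkpoints and DSTRF series."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .cascades import CascadeModel, LnParams, StpParams
from .cnn import CnnModel, CnnSpec
from .jacobian import DstrfSeries
from .stimulus import AuditorySpectrogram, DataSplit
from .strf import StrfWeights
from .synth import SyntheticDataset

__all__ = [
    "save_dataset",
    "load_split",
    "save_model",
    "load_model",
    "save_dstrf",
    "load_dstrf",
]


def save_dataset(path, dataset: SyntheticDataset) -> None:
    """Write a synthetic dataset (stimulus, responses, split) to HDF5."""
    with h5py.File(path, "w") as f:
        g = f.create_group("stimulus")
        d = g.create_dataset("spectrogram", data=dataset.spectrogram.values)
        d.attrs["frame_rate"] = dataset.spectrogram.frame_rate
        if dataset.spectrogram.center_freqs is not None:
            d.attrs["center_freqs"] = dataset.spectrogram.center_freqs
        r = f.create_group("response")
        r.create_dataset("trace", data=dataset.response)
        r.create_dataset("clean", data=dataset.clean)
        r.create_dataset("test_repeats", data=dataset.repeats)
        s = f.create_group("split")
        for name in ("train", "validation", "test"):
            s.attrs[name] = getattr(dataset.split, name)
        s.attrs["window_frames"] = dataset.split.window_frames
        f.attrs["neuron_kind"] = dataset.spec.kind
        f.attrs["noise_sd"] = dataset.spec.noise_sd
        f.attrs["seed"] = dataset.seed


def load_split(path) -> DataSplit:
    """Read the stimulus/response/split stored by :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        spec = f["stimulus/spectrogram"][()]
        response = f["response/trace"][()]
        repeats = f["response/test_repeats"][()] if "response/test_repeats" in f else None
        s = f["split"]
        return DataSplit(
            train=tuple(int(v) for v in s.attrs["train"]),
            validation=tuple(int(v) for v in s.attrs["validation"]),
            test=tuple(int(v) for v in s.attrs["test"]),
            spectrogram=spec,
            response=response,
            test_repeats=repeats,
            window_frames=int(s.attrs["window_frames"]),
        )


def save_model(path, model) -> None:
    """Checkpoint an encoding model (STRF, cascade or CNN)."""
    with h5py.File(path, "w") as f:
        if isinstance(model, StrfWeights):
            f.attrs["kind"] = "strf"
            f.create_dataset("W", data=model.W)
            f.attrs["bias"] = model.bias
            if model.penalty is not None:
                f.attrs["penalty"] = model.penalty
        elif isinstance(model, CascadeModel):
            f.attrs["kind"] = "stp" if model.stp is not None else "ln"
            g = f.create_group("ln")
            g.create_dataset("centers", data=model.ln.centers)
            g.create_dataset("widths", data=model.ln.widths)
            g.create_dataset("amps", data=model.ln.amps)
            g.create_dataset("fir", data=model.ln.fir)
            g.attrs["dexp"] = model.ln.dexp
            if model.stp is not None:
                g2 = f.create_group("stp")
                g2.create_dataset("u", data=model.stp.u)
                g2.create_dataset("tau", data=model.stp.tau)
                g2.attrs["d0"] = model.stp.d0
        elif isinstance(model, CnnModel):
            f.attrs["kind"] = "cnn"
            f.attrs["spec"] = json.dumps({
                "input_shape": list(model.spec.input_shape),
                "conv_channels": list(model.spec.conv_channels),
                "conv_kernel": model.spec.conv_kernel,
                "reduce_channels": list(model.spec.reduce_channels),
                "dense_hidden": model.spec.dense_hidden,
                "dropout_conv": model.spec.dropout_conv,
                "dropout_dense": model.spec.dropout_dense,
                "l2": model.spec.l2,
            })
            f.attrs["seed"] = model.seed
            for i, w in enumerate(model.get_weights()):
                f.create_dataset(f"weights/{i}", data=w)
        else:
            raise TypeError(f"cannot checkpoint {type(model).__name__}")


def load_model(path):
    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        if kind == "strf":
            return StrfWeights(W=f["W"][()], bias=float(f.attrs["bias"]),
                               penalty=float(f.attrs.get("penalty", np.nan)))
        if kind in ("ln", "stp"):
            g = f["ln"]
            ln = LnParams(centers=g["centers"][()], widths=g["widths"][()],
                          amps=g["amps"][()], fir=g["fir"][()],
                          dexp=tuple(g.attrs["dexp"]))
            stp = None
            if kind == "stp":
                g2 = f["stp"]
                stp = StpParams(u=g2["u"][()], tau=g2["tau"][()],
                                d0=float(g2.attrs["d0"]))
            return CascadeModel(ln=ln, stp=stp)
        if kind == "cnn":
            cfg = json.loads(f.attrs["spec"])
            spec = CnnSpec(
                input_shape=tuple(cfg["input_shape"]),
                conv_channels=tuple(cfg["conv_channels"]),
                conv_kernel=cfg["conv_kernel"],
                reduce_channels=tuple(cfg["reduce_channels"]),
                dense_hidden=cfg["dense_hidden"],
                dropout_conv=cfg["dropout_conv"],
                dropout_dense=cfg["dropout_dense"],
                l2=cfg["l2"],
            )
            model = CnnModel(spec, seed=int(f.attrs["seed"]))
            n = len(f["weights"])
            model.set_weights([f[f"weights/{i}"][()] for i in range(n)])
            return model
        raise ValueError(f"unknown checkpoint kind {kind!r}")


def save_dstrf(path, series: DstrfSeries, mask: np.ndarray | None = None,
               lag_convention: str = "lag 0 oldest, last lag current") -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("dstrf/values", data=series.values)
        d.attrs["model_id"] = series.model_id
        d.attrs["stimulus_id"] = series.stimulus_id
        d.attrs["lag_convention"] = lag_convention
        if mask is not None:
            f.create_dataset("dstrf/mask", data=mask.astype(bool))


def load_dstrf(path):
    with h5py.File(path, "r") as f:
        d = f["dstrf/values"]
        series = DstrfSeries(values=d[()], model_id=str(d.attrs.get("model_id", "")),
                             stimulus_id=str(d.attrs.get("stimulus_id", "")))
        mask = f["dstrf/mask"][()] if "dstrf/mask" in f else None
    return series, mask
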