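"""Readers and writers: photon HDF5 containers, CSV traces and curves.

Photon streams are stored in a Photon-HDF5-style layout: one
``photon_data_ch<i>`` group per channel holding a sorted ``timestamps``
dataset (seconds, float64), plus a ``setup`` group of acquisition metadata.
Binned streams are stored with a ``binned`` group (``counts`` dataset +
``bin_width`` attribute). CSV formats are plain headers:
``t_start_s,counts_ch0,counts_ch1`` for traces and ``lag_s,G,sd`` for
correlation curves (12 significant digits round-trip).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd

from .correlate import CorrelationCurve, IntensityTrace
from .simulate import PhotonStream

_EXPECTED = ("photon_data_ch<i>/timestamps (timestamp mode) or "
             "binned/counts + binned.attrs['bin_width'] (binned mode)")


def write_photon_h5(stream: PhotonStream, path: Union[str, Path],
                    **setup_attrs) -> None:
    """Write a photon stream to a Photon-HDF5-style container."""
    with h5py.File(path, "w") as f:
        setup = f.create_group("setup")
        setup.attrs["format"] = "fcskit-photon-h5"
        setup.attrs["duration"] = stream.duration
        for k, v in setup_attrs.items():
            setup.attrs[k] = v
        if stream.mode == "timestamps":
            for ch, ts in stream.timestamps.items():
                g = f.create_group(f"photon_data_ch{ch}")
                g.create_dataset("timestamps", data=np.asarray(ts, float))
        else:
            g = f.create_group("binned")
            g.create_dataset("counts", data=stream.counts)
            g.attrs["bin_width"] = stream.bin_width


def read_photon_h5(path: Union[str, Path]) -> PhotonStream:
    """Read a photon stream written by :func:`write_photon_h5`.

    Unsorted timestamps raise naming the first offending index; files
    without a recognizable layout raise listing the expected groups.
    """
    with h5py.File(path, "r") as f:
        meta = {}
        if "setup" in f:
            meta.update(dict(f["setup"].attrs))
        if "binned" in f:
            g = f["binned"]
            if "counts" not in g or "bin_width" not in g.attrs:
                raise ValueError(f"incomplete binned group; expected "
                                 f"{_EXPECTED}")
            return PhotonStream(counts=g["counts"][()],
                                bin_width=float(g.attrs["bin_width"]),
                                metadata=meta)
        channels = sorted(k for k in f if k.startswith("photon_data_ch"))
        if not channels:
            raise ValueError(
                f"unknown photon file schema in {path}; expected "
                f"{_EXPECTED}")
        ts = {}
        for name in channels:
            ch = int(name.removeprefix("photon_data_ch"))
            arr = f[name]["timestamps"][()]
            bad = np.nonzero(np.diff(arr) < 0)[0]
            if bad.size:
                raise ValueError(f"{name}: timestamps decrease at index "
                                 f"{bad[0] + 1}")
            ts[ch] = arr
        return PhotonStream(timestamps=ts, metadata=meta)


def write_trace_csv(trace: IntensityTrace, path: Union[str, Path]) -> None:
    """Write binned counts as ``t_start_s,counts_ch0,counts_ch1,...``."""
    n_ch = trace.n_channels
    header = "t_start_s," + ",".join(f"counts_ch{i}" for i in range(n_ch))
    t = np.arange(trace.n_bins) * trace.bin_width
    data = np.column_stack([t, trace.counts])
    fmt = ["%.12g"] + ["%d"] * n_ch
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt=fmt)


def read_trace_csv(path: Union[str, Path]) -> IntensityTrace:
    """Read a binned-counts CSV back into an IntensityTrace."""
    df = pd.read_csv(path)
    if "t_start_s" not in df.columns:
        raise ValueError("trace CSV must have a t_start_s column")
    ch_cols = [c for c in df.columns if c.startswith("counts_ch")]
    if not ch_cols:
        raise ValueError("trace CSV must have counts_ch<i> columns")
    t = df["t_start_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace CSV must have at least two bins")
    widths = np.diff(t)
    if np.any(np.abs(widths - widths[0]) > 1e-9 * widths[0]):
        raise ValueError("trace CSV bins are not uniform")
    counts = df[sorted(ch_cols)].to_numpy()
    if np.any(counts != np.round(counts)):
        raise ValueError("trace CSV counts must be integers")
    return IntensityTrace(counts.astype(np.int64), float(widths[0]))


def write_curve_csv(curve: CorrelationCurve, path: Union[str, Path]) -> None:
    """Write a correlation curve as ``lag_s,G[,sd]`` (12 significant digits)."""
    cols = {"lag_s": curve.lags, "G": curve.G}
    if curve.sd is not None:
        cols["sd"] = curve.sd
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.12g")


def read_curve_csv(path: Union[str, Path],
                   channel_pair=(0, 0)) -> CorrelationCurve:
    """Read a curve CSV; duplicate or non-monotone lags raise."""
    df = pd.read_csv(path)
    for col in ("lag_s", "G"):
        if col not in df.columns:
            raise ValueError(f"curve CSV missing column {col!r}")
    lags = df["lag_s"].to_numpy(float)
    if np.any(np.diff(lags) <= 0):
        raise ValueError("curve CSV lags must be strictly increasing "
                         "(duplicate or non-monotone lag found)")
    sd = df["sd"].to_numpy(float) if "sd" in df.columns else None
    return CorrelationCurve(lags, df["G"].to_numpy(float), sd=sd,
                            channel_pair=tuple(channel_pair))
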