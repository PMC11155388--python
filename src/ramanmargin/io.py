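"""File formats: HDF5 hypercubes, CSV spectra and labeled sets, JSON models.

HDF5 cube layout (all datasets at the file root):

* ``intensities`` — float64, rows × columns × bins
* ``axis_values`` — float64, bins (cm⁻¹)
* ``axis_coeffs`` — float64 polynomial pixel-map coefficients
* ``stage`` — string attribute on the file
* ``stage_log`` — JSON string dataset
* optional ``label_map`` (UTF-8 strings), ``qf_map``, ``included``,
  ``reasons`` when a scene / quality mask is attached
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .axis import WavenumberAxis
from .classify import BandClassifier
from .cube import HyperCube
from .quality import QualityMask
from .simulate import LabeledSpectrumSet

__all__ = [
    "write_cube", "read_cube", "write_mask", "read_mask",
    "write_spectrum_csv", "read_spectrum_csv",
    "write_labeled_set_csv", "read_labeled_set_csv",
    "write_model_json", "read_model_json",
    "FormatError",
]

_STR = h5py.string_dtype(encoding="utf-8")


class FormatError(RuntimeError):
    """A cube file is missing a required dataset."""


def write_cube(cube: HyperCube, path, *, label_map: np.ndarray | None = None,
               mask: QualityMask | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("intensities", data=cube.intensities)
        f.create_dataset("axis_values", data=cube.axis.values)
        f.create_dataset("axis_coeffs", data=cube.axis.pixel_map_coeffs)
        f.attrs["stage"] = cube.stage
        f.create_dataset("stage_log", data=json.dumps(cube.stage_log))
        if label_map is not None:
            f.create_dataset("label_map",
                             data=np.asarray(label_map, dtype=object), dtype=_STR)
        if mask is not None:
            _write_mask_group(f, mask)


def _write_mask_group(f, mask: QualityMask) -> None:
    f.create_dataset("qf_map", data=mask.qf_map)
    f.create_dataset("included", data=mask.included)
    f.create_dataset("reasons",
                     data=np.asarray(mask.reasons, dtype=object), dtype=_STR)
    f.attrs["qf_threshold"] = mask.threshold


def read_cube(path, *, with_label_map: bool = False, with_mask: bool = False):
    with h5py.File(path, "r") as f:
        for name in ("intensities", "axis_values", "axis_coeffs", "stage_log"):
            if name not in f:
                raise FormatError(f"cube file missing dataset {name!r}")
        if "stage" not in f.attrs:
            raise FormatError("cube file missing 'stage' attribute")
        axis = WavenumberAxis(f["axis_values"][:], pixel_map_coeffs=f["axis_coeffs"][:])
        cube = HyperCube(
            intensities=f["intensities"][:],
            axis=axis,
            stage=str(f.attrs["stage"]),
            stage_log=json.loads(f["stage_log"][()]),
        )
        out = [cube]
        if with_label_map:
            if "label_map" not in f:
                raise FormatError("cube file missing dataset 'label_map'")
            out.append(f["label_map"][:].astype(str).astype(object))
        if with_mask:
            out.append(_read_mask_group(f))
    return out[0] if len(out) == 1 else tuple(out)


def _read_mask_group(f) -> QualityMask:
    for name in ("qf_map", "included", "reasons"):
        if name not in f:
            raise FormatError(f"cube file missing dataset {name!r}")
    return QualityMask(
        qf_map=f["qf_map"][:],
        included=f["included"][:].astype(bool),
        reasons=f["reasons"][:].astype(str).astype(object),
        threshold=float(f.attrs.get("qf_threshold", 0.5)),
    )


def write_mask(mask: QualityMask, path) -> None:
    with h5py.File(path, "w") as f:
        _write_mask_group(f, mask)


def read_mask(path) -> QualityMask:
    with h5py.File(path, "r") as f:
        return _read_mask_group(f)


# -- single spectra and labeled sets (CSV) ------------------------------

def write_spectrum_csv(wavenumbers: np.ndarray, intensities: np.ndarray, path) -> None:
    pd.DataFrame({"wavenumber": wavenumbers, "intensity": intensities}).to_csv(
        path, index=False)


def read_spectrum_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["wavenumber"].to_numpy(), df["intensity"].to_numpy()


def write_labeled_set_csv(train: LabeledSpectrumSet, path) -> None:
    """Wide format: one row per spectrum, label column + one column per bin."""
    cols = [f"wn_{v:.2f}" for v in train.axis.values]
    df = pd.DataFrame(train.spectra, columns=cols)
    df.insert(0, "label", train.labels)
    df.to_csv(path, index=False)


def read_labeled_set_csv(path) -> LabeledSpectrumSet:
    df = pd.read_csv(path)
    labels = df["label"].to_numpy(dtype=object)
    wn = np.array([float(c[3:]) for c in df.columns if c.startswith("wn_")])
    spectra = df[[c for c in df.columns if c.startswith("wn_")]].to_numpy(float)
    return LabeledSpectrumSet(spectra, labels, WavenumberAxis(wn))


# -- classifier models (JSON) -------------------------------------------

def write_model_json(model: BandClassifier, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def read_model_json(path) -> BandClassifier:
    with open(path) as fh:
        return BandClassifier.from_dict(json.load(fh))
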