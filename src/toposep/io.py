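"""Reading continuous recordings and round-tripping epoch fixtures.

BrainVision support covers the subset produced by common recorder setups:
multiplexed binary data in IEEE float32 or signed int16 with per-channel
resolution, plus ``Stimulus`` markers from the ``.vmrk`` file.  Marker
positions are 1-based on disk and converted to 0-based sample indices.

Epoch fixtures use a single HDF5 container with an explicit schema version
so float payloads round-trip losslessly.
"""

from __future__ import annotations

import configparser
import os
from typing import Optional

import h5py
import numpy as np

from .containers import ContinuousRecording, EpochSet
from .montage import Montage, standard_montage

__all__ = [
    "load_brainvision",
    "write_epochs",
    "read_epochs",
    "UnsupportedDialectError",
    "EpochContainerError",
]

EPOCH_MAGIC = "toposep-epochs"
EPOCH_SCHEMA_VERSION = 1


class UnsupportedDialectError(ValueError):
    """BrainVision layout outside the supported multiplexed subset."""


class EpochContainerError(ValueError):
    """Epoch fixture file is not readable as a toposep container."""


def _read_ini(path) -> configparser.ConfigParser:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    except UnicodeDecodeError:
        with open(path, "r", encoding="latin-1") as fh:
            text = fh.read()
    # drop the identification preamble before the first section header
    lines = text.splitlines()
    start = next((i for i, l in enumerate(lines) if l.startswith("[")), 0)
    cp = configparser.ConfigParser(strict=False, interpolation=None)
    cp.optionxform = str
    cp.read_string("\n".join(lines[start:]))
    return cp


def load_brainvision(header_path, montage: Optional[Montage] = None) -> ContinuousRecording:
    """Load a BrainVision ``.vhdr``/``.vmrk``/``.eeg`` triplet.

    Parameters
    ----------
    header_path : path to the ``.vhdr`` file
    montage : optional Montage; when omitted, channel labels are resolved
        against the standard 10-10 electrode table.

    Returns data in microvolts (per-channel resolution applied) with
    ``Stimulus`` markers as 0-based ``(sample, description)`` events.
    """
    header_path = os.fspath(header_path)
    if not os.path.exists(header_path):
        raise FileNotFoundError(f"header file not found: {header_path}")
    hdr = _read_ini(header_path)
    common = hdr["Common Infos"]
    base = os.path.dirname(header_path)

    data_file = os.path.join(base, common["DataFile"])
    marker_file = os.path.join(base, common["MarkerFile"]) if "MarkerFile" in common else None
    if not os.path.exists(data_file):
        raise FileNotFoundError(f"data file referenced by header not found: {data_file}")
    if marker_file is not None and not os.path.exists(marker_file):
        raise FileNotFoundError(f"marker file referenced by header not found: {marker_file}")

    fmt = common.get("DataFormat", "BINARY").upper()
    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if fmt != "BINARY":
        raise UnsupportedDialectError(f"unsupported DataFormat {fmt!r} (only BINARY)")
    if orientation != "MULTIPLEXED":
        raise UnsupportedDialectError(
            f"unsupported DataOrientation {orientation!r} (only MULTIPLEXED)"
        )
    binfmt = hdr["Binary Infos"]["BinaryFormat"].upper()
    if binfmt == "IEEE_FLOAT_32":
        dtype = np.dtype("<f4")
    elif binfmt == "INT_16":
        dtype = np.dtype("<i2")
    else:
        raise UnsupportedDialectError(
            f"unsupported BinaryFormat {binfmt!r} (only IEEE_FLOAT_32 / INT_16)"
        )

    n_channels = int(common["NumberOfChannels"])
    # SamplingInterval is in microseconds
    sampling_rate = 1e6 / float(common["SamplingInterval"])

    labels, resolutions = [], []
    ch = hdr["Channel Infos"]
    for i in range(1, n_channels + 1):
        parts = ch[f"Ch{i}"].split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] != "" else "1"
        resolutions.append(float(res))
    resolutions = np.array(resolutions, dtype=float)

    raw = np.fromfile(data_file, dtype=dtype)
    if raw.size % n_channels:
        raise UnsupportedDialectError(
            f"data file size not a multiple of {n_channels} channels"
        )
    data = raw.reshape(-1, n_channels).T.astype(float)
    data *= resolutions[:, None]

    events: list[tuple[int, str]] = []
    if marker_file is not None:
        mrk = _read_ini(marker_file)
        if "Marker Infos" in mrk:
            for key, val in mrk["Marker Infos"].items():
                if not key.startswith("Mk"):
                    continue
                parts = val.split(",")
                if len(parts) < 3 or parts[0] != "Stimulus":
                    continue
                events.append((int(parts[2]) - 1, parts[1]))
    events.sort(key=lambda e: e[0])

    if montage is None:
        try:
            montage = standard_montage(tuple(labels))
        except KeyError as exc:
            raise KeyError(
                f"cannot resolve channel positions automatically ({exc}); "
                "pass an explicit montage"
            ) from exc
    reference = common.get("Reference", None)
    return ContinuousRecording(
        data=data,
        sampling_rate=sampling_rate,
        events=events,
        montage=montage,
        reference_label=reference,
    )


# --------------------------------------------------------------- fixtures

def write_epochs(epochs: EpochSet, path) -> None:
    """Write an EpochSet to the single-file HDF5 fixture container."""
    with h5py.File(path, "w") as f:
        f.attrs["magic"] = EPOCH_MAGIC
        f.attrs["schema_version"] = EPOCH_SCHEMA_VERSION
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["condition_frequency"] = epochs.condition[0]
        f.attrs["condition_location"] = epochs.condition[1]
        f.attrs["baseline_corrected"] = bool(epochs.baseline_corrected)
        f.attrs["reference"] = epochs.reference
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time", data=epochs.time)
        f.create_dataset("kept_mask", data=epochs.kept_mask)
        g = f.create_group("montage")
        g.create_dataset(
            "labels", data=np.array(epochs.montage.labels, dtype=h5py.string_dtype())
        )
        g.create_dataset("theta", data=epochs.montage.theta)
        g.create_dataset("phi", data=epochs.montage.phi)


def read_epochs(path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs`."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise EpochContainerError(f"not a readable epoch container: {path} ({exc})")
    with f:
        if f.attrs.get("magic") != EPOCH_MAGIC:
            raise EpochContainerError(f"{path} is not a toposep epoch container")
        version = int(f.attrs.get("schema_version", -1))
        if version != EPOCH_SCHEMA_VERSION:
            raise EpochContainerError(
                f"epoch container schema version {version} not supported "
                f"(expected {EPOCH_SCHEMA_VERSION})"
            )
        labels = tuple(s.decode() if isinstance(s, bytes) else str(s)
                       for s in f["montage/labels"][()])
        montage = Montage(labels, f["montage/theta"][()], f["montage/phi"][()])
        data = f["data"][()]
        if data.size == 0:
            data = data.reshape(0, len(labels), f["time"].shape[0])
        return EpochSet(
            data=data,
            time=f["time"][()],
            montage=montage,
            subject_id=str(f.attrs["subject_id"]),
            condition=(str(f.attrs["condition_frequency"]),
                       str(f.attrs["condition_location"])),
            kept_mask=f["kept_mask"][()].astype(bool),
            baseline_corrected=bool(f.attrs["baseline_corrected"]),
            reference=str(f.attrs["reference"]),
        )
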