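"""On-disk formats: HDF5 epoch container, NIfTI volumes, TSV tables.

The epoch container layout is::

    /data           (trials, channels, time) float64
    /time           (time,) seconds
    /labels         (trials,) UTF-8 condition strings
    /sensors/pos    (channels, 3) m
    /sensors/ori    (channels, 3)
    /sensors/names  (channels,) UTF-8
    attrs: sfreq

Volumetric images are written as NIfTI-1 with a millimetre RAS affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from samface.containers import EpochSet, GridSpec, SensorArray, VolumetricImage

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_image_nifti",
    "load_image_nifti",
    "epochs_from_fif",
    "save_json",
]


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` to the HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("time", data=epochs.time)
        f.create_dataset("labels", data=np.array(epochs.labels, dtype=object),
                         dtype=h5py.string_dtype("utf-8"))
        f.attrs["sfreq"] = epochs.sfreq
        if epochs.sensors is not None:
            g = f.create_group("sensors")
            g.create_dataset("pos", data=epochs.sensors.pos)
            g.create_dataset("ori", data=epochs.sensors.ori)
            g.create_dataset("names", data=np.array(epochs.sensors.names, dtype=object),
                             dtype=h5py.string_dtype("utf-8"))


def load_epochs(path: str | Path) -> EpochSet:
    """Read an :class:`EpochSet` from the HDF5 container."""
    with h5py.File(path, "r") as f:
        sensors = None
        if "sensors" in f:
            g = f["sensors"]
            sensors = SensorArray(
                pos=g["pos"][()],
                ori=g["ori"][()],
                names=[n.decode() if isinstance(n, bytes) else str(n) for n in g["names"][()]],
            )
        labels = np.array(
            [v.decode() if isinstance(v, bytes) else str(v) for v in f["labels"][()]]
        )
        return EpochSet(
            data=f["data"][()],
            sfreq=float(f.attrs["sfreq"]),
            time=f["time"][()],
            labels=labels,
            sensors=sensors,
        )


def save_image_nifti(image: VolumetricImage, path: str | Path) -> None:
    """Write a volumetric statistic image as NIfTI-1 (mm RAS affine)."""
    import nibabel as nib

    img = nib.Nifti1Image(image.values.astype(np.float32), image.grid.affine())
    img.header["descrip"] = image.semantics.encode()[:79]
    nib.save(img, str(path))


def load_image_nifti(path: str | Path, semantics: str = "power") -> VolumetricImage:
    """Read a NIfTI volume back into a :class:`VolumetricImage`."""
    import nibabel as nib

    img = nib.load(str(path))
    vals = np.asarray(img.get_fdata(), dtype=float)
    aff = img.affine
    spacing = float(aff[0, 0]) / 1000.0
    origin = aff[:3, 3] / 1000.0
    mask = np.isfinite(vals)
    grid = GridSpec(origin=origin, spacing=spacing, shape=vals.shape, mask=mask)
    vals = np.where(mask, vals, np.nan)
    return VolumetricImage(grid=grid, values=vals, semantics=semantics)


def epochs_from_fif(path: str | Path, face_event: int = 1, scrambled_event: int = 2) -> EpochSet:
    """Import epoched data from a FIF file (requires the optional mne extra).

    Magnetometer/gradiometer channels are taken as-is with their positions
    and orientations; events mapped to the two condition labels.
    """
    import mne  # optional dependency

    epo = mne.read_epochs(str(path), preload=True, verbose="error")
    picks = mne.pick_types(epo.info, meg=True)
    data = epo.get_data(picks=picks)
    chs = [epo.info["chs"][p] for p in picks]
    pos = np.array([c["loc"][:3] for c in chs])
    ori = np.array([c["loc"][9:12] for c in chs])
    norms = np.linalg.norm(ori, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    ori = ori / norms
    names = [c["ch_name"] for c in chs]
    ev = epo.events[:, 2]
    labels = np.where(ev == face_event, "face", np.where(ev == scrambled_event, "scrambled", "other"))
    return EpochSet(
        data=data,
        sfreq=float(epo.info["sfreq"]),
        time=epo.times.copy(),
        labels=labels,
        sensors=SensorArray(pos=pos, ori=ori, names=names),
    )


def save_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
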