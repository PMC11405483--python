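"""Multi-channel 3D voxel stacks and their on-disk formats.

A :class:`VoxelStack` holds one 3D intensity volume per named channel,
together with the physical voxel spacing.  Arrays use the (z, y, x) axis
order conventional for confocal z-stacks; physical positions are reported
as (x, y, z) vectors in micrometres, with x = column index * dx and so on.

Two container formats are supported:

* HDF5 — self-describing: one dataset per channel under the group
  ``channels/``, with ``voxel_size`` (dz, dy, dx, µm) and ``bit_depth``
  stored as root attributes.  This layout is this package's own; it is
  documented here and round-trips exactly.
* multi-page TIFF — a 4D ``CZYX`` (or 3D ``ZYX``) array.  Channel names
  come from the caller's channel map; voxel size is read from ImageJ-style
  metadata when present, otherwise it must be supplied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .errors import ChannelError, MetadataError

#: canonical channel names used throughout the pipeline
CANONICAL_CHANNELS = ("dna", "euchromatin", "heterochromatin", "edu", "wall")


@dataclass
class VoxelStack:
    """Named-channel 3D intensity volumes with physical voxel spacing.

    Parameters
    ----------
    channels
        Mapping of channel name to a 3D ``(z, y, x)`` array.
    voxel_size
        ``(dz, dy, dx)`` spacing in µm; all entries must be positive.
    bit_depth
        Intensity ceiling (e.g. 65535 for 16-bit acquisitions).
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    bit_depth: int = 65535

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack needs at least one channel")
        shapes = {ch: np.asarray(v).shape for ch, v in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 3 for s in shapes.values()):
            raise ValueError("all channels must be 3D (z, y, x)")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel size must be three positive values, got {self.voxel_size}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        for name, vol in self.channels.items():
            arr = np.asarray(vol)
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} has negative intensities")
            if arr.max() > self.bit_depth:
                raise ValueError(
                    f"channel {name!r} exceeds the bit-depth ceiling {self.bit_depth}")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ChannelError(
                f"channel {name!r} not in stack (have {sorted(self.channels)})"
            ) from None

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise ChannelError(f"missing channels {missing} (have {sorted(self.channels)})")


def write_stack(stack: VoxelStack, path: str | Path) -> Path:
    """Write a stack to HDF5 (``.h5``/``.hdf5``) or TIFF (``.tif``/``.tiff``)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.attrs["voxel_size"] = np.asarray(stack.voxel_size, dtype=float)
            f.attrs["bit_depth"] = int(stack.bit_depth)
            grp = f.create_group("channels")
            for name, vol in stack.channels.items():
                grp.create_dataset(name, data=vol, compression="gzip", compression_opts=1)
    elif suffix in (".tif", ".tiff"):
        names = sorted(stack.channels)
        data = np.stack([stack.channels[n] for n in names])  # CZYX
        dz, dy, dx = stack.voxel_size
        tifffile.imwrite(
            path,
            data.astype(np.float32),
            imagej=False,
            metadata={"axes": "CZYX", "channel_names": names, "voxel_size_zyx_um": [dz, dy, dx]},
        )
    else:
        raise ValueError(f"unsupported stack format {suffix!r}")
    return path


def read_stack(
    path: str | Path,
    channel_map: dict[str, int | str] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
    bit_depth: int | None = None,
) -> VoxelStack:
    """Read a multi-channel stack from HDF5 or TIFF.

    Parameters
    ----------
    channel_map
        Renames/selects channels.  For HDF5 the values are source dataset
        names (or integer indices into the sorted dataset list); for TIFF
        they are channel-axis indices.  ``None`` keeps the stored names
        (HDF5) or names TIFF channels ``ch0``, ``ch1``, ...
    voxel_size
        Overrides (dz, dy, dx) metadata; required for files that carry none.

    Raises
    ------
    ChannelError
        A requested channel name/index does not exist in the file.
    MetadataError
        No voxel size in the file and no override given.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "channels" not in f:
                raise MetadataError(f"{path}: no 'channels' group")
            grp = f["channels"]
            stored = sorted(grp.keys())
            if channel_map is None:
                channels = {n: grp[n][()] for n in stored}
            else:
                channels = {}
                for name, src in channel_map.items():
                    key = stored[src] if isinstance(src, int) and 0 <= src < len(stored) else src
                    if not isinstance(key, str) or key not in grp:
                        raise ChannelError(f"{path}: source channel {src!r} for {name!r} not found")
                    channels[name] = grp[key][()]
            vs = voxel_size or (tuple(f.attrs["voxel_size"]) if "voxel_size" in f.attrs else None)
            bd = bit_depth or int(f.attrs.get("bit_depth", 65535))
    elif suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if data.ndim == 3:
            data = data[None]
        if data.ndim != 4:
            raise MetadataError(f"{path}: expected 3D or 4D TIFF, got shape {data.shape}")
        n_ch = data.shape[0]
        stored_names = list(meta.get("channel_names", [f"ch{i}" for i in range(n_ch)]))
        if channel_map is None:
            channels = {stored_names[i]: data[i] for i in range(n_ch)}
        else:
            channels = {}
            for name, idx in channel_map.items():
                if isinstance(idx, str):
                    if idx not in stored_names:
                        raise ChannelError(f"{path}: channel {idx!r} not in {stored_names}")
                    idx = stored_names.index(idx)
                if not 0 <= idx < n_ch:
                    raise ChannelError(f"{path}: channel index {idx} out of range (n={n_ch})")
                channels[name] = data[idx]
        vs_meta = meta.get("voxel_size_zyx_um")
        vs = voxel_size or (tuple(vs_meta) if vs_meta is not None else None)
        bd = bit_depth or 65535
    else:
        raise ValueError(f"unsupported stack format {suffix!r}")
    if vs is None:
        raise MetadataError(f"{path}: no voxel size metadata; pass voxel_size explicitly")
    return VoxelStack(channels=channels, voxel_size=tuple(vs), bit_depth=bd)


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer label volume as TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels).astype(np.int32))
    return path


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))
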