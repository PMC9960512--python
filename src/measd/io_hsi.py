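"""Hyperspectral cube and label I/O.

A cube is held in memory as an ``N x L`` matrix of pixel spectra (``N``
pixels, ``L`` bands), regardless of the on-disk layout.  3-D rasters
(rows x cols x bands) are flattened row-major, and any label raster is
flattened in the identical order so pixel ``i`` always matches label ``i``.

Supported containers: ENVI (text ``.hdr`` plus raw binary, BSQ/BIL/BIP
interleaves), MATLAB ``.mat`` (classic via :mod:`scipy.io`, v7.3 via
:mod:`h5py`), NumPy ``.npz``, and plain CSV (one pixel per row).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np


class DataError(ValueError):
    """Raised when an input file or array cannot be interpreted as a cube."""


# ENVI "data type" codes <-> numpy dtypes (the subset used for reflectance data)
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
}
_DTYPE_TO_ENVI = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class SpectralCube:
    """An ``N x L`` matrix of pixel spectra with optional band metadata.

    Parameters
    ----------
    data
        Real matrix, shape ``(N, L)``; promoted to floating point.
    wavelengths
        Optional length-``L`` band-center wavelengths in nm.
    band_names
        Optional length-``L`` band labels.
    """

    data: np.ndarray
    wavelengths: np.ndarray | None = None
    band_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise DataError(f"cube data must be 2-D (N x L), got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        n, l = self.data.shape
        if n < 1 or l < 2:
            raise DataError(f"need N >= 1 pixels and L >= 2 bands, got N={n}, L={l}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("cube contains NaN/Inf; clean upstream or load with impute_nan=True")
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths.shape != (l,):
                raise DataError("wavelengths length must equal the number of bands")
        if self.band_names is not None and len(self.band_names) != l:
            raise DataError("band_names length must equal the number of bands")

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0]

    @property
    def n_bands(self) -> int:
        return self.data.shape[1]


@dataclass
class LabelData:
    """Per-pixel supervision: integer class ids or real regression targets.

    For classification rasters, id 0 conventionally marks unlabeled
    background; ids are remapped to a contiguous range on construction
    (background stays 0).
    """

    kind: str  # "classification" | "regression"
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.kind not in ("classification", "regression"):
            raise DataError(f"unknown label kind {self.kind!r}")
        self.values = np.asarray(self.values).ravel()
        if self.kind == "classification":
            vals = self.values.astype(np.int64)
            if vals.min(initial=0) < 0:
                raise DataError("classification ids must be >= 0")
            uniq = np.unique(vals)
            remap = {int(v): i for i, v in enumerate(uniq)}
            if 0 in remap:  # keep background at 0
                self.values = np.array([remap[int(v)] for v in vals])
            else:
                self.values = np.array([remap[int(v)] + 1 for v in vals]) - 1
        else:
            self.values = self.values.astype(np.float64)


def _flatten_raster(arr: np.ndarray) -> np.ndarray:
    """Flatten a (rows, cols, bands) raster to (N, L), row-major."""
    if arr.ndim == 3:
        return arr.reshape(-1, arr.shape[2])
    if arr.ndim == 2:
        return arr
    raise DataError(f"expected a 2-D or 3-D array, got ndim={arr.ndim}")


def _pick_array(
    mapping: dict[str, np.ndarray],
    key: str | None,
    what: str,
    ndims: tuple[int, ...] = (2, 3),
) -> np.ndarray:
    if key is not None:
        if key not in mapping:
            raise DataError(f"key {key!r} not found in {what}; available: {sorted(mapping)}")
        return np.asarray(mapping[key])
    candidates = {
        k: np.asarray(v)
        for k, v in mapping.items()
        if not k.startswith("__") and np.asarray(v).ndim in ndims
    }
    if len(candidates) != 1:
        raise DataError(
            f"ambiguous {what}: found {len(candidates)} candidate arrays "
            f"({sorted(candidates)}); pass key=<name>"
        )
    return next(iter(candidates.values()))


def _parse_envi_header(hdr_path: Path) -> dict[str, Any]:
    text = hdr_path.read_text()
    fields: dict[str, Any] = {}
    # key = value lines; brace-enclosed values may span lines
    buf = text.replace("\r\n", "\n")
    i = 0
    lines = buf.split("\n")
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{"):
            while "}" not in val and i < len(lines):
                val += " " + lines[i].strip()
                i += 1
            val = val.strip("{} ").strip()
        fields[key] = val
    return fields


def read_envi(path: str | Path, impute_nan: bool = False) -> SpectralCube:
    """Read an ENVI header+raw pair; ``path`` may point to either file."""
    path = Path(path)
    if path.suffix.lower() == ".hdr":
        hdr_path = path
        raw_path = path.with_suffix("")
        if not raw_path.exists():
            for ext in (".img", ".dat", ".raw", ".bsq", ".bil", ".bip"):
                if path.with_suffix(ext).exists():
                    raw_path = path.with_suffix(ext)
                    break
    else:
        raw_path = path
        hdr_path = path.with_suffix(path.suffix + ".hdr")
        if not hdr_path.exists():
            hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise DataError(f"no ENVI header found for {path}")
    hdr = _parse_envi_header(hdr_path)
    try:
        samples = int(hdr["samples"])
        lines_ = int(hdr["lines"])
        bands = int(hdr["bands"])
        dtype_code = int(hdr["data type"])
    except KeyError as exc:
        raise DataError(f"ENVI header missing field {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise DataError(f"unsupported ENVI data type code {dtype_code}")
    interleave = hdr.get("interleave", "bsq").lower()
    offset = int(hdr.get("header offset", 0))
    byte_order = int(hdr.get("byte order", 0))
    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("<" if byte_order == 0 else ">")
    raw = np.fromfile(raw_path, dtype=dtype, offset=offset, count=samples * lines_ * bands)
    if raw.size != samples * lines_ * bands:
        raise DataError(f"ENVI raw file {raw_path} is truncated")
    if interleave == "bsq":
        cube = raw.reshape(bands, lines_, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines_, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines_, samples, bands)
    else:
        raise DataError(f"unknown ENVI interleave {interleave!r}")
    wavelengths = None
    if "wavelength" in hdr:
        try:
            wavelengths = np.array([float(w) for w in hdr["wavelength"].split(",")])
        except ValueError:
            wavelengths = None
    data = _maybe_impute(_flatten_raster(cube).astype(np.float64), impute_nan)
    return SpectralCube(data, wavelengths=wavelengths)


def write_envi(
    cube: SpectralCube,
    path: str | Path,
    shape: tuple[int, int] | None = None,
    interleave: str = "bsq",
) -> None:
    """Write a cube as an ENVI raw file plus ``<path>.hdr``.

    ``shape`` gives the (rows, cols) raster layout; defaults to ``(N, 1)``.
    """
    path = Path(path)
    n, l = cube.data.shape
    rows, cols = shape if shape is not None else (n, 1)
    if rows * cols != n:
        raise DataError(f"shape {rows}x{cols} does not hold {n} pixels")
    raster = cube.data.reshape(rows, cols, l)
    interleave = interleave.lower()
    if interleave == "bsq":
        arr = raster.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = raster.transpose(0, 2, 1)
    elif interleave == "bip":
        arr = raster
    else:
        raise DataError(f"unknown ENVI interleave {interleave!r}")
    arr = np.ascontiguousarray(arr, dtype="<f8")
    arr.tofile(path)
    hdr = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {l}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_TO_ENVI[np.dtype('f8')]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if cube.wavelengths is not None:
        hdr.append("wavelength = {" + ", ".join(f"{w:g}" for w in cube.wavelengths) + "}")
    Path(str(path) + ".hdr").write_text("\n".join(hdr) + "\n")


def _maybe_impute(data: np.ndarray, impute_nan: bool) -> np.ndarray:
    if np.isinf(data).any():
        raise DataError("cube contains infinite values")
    if np.isnan(data).any():
        if not impute_nan:
            raise DataError("cube contains NaN; pass impute_nan=True to mean-impute per band")
        data = data.copy()
        means = np.nanmean(data, axis=0)
        idx = np.where(np.isnan(data))
        data[idx] = np.take(means, idx[1])
        if np.isnan(data).any():
            raise DataError("a band is entirely NaN; cannot impute")
    return data


def load_cube(
    path: str | Path,
    format: str | None = None,
    key: str | None = None,
    impute_nan: bool = False,
    header: bool = False,
    delimiter: str = ",",
) -> SpectralCube:
    """Load a hyperspectral cube from disk.

    Parameters
    ----------
    path
        File to read.
    format
        One of ``envi``, ``matlab``, ``npz``, ``csv``; inferred from the
        extension when omitted.
    key
        Variable/array name for ``matlab``/``npz`` containers; required if
        the container holds more than one 2-D/3-D array.
    impute_nan
        Replace NaN entries by the per-band mean instead of rejecting.
    header
        For CSV, whether the first row is a header line.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {
            ".hdr": "envi", ".img": "envi", ".dat": "envi", ".raw": "envi",
            ".bsq": "envi", ".bil": "envi", ".bip": "envi",
            ".mat": "matlab", ".npz": "npz", ".npy": "npz",
            ".csv": "csv", ".tsv": "csv", ".txt": "csv",
        }.get(suffix)
        if format is None:
            raise DataError(f"cannot infer format from extension {suffix!r}; pass format=")
    format = format.lower()
    if format == "envi":
        return read_envi(path, impute_nan=impute_nan)
    if format == "matlab":
        try:
            from scipy.io import loadmat

            mat = loadmat(path)
            arr = _pick_array(mat, key, f"MAT file {path.name}")
        except NotImplementedError:  # MATLAB v7.3 is HDF5-based
            import h5py

            with h5py.File(path, "r") as f:
                mapping = {k: np.asarray(f[k]) for k in f.keys()}
            arr = _pick_array(mapping, key, f"MAT v7.3 file {path.name}")
            arr = arr.T  # HDF5 stores MATLAB arrays transposed
    elif format == "npz":
        loaded = np.load(path)
        if isinstance(loaded, np.ndarray):
            arr = loaded
        else:
            arr = _pick_array({k: loaded[k] for k in loaded.files}, key, f"NPZ {path.name}")
    elif format == "csv":
        import pandas as pd

        df = pd.read_csv(path, header=0 if header else None, sep=delimiter)
        arr = df.to_numpy()
    else:
        raise DataError(f"unknown format {format!r}")
    if not np.issubdtype(np.asarray(arr).dtype, np.number):
        raise DataError(f"non-numeric data in {path}")
    data = _maybe_impute(_flatten_raster(np.asarray(arr)).astype(np.float64), impute_nan)
    return SpectralCube(data)


def load_labels(path: str | Path, kind: str, key: str | None = None) -> LabelData:
    """Load a label raster/vector (CSV or NPZ); flattened row-major like the cube."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if path.suffix.lower() == ".npz":
        loaded = np.load(path)
        arr = _pick_array(
            {k: loaded[k] for k in loaded.files}, key, f"NPZ {path.name}", ndims=(1, 2, 3)
        )
    else:
        import pandas as pd

        arr = pd.read_csv(path, header=None).to_numpy()
    return LabelData(kind=kind, values=np.asarray(arr).ravel())


def save_band_subsets(subsets: Sequence[Any], path: str | Path) -> None:
    """Write selected band subsets to CSV (default) or JSON, by extension.

    One row/record per subset, ordered by descending fitness, carrying both
    0-based and 1-based band indices so outputs can be compared against
    either indexing convention without ambiguity.
    """
    if len(subsets) == 0:
        raise DataError("no band subsets to save")
    path = Path(path)
    ordered = sorted(subsets, key=lambda s: -_subset_fitness(s))
    rows = []
    for rank, s in enumerate(ordered, start=1):
        bands = sorted(int(b) for b in _subset_bands(s))
        rows.append(
            {
                "rank": rank,
                "fitness": _subset_fitness(s),
                "bands_0based": " ".join(str(b) for b in bands),
                "bands_1based": " ".join(str(b + 1) for b in bands),
            }
        )
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    else:
        import pandas as pd

        pd.DataFrame(rows).to_csv(path, index=False)


def load_band_subsets(path: str | Path) -> list[dict[str, Any]]:
    """Read back a subset file written by :func:`save_band_subsets`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        import pandas as pd

        rows = pd.read_csv(path).to_dict("records")
    for row in rows:
        row["bands"] = [int(b) for b in str(row["bands_0based"]).split()]
    return rows


def _subset_bands(s: Any) -> Iterable[int]:
    return s["bands"] if isinstance(s, dict) else s.bands


def _subset_fitness(s: Any) -> float:
    f = s["fitness"] if isinstance(s, dict) else s.fitness
    return float(f) if f is not None else float("-inf")
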