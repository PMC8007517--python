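"""MSI data I/O: imzML read/write, ion-image materialization, tabular artifacts.

The imzML support here is a compact, self-contained implementation of the
continuous- and processed-mode flavours of the format (XML index file plus an
``.ibd`` binary companion holding the actual arrays). Processed-mode spectra
are binned onto a common m/z axis at load time with a greedy gap rule.
"""

from __future__ import annotations

import hashlib
import uuid
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, FormatError, ParameterError, ValidationError

# CV accessions used by the imzML reader/writer
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F32 = "MS:1000521"
_ACC_F64 = "MS:1000523"
_ACC_CONTINUOUS = "IMS:1000030"
_ACC_PROCESSED = "IMS:1000031"
_ACC_PIXEL_X = "IMS:1000050"
_ACC_PIXEL_Y = "IMS:1000051"
_ACC_PIXEL_SIZE_X = "IMS:1000046"
_ACC_UUID = "IMS:1000080"
_ACC_EXTERNAL = "IMS:1000101"
_ACC_EXT_OFFSET = "IMS:1000102"
_ACC_EXT_LENGTH = "IMS:1000103"
_ACC_EXT_ENCODED = "IMS:1000104"

_MZML_NS = "http://psi.hupo.org/ms/mzml"


@dataclass
class MSIDataset:
    """A rectangular-grid MSI experiment on a common m/z axis.

    Attributes
    ----------
    coords : (n_pixels, 2) int array
        0-based ``(x, y)`` grid positions, one per pixel, all unique.
    mz_axis : (n_channels,) float array
        Strictly increasing m/z values in Da.
    intensities : (n_pixels, n_channels) float array
        Non-negative intensities aligned to ``mz_axis``.
    pixel_size_um : float
        Physical pixel pitch in micrometers.
    meta : dict
        Free-form provenance strings.
    """

    coords: np.ndarray
    mz_axis: np.ndarray
    intensities: np.ndarray
    pixel_size_um: float = 50.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=int)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be an (n, 2) array of (x, y) positions")
        if self.mz_axis.ndim != 1 or np.any(np.diff(self.mz_axis) <= 0):
            raise ValidationError("mz_axis must be 1-D and strictly increasing")
        if self.intensities.shape != (len(self.coords), len(self.mz_axis)):
            raise ValidationError("intensities must be (n_pixels, n_channels)")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        uniq = {tuple(c) for c in self.coords}
        if len(uniq) != len(self.coords):
            raise ValidationError("duplicate pixel coordinates")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def n_channels(self) -> int:
        return len(self.mz_axis)

    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) of the bounding grid; row 0 corresponds to min y."""
        xs, ys = self.coords[:, 0], self.coords[:, 1]
        return int(ys.max() - ys.min() + 1), int(xs.max() - xs.min() + 1)


@dataclass
class IonImage:
    """One 2-D intensity map for a single m/z bin.

    ``pixels`` is rows x cols with row 0 at the smallest y; ``mask`` marks
    acquired pixels. Pixels outside the mask are forced to zero.
    """

    pixels: np.ndarray
    mz: float
    pixel_size_um: float
    mask: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.shape != self.mask.shape:
            raise ValidationError("pixels and mask shapes differ")
        if np.any(self.pixels[~self.mask] != 0):
            self.pixels = np.where(self.mask, self.pixels, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def ion_image(dataset: MSIDataset, mz: float, tol: float | None = None) -> IonImage:
    """Materialize the ion image for one mass bin.

    Pixel values are the sum of intensities of all axis entries within
    ``tol`` Da of ``mz``. ``tol`` defaults to half the median axis spacing
    (or 0 for a single-channel axis). Unacquired grid positions are masked.
    """
    if tol is None:
        spacings = np.diff(dataset.mz_axis)
        tol = float(np.median(spacings) / 2) if len(spacings) else 0.0
    if tol < 0:
        raise ParameterError("tol must be >= 0")
    sel = np.abs(dataset.mz_axis - mz) <= tol
    if not sel.any():
        raise EmptySelectionError(f"no m/z axis entry within {tol} Da of {mz}")
    values = dataset.intensities[:, sel].sum(axis=1)

    xs, ys = dataset.coords[:, 0], dataset.coords[:, 1]
    rows = ys - ys.min()
    cols = xs - xs.min()
    shape = dataset.grid_shape()
    pixels = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    pixels[rows, cols] = values
    mask[rows, cols] = True
    return IonImage(pixels=pixels, mz=float(mz), pixel_size_um=dataset.pixel_size_um, mask=mask)


def ion_images(dataset: MSIDataset) -> list[IonImage]:
    """One ion image per axis channel (tol=0 selection, vectorized)."""
    xs, ys = dataset.coords[:, 0], dataset.coords[:, 1]
    rows = ys - ys.min()
    cols = xs - xs.min()
    shape = dataset.grid_shape()
    mask = np.zeros(shape, dtype=bool)
    mask[rows, cols] = True
    out = []
    for k, mz in enumerate(dataset.mz_axis):
        pixels = np.zeros(shape)
        pixels[rows, cols] = dataset.intensities[:, k]
        out.append(IonImage(pixels=pixels, mz=float(mz),
                            pixel_size_um=dataset.pixel_size_um, mask=mask))
    return out


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------

def greedy_bin(sorted_mzs: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Greedy left-to-right binning of sorted m/z values.

    A gap greater than ``tol`` between consecutive values starts a new bin.
    Returns (bin centers = mean of members, per-value bin index).
    """
    sorted_mzs = np.asarray(sorted_mzs, dtype=float)
    if len(sorted_mzs) == 0:
        return np.empty(0), np.empty(0, dtype=int)
    gaps = np.diff(sorted_mzs) > tol
    idx = np.concatenate([[0], np.cumsum(gaps)])
    centers = np.array([sorted_mzs[idx == b].mean() for b in range(idx[-1] + 1)])
    return centers, idx


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, str]:
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("accession", "")] = child.get("value", "")
    return out


def _ibd_path(path: Path) -> Path:
    for suffix in (".ibd", ".IBD"):
        cand = path.with_suffix(suffix)
        if cand.exists():
            return cand
    return path.with_suffix(".ibd")


_DTYPES = {_ACC_F32: np.float32, _ACC_F64: np.float64,
           "MS:1000519": np.int32, "MS:1000522": np.int64}


def read_imzml(path, bin_tol: float = 0.01) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    Continuous-mode data keeps its common axis; processed-mode peak lists are
    binned with :func:`greedy_bin` at ``bin_tol`` Da.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ibd = _ibd_path(path)
    if not ibd.exists():
        raise FileNotFoundError(f"missing ibd companion for {path}")
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"not a valid imzML file: {exc}") from exc
    root = tree.getroot()

    mode = None
    pixel_size = None
    groups: dict[str, dict[str, str]] = {}
    for elem in root.iter():
        tag = _local(elem.tag)
        if tag == "fileContent":
            params = _cv_params(elem)
            if _ACC_CONTINUOUS in params:
                mode = "continuous"
            elif _ACC_PROCESSED in params:
                mode = "processed"
        elif tag == "referenceableParamGroup":
            groups[elem.get("id", "")] = _cv_params(elem)
        elif tag == "scanSettings":
            params = _cv_params(elem)
            if _ACC_PIXEL_SIZE_X in params:
                pixel_size = float(params[_ACC_PIXEL_SIZE_X])
    if mode is None:
        raise FormatError("fileContent declares neither continuous nor processed mode")

    blob = ibd.read_bytes()

    coords = []
    spectra = []  # (mz array, intensity array)
    for spectrum in root.iter():
        if _local(spectrum.tag) != "spectrum":
            continue
        x = y = None
        arrays: dict[str, np.ndarray] = {}
        for elem in spectrum.iter():
            tag = _local(elem.tag)
            if tag == "scan":
                params = _cv_params(elem)
                if _ACC_PIXEL_X in params:
                    x = int(params[_ACC_PIXEL_X])
                if _ACC_PIXEL_Y in params:
                    y = int(params[_ACC_PIXEL_Y])
            elif tag == "binaryDataArray":
                params = _cv_params(elem)
                for child in elem:
                    if _local(child.tag) == "referenceableParamGroupRef":
                        params = {**groups.get(child.get("ref", ""), {}), **params}
                kind = ("mz" if _ACC_MZ_ARRAY in params
                        else "intensity" if _ACC_INT_ARRAY in params else None)
                dtype = next((d for a, d in _DTYPES.items() if a in params), None)
                if kind is None or dtype is None:
                    raise FormatError("binaryDataArray missing array-type or data-type cvParam")
                offset = int(params[_ACC_EXT_OFFSET])
                length = int(params[_ACC_EXT_LENGTH])
                nbytes = length * np.dtype(dtype).itemsize
                if offset + nbytes > len(blob):
                    raise FormatError("external array extends past end of ibd file")
                arrays[kind] = np.frombuffer(blob, dtype=dtype, count=length,
                                             offset=offset).astype(float)
        if x is None or y is None or "mz" not in arrays or "intensity" not in arrays:
            raise FormatError("spectrum missing position or data arrays")
        coords.append((x - 1, y - 1))  # imzML positions are 1-based
        spectra.append((arrays["mz"], arrays["intensity"]))

    if not spectra:
        raise FormatError("imzML file contains no spectra")

    meta = {"source": str(path), "mode": mode}
    if mode == "continuous":
        axis = spectra[0][0]
        n = len(axis)
        if any(len(mz) != n or len(ints) != n for mz, ints in spectra):
            raise FormatError("inconsistent spectrum lengths in continuous mode")
        intensities = np.vstack([ints for _, ints in spectra])
    else:
        all_mzs, all_pix, all_int = [], [], []
        for pix, (mzs, ints) in enumerate(spectra):
            all_mzs.append(mzs)
            all_int.append(ints)
            all_pix.append(np.full(len(mzs), pix))
        flat_mz = np.concatenate(all_mzs)
        flat_int = np.concatenate(all_int)
        flat_pix = np.concatenate(all_pix)
        order = np.argsort(flat_mz, kind="stable")
        axis, bin_idx = greedy_bin(flat_mz[order], bin_tol)
        intensities = np.zeros((len(spectra), len(axis)))
        np.add.at(intensities, (flat_pix[order], bin_idx), flat_int[order])
        meta["bin_tol"] = repr(bin_tol)

    return MSIDataset(coords=np.array(coords), mz_axis=axis, intensities=intensities,
                      pixel_size_um=pixel_size if pixel_size else 1.0, meta=meta)


def _sub(parent, tag, **attrs):
    return ET.SubElement(parent, tag, {k: str(v) for k, v in attrs.items()})


def _cv(parent, accession, name, value=None):
    attrs = {"cvRef": accession.split(":")[0], "accession": accession, "name": name}
    if value is not None:
        attrs["value"] = str(value)
    return ET.SubElement(parent, "cvParam", attrs)


def write_imzml(dataset: MSIDataset, path, mode: str = "continuous") -> Path:
    """Write an imzML/ibd pair. Processed mode stores per-pixel nonzero peaks."""
    if mode not in ("continuous", "processed"):
        raise ParameterError("mode must be 'continuous' or 'processed'")
    if mode == "processed":
        peak_lists = []
        for row in dataset.intensities:
            nz = np.nonzero(row)[0]
            peak_lists.append((dataset.mz_axis[nz], row[nz]))
        return write_imzml_peaks(dataset.coords, peak_lists, path,
                                 pixel_size_um=dataset.pixel_size_um)

    path, ibd_path = _imzml_paths(path)
    digest = hashlib.md5(dataset.intensities.astype(np.float32).tobytes()
                         + dataset.mz_axis.tobytes()).digest()
    file_uuid = uuid.UUID(bytes=digest)

    chunks = [file_uuid.bytes]
    offset = 16
    records = []  # per spectrum: (mz_offset, mz_len, int_offset, int_len, n)
    mz_bytes = dataset.mz_axis.astype(np.float64).tobytes()
    mz_offset, mz_len = offset, len(dataset.mz_axis)
    chunks.append(mz_bytes)
    offset += len(mz_bytes)
    for row in dataset.intensities:
        data = row.astype(np.float32).tobytes()
        records.append((mz_offset, mz_len, offset, len(row), len(row)))
        chunks.append(data)
        offset += len(data)
    ibd_path.write_bytes(b"".join(chunks))
    _write_imzml_xml(path, dataset.coords, records, "continuous", file_uuid,
                     dataset.pixel_size_um)
    return path


def write_imzml_peaks(coords, peak_lists, path, pixel_size_um: float = 50.0) -> Path:
    """Write processed-mode imzML from explicit per-pixel (mz, intensity) lists."""
    path, ibd_path = _imzml_paths(path)
    coords = np.asarray(coords, dtype=int)
    if len(coords) != len(peak_lists):
        raise ParameterError("one peak list per coordinate required")
    hasher = hashlib.md5()
    for mzs, ints in peak_lists:
        hasher.update(np.asarray(mzs, dtype=np.float64).tobytes())
        hasher.update(np.asarray(ints, dtype=np.float32).tobytes())
    file_uuid = uuid.UUID(bytes=hasher.digest())

    chunks = [file_uuid.bytes]
    offset = 16
    records = []
    for mzs, ints in peak_lists:
        mzs = np.asarray(mzs, dtype=np.float64)
        ints = np.asarray(ints, dtype=np.float32)
        if len(mzs) != len(ints):
            raise ParameterError("peak list m/z and intensity lengths differ")
        records.append((offset, len(mzs), offset + mzs.nbytes, len(ints), len(mzs)))
        chunks.append(mzs.tobytes())
        chunks.append(ints.tobytes())
        offset += mzs.nbytes + ints.nbytes
    ibd_path.write_bytes(b"".join(chunks))
    _write_imzml_xml(path, coords, records, "processed", file_uuid, pixel_size_um)
    return path


def _imzml_paths(path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix.lower() != ".imzml":
        path = path.with_suffix(".imzML")
    return path, path.with_suffix(".ibd")


def _write_imzml_xml(path, coords, records, mode, file_uuid, pixel_size_um):
    root = ET.Element("mzML", {"xmlns": _MZML_NS, "version": "1.1"})
    fdesc = _sub(root, "fileDescription")
    fcontent = _sub(fdesc, "fileContent")
    if mode == "continuous":
        _cv(fcontent, _ACC_CONTINUOUS, "continuous")
    else:
        _cv(fcontent, _ACC_PROCESSED, "processed")
    _cv(fcontent, _ACC_UUID, "universally unique identifier", f"{{{file_uuid}}}")

    rpgl = _sub(root, "referenceableParamGroupList", count=2)
    mz_group = _sub(rpgl, "referenceableParamGroup", id="mzArray")
    _cv(mz_group, _ACC_MZ_ARRAY, "m/z array")
    _cv(mz_group, _ACC_F64, "64-bit float")
    _cv(mz_group, _ACC_EXTERNAL, "external data", "true")
    int_group = _sub(rpgl, "referenceableParamGroup", id="intensityArray")
    _cv(int_group, _ACC_INT_ARRAY, "intensity array")
    _cv(int_group, _ACC_F32, "32-bit float")
    _cv(int_group, _ACC_EXTERNAL, "external data", "true")

    ssl = _sub(root, "scanSettingsList", count=1)
    ss = _sub(ssl, "scanSettings", id="scanSettings1")
    _cv(ss, "IMS:1000042", "max count of pixels x", int(coords[:, 0].max()) + 1)
    _cv(ss, "IMS:1000043", "max count of pixels y", int(coords[:, 1].max()) + 1)
    _cv(ss, _ACC_PIXEL_SIZE_X, "pixel size (x)", pixel_size_um)

    run = _sub(root, "run", id="run1")
    slist = _sub(run, "spectrumList", count=len(coords), defaultDataProcessingRef="dp1")
    for i, ((x, y), rec) in enumerate(zip(coords, records)):
        mz_off, mz_len, int_off, int_len, n = rec
        spec = _sub(slist, "spectrum", id=f"spectrum={i + 1}", index=i, defaultArrayLength=n)
        scan_list = _sub(spec, "scanList", count=1)
        scan = _sub(scan_list, "scan")
        _cv(scan, _ACC_PIXEL_X, "position x", int(x) + 1)
        _cv(scan, _ACC_PIXEL_Y, "position y", int(y) + 1)
        bdal = _sub(spec, "binaryDataArrayList", count=2)
        for group, off, length, itemsize in (("mzArray", mz_off, mz_len, 8),
                                             ("intensityArray", int_off, int_len, 4)):
            bda = _sub(bdal, "binaryDataArray", encodedLength=0)
            _sub(bda, "referenceableParamGroupRef", ref=group)
            _cv(bda, _ACC_EXT_OFFSET, "external offset", off)
            _cv(bda, _ACC_EXT_LENGTH, "external array length", length)
            _cv(bda, _ACC_EXT_ENCODED, "external encoded length", length * itemsize)
            _sub(bda, "binary")
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Tabular artifacts
# ---------------------------------------------------------------------------

def write_assignments(labels: Sequence[int], mzs: Sequence[float], path) -> Path:
    """Write cluster assignments as CSV with header ``mz,cluster``."""
    labels = np.asarray(labels, dtype=int)
    mzs = np.asarray(mzs, dtype=float)
    if len(labels) != len(mzs):
        raise ParameterError("labels and mzs must have equal length")
    pd.DataFrame({"mz": mzs, "cluster": labels}).to_csv(path, index=False)
    return Path(path)


def read_assignments(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ``mz,cluster`` CSV; returns (mzs, labels)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalize parse failures
        raise FormatError(f"cannot parse assignments file: {exc}") from exc
    if list(df.columns) != ["mz", "cluster"]:
        raise FormatError(f"expected header 'mz,cluster', found {list(df.columns)}")
    if df["mz"].duplicated().any():
        raise FormatError("duplicate m/z rows in assignments file")
    return df["mz"].to_numpy(dtype=float), df["cluster"].to_numpy(dtype=int)


def write_vectors(vectors: np.ndarray, mzs: Sequence[float],
                  provenance: Sequence[str], path) -> Path:
    """Store an (n_images, D) embedding matrix plus m/z list and provenance."""
    import h5py

    try:
        vectors = np.asarray(vectors, dtype=np.float64)
    except ValueError as exc:
        raise ParameterError(f"vectors must form a 2-D matrix: {exc}") from exc
    if vectors.ndim != 2:
        raise ParameterError("vectors must form a 2-D matrix (ragged input?)")
    mzs = np.asarray(mzs, dtype=float)
    if len(mzs) != vectors.shape[0]:
        raise ParameterError("one m/z per vector required")
    with h5py.File(path, "w") as f:
        f.create_dataset("vectors", data=vectors)
        f.create_dataset("mz", data=mzs)
        f.create_dataset("provenance", data=np.array(list(provenance), dtype=object),
                         dtype=h5py.string_dtype("utf-8"))
    return Path(path)


def read_vectors(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    import h5py

    with h5py.File(path, "r") as f:
        for key in ("vectors", "mz"):
            if key not in f:
                raise FormatError(f"vectors bundle missing '{key}' dataset")
        vectors = f["vectors"][()]
        mzs = f["mz"][()]
        provenance = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in f.get("provenance", [])]
    return vectors, mzs, provenance
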