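"""Data containers for reflectance spectra and hyperspectral cubes.

Two containers are shared by every stage of the pipeline:

``SpectrumSet``
    A samples x wavelengths reflectance matrix with its wavelength axis,
    optional class labels and sample identifiers.  Round-trips losslessly
    through CSV (wavelengths as the header row).

``HyperCube``
    A rows x cols x bands reflectance cube with an optional ground-truth
    label image, serialised as an ENVI text header plus raw BIL binary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectrumSet", "HyperCube"]


def _check_wavelengths(wl: np.ndarray) -> np.ndarray:
    wl = np.asarray(wl, dtype=float)
    if wl.ndim != 1:
        raise ValueError("wavelengths must be a 1-D vector")
    if not np.all(np.isfinite(wl)):
        raise ValueError("wavelengths must be finite")
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    return wl


@dataclass
class SpectrumSet:
    """Reflectance spectra of a set of samples on a common wavelength grid.

    Parameters
    ----------
    wavelengths_nm : (n,) array
        Strictly increasing wavelength axis in nanometres.
    spectra : (m, n) array
        One reflectance spectrum per row.
    labels : (m,) array of str, optional
        Class label per sample (e.g. ``"beef"``).
    sample_ids : (m,) array of str, optional
        Stable identifiers, generated as ``s0000...`` when omitted.
    """

    wavelengths_nm: np.ndarray
    spectra: np.ndarray
    labels: np.ndarray | None = None
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = _check_wavelengths(self.wavelengths_nm)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if self.spectra.shape[1] != self.wavelengths_nm.size:
            raise ValueError(
                f"spectra have {self.spectra.shape[1]} columns but "
                f"{self.wavelengths_nm.size} wavelengths were given"
            )
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("reflectance values must be finite")
        m = self.spectra.shape[0]
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (m,):
                raise ValueError("labels length must match sample count")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:04d}" for i in range(m)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if self.sample_ids.shape != (m,):
                raise ValueError("sample_ids length must match sample count")

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.spectra.shape[1]

    def select(self, rows) -> "SpectrumSet":
        """Return the subset of samples at integer positions ``rows``."""
        rows = np.asarray(rows)
        return SpectrumSet(
            self.wavelengths_nm.copy(),
            self.spectra[rows],
            None if self.labels is None else self.labels[rows],
            self.sample_ids[rows],
        )

    def with_spectra(self, spectra, wavelengths_nm=None) -> "SpectrumSet":
        """Same samples, new spectral matrix (and optionally new grid)."""
        wl = self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm
        return SpectrumSet(wl, spectra, self.labels, self.sample_ids)

    # -- CSV interchange -----------------------------------------------------
    def to_csv(self, path) -> None:
        """Write ``sample_id,label,<wl0>,<wl1>,...`` with lossless floats."""
        df = pd.DataFrame(self.spectra,
                          columns=[repr(float(w)) for w in self.wavelengths_nm])
        df.insert(0, "label", self.labels if self.labels is not None else "")
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectrumSet":
        df = pd.read_csv(path, dtype={"sample_id": str, "label": str})
        if list(df.columns[:2]) != ["sample_id", "label"]:
            raise ValueError("expected 'sample_id,label,<wavelengths...>' header")
        wl = np.array([float(c) for c in df.columns[2:]])
        labels = df["label"].to_numpy()
        if all(pd.isna(v) or v == "" for v in labels):
            labels = None
        return cls(wl, df.iloc[:, 2:].to_numpy(float), labels, df["sample_id"].to_numpy())


@dataclass
class HyperCube:
    """A rows x cols x bands reflectance cube, optionally with ground truth.

    ``truth_map`` holds per-pixel class ids indexing into ``class_order``;
    ``truth_proportions`` is the per-class pixel fraction of the truth map.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    truth_map: np.ndarray | None = None
    truth_proportions: np.ndarray | None = None
    class_order: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        self.wavelengths_nm = _check_wavelengths(self.wavelengths_nm)
        if self.data.shape[2] != self.wavelengths_nm.size:
            raise ValueError("band count must match wavelength count")
        if self.truth_map is not None:
            self.truth_map = np.asarray(self.truth_map, dtype=int)
            if self.truth_map.shape != self.data.shape[:2]:
                raise ValueError("truth_map shape must match cube spatial shape")
        if self.truth_proportions is not None:
            self.truth_proportions = np.asarray(self.truth_proportions, dtype=float)
            if not np.isclose(self.truth_proportions.sum(), 1.0):
                raise ValueError("truth_proportions must sum to 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def pixels(self) -> SpectrumSet:
        """Flatten to a SpectrumSet (row-major pixel order)."""
        r, c, b = self.data.shape
        labels = None
        if self.truth_map is not None and self.class_order is not None:
            labels = np.asarray(self.class_order)[self.truth_map.ravel()]
        return SpectrumSet(self.wavelengths_nm, self.data.reshape(r * c, b), labels)

    # -- ENVI interchange ----------------------------------------------------
    def to_envi(self, path_stem) -> tuple[Path, Path]:
        """Write ``<stem>.hdr`` + ``<stem>.raw`` (BIL, float32, little-endian).

        The truth map, when present, is written alongside as
        ``<stem>_truth.hdr/.raw`` (single-band int16 BSQ).
        """
        stem = Path(path_stem)
        rows, cols, bands = self.data.shape
        hdr = stem.with_suffix(".hdr")
        raw = stem.with_suffix(".raw")
        wl = ", ".join(f"{w:.6f}" for w in self.wavelengths_nm)
        lines = [
            "ENVI",
            "description = {spectransfer synthetic cube}",
            f"samples = {cols}",
            f"lines = {rows}",
            f"bands = {bands}",
            "header offset = 0",
            "file type = ENVI Standard",
            "data type = 4",
            "interleave = bil",
            "byte order = 0",
            "wavelength units = Nanometers",
            "wavelength = {" + wl + "}",
        ]
        if self.class_order is not None:
            lines.append("class names = {" + ", ".join(self.class_order) + "}")
        hdr.write_text("\n".join(lines) + "\n")
        # BIL: line-interleaved -> (lines, bands, samples)
        np.ascontiguousarray(
            self.data.transpose(0, 2, 1).astype("<f4")
        ).tofile(raw)
        if self.truth_map is not None:
            thdr = stem.parent / (stem.name + "_truth.hdr")
            traw = stem.parent / (stem.name + "_truth.raw")
            thdr.write_text(
                "\n".join(
                    [
                        "ENVI",
                        f"samples = {cols}",
                        f"lines = {rows}",
                        "bands = 1",
                        "header offset = 0",
                        "data type = 2",
                        "interleave = bsq",
                        "byte order = 0",
                    ]
                )
                + "\n"
            )
            self.truth_map.astype("<i2").tofile(traw)
        return hdr, raw

    @classmethod
    def from_envi(cls, hdr_path) -> "HyperCube":
        hdr_path = Path(hdr_path)
        fields = _parse_envi_header(hdr_path.read_text())
        rows, cols, bands = (int(fields[k]) for k in ("lines", "samples", "bands"))
        dtype = {"2": "<i2", "4": "<f4", "5": "<f8"}[fields["data type"].strip()]
        raw_path = hdr_path.with_suffix(".raw")
        arr = np.fromfile(raw_path, dtype=dtype)
        interleave = fields.get("interleave", "bil").strip().lower()
        if interleave == "bil":
            cube = arr.reshape(rows, bands, cols).transpose(0, 2, 1)
        elif interleave == "bsq":
            cube = arr.reshape(bands, rows, cols).transpose(1, 2, 0)
        elif interleave == "bip":
            cube = arr.reshape(rows, cols, bands)
        else:
            raise ValueError(f"unsupported interleave {interleave!r}")
        if "wavelength" in fields:
            wl = np.array([float(v) for v in fields["wavelength"].split(",")])
        else:
            wl = np.arange(bands, dtype=float)
        class_order = None
        if "class names" in fields:
            class_order = [s.strip() for s in fields["class names"].split(",")]
        truth = None
        thdr = hdr_path.parent / (hdr_path.stem + "_truth.hdr")
        if thdr.exists():
            tcube = cls.from_envi(thdr)
            truth = tcube.data[:, :, 0].astype(int)
        props = None
        if truth is not None:
            counts = np.bincount(truth.ravel())
            props = counts / counts.sum()
        return cls(cube.astype(float), wl, truth, props, class_order)


def _parse_envi_header(text: str) -> dict[str, str]:
    """Parse 'key = value' ENVI header lines; {...} values may span lines."""
    fields: dict[str, str] = {}
    # collapse multi-line brace groups
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        value = value.strip()
        if value.startswith("{") and value.endswith("}"):
            value = value[1:-1].strip()
        fields[key.strip().lower()] = value
    return fields
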