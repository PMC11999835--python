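"""Pixel-wise adulteration mapping of hyperspectral cubes.

Every pixel spectrum of a slave-instrument cube is (optionally) passed
through a fitted calibration transfer, classified by a master-trained
classifier, and painted by species.  Class pixel fractions give the
predicted adulteration proportions, compared against the cube's ground
truth when available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import median_filter

from .datasets import HyperCube

__all__ = ["LabelMap", "ProportionReport", "classify_cube", "proportions",
           "render_map", "load_map", "DEFAULT_PALETTE"]

# Fig-style species colours: chicken yellow, beef blue, duck green
DEFAULT_PALETTE = {
    "chicken": (255, 215, 0),
    "beef": (0, 0, 255),
    "duck": (0, 160, 0),
}
_FALLBACK_COLOURS = [
    (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
]


@dataclass
class LabelMap:
    """Per-pixel class-id image with its class order and palette."""

    labels: np.ndarray
    class_order: list[str]
    palette: dict | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        if self.labels.min() < 0 or self.labels.max() >= len(self.class_order):
            raise ValueError("label ids must index class_order")
        if self.palette is None:
            self.palette = {}
        for i, name in enumerate(self.class_order):
            self.palette.setdefault(
                name,
                DEFAULT_PALETTE.get(name, _FALLBACK_COLOURS[i % len(_FALLBACK_COLOURS)]),
            )

    def smoothed(self, size: int = 3) -> "LabelMap":
        """Majority (median) filtered copy; off the default path."""
        return LabelMap(median_filter(self.labels, size=size),
                        self.class_order, dict(self.palette))


@dataclass
class ProportionReport:
    """Per-class predicted pixel fractions versus ground truth."""

    table: pd.DataFrame  # columns: class, predicted_fraction[, truth_fraction, abs_deviation]

    @property
    def mean_abs_deviation(self) -> float:
        if "abs_deviation" not in self.table:
            raise ValueError("no ground truth available")
        return float(self.table["abs_deviation"].mean())

    def summary(self) -> str:
        return self.table.to_string(index=False)


def classify_cube(cube: HyperCube, transfer, classifier, grid_nm=None) -> LabelMap:
    """Classify every pixel of a slave cube, optionally after transfer.

    ``transfer`` is a fitted transfer Results object (or None to classify
    the raw slave spectra); ``classifier`` is a fitted classifier Results
    object exposing ``predict``.  ``grid_nm`` names the wavelength grid the
    models were fitted on; it defaults to the transfer's stored grid, and
    the cube is interpolated onto it when they differ.
    """
    rows, cols, bands = cube.shape
    X = cube.data.reshape(rows * cols, bands)
    grid = np.asarray(grid_nm, dtype=float) if grid_nm is not None else (
        getattr(transfer, "grid_nm", None)
    )
    if grid is not None and (grid.size != bands or not np.allclose(grid, cube.wavelengths_nm)):
        if grid[0] < cube.wavelengths_nm[0] - 1e-9 or grid[-1] > cube.wavelengths_nm[-1] + 1e-9:
            raise ValueError(
                "cube wavelength coverage is insufficient for the transfer grid"
            )
        X = np.vstack([np.interp(grid, cube.wavelengths_nm, row) for row in X])
    if transfer is not None:
        X = transfer.transform(X)
    pred = classifier.predict(X)
    class_order = [str(c) for c in classifier.class_order]
    codes = np.searchsorted(class_order, pred.astype(str))
    return LabelMap(codes.reshape(rows, cols), class_order)


def proportions(label_map: LabelMap, truth: HyperCube | None = None) -> ProportionReport:
    """Class pixel fractions of a label map, with deviations vs ground truth."""
    counts = np.bincount(label_map.labels.ravel(),
                         minlength=len(label_map.class_order))
    frac = counts / counts.sum()
    df = pd.DataFrame({"class": label_map.class_order, "predicted_fraction": frac})
    if truth is not None and truth.truth_proportions is not None:
        order = truth.class_order or label_map.class_order
        truth_by_class = dict(zip(order, truth.truth_proportions))
        df["truth_fraction"] = [truth_by_class[c] for c in label_map.class_order]
        df["abs_deviation"] = (df["predicted_fraction"] - df["truth_fraction"]).abs()
    return ProportionReport(df)


def render_map(label_map: LabelMap, out_path) -> Path:
    """Write an indexed-colour PNG plus a ``.legend.txt`` sidecar."""
    out_path = Path(out_path)
    img = Image.fromarray(label_map.labels.astype(np.uint8), mode="P")
    palette = []
    for name in label_map.class_order:
        palette.extend(label_map.palette[name])
    img.putpalette(palette)
    img.save(out_path, format="PNG")
    legend = out_path.with_suffix(out_path.suffix + ".legend.txt")
    legend.write_text(
        "\n".join(
            f"{i}\t{name}\trgb{label_map.palette[name]}"
            for i, name in enumerate(label_map.class_order)
        )
        + "\n"
    )
    return out_path


def load_map(png_path, class_order: list[str]) -> LabelMap:
    """Recover a LabelMap from an indexed PNG written by :func:`render_map`."""
    img = Image.open(png_path)
    return LabelMap(np.asarray(img, dtype=int), list(class_order))
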