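"""Centroided MSI datasets: imzML read/write and ppm-windowed ion images.

A dataset is a list of sections (tissue cross-sections acquired on one slide),
each carrying a per-pixel centroided spectrum and a genotype group label
(``WT`` or ``MUT``). Ion images are extracted with a relative m/z tolerance
(default ±3 ppm) and no normalization — raw centroid intensities feed the
downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("glyconodule")

__all__ = [
    "Section",
    "MsiDataset",
    "IonImage",
    "load_dataset",
    "save_dataset",
    "extract_ion_image",
    "section_intensity_vector",
    "ion_image_to_csv",
    "ion_image_to_png",
]

GroupLabel = Literal["WT", "MUT"]
_VALID_GROUPS = ("WT", "MUT")


class MsiFormatError(ValueError):
    """Raised for unusable imzML inputs (continuous mode, missing labels)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Section:
    """One tissue section: occupied pixel coordinates plus centroid lists.

    ``coords`` are 0-based (x, y) pixel positions, row-major ordering is the
    stable pixel order used by :func:`section_intensity_vector`. ``spectra``
    holds one ``(mz, intensity)`` pair of 1-D arrays per occupied pixel, with
    strictly increasing m/z.
    """

    label: str
    group: GroupLabel
    width: int
    height: int
    coords: np.ndarray  # (n_pixels, 2) int
    spectra: list[tuple[np.ndarray, np.ndarray]]
    _flat: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.group not in _VALID_GROUPS:
            raise MsiFormatError(
                f"section {self.label!r}: group must be WT or MUT, got {self.group!r}"
            )
        self.coords = np.asarray(self.coords, dtype=int)
        if len(self.coords) != len(self.spectra):
            raise ValueError("coords and spectra length mismatch")
        order = np.lexsort((self.coords[:, 0], self.coords[:, 1]))
        if not np.array_equal(order, np.arange(len(order))):
            self.coords = self.coords[order]
            self.spectra = [self.spectra[i] for i in order]
        for mz, inten in self.spectra:
            if len(mz) != len(inten):
                raise ValueError("mz and intensity arrays differ in length")
            if len(mz) > 1 and not np.all(np.diff(mz) > 0):
                raise ValueError("m/z arrays must be strictly increasing")
            if len(inten) and np.any(np.asarray(inten) < 0):
                raise ValueError("negative intensity")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def flattened(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All centroids concatenated and sorted by m/z.

        Returns ``(mz, intensity, pixel_index)``; cached because every ion
        image extraction reuses it.
        """
        if self._flat is None:
            if self.n_pixels == 0:
                empty = np.array([])
                self._flat = (empty, empty, empty.astype(int))
            else:
                mzs = np.concatenate([s[0] for s in self.spectra])
                ints = np.concatenate([s[1] for s in self.spectra])
                idx = np.concatenate(
                    [np.full(len(s[0]), i, dtype=int) for i, s in enumerate(self.spectra)]
                )
                order = np.argsort(mzs, kind="stable")
                self._flat = (mzs[order], ints[order], idx[order])
        return self._flat


@dataclass
class MsiDataset:
    """Multi-section centroided MSI dataset with shared acquisition settings."""

    sections: list[Section]
    polarity: Literal["positive", "negative"] = "positive"
    mz_range: tuple[float, float] = (1000.0, 5000.0)
    pixel_pitch_um: float = 50.0

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")

    def section(self, label: str) -> Section:
        for s in self.sections:
            if s.label == label:
                return s
        raise KeyError(f"unknown section {label!r}")

    def sections_in_group(self, group: GroupLabel) -> list[Section]:
        return [s for s in self.sections if s.group == group]

    @property
    def section_labels(self) -> list[str]:
        return [s.label for s in self.sections]


@dataclass
class IonImage:
    """2-D intensity map of one ppm-window around a center m/z."""

    values: np.ndarray
    center_mz: float
    tol_ppm: float
    reducer: Literal["sum", "max"] = "sum"

    @property
    def half_width(self) -> float:
        return self.center_mz * self.tol_ppm * 1e-6


# ---------------------------------------------------------------------------
# imzML round trip (processed mode via pyimzml)
# ---------------------------------------------------------------------------

def save_dataset(dataset: MsiDataset, out_dir: str | Path) -> pd.DataFrame:
    """Write one processed-mode imzML/ibd pair per section plus a manifest.

    The manifest CSV (``manifest.csv``: file, label, group) is what
    :func:`load_dataset` consumes. Pixel coordinates are converted to the
    1-based convention of imzML.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sec in dataset.sections:
        fname = f"{sec.label}.imzML"
        with ImzMLWriter(
            str(out_dir / fname), polarity=dataset.polarity, mode="processed"
        ) as w:
            for (x, y), (mz, inten) in zip(sec.coords, sec.spectra):
                w.addSpectrum(
                    np.asarray(mz, float),
                    np.asarray(inten, float),
                    (int(x) + 1, int(y) + 1, 1),
                )
        rows.append(
            {
                "file": fname,
                "label": sec.label,
                "group": sec.group,
                "width": sec.width,
                "height": sec.height,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _is_continuous_mode(imzml_path: Path) -> bool:
    # IMS:1000030 = continuous, IMS:1000031 = processed; cheap header scan.
    head = imzml_path.read_text(errors="ignore")
    return "IMS:1000030" in head and "IMS:1000031" not in head


def load_dataset(
    manifest_path: str | Path,
    polarity: Literal["positive", "negative"] = "positive",
    mz_range: tuple[float, float] = (1000.0, 5000.0),
    pixel_pitch_um: float = 50.0,
) -> MsiDataset:
    """Load sections listed in a manifest CSV (columns: file, label, group)."""
    from pyimzml.ImzMLParser import ImzMLParser

    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"file", "label", "group"}
    if not required.issubset(manifest.columns):
        raise MsiFormatError(f"manifest must have columns {sorted(required)}")
    base = manifest_path.parent
    sections: list[Section] = []
    for row in manifest.itertuples():
        group = row.group
        if not isinstance(group, str) or group not in _VALID_GROUPS:
            raise MsiFormatError(
                f"file {row.file!r}: missing or invalid group label {group!r} "
                "(expected WT or MUT)"
            )
        path = base / str(row.file)
        if _is_continuous_mode(path):
            raise MsiFormatError(
                f"{path.name} is continuous-mode imzML; only processed "
                "(centroided) mode is supported — centroid the data first"
            )
        parser = ImzMLParser(str(path))
        coords = []
        spectra = []
        skipped = 0
        for i, (x, y, _z) in enumerate(parser.coordinates):
            try:
                mz, inten = parser.getspectrum(i)
            except Exception:  # pragma: no cover - corrupt binary region
                skipped += 1
                continue
            coords.append((int(x) - 1, int(y) - 1))
            spectra.append((np.asarray(mz, float), np.asarray(inten, float)))
        if skipped:
            logger.warning("%s: skipped %d unreadable spectra", path.name, skipped)
        coords_arr = np.asarray(coords, int)
        # grid dims from the manifest when present; else from occupied extent
        if "width" in manifest.columns and not pd.isna(row.width):
            width, height = int(row.width), int(row.height)
        else:
            width = int(coords_arr[:, 0].max()) + 1 if len(coords_arr) else 0
            height = int(coords_arr[:, 1].max()) + 1 if len(coords_arr) else 0
        sections.append(
            Section(
                label=str(row.label),
                group=group,
                width=width,
                height=height,
                coords=coords_arr,
                spectra=spectra,
            )
        )
    return MsiDataset(
        sections=sections,
        polarity=polarity,
        mz_range=mz_range,
        pixel_pitch_um=pixel_pitch_um,
    )


# ---------------------------------------------------------------------------
# Ion image extraction
# ---------------------------------------------------------------------------

def _pixel_values(
    section: Section, center_mz: float, tol_ppm: float, reducer: str
) -> np.ndarray:
    """Per-occupied-pixel reduced intensity inside ±tol_ppm of center_mz."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if reducer not in ("sum", "max"):
        raise ValueError(f"reducer must be 'sum' or 'max', got {reducer!r}")
    mzs, ints, idx = section.flattened()
    half = center_mz * tol_ppm * 1e-6
    lo = np.searchsorted(mzs, center_mz - half, side="left")
    hi = np.searchsorted(mzs, center_mz + half, side="right")
    out = np.zeros(section.n_pixels)
    if hi > lo:
        if reducer == "sum":
            np.add.at(out, idx[lo:hi], ints[lo:hi])
        else:
            np.maximum.at(out, idx[lo:hi], ints[lo:hi])
    return out


def extract_ion_image(
    dataset: MsiDataset,
    section: str,
    center_mz: float,
    tol_ppm: float = 3.0,
    reducer: Literal["sum", "max"] = "sum",
) -> IonImage:
    """Ion image of one section: reduce centroids within the ppm window.

    Pixels with no centroid in the window (and unoccupied grid positions)
    are 0. No normalization is applied.
    """
    sec = dataset.section(section)
    vals = _pixel_values(sec, center_mz, tol_ppm, reducer)
    img = np.zeros((sec.height, sec.width))
    img[sec.coords[:, 1], sec.coords[:, 0]] = vals
    return IonImage(values=img, center_mz=center_mz, tol_ppm=tol_ppm, reducer=reducer)


def section_intensity_vector(
    dataset: MsiDataset,
    section: str,
    center_mz: float,
    tol_ppm: float = 3.0,
    reducer: Literal["sum", "max"] = "sum",
) -> np.ndarray:
    """Occupied-pixel intensities in stable (row-major) pixel order."""
    sec = dataset.section(section)
    return _pixel_values(sec, center_mz, tol_ppm, reducer)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def ion_image_to_csv(image: IonImage, path: str | Path) -> None:
    pd.DataFrame(image.values).to_csv(path, index=False, header=False)


def ion_image_to_png(image: IonImage, path: str | Path, clip_percentile: float = 99.0) -> None:
    """Render to PNG with hot-spot clipping (display only, never statistics)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = image.values
    vmax = np.percentile(vals[vals > 0], clip_percentile) if np.any(vals > 0) else 1.0
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(vals, cmap="viridis", vmax=vmax, interpolation="nearest")
    ax.set_title(f"m/z {image.center_mz:.4f} ±{image.tol_ppm:g} ppm")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
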