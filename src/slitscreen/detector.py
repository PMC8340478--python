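"""Pupil / band-in-pupil detector contract plus a classical reference detector.

The screening pipeline treats the detector as a pluggable component: anything
with a pure ``detect(frame) -> Detection | None`` method can drive the
controller (a trained neural detector would be wired in through the same
contract).  The shipped :class:`ReferenceDetector` is a deterministic
classical pipeline — dark-region thresholding, a horizontal morphological
closing to bridge the bright band splitting the pupil, connected-component
circularity filtering, and a column-brightness band localiser — that detects
the band-in-pupil condition on phantom (and similarly clean) imagery without
any trained weights.

Also here: the Pascal-VOC XML reader/writer in the LabelImg dialect used for
bounding-box annotations, converting between VOC's 1-based inclusive pixel
coordinates and the package's 0-based half-open boxes.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "Detection",
    "PupilDetector",
    "ReferenceDetector",
    "VocParseError",
    "read_voc_annotations",
    "write_voc_annotation",
]

Box = tuple[int, int, int, int]


@dataclass(frozen=True)
class Detection:
    """One band-in-pupil detection: pupil box, confidence, class label."""

    box: Box  # (x, y, w, h), 0-based, half-open
    confidence: float
    label: str = "slit_in_pupil"

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


@runtime_checkable
class PupilDetector(Protocol):
    """Contract: pure per-frame detection of the band-in-pupil condition.

    ``detect`` returns a :class:`Detection` iff the slit band is judged to be
    inside the pupil on this frame, else ``None``; identical frames must give
    identical results.
    """

    def detect(self, frame: np.ndarray) -> Detection | None: ...


def _require_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 frame, got shape {frame.shape}")
    return frame


class ReferenceDetector:
    """Classical detector: dark circular pupil + brightest vertical band.

    Parameters
    ----------
    dark_threshold:
        Grayscale level below which a pixel counts as pupil-dark.
    circularity_min:
        Minimum ``4*pi*area / perimeter**2`` of the accepted dark component.
    band_bridge:
        Width (columns) of the horizontal closing that re-joins the two pupil
        lobes split by the bright band; must exceed the band width.
    band_min_contrast:
        Minimum column-profile peak-over-median contrast for a band to count
        as present at all.
    min_area:
        Minimum pupil component area in pixels.
    """

    def __init__(
        self,
        dark_threshold: float = 70.0,
        circularity_min: float = 0.6,
        band_bridge: int = 25,
        band_min_contrast: float = 10.0,
        min_area: int = 40,
    ):
        self.dark_threshold = dark_threshold
        self.circularity_min = circularity_min
        self.band_bridge = band_bridge
        self.band_min_contrast = band_min_contrast
        self.min_area = min_area

    # -- internals ---------------------------------------------------------

    def _find_pupil(
        self, gray: np.ndarray, band_center: float | None = None
    ) -> tuple[tuple[float, float, float], Box] | None:
        """Locate the pupil disc; returns ((cx, cy, r), raw component bbox).

        The bright band bleaches the dark pixels it covers, so near the pupil
        edge the dark component is a single lobe whose bounding box stops at
        the band.  The vertical extent survives (the band is vertical), which
        gives the radius; the circle centre is then reconstructed from the
        intact horizontal side of the lobe.
        """
        dark = gray < self.dark_threshold
        if not dark.any():
            return None
        closed = morphology.closing(
            dark, footprint=np.ones((3, self.band_bridge), dtype=bool)
        )
        labels = measure.label(closed)
        best = None
        for region in measure.regionprops(labels):
            if region.area < self.min_area:
                continue
            # Circularity of the convex hull: robust to the jagged outline
            # the band bleaching + closing leaves on the component itself.
            hull_area = float(region.image_convex.sum())
            hull_perimeter = measure.perimeter(region.image_convex)
            if hull_perimeter == 0:
                continue
            circularity = 4.0 * np.pi * hull_area / hull_perimeter**2
            if circularity < self.circularity_min:
                continue
            if best is None or region.area > best.area:
                best = region
        if best is None:
            return None
        minr, minc, maxr, maxc = best.bbox
        r = (maxr - minr - 1) / 2.0
        cy = (minr + maxr - 1) / 2.0
        # Candidate centres assuming the left or the right flank is intact.
        cx_from_right = (maxc - 1) - r
        cx_from_left = minc + r
        if abs(cx_from_right - cx_from_left) <= 4.0 or band_center is None:
            cx = (cx_from_left + cx_from_right) / 2.0
        elif band_center < (minc + maxc - 1) / 2.0:
            cx = cx_from_right  # band bleached the left flank
        else:
            cx = cx_from_left  # band bleached the right flank
        return (cx, cy, r), (minc, minr, maxc - minc, maxr - minr)

    def _find_band(self, gray: np.ndarray) -> tuple[float, np.ndarray] | None:
        """Band centre column (sub-pixel) from the column-brightness profile."""
        profile = gray.mean(axis=0)
        kernel = np.ones(5) / 5.0
        smooth = np.convolve(profile, kernel, mode="same")
        # Detrend: the iris/pupil darkening tilts the baseline, which would
        # bias the band centroid sideways; a wide median filter removes it.
        baseline = ndimage.median_filter(smooth, size=41, mode="nearest")
        resid = smooth - baseline
        peak = float(resid.max())
        if peak < self.band_min_contrast:
            return None
        argpeak = int(np.argmax(resid))
        band_cols = resid >= peak / 2.0
        # Keep only the run containing the peak.
        runs = measure.label(band_cols[None, :])
        band_cols = runs[0] == runs[0, argpeak]
        cols = np.flatnonzero(band_cols)
        weights = resid[cols]
        center = float(np.sum(cols * weights) / np.sum(weights))
        return center, band_cols

    # -- contract ----------------------------------------------------------

    def detect(self, frame: np.ndarray) -> Detection | None:
        frame = _require_frame(frame)
        gray = frame.astype(float) @ np.array([0.299, 0.587, 0.114])
        band = self._find_band(gray)
        if band is None:
            return None
        center, band_cols = band
        pupil = self._find_pupil(gray, band_center=center)
        if pupil is None:
            return None
        (cx, cy, r), _ = pupil
        if abs(center - cx) > r:
            return None
        height, width = gray.shape
        x = max(0, int(round(cx - r)))
        y = max(0, int(round(cy - r)))
        w = min(width - x, int(round(2 * r + 1)))
        h = min(height - y, int(round(2 * r + 1)))
        cols = np.flatnonzero(band_cols)
        overlap = np.count_nonzero((cols >= x) & (cols < x + w))
        confidence = overlap / max(1, cols.size)
        return Detection(box=(x, y, w, h), confidence=float(confidence))


# -- Pascal-VOC XML (LabelImg dialect) --------------------------------------


class VocParseError(ValueError):
    """Raised for malformed Pascal-VOC XML, naming the offending file."""


def _voc_boxes_from_tree(root: ET.Element, path: Path) -> list[tuple[str, Box]]:
    boxes: list[tuple[str, Box]] = []
    for obj in root.findall("object"):
        name_el = obj.find("name")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise VocParseError(f"{path}: <object> without <bndbox>")
        try:
            xmin = int(float(bnd.findtext("xmin")))  # type: ignore[arg-type]
            ymin = int(float(bnd.findtext("ymin")))  # type: ignore[arg-type]
            xmax = int(float(bnd.findtext("xmax")))  # type: ignore[arg-type]
            ymax = int(float(bnd.findtext("ymax")))  # type: ignore[arg-type]
        except (TypeError, ValueError) as exc:
            raise VocParseError(f"{path}: malformed <bndbox>: {exc}") from exc
        # VOC is 1-based with inclusive max; internal boxes are 0-based
        # half-open, so (1,1,10,10) -> (0, 0, 10, 10).
        box: Box = (xmin - 1, ymin - 1, xmax - xmin + 1, ymax - ymin + 1)
        boxes.append((name_el.text if name_el is not None else "", box))
    return boxes


def _parse_voc_file(path: Path) -> list[tuple[str, Box]]:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise VocParseError(f"{path}: not well-formed XML: {exc}") from exc
    return _voc_boxes_from_tree(tree.getroot(), path)


def read_voc_annotations(path) -> dict[int, list[tuple[str, Box]]]:
    """Read LabelImg Pascal-VOC XML into frame-indexed 0-based half-open boxes.

    ``path`` may be a single XML file (indexed by the digits in its stem, or 0
    if none) or a directory of per-frame XML files.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.xml"))
        if not files:
            raise VocParseError(f"{path}: no .xml files found")
    else:
        files = [path]
    out: dict[int, list[tuple[str, Box]]] = {}
    for f in files:
        digits = re.findall(r"\d+", f.stem)
        index = int(digits[-1]) if digits else 0
        out[index] = _parse_voc_file(f)
    return out


def write_voc_annotation(
    path,
    filename: str,
    image_size: tuple[int, int],
    boxes: list[tuple[str, Box]],
    folder: str = "frames",
) -> None:
    """Write one LabelImg-dialect VOC XML file for one frame.

    ``image_size`` is (width, height); boxes are internal 0-based half-open
    and are converted to VOC's 1-based inclusive pixels.
    """
    width, height = image_size
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = folder
    ET.SubElement(root, "filename").text = filename
    ET.SubElement(root, "path").text = str(Path(folder) / filename)
    source = ET.SubElement(root, "source")
    ET.SubElement(source, "database").text = "Unknown"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(width)
    ET.SubElement(size, "height").text = str(height)
    ET.SubElement(size, "depth").text = "3"
    ET.SubElement(root, "segmented").text = "0"
    for name, (x, y, w, h) in boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = name or "slit_in_pupil"
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(x + 1)
        ET.SubElement(bnd, "ymin").text = str(y + 1)
        ET.SubElement(bnd, "xmax").text = str(x + w)
        ET.SubElement(bnd, "ymax").text = str(y + h)
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=False)
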