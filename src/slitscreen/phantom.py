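"""Synthetic anterior-segment eye phantom videos with per-frame ground truth.

The generator renders a minimal concentric-disc model of the anterior eye
(sclera background, iris annulus, dark pupil disc) swept by a vertical slit
light band, emulating a hand-held slit-lamp sweep of up to 10 s.  It exists so
that every downstream stage — the Cb-channel gate, the pupil detector, the
state-machine controller and the lens classifier — can be exercised against
exact, programmatic ground truth.

Physics being emulated, qualitatively:

* The slit band is a bright, slightly blue-shifted stripe (slit lamps use a
  cold white source; ``slit_blue_gain`` boosts the blue channel inside the
  lit band, which is what makes the blue-difference chroma Cb respond to the
  band and gives the gate its signal).
* A turbid (cataractous) lens scatters the slit light (Tyndall effect):
  ``opacity_level`` mixes a bright speckle texture into the pupil region
  under the band.  Opacity above ``OPACITY_THRESHOLD`` is labelled cataract.
* The subject's head is fixed, so the pupil position and size are constant
  within a video.

Four sweep protocols are provided, mirroring common hand-held acquisition
habits: A left sclera -> right sclera, B the mirror image, C a random iris
start swept to the opposite sclera, and D entry from the left that reaches
the pupil centre and holds there for three seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "OPACITY_THRESHOLD",
    "EyePhantomParams",
    "GroundTruth",
    "PhantomVideoSpec",
    "band_center",
    "render_frame",
    "generate_video",
    "generate_dataset",
    "slit_in_pupil_flags",
]

#: Lens turbidity above which the phantom is labelled cataract.
OPACITY_THRESHOLD = 0.5

#: Seconds protocol D dwells on the pupil centre at the end of the sweep.
PROTOCOL_D_HOLD_S = 3.0

# Base colours (R, G, B), 8-bit scale.
_SCLERA = np.array([205.0, 193.0, 178.0])
_IRIS = np.array([115.0, 82.0, 58.0])
_PUPIL = np.array([28.0, 26.0, 30.0])

# Sub-stream tags so per-frame noise, the lens texture and protocol draws
# come from independent, reproducible streams of the one master seed.
_TEXTURE_STREAM = 7001
_PROTOCOL_STREAM = 7002
_NOISE_STREAM = 7003

Protocol = Literal["A", "B", "C", "D"]


@dataclass(frozen=True)
class EyePhantomParams:
    """Geometry, photometry and acquisition parameters of one phantom video.

    Distances are in pixels, intensities on the 8-bit scale unless noted.
    """

    image_width: int = 160
    image_height: int = 120
    pupil_center: tuple[int, int] = (80, 60)  # (x, y)
    pupil_radius: int = 18
    iris_radius: int = 40
    sclera_margin: int = 15
    slit_width: int = 10
    slit_intensity: float = 0.55  # 0-1 relative brightness of the band
    slit_blue_gain: float = 1.6  # multiplicative blue boost inside the band
    opacity_level: float = 0.0  # 0 = clear lens, > OPACITY_THRESHOLD = cataract
    noise_sigma: float = 2.0  # per-channel Gaussian noise std, intensity units
    fps: int = 20
    duration_s: float = 5.0
    protocol: Protocol = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pupil_radius < self.iris_radius):
            raise ValueError("pupil_radius must be smaller than iris_radius")
        limit = min(self.image_width, self.image_height) / 2 - self.sclera_margin
        if not self.iris_radius < limit:
            raise ValueError(
                "iris_radius must fit inside the image with the sclera margin: "
                f"need iris_radius < {limit}"
            )
        if not 0 < self.duration_s <= 10:
            raise ValueError("duration_s must be in (0, 10] seconds")
        if not 0.0 <= self.opacity_level <= 1.0:
            raise ValueError("opacity_level must be in [0, 1]")
        if not 0.0 <= self.slit_intensity <= 1.0:
            raise ValueError("slit_intensity must be in [0, 1]")
        if self.slit_blue_gain < 0:
            raise ValueError("slit_blue_gain must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.protocol not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.protocol == "D" and self.duration_s <= PROTOCOL_D_HOLD_S:
            raise ValueError(
                f"protocol D needs duration_s > {PROTOCOL_D_HOLD_S} s for the hold"
            )
        if self.n_frames < 1:
            raise ValueError("fps * duration_s must give at least one frame")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    @property
    def label(self) -> str:
        """Deterministic class label implied by the lens turbidity."""
        return "cataract" if self.opacity_level > OPACITY_THRESHOLD else "normal"

    @property
    def pupil_box(self) -> tuple[int, int, int, int]:
        """Tight bounding box of the pupil disc, (x, y, w, h), half-open."""
        cx, cy = self.pupil_center
        r = self.pupil_radius
        return (cx - r, cy - r, 2 * r + 1, 2 * r + 1)


@dataclass
class GroundTruth:
    """Exact per-frame annotations emitted alongside a phantom video."""

    slit_in_pupil: list[bool]
    pupil_box: tuple[int, int, int, int]
    class_label: str
    protocol: str
    band_centers: list[float] = field(default_factory=list)


def _sweep_endpoints(params: EyePhantomParams) -> tuple[float, float]:
    """Horizontal band positions at the left and right sclera rest points."""
    cx = params.pupil_center[0]
    reach = params.iris_radius + params.sclera_margin
    left = max(0.0, cx - reach)
    right = min(params.image_width - 1.0, cx + reach)
    return left, right


def _protocol_c_start(params: EyePhantomParams) -> float:
    """Protocol C's uniform-random start column inside the iris annulus."""
    rng = np.random.default_rng([params.seed, _PROTOCOL_STREAM])
    side = 1 if rng.random() < 0.5 else -1
    offset = rng.uniform(params.pupil_radius, params.iris_radius)
    return params.pupil_center[0] + side * offset


def band_center(params: EyePhantomParams, frame_index: int) -> float:
    """Horizontal centre column of the slit band at ``frame_index``.

    Trajectories by protocol: A sweeps left sclera -> right sclera at constant
    speed, B the mirror image, C starts at a random iris column and sweeps to
    the opposite sclera, D enters from the left sclera, reaches the pupil
    centre and holds for the final three seconds.
    """
    n = params.n_frames
    if not 0 <= frame_index < n:
        raise IndexError(f"frame_index {frame_index} outside [0, {n})")
    left, right = _sweep_endpoints(params)
    cx = float(params.pupil_center[0])
    t = frame_index / (n - 1) if n > 1 else 0.0
    if params.protocol == "A":
        return left + (right - left) * t
    if params.protocol == "B":
        return right - (right - left) * t
    if params.protocol == "C":
        start = _protocol_c_start(params)
        end = right if start <= cx else left
        return start + (end - start) * t
    # Protocol D: travel for duration_s - hold, then dwell at the centre.
    travel_frames = n - int(round(PROTOCOL_D_HOLD_S * params.fps))
    if frame_index >= travel_frames - 1:
        return cx
    u = frame_index / (travel_frames - 1) if travel_frames > 1 else 1.0
    return left + (cx - left) * u


def slit_in_pupil(params: EyePhantomParams, frame_index: int) -> bool:
    """True iff the band centre column lies within the pupil's horizontal extent."""
    cx = params.pupil_center[0]
    return abs(band_center(params, frame_index) - cx) <= params.pupil_radius


def slit_in_pupil_flags(params: EyePhantomParams) -> list[bool]:
    return [slit_in_pupil(params, i) for i in range(params.n_frames)]


def _band_profile(params: EyePhantomParams, center: float) -> np.ndarray:
    """Per-column band weight: rectangular core with Gaussian-soft edges."""
    cols = np.arange(params.image_width, dtype=float)
    half = params.slit_width / 2.0
    edge_sigma = 1.5
    dist = np.maximum(0.0, np.abs(cols - center) - half)
    return np.exp(-0.5 * (dist / edge_sigma) ** 2)


def _lens_texture(params: EyePhantomParams) -> np.ndarray:
    """Static per-video scattering texture, in [0, 1], fixed by the master seed."""
    rng = np.random.default_rng([params.seed, _TEXTURE_STREAM])
    return rng.random((params.image_height, params.image_width))


def render_frame(params: EyePhantomParams, frame_index: int) -> np.ndarray:
    """Render one RGB frame (uint8, H x W x 3), deterministic in (params, index).

    The static phantom is drawn first, then the Tyndall speckle of a turbid
    lens under the band, then the additive band light with its blue boost,
    then per-frame Gaussian sensor noise from a sub-stream keyed by
    ``(seed, frame_index)``.
    """
    h, w = params.image_height, params.image_width
    cx, cy = params.pupil_center
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - cx, yy - cy)

    img = np.empty((h, w, 3), dtype=float)
    img[:] = _SCLERA
    img[dist <= params.iris_radius] = _IRIS
    pupil_mask = dist <= params.pupil_radius
    img[pupil_mask] = _PUPIL

    center = band_center(params, frame_index)
    profile = _band_profile(params, center)  # per column
    lit = profile[None, :] * params.slit_intensity

    # Tyndall scattering in the lens region under the band (cataract signal).
    if params.opacity_level > 0:
        texture = _lens_texture(params)
        scatter = params.opacity_level * texture * 360.0 * lit
        img += (scatter * pupil_mask)[:, :, None]

    # Additive band light, then the blue-channel boost of the lit region.
    img += (lit * 230.0)[:, :, None]
    img[:, :, 2] *= 1.0 + (params.slit_blue_gain - 1.0) * lit

    if params.noise_sigma > 0:
        rng = np.random.default_rng([params.seed, _NOISE_STREAM, frame_index])
        img += rng.normal(0.0, params.noise_sigma, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_video(params: EyePhantomParams) -> tuple[np.ndarray, GroundTruth]:
    """Render the full frame stack (N x H x W x 3 uint8) with its ground truth."""
    n = params.n_frames
    frames = np.stack([render_frame(params, i) for i in range(n)])
    truth = GroundTruth(
        slit_in_pupil=slit_in_pupil_flags(params),
        pupil_box=params.pupil_box,
        class_label=params.label,
        protocol=params.protocol,
        band_centers=[band_center(params, i) for i in range(n)],
    )
    return frames, truth


@dataclass(frozen=True)
class PhantomVideoSpec:
    """One eye of a generated cohort: parameters plus its class label.

    Videos are rendered lazily via :func:`generate_video` to keep large
    cohorts out of memory.
    """

    params: EyePhantomParams
    label: str

    def render(self) -> tuple[np.ndarray, GroundTruth]:
        return generate_video(self.params)


def generate_dataset(
    n_eyes: int,
    cataract_fraction: float,
    base_params: EyePhantomParams | None = None,
    seed: int = 0,
) -> list[PhantomVideoSpec]:
    """Draw a labelled cohort of phantom eyes.

    Per eye the sweep protocol is uniform over {A, B, C, D} and the lens
    opacity is drawn from the class-conditional distribution: clear lenses
    U(0, 0.15), cataractous lenses U(0.6, 0.95).  Exactly
    ``round(n_eyes * cataract_fraction)`` eyes are cataract.
    """
    if n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")
    if not 0.0 <= cataract_fraction <= 1.0:
        raise ValueError("cataract_fraction must be in [0, 1]")
    if base_params is None:
        base_params = EyePhantomParams()
    rng = np.random.default_rng([seed, _PROTOCOL_STREAM])
    n_cat = int(round(n_eyes * cataract_fraction))
    labels = np.array(["cataract"] * n_cat + ["normal"] * (n_eyes - n_cat))
    rng.shuffle(labels)
    specs: list[PhantomVideoSpec] = []
    for i, label in enumerate(labels):
        protocol = str(rng.choice(["A", "B", "C", "D"]))
        if label == "cataract":
            opacity = float(rng.uniform(0.6, 0.95))
        else:
            opacity = float(rng.uniform(0.0, 0.15))
        params = replace(
            base_params,
            protocol=protocol,  # type: ignore[arg-type]
            opacity_level=opacity,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        specs.append(PhantomVideoSpec(params=params, label=label))
    return specs


def in_pupil_crop_dataset(
    n_per_class: int,
    base_params: EyePhantomParams | None = None,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[str]]:
    """Labelled pupil-box crops of band-in-pupil frames, for classifier training.

    Renders, per eye, the protocol-D dwell frame (band centred on the pupil)
    and crops the true pupil box — the same view the controller hands the
    classifier at run time.
    """
    if base_params is None:
        base_params = EyePhantomParams()
    params_d = replace(base_params, protocol="D")
    specs = generate_dataset(
        2 * n_per_class, cataract_fraction=0.5, base_params=params_d, seed=seed
    )
    crops: list[np.ndarray] = []
    labels: list[str] = []
    for spec in specs:
        p = replace(spec.params, protocol="D")
        mid = p.n_frames - 1  # dwell frame: band centred on the pupil
        frame = render_frame(p, mid)
        x, y, w, h = p.pupil_box
        crops.append(frame[y : y + h, x : x + w])
        labels.append(spec.label)
    return crops, labels
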