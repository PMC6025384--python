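"""Synthetic brain-slice phantoms with ground-truth cerebrum masks.

A phantom emulates the gross structure of a 2-D T1/T2 brain slice at the
level the downstream pipeline cares about: a dark background, a bright
skull ring, a dark cerebrospinal-fluid gap, and a textured elliptical
cerebrum.  "Abnormal" phantoms additionally carry bright lesion blobs
inside the cerebrum, so that sub-band texture statistics separate the two
classes.  Every image comes with the analytic cerebrum ellipse as a
ground-truth mask, which makes segmentation quality (Dice) measurable
without any external data.

Texture model: base intensity + smooth sinusoidal modulation + i.i.d.
Gaussian noise; lesions are anti-aliased disks.  This is deliberately the
simplest model that gives wavelet-band statistics a class signal; it does
not attempt MR physics (bias fields, Rician noise, partial volume).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "PhantomSpec",
    "LabeledImage",
    "generate_phantom",
    "generate_dataset",
]

Label = Literal["normal", "abnormal"]


class InvalidSpecError(ValueError):
    """Phantom geometry does not fit the canvas."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic brain slice.

    Defaults are sized for a 128x128 canvas with the skull ring centered
    so that pixel (30, 30) — the fixed region-growing seed used by the
    segmentation stage — always lies in the background.
    """

    height: int = 128
    width: int = 128
    skull_inner_radius: float = 39.0
    skull_outer_radius: float = 45.0
    skull_intensity: float = 0.95
    cerebrum_axes: tuple[float, float] = (34.0, 30.0)  # (row semi-axis, col semi-axis)
    cerebrum_intensity: float = 0.60
    noise_sd: float = 0.03
    modulation_amplitude: float = 0.04
    background_intensity: float = 0.02
    csf_intensity: float = 0.02
    ventricle_axes: tuple[float, float] = (7.0, 5.0)
    ventricle_enlargement: float = 2.4  # abnormal class only
    abnormal_texture_factor: float = 1.6  # texture multiplier, abnormal only
    lesion_count: int = 3
    lesion_radius_range: tuple[float, float] = (3.0, 6.0)
    lesion_intensity_offset: float = 0.30
    class_label: Label = "normal"
    seed: int = 0

    def validate(self) -> None:
        if self.height < 16 or self.width < 16:
            raise InvalidSpecError("canvas must be at least 16x16")
        if not (0 < self.skull_inner_radius < self.skull_outer_radius):
            raise InvalidSpecError("skull radii must satisfy 0 < inner < outer")
        if self.skull_outer_radius >= min(self.height, self.width) / 2:
            raise InvalidSpecError(
                "skull outer radius must be smaller than half the canvas"
            )
        a, b = self.cerebrum_axes
        if a <= 0 or b <= 0:
            raise InvalidSpecError("cerebrum axes must be positive")
        if max(a, b) >= self.skull_inner_radius:
            raise InvalidSpecError("cerebrum ellipse must fit inside the skull ring")
        va, vb = self.ventricle_axes
        scale = self.ventricle_enlargement if self.class_label == "abnormal" else 1.0
        if va * scale >= a or vb * scale >= b:
            raise InvalidSpecError("ventricle must fit inside the cerebrum")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise InvalidSpecError("lesion radius range must satisfy 0 < lo <= hi")
        if self.lesion_count < 0:
            raise InvalidSpecError("lesion count must be >= 0")
        if self.class_label not in ("normal", "abnormal"):
            raise InvalidSpecError(f"unknown class label {self.class_label!r}")


@dataclass(frozen=True)
class LabeledImage:
    """A phantom image with its analytic cerebrum mask and class label."""

    image: np.ndarray  # float in [0, 1]
    truth_mask: np.ndarray  # uint8 in {0, 1}
    label: Label
    image_id: str = ""


def _radial_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, float, float]:
    cr = spec.height / 2.0
    cc = spec.width / 2.0
    rows = np.arange(spec.height)[:, None] - cr
    cols = np.arange(spec.width)[None, :] - cc
    return rows, cols, cr, cc


def _soft_disk(rows: np.ndarray, cols: np.ndarray, r0: float, c0: float,
               radius: float) -> np.ndarray:
    """Anti-aliased disk indicator: 1 inside, 0 outside, linear 1-px ramp."""
    d = np.hypot(rows - r0, cols - c0)
    return np.clip(radius + 0.5 - d, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> LabeledImage:
    """Render one phantom slice deterministically from ``spec``.

    The same spec (including its seed) always yields a bit-identical image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols, cr, cc = _radial_grids(spec)
    r = np.hypot(rows, cols)

    img = np.full((spec.height, spec.width), spec.background_intensity)

    # Skull ring: bright annulus with 1-px anti-aliased rims.
    ring = np.clip(spec.skull_outer_radius + 0.5 - r, 0.0, 1.0) * np.clip(
        r - spec.skull_inner_radius + 0.5, 0.0, 1.0
    )
    inside_skull = r < spec.skull_inner_radius
    img[inside_skull] = spec.csf_intensity
    img = img * (1 - ring) + spec.skull_intensity * ring

    # Cerebrum ellipse with smooth sinusoidal texture modulation.
    a, b = spec.cerebrum_axes
    ell = (rows / a) ** 2 + (cols / b) ** 2
    cerebrum = ell <= 1.0
    phase_r, phase_c = rng.uniform(0, 2 * np.pi, size=2)
    mod_amp = spec.modulation_amplitude
    if spec.class_label == "abnormal":
        # degenerative tissue is texturally more heterogeneous: both the
        # smooth modulation and the fine-grained noise scale up
        mod_amp *= spec.abnormal_texture_factor
    modulation = mod_amp * (
        np.sin(2 * np.pi * rows / (2.2 * a) + phase_r)
        * np.cos(2 * np.pi * cols / (2.2 * b) + phase_c)
    )
    img[cerebrum] = spec.cerebrum_intensity + modulation[cerebrum]

    # Central dark ventricle; enlarged (atrophy-like) in the abnormal class.
    va, vb = spec.ventricle_axes
    if spec.class_label == "abnormal":
        va *= spec.ventricle_enlargement
        vb *= spec.ventricle_enlargement
    if va > 0 and vb > 0:
        ventricle = (rows / va) ** 2 + (cols / vb) ** 2 <= 1.0
        img[ventricle & cerebrum] = spec.csf_intensity

    # Lesions (abnormal class only): bright anti-aliased disks well inside
    # the cerebrum.
    if spec.class_label == "abnormal" and spec.lesion_count > 0:
        lo, hi = spec.lesion_radius_range
        for _ in range(spec.lesion_count):
            radius = rng.uniform(lo, hi)
            # rejection-free placement: sample inside the shrunken ellipse
            theta = rng.uniform(0, 2 * np.pi)
            rho = np.sqrt(rng.uniform(0, 1))
            r0 = cr + rho * (a - radius - 2.0) * np.sin(theta)
            c0 = cc + rho * (b - radius - 2.0) * np.cos(theta)
            disk = _soft_disk(np.arange(spec.height)[:, None],
                              np.arange(spec.width)[None, :], r0, c0, radius)
            img = img + spec.lesion_intensity_offset * disk * cerebrum

    if spec.noise_sd > 0:
        sd = spec.noise_sd
        noise = rng.normal(0.0, sd, size=img.shape)
        if spec.class_label == "abnormal" and spec.abnormal_texture_factor != 1.0:
            # degenerate tissue is texturally more heterogeneous: scale the
            # noise inside the cerebrum only, so the background and skull
            # stay identical between classes
            noise[cerebrum] *= spec.abnormal_texture_factor
        img = img + noise

    img = np.clip(img, 0.0, 1.0)
    truth = cerebrum.astype(np.uint8)
    return LabeledImage(image=img, truth_mask=truth, label=spec.class_label)


def generate_dataset(
    n_normal: int,
    n_abnormal: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    geometry_jitter: float = 2.0,
) -> list[LabeledImage]:
    """Generate ``n_normal + n_abnormal`` labeled phantoms.

    Per-image seeds and geometry jitter are derived deterministically from
    the master seed, so the dataset is reproducible bit-for-bit.  Jitter
    perturbs skull radii and cerebrum axes uniformly in
    ``[-geometry_jitter, +geometry_jitter]`` pixels (clamped to keep the
    geometry valid), so images are not copies of one another.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("counts must be >= 0")
    if base_spec is None:
        base_spec = PhantomSpec()
    master = np.random.SeedSequence(seed)
    labels: list[Label] = ["normal"] * n_normal + ["abnormal"] * n_abnormal
    children = master.spawn(len(labels))
    out: list[LabeledImage] = []
    for i, (label, child) in enumerate(zip(labels, children)):
        jit_rng = np.random.default_rng(child)
        img_seed = int(jit_rng.integers(0, 2**31 - 1))
        if geometry_jitter > 0:
            dj = jit_rng.uniform(-geometry_jitter, geometry_jitter, size=4)
        else:
            dj = np.zeros(4)
        a, b = base_spec.cerebrum_axes
        spec = dataclasses.replace(
            base_spec,
            class_label=label,
            seed=img_seed,
            skull_inner_radius=base_spec.skull_inner_radius + dj[0],
            skull_outer_radius=base_spec.skull_outer_radius + dj[1],
            cerebrum_axes=(
                min(a + dj[2], base_spec.skull_inner_radius + dj[0] - 2.0),
                min(b + dj[3], base_spec.skull_inner_radius + dj[0] - 2.0),
            ),
        )
        li = generate_phantom(spec)
        out.append(dataclasses.replace(li, image_id=f"phantom_{i:04d}_{label}"))
    return out
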