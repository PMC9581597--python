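"""Rigid alignment of cyclic staining rounds using the nuclear channel.

In cyclic immunofluorescence the same tissue field is re-stained and
re-imaged; between rounds the field is re-localised only approximately, so
the second-round stack is displaced from the first by a small 2D rigid
transform (rotation + translation).  The nuclear stain is present in every
round and serves as the registration reference.

The estimator here is deterministic: it sweeps a coarse-to-fine rotation
grid and, at each candidate angle, solves the translation by subpixel
phase cross-correlation, scoring candidates by normalised cross-correlation
(NCC).  NCC is invariant to global intensity scaling of either image, so
round-to-round photobleaching does not bias the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, warp

from .image import NUCLEI_CHANNEL, MultiplexImage


class DegenerateImageError(ValueError):
    """Raised when an input image carries no registration information."""


@dataclass(frozen=True)
class RigidTransform:
    """2D rigid transform: rotation about ``center`` followed by translation.

    Acting on a point ``p = (x, y)`` (x = column, y = row)::

        T(p) = R(theta) @ (p - c) + c + t

    with ``theta = rotation_deg`` (counter-clockwise in array coordinates),
    ``c = center`` and ``t = translation = (dx, dy)`` in pixels.
    The identity is ``(0 deg, (0, 0))``.
    """

    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)

    def _rot(self) -> np.ndarray:
        a = math.radians(self.rotation_deg)
        return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on column vectors (x, y, 1)."""
        rot = self._rot()
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        m = np.eye(3)
        m[:2, :2] = rot
        m[:2, 2] = c + t - rot @ c
        return m

    def inverse(self) -> "RigidTransform":
        """Exact inverse, expressed about the same center."""
        rot_inv = self._rot().T
        t = np.asarray(self.translation, dtype=float)
        return RigidTransform(
            rotation_deg=-self.rotation_deg,
            translation=tuple(-(rot_inv @ t)),
            center=self.center,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first), about self.center."""
        m = self.matrix() @ other.matrix()
        return RigidTransform.from_matrix(m, center=self.center)

    @classmethod
    def from_matrix(cls, m: np.ndarray, center: tuple[float, float] = (0.0, 0.0)) -> "RigidTransform":
        rotation = math.degrees(math.atan2(m[1, 0], m[0, 0]))
        c = np.array([*center, 1.0])
        t = (m @ c)[:2] - np.asarray(center, dtype=float)
        return cls(rotation_deg=rotation, translation=tuple(t), center=center)

    def apply_to_points(self, pts: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        return (self._rot() @ (pts - c).T).T + c + t

    @property
    def is_identity(self) -> bool:
        return self.rotation_deg == 0.0 and self.translation == (0.0, 0.0)


@dataclass(frozen=True)
class RegistrationResult:
    """Estimated transform plus an NCC quality score in [-1, 1]."""

    transform: RigidTransform
    quality: float
    low_quality: bool


def _warp_raster(raster: np.ndarray, transform: RigidTransform, order: int = 1) -> np.ndarray:
    # warp() wants the output->input map, i.e. the inverse transform.
    inv = AffineTransform(matrix=transform.inverse().matrix())
    return warp(raster, inv, order=order, mode="constant", cval=0.0, preserve_range=True)


def apply_transform(
    image: MultiplexImage | np.ndarray, transform: RigidTransform, *, order: int = 1
) -> tuple[MultiplexImage | np.ndarray, np.ndarray]:
    """Resample ``image`` under ``transform`` (all channels identically).

    Returns ``(warped, validity)`` where ``validity`` is a boolean mask of
    pixels whose value was interpolated entirely from in-view data; pixels
    pulled from outside the field are flagged invalid rather than
    extrapolated.
    """
    if isinstance(image, MultiplexImage):
        shape = image.shape
    else:
        image = np.asarray(image, dtype=float)
        shape = image.shape
    support = _warp_raster(np.ones(shape), transform, order=1)
    validity = support > 0.999
    if isinstance(image, MultiplexImage):
        warped_channels = {
            name: np.clip(_warp_raster(ch, transform, order=order), 0, None)
            for name, ch in image.channels.items()
        }
        meta = dict(image.metadata)
        meta["applied_transform"] = transform
        out: MultiplexImage | np.ndarray = MultiplexImage(
            warped_channels, round_id=image.round_id, metadata=meta
        )
    else:
        out = _warp_raster(image, transform, order=order)
    return out, validity


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        return 0.0
    return float(a @ b) / denom


def _score_angle(
    ref: np.ndarray, mov: np.ndarray, angle: float, center: tuple[float, float], margin: int, upsample: int
) -> tuple[float, np.ndarray]:
    """Derotate ``mov`` by ``angle``, solve translation, return (NCC, shift_rc)."""
    derot = _warp_raster(mov, RigidTransform(-angle, (0.0, 0.0), center))
    shift_rc, _, _ = phase_cross_correlation(ref, derot, upsample_factor=upsample)
    aligned = ndimage.shift(derot, shift_rc, order=1, mode="constant", cval=0.0)
    sl = (slice(margin, -margin or None), slice(margin, -margin or None))
    return _ncc(ref[sl], aligned[sl]), shift_rc


def estimate_rigid_transform(
    ref_nuclei: np.ndarray,
    mov_nuclei: np.ndarray,
    *,
    max_shift: float = 10.0,
    max_rotation: float = 5.0,
    coarse_step: float = 1.0,
    quality_floor: float = 0.2,
) -> RegistrationResult:
    """Estimate the rigid transform carrying ``ref_nuclei`` onto ``mov_nuclei``.

    The returned transform ``t`` satisfies ``apply_transform(ref, t) ~ mov``;
    aligning the moving round back into the reference frame therefore uses
    ``t.inverse()``.  The search assumes an approximate prealignment: it
    covers rotations within ``max_rotation`` degrees (coarse grid refined to
    0.02 degree) and translations solved by subpixel phase correlation.
    """
    ref = np.asarray(ref_nuclei, dtype=float)
    mov = np.asarray(mov_nuclei, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {mov.shape}")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise DegenerateImageError("constant image: no features to register")

    center = ((ref.shape[1] - 1) / 2.0, (ref.shape[0] - 1) / 2.0)
    margin = int(math.ceil(max_shift)) + 2

    def sweep(angles: np.ndarray, upsample: int) -> tuple[float, float, np.ndarray]:
        best = (-2.0, 0.0, np.zeros(2))
        for ang in angles:
            score, shift_rc = _score_angle(ref, mov, float(ang), center, margin, upsample)
            if score > best[0]:
                best = (score, float(ang), shift_rc)
        return best

    coarse = np.arange(-max_rotation, max_rotation + 1e-9, coarse_step)
    score, angle, shift_rc = sweep(coarse, upsample=10)
    fine = np.arange(angle - coarse_step, angle + coarse_step + 1e-9, coarse_step / 10)
    score, angle, shift_rc = sweep(fine, upsample=20)
    finest = np.arange(angle - 0.1, angle + 0.1 + 1e-9, 0.02)
    score, angle, shift_rc = sweep(finest, upsample=100)

    # The derotated moving image equals ref translated by d = -shift (phase
    # correlation reports the shift registering moving to reference); the
    # forward translation is that displacement rotated back by the angle.
    rot = RigidTransform(angle, (0.0, 0.0), center)._rot()
    d_xy = np.array([-shift_rc[1], -shift_rc[0]])
    t_xy = rot @ d_xy
    transform = RigidTransform(angle, (float(t_xy[0]), float(t_xy[1])), center)
    return RegistrationResult(transform=transform, quality=score, low_quality=score < quality_floor)


def align_rounds(
    round1: MultiplexImage,
    round2: MultiplexImage,
    *,
    nuclei_channel: str = NUCLEI_CHANNEL,
    max_shift: float = 10.0,
    max_rotation: float = 5.0,
    quality_floor: float = 0.2,
) -> MultiplexImage:
    """Register round 2 onto round 1 and merge the stacks.

    Round-2 channels are resampled into the round-1 frame; channel names
    already present in round 1 are kept from round 1 (the nuclear channel,
    re-imaged every round, is the usual duplicate).  The estimated transform,
    NCC quality, and a low-quality flag are recorded in the output metadata.
    """
    for img, label in ((round1, "round1"), (round2, "round2")):
        if nuclei_channel not in img:
            raise KeyError(f"{label} has no {nuclei_channel!r} channel")
    result = estimate_rigid_transform(
        round1[nuclei_channel],
        round2[nuclei_channel],
        max_shift=max_shift,
        max_rotation=max_rotation,
        quality_floor=quality_floor,
    )
    warped, validity = apply_transform(round2, result.transform.inverse())
    merged = {name: ch.copy() for name, ch in round1.channels.items()}
    for name, ch in warped.channels.items():
        if name not in merged:
            merged[name] = ch
    meta = dict(round1.metadata)
    meta.update(
        round_transform=result.transform,
        registration_quality=result.quality,
        registration_low_quality=result.low_quality,
        validity=validity,
    )
    return MultiplexImage(merged, round_id=round1.round_id, metadata=meta)
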