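"""Synthetic widefield micrographs with ground truth.

Every downstream stage of the pipeline is validated against images produced
here: isolated diffraction-limited spots, fields of multi-spectral fiducial
beads seen in two channels through a chromatic warp, and two-color
"nucleus" scenes of paired transcription foci at known separations.

Rendering model: each emitter contributes ``photons`` expected photons
distributed as a 2D Gaussian of standard deviation ``s = 0.21 λ / NA``,
*integrated over each pixel* (error-function differences). A uniform
background of ``b`` expected photons/pixel is added, Poisson shot noise
applied, the result multiplied by the camera gain, Gaussian read noise added
on the count scale, and counts rounded and clipped at zero. With
``shot_noise=False`` the expected (noise-free, unrounded) image is returned
instead, which serves as the exact oracle for the fitters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Emitter, FrameGeometry, Image, NoiseModel, OpticsModel, PositionError
from .localize import _axis_pixel_integrals, theoretical_width

__all__ = [
    "ChannelWarp",
    "GroundTruth",
    "render_spot",
    "render_frame",
    "render_bead_field",
    "render_nucleus_scene",
    "make_colocalized_pairs",
]


@dataclass(frozen=True)
class ChannelWarp:
    """Smooth map from true positions to their apparent position in channel B.

    Parameterized as translation + rotation about the frame center + low
    order polynomial terms: for position (x, y) nm relative to the frame
    center (xc, yc),

        dx = tx + (cos r - 1) x - sin r * y + qxx x^2 + qxy x y + qyy y^2
        dy = ty + sin r * x + (cos r - 1) y + rxx x^2 + rxy x y + ryy y^2

    Quadratic coefficients are in nm^-1. Keep displacements small relative
    to the frame so the map stays invertible.
    """

    tx_nm: float = 0.0
    ty_nm: float = 0.0
    rotation_rad: float = 0.0
    quad_x: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (qxx, qxy, qyy)
    quad_y: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_nm: tuple[float, float] = (0.0, 0.0)

    def displacement(self, positions_nm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(positions_nm, dtype=float))
        x = p[:, 0] - self.center_nm[0]
        y = p[:, 1] - self.center_nm[1]
        c, s = math.cos(self.rotation_rad), math.sin(self.rotation_rad)
        qx, qy = self.quad_x, self.quad_y
        dx = self.tx_nm + (c - 1) * x - s * y + qx[0] * x**2 + qx[1] * x * y + qx[2] * y**2
        dy = self.ty_nm + s * x + (c - 1) * y + qy[0] * x**2 + qy[1] * x * y + qy[2] * y**2
        return np.column_stack([dx, dy])

    def apply(self, positions_nm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(positions_nm, dtype=float))
        return p + self.displacement(p)

    def max_displacement(self, frame: FrameGeometry, grid: int = 21) -> float:
        """Largest displacement magnitude over a grid spanning the frame."""
        xs = np.linspace(0, frame.width_nm, grid)
        ys = np.linspace(0, frame.height_nm, grid)
        xx, yy = np.meshgrid(xs, ys)
        d = self.displacement(np.column_stack([xx.ravel(), yy.ravel()]))
        return float(np.hypot(d[:, 0], d[:, 1]).max())

    @classmethod
    def identity(cls) -> "ChannelWarp":
        return cls()

    @classmethod
    def translation(cls, tx_nm: float, ty_nm: float) -> "ChannelWarp":
        return cls(tx_nm=tx_nm, ty_nm=ty_nm)

    @classmethod
    def random_quadratic(
        cls,
        frame: FrameGeometry,
        max_displacement_nm: float,
        rng: np.random.Generator,
        translation_fraction: float = 0.4,
    ) -> "ChannelWarp":
        """A random translation + quadratic field scaled so the largest
        displacement over the frame equals ``max_displacement_nm``."""
        cx, cy = frame.width_nm / 2.0, frame.height_nm / 2.0
        t = rng.uniform(-1, 1, size=2) * translation_fraction * max_displacement_nm
        half = max(cx, cy)
        q = rng.uniform(-1, 1, size=6) / half**2  # order-1 displacement at edge
        warp = cls(tx_nm=float(t[0]), ty_nm=float(t[1]),
                   quad_x=tuple(q[:3]), quad_y=tuple(q[3:]),
                   center_nm=(cx, cy))
        m = warp.max_displacement(frame)
        if m == 0:
            return warp
        scale = max_displacement_nm / m
        return cls(tx_nm=warp.tx_nm * scale, ty_nm=warp.ty_nm * scale,
                   quad_x=tuple(v * scale for v in warp.quad_x),
                   quad_y=tuple(v * scale for v in warp.quad_y),
                   center_nm=(cx, cy))


@dataclass
class GroundTruth:
    """What was actually rendered: emitters per channel, warp and seed."""

    emitters: dict[str, list[Emitter]] = field(default_factory=dict)
    warp: Optional[ChannelWarp] = None
    seed: Optional[int] = None
    true_separations_nm: list[float] = field(default_factory=list)

    def positions(self, channel_id: str) -> np.ndarray:
        ems = self.emitters.get(channel_id, [])
        if not ems:
            return np.empty((0, 2))
        return np.array([[e.x_nm, e.y_nm] for e in ems])


def _expected_signal(emitters: Sequence[Emitter], frame: FrameGeometry,
                     s_nm: float) -> np.ndarray:
    xe, ye = frame.x_edges_nm(), frame.y_edges_nm()
    img = np.zeros((frame.height_px, frame.width_px))
    for e in emitters:
        ix = _axis_pixel_integrals(xe, e.x_nm, s_nm)
        iy = _axis_pixel_integrals(ye, e.y_nm, s_nm)
        img += e.photons * np.outer(iy, ix)
    return img


def _apply_camera(expected_photons: np.ndarray, noise: NoiseModel,
                  rng: np.random.Generator, shot_noise: bool) -> np.ndarray:
    if not shot_noise:
        return expected_photons * noise.gain_counts_per_photon
    counts = rng.poisson(expected_photons).astype(float)
    counts *= noise.gain_counts_per_photon
    if noise.read_noise_e > 0:
        counts += rng.normal(0.0, noise.read_noise_e, size=counts.shape)
    return np.clip(np.rint(counts), 0, None)


def render_frame(
    emitters: Sequence[Emitter],
    frame: FrameGeometry,
    optics: OpticsModel,
    noise: NoiseModel,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    shot_noise: bool = True,
    channel_id: str = "A",
    margin_sigmas: float = 3.0,
) -> Image:
    """Render any number of emitters into one channel frame."""
    s = theoretical_width(optics.wavelength_nm, optics.numerical_aperture)
    m = margin_sigmas * s
    for e in emitters:
        if not (m <= e.x_nm <= frame.width_nm - m and m <= e.y_nm <= frame.height_nm - m):
            raise PositionError(
                f"emitter at ({e.x_nm:.0f}, {e.y_nm:.0f}) nm closer than "
                f"{margin_sigmas} PSF widths to the frame edge")
    expected = _expected_signal(emitters, frame, s) + noise.background_photons_per_px
    if rng is None:
        rng = np.random.default_rng(seed)
    data = _apply_camera(expected, noise, rng, shot_noise)
    return Image(data=data, frame=frame, optics=optics, camera=noise,
                 channel_id=channel_id)


def render_spot(
    emitter: Emitter,
    frame: FrameGeometry,
    optics: OpticsModel,
    noise: NoiseModel,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    shot_noise: bool = True,
) -> Image:
    """Render a single isolated spot. See the module docstring for the model."""
    return render_frame([emitter], frame, optics, noise, seed=seed, rng=rng,
                        shot_noise=shot_noise, channel_id=emitter.channel_id)


def _sample_positions(n: int, frame: FrameGeometry, min_sep_nm: float,
                      margin_nm: float, rng: np.random.Generator,
                      max_tries: int = 20000) -> np.ndarray:
    pts: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(pts) == n:
            break
        cand = np.array([
            rng.uniform(margin_nm, frame.width_nm - margin_nm),
            rng.uniform(margin_nm, frame.height_nm - margin_nm),
        ])
        if all(np.hypot(*(cand - p)) >= min_sep_nm for p in pts):
            pts.append(cand)
    if len(pts) < n:
        raise RuntimeError(f"could not place {n} positions {min_sep_nm} nm apart")
    return np.array(pts)


def render_bead_field(
    n_beads: int,
    warp: ChannelWarp,
    frame: FrameGeometry,
    optics_per_channel: dict[str, OpticsModel],
    noise: NoiseModel,
    seed: int,
    photons: float = 20000.0,
    shot_noise: bool = True,
) -> tuple[dict[str, Image], GroundTruth]:
    """Render the same beads in two channels, channel B through the warp.

    Multi-spectral fiducial beads appear at identical true positions in both
    channels; chromatic aberration displaces their apparent channel-B
    positions by the warp. Beads closer than four PSF widths are resampled
    so every bead can be fitted as an isolated spot.
    """
    if n_beads < 15:
        raise ValueError("need at least 15 beads (>=12 fiducials plus hold-out)")
    if set(optics_per_channel) != {"A", "B"}:
        raise ValueError("optics_per_channel must have channels 'A' and 'B'")
    rng = np.random.default_rng(seed)
    s_max = max(theoretical_width(o.wavelength_nm, o.numerical_aperture)
                for o in optics_per_channel.values())
    margin = 4.0 * s_max
    true_pos = _sample_positions(n_beads, frame, 4.0 * s_max, margin, rng)
    apparent_b = warp.apply(true_pos)
    gt = GroundTruth(warp=warp, seed=seed)
    gt.emitters["A"] = [Emitter(x, y, photons, "A") for x, y in true_pos]
    gt.emitters["B"] = [Emitter(x, y, photons, "B") for x, y in apparent_b]
    images = {}
    for ch in ("A", "B"):
        images[ch] = render_frame(
            gt.emitters[ch], frame, optics_per_channel[ch], noise,
            rng=rng, shot_noise=shot_noise, channel_id=ch)
    return images, gt


def make_colocalized_pairs(
    n_pairs: int,
    separation_nm: float,
    frame: FrameGeometry,
    photons: float,
    rng: np.random.Generator,
    min_pair_spacing_nm: float = 2000.0,
    margin_nm: float = 1000.0,
) -> list[tuple[Emitter, Emitter, float]]:
    """Lay out two-color emitter pairs at a fixed true separation.

    Pair centers are spread so neighboring pairs stay isolated; the
    separation axis is drawn uniformly at random per pair.
    """
    centers = _sample_positions(n_pairs, frame, min_pair_spacing_nm, margin_nm, rng)
    out = []
    for cx, cy in centers:
        ang = rng.uniform(0, 2 * math.pi)
        dx = 0.5 * separation_nm * math.cos(ang)
        dy = 0.5 * separation_nm * math.sin(ang)
        a = Emitter(cx - dx, cy - dy, photons, "A")
        b = Emitter(cx + dx, cy + dy, photons, "B")
        out.append((a, b, float(separation_nm)))
    return out


def render_nucleus_scene(
    pairs: Sequence[tuple[Emitter, Emitter, float]],
    frame: FrameGeometry,
    optics_per_channel: dict[str, OpticsModel],
    noise: NoiseModel,
    warp: ChannelWarp,
    seed: int,
    shot_noise: bool = True,
    min_pair_spacing_nm: Optional[float] = None,
) -> tuple[dict[str, Image], GroundTruth]:
    """Render a two-color scene of paired transcription foci.

    Each pair is one allele seen in both channels: channel A and channel B
    emitters at a stated true separation. Channel-B emitters are rendered at
    their warp-displaced apparent positions; the ground truth keeps the true
    geometry so downstream recovery can be scored.
    """
    if set(optics_per_channel) != {"A", "B"}:
        raise ValueError("optics_per_channel must have channels 'A' and 'B'")
    s_max = max(theoretical_width(o.wavelength_nm, o.numerical_aperture)
                for o in optics_per_channel.values())
    if min_pair_spacing_nm is None:
        min_pair_spacing_nm = 8.0 * s_max
    centers = []
    for a, b, sep in pairs:
        if sep < 0:
            raise ValueError("separations must be non-negative")
        d = math.hypot(a.x_nm - b.x_nm, a.y_nm - b.y_nm)
        if not math.isclose(d, sep, rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError(f"stated separation {sep} nm does not match "
                             f"emitter geometry ({d:.3f} nm)")
        centers.append(((a.x_nm + b.x_nm) / 2, (a.y_nm + b.y_nm) / 2))
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if math.hypot(centers[i][0] - centers[j][0],
                          centers[i][1] - centers[j][1]) < min_pair_spacing_nm:
                raise PositionError(f"pairs {i} and {j} overlap "
                                    f"(closer than {min_pair_spacing_nm:.0f} nm)")
    rng = np.random.default_rng(seed)
    gt = GroundTruth(warp=warp, seed=seed,
                     true_separations_nm=[sep for _, _, sep in pairs])
    gt.emitters["A"] = [a for a, _, _ in pairs]
    true_b = np.array([[b.x_nm, b.y_nm] for _, b, _ in pairs])
    if len(true_b):
        apparent_b = warp.apply(true_b)
    else:
        apparent_b = true_b
    gt.emitters["B"] = [Emitter(x, y, b.photons, "B")
                        for (x, y), (_, b, _) in zip(apparent_b, pairs)]
    images = {}
    for ch in ("A", "B"):
        images[ch] = render_frame(
            gt.emitters[ch], frame, optics_per_channel[ch], noise,
            rng=rng, shot_noise=shot_noise, channel_id=ch)
    return images, gt
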