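"""Chromatic registration of color channels from fiducial bead fields.

Multi-spectral beads are imaged in both channels; the displacement between
the apparent positions of the same bead measures the local inter-channel
misalignment. A local-weighted-mean (LWM) transform built from at least 12
fiducial pairs maps channel-B coordinates into the channel-A frame: around
each control point a second-order polynomial map is fitted to its k nearest
control pairs, and a query point is corrected by the distance-weighted mean
of the surrounding local maps. For speed the correction field is evaluated
on a coarse grid and bilinearly interpolated; a direct (gridless) evaluator
is kept for validation.

The residual misalignment ``r`` — the RMS distance between corrected
channel-B and channel-A positions of *held-out* beads — is the part of the
chromatic error the correction does not remove, and must be propagated into
every two-color distance uncertainty downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .core import NanofishError

__all__ = [
    "FiducialPair",
    "RegistrationModel",
    "InsufficientFiducialsError",
    "match_fiducials",
    "build_lwm_transform",
    "apply_transform",
    "residual_error",
]


class InsufficientFiducialsError(NanofishError):
    """Fewer matched bead pairs than the transform requires."""


class DegenerateGeometryError(NanofishError):
    """Fiducial geometry too degenerate (e.g. collinear) for a local fit."""


@dataclass(frozen=True)
class FiducialPair:
    """One bead seen in both channels (positions in nm)."""

    position_a: tuple[float, float]
    position_b: tuple[float, float]
    pair_quality: float = 1.0


def _poly2_design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, y, x * y, x**2, y**2])


#: the transform refuses to build from fewer matched bead pairs than this
MIN_FIDUCIALS = 12

#: default neighbors per local polynomial fit; a 6-coefficient quadratic map
#: fitted to barely more points than coefficients near-interpolates each
#: bead's localization noise, so the default smooths over 20 neighbors
#: (clamped to the number of control pairs, never below MIN_FIDUCIALS)
DEFAULT_K = 20


@dataclass
class RegistrationModel:
    """LWM transform from channel-B coordinates to the channel-A frame."""

    pairs: list[FiducialPair]
    k: int = DEFAULT_K
    grid_pitch_px: int = 8
    pixel_size_nm: float = 200.0
    residual_nm: float = float("nan")
    method: str = "grid"  # "grid" (bilinear between grid nodes) or "direct"
    # fitted state
    _centers: np.ndarray = field(default=None, repr=False)
    _coeffs: np.ndarray = field(default=None, repr=False)
    _radii: np.ndarray = field(default=None, repr=False)
    _interp: object = field(default=None, repr=False)
    _bbox: tuple = field(default=None, repr=False)
    extrapolation_warnings: int = 0

    #: Gaussian falloff of the query blending weights, in units of each
    #: local map's neighborhood radius
    query_falloff: float = 0.5

    # -- evaluation ---------------------------------------------------------
    def _direct_eval(self, q: np.ndarray) -> np.ndarray:
        """Weighted mean of local polynomial maps at query points (n, 2)."""
        d = np.linalg.norm(q[:, None, :] - self._centers[None, :, :], axis=2)
        w = np.exp(-((d / (self.query_falloff * self._radii[None, :])) ** 2))
        # guard: far outside the fiducial cloud all weights underflow
        far = w.sum(axis=1) <= 1e-300
        if far.any():
            nearest = np.argmin(d[far], axis=1)
            w[far, :] = 0.0
            w[far, nearest] = 1.0
        w /= w.sum(axis=1, keepdims=True)
        # local map m evaluated at q in its centered, radius-scaled frame
        u = (q[:, None, :] - self._centers[None, :, :]) / self._radii[None, :, None]
        X = np.stack([np.ones(d.shape), u[..., 0], u[..., 1],
                      u[..., 0] * u[..., 1], u[..., 0] ** 2, u[..., 1] ** 2],
                     axis=2)  # (n, m, 6)
        vals = np.einsum("nmj,mjc->nmc", X, self._coeffs)
        return np.einsum("nm,nmc->nc", w, vals)

    def transform(self, positions_nm: np.ndarray) -> np.ndarray:
        """Map channel-B positions into the channel-A frame."""
        q = np.atleast_2d(np.asarray(positions_nm, dtype=float))
        if self.method == "direct" or self._interp is None:
            return self._direct_eval(q)
        (x0, x1), (y0, y1) = self._bbox
        inside = ((q[:, 0] >= x0) & (q[:, 0] <= x1) &
                  (q[:, 1] >= y0) & (q[:, 1] <= y1))
        out = np.empty_like(q)
        if inside.any():
            pts = np.column_stack([q[inside, 1], q[inside, 0]])  # (y, x) order
            out[inside, 0] = self._interp[0](pts)
            out[inside, 1] = self._interp[1](pts)
        if (~inside).any():
            self.extrapolation_warnings += int((~inside).sum())
            out[~inside] = self._direct_eval(q[~inside])
        return out


def match_fiducials(
    positions_a: np.ndarray,
    positions_b: np.ndarray,
    max_pair_dist_nm: float = 500.0,
    min_pairs: int = 12,
) -> list[FiducialPair]:
    """Pair bead localizations across channels.

    The median displacement (first-pass nearest neighbors) is subtracted
    from channel B, then mutual nearest neighbors within
    ``max_pair_dist_nm`` are kept. Deterministic: pairs are returned in
    channel-A order.
    """
    pa = np.atleast_2d(np.asarray(positions_a, dtype=float))
    pb = np.atleast_2d(np.asarray(positions_b, dtype=float))
    if len(pa) == 0 or len(pb) == 0:
        raise InsufficientFiducialsError("empty bead list")
    tree_b = cKDTree(pb)
    _, idx = tree_b.query(pa)
    shift = np.median(pb[idx] - pa, axis=0)
    pb_shifted = pb - shift
    tree_b = cKDTree(pb_shifted)
    tree_a = cKDTree(pa)
    d_ab, nn_ab = tree_b.query(pa)
    _, nn_ba = tree_a.query(pb_shifted)
    pairs: list[FiducialPair] = []
    for ia, (ib, dist) in enumerate(zip(nn_ab, d_ab)):
        if nn_ba[ib] == ia and dist <= max_pair_dist_nm:
            pairs.append(FiducialPair(tuple(pa[ia]), tuple(pb[ib])))
    if len(pairs) < min_pairs:
        raise InsufficientFiducialsError(
            f"only {len(pairs)} matched pairs; need at least {min_pairs}")
    return pairs


def build_lwm_transform(
    pairs: Sequence[FiducialPair],
    k: int = DEFAULT_K,
    grid_pitch_px: int = 8,
    pixel_size_nm: float = 200.0,
    method: str = "grid",
) -> RegistrationModel:
    """Fit the local-weighted-mean transform to matched fiducial pairs.

    Each control point's local map is a full second-order polynomial in
    (x, y) fitted by weighted least squares to its ``k`` nearest control
    pairs (clamped to the number of pairs), with Gaussian weights whose
    scale is the k-th neighbor distance. At least ``MIN_FIDUCIALS``
    matched pairs are required throughout the image.
    """
    pairs = list(pairs)
    if len(pairs) < MIN_FIDUCIALS:
        raise InsufficientFiducialsError(
            f"{len(pairs)} pairs < required minimum {MIN_FIDUCIALS}")
    pb = np.array([p.position_b for p in pairs])
    pa = np.array([p.position_a for p in pairs])
    tree = cKDTree(pb)
    n = len(pairs)
    kk = min(k, n)
    coeffs = np.empty((n, 6, 2))
    radii = np.empty(n)
    for m in range(n):
        d, idx = tree.query(pb[m], k=kk)
        rk = float(d[-1])
        if rk <= 0:
            rk = 1.0
        radii[m] = rk
        w = np.exp(-((d / rk) ** 2))
        u = (pb[idx] - pb[m]) / rk  # centered, scaled for conditioning
        X = _poly2_design(u[:, 0], u[:, 1])
        sw = np.sqrt(w)[:, None]
        Xw = X * sw
        if np.linalg.matrix_rank(Xw) < 6:
            raise DegenerateGeometryError(
                "fiducial neighborhood is degenerate (collinear beads?)")
        sol, *_ = np.linalg.lstsq(Xw, pa[idx] * sw, rcond=None)
        coeffs[m] = sol
    model = RegistrationModel(pairs=pairs, k=k, grid_pitch_px=grid_pitch_px,
                              pixel_size_nm=pixel_size_nm, method=method)
    model._centers = pb
    model._coeffs = coeffs
    model._radii = radii
    if method == "grid":
        pitch = grid_pitch_px * pixel_size_nm
        pad = 2 * pitch
        x0, x1 = pb[:, 0].min() - pad, pb[:, 0].max() + pad
        y0, y1 = pb[:, 1].min() - pad, pb[:, 1].max() + pad
        nx = max(int(math.ceil((x1 - x0) / pitch)) + 1, 2)
        ny = max(int(math.ceil((y1 - y0) / pitch)) + 1, 2)
        xs = np.linspace(x0, x1, nx)
        ys = np.linspace(y0, y1, ny)
        xx, yy = np.meshgrid(xs, ys)
        nodes = np.column_stack([xx.ravel(), yy.ravel()])
        vals = model._direct_eval(nodes)
        fx = vals[:, 0].reshape(ny, nx)
        fy = vals[:, 1].reshape(ny, nx)
        model._interp = (
            RegularGridInterpolator((ys, xs), fx, method="linear",
                                    bounds_error=False, fill_value=None),
            RegularGridInterpolator((ys, xs), fy, method="linear",
                                    bounds_error=False, fill_value=None),
        )
        model._bbox = ((x0, x1), (y0, y1))
    return model


def apply_transform(model: RegistrationModel,
                    positions_nm: np.ndarray) -> np.ndarray:
    """Correct channel-B positions into the channel-A frame.

    Queries outside the fiducial bounding box are evaluated directly and
    counted in ``model.extrapolation_warnings``. The transform is not a
    projection, so applying it twice does not equal applying it once.
    """
    return model.transform(positions_nm)


def residual_error(model: RegistrationModel,
                   heldout_pairs: Sequence[FiducialPair]) -> float:
    """Residual misalignment r on held-out beads (RMS, nm); stored in the model."""
    heldout_pairs = list(heldout_pairs)
    if not heldout_pairs:
        raise ValueError("hold-out set is empty")
    pb = np.array([p.position_b for p in heldout_pairs])
    pa = np.array([p.position_a for p in heldout_pairs])
    corrected = model.transform(pb)
    r = float(np.sqrt(np.mean(np.sum((corrected - pa) ** 2, axis=1))))
    model.residual_nm = r
    return r


# -- serialization ----------------------------------------------------------

def save_model(model: RegistrationModel, path: str | Path) -> None:
    """Write the control pairs plus a metadata header as TSV."""
    lines = [
        f"# nanofish registration model",
        f"# k\t{model.k}",
        f"# grid_pitch_px\t{model.grid_pitch_px}",
        f"# pixel_size_nm\t{model.pixel_size_nm}",
        f"# residual_nm\t{model.residual_nm}",
        f"# method\t{model.method}",
        "x_a_nm\ty_a_nm\tx_b_nm\ty_b_nm",
    ]
    for p in model.pairs:
        lines.append(f"{p.position_a[0]:.6f}\t{p.position_a[1]:.6f}"
                     f"\t{p.position_b[0]:.6f}\t{p.position_b[1]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> RegistrationModel:
    """Rebuild a registration model from a serialized control-pair table."""
    meta: dict[str, str] = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
        elif line and not line.startswith("x_a_nm"):
            rows.append([float(v) for v in line.split("\t")])
    pairs = [FiducialPair((r[0], r[1]), (r[2], r[3])) for r in rows]
    model = build_lwm_transform(
        pairs,
        k=int(meta.get("k", DEFAULT_K)),
        grid_pitch_px=int(meta.get("grid_pitch_px", 8)),
        pixel_size_nm=float(meta.get("pixel_size_nm", 200.0)),
        method=meta.get("method", "grid"),
    )
    model.residual_nm = float(meta.get("residual_nm", "nan"))
    return model
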