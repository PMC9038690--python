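"""Ground-truth-labelled synthetic inputs for the quantification and
statistics stages.

:func:`gen_wedge_colony` emulates a two-channel colony tile scan as a
label raster: a producer-dominated disk punctuated by wedge-shaped
consumer sectors that persist to the expansion edge (spatial jackpots),
optional interior consumer blobs that stop short of the edge, optional
concentric banding that pinches wedge widths, and salt-and-pepper label
noise.  The returned ground truth is sufficient to recompute every
expected metric analytically.

:func:`gen_two_phase_series` produces replicate metric trajectories with
a continuous two-phase linear mean (steep then shallow) plus Gaussian
noise, floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice_domain import CONSUMER, EMPTY, PRODUCER
from .quantify import DEFAULT_PIXEL_SIZE_UM, ColonyRaster

__all__ = ["WedgeColonyTruth", "gen_wedge_colony", "gen_two_phase_series"]


class InvalidConfigurationError(ValueError):
    pass


def _wrap(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


@dataclass
class WedgeColonyTruth:
    """Exact construction record of a synthetic colony."""

    radius_px: int
    pixel_size_um: float
    wedges: list[tuple[float, float]]  # (centre angle, full width), rad
    interior_blobs: list[tuple[float, float]]
    wedge_inner_frac: float
    blob_radial_range: tuple[float, float]
    band_pattern: list[tuple[float, float]]
    pinch_factor: float
    label_noise_rate: float
    seed: int

    @property
    def jackpot_count(self) -> int:
        return len(self.wedges)

    @property
    def total_wedge_angle(self) -> float:
        return sum(w for _, w in self.wedges)

    @property
    def expected_edge_ratio(self) -> float:
        """Consumer:producer area ratio in any full annulus near the edge."""
        theta = self.total_wedge_angle
        return theta / (2 * np.pi - theta)

    @property
    def expected_boundary_count(self) -> int:
        """Label transitions on a circle crossing all wedges (2 per wedge)."""
        return 2 * len(self.wedges)


def _check_disjoint(sectors: list[tuple[float, float]]) -> None:
    for i, (c1, w1) in enumerate(sectors):
        for c2, w2 in sectors[i + 1 :]:
            if abs(_wrap(c1 - c2)) < (w1 + w2) / 2.0:
                raise InvalidConfigurationError("overlapping wedges/blobs")


def gen_wedge_colony(
    radius_px: int = 300,
    n_jackpots: int = 3,
    wedge_angles: list[tuple[float, float]] | None = None,
    interior_blobs: int = 0,
    band_pattern: list[tuple[float, float]] | None = None,
    label_noise_rate: float = 0.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int = 0,
    wedge_inner_frac: float = 0.35,
    blob_radial_range: tuple[float, float] = (0.3, 0.65),
    pinch_factor: float = 0.5,
    wedge_width_range: tuple[float, float] = (0.15, 0.35),
) -> tuple[ColonyRaster, WedgeColonyTruth]:
    """Generate a disk colony with consumer wedges and full ground truth.

    ``wedge_angles`` fixes the jackpot sectors explicitly as
    (centre angle, full width) pairs in radians; otherwise
    ``n_jackpots`` non-overlapping sectors are drawn at random.
    ``band_pattern`` lists (r_lo_frac, r_hi_frac) annuli inside which
    wedge widths are multiplied by ``pinch_factor`` (concentric
    anoxic/oxic banding).  ``label_noise_rate`` flips occupied pixels
    between the two strains independently.
    """
    if not 0.0 <= label_noise_rate < 1.0:
        raise InvalidConfigurationError("noise rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    if wedge_angles is not None:
        wedges = [(float(c), float(w)) for c, w in wedge_angles]
    else:
        wedges = []
        for _ in range(n_jackpots):
            for _attempt in range(1000):
                c = rng.uniform(-np.pi, np.pi)
                w = rng.uniform(*wedge_width_range)
                if all(abs(_wrap(c - c2)) >= (w + w2) / 2.0 + 0.05 for c2, w2 in wedges):
                    wedges.append((c, w))
                    break
            else:  # pragma: no cover - would need an absurd request
                raise InvalidConfigurationError("could not place non-overlapping wedges")
    _check_disjoint(wedges)

    blobs: list[tuple[float, float]] = []
    for _ in range(interior_blobs):
        for _attempt in range(1000):
            c = rng.uniform(-np.pi, np.pi)
            w = rng.uniform(*wedge_width_range)
            if all(
                abs(_wrap(c - c2)) >= (w + w2) / 2.0 + 0.05 for c2, w2 in wedges + blobs
            ):
                blobs.append((c, w))
                break
        else:  # pragma: no cover
            raise InvalidConfigurationError("could not place non-overlapping blobs")

    n = 2 * radius_px + 1
    rows, cols = np.indices((n, n))
    dy = rows - radius_px
    dx = cols - radius_px
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    labels = np.where(r <= radius_px, PRODUCER, EMPTY).astype(np.uint8)

    def paint_sector(center_angle, width, r_lo, r_hi):
        half = width / 2.0
        in_band = np.ones_like(r, dtype=bool)
        if band_pattern:
            # pinch: inside each band annulus the effective half-width shrinks
            half_map = np.full_like(r, half)
            for lo, hi in band_pattern:
                band = (r >= lo * radius_px) & (r <= hi * radius_px)
                half_map[band] = half * pinch_factor
            sel = (
                (np.abs(_wrap(theta - center_angle)) <= half_map)
                & (r >= r_lo)
                & (r <= r_hi)
            )
        else:
            sel = (
                (np.abs(_wrap(theta - center_angle)) <= half)
                & (r >= r_lo)
                & (r <= r_hi)
            )
        labels[sel & (labels != EMPTY) & in_band] = CONSUMER

    for c, w in wedges:
        paint_sector(c, w, wedge_inner_frac * radius_px, radius_px + 1)
    for c, w in blobs:
        paint_sector(c, w, blob_radial_range[0] * radius_px, blob_radial_range[1] * radius_px)

    if label_noise_rate > 0:
        occ = labels != EMPTY
        flip = occ & (rng.random(labels.shape) < label_noise_rate)
        labels[flip] = np.where(labels[flip] == PRODUCER, CONSUMER, PRODUCER)

    raster = ColonyRaster(labels, pixel_size_um, center=(float(radius_px), float(radius_px)))
    truth = WedgeColonyTruth(
        radius_px=radius_px,
        pixel_size_um=pixel_size_um,
        wedges=wedges,
        interior_blobs=blobs,
        wedge_inner_frac=wedge_inner_frac,
        blob_radial_range=blob_radial_range,
        band_pattern=list(band_pattern or []),
        pinch_factor=pinch_factor,
        label_noise_rate=label_noise_rate,
        seed=seed,
    )
    return raster, truth


def gen_two_phase_series(
    n_replicates: int,
    n_transitions: int,
    slope1: float,
    slope2: float,
    breakpoint: int,
    start_value: float,
    noise_sd: float,
    seed: int = 0,
    floor: bool = True,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Replicate series with a continuous two-phase linear mean.

    Returns ``(x, y, truth)`` where ``x`` has shape (n_transitions,),
    ``y`` has shape (n_replicates, n_transitions), and ``truth`` records
    the generating parameters.  The mean follows ``slope1`` up to the
    breakpoint (an interior x value) and ``slope2`` after it; Gaussian
    noise with ``noise_sd`` is added independently, and values are
    floored at zero by default (ratios and indices are non-negative).
    """
    if noise_sd < 0:
        raise InvalidConfigurationError("noise_sd must be >= 0")
    x = np.arange(1, n_transitions + 1, dtype=float)
    if not x[0] < breakpoint < x[-1]:
        raise InvalidConfigurationError(
            f"breakpoint {breakpoint} must lie strictly inside [{x[0]}, {x[-1]}]"
        )
    rng = np.random.default_rng(seed)
    mean = start_value + slope1 * np.minimum(x - x[0], breakpoint - x[0])
    mean = mean + slope2 * np.maximum(x - breakpoint, 0.0)
    y = mean[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, n_transitions))
    if floor:
        np.maximum(y, 0.0, out=y)
    truth = {
        "slope1": slope1,
        "slope2": slope2,
        "breakpoint": breakpoint,
        "start_value": start_value,
        "noise_sd": noise_sd,
        "mean": mean,
    }
    return x, y, truth
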