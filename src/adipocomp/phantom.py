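"""Synthetic multi-echo phantom with SAT/VAT-like depots and known truth.

The phantom stands in for abdominal images: a subcutaneous-like outer ring
and visceral-like interior blobs on each slice, with spatially smooth truth
fields for NDB, fat fraction and R2*.  A deliberate one-voxel partial-volume
rim is placed on each depot boundary (reduced fat fraction, biased NDB) so
that the mask-erosion and fat-fraction-filter post-processing steps have real
contamination to remove.  Geometry is crude on purpose: segmentation itself
is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .protocol import AcquisitionProtocol, DEFAULT_PROTOCOL
from .spectrum import NMIDB_COEFF
from .signal import model_signal


@dataclass(frozen=True)
class DepotTruth:
    """Truth-field distribution for one depot: mean/SD pairs.

    NDB means default to values consistent with adipose fSFA around
    0.44 (SAT) and 0.47 (VAT); smoothness is the Gaussian-filter sigma (in
    voxels) applied to the spatial noise field.
    """

    ndb_mean: float
    ndb_sd: float = 0.2
    ff_mean: float = 0.9
    ff_sd: float = 0.03
    r2star_mean: float = 40.0
    r2star_sd: float = 8.0
    smoothness: float = 2.0


@dataclass(frozen=True)
class PhantomSpec:
    grid: tuple[int, int, int] = (96, 96, 6)
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 6.0)
    sat: DepotTruth = field(default_factory=lambda: DepotTruth(ndb_mean=2.1))
    vat: DepotTruth = field(
        default_factory=lambda: DepotTruth(ndb_mean=1.9, ff_mean=0.85, r2star_mean=45.0)
    )
    #: SAT annulus radii and VAT blob semi-axes, in voxels.
    sat_radii: tuple[float, float] = (34.0, 39.0)
    vat_axes: tuple[float, float] = (10.0, 7.0)
    #: partial-volume rim parameters applied to a 1-voxel boundary layer
    rim_ff: float = 0.15
    rim_ndb_bias: float = 0.8
    noise_sd: float = 0.0
    background_r2star: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.sat, self.vat):
            if not 0 < d.ndb_mean <= 6:
                raise ValueError("truth ndb mean must lie in (0, 6]")
            if not 0 <= d.ff_mean <= 1:
                raise ValueError("fat fraction mean must lie in [0, 1]")
        if self.sat_radii[0] >= self.sat_radii[1]:
            raise ValueError("sat annulus needs inner radius < outer radius")


@dataclass
class TruthMaps:
    """Ground-truth volumes; NMIDB honours the empirical constraint."""

    ndb: np.ndarray
    nmidb: np.ndarray
    fat_fraction: np.ndarray
    r2star: np.ndarray
    sat_mask: np.ndarray
    vat_mask: np.ndarray
    rim_mask: np.ndarray
    affine: np.ndarray

    @property
    def union_mask(self) -> np.ndarray:
        return self.sat_mask | self.vat_mask


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0]).astype(float)
    return aff


def _smooth_field(rng, grid, mean, sd, sigma):
    noise = rng.standard_normal(grid)
    if sigma > 0:
        noise = gaussian_filter(noise, sigma=sigma)
        s = noise.std()
        if s > 0:
            noise = noise / s
    return mean + sd * noise


def make_phantom(spec: PhantomSpec) -> TruthMaps:
    """Generate depot masks and truth fields; deterministic given spec.seed."""
    nx, ny, nz = spec.grid
    rng = np.random.default_rng(spec.seed)
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r = np.hypot(x - cx, y - cy)
    sat2d = (r >= spec.sat_radii[0]) & (r <= spec.sat_radii[1])
    a, b = spec.vat_axes
    vat2d = (
        ((x - cx + 12) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0
    ) | (((x - cx - 12) / a) ** 2 + ((y - cy + 6) / b) ** 2 <= 1.0)
    vat2d &= ~sat2d
    sat_mask = np.repeat(sat2d[:, :, None], nz, axis=2)
    vat_mask = np.repeat(vat2d[:, :, None], nz, axis=2)
    for name, m in (("sat", sat_mask), ("vat", vat_mask)):
        if m.sum() < 100:
            raise ValueError(f"degenerate geometry: {name} mask below 100 voxels")
    if np.any(sat_mask & vat_mask):  # guaranteed disjoint by construction
        raise ValueError("depot masks overlap")

    structure = np.zeros((3, 3, 1), dtype=bool)
    structure[:, :, 0] = True
    rim = np.zeros(spec.grid, dtype=bool)
    for m in (sat_mask, vat_mask):
        interior = binary_erosion(m, structure=structure)
        rim |= m & ~interior

    ndb = np.zeros(spec.grid)
    ff = np.zeros(spec.grid)
    r2 = np.full(spec.grid, spec.background_r2star, dtype=float)
    for m, d in ((sat_mask, spec.sat), (vat_mask, spec.vat)):
        ndb_f = _smooth_field(rng, spec.grid, d.ndb_mean, d.ndb_sd, d.smoothness)
        ff_f = _smooth_field(rng, spec.grid, d.ff_mean, d.ff_sd, d.smoothness)
        r2_f = _smooth_field(
            rng, spec.grid, d.r2star_mean, d.r2star_sd, d.smoothness
        )
        ndb[m] = np.clip(ndb_f[m], 0.2, 5.3)
        ff[m] = np.clip(ff_f[m], 0.0, 1.0)
        r2[m] = np.clip(r2_f[m], 1.0, 200.0)
    # partial-volume contamination on the 1-voxel boundary layer
    ff[rim] = spec.rim_ff
    ndb[rim] = np.clip(ndb[rim] + spec.rim_ndb_bias, 0.2, 5.9)
    nmidb = NMIDB_COEFF * ndb**2
    return TruthMaps(
        ndb=ndb,
        nmidb=nmidb,
        fat_fraction=ff,
        r2star=r2,
        sat_mask=sat_mask,
        vat_mask=vat_mask,
        rim_mask=rim,
        affine=_affine(spec.voxel_size),
    )


def render_multiecho(
    truth: TruthMaps,
    protocol: AcquisitionProtocol = DEFAULT_PROTOCOL,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    total_amplitude: float = 100.0,
) -> np.ndarray:
    """Render the multi-echo volume from truth maps (echo axis last).

    Per voxel the water/fat amplitudes are ``total_amplitude`` split by the
    truth fat fraction; voxels outside the depot masks are water-only.  With
    ``noise_sd > 0`` independent complex Gaussian noise is added per voxel
    and echo before taking the magnitude (Rician).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    water = total_amplitude * (1.0 - truth.fat_fraction)
    fat = total_amplitude * truth.fat_fraction
    out = model_signal(water, fat, truth.ndb, truth.r2star, protocol)
    # model_signal returns echo axis first; move it last
    out = np.moveaxis(out, 0, -1)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        # noiseless magnitude has arbitrary global phase; Rician noise on a
        # real-valued mean is distributionally identical
        re = out + rng.normal(0.0, noise_sd, out.shape)
        im = rng.normal(0.0, noise_sd, out.shape)
        out = np.hypot(re, im)
    return out
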