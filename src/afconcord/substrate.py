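"""Synthetic virtual-patient substrates and ECGI-like observations.

Patient atria enter the analysis through two channels that this module
emulates statistically:

* a patchy fibrosis distribution (in the clinic: LGE-MRI segmentation) —
  generated here as a thresholded Gaussian random field with a controlled
  fibrotic fraction ("burden") and spatial correlation length;
* a region-level set of RD-harboring regions observed during a mapped AF
  episode (in the clinic: ECGI phase mapping over ~15 s) — generated from
  the latent simulated RD regions by keeping each with probability
  ``p_manifest`` and adding each non-latent region with probability
  ``p_extra``.  This encodes the mechanistic expectation that clinically
  mapped RDs are a partial, noisy view: some fibrosis-capable sites never
  manifest, and some clinical RDs are sustained by mechanisms other than
  the fibrotic substrate.

The 7-zone region template mirrors the clinical anatomical scheme
(left/right PVs, posterior LA, superior/inferior RA, anterior LA,
inter-atrial groove) as a fixed 2x3 tiling plus a central vertical band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tissue import TissueGrid

#: fraction of sheet width given to the central inter-atrial-groove band
IAG_BAND_FRACTION = 0.1


def generate_fibrosis_map(grid: TissueGrid, density: float,
                          correlation_length: float = 5.0,
                          seed: int = 0) -> np.ndarray:
    """Patchy boolean fibrosis map with an exact realized fraction.

    A white-noise field is smoothed with a Gaussian kernel of standard
    deviation ``correlation_length`` (mm) and thresholded at its empirical
    (1 - density) quantile over conductive nodes, so the realized fibrotic
    fraction equals ``density`` up to single-node quantization regardless
    of the seed.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    if correlation_length < grid.dx:
        raise ValueError("correlation_length must be >= dx")
    out = np.zeros((grid.ny, grid.nx), dtype=bool)
    if density == 0.0:
        return out
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((grid.ny, grid.nx))
    field = ndimage.gaussian_filter(noise, sigma=correlation_length / grid.dx,
                                    mode="reflect")
    cond = grid.conductive
    if density == 1.0:
        out[cond] = True
        return out
    thr = np.quantile(field[cond], 1.0 - density)
    out[cond] = field[cond] > thr
    return out


def partition_regions(grid: TissueGrid) -> np.ndarray:
    """Deterministic 7-zone template over the sheet.

    A central vertical band (~10% of columns) forms zone 7, the
    inter-atrial-groove analog.  The left half (the "left atrium" side)
    is split into vertical thirds: zones 1 (left PVs, top), 3 (posterior
    LA, middle), 6 (anterior LA, bottom); the right half likewise into
    zones 2 (right PVs, top), 4 (superior RA, middle), 5 (inferior RA,
    bottom).  Pure function of the grid shape.
    """
    ny, nx = grid.ny, grid.nx
    region = np.zeros((ny, nx), dtype=np.int32)
    band = max(1, int(round(IAG_BAND_FRACTION * nx)))
    left_w = (nx - band) // 2
    band_lo = left_w
    band_hi = left_w + band
    thirds = [0, ny // 3, (2 * ny) // 3, ny]
    left_zones = (1, 3, 6)
    right_zones = (2, 4, 5)
    for k in range(3):
        sl = slice(thirds[k], thirds[k + 1])
        region[sl, :band_lo] = left_zones[k]
        region[sl, band_hi:] = right_zones[k]
    region[:, band_lo:band_hi] = 7
    region[~grid.conductive] = 0
    return region


@dataclass(frozen=True)
class VirtualPatient:
    """A synthetic fibrotic substrate with its generating parameters."""

    patient_id: object
    grid: TissueGrid
    fibrosis_burden: float
    seed: int


def make_virtual_patient(patient_id, density: float,
                         nx: int = 120, ny: int = 120, dx: float = 0.5,
                         correlation_length: float = 5.0, seed: int = 0,
                         d_long: float = 0.1, anisotropy: float = 0.25,
                         fibrosis_d_factor: float = 0.5,
                         fiber_angle: float = 0.0) -> VirtualPatient:
    """Build a virtual patient: sheet + fibrosis + region labels."""
    grid = TissueGrid.uniform(nx, ny, dx=dx, d_long=d_long,
                              anisotropy=anisotropy, fiber_angle=fiber_angle)
    fib = generate_fibrosis_map(grid, density, correlation_length, seed)
    grid = grid.with_fibrosis(fib, d_factor=fibrosis_d_factor)
    grid.region_id = partition_regions(grid)
    realized = float(fib[grid.conductive].mean()) if grid.n_conductive else 0.0
    return VirtualPatient(patient_id=patient_id, grid=grid,
                          fibrosis_burden=realized, seed=seed)


@dataclass(frozen=True)
class EcgiObservation:
    """Region-level RD observations from a synthetic mapped AF episode."""

    patient_id: object
    observed_regions: frozenset
    window_s: float
    p_manifest: float
    p_extra: float
    seed: int

    def __post_init__(self):
        if not set(self.observed_regions) <= set(range(1, 8)):
            raise ValueError("observed regions must be within 1..7")


def generate_ecgi_observation(latent_regions, p_manifest: float = 0.7,
                              p_extra: float = 0.1, seed: int = 0,
                              patient_id=None,
                              window_s: float = 15.0) -> EcgiObservation:
    """Sample the clinically observed RD-region set from the latent set.

    Each latent (fibrosis-capable) region manifests independently with
    probability ``p_manifest``; each non-latent region contributes a
    non-fibrosis-mediated RD independently with probability ``p_extra``.
    Deterministic given the seed.
    """
    for p in (p_manifest, p_extra):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    latent = set(latent_regions)
    if not latent <= set(range(1, 8)):
        raise ValueError("latent regions must be within 1..7")
    rng = np.random.default_rng(seed)
    observed = set()
    for r in range(1, 8):  # fixed iteration order for determinism
        u = rng.random()
        p = p_manifest if r in latent else p_extra
        if u < p:
            observed.add(r)
    return EcgiObservation(patient_id=patient_id,
                           observed_regions=frozenset(observed),
                           window_s=window_s, p_manifest=p_manifest,
                           p_extra=p_extra, seed=seed)


def estimate_observation_params(latents, observations) -> tuple[float, float]:
    """Binomial MLEs of (p_manifest, p_extra) from an ensemble.

    ``latents`` and ``observations`` are parallel sequences of region sets;
    the MLEs are the pooled observed fractions of latent and non-latent
    regions respectively.
    """
    n_lat = k_lat = n_non = k_non = 0
    for lat, obs in zip(latents, observations):
        lat = set(lat)
        obs = set(obs if not isinstance(obs, EcgiObservation)
                  else obs.observed_regions)
        for r in range(1, 8):
            if r in lat:
                n_lat += 1
                k_lat += r in obs
            else:
                n_non += 1
                k_non += r in obs
    if n_lat == 0 or n_non == 0:
        raise ValueError("need both latent and non-latent regions to estimate")
    return k_lat / n_lat, k_non / n_non


def mean_patch_area(fibrosis: np.ndarray, dx: float) -> float:
    """Mean connected-component area (mm²) of a fibrosis map."""
    lab, n = ndimage.label(fibrosis)
    if n == 0:
        return 0.0
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
    return float(sizes.mean() * dx * dx)
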