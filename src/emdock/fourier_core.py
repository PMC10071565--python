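"""Map <-> Fourier-space bookkeeping.

Real-space maps are held on orthogonal cubic-voxel grids treated as P1 boxes.
The forward transform uses the convention

    F(h) = sum_x rho(x) exp(-2 pi i h . x),

with x fractional in the box, which is exactly ``numpy.fft.fftn``.  All
signal/noise analysis downstream works on a Hermitian-unique half-set of
Fourier terms; because the maps are real, F(-h) = conj(F(h)) and the half-set
carries the full information content.
"""

from __future__ import annotations

import dataclasses
import warnings

import gemmi
import numpy as np

__all__ = [
    "MapGrid",
    "FourierTermSet",
    "OversamplingInfo",
    "read_map",
    "write_map",
    "map_to_fourier",
    "fourier_to_map",
    "extract_sphere",
    "oversampling_factor",
    "gaussian_atom_density",
]


@dataclasses.dataclass
class MapGrid:
    """Real-space map on a cubic-voxel grid.

    Parameters
    ----------
    values : (nx, ny, nz) float array
        Voxel values; axis 0 is x, axis 1 is y, axis 2 is z.
    voxel_size : float
        Voxel edge length in Angstrom (cubic voxels only).
    origin : (3,) int array
        Grid origin offset in voxels (MRC NXSTART-style).
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3, dtype=int))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=int)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3-D array")
        if min(self.values.shape) < 2:
            raise ValueError("grid must have at least 2 voxels per axis")
        if not self.voxel_size > 0:
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def box(self) -> np.ndarray:
        """Box edge lengths in Angstrom."""
        return np.asarray(self.shape, dtype=float) * self.voxel_size

    @property
    def box_volume(self) -> float:
        return float(np.prod(self.box))

    def copy(self) -> "MapGrid":
        return MapGrid(self.values.copy(), self.voxel_size, self.origin.copy())


@dataclasses.dataclass
class FourierTermSet:
    """Hermitian-unique set of Fourier terms of a real map.

    ``hkl`` holds signed integer indices, ``f`` the complex coefficients and
    ``s`` the inverse resolution |h*| in 1/Angstrom.  ``cell`` is the P1 box
    (a, b, c) and ``grid_shape`` the sampling the terms were computed on,
    needed to re-embed the terms for an inverse transform.
    """

    hkl: np.ndarray
    f: np.ndarray
    s: np.ndarray
    cell: np.ndarray
    grid_shape: tuple
    hermitian_half: bool = True

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=np.int32)
        self.f = np.asarray(self.f, dtype=np.complex128)
        self.s = np.asarray(self.s, dtype=np.float64)
        self.cell = np.asarray(self.cell, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.f)

    @property
    def n_terms(self) -> int:
        return len(self.f)

    def with_f(self, f: np.ndarray) -> "FourierTermSet":
        """Same index set, new coefficients."""
        return FourierTermSet(self.hkl, np.asarray(f, dtype=np.complex128),
                              self.s, self.cell, self.grid_shape,
                              self.hermitian_half)

    def select(self, mask: np.ndarray) -> "FourierTermSet":
        return FourierTermSet(self.hkl[mask], self.f[mask], self.s[mask],
                              self.cell, self.grid_shape, self.hermitian_half)

    def to_table(self, path) -> None:
        """Export as MTZ-style tabular text: h k l re im s."""
        data = np.column_stack([self.hkl,
                                self.f.real, self.f.imag, self.s])
        np.savetxt(path, data, fmt="%6d %6d %6d %16.8e %16.8e %12.6f",
                   header="h k l re im s")


@dataclasses.dataclass
class OversamplingInfo:
    """Volume ratio correcting LLG/eLLG/information sums for oversampling."""

    ordered_volume: float
    box_volume: float

    def __post_init__(self):
        if not 0 < self.ordered_volume <= self.box_volume:
            raise ValueError(
                "ordered volume must be positive and not exceed box volume")

    @property
    def factor(self) -> float:
        return self.ordered_volume / self.box_volume


def oversampling_factor(ordered_volume: float, box_volume: float) -> float:
    """Ratio of particle volume to reconstruction box volume, in (0, 1]."""
    return OversamplingInfo(ordered_volume, box_volume).factor


# ---------------------------------------------------------------------------
# Map I/O (MRC/CCP4 via gemmi)

def read_map(path) -> MapGrid:
    """Read an MRC/CCP4 map.  Values are taken as stored (no filtering).

    Anisotropic voxel spacings are rejected: resampling would silently change
    the error model.
    """
    m = gemmi.read_ccp4_map(str(path))
    grid = m.grid
    arr = np.array(grid, copy=True).astype(np.float64)
    cell = grid.unit_cell
    vox = np.array([cell.a / arr.shape[0], cell.b / arr.shape[1],
                    cell.c / arr.shape[2]])
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise ValueError("only orthogonal (P1 box) maps are supported")
    if np.ptp(vox) > 1e-4 * vox.mean():
        raise ValueError(
            f"anisotropic voxel size {vox} not supported (no resampling)")
    if len(set(arr.shape)) > 1:
        warnings.warn(f"non-cubic map grid {arr.shape}", UserWarning)
    origin = np.array([m.header_i32(5), m.header_i32(6), m.header_i32(7)])
    return MapGrid(arr, float(vox.mean()), origin)


def write_map(map_grid: MapGrid, path) -> None:
    """Write a MapGrid as a mode-2 (float32) CCP4/MRC map."""
    g = gemmi.FloatGrid(np.ascontiguousarray(
        map_grid.values.astype(np.float32)))
    a, b, c = map_grid.box
    g.unit_cell = gemmi.UnitCell(a, b, c, 90, 90, 90)
    g.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for i, word in enumerate((5, 6, 7)):
        m.set_header_i32(word, int(map_grid.origin[i]))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# FFT bookkeeping

def _hkl_grids(shape):
    """Signed hkl index arrays for an fftn output of the given shape."""
    hs = [np.fft.fftfreq(n, 1.0 / n).astype(np.int64) for n in shape]
    return np.meshgrid(*hs, indexing="ij")


def halfset_mask(shape, include_origin: bool = True) -> np.ndarray:
    """Boolean mask over an fftn grid selecting one term per Friedel pair.

    The convention keeps (l > 0), the (l = 0, k > 0) half-plane and the
    (l = k = 0, h >= 0) half-axis.  Indices equal to -N/2 (even grids) have
    no Friedel mate on the grid and are excluded.
    """
    H, K, L = _hkl_grids(shape)
    mask = (L > 0) | ((L == 0) & (K > 0)) | ((L == 0) & (K == 0) & (H > 0))
    if include_origin:
        mask |= (H == 0) & (K == 0) & (L == 0)
    for G, n in zip((H, K, L), shape):
        if n % 2 == 0:
            mask &= G != -(n // 2)
    return mask


def map_to_fourier(map_grid: MapGrid, resolution_limit: float) -> FourierTermSet:
    """Forward FFT of a map, returning the Hermitian-unique half-set.

    Only terms with s = |h*| <= 1/resolution_limit are kept (plus the origin
    term, retained for exact map synthesis).  The resolution limit must be at
    least twice the voxel size (Nyquist).
    """
    if resolution_limit < 2.0 * map_grid.voxel_size:
        raise ValueError(
            f"resolution limit {resolution_limit} beyond Nyquist "
            f"{2 * map_grid.voxel_size}")
    F = np.fft.fftn(map_grid.values)
    shape = map_grid.shape
    H, K, L = _hkl_grids(shape)
    box = map_grid.box
    s = np.sqrt((H / box[0]) ** 2 + (K / box[1]) ** 2 + (L / box[2]) ** 2)
    mask = halfset_mask(shape) & (s <= 1.0 / resolution_limit + 1e-12)
    hkl = np.column_stack([H[mask], K[mask], L[mask]])
    return FourierTermSet(hkl, F[mask], s[mask], box, shape)


def embed_full_grid(terms: FourierTermSet, f=None) -> np.ndarray:
    """Place a half-set (and its Friedel mates) onto a full complex fftn grid."""
    if f is None:
        f = terms.f
    grid = np.zeros(terms.grid_shape, dtype=np.complex128)
    h, k, l = terms.hkl.T
    grid[h, k, l] = f
    grid[-h, -k, -l] = np.conj(f)
    return grid


def fourier_to_map(terms: FourierTermSet, voxel_size=None) -> MapGrid:
    """Inverse transform of the symmetry-expanded half-set to a real map."""
    grid = embed_full_grid(terms)
    values = np.fft.ifftn(grid).real
    if voxel_size is None:
        voxel_size = float(terms.cell[0] / terms.grid_shape[0])
    return MapGrid(values, voxel_size)


# ---------------------------------------------------------------------------
# Subvolume extraction

def extract_sphere(map_grid: MapGrid, centre, radius: float,
                   padding: float = 5.0, taper_voxels: float = 3.0) -> MapGrid:
    """Cut a soft-edged spherical subvolume into its own cubic box.

    ``centre`` is in Angstrom relative to the map's first voxel.  Values
    outside the sphere are zeroed with a cosine taper of width
    ``taper_voxels`` voxels just inside the radius, to limit spectral ringing
    from the cut.  The output box edge is ~2*(radius + padding).
    """
    centre = np.asarray(centre, dtype=float)
    vox = map_grid.voxel_size
    if np.any(centre - radius < 0) or np.any(centre + radius > map_grid.box):
        raise ValueError("sphere extends outside the map box")
    half = int(np.ceil((radius + padding) / vox))
    cidx = np.rint(centre / vox).astype(int)
    lo = cidx - half
    hi = cidx + half
    shape = np.asarray(map_grid.shape)
    # Clip to the parent grid; zero-pad if padding overruns the box edge.
    out = np.zeros((2 * half,) * 3, dtype=np.float64)
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(hi, shape)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
        map_grid.values[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1],
                        src_lo[2]:src_hi[2]]
    # Radial cosine taper about the (possibly off-grid) sphere centre.
    ax = (np.arange(2 * half) + lo[:, None]) * vox  # (3, 2*half)
    dx = ax[0] - centre[0]
    dy = ax[1] - centre[1]
    dz = ax[2] - centre[2]
    r = np.sqrt(dx[:, None, None] ** 2 + dy[None, :, None] ** 2
                + dz[None, None, :] ** 2)
    t = taper_voxels * vox
    w = np.ones_like(r)
    w[r > radius] = 0.0
    ramp = (r > radius - t) & (r <= radius)
    if t > 0:
        w[ramp] = 0.5 * (1 + np.cos(np.pi * (r[ramp] - (radius - t)) / t))
    return MapGrid(out * w, vox, origin=lo + map_grid.origin)


# ---------------------------------------------------------------------------
# Gaussian-atom density synthesis (shared by the synthetic generator and the
# model-transform pipeline)

def gaussian_atom_density(coords, weights, width, shape, voxel_size: float,
                          support_sigmas: float = 6.0) -> np.ndarray:
    """Rasterize isotropic Gaussian atoms onto a grid.

    Each atom contributes ``w * (2 pi sigma^2)^(-3/2) * exp(-r^2/(2 sigma^2))``
    evaluated at voxel centres, truncated at ``support_sigmas`` sigma.

    Parameters
    ----------
    coords : (n, 3) array, Angstrom
    weights : (n,) array or scalar — e.g. electron counts
    width : scalar or (n,) array — Gaussian sigma in Angstrom
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    weights = np.broadcast_to(np.asarray(weights, dtype=float), (n,))
    width = np.broadcast_to(np.asarray(width, dtype=float), (n,))
    rho = np.zeros(shape, dtype=np.float64)
    shape = np.asarray(shape)
    for x, w, sig in zip(coords, weights, width):
        rad = support_sigmas * sig
        lo = np.floor((x - rad) / voxel_size).astype(int)
        hi = np.ceil((x + rad) / voxel_size).astype(int) + 1
        if np.any(hi <= 0) or np.any(lo >= shape):
            raise ValueError("atom outside the map box")
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        ax = [np.arange(lo[i], hi[i]) * voxel_size - x[i] for i in range(3)]
        r2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        norm = w / (2 * np.pi * sig ** 2) ** 1.5
        rho[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += \
            norm * np.exp(-r2 / (2 * sig ** 2))
    return rho


def spherical_kernel(shape, radius: int) -> np.ndarray:
    """Binary sphere of the given index radius, laid out for circular
    convolution on an fftn grid (centre at index 0, wrap-around)."""
    k = np.zeros(shape)
    r = int(radius)
    rng = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    inside = dx ** 2 + dy ** 2 + dz ** 2 <= radius ** 2
    k[dx[inside] % shape[0], dy[inside] % shape[1],
      dz[inside] % shape[2]] = 1.0
    return k


def local_mean_field(values: np.ndarray, valid: np.ndarray,
                     radius: int) -> np.ndarray:
    """Mean of ``values`` over a spherical index neighbourhood, masked to
    ``valid`` terms; circular convolution over the fftn layout."""
    kernel_ft = np.fft.fftn(spherical_kernel(values.shape, radius))
    m = valid.astype(float)
    counts = np.fft.ifftn(np.fft.fftn(m) * kernel_ft).real
    summed = np.fft.ifftn(np.fft.fftn(values * m) * kernel_ft).real
    return summed / np.maximum(counts, 1e-9)


def shell_profile(s: np.ndarray, values: np.ndarray, bins: int = 40,
                  min_count: int = 8, floor: float = 1e-300):
    """Adaptive shell means: equal-count bins, but never wider in s than the
    band split into ``bins`` equal widths.

    The width cap matters at low resolution, where equal-count binning
    would lump terms spanning orders of magnitude of power into one bin.
    Returns (bin centres, mean values).
    """
    order = np.argsort(s, kind="stable")
    sv = s[order]
    vv = np.maximum(values[order], floor)
    max_width = (sv[-1] - sv[0]) / bins
    target = max(len(sv) // bins, min_count)
    centres, means = [], []
    start = 0
    while start < len(sv):
        stop = start + min_count
        while stop < len(sv) and (stop - start) < target \
                and (sv[stop - 1] - sv[start]) < max_width:
            stop += 1
        stop = min(stop, len(sv))
        centres.append(sv[start:stop].mean())
        means.append(max(vv[start:stop].mean(), floor))
        start = stop
    return np.array(centres), np.array(means)


def radial_trend(values: np.ndarray, s_grid: np.ndarray, valid: np.ndarray,
                 bins: int = 40, floor: float = 1e-300) -> np.ndarray:
    """Smooth radial profile of a positive field over an fftn grid.

    Adaptive shell means of ``values`` over the valid terms,
    log-interpolated in s.  Used to pre-whiten steeply varying fields
    before local (neighbourhood-mean) estimation: the arithmetic mean over
    a sphere badly overestimates the central value of a field that varies
    by orders of magnitude across the sphere.
    """
    centres, means = shell_profile(s_grid[valid], values[valid], bins=bins,
                                   floor=floor)
    log_trend = np.interp(s_grid, centres, np.log(means))
    return np.exp(log_trend)


def check_hermitian(map_grid: MapGrid, resolution_limit: float,
                    tol: float = 1e-8) -> bool:
    """Sanity check: a real map must satisfy F(-h) = conj(F(h))."""
    F = np.fft.fftn(map_grid.values)
    dev = np.abs(F - np.conj(F[tuple(-np.indices(F.shape))]))
    return bool(dev.max() <= tol * np.abs(F).max())
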