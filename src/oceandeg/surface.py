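"""Numerical molecular surface areas.

Two conventions are provided for a set of atomic spheres and a spherical
solvent probe (default radius 1.40 Å, i.e. water):

``solvent_accessible``
    Shrake–Rupley dot sampling of the surface traced by the *probe centre*
    rolling over the van der Waals spheres; area is measured on spheres of
    radius ``r_i + probe``.

``solvent_excluded``
    The Connolly-style molecular surface: the boundary of the region obtained
    by eroding the probe-expanded union of atom spheres by the probe ball.
    This includes the reentrant (probe-concave) patches that a contact-only
    dot surface misses.  It is evaluated on a voxel grid: a Euclidean
    distance transform locates the erosion level set, exact distances to a
    dense dot sample of the expanded-union boundary refine the field in a
    narrow band, and marching cubes extracts the triangulated area.

Both estimators converge as sampling density increases; at the defaults the
single-sphere error is below 1% and the default-vs-10x-cost agreement on
random many-atom geometries is well below 1%.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

#: Bondi (1964) van der Waals radii in Å, frozen for surface computation.
BONDI_RADII: dict[int, float] = {
    1: 1.20,   # H
    6: 1.70,   # C
    7: 1.55,   # N
    8: 1.52,   # O
    9: 1.47,   # F
    14: 2.10,  # Si
    15: 1.80,  # P
    16: 1.80,  # S
    17: 1.75,  # Cl
    35: 1.85,  # Br
}

DEFAULT_PROBE_RADIUS = 1.40  # Å, water probe


class DegenerateGeometryError(ValueError):
    """Raised when two atoms share (numerically) identical coordinates."""


def _check_geometry(coords: np.ndarray, radii: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"coords must be (n, 3), got {coords.shape}")
    if radii.shape != (coords.shape[0],):
        raise ValueError("radii must match the number of atoms")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    if np.any(radii <= 0):
        raise ValueError("atomic radii must be positive")
    if len(coords) > 1:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(1e-6)
        if pairs:
            i, j = sorted(pairs)[0]
            raise DegenerateGeometryError(
                f"atoms {i} and {j} have overlapping identical coordinates"
            )
    return coords, radii


def fibonacci_sphere(n_dots: int) -> np.ndarray:
    """Quasi-uniform unit-sphere sample (golden-spiral lattice)."""
    i = np.arange(n_dots) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n_dots)
    azim = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.cos(azim) * np.sin(polar), np.sin(azim) * np.sin(polar), np.cos(polar))
    )


def _accessible_dots(
    coords: np.ndarray, radii: np.ndarray, probe: float, n_dots: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom accessible fractions and the surviving boundary dot cloud.

    A dot on sphere i (radius ``r_i + probe``) survives when it lies outside
    every other expanded sphere; surviving dots sample the boundary of the
    probe-expanded union exactly.
    """
    dots = fibonacci_sphere(n_dots)
    expanded = radii + probe
    tree = cKDTree(coords)
    fractions = np.empty(len(coords))
    clouds = []
    r_max = expanded.max()
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * dots
        nbrs = [j for j in tree.query_ball_point(coords[i], expanded[i] + r_max) if j != i]
        if nbrs:
            d2 = ((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(axis=2)
            keep = np.all(d2 >= (expanded[nbrs] ** 2)[None, :] - 1e-9, axis=1)
            pts = pts[keep]
            fractions[i] = keep.mean()
        else:
            fractions[i] = 1.0
        clouds.append(pts)
    return fractions, np.vstack(clouds)


def solvent_accessible_area(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_dots: int = 960,
) -> float:
    """Shrake–Rupley solvent-accessible surface area in Å²."""
    coords, radii = _check_geometry(coords, radii)
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    fractions, _ = _accessible_dots(coords, radii, probe_radius, n_dots)
    expanded = radii + probe_radius
    return float(np.sum(fractions * 4.0 * np.pi * expanded**2))


def solvent_excluded_area(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_dots: int = 400,
    grid_spacing: float = 0.35,
) -> float:
    """Connolly-style solvent-excluded (molecular) surface area in Å².

    ``n_dots`` controls the boundary dot sample used to refine the distance
    field; ``grid_spacing`` (Å) sets the marching-cubes voxel size.
    """
    coords, radii = _check_geometry(coords, radii)
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive for the excluded surface")
    expanded = radii + probe_radius

    pad = probe_radius + 3 * grid_spacing
    lo = (coords - radii[:, None]).min(axis=0) - pad
    hi = (coords + radii[:, None]).max(axis=0) + pad
    dims = np.ceil((hi - lo) / grid_spacing).astype(int) + 2

    # binary occupancy of the probe-expanded union, one local box per atom
    grid = np.zeros(dims, dtype=bool)
    for centre, rad in zip(coords, expanded):
        i0 = np.maximum(np.floor((centre - rad - lo) / grid_spacing).astype(int), 0)
        i1 = np.minimum(np.ceil((centre + rad - lo) / grid_spacing).astype(int) + 1, dims)
        axes = [lo[k] + grid_spacing * np.arange(i0[k], i1[k]) for k in range(3)]
        d2 = (
            (axes[0][:, None, None] - centre[0]) ** 2
            + (axes[1][None, :, None] - centre[1]) ** 2
            + (axes[2][None, None, :] - centre[2]) ** 2
        )
        grid[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= rad * rad

    d_in = ndimage.distance_transform_edt(grid, sampling=grid_spacing)
    d_out = ndimage.distance_transform_edt(~grid, sampling=grid_spacing)
    phi = np.where(grid, d_in, -d_out)

    # exact distances to the union boundary in a band around the erosion level
    band = np.abs(phi - probe_radius) <= 2.0 * grid_spacing + 0.3
    band_idx = np.argwhere(band)
    band_pts = lo + band_idx * grid_spacing
    _, boundary = _accessible_dots(coords, radii, probe_radius, n_dots)
    dist, _ = cKDTree(boundary).query(band_pts, workers=-1)
    phi[band] = np.where(grid[band], dist, -dist)

    verts, faces, _, _ = measure.marching_cubes(
        phi, level=probe_radius, spacing=(grid_spacing,) * 3
    )
    return float(measure.mesh_surface_area(verts, faces))


def surface_area(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    convention: str = "solvent_excluded",
    **kwargs,
) -> float:
    """Dispatch on the surface convention ({'solvent_excluded', 'solvent_accessible'})."""
    if convention == "solvent_excluded":
        return solvent_excluded_area(coords, radii, probe_radius, **kwargs)
    if convention == "solvent_accessible":
        return solvent_accessible_area(coords, radii, probe_radius, **kwargs)
    raise ValueError(f"unknown surface convention: {convention!r}")
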