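"""Interior billiard ray-tracing over a triangulated molecular surface.

A ray is launched from the center of a randomly chosen contact element,
antiparallel to its outward normal, and propagated by specular reflection
with a small random perturbation (uniform within a cone around the ideal
reflected direction) that keeps the trajectory from locking into periodic
orbits.  Reflections are located with a uniform-grid acceleration structure:
each element is registered in the grid cubes containing its corners (one to
three cubes), the ray walks the cubes it passes through, and candidate
elements from the surrounding cubes are intersection-tested; the nearest
valid intersection ends the current segment.  If propagation fails (e.g. a
ray escapes through a numerically degenerate spot) the trace is truncated
and restarted from a fresh contact element.

Every reflection stores the interpolated surface potential and the fragment
of the element's primary atom; every segment is tagged intra- or
inter-fragment by the fragments of its two bounding reflections.  The whole
trace is deterministic for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .fragmenter import Fragmentation
from .surface import CONTACT, TriSurface

__all__ = [
    "AccelerationGrid",
    "Reflection",
    "RayTrace",
    "build_grid",
    "start_ray",
    "reflect",
    "next_reflection",
    "next_reflection_brute",
    "trace",
]

DEFAULT_N_SEGMENTS = 100_000
DEFAULT_CONE_ANGLE = 3.0  # degrees; the perturbation cone half-angle
DEFAULT_GRID_SPACING = 0.5  # Angstrom; correctness is spacing-independent
MIN_HIT_DISTANCE = 1e-6  # self-hit guard along the ray, Angstrom
MAX_CONSECUTIVE_FAILURES = 50


# ---------------------------------------------------------------------------
# Acceleration grid
# ---------------------------------------------------------------------------

@dataclass
class AccelerationGrid:
    """Uniform grid; each element registered in the cubes of its corners."""

    origin: np.ndarray  # (3,)
    spacing: float
    dims: np.ndarray  # (3,) int
    cell_start: np.ndarray  # (n_cells + 1,) CSR offsets
    cell_faces: np.ndarray  # face indices, concatenated per cell

    def cells_of_face(self, face: int) -> np.ndarray:
        hits = []
        for c in range(len(self.cell_start) - 1):
            block = self.cell_faces[self.cell_start[c] : self.cell_start[c + 1]]
            if face in block:
                hits.append(c)
        return np.array(hits)


def build_grid(surf: TriSurface, spacing: float = DEFAULT_GRID_SPACING) -> AccelerationGrid:
    """Assign every element to the grid cubes that contain its corners."""
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    vmin = surf.vertices.min(axis=0)
    vmax = surf.vertices.max(axis=0)
    origin = vmin - 0.5 * spacing
    dims = np.maximum(np.ceil((vmax - origin) / spacing).astype(np.int64) + 1, 1)

    corners = surf.vertices[surf.faces]  # (F, 3, 3)
    cells = np.floor((corners - origin) / spacing).astype(np.int64)
    np.clip(cells, 0, dims - 1, out=cells)
    linear = (cells[..., 0] * dims[1] + cells[..., 1]) * dims[2] + cells[..., 2]  # (F, 3)

    n_faces = surf.n_faces
    face_ids = np.repeat(np.arange(n_faces, dtype=np.int64), 3)
    flat = linear.ravel()
    # drop duplicate (cell, face) pairs so each face sits in 1-3 distinct cubes
    keys = flat * n_faces + face_ids
    _, unique_idx = np.unique(keys, return_index=True)
    flat = flat[unique_idx]
    face_ids = face_ids[unique_idx]

    order = np.argsort(flat, kind="stable")
    flat = flat[order]
    face_ids = face_ids[order]
    n_cells = int(dims[0] * dims[1] * dims[2])
    counts = np.bincount(flat, minlength=n_cells)
    cell_start = np.zeros(n_cells + 1, dtype=np.int64)
    np.cumsum(counts, out=cell_start[1:])
    return AccelerationGrid(
        origin=origin,
        spacing=float(spacing),
        dims=dims,
        cell_start=cell_start,
        cell_faces=face_ids,
    )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ray_tri(o, d, a, b, c, tmin):
    """Moller-Trumbore; returns (t, u, v) or t = inf when there is no hit."""
    e1x = b[0] - a[0]
    e1y = b[1] - a[1]
    e1z = b[2] - a[2]
    e2x = c[0] - a[0]
    e2y = c[1] - a[1]
    e2z = c[2] - a[2]
    px = d[1] * e2z - d[2] * e2y
    py = d[2] * e2x - d[0] * e2z
    pz = d[0] * e2y - d[1] * e2x
    det = e1x * px + e1y * py + e1z * pz
    if abs(det) < 1e-14:
        return np.inf, 0.0, 0.0
    inv = 1.0 / det
    sx = o[0] - a[0]
    sy = o[1] - a[1]
    sz = o[2] - a[2]
    u = (sx * px + sy * py + sz * pz) * inv
    if u < -1e-9 or u > 1.0 + 1e-9:
        return np.inf, 0.0, 0.0
    qx = sy * e1z - sz * e1y
    qy = sz * e1x - sx * e1z
    qz = sx * e1y - sy * e1x
    v = (d[0] * qx + d[1] * qy + d[2] * qz) * inv
    if v < -1e-9 or u + v > 1.0 + 1e-9:
        return np.inf, 0.0, 0.0
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    if t <= tmin:
        return np.inf, 0.0, 0.0
    return t, u, v


@njit(cache=True)
def _next_hit_brute(o, d, exclude, verts, faces, tmin):
    best_t = np.inf
    best_f = -1
    best_u = 0.0
    best_v = 0.0
    for f in range(faces.shape[0]):
        if f == exclude:
            continue
        t, u, v = _ray_tri(o, d, verts[faces[f, 0]], verts[faces[f, 1]], verts[faces[f, 2]], tmin)
        if t < best_t or (t == best_t and t < np.inf and f < best_f):
            best_t = t
            best_f = f
            best_u = u
            best_v = v
    return best_f, best_t, best_u, best_v


@njit(cache=True)
def _next_hit_grid(
    o,
    d,
    exclude,
    verts,
    faces,
    origin,
    spacing,
    dims,
    cell_start,
    cell_faces,
    stamps,
    qid,
    tmin,
):
    """Nearest intersection via 3D DDA over the corner-registered grid.

    Candidate elements are gathered from the 27-cube neighbourhood of every
    cube the ray passes through; with element edges no longer than the cube
    spacing this finds exactly the brute-force nearest hit.
    """
    best_t = np.inf
    best_f = -1
    best_u = 0.0
    best_v = 0.0

    cx = int(math.floor((o[0] - origin[0]) / spacing))
    cy = int(math.floor((o[1] - origin[1]) / spacing))
    cz = int(math.floor((o[2] - origin[2]) / spacing))
    cx = min(max(cx, 0), dims[0] - 1)
    cy = min(max(cy, 0), dims[1] - 1)
    cz = min(max(cz, 0), dims[2] - 1)

    step = np.empty(3, dtype=np.int64)
    tmax = np.empty(3)
    tdelta = np.empty(3)
    cell = np.empty(3, dtype=np.int64)
    cell[0], cell[1], cell[2] = cx, cy, cz
    for k in range(3):
        if d[k] > 1e-300:
            step[k] = 1
            bound = origin[k] + (cell[k] + 1) * spacing
            tmax[k] = (bound - o[k]) / d[k]
            tdelta[k] = spacing / d[k]
        elif d[k] < -1e-300:
            step[k] = -1
            bound = origin[k] + cell[k] * spacing
            tmax[k] = (bound - o[k]) / d[k]
            tdelta[k] = -spacing / d[k]
        else:
            step[k] = 0
            tmax[k] = np.inf
            tdelta[k] = np.inf

    while True:
        for ox in range(-1, 2):
            nx = cell[0] + ox
            if nx < 0 or nx >= dims[0]:
                continue
            for oy in range(-1, 2):
                ny = cell[1] + oy
                if ny < 0 or ny >= dims[1]:
                    continue
                for oz in range(-1, 2):
                    nz = cell[2] + oz
                    if nz < 0 or nz >= dims[2]:
                        continue
                    c = (nx * dims[1] + ny) * dims[2] + nz
                    for ii in range(cell_start[c], cell_start[c + 1]):
                        f = cell_faces[ii]
                        if f == exclude or stamps[f] == qid:
                            continue
                        stamps[f] = qid
                        t, u, v = _ray_tri(
                            o, d, verts[faces[f, 0]], verts[faces[f, 1]], verts[faces[f, 2]], tmin
                        )
                        if t < best_t or (t == best_t and t < np.inf and f < best_f):
                            best_t = t
                            best_f = f
                            best_u = u
                            best_v = v
        t_next = min(tmax[0], tmax[1], tmax[2])
        if best_f >= 0 and t_next > best_t:
            break
        # advance to the next cube along the ray
        if tmax[0] <= tmax[1] and tmax[0] <= tmax[2]:
            k = 0
        elif tmax[1] <= tmax[2]:
            k = 1
        else:
            k = 2
        if step[k] == 0:
            break
        cell[k] += step[k]
        if cell[k] < 0 or cell[k] >= dims[k]:
            break
        tmax[k] += tdelta[k]
    return best_f, best_t, best_u, best_v


@njit(cache=True)
def _next_hit_grid_aabb(
    o,
    d,
    exclude,
    verts,
    faces,
    origin,
    spacing,
    dims,
    cell_start,
    cell_faces,
    stamps,
    qid,
    tmin,
):
    """Nearest intersection over a grid with AABB-complete registration.

    Every element is registered in all cubes its bounding box overlaps, so
    only the cube currently holding the ray needs scanning; the result is
    identical to the brute-force nearest hit.
    """
    best_t = np.inf
    best_f = -1
    best_u = 0.0
    best_v = 0.0

    cell = np.empty(3, dtype=np.int64)
    for k in range(3):
        c = int(math.floor((o[k] - origin[k]) / spacing))
        cell[k] = min(max(c, 0), dims[k] - 1)
    step = np.empty(3, dtype=np.int64)
    tmax = np.empty(3)
    tdelta = np.empty(3)
    for k in range(3):
        if d[k] > 1e-300:
            step[k] = 1
            tmax[k] = (origin[k] + (cell[k] + 1) * spacing - o[k]) / d[k]
            tdelta[k] = spacing / d[k]
        elif d[k] < -1e-300:
            step[k] = -1
            tmax[k] = (origin[k] + cell[k] * spacing - o[k]) / d[k]
            tdelta[k] = -spacing / d[k]
        else:
            step[k] = 0
            tmax[k] = np.inf
            tdelta[k] = np.inf

    while True:
        c = (cell[0] * dims[1] + cell[1]) * dims[2] + cell[2]
        for ii in range(cell_start[c], cell_start[c + 1]):
            f = cell_faces[ii]
            if f == exclude or stamps[f] == qid:
                continue
            stamps[f] = qid
            t, u, v = _ray_tri(
                o, d, verts[faces[f, 0]], verts[faces[f, 1]], verts[faces[f, 2]], tmin
            )
            if t < best_t or (t == best_t and t < np.inf and f < best_f):
                best_t = t
                best_f = f
                best_u = u
                best_v = v
        t_next = min(tmax[0], tmax[1], tmax[2])
        if best_f >= 0 and t_next > best_t:
            break
        if tmax[0] <= tmax[1] and tmax[0] <= tmax[2]:
            k = 0
        elif tmax[1] <= tmax[2]:
            k = 1
        else:
            k = 2
        if step[k] == 0:
            break
        cell[k] += step[k]
        if cell[k] < 0 or cell[k] >= dims[k]:
            break
        tmax[k] += tdelta[k]
    return best_f, best_t, best_u, best_v


@njit(cache=True)
def _perturbed_reflection(d, n, cone_rad):
    """Specular reflection of d off outward normal n, cone-perturbed.

    The perturbation is uniform over the spherical cap of half-angle
    ``cone_rad`` around the ideal direction; candidates pointing back out of
    the surface are redrawn (the ideal direction is the fallback).
    """
    dn = d[0] * n[0] + d[1] * n[1] + d[2] * n[2]
    rx = d[0] - 2.0 * dn * n[0]
    ry = d[1] - 2.0 * dn * n[1]
    rz = d[2] - 2.0 * dn * n[2]
    if cone_rad <= 0.0:
        return rx, ry, rz
    # orthonormal basis around the ideal direction
    if abs(rx) < 0.9:
        ax, ay, az = 1.0, 0.0, 0.0
    else:
        ax, ay, az = 0.0, 1.0, 0.0
    e1x = ay * rz - az * ry
    e1y = az * rx - ax * rz
    e1z = ax * ry - ay * rx
    norm = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x /= norm
    e1y /= norm
    e1z /= norm
    e2x = ry * e1z - rz * e1y
    e2y = rz * e1x - rx * e1z
    e2z = rx * e1y - ry * e1x
    cos_cone = math.cos(cone_rad)
    for _ in range(20):
        cosa = 1.0 - np.random.random() * (1.0 - cos_cone)
        sina = math.sqrt(max(0.0, 1.0 - cosa * cosa))
        phi = 2.0 * math.pi * np.random.random()
        cx = rx * cosa + (e1x * math.cos(phi) + e2x * math.sin(phi)) * sina
        cy = ry * cosa + (e1y * math.cos(phi) + e2y * math.sin(phi)) * sina
        cz = rz * cosa + (e1z * math.cos(phi) + e2z * math.sin(phi)) * sina
        if cx * n[0] + cy * n[1] + cz * n[2] < -1e-9:
            return cx, cy, cz
    return rx, ry, rz


@njit(cache=True)
def _trace_kernel(
    verts,
    faces,
    normals,
    centers,
    face_mep,  # (F, 3) vertex MEPs per face corner
    contact_faces,
    n_segments,
    cone_rad,
    seed,
    origin,
    spacing,
    dims,
    cell_start,
    cell_faces,
    tmin,
    max_consecutive_failures,
    max_restarts,
):
    np.random.seed(seed)
    n_faces = faces.shape[0]
    cap = n_segments + max_restarts + 2
    positions = np.empty((cap, 3))
    elements = np.empty(cap, dtype=np.int64)
    meps = np.empty(cap)
    runs = np.empty(cap, dtype=np.int64)
    dirs = np.empty((cap, 3))
    stamps = np.full(n_faces, -1, dtype=np.int64)

    o = np.empty(3)
    d = np.empty(3)
    qid = 0
    n_ref = 0
    n_seg = 0
    n_run = 0
    consecutive_failures = 0
    status = 0  # 0 ok, 1 too many consecutive failures, 2 restart budget spent

    while n_seg < n_segments:
        if n_run > 0 and n_run > max_restarts:
            status = 2
            break
        f0 = contact_faces[np.random.randint(0, len(contact_faces))]
        for k in range(3):
            o[k] = centers[f0, k]
            d[k] = -normals[f0, k]
        positions[n_ref, 0] = o[0]
        positions[n_ref, 1] = o[1]
        positions[n_ref, 2] = o[2]
        elements[n_ref] = f0
        meps[n_ref] = (face_mep[f0, 0] + face_mep[f0, 1] + face_mep[f0, 2]) / 3.0
        runs[n_ref] = n_run
        dirs[n_ref, 0] = d[0]
        dirs[n_ref, 1] = d[1]
        dirs[n_ref, 2] = d[2]
        n_ref += 1
        run_len = 0
        prev = f0

        while n_seg < n_segments:
            qid += 1
            bf, bt, u, v = _next_hit_grid_aabb(
                o, d, prev, verts, faces, origin, spacing, dims,
                cell_start, cell_faces, stamps, qid, tmin,
            )
            if bf < 0:
                break
            hx = o[0] + bt * d[0]
            hy = o[1] + bt * d[1]
            hz = o[2] + bt * d[2]
            dn = d[0] * normals[bf, 0] + d[1] * normals[bf, 1] + d[2] * normals[bf, 2]
            if abs(dn) < 1e-12:
                break  # grazing incidence: restart
            nxv = normals[bf]
            ox_, oy_, oz_ = _perturbed_reflection(d, nxv, cone_rad)
            positions[n_ref, 0] = hx
            positions[n_ref, 1] = hy
            positions[n_ref, 2] = hz
            elements[n_ref] = bf
            meps[n_ref] = (
                (1.0 - u - v) * face_mep[bf, 0] + u * face_mep[bf, 1] + v * face_mep[bf, 2]
            )
            runs[n_ref] = n_run
            dirs[n_ref, 0] = ox_
            dirs[n_ref, 1] = oy_
            dirs[n_ref, 2] = oz_
            n_ref += 1
            n_seg += 1
            run_len += 1
            o[0], o[1], o[2] = hx, hy, hz
            d[0], d[1], d[2] = ox_, oy_, oz_
            prev = bf

        n_run += 1
        if run_len == 0:
            consecutive_failures += 1
            if consecutive_failures > max_consecutive_failures:
                status = 1
                break
        else:
            consecutive_failures = 0

    return (
        positions[:n_ref],
        elements[:n_ref],
        meps[:n_ref],
        runs[:n_ref],
        dirs[:n_ref],
        n_seg,
        n_run,
        status,
    )


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reflection:
    """A single ray/surface intersection."""

    position: np.ndarray
    element: int
    t: float
    barycentric: tuple[float, float]  # (u, v) toward corners 1 and 2
    mep: float | None = None
    primary_atom: int | None = None
    fragment: int | None = None


def start_ray(
    surf: TriSurface, rng: np.random.Generator, mode: str = "interior"
) -> tuple[np.ndarray, np.ndarray]:
    """Launch point and direction: a random contact element center, inward."""
    if mode != "interior":
        raise NotImplementedError(f"ray-trace mode {mode!r} is not implemented")
    if surf.face_class is None:
        raise ValueError("surface is not classified; run classify_elements")
    contact = np.flatnonzero(surf.face_class == CONTACT)
    if len(contact) == 0:
        raise ValueError("surface has no contact elements to launch from")
    f = int(contact[rng.integers(0, len(contact))])
    return surf.face_centers[f].copy(), -surf.face_normals[f].copy()


def reflect(
    d_in: np.ndarray,
    n: np.ndarray,
    cone_angle: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Specular reflection with an optional uniform cone perturbation.

    ``n`` is the unit normal facing the incoming ray (``d_in . n < 0``);
    with ``cone_angle == 0`` this is the exact mirror law.
    """
    d_in = np.asarray(d_in, dtype=float)
    n = np.asarray(n, dtype=float)
    dn = float(d_in @ n)
    if dn >= 0:
        raise ValueError("reflect expects the ray to approach the surface (d.n < 0)")
    if cone_angle < 0:
        raise ValueError("cone_angle must be >= 0")
    ideal = d_in - 2.0 * dn * n
    if cone_angle == 0.0:
        return ideal
    if rng is None:
        raise ValueError("a random generator is required when cone_angle > 0")
    cone = math.radians(cone_angle)
    if abs(ideal[0]) < 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    else:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, ideal)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(ideal, e1)
    for _ in range(20):
        cosa = 1.0 - rng.random() * (1.0 - math.cos(cone))
        sina = math.sqrt(max(0.0, 1.0 - cosa * cosa))
        phi = 2.0 * math.pi * rng.random()
        cand = ideal * cosa + (e1 * math.cos(phi) + e2 * math.sin(phi)) * sina
        if float(cand @ n) > 1e-9:  # stays on the incoming side's far half-space
            return cand
    return ideal


def _aabb_grid_arrays(surf: TriSurface, spacing: float):
    """Internal trace grid: faces registered in every cube their bounding box
    overlaps (complete for any element size, so a single-cube scan suffices)."""
    vmin = surf.vertices.min(axis=0)
    vmax = surf.vertices.max(axis=0)
    origin = vmin - 0.5 * spacing
    dims = np.maximum(np.ceil((vmax - origin) / spacing).astype(np.int64) + 1, 1)
    corners = surf.vertices[surf.faces]
    lo = np.floor((corners.min(axis=1) - origin) / spacing).astype(np.int64)
    hi = np.floor((corners.max(axis=1) - origin) / spacing).astype(np.int64)
    np.clip(lo, 0, dims - 1, out=lo)
    np.clip(hi, 0, dims - 1, out=hi)
    cells = []
    face_ids = []
    for f in range(surf.n_faces):
        for i in range(lo[f, 0], hi[f, 0] + 1):
            for j in range(lo[f, 1], hi[f, 1] + 1):
                for k in range(lo[f, 2], hi[f, 2] + 1):
                    cells.append((i * dims[1] + j) * dims[2] + k)
                    face_ids.append(f)
    cells = np.asarray(cells, dtype=np.int64)
    face_ids = np.asarray(face_ids, dtype=np.int64)
    order = np.argsort(cells, kind="stable")
    cells = cells[order]
    face_ids = face_ids[order]
    n_cells = int(dims[0] * dims[1] * dims[2])
    cell_start = np.zeros(n_cells + 1, dtype=np.int64)
    np.cumsum(np.bincount(cells, minlength=n_cells), out=cell_start[1:])
    return (
        np.ascontiguousarray(origin, dtype=np.float64),
        float(spacing),
        dims,
        cell_start,
        face_ids,
    )


def _grid_arrays(grid: AccelerationGrid):
    return (
        np.ascontiguousarray(grid.origin, dtype=np.float64),
        float(grid.spacing),
        np.ascontiguousarray(grid.dims, dtype=np.int64),
        np.ascontiguousarray(grid.cell_start, dtype=np.int64),
        np.ascontiguousarray(grid.cell_faces, dtype=np.int64),
    )


def _make_reflection(surf: TriSurface, f: int, t: float, point, direction, u, v) -> Reflection:
    pos = np.asarray(point, dtype=float) + t * np.asarray(direction, dtype=float)
    mep = None
    if surf.vertex_mep is not None:
        m = surf.vertex_mep[surf.faces[f]]
        mep = float((1.0 - u - v) * m[0] + u * m[1] + v * m[2])
    primary = int(surf.primary_atom[f]) if surf.primary_atom is not None else None
    return Reflection(
        position=pos,
        element=int(f),
        t=float(t),
        barycentric=(float(u), float(v)),
        mep=mep,
        primary_atom=primary,
    )


def next_reflection(
    grid: AccelerationGrid,
    surf: TriSurface,
    point: np.ndarray,
    direction: np.ndarray,
    exclude: int = -1,
) -> Reflection | None:
    """Nearest reflection ahead of ``point`` using the acceleration grid.

    Returns ``None`` on propagation failure (no intersection found).  The
    grid must have spacing at least the longest element edge for the cube
    walk to be exhaustive (``trace`` arranges this automatically).
    """
    o = np.ascontiguousarray(point, dtype=np.float64)
    d = np.ascontiguousarray(direction, dtype=np.float64)
    stamps = np.full(surf.n_faces, -1, dtype=np.int64)
    origin, spacing, dims, cell_start, cell_faces = _grid_arrays(grid)
    f, t, u, v = _next_hit_grid(
        o, d, exclude, surf.vertices, surf.faces, origin, spacing, dims,
        cell_start, cell_faces, stamps, 0, MIN_HIT_DISTANCE,
    )
    if f < 0:
        return None
    return _make_reflection(surf, f, t, o, d, u, v)


def next_reflection_brute(
    surf: TriSurface,
    point: np.ndarray,
    direction: np.ndarray,
    exclude: int = -1,
) -> Reflection | None:
    """Reference nearest-reflection search scanning every element."""
    o = np.ascontiguousarray(point, dtype=np.float64)
    d = np.ascontiguousarray(direction, dtype=np.float64)
    f, t, u, v = _next_hit_brute(o, d, exclude, surf.vertices, surf.faces, MIN_HIT_DISTANCE)
    if f < 0:
        return None
    return _make_reflection(surf, f, t, o, d, u, v)


@dataclass
class RayTrace:
    """Ordered reflections of a complete trace, plus derived segments."""

    positions: np.ndarray  # (K, 3) reflection points (run starts included)
    elements: np.ndarray  # (K,) element index per reflection
    meps: np.ndarray  # (K,) interpolated MEP per reflection
    run_ids: np.ndarray  # (K,) which restart-separated run
    directions: np.ndarray  # (K, 3) outgoing direction at each reflection
    fragments: np.ndarray  # (K,) fragment of the element's primary atom
    seed: int
    cone_angle: float  # degrees
    restart_count: int  # runs beyond the first

    segment_lengths: np.ndarray = field(init=False)
    segment_fragments: np.ndarray = field(init=False)  # (n, 2)

    def __post_init__(self) -> None:
        same_run = self.run_ids[1:] == self.run_ids[:-1]
        delta = self.positions[1:] - self.positions[:-1]
        self.segment_lengths = np.linalg.norm(delta, axis=1)[same_run]
        pairs = np.stack([self.fragments[:-1], self.fragments[1:]], axis=1)
        self.segment_fragments = pairs[same_run]

    @property
    def n_reflections(self) -> int:
        return len(self.positions)

    @property
    def n_segments(self) -> int:
        return len(self.segment_lengths)

    @property
    def n_runs(self) -> int:
        return self.restart_count + 1

    @property
    def intra_mask(self) -> np.ndarray:
        return self.segment_fragments[:, 0] == self.segment_fragments[:, 1]

    def interior_reflections(self) -> np.ndarray:
        """Indices of reflections with both an incoming and outgoing segment."""
        k = len(self.run_ids)
        idx = np.arange(1, k - 1)
        mask = (self.run_ids[idx] == self.run_ids[idx - 1]) & (
            self.run_ids[idx] == self.run_ids[idx + 1]
        )
        return idx[mask]

    def segment_counts(self) -> dict:
        """Segment tallies per fragment and unordered fragment pair."""
        intra: dict[int, int] = {}
        inter: dict[tuple[int, int], int] = {}
        for (a, b) in self.segment_fragments:
            a, b = int(a), int(b)
            if a == b:
                intra[a] = intra.get(a, 0) + 1
            else:
                key = (min(a, b), max(a, b))
                inter[key] = inter.get(key, 0) + 1
        return {"intra": intra, "inter": inter}

    def dump(self, path) -> None:
        """Tab-separated trace dump (positions, MEPs, fragments) for debugging."""
        import pandas as pd

        pd.DataFrame(
            {
                "run": self.run_ids,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "element": self.elements,
                "mep": self.meps,
                "fragment": self.fragments,
            }
        ).to_csv(path, sep="\t", index=False)


def trace(
    surf: TriSurface,
    frag: Fragmentation | None = None,
    n_segments: int = DEFAULT_N_SEGMENTS,
    cone_angle: float = DEFAULT_CONE_ANGLE,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    seed: int = 0,
    max_consecutive_failures: int = MAX_CONSECUTIVE_FAILURES,
) -> RayTrace:
    """Run a full interior ray-trace until ``n_segments`` segments are banked.

    The accelerated intersection search is exactly equivalent to a
    brute-force scan over all elements.  With ``frag`` omitted the whole
    molecule is treated as one fragment.
    """
    if surf.face_class is None or surf.primary_atom is None:
        raise ValueError("surface must be classified with primary atoms assigned")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    contact = np.flatnonzero(surf.face_class == CONTACT)
    if len(contact) == 0:
        raise ValueError("surface has no contact elements")

    if frag is None:
        face_frag = np.zeros(surf.n_faces, dtype=np.int64)
    else:
        face_frag = frag.atom_fragment[surf.primary_atom].astype(np.int64)
    vertex_mep = (
        surf.vertex_mep if surf.vertex_mep is not None else np.zeros(len(surf.vertices))
    )
    face_mep = np.ascontiguousarray(vertex_mep[surf.faces], dtype=np.float64)

    origin, spacing, dims, cell_start, cell_faces = _aabb_grid_arrays(
        surf, float(grid_spacing)
    )

    max_restarts = max(1000, n_segments // 10)
    positions, elements, meps, runs, dirs, n_seg, n_runs, status = _trace_kernel(
        surf.vertices,
        surf.faces,
        np.ascontiguousarray(surf.face_normals),
        np.ascontiguousarray(surf.face_centers),
        face_mep,
        contact.astype(np.int64),
        int(n_segments),
        math.radians(cone_angle),
        int(seed),
        origin,
        spacing,
        dims,
        cell_start,
        cell_faces,
        MIN_HIT_DISTANCE,
        int(max_consecutive_failures),
        int(max_restarts),
    )
    if status == 1:
        raise RuntimeError(
            "ray propagation failed repeatedly from fresh starts; "
            "the mesh is likely open or degenerate"
        )
    if status == 2:
        raise RuntimeError(
            "restart budget exhausted before reaching the requested segment "
            "count; the mesh is likely of poor quality"
        )
    return RayTrace(
        positions=positions,
        elements=elements,
        meps=meps,
        run_ids=runs,
        directions=dirs,
        fragments=face_frag[elements],
        seed=int(seed),
        cone_angle=float(cone_angle),
        restart_count=int(n_runs - 1),
    )
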