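"""Dendritic arbor representation, SWC I/O and morphometrics.

Arbors are planar rooted trees: dendritic-arborization dendrites tile the
2D epidermal sheet, so all coordinates live in the z = 0 plane (3D SWC
input is accepted with z dropped and a warning).

Morphometrics implemented here follow the conventions of the poking
experiments they support:

* *modified Sholl density* — intersections of the arbor with a soma-centred
  circle divided by that circle's circumference (units μm⁻¹), which for a
  mostly-radial planar arbor equals the local dendritic length per unit
  area;
* total dendritic length;
* distance-to-nearest-dendrite maps over the territory;
* stimulus-position sampling (proximal ~100 μm ring, distal ~200 μm ring,
  "dendrite-off" positions at a prescribed distance from any dendrite, and
  uniform positions over the territory disc).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Arbor",
    "ShollProfile",
    "DistanceMap",
    "SwcFormatError",
    "read_swc",
    "write_swc",
    "total_length",
    "sholl",
    "distance_map",
    "sample_stimulus_positions",
    "DEFAULT_TERRITORY_RADIUS",
]

#: default dendritic-territory radius (μm); the distal stimulus circle is
#: 200 μm, the territory disc extends slightly beyond it.
DEFAULT_TERRITORY_RADIUS: float = 220.0

ARBOR_CLASSES = ("c4da_wt", "c4da_cti", "c3da", "custom")


class SwcFormatError(ValueError):
    """Raised for malformed SWC files (cycles, multiple roots, bad parents)."""


@dataclass
class Arbor:
    """Planar dendritic tree.

    ``nodes`` is an (N, 2) array of xy positions in μm; ``parents`` holds the
    parent index of each node (-1 for the root).  Node 0 is the soma/root.
    Segments are the directed parent→child edges.
    """

    nodes: np.ndarray
    parents: np.ndarray
    class_label: str = "custom"
    radii: np.ndarray | None = None  # per-node SWC radii, μm (cosmetic)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 2)
        self.parents = np.asarray(self.parents, dtype=int)
        if self.class_label not in ARBOR_CLASSES:
            raise ValueError(f"unknown arbor class {self.class_label!r}")
        self._validate_tree()

    def _validate_tree(self) -> None:
        n = len(self.nodes)
        if len(self.parents) != n:
            raise SwcFormatError("parents array length mismatch")
        roots = np.flatnonzero(self.parents < 0)
        if len(roots) != 1 or roots[0] != 0:
            raise SwcFormatError(f"arbor must have exactly one root at index 0, got roots {roots}")
        if np.any(self.parents[1:] >= np.arange(1, n)):
            # topological order (parent before child) rules out cycles
            raise SwcFormatError("node parents must precede their children (cycle or bad index)")

    @property
    def soma(self) -> np.ndarray:
        """Soma position (root node), μm."""
        return self.nodes[0]

    @property
    def n_segments(self) -> int:
        return len(self.nodes) - 1

    def segments(self) -> np.ndarray:
        """(M, 2, 2) array of segment endpoints [start, end] in μm."""
        child = np.arange(1, len(self.nodes))
        return np.stack([self.nodes[self.parents[child]], self.nodes[child]], axis=1)

    def segment_lengths(self) -> np.ndarray:
        seg = self.segments()
        return np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1)

    def discretize(self, step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Split segments into sub-segments of length ≤ ``step``.

        Returns (midpoints (K, 2), lengths (K,)); used for overlaying field
        maps on the arbor.
        """
        if step <= 0:
            raise ValueError("discretization step must be positive")
        seg = self.segments()
        lens = np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1)
        pieces = np.maximum(1, np.ceil(lens / step).astype(int))
        mids, sublens = [], []
        for (p, q), L, k in zip(seg, lens, pieces):
            t = (np.arange(k) + 0.5) / k
            mids.append(p + t[:, None] * (q - p))
            sublens.append(np.full(k, L / k))
        return np.concatenate(mids), np.concatenate(sublens)

    def sample_points(self, spacing: float = 1.0) -> np.ndarray:
        """Points sampled along all segments at ≤ ``spacing`` (includes midpoints)."""
        return self.discretize(step=spacing)[0]


@dataclass
class ShollProfile:
    """Modified Sholl profile: ring radii, crossing counts, and density.

    density[i] = intersections[i] / (2π radii[i]) — crossings per μm of ring
    circumference.
    """

    radii: np.ndarray
    intersections: np.ndarray
    density: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.intersections = np.asarray(self.intersections, dtype=int)
        if np.any(self.radii <= 0):
            raise ValueError("Sholl ring radii must be positive")
        self.density = self.intersections / (2.0 * np.pi * self.radii)


@dataclass
class DistanceMap:
    """Gridded Euclidean distance (μm) to the nearest dendritic segment.

    ``values[i, j]`` is the distance at pixel centre
    (origin + (j·px, i·px)); the grid is square and centred on ``center``.
    """

    values: np.ndarray
    pixel_size: float
    center: np.ndarray  # world coordinates of the map centre (usually the soma)

    @property
    def extent(self) -> float:
        """Half-width of the map in μm."""
        return (self.values.shape[0] - 1) * self.pixel_size / 2.0

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """World x/y coordinates of pixel centres (1D each)."""
        n = self.values.shape[0]
        half = (n - 1) / 2.0
        offs = (np.arange(n) - half) * self.pixel_size
        return self.center[0] + offs, self.center[1] + offs


def read_swc(path: str | Path, class_label: str = "custom") -> Arbor:
    """Read a standard 7-column SWC file into an :class:`Arbor`.

    Columns: index, type, x, y, z, radius, parent.  Requires a single root;
    nonzero z coordinates are dropped with a warning (arbors are planar).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcFormatError(f"expected 7 SWC columns, got {len(parts)}: {line!r}")
            rows.append([float(v) for v in parts])
    if not rows:
        raise SwcFormatError(f"empty SWC file: {path}")
    arr = np.asarray(rows)
    ids = arr[:, 0].astype(int)
    if len(np.unique(ids)) != len(ids):
        raise SwcFormatError("duplicate SWC sample ids")
    if np.any(np.abs(arr[:, 4]) > 1e-9):
        warnings.warn("3D SWC input: z coordinates dropped (arbors are planar)")
    id_to_row = {i: k for k, i in enumerate(ids)}
    parents_raw = arr[:, 6].astype(int)
    roots = np.flatnonzero(parents_raw == -1)
    if len(roots) != 1:
        raise SwcFormatError(f"SWC must have exactly one root, found {len(roots)}")
    for p in parents_raw:
        if p != -1 and p not in id_to_row:
            raise SwcFormatError(f"SWC parent id {p} does not exist")

    # keep the file's own order when it is already topological (the usual
    # case and what write_swc emits), so write∘read is the identity there;
    # otherwise fall back to a depth-first reorder from the root
    already_sorted = roots[0] == 0 and all(
        id_to_row[p] < k for k, p in enumerate(parents_raw) if p != -1
    )
    if already_sorted:
        order = list(range(len(ids)))
    else:
        order = []
        children: dict[int, list[int]] = {}
        for k, p in enumerate(parents_raw):
            children.setdefault(p, []).append(k)
        stack = [roots[0]]
        seen: set[int] = set()
        while stack:
            k = stack.pop()
            if k in seen:
                raise SwcFormatError("cycle detected in SWC parent links")
            seen.add(k)
            order.append(k)
            stack.extend(reversed(children.get(ids[k], [])))
        if len(order) != len(ids):
            raise SwcFormatError(
                "SWC contains nodes unreachable from the root (cycle or forest)"
            )

    new_index = {ids[k]: i for i, k in enumerate(order)}
    nodes = arr[order][:, 2:4]
    radii = arr[order][:, 5]
    parents = np.array(
        [-1 if parents_raw[k] == -1 else new_index[parents_raw[k]] for k in order]
    )
    return Arbor(nodes=nodes, parents=parents, class_label=class_label, radii=radii)


def write_swc(arbor: Arbor, path: str | Path) -> None:
    """Write an :class:`Arbor` as standard 7-column SWC (z = 0)."""
    radii = arbor.radii if arbor.radii is not None else np.full(len(arbor.nodes), 0.5)
    with open(path, "w") as fh:
        fh.write(f"# planar dendritic arbor, class={arbor.class_label}\n")
        fh.write("# index type x y z radius parent\n")
        for i, ((x, y), p, r) in enumerate(zip(arbor.nodes, arbor.parents, radii)):
            typ = 1 if i == 0 else 3  # soma / basal dendrite
            fh.write(f"{i + 1} {typ} {x:.6f} {y:.6f} 0.0 {r:.3f} {p + 1 if p >= 0 else -1}\n")


def total_length(arbor: Arbor) -> float:
    """Total dendritic length: sum of segment Euclidean lengths (μm)."""
    if arbor.n_segments == 0:
        warnings.warn("arbor has no segments; total length is 0")
        return 0.0
    return float(arbor.segment_lengths().sum())


def _circle_crossings(seg: np.ndarray, center: np.ndarray, rho: float) -> int:
    """Number of intersection points of segments with the circle |p - c| = rho.

    Parametrizes each segment p1 + t (p2 - p1) and counts quadratic roots in
    the half-open interval [0, 1): shared endpoints between parent and child
    segments are counted once, and a tangent contact counts once.
    """
    u = seg[:, 0] - center
    v = seg[:, 1] - seg[:, 0]
    a = np.einsum("ij,ij->i", v, v)
    b = 2.0 * np.einsum("ij,ij->i", u, v)
    c = np.einsum("ij,ij->i", u, u) - rho * rho
    count = 0
    eps = 1e-9
    disc = b * b - 4.0 * a * c
    ok = (a > 0) & (disc > -eps * np.maximum(a, 1.0))
    sq = np.sqrt(np.clip(disc, 0.0, None))
    for ai, bi, sqi, di in zip(a[ok], b[ok], sq[ok], disc[ok]):
        t1 = (-bi - sqi) / (2.0 * ai)
        t2 = (-bi + sqi) / (2.0 * ai)
        if di <= eps * max(ai, 1.0):  # tangency: one geometric contact
            if -eps <= t1 < 1.0 - eps:
                count += 1
        else:
            for t in (t1, t2):
                if -eps <= t < 1.0 - eps:
                    count += 1
    return count


def sholl(arbor: Arbor, ring_spacing: float = 10.0, max_radius: float | None = None) -> ShollProfile:
    """Modified Sholl analysis around the soma.

    Counts arbor crossings of concentric circles at radii Δr, 2Δr, … and
    reports the density = crossings / circumference at each ring.
    """
    if ring_spacing <= 0:
        raise ValueError("ring spacing must be positive")
    seg = arbor.segments()
    dist = np.linalg.norm(arbor.nodes - arbor.soma, axis=1)
    bbox_ok = (
        np.all(arbor.soma >= arbor.nodes.min(axis=0) - 1e-9)
        and np.all(arbor.soma <= arbor.nodes.max(axis=0) + 1e-9)
    )
    if not bbox_ok:
        warnings.warn("soma lies outside the arbor bounding box; Sholl still computed")
    if max_radius is None:
        max_radius = float(dist.max()) + ring_spacing
    radii = np.arange(ring_spacing, max_radius + 1e-9, ring_spacing)
    counts = np.array([_circle_crossings(seg, arbor.soma, rho) for rho in radii])
    return ShollProfile(radii=radii, intersections=counts)


def _point_segment_distance(points: np.ndarray, seg: np.ndarray) -> np.ndarray:
    """Exact min distance of each point to any segment; O(P·M), chunked over P."""
    p1 = seg[:, 0]
    d = seg[:, 1] - seg[:, 0]
    dd = np.einsum("ij,ij->i", d, d)
    dd_safe = np.where(dd > 0, dd, 1.0)
    out = np.empty(len(points))
    chunk = max(1, int(4e6 // max(len(seg), 1)))
    for s in range(0, len(points), chunk):
        pts = points[s : s + chunk]
        w = pts[:, None, :] - p1[None, :, :]
        t = np.clip(np.einsum("pmj,mj->pm", w, d) / dd_safe, 0.0, 1.0)
        proj = p1[None, :, :] + t[..., None] * d[None, :, :]
        dist = np.linalg.norm(pts[:, None, :] - proj, axis=2)
        out[s : s + chunk] = dist.min(axis=1)
    return out


def distance_map(
    arbor: Arbor,
    pixel_size: float = 2.0,
    extent: float | None = None,
    method: str = "kdtree",
) -> DistanceMap:
    """Distance-to-nearest-dendrite map over a square window centred on the soma.

    ``extent`` is the half-width (μm; default covers the territory disc).
    ``method='kdtree'`` queries a KD-tree of points sampled along segments at
    half-pixel spacing (error well under half a pixel); ``method='exact'``
    computes exact point-to-segment distances (slow, used as an oracle).
    """
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    if extent is None:
        extent = max(
            DEFAULT_TERRITORY_RADIUS,
            float(np.abs(arbor.nodes - arbor.soma).max()),
        )
    n = int(np.floor(2 * extent / pixel_size)) + 1
    offs = (np.arange(n) - (n - 1) / 2.0) * pixel_size
    gx, gy = np.meshgrid(arbor.soma[0] + offs, arbor.soma[1] + offs)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if method == "exact":
        vals = _point_segment_distance(pts, arbor.segments())
    elif method == "kdtree":
        cloud = arbor.sample_points(spacing=pixel_size / 2.0)
        tree = cKDTree(cloud)
        vals, _ = tree.query(pts, workers=-1)
    else:
        raise ValueError(f"unknown distance-map method {method!r}")
    return DistanceMap(values=vals.reshape(n, n), pixel_size=pixel_size, center=arbor.soma.copy())


def sample_stimulus_positions(
    arbor: Arbor,
    n: int,
    mode: str,
    seed: int | np.random.Generator = 0,
    distance: float | None = None,
    territory_radius: float = DEFAULT_TERRITORY_RADIUS,
    ring_tolerance: float = 5.0,
) -> np.ndarray:
    """Sample ``n`` probe placements on the arbor's territory.

    Modes
    -----
    ``proximal`` / ``distal``
        Points on the dendrite near the 100 μm / 200 μm soma-centred circle
        (within ``ring_tolerance``).
    ``d_off``
        Points whose distance to the nearest dendrite is ``distance`` ± 2 μm
        (rejection sampling over the territory disc).
    ``uniform``
        Uniform over the territory disc.
    """
    if n < 1:
        raise ValueError("need n >= 1 positions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "uniform":
        theta = rng.uniform(0, 2 * np.pi, n)
        rad = territory_radius * np.sqrt(rng.uniform(0, 1, n))
        return arbor.soma + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
    if mode in ("proximal", "distal"):
        ring = 100.0 if mode == "proximal" else 200.0
        pts = arbor.sample_points(spacing=1.0)
        r = np.linalg.norm(pts - arbor.soma, axis=1)
        candidates = pts[np.abs(r - ring) <= ring_tolerance]
        if len(candidates) == 0:
            raise ValueError(f"no dendrite within {ring_tolerance} μm of the {ring} μm ring")
        idx = rng.integers(0, len(candidates), n)
        return candidates[idx]
    if mode == "d_off":
        if distance is None:
            raise ValueError("d_off mode requires a target distance")
        seg = arbor.segments()
        tol = 2.0
        picked: list[np.ndarray] = []
        for _ in range(200):
            theta = rng.uniform(0, 2 * np.pi, 4 * n)
            rad = territory_radius * np.sqrt(rng.uniform(0, 1, 4 * n))
            cand = arbor.soma + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
            dmin = _point_segment_distance(cand, seg)
            good = cand[np.abs(dmin - distance) <= tol]
            picked.extend(good)
            if len(picked) >= n:
                return np.asarray(picked[:n])
        raise ValueError(
            f"could not find positions at distance {distance}±{tol} μm from a dendrite"
        )
    raise ValueError(f"unknown sampling mode {mode!r}")
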