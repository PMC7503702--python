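"""Synthetic spatial point patterns with the structure the analysis assumes.

Three generators cover the regimes seen in nuclei-position data from
cultured cells:

* :func:`generate_homogeneous` — homogeneous Poisson process, the
  complete-spatial-randomness control (glia-like even spreading).  The
  default study condition is a seeding density of 130 cells/mm².
* :func:`generate_clustered` — Thomas process (Poisson parents, Gaussian
  offspring), a neuron-like pattern with dense agglomerations.
* :func:`generate_blobs` — planted Gaussian blobs at known centres, the
  ground-truth fixture for cluster-number recovery tests.

:func:`rasterize` converts a pattern to a nuclei-like binary image by
stamping each point as a filled disk.
"""

from __future__ import annotations

import numpy as np

from .geometry import BinaryImage, FieldGeometry, PointPattern

__all__ = [
    "CLUST_A",
    "clust_a",
    "generate_homogeneous",
    "generate_clustered",
    "generate_blobs",
    "random_separated_blobs",
    "rasterize",
]

#: Frozen well-separated four-blob fixture used throughout the test and
#: acceptance suites.  Centres sit 1200 µm apart = 20 standard deviations,
#: so the planted structure is unambiguous.
CLUST_A = {
    "field": FieldGeometry(2000.0, 2000.0, 2.0),
    "centers": [(400.0, 400.0), (400.0, 1600.0), (1600.0, 400.0), (1600.0, 1600.0)],
    "n_per_blob": 200,
    "sd": 60.0,
    "seed": 42,
}


def clust_a() -> PointPattern:
    """Generate the frozen CLUST-A fixture (800 points, 4 planted blobs)."""
    return generate_blobs(
        CLUST_A["centers"],
        CLUST_A["n_per_blob"],
        CLUST_A["sd"],
        CLUST_A["field"],
        seed=CLUST_A["seed"],
    )


def generate_homogeneous(
    intensity: float, field: FieldGeometry, seed: int | np.random.SeedSequence = 0
) -> PointPattern:
    """Homogeneous Poisson point process.

    Parameters
    ----------
    intensity : float
        Expected point density in cells per mm² (the study seeding density
        is 130 cells/mm²).
    field : FieldGeometry
    seed : int or SeedSequence

    Returns
    -------
    PointPattern
        Count is Poisson with mean ``intensity × area``; positions are
        i.i.d. uniform over the field.
    """
    if intensity < 0:
        raise ValueError("intensity must be non-negative (cells per mm^2)")
    rng = np.random.default_rng(seed)
    n = rng.poisson(intensity * field.area_mm2)
    xy = rng.uniform([0.0, 0.0], [field.width, field.height], size=(n, 2))
    return PointPattern(xy, field)


def generate_clustered(
    parent_intensity: float,
    mean_offspring: float,
    spread_sd: float,
    field: FieldGeometry,
    seed: int | np.random.SeedSequence = 0,
) -> PointPattern:
    """Thomas-process clustered pattern.

    Parents form a homogeneous Poisson process with *parent_intensity*
    (per mm²); each parent receives a Poisson(*mean_offspring*) number of
    children displaced by an isotropic Gaussian with standard deviation
    *spread_sd* µm.  Children falling outside the field are discarded (not
    reflected), so near the border the realized density is slightly below
    κ·µ; with ``spread_sd`` much smaller than the field this edge loss is
    a few percent at most.  Labels record the parent index of each child.
    """
    if parent_intensity < 0 or mean_offspring < 0 or spread_sd < 0:
        raise ValueError("rate and scale parameters must be non-negative")
    rng = np.random.default_rng(seed)
    n_parents = rng.poisson(parent_intensity * field.area_mm2)
    parents = rng.uniform([0.0, 0.0], [field.width, field.height], size=(n_parents, 2))
    pts: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for i, p in enumerate(parents):
        n_child = rng.poisson(mean_offspring)
        if n_child == 0:
            continue
        xy = p + rng.normal(0.0, spread_sd, size=(n_child, 2))
        inside = (
            (xy[:, 0] >= 0)
            & (xy[:, 0] <= field.width)
            & (xy[:, 1] >= 0)
            & (xy[:, 1] <= field.height)
        )
        pts.append(xy[inside])
        labels.append(np.full(int(inside.sum()), i))
    if pts:
        points = np.concatenate(pts)
        lab = np.concatenate(labels)
    else:
        points = np.empty((0, 2))
        lab = np.empty(0, dtype=int)
    return PointPattern(points, field, lab)


def generate_blobs(
    centers,
    n_per_blob: int,
    sd: float,
    field: FieldGeometry,
    seed: int | np.random.SeedSequence = 0,
) -> PointPattern:
    """Planted isotropic Gaussian blobs at known centres.

    Each of the given centres receives exactly *n_per_blob* points with
    isotropic spread *sd*; coordinates are clipped to the field so the
    planted label partition is preserved exactly.  Labels are blob indices.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    if len(centers) == 0:
        raise ValueError("centers must be non-empty")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if (
        centers[:, 0].min() < 0
        or centers[:, 0].max() > field.width
        or centers[:, 1].min() < 0
        or centers[:, 1].max() > field.height
    ):
        raise ValueError("all centers must lie inside the field")
    rng = np.random.default_rng(seed)
    pts = []
    labels = []
    for i, c in enumerate(centers):
        xy = c + rng.normal(0.0, sd, size=(n_per_blob, 2))
        xy[:, 0] = np.clip(xy[:, 0], 0.0, field.width)
        xy[:, 1] = np.clip(xy[:, 1], 0.0, field.height)
        pts.append(xy)
        labels.append(np.full(n_per_blob, i))
    return PointPattern(
        np.concatenate(pts) if pts else np.empty((0, 2)),
        field,
        np.concatenate(labels) if labels else None,
    )


def random_separated_blobs(
    k: int,
    field: FieldGeometry,
    sd: float = 60.0,
    n_per_blob: int = 150,
    min_separation: float | None = None,
    seed: int | np.random.SeedSequence = 0,
    margin: float | None = None,
) -> PointPattern:
    """Planted blobs at random centres with a guaranteed minimum separation.

    Centres are placed by rejection sampling until pairwise distances are
    at least *min_separation* (default 10·sd, well beyond the overlap
    regime).  Used for cluster-number recovery experiments where the true
    k must be unambiguous.
    """
    if min_separation is None:
        min_separation = 10.0 * sd
    if margin is None:
        margin = 2.0 * sd
    rng = np.random.default_rng(seed)
    lo = np.array([margin, margin])
    hi = np.array([field.width - margin, field.height - margin])
    if np.any(hi <= lo):
        raise ValueError("field too small for the requested margin")
    for _ in range(10_000):
        centers = rng.uniform(lo, hi, size=(k, 2))
        d = np.sqrt(((centers[:, None] - centers[None]) ** 2).sum(-1))
        if k == 1 or d[np.triu_indices(k, 1)].min() >= min_separation:
            break
    else:
        raise RuntimeError(
            f"could not place {k} centers separated by {min_separation} in the field"
        )
    return generate_blobs(centers, n_per_blob, sd, field, seed=rng)


def rasterize(pattern: PointPattern, nucleus_radius: float) -> BinaryImage:
    """Stamp each point as a filled disk, producing a nuclei-like mask.

    A pixel is foreground when its centre lies within *nucleus_radius* of
    any point (pixel centres at ``(j+0.5, i+0.5) · pixel_size``).
    Overlapping disks union.
    """
    ps = pattern.field.pixel_size
    if nucleus_radius < ps / 2:
        raise ValueError(
            "nucleus_radius must be at least half a pixel, otherwise points vanish"
        )
    ny, nx = pattern.field.shape
    img = np.zeros((ny, nx), dtype=bool)
    r2 = nucleus_radius**2
    halo = int(np.ceil(nucleus_radius / ps)) + 1
    for x, y in pattern.points:
        jc = int(x / ps)
        ic = int(y / ps)
        i0, i1 = max(ic - halo, 0), min(ic + halo + 1, ny)
        j0, j1 = max(jc - halo, 0), min(jc + halo + 1, nx)
        if i0 >= i1 or j0 >= j1:
            continue
        ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
        cx = (jj + 0.5) * ps
        cy = (ii + 0.5) * ps
        img[i0:i1, j0:j1] |= (cx - x) ** 2 + (cy - y) ** 2 <= r2
    return BinaryImage(img, ps)
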