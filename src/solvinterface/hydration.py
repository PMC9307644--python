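"""Explicit-water placement and benchmarking.

The central object is a voxel grid of water-oxygen probability (a PDM).
Waters are placed greedily at the live voxel of highest probability, with a
clash-resolution loop that pushes a clashing water directly away from the
nearest offending protein atom for at most ``max_clash_cycles`` cycles;
after each successful placement all live voxels within one water radius of
the new oxygen are retired.

The interfacial space of a two-sided complex is the voxel set lying in the
first solvation layer of BOTH sides, where a side's first solvation layer
is the shell between its van der Waals surface and the surface traced by a
probe of radius vdW(H2O) + 0.5 Å.  The META pool merges priority-ranked
predictor outputs with redundancy removal at 2·vdW(H2O) + 0.5 Å, and the
RANDOM baseline packs waters uniformly into the interfacial space at the
same exclusion distance until saturation.

Predicted and experimental water oxygens are matched at the vdW(H2O) =
1.4 Å threshold and scored with precision, recall and the F-score
F = 2·Pre·Rec/(Pre + Rec).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from solvinterface.structio import VDW_WATER, StructureModel

__all__ = [
    "GridMap",
    "SolvationParams",
    "WaterSet",
    "InterfacialSpace",
    "BenchmarkResult",
    "KernelParams",
    "build_pdm",
    "place_waters",
    "compute_interfacial_space",
    "meta_pool",
    "random_waters",
    "select_interfacial_waters",
    "benchmark_waters",
    "score_counts",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class SolvationParams:
    """Distance thresholds of the water-placement pipeline (Å).

    All are parameterized by the water vdW radius and a 0.5 Å contact
    buffer: the solvation-layer probe is vdW(H2O) + 0.5, match threshold
    for benchmarking is vdW(H2O), and the redundancy/exclusion distance is
    2·vdW(H2O) + 0.5.
    """

    vdw_water: float = VDW_WATER
    contact_buffer: float = 0.5
    max_clash_cycles: int = 10
    clash_epsilon: float = 0.01

    @property
    def layer_probe(self) -> float:
        return self.vdw_water + self.contact_buffer

    @property
    def match_threshold(self) -> float:
        return self.vdw_water

    @property
    def redundancy_threshold(self) -> float:
        return 2.0 * self.vdw_water + self.contact_buffer


DEFAULT_PARAMS = SolvationParams()


@dataclass
class GridMap:
    """Regular voxel grid of non-negative water-oxygen probability."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray  # shape (nx, ny, nz)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_voxels(self):
        return self.values.size

    def centers(self) -> np.ndarray:
        """All voxel centers, flattened in C order, shape (N, 3)."""
        nx, ny, nz = self.shape
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3)
        return self.origin + idx * self.spacing

    def center_of(self, flat_index: int) -> np.ndarray:
        idx = np.unravel_index(flat_index, self.shape)
        return self.origin + np.array(idx) * self.spacing

    def nearest_index(self, points: np.ndarray):
        """Nearest-voxel flat indices; -1 for points outside the grid."""
        points = np.atleast_2d(points)
        idx = np.rint((points - self.origin) / self.spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        flat = np.full(len(points), -1, dtype=int)
        if inside.any():
            flat[inside] = np.ravel_multi_index(idx[inside].T, self.shape)
        return flat

    def bbox(self):
        return self.origin, self.origin + (np.array(self.shape) - 1) * self.spacing

    # -- persistence -----------------------------------------------------
    def save(self, path):
        np.savez(path, origin=self.origin, spacing=self.spacing, values=self.values)

    @classmethod
    def load(cls, path):
        data = np.load(path)
        return cls(data["origin"], float(data["spacing"]), data["values"])

    def to_ccp4(self, path):
        """Export as a CCP4/MRC-style density map for visual inspection."""
        import gemmi

        grid = gemmi.FloatGrid(*self.shape)
        arr = np.asarray(grid.array)
        arr[...] = self.values
        extent = np.array(self.shape) * self.spacing
        grid.set_unit_cell(gemmi.UnitCell(*extent, 90, 90, 90))
        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = grid
        ccp4.update_ccp4_header()
        ccp4.write_ccp4_map(str(path))


@dataclass
class WaterSet:
    """Predicted or experimental water oxygen positions."""

    positions: np.ndarray
    source: str = ""
    priority: int | None = None
    scores: np.ndarray | None = None
    labels: list | None = None  # per-water provenance (META survivors)
    seed: int | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self):
        return len(self.positions)

    def subset(self, mask) -> "WaterSet":
        mask = np.asarray(mask)
        return WaterSet(
            self.positions[mask],
            source=self.source,
            priority=self.priority,
            scores=None if self.scores is None else self.scores[mask],
            labels=None if self.labels is None else
            [l for l, m in zip(self.labels, mask) if m],
            seed=self.seed,
        )


@dataclass
class InterfacialSpace:
    """Voxels lying in the first solvation layer of both partition sides."""

    origin: np.ndarray
    spacing: float
    shape: tuple
    flagged: np.ndarray  # sorted flat voxel indices

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=int)

    @property
    def n_flagged(self):
        return len(self.flagged)

    def flagged_centers(self) -> np.ndarray:
        if self.n_flagged == 0:
            return np.empty((0, 3))
        idx = np.array(np.unravel_index(self.flagged, self.shape)).T
        return self.origin + idx * self.spacing

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel membership test for an (n, 3) point array."""
        points = np.atleast_2d(points)
        if len(points) == 0:
            return np.zeros(0, dtype=bool)
        grid = GridMap(self.origin, self.spacing, np.empty(self.shape))
        flat = grid.nearest_index(points)
        ok = flat >= 0
        ok[ok] = np.isin(flat[ok], self.flagged)
        return ok


@dataclass(frozen=True)
class BenchmarkResult:
    """Water-placement benchmark counts and metrics."""

    tp: int
    fn: int
    fp: int
    pre: float
    rec: float
    f1: float

    def as_dict(self):
        return {"TP": self.tp, "FN": self.fn, "FP": self.fp,
                "Pre": self.pre, "Rec": self.rec, "F1": self.f1}


# ---------------------------------------------------------------------------
# PDM construction


@dataclass(frozen=True)
class KernelParams:
    """Radial placement kernel for one atom class: w·exp(−(d−μ)²/2σ²)."""

    mu: float
    sigma: float
    weight: float


#: First-shell kernel defaults: polar/charged N and O peak at hydrogen-bond
#: distance, carbons and sulfur at van der Waals contact distance with a
#: broader, down-weighted shell.
DEFAULT_KERNELS = {
    "polar": KernelParams(mu=2.8, sigma=0.35, weight=1.0),
    "apolar": KernelParams(mu=3.5, sigma=0.5, weight=0.25),
}


def _heavy_arrays(model: StructureModel, atoms=None):
    atoms = [a for a in (atoms if atoms is not None else model.atoms)
             if a.element != "H"]
    pos = np.array([a.pos for a in atoms]).reshape(-1, 3)
    radii = np.array([a.vdw_radius for a in atoms])
    return atoms, pos, radii


def build_pdm(model: StructureModel, kernel_params: dict | None = None,
              spacing: float = 0.5, margin: float | None = None,
              params: SolvationParams = DEFAULT_PARAMS) -> GridMap:
    """Approximate water-oxygen probability density around a structure.

    Each heavy atom contributes a Gaussian radial shell (atom-class kernel);
    voxels whose centers fall inside any atom's vdW sphere are zeroed.  The
    grid covers the model bounding box plus a 2·layer_probe margin.  The
    grid interface is pluggable: any externally trained probability map
    with the same layout can replace this construction.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    kernels = kernel_params or DEFAULT_KERNELS
    if not model.annotated:
        raise ValueError("model must be annotated (vdW radii required)")
    atoms, pos, radii = _heavy_arrays(model)
    if len(atoms) == 0:
        raise ValueError("cannot build a PDM for an empty model")
    if margin is None:
        margin = 2.0 * params.layer_probe
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)
    values = np.zeros(shape)

    axes = [lo[d] + np.arange(shape[d]) * spacing for d in range(3)]

    def window(center, cutoff):
        lo_i, hi_i, local = [], [], []
        for d in range(3):
            i0 = max(0, int(np.floor((center[d] - cutoff - lo[d]) / spacing)))
            i1 = min(shape[d] - 1, int(np.ceil((center[d] + cutoff - lo[d]) / spacing)))
            if i1 < i0:
                return None
            lo_i.append(i0)
            hi_i.append(i1)
            local.append(axes[d][i0:i1 + 1] - center[d])
        dx, dy, dz = np.meshgrid(*local, indexing="ij")
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        sl = tuple(slice(lo_i[d], hi_i[d] + 1) for d in range(3))
        return sl, dist

    for a, p in zip(atoms, pos):
        k = kernels["polar"] if a.element in ("N", "O") else kernels["apolar"]
        cutoff = k.mu + 4.0 * k.sigma
        win = window(p, cutoff)
        if win is None:
            continue
        sl, dist = win
        values[sl] += k.weight * np.exp(-((dist - k.mu) ** 2) / (2.0 * k.sigma ** 2))

    for a, p, r in zip(atoms, pos, radii):
        win = window(p, r)
        if win is None:
            continue
        sl, dist = win
        values[sl][dist < r] = 0.0  # basic slicing: view, writes through

    return GridMap(lo, spacing, values)


# ---------------------------------------------------------------------------
# Greedy placement


def place_waters(pdm: GridMap, model: StructureModel,
                 params: SolvationParams = DEFAULT_PARAMS) -> WaterSet:
    """Place waters greedily at the highest-probability live voxels.

    Each placement resolves van der Waals clashes with the protein by
    moving the water directly away from the nearest clashing atom, at most
    ``params.max_clash_cycles`` times; unresolvable placements are
    abandoned.  After a successful placement every live voxel within
    vdW(H2O) of the new oxygen is retired; the seed voxel is retired in all
    cases.  Placement stops when no live voxel with positive value remains.
    Output is ordered by placement.
    """
    atoms, apos, aradii = _heavy_arrays(model)
    if len(atoms):
        glo, ghi = pdm.bbox()
        if np.any(apos.min(axis=0) > ghi) or np.any(apos.max(axis=0) < glo):
            raise GeometryError("grid and model bounding boxes do not overlap")
        atom_tree = cKDTree(apos)
        max_reach = aradii.max() + params.vdw_water
    else:
        atom_tree = None

    live = pdm.values.flatten().copy()
    centers = pdm.centers()
    center_tree = cKDTree(centers)

    placed, scores = [], []
    while True:
        seed_idx = int(np.argmax(live))
        value = live[seed_idx]
        if value <= 0:
            break
        pos = centers[seed_idx].copy()
        ok = True
        if atom_tree is not None:
            for _ in range(params.max_clash_cycles + 1):
                neigh = atom_tree.query_ball_point(pos, max_reach)
                clashing = [
                    j for j in neigh
                    if np.linalg.norm(pos - apos[j]) < aradii[j] + params.vdw_water
                ]
                if not clashing:
                    break
                j = min(clashing, key=lambda j: np.linalg.norm(pos - apos[j]))
                delta = pos - apos[j]
                dist = np.linalg.norm(delta)
                direction = delta / dist if dist > 0 else np.array([1.0, 0.0, 0.0])
                pos = apos[j] + direction * (
                    aradii[j] + params.vdw_water + params.clash_epsilon
                )
            else:
                ok = False
        if ok:
            placed.append(pos)
            scores.append(value)
            for j in center_tree.query_ball_point(pos, params.vdw_water):
                live[j] = 0.0
        live[seed_idx] = 0.0

    return WaterSet(np.array(placed).reshape(-1, 3), source="pdm-guided",
                    priority=0, scores=np.array(scores))


# ---------------------------------------------------------------------------
# Interfacial space


def _side_gap_flags(centers, pos, radii, probe):
    """min over atoms of (|x−a| − r_a) in (0, probe] per voxel center."""
    if len(pos) == 0:
        return np.zeros(len(centers), dtype=bool)
    tree = cKDTree(pos)
    reach = probe + radii.max()
    flags = np.zeros(len(centers), dtype=bool)
    neighbors = tree.query_ball_point(centers, reach)
    for i, neigh in enumerate(neighbors):
        if not neigh:
            continue
        d = np.linalg.norm(centers[i] - pos[neigh], axis=1) - radii[neigh]
        gap = d.min()
        flags[i] = 0.0 < gap <= probe
    return flags


def compute_interfacial_space(model: StructureModel, spacing: float = 0.5,
                              params: SolvationParams = DEFAULT_PARAMS
                              ) -> InterfacialSpace:
    """Voxels in the first solvation layer of both sides of the partition."""
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    model.require_partition()
    ab_atoms, ab_pos, ab_r = _heavy_arrays(model, model.side_atoms("antibody"))
    ag_atoms, ag_pos, ag_r = _heavy_arrays(model, model.side_atoms("antigen"))

    all_pos = np.vstack([ab_pos, ag_pos])
    lo = all_pos.min(axis=0) - params.layer_probe
    hi = all_pos.max(axis=0) + params.layer_probe
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)
    grid = GridMap(lo, spacing, np.empty(shape))
    centers = grid.centers()

    flags = _side_gap_flags(centers, ab_pos, ab_r, params.layer_probe)
    flags &= _side_gap_flags(centers, ag_pos, ag_r, params.layer_probe)
    return InterfacialSpace(lo, spacing, shape, np.flatnonzero(flags))


# ---------------------------------------------------------------------------
# META pooling, RANDOM baseline, selection, benchmarking


def _greedy_exclusion(points, threshold, keep_extra=None):
    """Keep points in order, dropping any within `threshold` of a kept one."""
    kept_pos, kept_idx = [], []
    for i, p in enumerate(points):
        if kept_pos:
            d = np.linalg.norm(np.array(kept_pos) - p, axis=1)
            if (d <= threshold).any():
                continue
        kept_pos.append(p)
        kept_idx.append(i)
    return np.array(kept_pos).reshape(-1, 3), kept_idx


def meta_pool(watersets, params: SolvationParams = DEFAULT_PARAMS) -> WaterSet:
    """Pool predictor outputs with priority-ordered redundancy removal.

    Waters are swept in order of (priority rank, input order); a water
    survives iff no already-kept water lies within the redundancy threshold
    2·vdW(H2O) + 0.5 Å.  Deduplication is global, so near-duplicates within
    one source are also removed.  Survivors carry their source label.
    """
    priorities = [ws.priority for ws in watersets]
    if any(p is None for p in priorities) or len(set(priorities)) != len(priorities):
        raise ValueError("each water set pooled by META needs a distinct priority rank")
    ordered = sorted(watersets, key=lambda ws: ws.priority)
    points, labels = [], []
    for ws in ordered:
        for p in ws.positions:
            points.append(p)
            labels.append(ws.source)
    kept, idx = _greedy_exclusion(np.array(points).reshape(-1, 3),
                                  params.redundancy_threshold)
    return WaterSet(kept, source="META", labels=[labels[i] for i in idx])


def random_waters(space: InterfacialSpace, params: SolvationParams = DEFAULT_PARAMS,
                  seed: int = 0) -> WaterSet:
    """Uniform non-overlapping water packing of the interfacial space.

    Greedy acceptance over a seeded random permutation of the flagged voxel
    centers with pairwise exclusion at 2·vdW(H2O) + 0.5 Å; by construction
    every remaining flagged voxel lies within the exclusion distance of an
    accepted water (saturation).  Deterministic for a fixed seed.
    """
    centers = space.flagged_centers()
    if len(centers) == 0:
        return WaterSet(np.empty((0, 3)), source="RANDOM", seed=seed)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(centers))
    kept, _ = _greedy_exclusion(centers[perm], params.redundancy_threshold)
    return WaterSet(kept, source="RANDOM", seed=seed)


def select_interfacial_waters(waters: WaterSet, space: InterfacialSpace) -> WaterSet:
    """Subset of waters whose oxygen falls in a flagged interfacial voxel."""
    return waters.subset(space.contains(waters.positions))


def score_counts(tp: int, fn: int, fp: int) -> BenchmarkResult:
    """Precision, recall and F-score from match counts (0/0 defined as 0)."""
    for name, v in (("TP", tp), ("FN", fn), ("FP", fp)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2.0 * pre * rec / (pre + rec) if pre + rec else 0.0
    return BenchmarkResult(tp=int(tp), fn=int(fn), fp=int(fp),
                           pre=pre, rec=rec, f1=f1)


def benchmark_waters(predicted: WaterSet, reference: WaterSet,
                     params: SolvationParams = DEFAULT_PARAMS) -> BenchmarkResult:
    """Match predicted against reference oxygens at the vdW(H2O) threshold.

    TP: reference waters with at least one predicted water within 1.4 Å;
    FN: reference waters with none; FP: predicted waters with no reference
    water within 1.4 Å.
    """
    pred, ref = predicted.positions, reference.positions
    t = params.match_threshold
    if len(pred) == 0:
        return score_counts(0, len(ref), 0)
    if len(ref) == 0:
        return score_counts(0, 0, len(pred))
    pred_tree = cKDTree(pred)
    ref_tree = cKDTree(ref)
    d_ref, _ = pred_tree.query(ref)
    d_pred, _ = ref_tree.query(pred)
    tp = int((d_ref <= t).sum())
    fn = int((d_ref > t).sum())
    fp = int((d_pred > t).sum())
    return score_counts(tp, fn, fp)
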