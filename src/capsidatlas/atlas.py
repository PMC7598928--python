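"""Configuration-space atlasing of a two-rigid-body interface assembly system.

The assembly landscape of two rigid units is the 6-dimensional space of
relative poses.  Classifying every candidate interaction (discretized
Lennard-Jones well) as active/inactive/forbidden partitions the feasible part
of that space into *active constraint regions*: all poses sharing one active
constraint graph.  Generically each active constraint lowers the effective
dimension by one, so regions stratify from 5-D (one constraint) down to 0-D
basin bottoms with >= 6 independent constraints.

The atlas is built by recursive boundary search: each region's interior is
swept through a Cayley chart (distance parameters between non-constrained
cross-unit atom pairs), each Cayley sample is realized back to Cartesian
poses by least squares on the distance targets, and any realized pose whose
active set strictly contains the region's own edge set seeds a boundary
(child) region.  Active constraints are held at their well centers during
realization while interval membership is used for classification.

An exhaustive pose-grid oracle is provided for micro systems so the
recursive search can be validated against brute force.
"""

from __future__ import annotations

import zlib
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .energy import EnergyModel
from .errors import ConstraintViolationError, UnknownInteractionError
from .geometry import AssemblyConfiguration, Pose, RigidUnit, similarity_distance


# ---------------------------------------------------------------------------
# Parameters and system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtlasParams:
    """Tunable knobs of the atlasing run (all lengths in Angstrom)."""

    epsilon: float = 0.5           # similarity threshold for distinct configs
    cayley_step: float = 0.5       # grid step in Cayley space
    realization_tol: float = 0.05  # max residual for an accepted realization
    max_samples_per_region: int = 400
    seed: int = 0
    rank_tol: float = 1e-6         # relative singular-value cutoff
    n_multistarts: int = 24        # deterministic quaternion-grid starts

    def __post_init__(self) -> None:
        for name in ("epsilon", "cayley_step", "realization_tol",
                     "max_samples_per_region"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class InterfaceAssemblySystem:
    """Two rigid units, their candidate interactions, and the true pose the
    pair occupies in the assembled capsid."""

    fixed_unit: RigidUnit
    mobile_unit: RigidUnit
    energy_model: EnergyModel
    true_pose: Pose
    system_label: str = "system"

    def __post_init__(self) -> None:
        self._F = self.fixed_unit.coords
        self._M = self.mobile_unit.coords
        rf = self.fixed_unit.radii
        rm = self.mobile_unit.radii
        self._vdw = rf[:, None] + rm[None, :]
        self._well_ai = np.array(
            [self.fixed_unit.index_of(w.atom_a) for w in self.wells], dtype=int
        )
        self._well_bi = np.array(
            [self.mobile_unit.index_of(w.atom_b) for w in self.wells], dtype=int
        )
        self._well_lo = np.array([w.lo for w in self.wells])
        self._well_hi = np.array([w.hi for w in self.wells])
        true_cfg = self.configuration(self.true_pose)
        if active_set(self, true_cfg) is None:
            raise ValueError("true pose is steric-infeasible")

    @property
    def wells(self):
        return self.energy_model.wells

    @property
    def interaction_ids(self) -> tuple[str, ...]:
        return tuple(w.interaction_id for w in self.wells)

    def configuration(self, pose: Pose) -> AssemblyConfiguration:
        return AssemblyConfiguration(self.fixed_unit, self.mobile_unit, pose)

    def well_center_target(self, interaction_id: str) -> tuple[int, int, float]:
        k = self.interaction_ids.index(interaction_id)
        return (int(self._well_ai[k]), int(self._well_bi[k]),
                float(self.energy_model.wells[k].center))


# ---------------------------------------------------------------------------
# Active sets and effective dimension
# ---------------------------------------------------------------------------

def active_set(system: InterfaceAssemblySystem,
               config: AssemblyConfiguration) -> frozenset | None:
    """Active-constraint edge set of a configuration, or None if any cross
    pair is inside hard-sphere contact (infeasible)."""
    mob = config.mobile_coords
    diff = system._F[:, None, :] - mob[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    if np.any(d < system._vdw - 1e-9):
        return None
    dw = d[system._well_ai, system._well_bi]
    on = (dw >= system._well_lo) & (dw <= system._well_hi)
    ids = system.interaction_ids
    return frozenset(ids[k] for k in np.nonzero(on)[0])


@dataclass(frozen=True)
class ActiveConstraintGraph:
    """Label of an active constraint region: the set of active interactions
    (edges) and the region's effective dimension."""

    edges: frozenset
    effective_dimension: int

    @property
    def label(self) -> str:
        return "+".join(sorted(self.edges)) if self.edges else "(free)"


def _constraint_rows(system: InterfaceAssemblySystem, edges,
                     config: AssemblyConfiguration) -> np.ndarray:
    """Jacobian of the active distance constraints w.r.t. the mobile pose
    (3 rotation + 3 translation parameters) at a witness configuration."""
    pairs = sorted({
        (system.well_center_target(e)[0], system.well_center_target(e)[1])
        for e in edges
    })
    t = config.pose.translation
    rows = []
    for i, j in pairs:
        a = system._F[i]
        y = config.mobile_coords[j]
        delta = y - a
        d = np.linalg.norm(delta)
        u = delta / d if d > 1e-12 else np.zeros(3)
        rows.append(np.concatenate([np.cross(y - t, u), u]))
    return np.array(rows) if rows else np.zeros((0, 6))


def effective_dimension(system: InterfaceAssemblySystem, edges,
                        witness: AssemblyConfiguration,
                        rank_tol: float = 1e-6) -> int:
    """6 minus the numerical rank of the constraint Jacobian at the witness.

    Duplicate wells on the same atom pair contribute a single row.  Raises
    ConstraintViolationError when the witness does not satisfy every edge's
    well interval.
    """
    got = active_set(system, witness)
    if got is None or not set(edges) <= got:
        raise ConstraintViolationError(
            f"witness does not satisfy {sorted(set(edges) - (got or set()))}"
        )
    J = _constraint_rows(system, edges, witness)
    if J.shape[0] == 0:
        return 6
    s = np.linalg.svd(J, compute_uv=False)
    rank = int(np.sum(s > rank_tol * s[0]))
    return max(0, 6 - rank)


# ---------------------------------------------------------------------------
# Cayley charts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CayleyParameter:
    fixed_index: int
    mobile_index: int
    lo: float
    hi: float


def cayley_chart(system: InterfaceAssemblySystem, edges,
                 witness: AssemblyConfiguration,
                 rank_tol: float = 1e-6) -> list[CayleyParameter]:
    """Greedily choose non-edge cross-unit atom pairs whose distances,
    together with the active distances, pin the relative pose.

    Pairs are added in lexicographic order whenever they increase the rank of
    the combined constraint Jacobian at the witness; the chart is complete
    when rank 6 is reached or no candidate helps (rank saturation on very
    small units — the documented fallback).  Per-parameter bounds come from
    triangle inequalities over shared-atom triples with the active distances
    plus the steric lower bound.
    """
    well_pairs = {
        (int(a), int(b)) for a, b in zip(system._well_ai, system._well_bi)
    }
    active_pairs = sorted({
        (system.well_center_target(e)[0], system.well_center_target(e)[1])
        for e in edges
    })
    J = _constraint_rows(system, edges, witness)

    def rank(M: np.ndarray) -> int:
        if M.shape[0] == 0:
            return 0
        s = np.linalg.svd(M, compute_uv=False)
        return int(np.sum(s > rank_tol * s[0]))

    current = rank(J)
    chart: list[tuple[int, int]] = []
    nf, nm = len(system._F), len(system._M)
    candidates = [
        (i, j) for i in range(nf) for j in range(nm)
        if (i, j) not in well_pairs
    ]
    t = witness.pose.translation
    for i, j in candidates:
        if current >= 6:
            break
        a = system._F[i]
        y = witness.mobile_coords[j]
        delta = y - a
        d = np.linalg.norm(delta)
        u = delta / d if d > 1e-12 else np.zeros(3)
        row = np.concatenate([np.cross(y - t, u), u])[None, :]
        J2 = np.vstack([J, row])
        if rank(J2) > current:
            J = J2
            current = rank(J2)
            chart.append((i, j))

    # interval bounds per parameter
    centers = {
        (system.well_center_target(e)[0], system.well_center_target(e)[1]):
        system.well_center_target(e)[2]
        for e in edges
    }
    diam = (_diameter(system._F) + _diameter(system._M))
    fallback_hi = (max(system._well_hi) if len(system._well_hi) else 4.0) + diam
    params = []
    for i, j in chart:
        lo = float(system._vdw[i, j])
        hi = fallback_hi
        for (ai, bj), delta in centers.items():
            if ai == i:  # shared fixed atom: triangle over mobile atoms j, bj
                m = float(np.linalg.norm(system._M[j] - system._M[bj]))
                lo = max(lo, abs(delta - m))
                hi = min(hi, delta + m)
            if bj == j:  # shared mobile atom: triangle over fixed atoms i, ai
                m = float(np.linalg.norm(system._F[i] - system._F[ai]))
                lo = max(lo, abs(delta - m))
                hi = min(hi, delta + m)
        if not lo < hi:  # inconsistent narrow intersection: widen to steric box
            lo, hi = float(system._vdw[i, j]), fallback_hi
        params.append(CayleyParameter(i, j, lo, hi))
    return params


def _diameter(X: np.ndarray) -> float:
    if len(X) == 1:
        return 0.0
    diff = X[:, None, :] - X[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


# ---------------------------------------------------------------------------
# Realization: Cayley values -> Cartesian poses
# ---------------------------------------------------------------------------

def _multistart_poses(system: InterfaceAssemblySystem, mean_target: float,
                      n: int) -> list[Pose]:
    """Deterministic multistart poses: the 24 rotations of the octahedral
    quaternion grid, each with a translation roughly matching centroids."""
    rots = Rotation.create_group("O").as_matrix()
    dirs = np.vstack([np.eye(3), -np.eye(3)])
    cf = system._F.mean(axis=0)
    cm = system._M.mean(axis=0)
    r_f = float(np.linalg.norm(system._F - cf, axis=1).max())
    r_m = float(np.linalg.norm(system._M - cm, axis=1).max())
    sep = r_f + r_m + mean_target  # start with the units clearly apart
    poses = []
    for k in range(min(n, len(rots))):
        R = rots[k]
        t = cf - R @ cm + sep * dirs[k % len(dirs)]
        poses.append(Pose(R, t))
    return poses


def _rodrigues(w: np.ndarray) -> np.ndarray:
    theta = float(np.linalg.norm(w))
    if theta < 1e-12:
        K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
        return np.eye(3) + K
    k = w / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _lm_pose(F: np.ndarray, M: np.ndarray, tv: np.ndarray,
             R0: np.ndarray, t0: np.ndarray,
             tol: float, max_iter: int = 60) -> tuple[np.ndarray, np.ndarray, float]:
    """Levenberg-Marquardt on the pose (rotation updated multiplicatively by
    Rodrigues steps) for distance targets tv between F[i] and R M[i] + t.

    Returns (R, t, max_abs_residual)."""
    R, t = R0, t0.copy()
    y = M @ R.T + t
    delta = y - F
    d = np.sqrt((delta ** 2).sum(-1))
    d = np.maximum(d, 1e-12)
    r = d - tv
    cost = float(r @ r)
    lam = 1e-3
    for _ in range(max_iter):
        if np.abs(r).max() < 0.2 * tol:
            break
        u = delta / d[:, None]
        J = np.hstack([np.cross(y - t, u), u])
        A = J.T @ J
        g = J.T @ r
        A[np.diag_indices(6)] += lam * (np.diag(A) + 1.0)
        try:
            dp = np.linalg.solve(A, -g)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            break
        # trust region: rotation steps beyond ~30 deg or translations beyond
        # 2 A leave the linearization's validity
        s = min(1.0,
                0.5 / max(float(np.linalg.norm(dp[:3])), 1e-12),
                2.0 / max(float(np.linalg.norm(dp[3:])), 1e-12))
        dp = dp * s
        Rn = _rodrigues(dp[:3]) @ R
        tn = t + dp[3:]
        yn = M @ Rn.T + tn
        dn = np.sqrt(((yn - F) ** 2).sum(-1))
        dn = np.maximum(dn, 1e-12)
        rn = dn - tv
        cn = float(rn @ rn)
        if cn < cost:
            R, t, y, d, r, cost = Rn, tn, yn, dn, rn, cn
            delta = y - F
            lam = max(lam * 0.3, 1e-9)
        else:
            lam *= 4.0
            if lam > 1e7:
                break
    return R, t, float(np.abs(r).max())


def realize(system: InterfaceAssemblySystem,
            targets: list[tuple[int, int, float]],
            params: AtlasParams,
            starts: list[Pose] | None = None,
            dedup: float | None = None) -> list[AssemblyConfiguration]:
    """Solve for poses satisfying each (fixed atom, mobile atom, distance)
    target within realization_tol; steric-infeasible poses are dropped and
    near-duplicate solutions merged.

    An empty result is valid (the targets may be geometrically inconsistent,
    e.g. violate a triangle inequality).
    """
    if not targets:
        return []
    ai = np.array([t[0] for t in targets], dtype=int)
    bj = np.array([t[1] for t in targets], dtype=int)
    tv = np.array([t[2] for t in targets])
    F = system._F[ai]
    M = system._M[bj]

    if starts is None:
        starts = _multistart_poses(system, float(tv.mean()), params.n_multistarts)
    eps = dedup if dedup is not None else params.epsilon
    out: list[AssemblyConfiguration] = []
    for pose in starts:
        R, t, maxres = _lm_pose(F, M, tv, pose.rotation, pose.translation,
                                params.realization_tol)
        if maxres > params.realization_tol:
            continue
        U, _, Vt = np.linalg.svd(R)  # re-orthonormalize accumulated product
        Rs = U @ Vt
        if np.linalg.det(Rs) < 0:
            Rs = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
        cfg = system.configuration(Pose(Rs, t))
        if active_set(system, cfg) is None:
            continue
        if all(similarity_distance(cfg, c) >= eps for c in out):
            out.append(cfg)
    return out


# ---------------------------------------------------------------------------
# Atlas data structures
# ---------------------------------------------------------------------------

def region_label(edges) -> str:
    return "+".join(sorted(edges)) if edges else "(free)"


@dataclass
class AtlasRegion:
    """One active constraint region: its graph, chart, and the epsilon-
    deduplicated configurations found inside it."""

    edges: frozenset
    dim: int
    chart: list[CayleyParameter] = field(default_factory=list)
    configurations: list[AssemblyConfiguration] = field(default_factory=list)
    parents: set = field(default_factory=set)
    children: set = field(default_factory=set)

    @property
    def label(self) -> str:
        return region_label(self.edges)

    @property
    def graph(self) -> ActiveConstraintGraph:
        return ActiveConstraintGraph(self.edges, self.dim)

    def add_config(self, cfg: AssemblyConfiguration, epsilon: float) -> bool:
        if all(similarity_distance(cfg, c) >= epsilon for c in self.configurations):
            self.configurations.append(cfg)
            return True
        return False


@dataclass
class Atlas:
    """DAG of active constraint regions, stratified by effective dimension."""

    system: InterfaceAssemblySystem
    params: AtlasParams
    regions: dict = field(default_factory=dict)  # label -> AtlasRegion

    def zero_dim_regions(self) -> list[AtlasRegion]:
        return [r for label, r in sorted(self.regions.items()) if r.dim == 0]

    def region_census(self) -> dict:
        return {
            label: (r.dim, len(r.configurations))
            for label, r in sorted(self.regions.items())
        }

    def to_jsonable(self) -> dict:
        nodes = []
        for label, r in sorted(self.regions.items()):
            nodes.append({
                "label": label,
                "edges": sorted(r.edges),
                "dimension": r.dim,
                "n_configurations": len(r.configurations),
                "parents": sorted(r.parents),
                "children": sorted(r.children),
            })
        return {
            "system": self.system.system_label,
            "epsilon": self.params.epsilon,
            "seed": self.params.seed,
            "regions": nodes,
        }


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------

def _region_rng(params: AtlasParams, label: str) -> np.random.Generator:
    return np.random.default_rng(
        (params.seed * 2654435761 + zlib.crc32(label.encode())) % (2 ** 31)
    )


def _chart_values(chart: list[CayleyParameter], system,
                  cfg: AssemblyConfiguration) -> np.ndarray:
    return np.array([
        float(np.linalg.norm(cfg.mobile_coords[c.mobile_index]
                             - system._F[c.fixed_index]))
        for c in chart
    ])


def build_atlas(system: InterfaceAssemblySystem, params: AtlasParams) -> Atlas:
    """Recursive boundary search over active constraint regions.

    Each candidate interaction seeds its 1-edge region.  Regions are
    processed level by level (by number of active constraints): the region's
    Cayley chart is swept, each sample realized, and realized poses whose
    active set strictly contains the region's edges register boundary (child)
    regions, with intermediate one-more-edge regions inserted so the
    stratification (parent with exactly one fewer edge) always holds.
    Deterministic for a fixed seed and parameter set.
    """
    atlas = Atlas(system=system, params=params)
    witnesses: dict[str, list[AssemblyConfiguration]] = {}
    regions = atlas.regions

    def ensure_region(edges: frozenset, witness: AssemblyConfiguration | None):
        label = region_label(edges)
        if label not in regions:
            dim = None
            if witness is not None:
                try:
                    dim = effective_dimension(system, edges, witness, params.rank_tol)
                except ConstraintViolationError:
                    dim = None
            if dim is None:
                dim = max(0, 6 - len(edges))  # generic fallback, refined later
            regions[label] = AtlasRegion(edges=edges, dim=dim)
        if witness is not None:
            witnesses.setdefault(label, []).append(witness)
        return regions[label]

    def register_discovery(parent_edges: frozenset, found: frozenset,
                           cfg: AssemblyConfiguration):
        """Insert the chain parent ⊂ ... ⊂ found one edge at a time."""
        chain = parent_edges
        for e in sorted(found - parent_edges):
            chain = chain | {e}
            ensure_region(chain, cfg)

    # seed the 1-edge regions
    for iid in sorted(system.interaction_ids):
        edges = frozenset([iid])
        target = system.well_center_target(iid)
        for cfg in realize(system, [target], params, dedup=params.epsilon):
            aset = active_set(system, cfg)
            if aset is None or iid not in aset:
                continue
            ensure_region(edges, cfg)
            if aset != edges:
                register_discovery(edges, aset, cfg)

    # process levels in increasing edge count
    level = 1
    processed: set[str] = set()
    while True:
        todo = sorted(
            label for label, r in regions.items()
            if len(r.edges) == level and label not in processed
        )
        if not todo:
            if any(len(r.edges) > level for r in regions.values()):
                level += 1
                continue
            break
        for label in todo:
            processed.add(label)
            region = regions[label]
            region_witnesses = witnesses.get(label, [])
            # keep witness configurations whose active set matches exactly
            own = [c for c in region_witnesses
                   if active_set(system, c) == region.edges]
            for cfg in own:
                region.add_config(cfg, params.epsilon)
            witness = (own or region_witnesses or [None])[0]
            if witness is None:
                continue
            region.dim = effective_dimension(system, region.edges, witness,
                                             params.rank_tol)
            targets = [system.well_center_target(e) for e in sorted(region.edges)]

            if region.dim == 0:
                starts = [c.pose for c in region_witnesses[:6]]
                starts += _multistart_poses(
                    system, float(np.mean([t[2] for t in targets])),
                    params.n_multistarts)
                for cfg in realize(system, targets, params, starts=starts,
                                   dedup=params.epsilon):
                    aset = active_set(system, cfg)
                    if aset is None or not region.edges <= aset:
                        continue
                    if aset == region.edges:
                        region.add_config(cfg, params.epsilon)
                    else:
                        register_discovery(region.edges, aset, cfg)
                continue

            region.chart = cayley_chart(system, region.edges, witness,
                                        params.rank_tol)
            if not region.chart:
                continue
            # breadth-first walk through Cayley space: anchor a step lattice
            # on the first witness and expand only from samples that realize,
            # so nearly every sample lands inside (or on the boundary of) the
            # region instead of in the geometrically inconsistent bulk of the
            # chart's bounding box
            rng = _region_rng(params, label)
            chart = region.chart
            los = np.array([c.lo for c in chart])
            his = np.array([c.hi for c in chart])
            step = params.cayley_step
            base = _chart_values(chart, system, witness)
            queue: deque = deque()
            visited: set[tuple] = set()
            seen_w = []
            for wcfg in region_witnesses:
                if all(similarity_distance(wcfg, s) >= params.epsilon
                       for s in seen_w):
                    seen_w.append(wcfg)
                    vals = _chart_values(chart, system, wcfg)
                    idx = tuple(np.round((vals - base) / step).astype(int))
                    queue.append((idx, wcfg.pose))
            budget = params.max_samples_per_region
            while queue and budget > 0:
                idx, start_pose = queue.popleft()
                if idx in visited:
                    continue
                visited.add(idx)
                values = base + np.array(idx, dtype=float) * step
                values = values + rng.uniform(-0.2, 0.2, len(chart)) * step
                if np.any(values < los - 0.25 * step) or \
                        np.any(values > his + 0.25 * step):
                    continue
                budget -= 1
                full = targets + [
                    (c.fixed_index, c.mobile_index, float(v))
                    for c, v in zip(chart, values)
                ]
                sols = realize(system, full, params, starts=[start_pose],
                               dedup=params.epsilon)
                next_pose = None
                for cfg in sols:
                    aset = active_set(system, cfg)
                    if aset is None or not region.edges <= aset:
                        continue
                    next_pose = cfg.pose
                    if aset == region.edges:
                        region.add_config(cfg, params.epsilon)
                    else:
                        register_discovery(region.edges, aset, cfg)
                if next_pose is not None:
                    for d in range(len(chart)):
                        for delta in (-1, 1):
                            nidx = list(idx)
                            nidx[d] += delta
                            nidx = tuple(nidx)
                            if nidx not in visited:
                                queue.append((nidx, next_pose))

    # drop regions that ended up empty and have no realized descendant
    with_configs = {l for l, r in regions.items() if r.configurations}
    keep = set(with_configs)
    for l, r in regions.items():
        if any(r.edges < regions[k].edges for k in with_configs):
            keep.add(l)
    for l in list(regions):
        if l not in keep:
            del regions[l]

    # parent/child links: registered regions differing by exactly one edge
    labels = sorted(regions)
    for la in labels:
        for lb in labels:
            ra, rb = regions[la], regions[lb]
            if len(rb.edges) == len(ra.edges) + 1 and ra.edges < rb.edges:
                ra.children.add(lb)
                rb.parents.add(la)
    return atlas


# ---------------------------------------------------------------------------
# Exhaustive oracle for micro systems
# ---------------------------------------------------------------------------

def _halton(n: int, dim: int) -> np.ndarray:
    primes = [2, 3, 5, 7][:dim]
    out = np.zeros((n, dim))
    for d, p in enumerate(primes):
        base = p
        for i in range(1, n + 1):
            f, x, k = 1.0, 0.0, i
            while k > 0:
                f /= base
                x += f * (k % base)
                k //= base
            out[i - 1, d] = x
    return out


def rotation_grid(n: int) -> np.ndarray:
    """Deterministic quasi-uniform rotations via Shoemake's map applied to a
    Halton sequence, as (n, 3, 3) matrices."""
    u = _halton(n, 3)
    u1, u2, u3 = u[:, 0], u[:, 1], u[:, 2]
    q = np.stack([
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
        np.sqrt(u1) * np.cos(2 * np.pi * u3),
    ], axis=1)
    return Rotation.from_quat(q).as_matrix()


def oracle_enumerate(system: InterfaceAssemblySystem, grid_resolution: float,
                     n_rotations: int = 240,
                     epsilon: float = 0.5) -> tuple[dict, bool]:
    """Exhaustively grid relative poses of a micro system (<= 4 atoms per
    unit) and classify each pose's active set.

    Returns (census, warning): census maps each realized non-empty active-set
    label to its epsilon-deduplicated configuration count; warning is True
    when the grid found no active pose at all (resolution too coarse).
    """
    if len(system._F) > 4 or len(system._M) > 4:
        raise ValueError("oracle_enumerate is restricted to micro systems")
    F, M = system._F, system._M
    cf = F.mean(axis=0)
    r_f = float(np.linalg.norm(F - cf, axis=1).max())
    r_m = float(np.linalg.norm(M - M.mean(axis=0), axis=1).max())
    reach = r_f + r_m + (float(system._well_hi.max())
                         if len(system._well_hi) else 4.0) + grid_resolution
    axes = [np.arange(c - reach, c + reach + 1e-9, grid_resolution) for c in cf]
    T = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    Rs = rotation_grid(n_rotations)

    lo, hi = system._well_lo, system._well_hi
    ai, bi = system._well_ai, system._well_bi
    ids = system.interaction_ids
    census_configs: dict[frozenset, list[np.ndarray]] = {}
    for R in Rs:
        MR = M @ R.T  # (nm, 3)
        # translations broadcast: mobile coords = MR[None] + T[:, None]
        for start in range(0, len(T), 4096):
            Tb = T[start:start + 4096]
            mob = MR[None, :, :] + Tb[:, None, :]
            diff = F[None, :, None, :] - mob[:, None, :, :]
            d = np.sqrt((diff ** 2).sum(-1))  # (b, nf, nm)
            feasible = ~np.any(d < system._vdw[None] - 1e-9, axis=(1, 2))
            dw = d[:, ai, bi]
            on = (dw >= lo) & (dw <= hi)
            rows = np.nonzero(feasible & on.any(axis=1))[0]
            for r in rows:
                key = frozenset(ids[k] for k in np.nonzero(on[r])[0])
                census_configs.setdefault(key, []).append(mob[r].ravel())
    census = {}
    for key in sorted(census_configs, key=lambda k: region_label(k)):
        vecs = np.array(census_configs[key])
        kept = np.empty_like(vecs)
        k = 0
        for vec in vecs:
            if k == 0 or np.min(np.linalg.norm(kept[:k] - vec, axis=1)) >= epsilon:
                kept[k] = vec
                k += 1
        census[region_label(key)] = k
    return census, len(census) == 0


# ---------------------------------------------------------------------------
# Basin decomposition
# ---------------------------------------------------------------------------

@dataclass
class Basin:
    """A 0-dimensional bottom region plus the configurations of ancestor
    regions (graphs that are subgraphs of the bottom graph) assigned to it."""

    bottom_label: str
    bottom_edges: frozenset
    members: list = field(default_factory=list)  # (region_label, n_active, cfg)
    is_true_basin: bool = False


def basin_decomposition(atlas: Atlas,
                        true_pose: Pose | None = None
                        ) -> tuple[list[Basin], int | None]:
    """Assign every configuration in a region whose graph is a subgraph of at
    least one bottom graph to the basin of its nearest bottom configuration
    (ties to the lexicographically smallest bottom label).

    The true basin is the one whose bottom contains the configuration nearest
    the true pose within epsilon; None when absent.
    """
    bottoms = atlas.zero_dim_regions()
    basins = [Basin(b.label, b.edges) for b in bottoms]
    if not bottoms:
        return [], None
    bot_configs = [b.configurations for b in bottoms]

    for label, region in sorted(atlas.regions.items()):
        candidate_idx = [
            k for k, b in enumerate(bottoms) if region.edges <= b.edges
        ]
        if not candidate_idx:
            continue
        for cfg in region.configurations:
            best, best_d = None, np.inf
            for k in candidate_idx:
                for bc in bot_configs[k]:
                    d = similarity_distance(cfg, bc)
                    if d < best_d - 1e-12:
                        best, best_d = k, d
            if best is not None:
                basins[best].members.append((label, len(region.edges), cfg))

    true_idx = None
    if true_pose is not None:
        true_cfg = atlas.system.configuration(true_pose)
        best, best_d = None, np.inf
        for k, cfgs in enumerate(bot_configs):
            for bc in cfgs:
                d = similarity_distance(true_cfg, bc)
                if d < best_d - 1e-12:
                    best, best_d = k, d
        if best is not None and best_d <= atlas.params.epsilon:
            true_idx = best
            basins[best].is_true_basin = True
    return basins, true_idx


def restrict_atlas(atlas: Atlas, knockout) -> Atlas:
    """The sub-atlas whose regions' edge sets are disjoint from the knockout
    (the paper's atlas restriction — regions are kept, never re-sampled)."""
    knockout = frozenset(knockout)
    unknown = knockout - set(atlas.system.interaction_ids)
    if unknown:
        raise UnknownInteractionError(f"unknown interaction ids: {sorted(unknown)}")
    kept = {
        label: r for label, r in atlas.regions.items()
        if not (r.edges & knockout)
    }
    out = Atlas(system=atlas.system, params=atlas.params)
    for label, r in kept.items():
        out.regions[label] = AtlasRegion(
            edges=r.edges, dim=r.dim, chart=r.chart,
            configurations=list(r.configurations),
            parents={p for p in r.parents if p in kept},
            children={c for c in r.children if c in kept},
        )
    return out
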