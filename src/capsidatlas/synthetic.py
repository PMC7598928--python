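"""Synthetic desk-scale inputs with the structure the method assumes.

Two generators are provided:

* planted two-rigid-body interface systems — small abstract rigid units
  (5-20 atoms each) with discretized wells centred on the cross-unit
  distances of one or more planted poses, so the landscape is guaranteed to
  contain designed minima with at least six simultaneously active
  constraints;
* synthetic capsid datasets — (bar-code feature, disrupt label) tables drawn
  from the two-scale model itself with known parameters, for
  parameter-recovery experiments.

The packaged in-vitro mutagenesis label tables for AAV2, MVM and BMV are also
loaded from here (checksum-pinned CSV transcriptions).
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial.transform import Rotation

from .atlas import InterfaceAssemblySystem, active_set
from .energy import DiscretizedWell, EnergyModel
from .errors import DegenerateDataError, FixtureError
from .geometry import DEFAULT_VDW_RADIUS, Atom, Pose, RigidUnit
from .model import (KnockoutFeatures, MutagenesisRecord, TrainingPair,
                    TwoScaleParams, capsid_cruciality)

_TABLE_FILES = {
    "AAV2": "aav2_mutagenesis.csv",
    "MVM": "mvm_mutagenesis.csv",
    "BMV": "bmv_mutagenesis.csv",
}
_TABLE_SHA256 = {
    "AAV2": "8ae08cbcc6f1222d27c24abfba6bcad3ac8a84a32a5877f66d1d10c8ad64b88b",
    "MVM": "506a6886bb015a1139999dab42c9464d0ec4ee91a51d4f2f5c47177431518664",
    "BMV": "342e72866ecf98a8f3ed9923468c0d06f2db3f303825001cd043c4f3f3393abc",
}
_RESULT_TO_LABEL = {
    "Disrupt": "disrupt",
    "Non-Disrupt": "non-disrupt",
    "Partial Disrupt": "partial",
}


@dataclass(frozen=True)
class PlantedSystemSpec:
    """Recipe for a planted two-rigid-body interface system."""

    atoms_per_unit: int = 8
    n_wells: int = 8
    n_planted_minima: int = 1
    half_width: float = 0.4  # Angstrom, half-width of each well
    seed: int = 0

    def __post_init__(self):
        if not 5 <= self.atoms_per_unit <= 20:
            raise ValueError("atoms_per_unit must be within 5..20")
        if self.n_wells < 6 * self.n_planted_minima:
            raise ValueError("need at least 6 wells per planted minimum")
        if self.n_planted_minima < 1:
            raise ValueError("need at least one planted minimum")
        if not self.half_width > 0:
            raise ValueError("half_width must be positive")


def _random_unit_coords(rng: np.random.Generator, n: int,
                        min_sep: float = 2.6, radius: float = 4.0,
                        tries: int = 4000) -> np.ndarray:
    pts: list[np.ndarray] = []
    for _ in range(tries):
        cand = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(cand) > radius:
            continue
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
        if len(pts) == n:
            arr = np.array(pts)
            return arr - arr.mean(axis=0)
    raise FixtureError(f"could not pack {n} atoms with separation {min_sep}")


def _make_unit(rng: np.random.Generator, n: int, prefix: str) -> RigidUnit:
    coords = _random_unit_coords(rng, n)
    atoms = tuple(
        Atom(f"{prefix}{i}", residue_id=i, chain_id=prefix, position=coords[i],
             vdw_radius=DEFAULT_VDW_RADIUS)
        for i in range(n)
    )
    return RigidUnit(atoms, unit_label=prefix, composition="monomer")


def _place_pose(rng: np.random.Generator, F: np.ndarray, M: np.ndarray,
                hw: float, direction: np.ndarray,
                target_gap: tuple[float, float] = (0.55, 0.9)) -> Pose:
    """Slide the rotated mobile unit along `direction` until the minimum
    cross distance sits in vdw_sum + target_gap (so well centres clear the
    steric floor by more than the half-width)."""
    R = Rotation.from_quat(rng.normal(size=4)).as_matrix()
    if np.linalg.det(R) < 0:  # defensive; quat rotations are proper
        R = -R
    vdw = 2 * DEFAULT_VDW_RADIUS
    lo_gap, hi_gap = target_gap
    assert lo_gap > hw + 0.05

    def min_cross(s: float) -> float:
        mob = M @ R.T + direction * s
        d = np.sqrt(((F[:, None] - mob[None]) ** 2).sum(-1))
        return float(d.min())

    s_lo, s_hi = 0.0, 40.0
    for _ in range(80):
        s = 0.5 * (s_lo + s_hi)
        g = min_cross(s) - vdw
        if g < lo_gap:
            s_lo = s
        elif g > hi_gap:
            s_hi = s
        else:
            return Pose(R, direction * s)
    raise FixtureError("could not place pose with the requested contact gap")


def make_planted_interface_system(spec: PlantedSystemSpec
                                  ) -> InterfaceAssemblySystem:
    """Build a planted system whose true pose activates >= 6 designed wells.

    Pure function of the spec (identical seed -> bit-identical system).  With
    several planted minima the wells are split evenly between the poses and
    rejection sampling enforces that each pose activates only its own wells
    and that poses are well separated (> 3 * 0.5 A in similarity distance).
    """
    rng = np.random.default_rng(spec.seed)
    fixed = _make_unit(rng, spec.atoms_per_unit, "F")
    mobile = _make_unit(rng, spec.atoms_per_unit, "M")
    F, M = fixed.coords, mobile.coords
    vdw = 2 * DEFAULT_VDW_RADIUS
    k = spec.n_planted_minima
    per_pose = spec.n_wells // k
    extra = spec.n_wells - per_pose * k

    for attempt in range(60):
        dirs = rng.normal(size=(k, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        if k > 1:
            # demand widely spread approach directions
            ok = all(np.dot(dirs[i], dirs[j]) < 0.2
                     for i in range(k) for j in range(i + 1, k))
            if not ok:
                continue
        try:
            poses = [_place_pose(rng, F, M, spec.half_width, d) for d in dirs]
        except FixtureError:
            continue
        wells: list[DiscretizedWell] = []
        fine = True
        for p_idx, pose in enumerate(poses):
            mob = pose.apply(M)
            d = np.sqrt(((F[:, None] - mob[None]) ** 2).sum(-1))
            flat = [(d[i, j], i, j) for i in range(len(F)) for j in range(len(M))
                    if d[i, j] - spec.half_width >= vdw + 1e-6]
            flat.sort()
            want = per_pose + (1 if p_idx < extra else 0)
            used = {(w.atom_a, w.atom_b) for w in wells}
            # pick nearest pairs, but force the constraint Jacobian at the
            # planted pose up to rank 6 first so the planted minimum is a
            # rigid (0-dimensional) bottom, not a motion curve
            t = pose.translation
            rows: list[np.ndarray] = []
            picked: list[tuple] = []

            def rank_of(extra_row=None):
                J = rows + ([extra_row] if extra_row is not None else [])
                if not J:
                    return 0
                s = np.linalg.svd(np.array(J), compute_uv=False)
                return int(np.sum(s > 1e-6 * s[0]))

            for dist, i, j in flat:  # pass 1: rank-raising pairs
                if rank_of() >= 6 or len(picked) == want:
                    break
                if (f"F{i}", f"M{j}") in used:
                    continue
                y = mob[j]
                u = (y - F[i]) / dist
                row = np.concatenate([np.cross(y - t, u), u])
                if rank_of(row) > rank_of():
                    rows.append(row)
                    picked.append((dist, i, j))
                    used.add((f"F{i}", f"M{j}"))
            for dist, i, j in flat:  # pass 2: nearest fills
                if len(picked) == want:
                    break
                if (f"F{i}", f"M{j}") in used:
                    continue
                picked.append((dist, i, j))
                used.add((f"F{i}", f"M{j}"))
            if len(picked) < want or rank_of() < 6:
                fine = False
                break
            for n, (dist, i, j) in enumerate(picked):
                wells.append(DiscretizedWell(
                    atom_a=f"F{i}", atom_b=f"M{j}",
                    lo=dist - spec.half_width, hi=dist + spec.half_width,
                    interaction_id=f"w{p_idx}_{n}", residue_pair=(i, j),
                ))
        if not fine:
            continue
        model = EnergyModel(wells=tuple(wells))
        system = InterfaceAssemblySystem(
            fixed_unit=fixed, mobile_unit=mobile, energy_model=model,
            true_pose=poses[0], system_label=f"planted-{spec.seed}",
        )
        # each pose must activate exactly its own well group
        sound = True
        for p_idx, pose in enumerate(poses):
            aset = active_set(system, system.configuration(pose))
            own = {w.interaction_id for w in wells
                   if w.interaction_id.startswith(f"w{p_idx}_")}
            if aset != own:
                sound = False
                break
        if k > 1:
            cfgs = [system.configuration(p) for p in poses]
            from .geometry import similarity_distance
            for i in range(k):
                for j in range(i + 1, k):
                    if similarity_distance(cfgs[i], cfgs[j]) <= 3 * 0.5:
                        sound = False
        if sound:
            return system
    raise FixtureError("rejection sampling failed to plant the system")


# ---------------------------------------------------------------------------
# Synthetic capsid datasets for parameter recovery
# ---------------------------------------------------------------------------

def make_synthetic_capsid_dataset(n_residues: int, params_true: TwoScaleParams,
                                  pathways, noise: float = 0.0, seed: int = 0,
                                  correlation: float = 0.7,
                                  pair_source: str = "labels"):
    """Draw bar-code features per residue, score them with the true two-scale
    parameters, and label by the median of the true cruciality score.

    The two bar-code components are coupled with weight ``correlation``
    (they track each other closely in real atlases).  Training pairs come
    from the binary labels (``pair_source="labels"``, every disrupt crossed
    with every non-disrupt — the in-vitro setting) or from the full known
    cruciality order (``pair_source="true-order"`` — oracle supervision for
    parameter-recovery experiments).

    Returns (features, labels, pairs, H_true).  Raises DegenerateDataError if
    labelling collapses to a single class.
    """
    if pair_source not in ("labels", "true-order"):
        raise ValueError(f"unknown pair_source {pair_source!r}")
    if not pathways:
        raise ValueError("need at least one connectivity pathway")
    rng = np.random.default_rng(seed)
    types = params_true.types
    features: dict[str, KnockoutFeatures] = {}
    for k in range(n_residues):
        per_type = {}
        for t in types:
            mm = float(rng.uniform())
            mc = float(np.clip(correlation * mm
                               + (1 - correlation) * rng.uniform(), 0, 1))
            per_type[t] = (mm, mc)
        r = f"r{k:03d}"
        features[r] = KnockoutFeatures(knockout=r, per_type=per_type)
    H_true = {r: capsid_cruciality(f, params_true, pathways)
              for r, f in features.items()}
    thresh = float(np.median(list(H_true.values())))
    labels = {}
    for r, h in H_true.items():
        lab = "disrupt" if h > thresh else "non-disrupt"
        if noise > 0 and rng.uniform() < noise:
            lab = "non-disrupt" if lab == "disrupt" else "disrupt"
        labels[r] = lab
    classes = set(labels.values())
    if len(classes) < 2:
        raise DegenerateDataError("labelling produced a single class")
    if pair_source == "true-order":
        rs = sorted(H_true)
        pairs = [TrainingPair(i, j) for i in rs for j in rs
                 if H_true[i] > H_true[j]]
    else:
        dis = sorted(r for r, l in labels.items() if l == "disrupt")
        non = sorted(r for r, l in labels.items() if l == "non-disrupt")
        pairs = [TrainingPair(i, j) for i in dis for j in non]
    return features, labels, pairs, H_true


# ---------------------------------------------------------------------------
# Packaged mutagenesis tables
# ---------------------------------------------------------------------------

def load_mutagenesis_tables(virus: str) -> list[MutagenesisRecord]:
    """Row-faithful transcription of the packaged in-vitro mutagenesis
    results for AAV2, MVM or BMV (checksum-verified)."""
    if virus not in _TABLE_FILES:
        raise KeyError(f"unknown virus {virus!r}; choose from "
                       f"{sorted(_TABLE_FILES)}")
    ref = resources.files("capsidatlas.data") / _TABLE_FILES[virus]
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE_SHA256[virus]:
        raise ValueError(f"packaged table for {virus} failed its checksum")
    records = []
    for row in csv.DictReader(raw.decode().splitlines()):
        records.append(MutagenesisRecord(
            virus=virus, residue=int(row["residue"]),
            label=_RESULT_TO_LABEL[row["result"]], source=row["source"],
        ))
    return records
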