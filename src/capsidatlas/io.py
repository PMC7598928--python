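"""Serialization of systems, atlases, graphs and reports.

System configs are YAML (units inline or referenced as PDB + chain); atlases
and graphs are JSON.  Every artifact written by the command line embeds a
provenance block (package version, seed, config hash) for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from . import __version__
from .atlas import Atlas, AtlasParams, AtlasRegion, InterfaceAssemblySystem
from .capsid import DualGraph
from .energy import DiscretizedWell, EnergyModel
from .geometry import Atom, Pose, RigidUnit, load_monomer

import networkx as nx


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

def provenance(seed, config_obj) -> dict:
    blob = json.dumps(config_obj, sort_keys=True, default=str).encode()
    return {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
    }


def provenance_comment(seed, config_obj) -> str:
    p = provenance(seed, config_obj)
    return f"# capsidatlas v{p['version']} seed={p['seed']} config={p['config_hash']}"


# ---------------------------------------------------------------------------
# Pose / unit / system configs
# ---------------------------------------------------------------------------

def pose_to_dict(pose: Pose) -> dict:
    q = Rotation.from_matrix(pose.rotation).as_quat()
    return {
        "quaternion_xyzw": [float(x) for x in q],
        "translation": [float(x) for x in pose.translation],
    }


def pose_from_dict(d: dict) -> Pose:
    R = Rotation.from_quat(d["quaternion_xyzw"]).as_matrix()
    return Pose(R, np.array(d["translation"], dtype=float))


def unit_to_dict(unit: RigidUnit) -> dict:
    return {
        "label": unit.unit_label,
        "composition": unit.composition,
        "atoms": [
            {
                "id": a.atom_id, "residue": int(a.residue_id),
                "chain": a.chain_id,
                "xyz": [float(x) for x in a.position],
                "vdw": float(a.vdw_radius),
            }
            for a in unit.atoms
        ],
    }


def unit_from_dict(d: dict) -> RigidUnit:
    if "pdb" in d:
        return load_monomer(d["pdb"], d["chain"], d.get("residues"),
                            unit_label=d.get("label"))
    atoms = tuple(
        Atom(a["id"], int(a["residue"]), a["chain"],
             np.array(a["xyz"], dtype=float), float(a.get("vdw", 1.2)))
        for a in d["atoms"]
    )
    return RigidUnit(atoms, unit_label=d.get("label", "unit"),
                     composition=d.get("composition", "monomer"))


def system_to_dict(system: InterfaceAssemblySystem,
                   params: AtlasParams | None = None) -> dict:
    em = system.energy_model
    out = {
        "system_label": system.system_label,
        "fixed_unit": unit_to_dict(system.fixed_unit),
        "mobile_unit": unit_to_dict(system.mobile_unit),
        "energy": {
            "E_l": em.E_l, "E_h": em.E_h, "temperature": em.temperature,
        },
        "wells": [
            {
                "id": w.interaction_id, "atom_a": w.atom_a, "atom_b": w.atom_b,
                "lo": float(w.lo), "hi": float(w.hi),
                "residue_pair": [int(r) for r in w.residue_pair],
                "vdw_sum": float(w.vdw_sum),
            }
            for w in em.wells
        ],
        "true_pose": pose_to_dict(system.true_pose),
    }
    if params is not None:
        out["atlas"] = {
            "epsilon": params.epsilon, "cayley_step": params.cayley_step,
            "realization_tol": params.realization_tol,
            "max_samples_per_region": params.max_samples_per_region,
            "seed": params.seed,
        }
    return out


def system_from_dict(d: dict) -> tuple[InterfaceAssemblySystem, AtlasParams]:
    wells = tuple(
        DiscretizedWell(
            atom_a=w["atom_a"], atom_b=w["atom_b"], lo=float(w["lo"]),
            hi=float(w["hi"]), interaction_id=w["id"],
            residue_pair=tuple(w.get("residue_pair", (0, 0))),
            vdw_sum=float(w.get("vdw_sum", 2.4)),
        )
        for w in d["wells"]
    )
    e = d.get("energy", {})
    model = EnergyModel(
        wells=wells, E_l=float(e.get("E_l", -0.997)),
        E_h=float(e.get("E_h", 0.0)),
        temperature=float(e.get("temperature", 298.15)),
    )
    system = InterfaceAssemblySystem(
        fixed_unit=unit_from_dict(d["fixed_unit"]),
        mobile_unit=unit_from_dict(d["mobile_unit"]),
        energy_model=model,
        true_pose=pose_from_dict(d["true_pose"]),
        system_label=d.get("system_label", "system"),
    )
    a = d.get("atlas", {})
    params = AtlasParams(
        epsilon=float(a.get("epsilon", 0.5)),
        cayley_step=float(a.get("cayley_step", 0.5)),
        realization_tol=float(a.get("realization_tol", 0.05)),
        max_samples_per_region=int(a.get("max_samples_per_region", 400)),
        seed=int(a.get("seed", 0)),
    )
    return system, params


def save_system(system: InterfaceAssemblySystem, params: AtlasParams,
                path: str | Path) -> None:
    doc = system_to_dict(system, params)
    doc["provenance"] = provenance(params.seed, doc)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_system(path: str | Path) -> tuple[InterfaceAssemblySystem, AtlasParams]:
    return system_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Atlas JSON (round-trippable: configurations stored as poses)
# ---------------------------------------------------------------------------

def atlas_to_dict(atlas: Atlas) -> dict:
    nodes = []
    for label, r in sorted(atlas.regions.items()):
        nodes.append({
            "label": label,
            "edges": sorted(r.edges),
            "dimension": r.dim,
            "parents": sorted(r.parents),
            "children": sorted(r.children),
            "configurations": [pose_to_dict(c.pose) for c in r.configurations],
        })
    return {
        "system": atlas.system.system_label,
        "params": {
            "epsilon": atlas.params.epsilon,
            "cayley_step": atlas.params.cayley_step,
            "realization_tol": atlas.params.realization_tol,
            "max_samples_per_region": atlas.params.max_samples_per_region,
            "seed": atlas.params.seed,
        },
        "regions": nodes,
    }


def atlas_from_dict(data: dict, system: InterfaceAssemblySystem) -> Atlas:
    params = AtlasParams(**data["params"])
    atlas = Atlas(system=system, params=params)
    for node in data["regions"]:
        region = AtlasRegion(edges=frozenset(node["edges"]),
                             dim=int(node["dimension"]))
        region.parents = set(node["parents"])
        region.children = set(node["children"])
        for pd in node["configurations"]:
            region.configurations.append(
                system.configuration(pose_from_dict(pd))
            )
        atlas.regions[region.label] = region
    return atlas


def save_atlas(atlas: Atlas, path: str | Path) -> None:
    doc = atlas_to_dict(atlas)
    doc["provenance"] = provenance(atlas.params.seed, doc["params"])
    Path(path).write_text(json.dumps(doc, indent=1))


def load_atlas(path: str | Path, system: InterfaceAssemblySystem) -> Atlas:
    return atlas_from_dict(json.loads(Path(path).read_text()), system)


# ---------------------------------------------------------------------------
# Dual graph JSON / TSV
# ---------------------------------------------------------------------------

def dualgraph_to_dict(dg: DualGraph) -> dict:
    return {
        "T": dg.T,
        "nodes": [
            {"id": list(n), "chain": dg.graph.nodes[n]["chain"]}
            for n in sorted(dg.graph.nodes)
        ],
        "edges": [
            {"u": list(sorted(e)[0]), "v": list(sorted(e)[1]),
             "type": dg.edge_type[e]}
            for e in sorted(dg.edge_type, key=lambda e: tuple(sorted(e)))
        ],
        "type_annotations": dg.type_annotations,
    }


def dualgraph_from_dict(data: dict) -> DualGraph:
    G = nx.Graph()
    for n in data["nodes"]:
        G.add_node(tuple(n["id"]), chain=n["chain"])
    edge_type = {}
    for e in data["edges"]:
        u, v = tuple(e["u"]), tuple(e["v"])
        G.add_edge(u, v)
        edge_type[frozenset((u, v))] = e["type"]
    return DualGraph(T=int(data["T"]), graph=G, positions={}, rotations=[],
                     edge_type=edge_type,
                     type_annotations=data.get("type_annotations", {}))


def save_dualgraph(dg: DualGraph, path: str | Path, seed: int = 0) -> None:
    doc = dualgraph_to_dict(dg)
    doc["provenance"] = provenance(seed, {"T": dg.T})
    Path(path).write_text(json.dumps(doc, indent=1))


def dualgraph_edges_tsv(dg: DualGraph) -> str:
    lines = ["u\tv\ttype"]
    for e in sorted(dg.edge_type, key=lambda e: tuple(sorted(e))):
        u, v = sorted(e)
        lines.append(f"{u}\t{v}\t{dg.edge_type[e]}")
    return "\n".join(lines) + "\n"
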