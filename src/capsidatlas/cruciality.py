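"""Interaction-cruciality bar-codes from interface assembly atlases.

Two partition-function surrogates are read off an atlas:

* ``nu_minima`` — the number of epsilon-distinct configurations in the union
  of all 0-dimensional (minimum-energy) regions;
* ``nu_capsid`` — the normalized, Boltzmann-weighted share of the basin that
  contains the true realization: each configuration assigned to a basin
  contributes w(N_a) with N_a the active-constraint count of its own region,
  and the ratio (true basin) / (all basins) approximates the probability that
  assembly ends in the successful configuration.

Removing an interaction (or every interaction of a residue — a knockout)
restricts the atlas to the regions whose graphs avoid it; the cruciality
bar-code is the pair of ratios

    mu_minima = nu_minima(restricted) / nu_minima(full),
    mu_capsid = nu_capsid(restricted) / nu_capsid(full).

Small values mean the knockout destroys most minima or most of the true
basin — a crucial interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .atlas import Atlas, Basin, basin_decomposition, restrict_atlas
from .errors import UnknownInteractionError
from .geometry import similarity_distance


def nu_minima(atlas: Atlas) -> int:
    """Number of epsilon-distinct configurations across all 0-D regions."""
    eps = atlas.params.epsilon
    kept = []
    for region in atlas.zero_dim_regions():
        for cfg in region.configurations:
            if all(similarity_distance(cfg, k) >= eps for k in kept):
                kept.append(cfg)
    return len(kept)


def nu_capsid(atlas: Atlas, basins: list[Basin], true_idx: int | None,
              zero_dim_only: bool = False) -> float:
    """Weighted share of the true basin among all basins, in [0, 1].

    With ``zero_dim_only`` the sums run over bottom (0-D) configurations
    alone instead of whole basins.
    """
    if not basins:
        warnings.warn("no basins: nu_capsid undefined, returning 0")
        return 0.0
    w = atlas.system.energy_model.weight

    def basin_weight(b: Basin) -> float:
        if zero_dim_only:
            region = atlas.regions.get(b.bottom_label)
            if region is None:
                return 0.0
            return len(region.configurations) * w(len(region.edges))
        return float(sum(w(n_active) for _, n_active, _ in b.members))

    denom = sum(basin_weight(b) for b in basins)
    if denom == 0:
        warnings.warn("empty basins: nu_capsid undefined, returning 0")
        return 0.0
    if true_idx is None:
        return 0.0
    return basin_weight(basins[true_idx]) / denom


@dataclass(frozen=True)
class CrucialityBarcode:
    """(mu_minima, mu_capsid) for one knockout in one assembly system."""

    knockout: frozenset
    mu_minima: float
    mu_capsid: float
    system_label: str = ""
    undefined: bool = False  # x/0: full-atlas true basin carried no weight
    detail: dict = field(default_factory=dict, compare=False)

    @property
    def knockout_label(self) -> str:
        return "+".join(sorted(self.knockout)) if self.knockout else "wild-type"


def barcode(atlas: Atlas, basins: list[Basin], true_idx: int | None,
            knockout, zero_dim_only: bool = False) -> CrucialityBarcode:
    """Cruciality bar-code of a knockout against a built atlas.

    Conventions: 0/0 -> 1 (the knockout is irrelevant to an already-empty
    quantity); x/0 -> flagged undefined.
    """
    knockout = frozenset(knockout)
    nm_full = nu_minima(atlas)
    nc_full = nu_capsid(atlas, basins, true_idx, zero_dim_only)

    restricted = restrict_atlas(atlas, knockout)
    rbasins, rtrue = basin_decomposition(restricted, atlas.system.true_pose)
    nm_r = nu_minima(restricted)
    nc_r = nu_capsid(restricted, rbasins, rtrue, zero_dim_only)

    def ratio(num: float, den: float) -> tuple[float, bool]:
        if den == 0:
            return (1.0, False) if num == 0 else (float("nan"), True)
        return num / den, False

    mm, und1 = ratio(nm_r, nm_full)
    mc, und2 = ratio(nc_r, nc_full)
    return CrucialityBarcode(
        knockout=knockout, mu_minima=mm, mu_capsid=mc,
        system_label=atlas.system.system_label, undefined=und1 or und2,
        detail={
            "nu_minima_full": nm_full, "nu_minima_restricted": nm_r,
            "nu_capsid_full": nc_full, "nu_capsid_restricted": nc_r,
        },
    )


def residue_knockout(system, residue_id: int) -> frozenset:
    """All interaction ids whose wells involve the given residue, modelling
    simultaneous disabling by site-directed mutagenesis."""
    ids = frozenset(
        w.interaction_id for w in system.wells if residue_id in w.residue_pair
    )
    if not ids:
        raise UnknownInteractionError(
            f"residue {residue_id} carries no candidate interaction"
        )
    return ids


def cumulative_interface_barcode(barcodes: list[CrucialityBarcode]
                                 ) -> tuple[float, float]:
    """Component-wise mean of one knockout's bar-codes over an interface's
    assembly systems."""
    if not barcodes:
        raise ValueError("need at least one barcode to average")
    ks = {b.knockout for b in barcodes}
    if len(ks) != 1:
        raise ValueError("cannot average barcodes of different knockouts")
    return (
        float(np.mean([b.mu_minima for b in barcodes])),
        float(np.mean([b.mu_capsid for b in barcodes])),
    )


@dataclass
class InterfaceCrucialityTable:
    """Cumulative (mu_minima, mu_capsid) per knockout for one interface type."""

    interface_type: str
    rows: dict = field(default_factory=dict)  # knockout label -> (mm, mc)

    def add(self, knockout_label: str, mu_minima: float, mu_capsid: float):
        self.rows[knockout_label] = (float(mu_minima), float(mu_capsid))


WILD_TYPE = "wild-type"


def rank_by_barcode(table: InterfaceCrucialityTable) -> list[str]:
    """Knockouts ordered for display: wild type first, then descending
    mu_capsid (least crucial first), ties by descending mu_minima, then by
    knockout label."""
    if not table.rows:
        raise ValueError("empty cruciality table")
    rows = dict(table.rows)
    wt = [WILD_TYPE] if WILD_TYPE in rows else []
    rows.pop(WILD_TYPE, None)
    ordered = sorted(
        rows, key=lambda k: (-rows[k][1], -rows[k][0], k)
    )
    return wt + ordered
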