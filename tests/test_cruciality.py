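import numpy as np
import pytest

from capsidatlas.atlas import basin_decomposition, restrict_atlas
from capsidatlas.cruciality import (WILD_TYPE, CrucialityBarcode,
                                    InterfaceCrucialityTable, barcode,
                                    cumulative_interface_barcode, nu_capsid,
                                    nu_minima, rank_by_barcode,
                                    residue_knockout)
from capsidatlas.errors import UnknownInteractionError


class TestNuMinima:
    def test_no_zero_dim_regions(self, handmade_atlas):
        stripped = restrict_atlas(handmade_atlas, set())
        for label in list(stripped.regions):
            if stripped.regions[label].dim == 0:
                del stripped.regions[label]
        assert nu_minima(stripped) == 0

    def test_counts_bottom_configurations(self, handmade_atlas):
        assert nu_minima(handmade_atlas) == 2  # one per hand-built bottom

    def test_bottom_configs_are_genuine_minima(self, small_system,
                                               small_params, small_atlas):
        # every stored 0-D configuration must satisfy all its well-center
        # distance targets within the realization tolerance, and every
        # solution an independent multistart search finds must already be
        # in the atlas (the recursive search dominates the direct oracle)
        import numpy as np
        from capsidatlas.atlas import _multistart_poses, active_set, realize
        from capsidatlas.geometry import similarity_distance
        targets = [small_system.well_center_target(i)
                   for i in sorted(small_system.interaction_ids)]
        bottoms = small_atlas.zero_dim_regions()
        bottom_cfgs = [c for r in bottoms for c in r.configurations]
        assert bottom_cfgs
        # membership contract: every stored distance lies inside its well
        wells = {w.interaction_id: w for w in small_system.wells}
        for region in bottoms:
            for cfg in region.configurations:
                for iid in region.edges:
                    w = wells[iid]
                    i = small_system.fixed_unit.index_of(w.atom_a)
                    j = small_system.mobile_unit.index_of(w.atom_b)
                    d = float(np.linalg.norm(
                        cfg.mobile_coords[j] - small_system.fixed_unit.coords[i]))
                    assert w.lo <= d <= w.hi
        starts = _multistart_poses(small_system, 3.0, 24)
        starts += [small_system.true_pose]
        oracle = [s for s in realize(small_system, targets, small_params,
                                     starts=starts)
                  if active_set(small_system, s) == frozenset(
                      small_system.interaction_ids)]
        assert oracle
        for sol in oracle:
            assert min(similarity_distance(sol, c) for c in bottom_cfgs) \
                < small_params.epsilon
        assert nu_minima(small_atlas) >= len(oracle)


class TestNuCapsid:
    def test_true_basin_share_is_half_for_symmetric_bottoms(self, handmade_atlas):
        basins, ti = basin_decomposition(
            handmade_atlas, handmade_atlas.system.true_pose
        )
        assert ti is not None
        assert nu_capsid(handmade_atlas, basins, ti) == pytest.approx(0.5)

    def test_single_basin_is_one(self, handmade_atlas):
        ids = {"c", "d"}
        sub = restrict_atlas(handmade_atlas, ids)
        basins, ti = basin_decomposition(sub, sub.system.true_pose)
        assert len(basins) == 1 and ti == 0
        assert nu_capsid(sub, basins, ti) == pytest.approx(1.0)

    def test_true_pose_matching_no_bottom_gives_zero(self, handmade_atlas):
        from capsidatlas.geometry import Pose
        far = Pose(np.eye(3), np.array([50.0, 0.0, 0.0]))
        basins, ti = basin_decomposition(handmade_atlas, far)
        assert ti is None
        assert nu_capsid(handmade_atlas, basins, ti) == 0.0

    def test_no_basins_warns_and_returns_zero(self, handmade_atlas):
        stripped = restrict_atlas(handmade_atlas, set())
        for label in list(stripped.regions):
            if stripped.regions[label].dim == 0:
                del stripped.regions[label]
        with pytest.warns(UserWarning):
            assert nu_capsid(stripped, [], None) == 0.0

    def test_bounded_in_unit_interval(self, small_atlas, small_basins):
        basins, ti = small_basins
        assert 0.0 <= nu_capsid(small_atlas, basins, ti) <= 1.0

    def test_zero_dim_only_variant(self, handmade_atlas):
        basins, ti = basin_decomposition(
            handmade_atlas, handmade_atlas.system.true_pose
        )
        v = nu_capsid(handmade_atlas, basins, ti, zero_dim_only=True)
        assert v == pytest.approx(0.5)  # symmetric bottoms, equal weights


class TestBasinAssignment:
    def test_ancestors_follow_their_bottom(self, handmade_atlas):
        basins, ti = basin_decomposition(
            handmade_atlas, handmade_atlas.system.true_pose
        )
        by_label = {b.bottom_label: b for b in basins}
        # {a} configs are subgraphs of bottom {a,b} only
        assert {m[0] for m in by_label["a+b"].members} == {"a+b", "a"}
        assert {m[0] for m in by_label["c+d"].members} == {"c+d", "c"}

    def test_non_subgraph_regions_unassigned(self, handmade_atlas):
        basins, _ = basin_decomposition(
            handmade_atlas, handmade_atlas.system.true_pose
        )
        assigned = sum(len(b.members) for b in basins)
        total = sum(len(r.configurations)
                    for r in handmade_atlas.regions.values())
        assert assigned == total  # every hand-built region is a subgraph here


class TestBarcode:
    def test_wild_type_is_unity(self, small_atlas, small_basins):
        basins, ti = small_basins
        bc = barcode(small_atlas, basins, ti, frozenset())
        assert (bc.mu_minima, bc.mu_capsid) == (1.0, 1.0)

    def test_knockout_in_true_bottom_zeroes_mu_capsid(self, handmade_atlas):
        basins, ti = basin_decomposition(
            handmade_atlas, handmade_atlas.system.true_pose
        )
        bc = barcode(handmade_atlas, basins, ti, {"a"})
        assert bc.mu_capsid == 0.0
        assert bc.mu_minima == pytest.approx(0.5)

    def test_mu_minima_in_unit_interval(self, small_atlas, small_basins):
        basins, ti = small_basins
        for iid in sorted(small_atlas.system.interaction_ids):
            bc = barcode(small_atlas, basins, ti, {iid})
            assert 0.0 <= bc.mu_minima <= 1.0

    def test_restriction_monotone_in_knockout_set(self, small_atlas, small_basins):
        basins, ti = small_basins
        ids = sorted(small_atlas.system.interaction_ids)
        prev = None
        for k in range(1, len(ids) + 1):
            bc = barcode(small_atlas, basins, ti, set(ids[:k]))
            nm = bc.detail["nu_minima_restricted"]
            if prev is not None:
                assert nm <= prev
            prev = nm

    def test_residue_knockout_matches_single_interaction(self, handmade_atlas):
        system = handmade_atlas.system
        # residue 10 participates only in well "a" in the handmade system
        ko = residue_knockout(system, 10)
        assert ko == frozenset({"a"})
        basins, ti = basin_decomposition(handmade_atlas, system.true_pose)
        direct = barcode(handmade_atlas, basins, ti, {"a"})
        via_residue = barcode(handmade_atlas, basins, ti, ko)
        assert (via_residue.mu_minima, via_residue.mu_capsid) == (
            direct.mu_minima, direct.mu_capsid)

    def test_unknown_residue_rejected(self, handmade_atlas):
        with pytest.raises(UnknownInteractionError):
            residue_knockout(handmade_atlas.system, 99)


class TestCumulative:
    def test_identity_and_mean(self):
        b0 = CrucialityBarcode(frozenset({"x"}), 0.0, 0.0, "s1")
        b1 = CrucialityBarcode(frozenset({"x"}), 1.0, 1.0, "s2")
        assert cumulative_interface_barcode([b1, b1]) == (1.0, 1.0)
        assert cumulative_interface_barcode([b0, b1]) == (0.5, 0.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            cumulative_interface_barcode([])

    def test_mixed_knockouts_rejected(self):
        b0 = CrucialityBarcode(frozenset({"x"}), 0.5, 0.5)
        b1 = CrucialityBarcode(frozenset({"y"}), 0.5, 0.5)
        with pytest.raises(ValueError):
            cumulative_interface_barcode([b0, b1])


class TestRanking:
    def test_wild_type_first_then_descending(self):
        table = InterfaceCrucialityTable("2f")
        table.add(WILD_TYPE, 1.0, 1.0)
        table.add("k1", 0.9, 0.2)
        table.add("k2", 0.3, 0.8)
        table.add("k3", 0.8, 0.8)  # ties with k2 on mu_capsid
        order = rank_by_barcode(table)
        assert order[0] == WILD_TYPE
        assert order[1:] == ["k3", "k2", "k1"]

    def test_already_sorted_unchanged(self):
        table = InterfaceCrucialityTable("2f")
        for k, (mm, mc) in [("a", (0.9, 0.9)), ("b", (0.5, 0.5)), ("c", (0.1, 0.1))]:
            table.add(k, mm, mc)
        assert rank_by_barcode(table) == ["a", "b", "c"]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            table = InterfaceCrucialityTable("x")
            n = int(rng.integers(2, 12))
            for k in range(n):
                table.add(f"k{k}", float(rng.choice([0.2, 0.5, 0.8])),
                          float(rng.choice([0.2, 0.5, 0.8])))
            oracle = sorted(
                table.rows,
                key=lambda k: (-table.rows[k][1], -table.rows[k][0], k),
            )
            assert rank_by_barcode(table) == oracle

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            rank_by_barcode(InterfaceCrucialityTable("x"))
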