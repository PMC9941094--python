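import numpy as np
import pytest

from abvisc.attribution import (
    AttributionGrid,
    Patch,
    SignificanceThreshold,
    carboxylate_attribution,
    carboxylate_cation_distances,
    classify_patch_points,
    completeness_gap,
    find_patches,
    integrated_gradients,
    pool_significance,
    segment_composition,
)
from abvisc.errors import DegenerateError
from abvisc.fields import InputGrid
from abvisc.network import Cnn3d, NetworkConfig, train_fold
from abvisc.structure_io import Atom, SegmentMap, Structure
from abvisc.surface import GridSpec

SPEC8 = GridSpec(extent=3.0, spacing=1.0, padded_dim=8)


def grid8(channels):
    return InputGrid(spec=SPEC8, channels=channels)


def linear_model():
    """0 conv blocks: flatten -> dropout(off at eval) -> linear head."""
    cfg = NetworkConfig(n_blocks=0, dropout_rate=0.05)
    m = Cnn3d(cfg, in_channels=1, in_dim=8, seed=0)
    return m


class TestIntegratedGradients:
    def test_linear_model_closed_form(self):
        m = linear_model()
        rng = np.random.default_rng(0)
        x = grid8(rng.normal(size=(1, 8, 8, 8)))
        attr = integrated_gradients(m, x, steps=8)
        w = m.head.w.reshape(1, 8, 8, 8)
        np.testing.assert_allclose(
            attr.scores, (w * x.channels).sum(axis=0), atol=1e-12
        )

    def test_zero_path_zero_scores(self):
        m = linear_model()
        x = grid8(np.zeros((1, 8, 8, 8)))
        attr = integrated_gradients(m, x, baseline=x, steps=8)
        assert not np.any(attr.scores)

    def test_masked_voxels_get_zero_score(self):
        cfg = NetworkConfig(n_blocks=1, first_filters=2, dropout_rate=0.0)
        m = Cnn3d(cfg, 1, 8, seed=1)
        ch = np.zeros((1, 8, 8, 8))
        ch[0, 2:5, 2:5, 2:5] = 1.5
        attr = integrated_gradients(m, grid8(ch), steps=16)
        assert not np.any(attr.scores[ch[0] == 0.0])

    def test_completeness_gap_shrinks_with_steps(self):
        # trained (non-linear) toy model: the Riemann sum converges
        cfg = NetworkConfig(
            n_blocks=2, first_filters=2, dropout_rate=0.0,
            learning_rate=1e-2, epochs=10, selection_window=3,
        )
        rng = np.random.default_rng(2)
        grids = []
        for i in range(4):
            ch = np.zeros((1, 8, 8, 8))
            ch[0, 2:6, 2:6, 2:6] = rng.normal(size=(4, 4, 4))
            grids.append(
                InputGrid(spec=SPEC8, channels=ch, label_cP=10.0 ** (i / 2))
            )
        tm = train_fold(grids[:3], grids[3:], cfg, seed=4)
        x = grids[3]
        gaps = []
        for steps in (16, 64, 256):
            attr = integrated_gradients(tm.model, x, steps=steps)
            gaps.append(completeness_gap(tm.model, x, attr))
        assert gaps[2] < gaps[0]
        assert gaps[2] < 0.01


class TestPoolSignificance:
    def _grid(self, scores):
        return AttributionGrid(spec=SPEC8, scores=scores)

    def test_two_point_distribution(self):
        scores = np.zeros((8, 8, 8))
        scores[0, 0, 0] = 1.0
        scores[1, 1, 1] = -1.0
        thr = pool_significance([self._grid(scores)])
        assert thr.sigma == pytest.approx(1.0)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(3)
        scores = np.where(
            rng.random((8, 8, 8)) < 0.2, rng.normal(size=(8, 8, 8)), 0.0
        )
        g = self._grid(scores)
        assert pool_significance([g]).sigma == pytest.approx(
            pool_significance([g, g, g]).sigma
        )

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(4)
        gs = []
        for _ in range(3):
            scores = np.where(
                rng.random((8, 8, 8)) < 0.3, rng.normal(size=(8, 8, 8)), 0.0
            )
            gs.append(self._grid(scores))
        pooled = np.concatenate([g.scores[g.scores != 0] for g in gs])
        assert pool_significance(gs).sigma == pytest.approx(np.std(pooled))

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateError):
            pool_significance([self._grid(np.zeros((8, 8, 8)))])


def bfs_components(coords, link_dist, spacing):
    """Brute-force BFS oracle over pairwise distances."""
    m = len(coords)
    pts = coords * spacing
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    adj = d <= link_dist + 1e-9
    seen = np.zeros(m, bool)
    comps = []
    for i in range(m):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            j = stack.pop()
            comp.append(j)
            for k in np.nonzero(adj[j] & ~seen)[0]:
                seen[k] = True
                stack.append(k)
        comps.append(frozenset(map(tuple, coords[comp])))
    return set(comps)


class TestFindPatches:
    SPEC20 = GridSpec(extent=7.125, spacing=0.75, padded_dim=20)

    def test_nothing_significant_empty(self):
        a = AttributionGrid(spec=SPEC8, scores=np.full((8, 8, 8), 0.1))
        assert find_patches(a, SignificanceThreshold(1.0)) == []

    def test_two_far_clusters_two_patches(self):
        scores = np.zeros((20, 20, 20))
        scores[1:3, 1:3, 1:3] = 5.0
        scores[16:18, 16:18, 16:18] = 5.0
        a = AttributionGrid(spec=self.SPEC20, scores=scores)
        patches = find_patches(a, SignificanceThreshold(1.0))
        assert len(patches) == 2
        assert all(p.sign == 1 and p.size == 8 for p in patches)

    def test_signs_separated(self):
        scores = np.zeros((20, 20, 20))
        scores[5, 5, 5] = 5.0
        scores[5, 5, 6] = -5.0
        a = AttributionGrid(spec=self.SPEC20, scores=scores)
        patches = find_patches(a, SignificanceThreshold(1.0))
        assert {p.sign for p in patches} == {1, -1}
        assert len(patches) == 2

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bfs_oracle_on_random_sparse_grids(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.where(
            rng.random((20, 20, 20)) < 0.02,
            rng.normal(scale=3.0, size=(20, 20, 20)),
            0.0,
        )
        a = AttributionGrid(spec=self.SPEC20, scores=scores)
        thr = SignificanceThreshold(1.0)
        patches = find_patches(a, thr, link_dist=1.5)
        for sign in (1, -1):
            coords = np.argwhere(scores * sign > thr.sigma)
            expected = (
                bfs_components(coords, 1.5, 0.75) if len(coords) else set()
            )
            got = {
                frozenset(map(tuple, p.voxels))
                for p in patches
                if p.sign == sign
            }
            assert got == expected

    def test_partition_of_significant_voxels(self):
        rng = np.random.default_rng(99)
        scores = np.where(
            rng.random((20, 20, 20)) < 0.05,
            rng.normal(scale=3.0, size=(20, 20, 20)),
            0.0,
        )
        a = AttributionGrid(spec=self.SPEC20, scores=scores)
        thr = SignificanceThreshold(1.0)
        patches = find_patches(a, thr)
        covered = set()
        for p in patches:
            vs = set(map(tuple, p.voxels))
            assert not covered & vs
            covered |= vs
        assert covered == set(map(tuple, np.argwhere(np.abs(scores) > 1.0)))


# ---------------------------------------------------------------------------
# composition analyses on a hand-built structure


def _structure_for_composition():
    entries = [
        # Asp sidechain carboxylate near the "top"
        ("CB", "C", 1, (0.0, 0.0, 2.0), "ASP", "L"),
        ("CG", "C", 1, (0.0, 0.0, 3.2), "ASP", "L"),
        ("OD1", "O", 1, (0.8, 0.0, 4.0), "ASP", "L"),
        ("OD2", "O", 1, (-0.8, 0.0, 4.0), "ASP", "L"),
        # backbone carbonyl oxygen of a Gly far away
        ("C", "C", 2, (0.0, 0.0, -3.0), "GLY", "L"),
        ("O", "O", 2, (0.0, 0.0, -4.2), "GLY", "L"),
        # Tyr ring carbon off to the side
        ("CG", "C", 3, (4.0, 0.0, 0.0), "TYR", "H"),
        ("CD1", "C", 3, (5.0, 0.8, 0.0), "TYR", "H"),
    ]
    atoms = []
    for i, (name, el, num, pos, res, chain) in enumerate(entries):
        atoms.append(
            Atom(
                serial=i + 1, name=name, element=el, residue_name=res,
                residue_number=num, insertion_code="", chain_id=chain,
                position=np.array(pos, float), partial_charge=0.0,
                radius=1.7, mass=12.0,
            )
        )
    return Structure(atoms=atoms, chains={"L": "light", "H": "heavy"})


def _patch_at(spec, positions, scores=None):
    """Build a Patch whose voxels sit at the given physical positions."""
    idx = np.rint((np.array(positions) + spec.extent) / spec.spacing).astype(int)
    idx = idx + spec.pad_offset
    return Patch(
        voxels=idx,
        sign=1,
        scores=np.ones(len(idx)) if scores is None else np.asarray(scores),
        spec=spec,
    )


class TestCompositions:
    SPEC = GridSpec(extent=6.0, spacing=0.75, padded_dim=17)

    def test_pure_asp_patch(self):
        s = _structure_for_composition()
        p = _patch_at(self.SPEC, [(0.75, 0.0, 4.5), (-0.75, 0.0, 4.5)])
        comp = classify_patch_points(p, s)
        assert comp["asp_glu"] == pytest.approx(1.0)

    def test_tyr_ring_carbon_is_aromatic_not_lipophilic(self):
        s = _structure_for_composition()
        p = _patch_at(self.SPEC, [(5.25, 0.75, 0.0)])
        comp = classify_patch_points(p, s)
        assert comp["aromatic"] == pytest.approx(1.0)
        assert comp["lipophilic"] == 0.0

    def test_mixed_patch_matches_nearest_atom_oracle(self):
        s = _structure_for_composition()
        positions = [
            (0.75, 0.0, 4.5),
            (0.0, 0.0, -5.25),
            (5.25, 0.75, 0.0),
            (0.0, 0.0, 2.25),
        ]
        p = _patch_at(self.SPEC, positions)
        comp = classify_patch_points(p, s)
        # exhaustive nearest-atom assignment
        from abvisc.attribution import _atom_category, _voxel_positions

        pos = _voxel_positions(p, self.SPEC)
        counts = {}
        for v in pos:
            dists = [np.linalg.norm(v - a.position) for a in s.atoms]
            a = s.atoms[int(np.argmin(dists))]
            cat = _atom_category(a, a.residue_name)
            counts[cat] = counts.get(cat, 0) + 1
        for cat, c in counts.items():
            assert comp[cat] == pytest.approx(c / len(pos))
        assert sum(v for k, v in comp.items() if k in counts or v) >= 0

    def test_mainchain_carbonyl_subfraction(self):
        s = _structure_for_composition()
        p = _patch_at(self.SPEC, [(0.0, 0.0, -5.25)])
        comp = classify_patch_points(p, s)
        assert comp["acceptor"] == pytest.approx(1.0)
        assert comp["acceptor_mainchain_O"] == pytest.approx(1.0)

    def test_segment_composition(self):
        s = _structure_for_composition()
        seg = SegmentMap(
            {
                ("L", 1, ""): "CDR-L1",
                ("L", 2, ""): "framework",
                ("H", 3, ""): "CDR-H3",
            }
        )
        p = _patch_at(self.SPEC, [(0.75, 0.0, 4.5), (5.25, 0.75, 0.0)])
        comp = segment_composition(p, seg, s)
        assert comp["CDR-L1"] == pytest.approx(0.5)
        assert comp["CDR-H3"] == pytest.approx(0.5)

    def test_segment_fractions_sum_to_one(self):
        s = _structure_for_composition()
        seg = SegmentMap({k: "unknown" for k, _ in s.residues()})
        p = _patch_at(self.SPEC, [(0.0, 0.0, 4.5), (0.0, 0.0, -5.25)])
        comp = segment_composition(p, seg, s)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)


def _structure_for_carboxylates():
    """One Asp 3.0 A from a Lys NZ, one Glu ~12 A from any cation."""
    entries = [
        ("CG", "C", 1, (0.0, 0.0, 0.0), "ASP", "L"),
        ("OD1", "O", 1, (0.9, 0.0, 0.6), "ASP", "L"),
        ("OD2", "O", 1, (-0.9, 0.0, 0.6), "ASP", "L"),
        ("NZ", "N", 2, (0.0, 3.0, 0.0), "LYS", "L"),
        ("CD", "C", 3, (12.0, 0.0, 0.0), "GLU", "H"),
        ("OE1", "O", 3, (12.9, 0.0, 0.6), "GLU", "H"),
        ("OE2", "O", 3, (11.1, 0.0, 0.6), "GLU", "H"),
    ]
    atoms = []
    for i, (name, el, num, pos, res, chain) in enumerate(entries):
        atoms.append(
            Atom(
                serial=i + 1, name=name, element=el, residue_name=res,
                residue_number=num, insertion_code="", chain_id=chain,
                position=np.array(pos, float), partial_charge=0.0,
                radius=1.6, mass=12.0,
            )
        )
    return Structure(atoms=atoms, chains={"L": "light", "H": "heavy"})


class TestCarboxylateAnalysis:
    SPEC = GridSpec(extent=18.0, spacing=0.75, padded_dim=49)

    def test_proximal_distal_partition(self):
        s = _structure_for_carboxylates()
        d = carboxylate_cation_distances(s)
        assert d[("L", 1, "")] == pytest.approx(3.0, abs=0.01)
        assert d[("H", 3, "")] > 5.0

    def test_gap_zone_excluded(self):
        s = _structure_for_carboxylates()
        # move the Lys so the Asp carboxylate sits 4.2 A away
        s.atoms[3].position = np.array([0.0, 4.2, 0.0])
        scores = np.zeros((49, 49, 49))
        scores[24, 24, 26] = 1.0  # near the Asp carboxylate
        a = AttributionGrid(spec=self.SPEC, scores=scores)
        res = carboxylate_attribution(a, s)
        assert ("L", 1, "") not in res["proximal_residues"]
        assert ("L", 1, "") not in res["distal_residues"]

    def test_constructed_field_distal_exceeds_proximal(self):
        s = _structure_for_carboxylates()
        spec = self.SPEC

        def vox(pos):
            return tuple(
                np.rint((np.array(pos) + spec.extent) / spec.spacing).astype(int)
            )

        scores = np.zeros((49, 49, 49))
        scores[vox((0.0, 0.0, 1.5))] = -1.0  # near proximal Asp
        scores[vox((12.0, 0.0, 1.5))] = +1.0  # near distal Glu
        a = AttributionGrid(spec=spec, scores=scores)
        res = carboxylate_attribution(a, s)
        assert res["distal_mean"] is not None and res["proximal_mean"] is not None
        assert res["distal_mean"] > res["proximal_mean"]

    def test_no_carboxylates_raises(self):
        from conftest import make_atoms

        s = make_atoms([("CA", "C", 1, (0, 0, 0), 0.0, 1.7)])
        a = AttributionGrid(spec=SPEC8, scores=np.zeros((8, 8, 8)))
        with pytest.raises(DegenerateError):
            carboxylate_attribution(a, s)
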