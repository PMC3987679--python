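import math

import numpy as np
import pytest

from shiftbench import (
    DegenerateSpectrumError,
    PredictionSet,
    ProtonGroup,
    TreeNode,
    TreeParams,
    binning_similarity,
    build_tree,
    node_similarity,
    normalize_total,
    prepare_tree,
    simulate_spectrum,
    spectrum_similarity,
    tree_similarity,
)

from conftest import make_spectrum


def singlet(shift, **kwargs):
    return simulate_spectrum(PredictionSet("s", (ProtonGroup(shift, 1),)), **kwargs)


def walk(node):
    yield node
    if node.children:
        yield from walk(node.children[0])
        yield from walk(node.children[1])


class TestBuildTree:
    def test_symmetric_two_peak(self):
        y = np.zeros(101)
        g = np.linspace(10, 0, 101)
        y[np.argmin(abs(g - 7.0))] = 0.5
        y[np.argmin(abs(g - 3.0))] = 0.5
        t = build_tree(make_spectrum(y))
        assert t.com == pytest.approx(5.0)
        assert not t.is_leaf
        assert t.children[0].mass == pytest.approx(0.5)
        assert t.children[1].mass == pytest.approx(0.5)

    def test_delta_peak_com_constant(self):
        y = np.zeros(64)
        y[20] = 1.0
        s = make_spectrum(y)
        centre = s.ppm_grid()[20]
        t = build_tree(s)
        node = t
        while True:
            assert node.com == pytest.approx(centre)
            heavy = [c for c in (node.children or ()) if c.mass > 0]
            if not heavy:
                break
            (node,) = heavy

    def test_structural_conservation_random(self, rng):
        for _ in range(5):
            s = normalize_total(make_spectrum(rng.random(1024)))
            t = build_tree(s)
            for node in walk(t):
                if node.children:
                    left, right = node.children
                    assert left.mass + right.mass == pytest.approx(
                        node.mass, abs=1e-9
                    )
                    # children tile the parent region exactly
                    assert left.hi == node.hi and right.lo == node.lo
                    assert left.lo == right.hi

    def test_leaf_masses_sum_to_root(self, rng):
        s = normalize_total(make_spectrum(rng.random(512)))
        t = build_tree(s)
        leaves = [n.mass for n in walk(t) if n.is_leaf]
        assert sum(leaves) == pytest.approx(t.mass, abs=1e-9)

    def test_zero_mass_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            build_tree(make_spectrum(np.zeros(16)))

    def test_max_depth_respected(self, rng):
        s = normalize_total(make_spectrum(rng.random(1024)))
        t = build_tree(s, TreeParams(max_depth=3))
        def depth(n):
            return 1 + max((depth(c) for c in n.children), default=0) if n.children else 1
        assert depth(t) <= 4


class TestNodeSimilarity:
    def test_identical_nodes(self):
        a = TreeNode(0, 10, 0.4, 5.0)
        assert node_similarity(a, a) == 1.0

    def test_com_decay_scale(self):
        p = TreeParams()
        a = TreeNode(0, 10, 0.4, 5.0)
        b = TreeNode(0, 10, 0.4, 5.0 + p.com_scale)
        assert node_similarity(a, b, p) == pytest.approx(math.exp(-1))

    def test_mass_ratio(self):
        a = TreeNode(0, 10, 0.2, 5.0)
        b = TreeNode(0, 10, 0.1, 5.0)
        assert node_similarity(a, b) == pytest.approx(0.5)

    def test_empty_matches_empty_only(self):
        e = TreeNode(0, 10, 0.0, 5.0)
        f = TreeNode(0, 10, 0.3, 5.0)
        assert node_similarity(e, e) == 1.0
        assert node_similarity(e, f) == 0.0

    def test_symmetry(self):
        a = TreeNode(0, 10, 0.2, 4.0)
        b = TreeNode(0, 10, 0.7, 6.5)
        assert node_similarity(a, b) == node_similarity(b, a)


class TestTreeSimilarity:
    def test_self_similarity_is_one(self, rng):
        s = make_spectrum(rng.random(256))
        t = prepare_tree(s)
        assert tree_similarity(t, t) == 1.0

    def test_small_shift_beats_large_shift(self):
        s0 = singlet(5.0)
        near = spectrum_similarity(s0, singlet(5.05))
        far = spectrum_similarity(s0, singlet(10.0))
        assert near > far

    def test_symmetry_on_random_pairs(self, rng):
        p = TreeParams()
        for _ in range(20):
            a = prepare_tree(make_spectrum(rng.random(256)), p)
            b = prepare_tree(make_spectrum(rng.random(256)), p)
            assert tree_similarity(a, b, p) == pytest.approx(
                tree_similarity(b, a, p), abs=1e-12
            )

    def test_range_zero_one(self, rng):
        p = TreeParams()
        for _ in range(20):
            a = prepare_tree(make_spectrum(rng.random(128)), p)
            b = prepare_tree(make_spectrum(rng.random(128)), p)
            assert 0.0 <= tree_similarity(a, b, p) <= 1.0

    def test_mismatched_windows_rejected(self, rng):
        a = prepare_tree(make_spectrum(rng.random(64), ppm_max=10, ppm_min=0))
        b = prepare_tree(make_spectrum(rng.random(64), ppm_max=8, ppm_min=0))
        with pytest.raises(ValueError):
            tree_similarity(a, b)


class TestSpectrumSimilarity:
    def test_self_is_one(self):
        s = singlet(5.0)
        assert spectrum_similarity(s, s) == 1.0

    def test_monotone_decay_with_displacement(self):
        s0 = singlet(5.0)
        sims = [
            spectrum_similarity(s0, singlet(5.0 + d))
            for d in (0.0, 0.02, 0.05, 0.1, 0.5, 2.0)
        ]
        assert sims[0] == pytest.approx(1.0)
        assert all(a >= b - 1e-12 for a, b in zip(sims, sims[1:]))

    def test_zero_spectrum_rejected(self):
        s = singlet(5.0)
        with pytest.raises(DegenerateSpectrumError):
            spectrum_similarity(s, make_spectrum(np.zeros(s.n_points),
                                                 ppm_max=s.ppm_max, ppm_min=s.ppm_min))

    def test_different_grids_rejected(self, rng):
        a = make_spectrum(rng.random(64))
        b = make_spectrum(rng.random(128))
        with pytest.raises(ValueError):
            spectrum_similarity(a, b)


class TestBinningSimilarity:
    def test_identical_spectra(self, rng):
        s = make_spectrum(rng.random(512))
        assert binning_similarity(s, s, 64) == pytest.approx(1.0)

    def test_disjoint_peaks_orthogonal(self):
        a = np.zeros(256)
        b = np.zeros(256)
        a[10] = 1.0
        b[200] = 1.0
        assert binning_similarity(make_spectrum(a), make_spectrum(b), 16) == 0.0

    def test_matches_direct_cosine(self, rng):
        from shiftbench import bin_spectrum

        s1 = make_spectrum(rng.random(512))
        s2 = make_spectrum(rng.random(512))
        got = binning_similarity(s1, s2, 32)
        v1 = bin_spectrum(normalize_total(s1), 32).intensities
        v2 = bin_spectrum(normalize_total(s2), 32).intensities
        want = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        assert got == pytest.approx(want, abs=1e-12)


class TestShiftRobustness:
    def test_tree_beats_binning_for_small_displacement(self):
        """A small (0.05 ppm) displacement of one multiplet hurts the tree
        similarity less than the 256-bin cosine baseline, on average over
        sub-bin positions of the spectrum.

        Averaging matters because the binning baseline is bimodal: it stays
        near 1 while the displaced lines remain inside their bins and
        collapses once they cross an edge, whereas the tree degrades smoothly
        with the displacement.
        """
        tree_sims, bin_sims = [], []
        for off in np.linspace(0.0, 0.073, 10):  # spans one 256-bin width
            groups = (
                ProtonGroup(7.2 + off, 1, ((8.0, 1),)),
                ProtonGroup(4.1 + off, 2, ((7.0, 2),)),
                ProtonGroup(1.3 + off, 3, ((7.0, 1),)),
            )
            moved = groups[:2] + (ProtonGroup(1.35 + off, 3, ((7.0, 1),)),)
            a = simulate_spectrum(PredictionSet("m", groups))
            b = simulate_spectrum(PredictionSet("m", moved))
            tree_sims.append(spectrum_similarity(a, b))
            bin_sims.append(binning_similarity(a, b, 256))
        assert np.mean(tree_sims) > np.mean(bin_sims)

    def test_retrieval_sanity_tree_vs_binning(self):
        """On 50 synthetic molecules with 0.02 ppm prediction noise, tree
        retrieval is at least as good as 256-bin cosine retrieval (within an
        MRR margin of 0.05)."""
        from shiftbench import (
            SimilarityMatrix,
            SynthConfig,
            generate_truth,
            make_experimental,
            mrr,
            perturb_predictions,
            query_outcomes,
            report_from_matrix,
            similarity_matrix,
            simulate_all,
        )

        cfg = SynthConfig(n_molecules=50, seed=11)
        truth = generate_truth(cfg)
        experimental = make_experimental(truth, noise=0.01, seed=11)
        simulated = simulate_all(perturb_predictions(truth, 0.02, 11))
        ids = [s.molecule_id for s in experimental]
        tree_mrr = report_from_matrix(similarity_matrix(experimental, simulated)).mrr
        vals = np.array(
            [[binning_similarity(e, s, 256) for s in simulated] for e in experimental]
        )
        bin_mrr = mrr(query_outcomes(SimilarityMatrix(ids, vals)))
        assert tree_mrr >= bin_mrr - 0.05


class TestTreeParamsSerialization:
    def test_yaml_roundtrip(self, tmp_path):
        p = TreeParams(max_depth=6, min_mass=0.02, com_scale=0.15)
        f = tmp_path / "tree.yaml"
        p.save(f)
        assert TreeParams.load(f) == p

    def test_tree_json_export(self, tmp_path, rng):
        import json

        t = prepare_tree(make_spectrum(rng.random(128)))
        f = tmp_path / "tree.json"
        t.to_json(f)
        d = json.loads(f.read_text())
        assert {"lo", "hi", "mass", "com"} <= set(d)
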