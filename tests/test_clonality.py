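import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cloneweave import clonality as cl
from cloneweave.variants import CnvSegment


class TestCcfFormula:
    @pytest.mark.parametrize(
        "vaf,purity,cnt,cnn,m,expected",
        [
            (0.5, 1.0, 2, 2, 1, 1.0),    # pure diploid clonal het
            (0.25, 0.5, 2, 2, 1, 1.0),   # half purity halves the VAF
            (0.1, 0.8, 4, 2, 2, 0.225),  # gained locus, two mutated copies
        ],
    )
    def test_hand_computed_values(self, vaf, purity, cnt, cnn, m, expected):
        assert cl.compute_ccf(vaf, purity, cnt, cnn, m) == pytest.approx(expected)

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError):
            cl.compute_ccf(0.5, 0.0)

    @given(
        st.floats(0.01, 0.45),
        st.floats(0.05, 1.0),
        st.integers(1, 4),
    )
    @settings(deadline=None)
    def test_linear_in_vaf_and_decreasing_in_multiplicity(self, vaf, purity, cnt):
        one = cl.compute_ccf(vaf, purity, cnt, 2, 1)
        if one < cl.CCF_MAX and 2 * vaf <= 1:
            doubled = cl.compute_ccf(2 * vaf, purity, cnt, 2, 1)
            assert doubled == pytest.approx(min(2 * one, cl.CCF_MAX), rel=1e-9)
        if cnt >= 2:
            assert cl.compute_ccf(vaf, purity, cnt, 2, 2) <= one + 1e-12

    def test_pure_diploid_identity(self):
        for vaf in (0.1, 0.25, 0.5):
            assert cl.compute_ccf(vaf, 1.0, 2, 2, 1) == pytest.approx(2 * vaf)


class TestMultiplicity:
    @pytest.mark.parametrize(
        "vaf,purity,cnt,expected",
        [(0.5, 1.0, 2, 1), (0.9, 1.0, 2, 2), (0.05, 0.5, 3, 1)],
    )
    def test_rounding_and_clipping(self, vaf, purity, cnt, expected):
        assert cl.estimate_multiplicity(vaf, purity, cnt) == expected


class TestClonalStatus:
    def test_threshold_boundary(self):
        assert cl.call_clonal_status(1.0) == "clonal"
        assert cl.call_clonal_status(0.9) == "clonal"
        assert cl.call_clonal_status(0.89) == "subclonal"

    def test_clonal_mutations_mostly_called_clonal_at_depth_200(self):
        # truly clonal pure diploid het (VAF 0.5) at depth 200: the CCF
        # sampling s.d. is ~0.07, so >90% of draws clear the 0.9 threshold
        rng = np.random.default_rng(0)
        purity, depth = 1.0, 200
        alts = rng.binomial(depth, purity / 2, size=1000)
        n_clonal = sum(
            cl.call_clonal_status(cl.compute_ccf(a / depth, purity)) == "clonal"
            for a in alts
        )
        assert n_clonal >= 900


class TestCloneInference:
    def test_homogeneous_ccf_gives_single_clone(self):
        rng = np.random.default_rng(1)
        depth = 200
        c = np.full(2, 0.4)  # CCF-to-VAF factor per region
        total = rng.poisson(depth, (60, 2))
        alt = rng.binomial(total, 0.4)  # CCF 1 in both regions
        model = cl.infer_clones(alt, total, c, max_clones=5, seed=0)
        assert len(model.clones) == 1
        assert np.allclose(model.clonality.to_numpy(), 1.0, atol=0.05)

    def test_two_separated_clusters_recovered(self):
        rng = np.random.default_rng(2)
        depth, n = 200, 100
        c = np.full(2, 0.5)
        ccf = np.vstack(
            [np.tile([1.0, 1.0], (n, 1)), np.tile([0.4, 0.0], (n, 1))]
        )
        total = rng.poisson(depth, ccf.shape)
        alt = rng.binomial(total, ccf * c)
        model = cl.infer_clones(alt, total, c, max_clones=6, seed=0)
        assert len(model.clones) == 2
        labels = np.array(
            [model.assignment[f"M{i + 1}"] for i in range(2 * n)]
        )
        # cluster 1 is the trunk-like high-clonality cluster
        accuracy = (
            (labels[:n] == "C1").sum() + (labels[n:] == "C2").sum()
        ) / (2 * n)
        assert accuracy >= 0.95
        assert model.clonality.loc["C1"].to_numpy() == pytest.approx(
            [1.0, 1.0], abs=0.05
        )
        assert model.clonality.loc["C2", model.clonality.columns[0]] == pytest.approx(
            0.4, abs=0.05
        )

    def test_loglik_nondecreasing_and_deterministic(self, sim_patient):
        _, sim = sim_patient
        m1 = cl.infer_clones_for_patient(sim.records, sim.regions, sim.segments, seed=7)
        m2 = cl.infer_clones_for_patient(sim.records, sim.regions, sim.segments, seed=7)
        trace = np.array(m1.loglik_trace)
        assert (np.diff(trace) >= -1e-6).all()
        assert m1.assignment == m2.assignment
        assert m1.clonality.equals(m2.clonality)

    def test_single_mutation_returns_single_clone_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            model = cl.infer_clones(
                np.array([[20, 10]]), np.array([[80, 80]]), np.full(2, 0.5), seed=0
            )
        assert model.clones == ["C1"]


class TestDominantSubclones:
    def _model(self, values, regions=("R1",)):
        import pandas as pd

        clones = [f"C{i + 1}" for i in range(len(values))]
        return cl.CloneModel(
            clones=clones,
            clonality=pd.DataFrame(
                np.array(values).reshape(len(values), len(regions)),
                index=clones, columns=list(regions),
            ),
            assignment={},
            bic=0.0,
        )

    def test_strict_inequality_at_half(self):
        model = self._model([0.5, 0.8, 0.15])
        assert cl.dominant_subclones(model, "R1") == {"C2"}

    def test_random_models_match_brute_force(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 1, 5)
            model = self._model(vals)
            expected = {f"C{i + 1}" for i, v in enumerate(vals) if v > 0.5}
            assert cl.dominant_subclones(model, "R1") == expected

    def test_unknown_region_rejected(self):
        with pytest.raises(KeyError):
            cl.dominant_subclones(self._model([0.6]), "nope")


class TestClonalRelationship:
    def _model_from_sets(self, sets):
        import pandas as pd

        clones = list(sets)
        assignment = {k: c for c, keys in sets.items() for k in keys}
        return cl.CloneModel(
            clones=clones,
            clonality=pd.DataFrame(
                np.ones((len(clones), 1)), index=clones, columns=["R1"]
            ),
            assignment=assignment,
            bic=0.0,
        )

    def test_disjoint_tumours_not_clonal(self):
        a = self._model_from_sets({"C1": {f"a{i}" for i in range(10)}})
        b = self._model_from_sets({"C1": {f"b{i}" for i in range(10)}})
        assert cl.classify_clonal_relationship(a, b) == (0, "not clonal")

    def test_one_shared_clone_detected(self):
        shared = {f"s{i}" for i in range(8)}
        a = self._model_from_sets({"C1": {f"a{i}" for i in range(10)}, "C2": shared})
        b = self._model_from_sets({"C1": {f"b{i}" for i in range(12)}, "C2": shared})
        assert cl.classify_clonal_relationship(a, b) == (1, "one subclone in common")

    def test_two_shared_clones_clonally_related(self):
        s1 = {f"s{i}" for i in range(6)}
        s2 = {f"t{i}" for i in range(6)}
        a = self._model_from_sets({"C1": s1, "C2": s2})
        b = self._model_from_sets({"C1": s1, "C2": s2, "C3": {"x1", "x2"}})
        n, label = cl.classify_clonal_relationship(a, b)
        assert (n, label) == (2, "clonally related")

    def test_symmetric_in_tumour_order(self):
        shared = {f"s{i}" for i in range(8)}
        a = self._model_from_sets({"C1": {f"a{i}" for i in range(10)}, "C2": shared})
        b = self._model_from_sets({"C1": shared, "C2": {f"b{i}" for i in range(5)}})
        assert (
            cl.classify_clonal_relationship(a, b)[0]
            == cl.classify_clonal_relationship(b, a)[0]
        )


class TestDifferentialCnv:
    def _segments(self, region_ids, log2_by_chrom, noise=0.0, rng=None):
        segs = []
        for rid in region_ids:
            for chrom, val in log2_by_chrom.items():
                jitter = rng.normal(0, noise) if (rng is not None and noise) else 0.0
                segs.append(CnvSegment(rid, chrom, 1, 10_000, val + jitter))
        return segs

    def test_identical_profiles_yield_no_hits(self):
        profile = {"1": 0.0, "2": 0.5, "3": -0.2}
        a = self._segments(["A1", "A2", "A3"], profile)
        b = self._segments(["B1", "B2", "B3"], profile)
        hits = cl.differential_cnv(a, b)
        assert hits.empty

    def test_shifted_bin_detected_with_exact_rank_test(self):
        base = {"1": 0.0, "2": 0.0, "3": 0.0}
        shifted = dict(base, **{"3": 2.0})
        a = self._segments(["A1", "A2", "A3"], shifted)
        b = self._segments(["B1", "B2", "B3"], base)
        # smallest exact two-sided rank-sum p at 3 vs 3 is 0.1
        hits = cl.differential_cnv(a, b, p_thresh=0.15, q_thresh=0.5)
        assert list(hits["chrom"]) == ["3"]
        assert hits["p"].iloc[0] == pytest.approx(0.1, abs=1e-9)

    def test_single_region_fallback_rule(self):
        a = self._segments(["A1"], {"1": 2.5, "2": 0.0})
        b = self._segments(["B1", "B2"], {"1": 0.0, "2": 0.0})
        with pytest.warns(UserWarning, match="fallback"):
            hits = cl.differential_cnv(a, b, p_thresh=0.05, q_thresh=0.5)
        assert list(hits["chrom"]) == ["1"]

    def test_simulated_differential_arms_recovered_with_fdr_control(self):
        rng = np.random.default_rng(42)
        n_true, n_null = 4, 18
        false_disc, disc, missed = 0, 0, 0
        for _ in range(10):
            base = {str(c): 0.0 for c in range(1, n_true + n_null + 1)}
            shifted = dict(base, **{str(c): 2.0 for c in range(1, n_true + 1)})
            a = self._segments([f"A{i}" for i in range(5)], shifted, 0.1, rng)
            b = self._segments([f"B{i}" for i in range(5)], base, 0.1, rng)
            hits = cl.differential_cnv(a, b)
            got = set(hits["chrom"])
            truth = {str(c) for c in range(1, n_true + 1)}
            false_disc += len(got - truth)
            disc += len(got)
            missed += len(truth - got)
        assert missed == 0
        if disc:
            assert false_disc / disc <= 0.15
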