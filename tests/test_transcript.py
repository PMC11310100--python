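import numpy as np
import pandas as pd
import pytest

from rehoscales.synthdata import SimulationConfig, make_atlas, make_expression_bundle
from rehoscales.transcript import (
    ProbeBundle,
    SampleAnnotation,
    assign_samples,
    differential_stability,
    filter_probes_background,
    process_bundle,
    regional_expression,
    select_representative_probes,
)


def toy_bundle(expr_rows, probe2gene, calls, rnaseq_rows, donors=None):
    samples = [f"s{i}" for i in range(len(next(iter(expr_rows.values()))))]
    expression = pd.DataFrame(expr_rows, index=samples).T[samples]
    pacalls = pd.DataFrame(calls, index=samples).T[samples]
    rnaseq = pd.DataFrame(rnaseq_rows, index=samples).T[samples]
    if donors is None:
        donors = pd.Series("d1", index=samples)
    return ProbeBundle(
        expression=expression,
        probe2gene=pd.Series(probe2gene),
        pacalls=pacalls,
        rnaseq=rnaseq,
        donors=donors,
    )


class TestBackgroundFilter:
    def test_boundary_is_strict(self):
        # present in 100%, exactly 50%, and 25% of 4 samples
        bundle = toy_bundle(
            {"p_all": [1, 2, 3, 4], "p_half": [1, 2, 3, 4], "p_low": [1, 2, 3, 4]},
            {"p_all": "gA", "p_half": "gB", "p_low": "gC"},
            {"p_all": [1, 1, 1, 1], "p_half": [1, 1, 0, 0], "p_low": [1, 0, 0, 0]},
            {"gA": [1, 2, 3, 4]},
        )
        kept = set(filter_probes_background(bundle))
        assert kept == {"p_all"}  # "over 50%" excludes the exact-half probe

    def test_toy_enumeration(self):
        calls = {
            "p1": [1, 1, 1, 0, 0],  # 60% -> kept
            "p2": [1, 1, 0, 0, 0],  # 40% -> dropped
            "p3": [1, 1, 1, 1, 1],  # 100% -> kept
            "p4": [0, 0, 0, 0, 0],  # 0% -> dropped
        }
        expr = {p: [1.0, 2, 3, 4, 5] for p in calls}
        bundle = toy_bundle(expr, {p: "g" for p in calls}, calls, {"g": [1, 2, 3, 4, 5]})
        assert set(filter_probes_background(bundle)) == {"p1", "p3"}


class TestRepresentativeProbes:
    def test_monotone_transform_scores_rho_one(self):
        x = [0.5, 1.5, -0.3, 2.2, 0.1]
        bundle = toy_bundle(
            {"pA": x, "pB": [0.0, 0.1, -0.1, 0.05, 0.02]},
            {"pA": "g1", "pB": "g1"},
            {"pA": [1] * 5, "pB": [1] * 5},
            {"g1": list(np.exp(x))},
        )
        out = select_representative_probes(bundle)
        assert list(out.index) == ["g1"]
        assert np.allclose(out.loc["g1"].to_numpy(), x)

    def test_gene_dropped_when_all_probes_below_threshold(self):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(10).tolist()
        bundle = toy_bundle(
            {"p1": noise, "p2": rng.standard_normal(10).tolist()},
            {"p1": "g1", "p2": "g1"},
            {"p1": [1] * 10, "p2": [1] * 10},
            {"g1": rng.standard_normal(10).tolist()},
        )
        out = select_representative_probes(bundle, rho_threshold=0.99)
        assert len(out) == 0

    def test_two_gene_four_probe_selection_matches_enumeration(self):
        rng = np.random.default_rng(1)
        base1, base2 = rng.standard_normal(12), rng.standard_normal(12)
        probes = {
            "a1": base1 + 0.1 * rng.standard_normal(12),
            "a2": base1 + 1.5 * rng.standard_normal(12),
            "b1": base2 + 1.5 * rng.standard_normal(12),
            "b2": base2 + 0.1 * rng.standard_normal(12),
        }
        bundle = toy_bundle(
            {k: v.tolist() for k, v in probes.items()},
            {"a1": "gA", "a2": "gA", "b1": "gB", "b2": "gB"},
            {k: [1] * 12 for k in probes},
            {"gA": base1.tolist(), "gB": base2.tolist()},
        )
        out = select_representative_probes(bundle)
        # exhaustive check: highest-spearman probe per gene
        from scipy.stats import spearmanr

        for gene, candidates in (("gA", ["a1", "a2"]), ("gB", ["b1", "b2"])):
            rhos = {p: spearmanr(probes[p], bundle.rnaseq.loc[gene]).statistic for p in candidates}
            winner = max(sorted(rhos), key=lambda p: rhos[p])
            assert np.allclose(out.loc[gene].to_numpy(), probes[winner])

    def test_gene_without_rnaseq_removed(self):
        x = [1.0, 2, 3, 4, 5]
        bundle = toy_bundle(
            {"p1": x, "p2": x},
            {"p1": "gKnown", "p2": "gUnknown"},
            {"p1": [1] * 5, "p2": [1] * 5},
            {"gKnown": x},
        )
        out = select_representative_probes(bundle)
        assert list(out.index) == ["gKnown"]

    def test_too_few_shared_samples_refused(self):
        x = [1.0, 2, 3]
        bundle = toy_bundle({"p1": x}, {"p1": "g"}, {"p1": [1] * 3}, {"g": x})
        with pytest.raises(ValueError, match="shared"):
            select_representative_probes(bundle)


class TestDifferentialStability:
    def test_identical_profiles_score_one(self):
        genes = pd.DataFrame(
            np.tile([[1.0, 2, 3, 4, 1, 2, 3, 4]], (3, 1)),
            index=["g1", "g2", "g3"],
            columns=[f"s{i}" for i in range(8)],
        )
        donors = pd.Series(["d1"] * 4 + ["d2"] * 4, index=genes.columns)
        regions = pd.Series([1, 2, 3, 4, 1, 2, 3, 4], index=genes.columns)
        ds = differential_stability(genes, donors, regions)
        assert np.allclose(ds.scores, 1.0)

    def test_reversed_profiles_score_minus_one(self):
        genes = pd.DataFrame(
            [[1.0, 2, 3, 4, 4, 3, 2, 1]], index=["g1"], columns=[f"s{i}" for i in range(8)]
        )
        donors = pd.Series(["d1"] * 4 + ["d2"] * 4, index=genes.columns)
        regions = pd.Series([1, 2, 3, 4, 1, 2, 3, 4], index=genes.columns)
        ds = differential_stability(genes, donors, regions)
        assert ds.scores["g1"] == pytest.approx(-1.0)

    def test_hand_correlation_two_donors_four_regions(self):
        profile_d1 = np.array([1.0, 2.0, 4.0, 3.0])
        profile_d2 = np.array([2.0, 1.0, 5.0, 4.0])
        genes = pd.DataFrame(
            [np.concatenate([profile_d1, profile_d2])],
            index=["g1"],
            columns=[f"s{i}" for i in range(8)],
        )
        donors = pd.Series(["d1"] * 4 + ["d2"] * 4, index=genes.columns)
        regions = pd.Series([1, 2, 3, 4, 1, 2, 3, 4], index=genes.columns)
        ds = differential_stability(genes, donors, regions)
        assert ds.scores["g1"] == pytest.approx(np.corrcoef(profile_d1, profile_d2)[0, 1])

    def test_top_half_rounding_is_ceiling(self):
        rng = np.random.default_rng(2)
        n_genes = 5
        genes = pd.DataFrame(
            rng.standard_normal((n_genes, 8)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(8)],
        )
        donors = pd.Series(["d1"] * 4 + ["d2"] * 4, index=genes.columns)
        regions = pd.Series([1, 2, 3, 4, 1, 2, 3, 4], index=genes.columns)
        ds = differential_stability(genes, donors, regions)
        assert len(ds.retained) == 3  # ceil(5/2)

    def test_single_donor_rejected(self):
        genes = pd.DataFrame([[1.0, 2, 3]], index=["g"], columns=["s0", "s1", "s2"])
        donors = pd.Series(["d1"] * 3, index=genes.columns)
        regions = pd.Series([1, 2, 3], index=genes.columns)
        with pytest.raises(ValueError, match="donors"):
            differential_stability(genes, donors, regions)


class TestSampleAssignment:
    def test_sample_at_voxel_centre_hits_its_region(self, tiny_atlas):
        labels = tiny_atlas.labels[2]
        vox = np.argwhere(labels == 3)[0]
        world = tiny_atlas.affine[:3, :3] @ vox + tiny_atlas.affine[:3, 3]
        ann = SampleAnnotation(
            pd.DataFrame(
                {
                    "sample_id": ["s1"],
                    "donor": ["d1"],
                    "x": [world[0]],
                    "y": [world[1]],
                    "z": [world[2]],
                    "hemisphere": ["L"],
                    "compartment": ["cortical"],
                }
            )
        )
        assert assign_samples(ann, tiny_atlas, 2)["s1"] == 3

    def test_brute_force_oracle_on_random_samples(self, tiny_atlas):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-10, 10, size=(3, 3))
        ann = SampleAnnotation(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(3)],
                    "donor": "d1",
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                    "z": pts[:, 2],
                    "hemisphere": "L",
                    "compartment": "cortical",
                }
            )
        )
        got = assign_samples(ann, tiny_atlas, 2, max_distance=np.inf)
        labels = tiny_atlas.labels[2]
        ijk = np.argwhere(labels > 0)
        centres = (tiny_atlas.affine[:3, :3] @ ijk.T).T + tiny_atlas.affine[:3, 3]
        for i, pt in enumerate(pts):
            d = np.linalg.norm(centres - pt, axis=1)
            winners = labels[tuple(ijk[d <= d.min() + 1e-9].T)]
            assert got[f"s{i}"] == winners.min()

    def test_distant_sample_unassigned(self, tiny_atlas):
        ann = SampleAnnotation(
            pd.DataFrame(
                {
                    "sample_id": ["far"],
                    "donor": ["d1"],
                    "x": [500.0],
                    "y": [0.0],
                    "z": [0.0],
                    "hemisphere": ["L"],
                    "compartment": ["cortical"],
                }
            )
        )
        assert np.isnan(assign_samples(ann, tiny_atlas, 2)["far"])


class TestRegionalExpression:
    def test_one_sample_per_region_is_reindexing(self):
        genes = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["s0", "s1", "s2"])
        assignments = pd.Series({"s0": 3, "s1": 1, "s2": 2})
        out = regional_expression(genes, assignments)
        assert list(out.columns) == [1, 2, 3]
        assert out.loc["g"].tolist() == [2.0, 3.0, 1.0]

    def test_region_mean_matches_hand_sum(self):
        genes = pd.DataFrame(
            [[1.0, 3.0, 10.0], [2.0, 4.0, 20.0]], index=["g1", "g2"], columns=["s0", "s1", "s2"]
        )
        assignments = pd.Series({"s0": 1, "s1": 1, "s2": 2})
        out = regional_expression(genes, assignments)
        assert out.loc["g1", 1] == pytest.approx(2.0)
        assert out.loc["g2", 1] == pytest.approx(3.0)
        assert out.loc["g1", 2] == pytest.approx(10.0)


class TestPipelineOrder:
    def test_noiseless_bundle_roundtrips_exactly(self, tiny_atlas, tiny_config):
        import dataclasses

        from rehoscales.synthdata import synthetic_effect_map

        cfg = dataclasses.replace(
            tiny_config, noise_sd=0.0, probes_per_gene=1, absent_probe_fraction=0.0,
            n_genes=40, n_modules=2, module_sizes=(15, 15), n_expression_samples=40,
        )
        tmap = synthetic_effect_map(tiny_atlas, cfg.effect_regions, seed=9)
        bundle, ann, truth = make_expression_bundle(cfg, tiny_atlas, tmap)
        genes = select_representative_probes(bundle, filter_probes_background(bundle))
        expected = bundle.expression.copy()
        expected.index = [p.rsplit("_p", 1)[0] for p in expected.index]
        assert genes.shape == expected.shape
        assert np.allclose(genes.to_numpy(), expected.loc[genes.index].to_numpy())

    def test_background_before_rho_filter_changes_outcome(self):
        # probe pA: tracks RNA-seq (high rho) but below background ->
        # correct order drops it and selects pB; reversed order would pick pA
        x = np.linspace(0, 1, 8)
        noisy = (x + np.array([0.05, -0.08, 0.1, -0.02, 0.07, -0.01, 0.03, -0.06])).tolist()
        bundle = toy_bundle(
            {"pA": x.tolist(), "pB": noisy},
            {"pA": "g", "pB": "g"},
            {"pA": [1, 1, 0, 0, 0, 0, 0, 0], "pB": [1] * 8},
            {"g": x.tolist()},
        )
        kept = filter_probes_background(bundle)
        assert "pA" not in set(kept)
        out = select_representative_probes(bundle, kept)
        assert np.allclose(out.loc["g"].to_numpy(), noisy)
        # without the background stage the cleaner probe would win instead
        out_unfiltered = select_representative_probes(bundle)
        assert np.allclose(out_unfiltered.loc["g"].to_numpy(), x)

    def test_process_bundle_restricts_to_left_hemisphere(self, tiny_atlas, tiny_config, tiny_bundle):
        (bundle, ann, truth), _ = tiny_bundle
        processed = process_bundle(bundle, ann, tiny_atlas, ds_scale=2)
        assert processed.log["n_samples"] == (ann.table["hemisphere"] == "L").sum()
        assert processed.log["n_genes_retained_ds"] == int(np.ceil(
            processed.log["n_genes_representative"] / 2
        ))
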