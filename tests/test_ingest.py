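"""Probe mapping, contrast definition, normalization and assembly tests."""

import numpy as np
import pandas as pd
import pytest

from crosscomp import simulate as sim
from crosscomp.errors import (
    AssemblyError,
    ConfigurationError,
    DefinitionError,
    DomainError,
    FitError,
    ParseError,
)
from crosscomp.ingest import (
    PROCESSING_STEPS,
    ChannelInfo,
    ContrastDefinition,
    HybridizationTable,
    assemble_compendium,
    build_compendium_from_raw,
    compute_contrast_logratios,
    define_contrasts,
    loess_normalize_dual,
    map_probes,
    quantile_normalize,
)

GENE_INDEX = pd.DataFrame(
    {
        "gene_id": ["b0001", "b0002", "b0003"],
        "alt_tags": ["JW0001", "JW0002", ""],
        "gene_name": ["thrA", "thrB", "thrC"],
    }
)


# ---------------------------------------------------------------------------
# probe mapping
# ---------------------------------------------------------------------------


class TestMapProbes:
    def test_identifier_preference_order(self):
        probes = pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "locus_tag": ["b0001", "zzz", ""],
                "alt_tags": ["JW0002", "", ""],  # ignored for p1: locus wins
                "gene_name": ["", "thrB", "thrC"],
            }
        )
        pm = map_probes(probes, GENE_INDEX)
        assert pm.mapping["p1"] == "b0001" and pm.provenance["p1"] == "locus_tag"
        assert pm.mapping["p2"] == "b0002" and pm.provenance["p2"] == "gene_name"
        assert pm.mapping["p3"] == "b0003" and pm.provenance["p3"] == "gene_name"

    def test_ambiguity_at_winning_tier_unmaps(self):
        probes = pd.DataFrame(
            {
                "probe_id": ["p1"],
                "locus_tag": [""],
                "alt_tags": ["JW0001|JW0002"],
                "gene_name": ["thrC"],  # never reached: alt tier won
            }
        )
        pm = map_probes(probes, GENE_INDEX)
        assert "p1" not in pm.mapping.index
        assert pm.provenance["p1"] == "unmapped"

    def test_sequence_hits_unique_best(self):
        probes = pd.DataFrame({"probe_id": ["p1", "p2", "p3"]})
        hits = pd.DataFrame(
            {
                "probe_id": ["p1", "p1", "p2", "p2", "p3"],
                "gene_id": ["b0001", "b0002", "b0001", "b0002", "b0003"],
                "identity": [100.0, 97.0, 99.0, 99.0, 100.0],
                "coverage": [1.0, 1.0, 0.95, 0.95, 0.5],
            }
        )
        pm = map_probes(probes, GENE_INDEX, hits=hits)
        assert pm.mapping["p1"] == "b0001"  # unique best
        assert pm.provenance["p1"] == "sequence"
        assert pm.provenance["p2"] == "unmapped"  # tied best between two genes
        assert pm.provenance["p3"] == "unmapped"  # fails coverage threshold

    def test_malformed_hits_and_empty_index(self):
        probes = pd.DataFrame({"probe_id": ["p1"]})
        with pytest.raises(ParseError):
            map_probes(
                probes,
                GENE_INDEX,
                hits=pd.DataFrame(
                    {"probe_id": ["p1"], "gene_id": ["b0001"],
                     "identity": [150.0], "coverage": [1.0]}
                ),
            )
        with pytest.raises(ConfigurationError):
            map_probes(probes, [])


# ---------------------------------------------------------------------------
# contrast definition
# ---------------------------------------------------------------------------


def _dual_hyb(hyb_id="h1", ch2_bio=True, exp="E1"):
    intens = pd.DataFrame({"ch1": [100.0] * 3, "ch2": [200.0] * 3})
    return HybridizationTable(
        experiment_id=exp,
        platform_id="P1",
        hybridization_id=hyb_id,
        channel_layout="dual",
        intensities=intens,
        channels={
            "ch1": ChannelInfo(role="reference", biological=True),
            "ch2": ChannelInfo(role="test", biological=ch2_bio),
        },
    )


def _single_hyb(hyb_id, role, exp="E1"):
    return HybridizationTable(
        experiment_id=exp,
        platform_id="P1",
        hybridization_id=hyb_id,
        channel_layout="single",
        intensities=pd.DataFrame({"ch1": [100.0] * 3}),
        channels={"ch1": ChannelInfo(role=role)},
    )


class TestDefineContrasts:
    def test_dual_both_biological_gives_within_array_contrast(self):
        (d,) = define_contrasts([_dual_hyb()])
        assert d.test_members == (("h1", "ch2"),)
        assert d.reference_members == (("h1", "ch1"),)

    def test_non_biological_channel_demotes_to_single(self):
        # the test channel is genomic DNA: reference channel survives as a
        # single-channel member, which needs a designated reference
        hybs = [_dual_hyb(ch2_bio=False), _single_hyb("ref1", "reference")]
        defs = define_contrasts(hybs)
        assert len(defs) == 1
        assert defs[0].test_members == (("h1", "ch1"),)
        assert defs[0].reference_members == (("ref1", "ch1"),)

    def test_single_channel_one_ref_three_tests(self):
        hybs = [_single_hyb("r", "reference")] + [
            _single_hyb(f"t{i}", "test") for i in range(3)
        ]
        defs = define_contrasts(hybs)
        assert len(defs) == 3
        assert all(d.reference_members == (("r", "ch1"),) for d in defs)

    def test_no_reference_raises(self):
        with pytest.raises(DefinitionError):
            define_contrasts([_single_hyb("t1", "test")])

    def test_pairing_hints_override(self):
        hybs = [_single_hyb("r", "reference"), _single_hyb("t1", "test")]
        hints = {("E1", "P1"): [((("t1", "ch1"),), (("r", "ch1"),))]}
        defs = define_contrasts(hybs, pairing_hints=hints)
        assert len(defs) == 1 and defs[0].test_members == (("t1", "ch1"),)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        mat = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(mat)
        pd.testing.assert_frame_equal(out, mat)

    def test_reference_algorithm_hand_case(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(mat)
        assert list(out["a"]) == [2.5, 3.5, 4.5]
        assert list(out["b"]) == [2.5, 3.5, 4.5]

    def test_columns_share_sorted_multiset_and_idempotent(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.lognormal(6, 1, size=(200, 5)))
        out = quantile_normalize(mat)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 5):
            assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref, atol=1e-12)
        again = quantile_normalize(out)
        assert np.allclose(again.to_numpy(), out.to_numpy(), rtol=1e-12, atol=1e-12)

    def test_ties_get_mean_of_tied_rank_references(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [10.0, 20.0, 30.0]})
        out = quantile_normalize(mat)
        # reference curve: mean of sorted columns = (5.5, 10.5, 17.5);
        # the tied pair in column a shares mean(5.5, 10.5) = 8.0
        assert list(out["a"]) == [8.0, 8.0, 17.5]

    def test_missing_values_preserved_and_single_column_warns(self):
        mat = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(mat)
        assert np.isnan(out.loc[1, "a"]) and out.notna().sum().sum() == 5
        with pytest.warns(UserWarning):
            quantile_normalize(mat[["a"]])


class TestLoessNormalize:
    def test_equal_channels_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(7, 1, size=100)
        out = loess_normalize_dual(x, x)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_constant_offset_absorbed(self):
        rng = np.random.default_rng(1)
        ref = rng.lognormal(7, 1, size=200)
        out = loess_normalize_dual(ref * 2**1.7, ref)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_planted_intensity_trend_removed(self):
        rng = np.random.default_rng(2)
        n = 800
        A = rng.normal(10, 1.5, size=n)
        M = 0.5 * A + rng.normal(0, 0.1, size=n)
        test = 2.0 ** (A + M / 2)
        ref = 2.0 ** (A - M / 2)
        corrected = loess_normalize_dual(test, ref)
        slope_before = np.polyfit(A, M, 1)[0]
        slope_after = np.polyfit(A, corrected, 1)[0]
        assert abs(slope_before) > 0.4
        assert abs(slope_after) <= 0.05

    def test_domain_and_fit_errors(self):
        with pytest.raises(FitError):
            loess_normalize_dual([1.0] * 10, [2.0] * 10)
        with pytest.raises(DomainError):
            loess_normalize_dual([-1.0] * 40, [2.0] * 40)


# ---------------------------------------------------------------------------
# logratio computation and assembly
# ---------------------------------------------------------------------------


def _gene_log2(data):
    frame = pd.DataFrame(data, index=["g1"])
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return frame


class TestContrastLogratios:
    def test_hand_cases(self):
        d = ContrastDefinition("c", "E1", "P1", (("t", "ch1"),), (("r", "ch1"),))
        assert compute_contrast_logratios(
            _gene_log2({("t", "ch1"): [5.0], ("r", "ch1"): [5.0]}), d
        )["g1"] == 0.0
        assert compute_contrast_logratios(
            _gene_log2({("t", "ch1"): [np.log2(400)], ("r", "ch1"): [np.log2(100)]}), d
        )["g1"] == pytest.approx(2.0)

    def test_multiple_references_use_log_mean(self):
        d = ContrastDefinition(
            "c", "E1", "P1", (("t", "ch1"),), (("r1", "ch1"), ("r2", "ch1"))
        )
        frame = _gene_log2(
            {
                ("t", "ch1"): [np.log2(400)],
                ("r1", "ch1"): [np.log2(100)],
                ("r2", "ch1"): [np.log2(200)],
            }
        )
        assert compute_contrast_logratios(frame, d)["g1"] == pytest.approx(1.5)

    def test_missing_side_gives_missing_and_unknown_member_raises(self):
        d = ContrastDefinition("c", "E1", "P1", (("t", "ch1"),), (("r", "ch1"),))
        out = compute_contrast_logratios(
            _gene_log2({("t", "ch1"): [np.nan], ("r", "ch1"): [1.0]}), d
        )
        assert np.isnan(out["g1"])
        with pytest.raises(DefinitionError):
            compute_contrast_logratios(_gene_log2({("t", "ch1"): [1.0]}), d)


class TestAssembleCompendium:
    META = {"c1": ("E1", "P1"), "c2": ("E2", "P2")}

    def test_full_coverage_has_no_missing(self):
        comp = assemble_compendium(
            [("c1", pd.Series({"g1": 0.5, "g2": -0.5}))],
            {"c1": ("E1", "P1")},
            ["g1", "g2"],
        )
        assert comp.missing_fraction == 0.0

    def test_platform_absent_gene_is_missing_there_only(self):
        comp = assemble_compendium(
            [
                ("c1", pd.Series({"g1": 0.5})),
                ("c2", pd.Series({"g1": 0.1, "g2": -0.5})),
            ],
            self.META,
            ["g1", "g2"],
        )
        assert np.isnan(comp.values.loc["g2", "c1"])
        assert comp.values.loc["g2", "c2"] == -0.5

    def test_disjoint_contrasts_give_one_observation_per_row(self):
        comp = assemble_compendium(
            [
                ("c1", pd.Series({"g1": 0.5})),
                ("c2", pd.Series({"g2": -0.5})),
            ],
            self.META,
            ["g1", "g2"],
        )
        assert list(comp.values.notna().sum(axis=1)) == [1, 1]

    def test_duplicate_contrast_ids_abort(self):
        with pytest.raises(AssemblyError):
            assemble_compendium(
                [("c1", pd.Series({"g1": 0.0})), ("c1", pd.Series({"g1": 1.0}))],
                self.META,
                ["g1"],
            )


def test_pipeline_has_no_background_or_mismatch_correction():
    assert not any(
        "background" in step or "mismatch" in step for step in PROCESSING_STEPS
    )


def test_pipeline_identity_on_clean_background_data():
    """Dye bias 0, noise 0, 1 probe/gene: assembly reproduces truth exactly."""
    _, truth = sim.generate_compendium(
        n_genes=60,
        n_experiments=2,
        contrasts_per_experiment=3,
        planted_modules=(),
        noise_sd=0.0,
        missing_rate=0.0,
        seed=4,
    )
    specs = (
        sim.PlatformSpec("D1", "dual", probes_per_gene=1),
        sim.PlatformSpec("S1", "single", probes_per_gene=1),
    )
    study = sim.generate_raw_experiments(
        truth, specs, dye_bias_amplitude=0.0, probe_jitter_log2_sd=0.0, missing_rate=0.0
    )
    comp, _ = build_compendium_from_raw(
        study.hybridizations,
        study.contrast_definitions,
        study.probe_annotations,
        study.gene_index,
    )
    expected = truth.true_logratios.loc[comp.gene_ids, comp.contrast_ids]
    assert np.allclose(comp.values.to_numpy(), expected.to_numpy(), atol=1e-9)
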