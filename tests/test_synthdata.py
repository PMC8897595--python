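"""Generators: construction guarantees, truth consistency, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from majorsat import loading, qpcr, synthdata
from majorsat.synthdata import (
    CountTableSpec,
    ImageSceneSpec,
    PlantedSite,
    TandemRepeatSpec,
    gen_count_table,
    gen_ct_table,
    gen_nuclear_images,
    gen_tandem_repeat,
)

from conftest import brute_force_site_count


class TestTandemRepeat:
    def test_forced_construction(self):
        spec = TandemRepeatSpec(
            unit_length=234, n_units=100,
            planted_sites=(PlantedSite("GTCTTCCA", 50),), rng_seed=0,
        )
        seq, truth = gen_tandem_repeat(spec)
        assert len(seq) == 23_400
        assert len(truth) == 100
        assert all(
            seq[row.start : row.end] == row.motif for row in truth.itertuples()
        )

    def test_degenerate_empty(self):
        seq, truth = gen_tandem_repeat(TandemRepeatSpec(n_units=0))
        assert seq == "" and truth.empty

    def test_truth_count_matches_sliding_window_oracle(self):
        """Rejection sampling guarantees the oracle count equals the truth
        count: no spurious occurrences survive."""
        spec = TandemRepeatSpec(
            unit_length=60, n_units=50, gc_fraction=0.5,
            planted_sites=(PlantedSite("ACGTACGT", 10, every_k_units=2),
                           PlantedSite("TTTTCCCC", 30)),
            rng_seed=11,
        )
        seq, truth = gen_tandem_repeat(spec)
        for motif, group in truth.groupby("motif"):
            assert brute_force_site_count(seq, motif) == len(group)

    def test_every_k_units(self):
        spec = TandemRepeatSpec(
            unit_length=50, n_units=10,
            planted_sites=(PlantedSite("ACGTACGT", 0, every_k_units=3),),
        )
        _, truth = gen_tandem_repeat(spec)
        assert list(truth["unit_index"]) == [0, 3, 6, 9]

    def test_determinism(self):
        spec = TandemRepeatSpec(n_units=5, rng_seed=42)
        assert gen_tandem_repeat(spec)[0] == gen_tandem_repeat(spec)[0]

    def test_non_acgt_motif_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            TandemRepeatSpec(planted_sites=(PlantedSite("ACGU", 0),))

    def test_motif_must_fit_in_unit(self):
        with pytest.raises(ValueError, match="fit"):
            TandemRepeatSpec(unit_length=10, planted_sites=(PlantedSite("ACGTACGT", 5),))

    def test_impossible_rejection_reported(self):
        # planting "AA" in every 2 bp unit tiles the array with A; the
        # junction occurrence at position 1 overlaps only planted bases and
        # can never be redrawn away
        spec = TandemRepeatSpec(
            unit_length=2, n_units=2, planted_sites=(PlantedSite("AA", 0),)
        )
        with pytest.raises(RuntimeError, match="permissive"):
            gen_tandem_repeat(spec, max_attempts=5)


class TestCountTable:
    def test_null_effect_zero_dispersion_gives_equal_cpm(self):
        spec = CountTableSpec(n_mirnas=20, effect_log2fc=0.0, dispersion=0.0,
                              library_size_rip=2_000_000)
        table, _ = gen_count_table(spec)
        c = loading.cpm(table)
        assert np.allclose(c["input"], c["rip"])

    def test_single_mirna_normalization_closure(self):
        spec = CountTableSpec(n_mirnas=1, dispersion=0.0)
        table, _ = gen_count_table(spec)
        c = loading.cpm(table)
        assert np.allclose(c.to_numpy(), 1e6)

    def test_planted_log2fc_recovered_from_emitted_table(self):
        """Mean empirical log2 cpm ratio of enriched ids ~ effect, recomputed
        from the table itself (Monte-Carlo tolerance)."""
        spec = CountTableSpec.with_random_effects(
            500, 50, rng_seed=13, effect_log2fc=2.0, dispersion=0.05
        )
        table, truth = gen_count_table(spec)
        c = loading.cpm(table)
        enriched = truth.loc[truth.true_class == "enriched", "mirna_id"]
        ratio = np.log2((c.loc[enriched, "rip"] + 1) / (c.loc[enriched, "input"] + 1))
        # library renormalization shifts all ratios by a common composition
        # offset; compare against the neutral background instead of zero
        neutral = truth.loc[truth.true_class == "neutral", "mirna_id"]
        expressed = c.loc[neutral, "input"] > 31
        offset = np.log2(
            (c.loc[neutral, "rip"][expressed.values] + 1)
            / (c.loc[neutral, "input"][expressed.values] + 1)
        ).mean()
        assert abs(ratio.mean() - offset - 2.0) < 0.3

    def test_overlapping_effect_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            CountTableSpec(enriched_ids=("miR-0001",), depleted_ids=("miR-0001",))

    def test_determinism(self):
        spec = CountTableSpec.with_random_effects(100, 10, rng_seed=3)
        t1, _ = gen_count_table(spec)
        t2, _ = gen_count_table(spec)
        pd.testing.assert_frame_equal(t1, t2)


class TestCtTable:
    def test_unit_fold_gives_zero_ddct(self):
        ct = gen_ct_table([("t", 1.0, 20.0)], noise_sd=0.0)
        folds = qpcr.expression_fold_table(ct, "reference", "control")
        assert np.allclose(folds["fold"], 1.0)

    def test_fold_four_is_two_cycles_below(self):
        ct = gen_ct_table([("t", 4.0, 20.0)], noise_sd=0.0)
        mean = ct.groupby(["sample", "target"])["ct"].mean()
        assert mean[("treated", "t")] == pytest.approx(
            mean[("control", "t")] - 2.0
        )

    def test_noisy_folds_distribute_around_truth(self):
        """100 replicates at noise 0.2 cycles: downstream fold estimates are
        centred on the planted truth."""
        ct = gen_ct_table([("t", 4.0, 20.0)], noise_sd=0.2, rng_seed=9,
                          n_replicates=100)
        per_rep = []
        for rep, grp in ct.groupby("replicate"):
            folds = qpcr.expression_fold_table(grp, "reference", "control")
            per_rep.append(folds["fold"].iloc[folds.index[folds["condition"] == "treated"][0]])
        log2_mean = np.mean(np.log2(per_rep))
        assert abs(log2_mean - 2.0) < 0.15

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            gen_ct_table([("t", 0.0, 20.0)])


class TestNuclearImages:
    def test_full_colocalization_scene(self):
        """p_coloc = 1: every marker focus in the truth is flagged and sits
        on a chromocenter centre."""
        spec = ImageSceneSpec(
            n_nuclei=1, chromocenters_per_nucleus=8.0,
            marker_foci_per_nucleus=5.0, p_coloc=1.0, snr=math.inf, rng_seed=0,
        )
        _, _, truth = gen_nuclear_images(spec)
        foci_rows = truth.objects[truth.objects.kind == "marker_focus"]
        chromo = truth.objects[truth.objects.kind == "chromocenter"]
        assert len(foci_rows) > 0
        assert foci_rows["colocalized"].all()
        for f in foci_rows.itertuples():
            d = np.hypot(chromo["row"] - f.row, chromo["col"] - f.col)
            assert d.min() <= 1.0

    def test_zero_colocalization_scene(self):
        spec = ImageSceneSpec(n_nuclei=2, p_coloc=0.0, snr=math.inf, rng_seed=3)
        _, _, truth = gen_nuclear_images(spec)
        foci_rows = truth.objects[truth.objects.kind == "marker_focus"]
        chromo = truth.objects[truth.objects.kind == "chromocenter"]
        assert not foci_rows["colocalized"].any()
        for f in foci_rows.itertuples():
            d = np.hypot(chromo["row"] - f.row, chromo["col"] - f.col)
            assert d.min() >= 2 * spec.chromocenter_radius_px

    def test_planted_foci_are_local_maxima(self):
        """The pixel argmax of each focus's neighbourhood in the emitted
        image equals its truth coordinate (within the sub-pixel placement)."""
        spec = ImageSceneSpec(rng_seed=4, snr=math.inf)
        _, marker, truth = gen_nuclear_images(spec)
        proj = marker.max(axis=0).astype(float)
        for f in truth.objects[truth.objects.kind == "marker_focus"].itertuples():
            r, c = int(round(f.row)), int(round(f.col))
            patch = proj[r - 4 : r + 5, c - 4 : c + 5]
            pr, pc = np.unravel_index(np.argmax(patch), patch.shape)
            assert math.hypot(pr - 4 + r - f.row, pc - 4 + c - f.col) <= 1.0

    def test_truth_independent_of_z_slices(self):
        base = dict(rng_seed=7, n_nuclei=2)
        _, _, t1 = gen_nuclear_images(ImageSceneSpec(z_slices=1, **base))
        _, _, t5 = gen_nuclear_images(ImageSceneSpec(z_slices=5, **base))
        pd.testing.assert_frame_equal(t1.objects, t5.objects)
        pd.testing.assert_frame_equal(t1.nuclei, t5.nuclei)

    def test_determinism(self):
        spec = ImageSceneSpec(rng_seed=8)
        d1, m1, _ = gen_nuclear_images(spec)
        d2, m2, _ = gen_nuclear_images(spec)
        assert np.array_equal(d1, d2) and np.array_equal(m1, m2)

    def test_overcrowded_scene_fails_loudly(self):
        spec = ImageSceneSpec(image_shape=(128, 128), n_nuclei=10)
        with pytest.raises(RuntimeError, match="place"):
            gen_nuclear_images(spec)

    def test_write_scene_round_trip(self, tmp_path):
        import tifffile

        spec = ImageSceneSpec(rng_seed=9, n_nuclei=2, z_slices=2)
        paths = synthdata.write_scene(spec, tmp_path)
        dapi, marker, truth = gen_nuclear_images(spec)
        assert np.array_equal(tifffile.imread(paths["dapi"]), dapi)
        loaded = pd.read_csv(paths["nuclei"])
        pd.testing.assert_frame_equal(loaded, truth.nuclei)
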