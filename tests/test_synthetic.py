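"""The cohort generator: contracts, determinism, and target recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from csdskit import io as kio
from csdskit.ephys import measure_passive, measure_spike_properties
from csdskit.synthetic import (
    CELLS,
    EphysCellParams,
    ExprSpec,
    GroupDesign,
    default_effects,
    generate_behavior_cohort,
    generate_ephys_recordings,
    generate_expression_dataset,
    generate_gene_families,
)


def zero_sd_effects():
    eff = default_effects()
    eff.behavior = {
        cell: {p: (mu, 0.0) for p, (mu, sd) in params.items()}
        for cell, params in eff.behavior.items()
    }
    eff.si_ratio = {cell: (mu, 0.0) for cell, (mu, sd) in eff.si_ratio.items()}
    eff.si_no_target = (60.0, 0.0)
    return eff


class TestBehaviorCohort:
    def test_shape_and_bounds(self, design, effects):
        beh, si, truth = generate_behavior_cohort(design, effects, seed=3)
        assert len(beh) == 4 * design.n_per_group
        assert len(truth.animal_cells) == len(beh)
        assert (beh["of_time_center_s"] + beh["of_time_periphery_s"]
                <= 600.0 + 1e-9).all()
        assert (beh["ld_time_light_s"] + beh["ld_time_dark_s"]
                <= 480.0 + 1e-9).all()
        assert (beh["epm_time_open_s"] + beh["epm_time_center_s"]
                <= 300.0 + 1e-9).all()
        for col in ("ld_entries_light", "epm_entries_open", "epm_head_dips"):
            assert (beh[col] >= 0).all()
            assert beh[col].dtype.kind == "i"
        assert (si[["time_zone_no_target_s", "time_zone_target_s"]]
                <= 300.0 + 1e-9).all().all()

    def test_zero_sd_makes_cells_homogeneous(self, design):
        beh, si, _ = generate_behavior_cohort(design, zero_sd_effects(),
                                              seed=1)
        for (_, _), group in beh.groupby(["diet", "stress"]):
            values = group.drop(columns=["animal_id"])
            assert (values.nunique() == 1).all()
        for (_, _), group in si.groupby(["diet", "stress"]):
            assert group["time_zone_target_s"].nunique() == 1

    def test_same_seed_byte_identical_files(self, design, effects, tmp_path):
        for run in ("x", "y"):
            beh, si, _ = generate_behavior_cohort(design, effects, seed=9)
            kio.write_behavior(beh, tmp_path / f"beh_{run}.csv")
            kio.write_social(si, tmp_path / f"si_{run}.csv")
        assert (tmp_path / "beh_x.csv").read_bytes() == \
            (tmp_path / "beh_y.csv").read_bytes()
        assert (tmp_path / "si_x.csv").read_bytes() == \
            (tmp_path / "si_y.csv").read_bytes()

    def test_si_group_means_hit_targets_within_clt_bound(self, effects):
        design = GroupDesign(n_per_group=10)
        effects.si_ratio[("control", "csds")] = (0.8, 0.05)
        effects.si_ratio[("n3_suppl", "csds")] = (1.19, 0.05)
        beh, si, _ = generate_behavior_cohort(design, effects, seed=21)
        si["ratio"] = si["time_zone_target_s"] / si["time_zone_no_target_s"]
        for cell, target in ((("control", "csds"), 0.8),
                             (("n3_suppl", "csds"), 1.19)):
            got = si[(si["diet"] == cell[0])
                     & (si["stress"] == cell[1])]["ratio"].mean()
            assert abs(got - target) <= 3 * 0.05 / np.sqrt(10)

    def test_cell_means_converge_at_large_n(self, effects):
        design = GroupDesign(n_per_group=1000)
        beh, _, _ = generate_behavior_cohort(design, effects, seed=2)
        cell = beh[(beh["diet"] == "control") & (beh["stress"] == "none")]
        mu, sd = effects.behavior[("control", "none")]["of_time_center_s"]
        assert abs(cell["of_time_center_s"].mean() - mu) \
            <= 3 * sd / np.sqrt(1000)

    def test_missing_cell_is_a_configuration_error(self, design, effects):
        del effects.behavior[("control", "csds")]
        with pytest.raises(ValueError, match="missing cells"):
            generate_behavior_cohort(design, effects, seed=0)

    def test_round_trip_through_readers(self, design, effects, tmp_path):
        beh, si, _ = generate_behavior_cohort(design, effects, seed=5)
        kio.write_behavior(beh, tmp_path / "b.csv")
        back = kio.read_behavior(tmp_path / "b.csv")
        pd.testing.assert_frame_equal(back, beh.round(6),
                                      check_exact=False, atol=1e-6)


class TestEphysGenerator:
    def test_subthreshold_matches_closed_form_rc(self, design, effects):
        for cell in CELLS:
            effects.ephys[cell] = dataclasses.replace(
                effects.ephys[cell],
                rmp_mV=(-80.0, 0.0), rin_MOhm=(150.0, 0.0),
                tau_ms=(15.0, 0.0),
            )
        sweeps, _, truth = generate_ephys_recordings(
            design, effects, seed=1, neurons_per_cell=1,
        )
        ss = sweeps[0]
        sw = next(s for s in ss.sweeps if s.current_pA == -50.0)
        fs = ss.sampling_rate
        on = int(sw.step_onset_s * fs)
        off = int(sw.step_offset_s * fs)
        t = (np.arange(off - on)) / fs
        v_inf = -80.0 + 150.0 * (-50.0) * 1e-3
        expected = v_inf + (-80.0 - v_inf) * np.exp(-t / 15e-3)
        assert np.max(np.abs(sw.voltage_mV[on:off] - expected)) < 0.1

    def test_rheobase_step_is_first_to_spike(self, design, effects):
        for cell in CELLS:
            # Rin chosen so a 120 pA rheobase still yields a threshold
            # near -40 mV and an overshooting AP
            effects.ephys[cell] = dataclasses.replace(
                effects.ephys[cell], rheobase_pA=(120.0, 0.0),
                delay_ms=(250.0, 0.0), rin_MOhm=(330.0, 0.0),
            )
        sweeps, _, truth = generate_ephys_recordings(
            design, effects, seed=4, neurons_per_cell=1,
        )
        for ss in sweeps:
            p = measure_passive(ss)
            assert p.rheobase_pA == 120.0
            s = measure_spike_properties(ss)
            assert s.delay_to_first_spike_ms == pytest.approx(250.0, abs=0.5)

    def test_depression_factor_one_means_no_ltd(self, design, effects):
        for cell in CELLS:
            effects.ephys[cell] = dataclasses.replace(
                effects.ephys[cell], ltd_factor=(1.0, 0.0),
            )
        _, epsc, _ = generate_ephys_recordings(
            design, effects, seed=2, neurons_per_cell=1, epsc_noise_frac=0.0,
        )
        for series in epsc:
            pre = series.amplitudes_pA[series.times_s
                                       < series.protocol_onset_s]
            post = series.amplitudes_pA[series.times_s
                                        >= series.protocol_end_s]
            assert post.mean() == pytest.approx(pre.mean(), rel=1e-9)

    def test_invalid_membrane_parameters_rejected(self):
        with pytest.raises(ValueError, match="tau_ms"):
            EphysCellParams(
                rmp_mV=(-80, 1), rin_MOhm=(150, 10), tau_ms=(-5, 1),
                rheobase_pA=(240, 20), delay_ms=(300, 40),
                ap_amplitude_mV=(61, 3), ap_rise_mV_per_ms=(35, 3),
                ap_decay_mV_per_ms=(18, 2), epsc_baseline_pA=(200, 30),
                ltd_factor=(0.7, 0.05),
            )

    def test_sweep_round_trip_through_h5(self, design, effects, tmp_path):
        sweeps, epsc, _ = generate_ephys_recordings(
            GroupDesign(n_per_group=2), effects, seed=3, neurons_per_cell=1,
        )
        kio.write_sweeps_h5(sweeps, tmp_path / "s.h5")
        back = kio.read_sweeps_h5(tmp_path / "s.h5")
        assert [b.neuron_id for b in back] == [s.neuron_id for s in sweeps]
        np.testing.assert_allclose(
            back[0].sweeps[0].voltage_mV, sweeps[0].sweeps[0].voltage_mV,
            atol=1e-3,  # float32 storage
        )
        kio.write_epsc(epsc, tmp_path / "e.csv")
        back_e = kio.read_epsc(tmp_path / "e.csv")
        np.testing.assert_allclose(back_e[0].amplitudes_pA,
                                   epsc[0].amplitudes_pA, atol=1e-6)


class TestExpressionGenerator:
    def test_structure_and_housekeeping(self, design):
        spec = ExprSpec()
        m, truth = generate_expression_dataset(spec, design, seed=7)
        assert m.values.shape == (89, 2 * design.n_per_group)
        assert "Gapdh" in m.values.index
        assert sum(truth.gene_flags.values()) == 25
        assert not truth.gene_flags["Gapdh"]
        assert (m.values > 0).all().all()

    def test_planted_batch_offset_is_exact_without_noise(self, design):
        spec = ExprSpec(noise_sd=0.0, batch_offset=2.0)
        m, _ = generate_expression_dataset(spec, design, seed=1)
        log2 = np.log2(m.values)
        b1 = m.sample_meta.index[m.sample_meta["batch"] == "B1"]
        b2 = m.sample_meta.index[m.sample_meta["batch"] == "B2"]
        # compare within one group so the diet effect cancels
        ctrl = m.sample_meta.index[m.sample_meta["group"] == "control"]
        diff = (log2[[c for c in b2 if c in ctrl]].mean(axis=1)
                - log2[[c for c in b1 if c in ctrl]].mean(axis=1))
        assert np.allclose(diff, 2.0, atol=1e-12)

    def test_zero_effect_leaves_no_group_difference(self, design):
        spec = ExprSpec(log2_effect=0.0, noise_sd=0.0, batch_offset=0.0)
        m, truth = generate_expression_dataset(spec, design, seed=2)
        log2 = np.log2(m.values)
        groups = m.sample_meta["group"]
        a = log2.loc[:, (groups == "control").to_numpy()].mean(axis=1)
        b = log2.loc[:, (groups == "n3_suppl").to_numpy()].mean(axis=1)
        assert np.allclose(a, b, atol=1e-12)
        assert sum(truth.gene_flags.values()) == 25  # flags still present

    def test_too_many_flags_rejected(self, design):
        with pytest.raises(ValueError, match="n_true_up"):
            ExprSpec(n_genes=10, n_true_up=11)

    def test_round_trip_through_tsv(self, design, tmp_path):
        m, _ = generate_expression_dataset(ExprSpec(), design, seed=3)
        kio.write_expression(m, tmp_path / "x.tsv", tmp_path / "s.tsv")
        back = kio.read_expression(tmp_path / "x.tsv", tmp_path / "s.tsv")
        assert back.scale == "linear"
        pd.testing.assert_frame_equal(back.values, m.values,
                                      check_exact=False, rtol=1e-6)
        pd.testing.assert_frame_equal(back.sample_meta, m.sample_meta)


class TestGeneFamilies:
    def test_sizes_within_bounds_and_seed_reproducible(self, tmp_path):
        a = generate_gene_families(n_families=50, size_range=(5, 200), seed=6)
        b = generate_gene_families(n_families=50, size_range=(5, 200), seed=6)
        sizes = [len(m) for m in a.families.values()]
        assert len(a.families) == 50
        assert min(sizes) >= 5 and max(sizes) <= 200
        assert a.families == b.families
        a.to_gmt(tmp_path / "f.gmt")
        from csdskit.enrichment import GeneSetCollection
        back = GeneSetCollection.from_gmt(tmp_path / "f.gmt",
                                          genome_size=a.genome_size)
        assert back.families == a.families

    def test_nested_families_are_strict_subsets(self):
        col = generate_gene_families(n_families=40, nest_prob=0.6, seed=8)
        nested = [
            (x, y)
            for x in col.families
            for y in col.families
            if x != y and col.families[x] < col.families[y]
        ]
        assert nested, "expected at least one strict inclusion"

    def test_genome_must_cover_largest_family(self):
        with pytest.raises(ValueError):
            generate_gene_families(n_families=2, genome_size=10,
                                   size_range=(5, 200), seed=0)
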