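"""Synthetic-data generator: determinism, structure, truth bookkeeping."""
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from endosource import peaks as pk, pipeline as pl, simulate as sim


class TestMakeTaxonPool:
    def test_full_range_forces_distinct_sizes(self):
        pool = sim.make_taxon_pool(314, (27, 340), rng_seed=1)
        fwd = [t.fwd_size for t in pool.taxa]
        assert len(set(fwd)) == 314

    def test_seed_determinism(self):
        a = sim.make_taxon_pool(50, rng_seed=1)
        b = sim.make_taxon_pool(50, rng_seed=1)
        assert a == b

    def test_too_many_taxa_error_names_both_numbers(self):
        with pytest.raises(ValueError, match="400.*314"):
            sim.make_taxon_pool(400, (27, 340))

    def test_sizes_within_declared_range(self):
        pool = sim.make_taxon_pool(100, (50, 400), rng_seed=2)
        assert all(50 <= t.fwd_size <= 400 and 50 <= t.rev_size <= 400
                   for t in pool.taxa)


class TestAssemblyParams:
    def test_counts_must_fit_pool(self):
        with pytest.raises(ValueError, match="pool_size"):
            sim.AssemblyParams(n_seed_taxa=300, n_promiscuous_taxa=100)

    @pytest.mark.parametrize("kw", [
        {"detection_prob": 1.5}, {"false_peak_rate": -1.0}, {"n_seed_taxa": -1},
    ])
    def test_invalid_parameters(self, kw):
        with pytest.raises(ValueError):
            sim.AssemblyParams(**kw)


class TestSimulateExperiment:
    def test_noiseless_trials_have_identical_categories(self, noiseless_exp):
        df = pk.bin_sizes(noiseless_exp.peaks)
        for sid, sdf in df.groupby("sample_id"):
            if sid == "water":
                continue
            per_trial = [
                frozenset(zip(t["dye"], t["size_cat"]))
                for _, t in sdf.groupby(["bio_rep", "tech_rep"])
            ]
            assert len(set(per_trial)) == 1, sid

    def test_no_soil_taxa_means_every_plant_peak_is_inherited(self, pool314):
        params = sim.AssemblyParams(
            n_promiscuous_taxa=0, n_soilA_specific=0, n_soilB_specific=0,
            detection_prob=1.0, false_peak_rate=0.0, rng_seed=4,
        )
        exp = sim.simulate_experiment(params, pool314)
        df = pk.bin_sizes(exp.peaks)
        seed_or_sand = set()
        plant = {}
        for sid, sdf in df.groupby("sample_id"):
            cats = set(zip(sdf["dye"], sdf["size_cat"]))
            meta = exp.manifest["samples"][sid]
            if meta["kind"] == "seed" or (meta["kind"] == "plant"
                                          and meta["substrate"] == "sand"):
                seed_or_sand |= cats
            elif meta["kind"] == "plant":
                plant[sid] = cats
        assert plant
        for sid, cats in plant.items():
            assert cats <= seed_or_sand, sid

    def test_group_structure_matches_provenance_roles(self, noiseless_exp):
        truth = noiseless_exp.truth
        seed_cats = truth.categories("G1_seed")
        sand = truth.categories("G1_sand")
        on_a = truth.categories("G1_soilA")
        soil_a = truth.categories("soilA")
        assert seed_cats == sand  # sand-grown plants carry only inherited taxa
        assert truth.categories("G1_soilA", sim.Origin.SEED_INHERITED) == seed_cats
        both = truth.categories("G1_soilA", sim.Origin.BOTH_SOILS)
        assert both == truth.categories("G1_soilB", sim.Origin.BOTH_SOILS)
        assert both <= soil_a
        spec_a = truth.categories("G1_soilA", sim.Origin.SOIL_SPECIFIC)
        assert spec_a & truth.categories("soilB") == frozenset()
        assert on_a == seed_cats | both | spec_a

    def test_water_contains_only_noise(self, pool314):
        params = sim.AssemblyParams(false_peak_rate=2.0, rng_seed=5)
        exp = sim.simulate_experiment(params, pool314)
        wdf = exp.peaks[exp.peaks["sample_id"] == "water"]
        assert (wdf["height"] <= 80.0).all()

    def test_short_cell_has_four_trials(self, pool314, noiseless_params):
        exp = sim.simulate_design(
            noiseless_params, pool314, genotypes=("A", "B"), short_cell=("B", "sand")
        )
        assert exp.manifest["samples"]["B_sand_root"]["n_trials"] == 4
        assert exp.manifest["samples"]["A_sand_root"]["n_trials"] == 6
        assert exp.manifest["samples"]["A_seed"]["n_trials"] == 3

    def test_design_too_large_for_pool(self, noiseless_params):
        small = sim.make_taxon_pool(40, rng_seed=1)
        with pytest.raises(ValueError, match="pool"):
            sim.simulate_design(noiseless_params, small, genotypes=("A", "B"))


def _tree_hash(directory):
    h = hashlib.sha256()
    for p in sorted(Path(directory).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestFixtureIO:
    def test_round_trip_lossless(self, tmp_path, noiseless_exp):
        sim.write_fixture(noiseless_exp, tmp_path / "fx")
        peaks_df, truth, manifest = sim.read_fixture(tmp_path / "fx")
        cols = list(noiseless_exp.peaks.columns)
        a = noiseless_exp.peaks.sort_values(cols).reset_index(drop=True)
        b = peaks_df.sort_values(cols).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        assert truth.labels == noiseless_exp.truth.labels
        assert manifest == noiseless_exp.manifest

    def test_empty_trial_file_is_header_valid(self, tmp_path, noiseless_exp):
        sim.write_fixture(noiseless_exp, tmp_path / "fx")
        water = tmp_path / "fx" / "water_1_1.csv"
        assert water.exists()
        df = pk.read_peak_table(water)
        assert df.empty and list(df.columns) == list(pk.REQUIRED_COLUMNS)

    def test_truth_sidecar_counts_non_noise_categories(self, tmp_path, noiseless_exp):
        sim.write_fixture(noiseless_exp, tmp_path / "fx")
        tdf = pd.read_csv(tmp_path / "fx" / "truth.tsv", sep="\t")
        assert len(tdf) == len(noiseless_exp.truth.labels)

    def test_identical_params_give_byte_identical_fixtures(self, tmp_path, pool314):
        params = sim.AssemblyParams(rng_seed=11)
        for d in ("a", "b"):
            sim.write_fixture(sim.simulate_design(params, pool314), tmp_path / d)
        assert _tree_hash(tmp_path / "a") == _tree_hash(tmp_path / "b")


class TestNoiseMonotonicity:
    def test_no_match_fraction_nondecreasing_in_false_peak_rate(self, pool314):
        """More spurious peaks can only raise the unexplained fraction."""
        means = []
        for rate in (0.0, 8.0):
            fracs = []
            for seed in range(20):
                params = sim.AssemblyParams(
                    detection_prob=1.0, false_peak_rate=rate, rng_seed=100 + seed
                )
                exp = sim.simulate_experiment(params, pool314)
                res = pl.analyze_experiment(exp)
                fracs.extend(bd.ambiguous for bd in res.breakdowns.values())
            means.append(np.mean(fracs))
        assert means[0] <= means[1] + 1e-12
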