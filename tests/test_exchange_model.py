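"""Forward exchange-kinetics simulator: kinetics, map, library, activities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdxscreen.consolidation import sequence_coverage
from hdxscreen.exchange_model import (
    DEFAULT_REGIONS,
    CompoundSpec,
    ProteinModel,
    Region,
    SimulationConfig,
    build_default_protein,
    default_assay_links,
    generate_peptide_map,
    peptide_percent_d,
    region_score,
    simulate_activities,
    simulate_compound_library,
    simulate_dataset,
    simulate_peptide_observations,
    simulate_residue_fraction,
)
from hdxscreen.uptake import (
    CentroidTriple,
    Peptide,
    exchangeable_positions,
    percent_deuterium,
)


def _flat_protein(log10p=0.0, kint=0.1, length=20, first=1):
    return ProteinModel(
        sequence="A" * length,
        first_index=first,
        regions=(Region("H", first, first + length - 1),),
        baseline_log10_protection=np.full(length, float(log10p)),
        intrinsic_rate=np.full(length, float(kint)),
    )


class TestResidueKinetics:
    def test_closed_form_single_exponential(self):
        # P = 1, k_int = 0.1/s, t = 10 s -> 1 - e^-1
        p = _flat_protein(log10p=0.0, kint=0.1)
        assert simulate_residue_fraction(p, None, 5, 10.0) == pytest.approx(
            1.0 - np.exp(-1.0), abs=1e-12
        )

    def test_no_time_no_exchange(self):
        assert simulate_residue_fraction(_flat_protein(), None, 3, 0.0) == 0.0

    def test_full_protection_limit(self):
        p = _flat_protein(log10p=12.0)
        assert simulate_residue_fraction(p, None, 3, 14400.0) == pytest.approx(0.0, abs=1e-6)

    def test_residue_out_of_bounds(self):
        with pytest.raises(IndexError):
            simulate_residue_fraction(_flat_protein(), None, 21, 1.0)

    def test_negative_time(self):
        with pytest.raises(ValueError):
            simulate_residue_fraction(_flat_protein(), None, 1, -1.0)

    @given(
        t1=st.floats(0.0, 2e4),
        t2=st.floats(0.0, 2e4),
        dp=st.floats(0.0, 3.0),
        kint=st.floats(0.01, 30.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_time_and_protection(self, t1, t2, dp, kint):
        """Uptake is nondecreasing in t and nonincreasing in protection."""
        lo, hi = sorted((t1, t2))
        p0 = _flat_protein(log10p=0.5, kint=kint)
        p1 = _flat_protein(log10p=0.5 + dp, kint=kint)
        assert simulate_residue_fraction(p0, None, 1, lo) <= simulate_residue_fraction(
            p0, None, 1, hi
        ) + 1e-12
        assert simulate_residue_fraction(p1, None, 1, hi) <= simulate_residue_fraction(
            p0, None, 1, hi
        ) + 1e-12

    def test_compound_effect_shifts_protection(self):
        p = _flat_protein(log10p=0.5)
        comp = CompoundSpec(id="c", pharm_class="agonist", region_effects={"H": 1.0})
        assert simulate_residue_fraction(p, comp, 1, 100.0) < simulate_residue_fraction(
            p, None, 1, 100.0
        )

    def test_occupancy_scales_effect(self):
        p = _flat_protein(log10p=0.5)
        full = CompoundSpec("c", "agonist", {"H": 1.0}, occupancy=1.0)
        half = CompoundSpec("c", "agonist", {"H": 1.0}, occupancy=0.5)
        f_full = simulate_residue_fraction(p, full, 1, 100.0)
        f_half = simulate_residue_fraction(p, half, 1, 100.0)
        f_none = simulate_residue_fraction(p, None, 1, 100.0)
        assert f_full < f_half < f_none


class TestPeptideObservations:
    def test_zero_noise_equals_analytic_mean(self):
        protein = build_default_protein(seed=3)
        pep = Peptide(
            id="p",
            sequence=protein.sequence[10:22],
            start=protein.first_index + 10,
            end=protein.first_index + 21,
        )
        cfg = SimulationConfig(n_replicates=2, noise_sd_percent_d=0.0, seed=1)
        obs = simulate_peptide_observations(protein, pep, None, cfg)
        pos = np.asarray(exchangeable_positions(pep)) - protein.first_index
        for t, sub in obs.groupby("timepoint_s"):
            manual = 100.0 * np.mean(
                [
                    simulate_residue_fraction(protein, None, protein.first_index + i, t)
                    for i in pos
                ]
            )
            assert sub["percent_d"].to_numpy() == pytest.approx(manual, abs=1e-9)

    def test_seed_determinism(self):
        protein = build_default_protein(seed=3)
        pep = Peptide("p", protein.sequence[:10], protein.first_index, protein.first_index + 9)
        cfg = SimulationConfig(seed=11)
        a = simulate_peptide_observations(protein, pep, None, cfg)
        b = simulate_peptide_observations(protein, pep, None, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_values_clipped_to_bounds(self):
        protein = build_default_protein(seed=3)
        pep = Peptide("p", protein.sequence[:10], protein.first_index, protein.first_index + 9)
        cfg = SimulationConfig(noise_sd_percent_d=40.0, seed=5)
        obs = simulate_peptide_observations(protein, pep, None, cfg)
        assert obs["percent_d"].between(0.0, 100.0).all()

    def test_raw_mode_round_trips_percent_d(self):
        """Centroid emission is the algebraic inverse of percent_deuterium."""
        protein = build_default_protein(seed=3)
        pep = Peptide("p", protein.sequence[:12], protein.first_index, protein.first_index + 11, 2)
        cfg = SimulationConfig(n_replicates=2, noise_sd_percent_d=0.0, seed=1)
        plain = simulate_peptide_observations(protein, pep, None, cfg)
        raw = simulate_peptide_observations(protein, pep, None, cfg, raw=True)
        back = [
            percent_deuterium(CentroidTriple(r.undeut_mz, r.obs_mz, r.dmax_mz, pep.charge))
            for r in raw.itertuples()
        ]
        assert back == pytest.approx(plain["percent_d"].tolist(), abs=1e-9)


class TestPeptideMap:
    def test_full_tiling_of_toy_sequence(self):
        peps = generate_peptide_map("ACDEFGHIKLMNQRSTVWYA", target_coverage=1.0, seed=0)
        assert sequence_coverage(peps, 20) == pytest.approx(100.0)

    def test_default_preset_matches_digest_scale(self):
        protein = build_default_protein(seed=0)
        peps = generate_peptide_map(
            protein.sequence, first_index=protein.first_index, seed=4
        )
        assert len(peps) == 54
        cov = sequence_coverage(peps, len(protein.sequence), protein.first_index)
        assert 96.0 <= cov <= 100.0

    def test_seed_reproducibility(self):
        protein = build_default_protein(seed=0)
        a = generate_peptide_map(protein.sequence, first_index=265, seed=9)
        b = generate_peptide_map(protein.sequence, first_index=265, seed=9)
        assert [(p.id, p.sequence) for p in a] == [(p.id, p.sequence) for p in b]

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            generate_peptide_map("A" * 200, n_peptides=2, mean_length=10, seed=0)


class TestCompoundLibrary:
    def test_pure_agonist_library_has_h12_effects(self):
        lib = simulate_compound_library(5, {"agonist": 1.0}, seed=1)
        assert len(lib) == 5
        assert all(c.region_effects.get("H12", 0) > 0 for c in lib)

    def test_null_library_has_no_effects(self):
        lib = simulate_compound_library(4, {"null": 1.0}, seed=1)
        assert all(not c.region_effects for c in lib)

    def test_default_class_counts(self):
        lib = simulate_compound_library(seed=0)
        counts = pd.Series([c.pharm_class for c in lib]).value_counts()
        assert counts["agonist"] == 13
        assert counts["partial_agonist"] == 13
        assert counts["inverse_agonist"] == 12

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            simulate_compound_library(5, {"superagonist": 1.0}, seed=0)

    def test_binding_signature_shared_by_all_binders(self):
        lib = simulate_compound_library(seed=0)
        for c in lib:
            assert {"BSR", "H3", "H7"} <= set(c.region_effects)


class TestActivities:
    def test_zero_noise_is_exactly_linear(self):
        protein = build_default_protein(seed=2)
        lib = simulate_compound_library(10, seed=2)
        links = default_assay_links(protein, lib)
        # strip the tuned noise
        from dataclasses import replace

        noiseless = type(links)(
            links={a: replace(s, noise_sd=0.0) for a, s in links.links.items()}
        )
        acts = simulate_activities(lib, noiseless, seed=0)
        spec = links.links["alphascreen"]
        sub = acts[acts.assay == "alphascreen"].set_index("compound")["value"]
        for c in lib:
            expected = spec.intercept + spec.slope * spec.scores[c.id]
            assert sub[c.id] == pytest.approx(expected)

    def test_missing_score_rejected(self):
        protein = build_default_protein(seed=2)
        lib = simulate_compound_library(4, seed=2)
        links = default_assay_links(protein, lib[:2])
        with pytest.raises(ValueError, match="score"):
            simulate_activities(lib, links, seed=0)

    def test_region_score_sign_convention(self):
        """Protection makes the planted score negative (less uptake)."""
        protein = build_default_protein(seed=2)
        comp = CompoundSpec("c", "agonist", {"H12": 2.0})
        assert region_score(protein, comp, "H12", 10.0) < 0
        assert region_score(protein, None, "H12", 10.0) == 0.0


class TestDatasetInvariants:
    def test_dataset_determinism_byte_exact(self, tiny_study):
        from hdxscreen.exchange_model import simulate_screen_study

        again = simulate_screen_study(seed=7, n_compounds=12)
        assert tiny_study.observations.to_csv(index=False) == again.observations.to_csv(
            index=False
        )
        assert tiny_study.activities.to_csv(index=False) == again.activities.to_csv(
            index=False
        )

    def test_all_values_in_bounds(self, tiny_study):
        assert tiny_study.observations["percent_d"].between(0, 100).all()

    def test_paired_vehicle_layout(self, tiny_study):
        obs = tiny_study.observations
        veh = obs[obs.condition == "vehicle"]
        assert set(veh.experiment) == {c.id for c in tiny_study.compounds}

    def test_prenoise_values_exactly_in_bounds(self):
        protein = build_default_protein(seed=1)
        peps = generate_peptide_map(protein.sequence, first_index=265, seed=1)
        clean = peptide_percent_d(protein, peps, None, (0.0, 10.0, 14400.0))
        assert (clean >= 0.0).all() and (clean <= 100.0).all()

    def test_shared_vehicle_mode(self):
        protein = build_default_protein(seed=1)
        peps = generate_peptide_map(protein.sequence, first_index=265, seed=1)[:5]
        lib = simulate_compound_library(3, seed=1)
        cfg = SimulationConfig(timepoints=(10.0,), n_replicates=2, seed=0)
        obs = simulate_dataset(protein, peps, lib, cfg, paired_vehicle=False)
        veh = obs[obs.condition == "vehicle"]
        assert set(veh.experiment) == {"vehicle"}
        assert len(veh) == 5 * 2
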