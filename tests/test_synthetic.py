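import dataclasses
import math

import numpy as np
import pytest

from degdet.degrons import degron_set_from_pairs, scan_c_degrons, scan_n_degrons
from degdet.disorder_topology import call_terminal_idrs, classify_ta, topology_from_string
from degdet.hydropathy import KYTE_DOOLITTLE, ctth
from degdet.kferq import find_kferq_motifs
from degdet.synthetic_data import (AA, DEFAULT_COMPOSITION, SpecError, SyntheticSpec,
                                   default_two_group_specs, expected_odds_ratio,
                                   generate_dataset, generate_two_group_study,
                                   tilted_composition)


def base_mean_kd(comp=DEFAULT_COMPOSITION):
    return sum(comp[a] * KYTE_DOOLITTLE[a] for a in comp)


class TestSpecValidation:
    def test_zero_sequences_rejected(self):
        with pytest.raises(SpecError):
            SyntheticSpec(n_sequences=0)

    def test_floor_below_analyzable_length_rejected(self):
        with pytest.raises(SpecError):
            SyntheticSpec(n_sequences=10, length_floor=30)

    def test_composition_must_sum_to_one(self):
        comp = dict(DEFAULT_COMPOSITION)
        comp["A"] += 0.01
        with pytest.raises(SpecError, match="sum"):
            SyntheticSpec(n_sequences=10, composition=comp)

    def test_infeasible_tail_shift_rejected(self):
        with pytest.raises(SpecError, match="shift"):
            SyntheticSpec(n_sequences=10, tail_kd_shift=20.0)

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(SpecError):
            SyntheticSpec(n_sequences=10, p_ta=1.5)

    def test_planting_requires_motifs(self):
        with pytest.raises(SpecError, match="motifs"):
            SyntheticSpec(n_sequences=10, p_c_degron=0.5)


class TestTiltedComposition:
    def test_zero_shift_identity(self):
        assert tilted_composition(DEFAULT_COMPOSITION, 0.0) == DEFAULT_COMPOSITION

    @pytest.mark.parametrize("shift", [0.15, -0.3, 1.0])
    def test_mean_moves_by_shift(self, shift):
        tilted = tilted_composition(DEFAULT_COMPOSITION, shift)
        assert sum(tilted.values()) == pytest.approx(1.0)
        assert base_mean_kd(tilted) == pytest.approx(base_mean_kd() + shift, abs=1e-9)


class TestGeneration:
    def test_determinism_byte_identical(self):
        spec = SyntheticSpec(n_sequences=50, seed=11, p_c_degron=0.3,
                             c_degron_motifs=("GG",), p_ta=0.2, p_n_idr=0.2)
        ds1, t1, c1 = generate_dataset(spec)
        ds2, t2, c2 = generate_dataset(spec)
        assert [r.sequence for r in ds1] == [r.sequence for r in ds2]
        assert t1.equals(t2)
        assert c1["topology"] == c2["topology"]

    def test_lengths_respect_floor(self):
        spec = SyntheticSpec(n_sequences=200, seed=1)
        ds, _, _ = generate_dataset(spec, with_companions=False)
        assert min(len(r) for r in ds) >= 60

    def test_composition_matches_spec_within_3sd(self):
        spec = SyntheticSpec(n_sequences=900, seed=5, start_with_met=False)
        ds, _, _ = generate_dataset(spec, with_companions=False)
        pooled = "".join(r.sequence for r in ds)
        n = len(pooled)
        assert n > 100_000
        for a in AA:
            p = DEFAULT_COMPOSITION[a]
            sd = math.sqrt(n * p * (1 - p))
            assert abs(pooled.count(a) - n * p) < 3.5 * sd, a

    def test_tail_shift_realized_within_tolerance(self):
        spec = SyntheticSpec(n_sequences=1000, seed=2, tail_kd_shift=0.5)
        ds, _, _ = generate_dataset(spec, with_companions=False)
        mean_ctth = np.mean([ctth(r.sequence) for r in ds])
        assert mean_ctth == pytest.approx(base_mean_kd() + 0.5, abs=0.05)

    def test_met_start_control(self):
        ds, _, _ = generate_dataset(SyntheticSpec(n_sequences=20, seed=3),
                                    with_companions=False)
        assert all(r.sequence.startswith("M") for r in ds)
        ds2, _, _ = generate_dataset(
            SyntheticSpec(n_sequences=200, seed=3, start_with_met=False),
            with_companions=False)
        assert any(not r.sequence.startswith("M") for r in ds2)


@pytest.fixture(scope="module")
def bundle():
    spec = SyntheticSpec(
        n_sequences=400, seed=17,
        p_n_degron=0.3, n_degron_motifs=("RV", "DI"),
        p_c_degron=0.3, c_degron_motifs=("GG", "EE"),
        p_kferq_canonical=0.3, p_kferq_phospho=0.2, p_kferq_acetyl=0.2,
        p_ta=0.2, p_n_idr=0.25, p_c_idr=0.25,
    )
    ds, truth, companions = generate_dataset(spec)
    return spec, ds, truth.set_index("id"), companions


class TestPlantingRoundTrip:

    def test_planted_degrons_rediscovered(self, bundle):
        spec, ds, truth, _ = bundle
        n_set = degron_set_from_pairs([(m, -0.5) for m in spec.n_degron_motifs], "N")
        c_set = degron_set_from_pairs([(m, -0.5) for m in spec.c_degron_motifs], "C")
        for rec in ds:
            row = truth.loc[rec.id]
            if row.n_degron_motif:
                assert row.n_degron_motif in {h.motif for h in scan_n_degrons(rec.sequence, n_set)}
            else:
                assert not scan_n_degrons(rec.sequence, n_set)  # prevalence-exact
            if row.c_degron_motif:
                assert row.c_degron_motif in {h.motif for h in scan_c_degrons(rec.sequence, c_set)}
            else:
                assert not scan_c_degrons(rec.sequence, c_set)

    def test_planted_kferq_rediscovered(self, bundle):
        _, ds, truth, _ = bundle
        for rec in ds:
            row = truth.loc[rec.id]
            classes = {h.motif_class for h in find_kferq_motifs(rec.sequence)}
            if row.kferq_canonical_n:
                assert "canonical" in classes
            if row.kferq_phospho_n:
                assert "phospho_activated" in classes
            if row.kferq_acetyl_n:
                assert "acetyl_activated" in classes

    def test_planted_ta_rediscovered(self, bundle):
        _, ds, truth, companions = bundle
        for rec in ds:
            row = truth.loc[rec.id]
            topo = topology_from_string(rec.id, companions["topology"][rec.id])
            cls = classify_ta(topo, len(rec))
            assert cls.is_ta_like == bool(row.ta_planted)

    def test_planted_idrs_rediscovered(self, bundle):
        _, ds, truth, companions = bundle
        for rec in ds:
            row = truth.loc[rec.id]
            call = call_terminal_idrs(companions["disorder"][rec.id])
            if row.n_idr_planted:
                assert call.n_idr
            if row.c_idr_planted:
                assert call.c_idr

    def test_companion_shapes_match_sequences(self, bundle):
        _, ds, _, companions = bundle
        for rec in ds:
            assert len(companions["disorder"][rec.id]) == len(rec)
            assert len(companions["topology"][rec.id]) == len(rec)
        agg = companions["aggregation"]
        assert set(agg.columns) >= {"id", "position", "energy", "probability"}


class TestBackgroundRates:
    def test_unplanted_c_degron_presence_matches_composition(self):
        """With no planting the anchored-match rate is composition-driven."""
        spec = SyntheticSpec(n_sequences=3000, seed=23, start_with_met=False)
        ds, _, _ = generate_dataset(spec, with_companions=False)
        motifs = ["GG", "RG", "KG", "EE", "PG", "VV"]  # distinct 2-mers: disjoint
        cset = degron_set_from_pairs([(m, -0.5) for m in motifs], "C")
        observed = np.mean([bool(scan_c_degrons(r.sequence, cset)) for r in ds])
        expected = sum(DEFAULT_COMPOSITION[m[0]] * DEFAULT_COMPOSITION[m[1]]
                       for m in motifs)
        sd = math.sqrt(expected * (1 - expected) / len(ds))
        assert abs(observed - expected) < 4 * sd


class TestTwoGroupStudy:
    def test_expected_or_arithmetic(self):
        assert expected_odds_ratio(0.168, 0.084) == pytest.approx(
            (0.168 / 0.832) / (0.084 / 0.916))
        assert expected_odds_ratio(0.168, 0.084) == pytest.approx(2.20, abs=0.01)

    def test_default_study_records_expected_effects(self):
        _, _, _, _, expected = generate_two_group_study(seed=1, n=200)
        assert expected["true_c_degron_or"] == pytest.approx(2.2019, abs=1e-3)
        assert expected["true_ctth_diff"] == pytest.approx(0.15)

    def test_equal_specs_give_null_expectations(self):
        cp, _ = default_two_group_specs(n=100, seed=4)
        twin = dataclasses.replace(cp, dataset_label="NCP", seed=cp.seed + 1)
        _, _, _, _, expected = generate_two_group_study(cp, twin)
        assert expected["true_ctth_diff"] == 0.0
        assert expected["true_c_degron_or"] == pytest.approx(1.0)

    def test_realized_prevalences_near_spec(self):
        cp_ds, ncp_ds, cp_truth, ncp_truth, _ = generate_two_group_study(seed=9, n=2000)
        assert cp_truth.c_degron_motif.astype(bool).mean() == pytest.approx(0.084, abs=0.03)
        assert ncp_truth.c_degron_motif.astype(bool).mean() == pytest.approx(0.168, abs=0.03)
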