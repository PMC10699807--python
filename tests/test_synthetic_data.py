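"""Ground-truth generator: EX2 kinetics, map statistics, linkage, determinism."""

import numpy as np
import pandas as pd
import pytest

from hdxfold.chem_rates import sequence_intrinsic_rates
from hdxfold.constants import R_KCAL, T_REF
from hdxfold.hdx_io import PeptideRecord, exchangeable_count
from hdxfold.synthetic_data import (
    GroundTruthProfile,
    SimulationSpec,
    flat_profile,
    ligand_linked_profile,
    linkage_ddg,
    make_peptide_map,
    paper_style_conditions,
    simulate_ex2_uptake,
)

SEQ = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAKTAYIAKQRQISFVKSHFSRQLEERL"


def _clean_spec(seed, **kwargs):
    """Spec with negligible back-/in-exchange and no replicate noise."""
    defaults = dict(
        seed=seed,
        noise_sd=0.0,
        replicates=1,
        back_exchange_mean=1e-6,
        back_exchange_iqr=1e-7,
        in_exchange_mean=1e-6,
        in_exchange_iqr=1e-7,
    )
    defaults.update(kwargs)
    return SimulationSpec(**defaults)


class TestProfile:
    def test_ln_pf_must_be_finite(self):
        with pytest.raises(ValueError):
            GroundTruthProfile("AAA", np.array([1.0, np.inf, 0.0]))

    def test_delta_g_undefined_below_pf_one(self):
        p = GroundTruthProfile("AAAA", np.array([0.0, -1.0, 2.0, 5.0]))
        dg = p.delta_g()
        assert np.isnan(dg[0]) and np.isnan(dg[1])
        assert np.all(np.isfinite(dg[2:]))


class TestSimulateEx2:
    def test_pf_one_follows_intrinsic_curve(self, fast_condition):
        spec = _clean_spec(1, conditions={"fast": fast_condition},
                           timepoints={"fast": (1.0, 10.0, 100.0)},
                           reference_condition="fast")
        profile = flat_profile(SEQ, ln_pf=0.0)
        table = simulate_ex2_uptake({"s": profile}, spec)
        up = table[table.row_type == "uptake"]
        k_chem = sequence_intrinsic_rates(SEQ, fast_condition)
        row = up.iloc[0]
        idx = np.arange(int(row.start) + 1, int(row.end))  # peptide pos >= 3
        idx = idx[[SEQ[i] != "P" for i in idx]]
        expected = np.nansum(0.93 * (1 - np.exp(-k_chem[idx] * row.time_s)))
        assert row.uptake_da == pytest.approx(expected, rel=1e-4)

    def test_saturation_at_long_times(self, fast_condition):
        spec = _clean_spec(1, conditions={"fast": fast_condition},
                           timepoints={"fast": (1e9,)}, reference_condition="fast")
        profile = flat_profile(SEQ, ln_pf=np.log(50.0))
        table = simulate_ex2_uptake({"s": profile}, spec)
        up = table[table.row_type == "uptake"]
        for row in up.itertuples():
            n_ex = exchangeable_count(
                PeptideRecord("SYN", int(row.start), int(row.end), row.sequence)
            )
            assert row.uptake_da == pytest.approx(0.93 * n_ex, rel=1e-4)

    def test_bit_identical_given_seed(self):
        spec_a = SimulationSpec(seed=11)
        spec_b = SimulationSpec(seed=11)
        profile = flat_profile(SEQ, ln_pf=6.0)
        a = simulate_ex2_uptake({"s": profile}, spec_a)
        b = simulate_ex2_uptake({"s": profile}, spec_b)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        profile = flat_profile(SEQ, ln_pf=6.0)
        a = simulate_ex2_uptake({"s": profile}, SimulationSpec(seed=11))
        b = simulate_ex2_uptake({"s": profile}, SimulationSpec(seed=12))
        assert not a["uptake_da"].equals(b["uptake_da"])

    def test_controls_emitted_per_peptide(self):
        profile = flat_profile(SEQ, ln_pf=6.0)
        table = simulate_ex2_uptake({"s": profile}, SimulationSpec(seed=2))
        ctrl = table[table.row_type.isin(["nd", "inx", "fd"])]
        per_pep = ctrl.groupby(["start", "end"])["row_type"].nunique()
        assert (per_pep == 3).all()

    def test_back_exchange_statistics_match_design(self):
        profile = flat_profile("A" * 400, ln_pf=6.0)
        spec = SimulationSpec(seed=3, redundancy=8.0)
        table = simulate_ex2_uptake({"s": profile}, spec)
        ctrl = table[table.row_type == "fd"].copy()
        n_ex = ctrl.apply(
            lambda r: exchangeable_count(
                PeptideRecord("SYN", int(r.start), int(r.end), r.sequence)
            ),
            axis=1,
        )
        bx = 1 - ctrl["uptake_da"] / (0.93 * n_ex)
        assert bx.mean() == pytest.approx(0.27, abs=0.04)


class TestLigandLinkage:
    def test_zero_ligand_is_identity(self):
        apo = flat_profile(SEQ, ln_pf=5.0)
        bound = ligand_linked_profile(apo, kd=6.0, ligand_conc=0.0,
                                      site_residues=range(10, 20))
        np.testing.assert_allclose(bound.ln_pf, apo.ln_pf)

    def test_ligand_at_kd_gives_rt_ln2(self):
        assert linkage_ddg(6.0, 6.0) == pytest.approx(
            R_KCAL * T_REF * np.log(2.0)
        )
        assert linkage_ddg(6.0, 6.0) == pytest.approx(0.41, abs=0.005)

    def test_sixty_fold_excess_gives_2p4(self):
        ddg = linkage_ddg(6.0, 60 * 6.0)
        assert float(f"{ddg:.2g}") == pytest.approx(2.4)

    def test_only_site_residues_shift(self):
        apo = flat_profile(SEQ, ln_pf=5.0)
        site = list(range(10, 20))
        bound = ligand_linked_profile(apo, kd=1.0, ligand_conc=19.0, site_residues=site)
        shifted = np.where(bound.ln_pf != apo.ln_pf)[0] + 1
        assert list(shifted) == site


class TestPeptideMap:
    def test_length_and_redundancy_statistics(self):
        rng = np.random.default_rng(5)
        seq = "ADEFGHIKLMNQRSTVWY" * 23  # 414 residues
        peptides = make_peptide_map(seq, rng=rng, mean_length=12.2, redundancy=4.3)
        lengths = np.array([p.length for p in peptides])
        coverage = sum(p.length for p in peptides) / len(seq)
        assert abs(lengths.mean() - 12.2) <= 1.0
        assert abs(coverage - 4.3) <= 1.0

    def test_deterministic_given_seed(self):
        a = make_peptide_map(SEQ, rng=np.random.default_rng(9))
        b = make_peptide_map(SEQ, rng=np.random.default_rng(9))
        assert [(p.start, p.end) for p in a] == [(p.start, p.end) for p in b]

    def test_redundancy_one_tiles_without_overlap(self):
        peptides = make_peptide_map(SEQ, rng=np.random.default_rng(1), redundancy=1.0)
        spans = sorted((p.start, p.end) for p in peptides)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 == e1 + 1

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            make_peptide_map("MKTAYIAK", rng=np.random.default_rng(1))


class TestSpecValidation:
    def test_seed_mandatory(self):
        with pytest.raises(TypeError):
            SimulationSpec()  # type: ignore[call-arg]

    def test_fractions_validated(self):
        with pytest.raises(ValueError):
            SimulationSpec(seed=1, back_exchange_mean=1.5)

    def test_unknown_timepoint_condition_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(seed=1, timepoints={"bogus": (1.0,)})

    def test_reference_condition_must_exist(self):
        with pytest.raises(ValueError):
            SimulationSpec(seed=1, conditions=paper_style_conditions(),
                           reference_condition="nope")
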