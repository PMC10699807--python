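"""Differential HDX: hybrid test, residue aggregation, structure mapping."""

import numpy as np
import pandas as pd
import pytest

from hdxfold.differential import (
    differential_matrix,
    global_threshold,
    hybrid_significance,
    read_structure_bfactors,
    residue_ddg,
    write_structure_map,
)
from hdxfold.hdx_io import PeptideRecord
from hdxfold.synthetic_data import binding_study, simulate_ex2_uptake


def _replicate_table(deltas, sd, n_rep=3, seed=0):
    """Long table for len(deltas) peptides, two states offset by deltas."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, delta in enumerate(deltas):
        start, end = 10 * i + 1, 10 * i + 10
        for state, offset in (("A", 0.0), ("B", delta)):
            for r in range(n_rep):
                rows.append(
                    {
                        "start": start,
                        "end": end,
                        "state": state,
                        "time_s": 100.0,
                        "replicate": f"r{r}",
                        "uptake_da": 2.0 + offset + rng.normal(0, sd),
                    }
                )
    return pd.DataFrame(rows)


class TestGlobalThreshold:
    def test_closed_form_at_repeatability(self):
        assert global_threshold(0.06, alpha=0.05) == pytest.approx(0.166, abs=0.001)

    def test_positive_sd_required(self):
        with pytest.raises(ValueError):
            global_threshold(0.0)


class TestHybridSignificance:
    def test_identical_states_flag_nothing(self):
        table = _replicate_table([0.0] * 20, sd=0.06)
        cells = differential_matrix(table, "A", "B")
        flagged, _ = hybrid_significance(cells)
        assert int(flagged["significant"].sum()) == 0

    def test_constructed_positives_all_flagged(self):
        # 10 offset peptides among 30: exactly those 10 cross both criteria
        deltas = [0.5] * 10 + [0.0] * 20
        table = _replicate_table(deltas, sd=0.06)
        cells = differential_matrix(table, "A", "B").sort_values("start")
        flagged, threshold = hybrid_significance(cells)
        flagged = flagged.sort_values("start").reset_index(drop=True)
        assert threshold == pytest.approx(0.166, abs=0.03)
        assert flagged.loc[:9, "significant"].all()
        assert not flagged.loc[10:, "significant"].any()

    def test_no_replicates_is_hard_error(self):
        table = _replicate_table([0.0] * 3, sd=0.06, n_rep=1)
        cells = differential_matrix(table, "A", "B")
        with pytest.raises(ValueError, match="replicated"):
            hybrid_significance(cells)

    def test_antisymmetry_of_delta(self):
        table = _replicate_table([0.4] * 5, sd=0.05)
        ab = differential_matrix(table, "A", "B")
        ba = differential_matrix(table, "B", "A")
        np.testing.assert_allclose(
            ab.sort_values("start")["delta_da"].to_numpy(),
            -ba.sort_values("start")["delta_da"].to_numpy(),
        )

    def test_null_simulation_flag_rate_below_7_percent(self):
        # identical ground truth, replicate SD 0.06 Da, 3 replicates, ~1000 cells
        profiles, spec, _, _ = binding_study(seed=5, length=320, ddg_kcal=0.0)
        table = simulate_ex2_uptake(profiles, spec)
        rows = table[
            (table.row_type == "uptake") & (table.condition == spec.reference_condition)
        ]
        cells = differential_matrix(rows, "apo", "bound")
        assert len(cells) >= 1000
        flagged, _ = hybrid_significance(cells, alpha=0.05)
        assert flagged["significant"].mean() <= 0.07


class TestResidueDdg:
    def _pep(self, start, end):
        return PeptideRecord("P", start, end, "A" * (end - start + 1))

    def test_mean_over_covering_peptides(self):
        ddgs = [(self._pep(1, 10), 1.0), (self._pep(5, 14), 2.0)]
        rmap = residue_ddg(ddgs)
        # residues 7..10 are exchange-competent in both peptides
        assert rmap.loc[8, "ddg"] == pytest.approx(1.5)
        assert rmap.loc[8, "n_peptides"] == 2

    def test_single_peptide_passthrough_and_coverage_gaps(self):
        rmap = residue_ddg([(self._pep(1, 10), 1.8)])
        assert rmap.loc[5, "ddg"] == pytest.approx(1.8)
        assert 1 not in rmap.index  # first two residues never report
        assert 20 not in rmap.index  # uncovered residues absent, not zero

    def test_permutation_invariance(self):
        items = [(self._pep(1, 10), 1.0), (self._pep(5, 14), 2.0), (self._pep(8, 17), 0.5)]
        a = residue_ddg(items)
        b = residue_ddg(items[::-1])
        pd.testing.assert_frame_equal(a, b)


class TestStructureMap:
    @pytest.fixture()
    def toy_pdb(self, tmp_path):
        import gemmi

        st = gemmi.Structure()
        st.name = "toy"
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        for i, resname in enumerate(["ALA", "GLY", "SER"], start=9):
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(float(i), 0.0, 0.0)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        path = tmp_path / "toy.pdb"
        st.write_pdb(str(path))
        return path

    def test_mapped_residue_gets_value_others_sentinel(self, toy_pdb, tmp_path):
        out = tmp_path / "mapped.pdb"
        unmatched = write_structure_map(toy_pdb, {10: 1.8}, out)
        assert unmatched == []
        b = read_structure_bfactors(out)
        assert b[10] == pytest.approx(1.8, abs=0.005)
        assert b[9] == pytest.approx(0.0)
        assert b[11] == pytest.approx(0.0)

    def test_empty_map_all_sentinel(self, toy_pdb, tmp_path):
        out = tmp_path / "mapped.pdb"
        write_structure_map(toy_pdb, {}, out)
        assert set(read_structure_bfactors(out).values()) == {0.0}

    def test_roundtrip_to_pdb_precision(self, toy_pdb, tmp_path):
        values = {9: 1.234, 10: -0.567, 11: 2.999}
        out = tmp_path / "mapped.pdb"
        write_structure_map(toy_pdb, values, out)
        b = read_structure_bfactors(out)
        for k, v in values.items():
            assert b[k] == pytest.approx(v, abs=0.005)  # B-factor has 2 decimals

    def test_unmatched_residues_reported(self, toy_pdb, tmp_path):
        unmatched = write_structure_map(toy_pdb, {10: 1.0, 99: 2.0}, tmp_path / "m.pdb")
        assert unmatched == [99]
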