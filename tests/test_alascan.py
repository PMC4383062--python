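"""Alanine scanning: classification thresholds, identity controls, the
designed hot spot, and replay of the published per-term table."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbsakit.alascan import classify, scan_interface, scan_residue, scan_table
from pbsakit.pipeline import binding_free_energy
from pbsakit.structure import Trajectory
from pbsakit.synthetic import load_printed_fixture

SCAN_FRAMES = [0, 60, 120, 180, 240]


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (-15.65, "hot"),
            (-7.48, "hot"),
            (-4.0, "hot"),  # boundary resolves to hot
            (-3.99, "warm"),
            (-2.10, "warm"),
            (-2.0, "warm"),  # boundary resolves to warm
            (-1.99, "null"),
            (0.24, "null"),
        ],
    )
    def test_thresholds(self, value, expected):
        assert classify(value, "ARG") == expected

    def test_gly_pro_always_excluded(self):
        assert classify(-20.0, "GLY") == "excluded"
        assert classify(-20.0, "PRO") == "excluded"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify(float("nan"), "ARG")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(value=st.floats(-30, 10, allow_nan=False))
    def test_pure_function_of_subtotal(self, value):
        c = classify(value, "MET")
        if value <= -4.0:
            assert c == "hot"
        elif value <= -2.0:
            assert c == "warm"
        else:
            assert c == "null"


class TestScanResidue:
    def test_ala_to_ala_identity(self, toy_trajectory, fast_config, toy_complex):
        _, _, params = toy_complex
        rec = scan_residue(
            toy_trajectory, {"A"}, {"B"}, ("B", 2, "ALA"),
            config=fast_config, params=params, frames=SCAN_FRAMES,
        )
        assert rec.dd_g_subtotal == 0.0
        assert rec.dd_e_vdw == 0.0
        assert rec.classification == "null"

    def test_gly_target_excluded_without_energies(self, toy_trajectory,
                                                  fast_config, toy_complex):
        _, _, params = toy_complex
        rec = scan_residue(
            toy_trajectory, {"A"}, {"B"}, ("A", 1, "GLY"),
            config=fast_config, params=params, frames=SCAN_FRAMES,
        )
        assert rec.classification == "excluded"
        assert rec.dd_g_subtotal == 0.0

    def test_buried_hydrophobic_hot_with_vdw_dominant(
        self, toy_trajectory, fast_config, toy_complex, met_scan
    ):
        rec = met_scan
        assert rec.classification == "hot"
        assert rec.dd_g_subtotal <= -4.0
        assert rec.dd_e_vdw < 0
        assert abs(rec.dd_e_vdw) > abs(rec.dd_e_ele)
        assert abs(rec.dd_e_vdw) > abs(rec.dd_g_solv)
        # component identities
        assert rec.dd_e_gas == pytest.approx(rec.dd_e_vdw + rec.dd_e_ele)
        assert rec.dd_g_solv == pytest.approx(rec.dd_g_np + rec.dd_g_pb)
        assert rec.dd_g_subtotal == pytest.approx(rec.dd_e_gas + rec.dd_g_solv)

    def test_matches_direct_recomputation_oracle(
        self, toy_trajectory, fast_config, toy_complex, met_scan
    ):
        """Independent route: build the mutant trajectory explicitly and push
        wild and mutant through the binding pipeline."""
        from pbsakit.structure import truncate_to_alanine

        system, _, params = toy_complex
        mut = truncate_to_alanine(system, ("B", 3, "MET"), params=params)
        sub_wild = Trajectory(
            system=system,
            snapshots=[toy_trajectory.snapshots[f] for f in SCAN_FRAMES],
        )
        sub_mut = Trajectory(
            system=mut.system,
            snapshots=[
                mut.map_snapshot(toy_trajectory.snapshots[f]) for f in SCAN_FRAMES
            ],
        )
        wild = binding_free_energy(sub_wild, {"A"}, {"B"}, config=fast_config)
        mutant = binding_free_energy(sub_mut, {"A"}, {"B"}, config=fast_config)
        dd_vdw = wild.delta["e_vdw"].mean - mutant.delta["e_vdw"].mean
        dd_ele = wild.delta["e_ele"].mean - mutant.delta["e_ele"].mean
        dd_np = wild.delta["g_sol_np"].mean - mutant.delta["g_sol_np"].mean
        dd_pb = wild.delta["g_sol_pb"].mean - mutant.delta["g_sol_pb"].mean
        assert met_scan.dd_e_vdw == pytest.approx(dd_vdw, abs=1e-8)
        assert met_scan.dd_e_ele == pytest.approx(dd_ele, abs=1e-8)
        assert met_scan.dd_g_np == pytest.approx(dd_np, abs=1e-8)
        # PB grids are pinned independently on the two routes; agreement is
        # bounded by the grid-placement artifact
        assert met_scan.dd_g_pb == pytest.approx(dd_pb, abs=0.3)

    def test_scan_isolation(self, toy_trajectory, fast_config, toy_complex):
        """Scanning one residue leaves the wild-type system untouched."""
        system, ref, params = toy_complex
        before = system.coordinates().copy()
        n_atoms = system.n_atoms
        scan_residue(
            toy_trajectory, {"A"}, {"B"}, ("B", 1, "SER"),
            config=fast_config, params=params, frames=[0],
        )
        assert system.n_atoms == n_atoms
        np.testing.assert_array_equal(system.coordinates(), before)


class TestScanInterface:
    def test_summary_counts_and_table(self, toy_trajectory, fast_config,
                                      toy_complex, met_scan):
        _, _, params = toy_complex
        keys = [("B", 3, "MET"), ("B", 2, "ALA"), ("A", 1, "GLY")]
        records, summary = scan_interface(
            toy_trajectory, {"A"}, {"B"}, keys,
            config=fast_config, params=params, frames=SCAN_FRAMES,
        )
        assert summary["hot_ligand"] == 1
        assert summary["hot_receptor"] == 0
        assert summary["excluded"] == 1
        df = scan_table(records)
        assert list(df["class"]) == ["hot", "null", "excluded"]
        assert set(df.columns) >= {
            "ddE_vdw", "ddE_electrostatic", "ddE_gas", "ddG_sol_nonpol",
            "ddG_sol_PB", "ddG_solvation", "ddG_subtotal", "class",
        }

    def test_empty_and_excluded_only(self, toy_trajectory, fast_config,
                                     toy_complex):
        _, _, params = toy_complex
        records, summary = scan_interface(
            toy_trajectory, {"A"}, {"B"}, [],
            config=fast_config, params=params, frames=[0],
        )
        assert records == []
        assert summary["hot_receptor"] == summary["hot_ligand"] == 0
        records, summary = scan_interface(
            toy_trajectory, {"A"}, {"B"}, [("A", 1, "GLY"), ("A", 5, "GLY")],
            config=fast_config, params=params, frames=[0],
        )
        assert all(r.classification == "excluded" for r in records)
        assert summary["hot_receptor"] + summary["warm_receptor"] == 0


class TestPrintedTableReplay:
    def test_component_sums_reproduce_subtotals(self):
        fx = load_printed_fixture("table3")
        for res, row in fx.values.items():
            total = (
                row["dd_e_vdw"] + row["dd_e_ele"] + row["dd_g_np"] + row["dd_g_pb"]
            )
            if res not in fx.flags:
                assert total == pytest.approx(
                    row["dd_g_subtotal"], abs=0.0105
                ), res
        # the flag list covers every genuinely inconsistent printed cell
        for res in ("Thr885", "Met346", "Ser361", "Val359"):
            row = fx.values[res]
            total = (
                row["dd_e_vdw"] + row["dd_e_ele"] + row["dd_g_np"] + row["dd_g_pb"]
            )
            assert abs(total - row["dd_g_subtotal"]) > 0.0105
            assert res in fx.flags

    def test_rosters_match_published_counts(self):
        fx = load_printed_fixture("table3")
        calls = {
            res: classify(row["dd_g_subtotal"], res[:3].upper())
            for res, row in fx.values.items()
        }
        hot_rec = [r for r, c in calls.items()
                   if c == "hot" and fx.values[r]["side"] == "receptor"]
        hot_lig = [r for r, c in calls.items()
                   if c == "hot" and fx.values[r]["side"] == "ligand"]
        warm_rec = [r for r, c in calls.items()
                    if c == "warm" and fx.values[r]["side"] == "receptor"]
        assert sorted(hot_rec) == sorted(
            ["Glu904", "Glu907", "Arg908", "Gln911", "Met928", "Ile929"]
        )
        assert sorted(hot_lig) == sorted(
            ["Leu338", "Tyr341", "Asn343", "Met346", "Thr349", "Gln350",
             "Phe352", "Tyr358"]
        )
        assert sorted(warm_rec) == sorted(
            ["Thr885", "Ile894", "Tyr920", "Val924"]
        )
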