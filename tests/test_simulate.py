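"""Synthetic-data generator: determinism, planted margins, truth bookkeeping."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from spermre.contribution import TWOFOLD, classify_res
from spermre.io import read_abundance, read_dbp_list, read_gmt
from spermre.overlap import consistent_responders, movement_table
from spermre.simulate import (
    SimulationConfig,
    simulate_abundances,
    simulate_dbp_lists,
    simulate_panel_coverage,
    simulate_transcript_tracks,
    simulate_visit_means,
    write_simulation,
)
from spermre.tii import compute_tii, filter_q4
from spermre.integrity import call_integrity


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(frac_fivefold=0.9, frac_maternal=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(margin=0.0)


def test_planted_class_counts_exact(sim_small):
    cfg, _, _, _, truth = sim_small
    counts = truth["cls"].value_counts()
    assert counts["fivefold"] == round(cfg.frac_fivefold * cfg.n_res)
    assert counts["twofold"] == round(cfg.frac_twofold * cfg.n_res)
    assert counts["sperm_specific"] == round(cfg.frac_sperm_specific * cfg.n_res)


def test_realized_medians_honor_margins(sim_small):
    cfg, sperm, oocyte, zygote, truth = sim_small
    d, t = cfg.margin, cfg.thresholds
    s_med = sperm.median_per_re()
    o_med = oocyte.median_per_re()
    z_med = zygote.median_per_re()
    ff = truth.index[truth["cls"] == "fivefold"]
    assert (s_med[ff] >= t.sperm_min_5x * (1 + d) - 1e-9).all()
    assert (o_med[ff] <= t.oocyte_max_5x * (1 - d) + 1e-9).all()
    assert (z_med[ff] >= t.zygote_min * (1 + d) - 1e-9).all()
    ss = truth.index[truth["cls"] == "sperm_specific"]
    assert (o_med[ss] <= t.oocyte_absent * (1 - d) + 1e-9).all()
    null = truth.index[truth["cls"] == "null"]
    assert (z_med[null] <= t.zygote_min * (1 - d) + 1e-9).all()


def test_same_seed_reproduces_matrices(sim_small):
    cfg, sperm, *_ = sim_small
    sperm2, *_ = simulate_abundances(cfg)
    pd.testing.assert_frame_equal(sperm.data, sperm2.data)


def test_write_simulation_is_byte_identical(tmp_path):
    cfg = SimulationConfig(seed=5)
    write_simulation(cfg, tmp_path / "a")
    write_simulation(cfg, tmp_path / "b")
    for name in ("sperm.tsv", "zygote.tsv", "truth_res.tsv", "dbp_B1H.tsv",
                 "sets.gmt", "panel.bed", "coverage/S01.bedGraph"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                           shallow=False), name


def test_seeds_differ(tmp_path):
    a, *_ = simulate_abundances(SimulationConfig(seed=1, n_res=200))
    b, *_ = simulate_abundances(SimulationConfig(seed=2, n_res=200))
    assert not a.data.equals(b.data)


def test_generated_files_satisfy_reader_invariants(tmp_path):
    paths = write_simulation(SimulationConfig(seed=5), tmp_path)
    am = read_abundance(paths["sperm"], paths["sperm_meta"])
    assert (am.data.to_numpy() >= 0).all()
    dbp = read_dbp_list(paths["dbp_B1H"])
    assert ((dbp["empirical_p"] > 0) & (dbp["empirical_p"] <= 0.05)).all()
    coll = read_gmt(paths["gmt"])
    assert "PLANTED_CELLULAR_STRESS_RESPONSE" in coll


def test_capping_branch_is_exercised(sim_small):
    _, _, _, _, truth = sim_small
    assert truth["capped"].any()


def test_dbp_lists_planted_overlap_and_consistency():
    cfg = SimulationConfig(seed=9)
    *_, truth = simulate_abundances(cfg)
    comparisons, dbp_truth = simulate_dbp_lists(cfg, truth)
    n_olap = round(cfg.dbp_overlap_fraction * cfg.dbp_n_per_segment)
    pat_genes = set(truth.loc[truth["cls"].isin(
        ["fivefold", "twofold", "sperm_specific"]), "gene"])
    for c in comparisons:
        assert len(c.entries) == cfg.dbp_n_per_segment
        got = {g for g in c.entries["gene"] if g in pat_genes}
        assert len(got) == n_olap
        assert sorted(got) == dbp_truth["overlap_genes"][c.segment]
    # the consistency rule recovers exactly the planted consistent set
    moves = pd.concat(
        c.entries.assign(segment=c.segment)[["gene", "segment", "direction"]]
        for c in comparisons
    )
    assert consistent_responders(moves) == dbp_truth["consistent_genes"]


def test_visit_means_recover_planted_movement():
    cfg = SimulationConfig(seed=9)
    *_, truth = simulate_abundances(cfg)
    comparisons, _ = simulate_dbp_lists(cfg, truth)
    by_seg = {c.segment: c for c in comparisons}
    vms = simulate_visit_means(cfg, comparisons)
    for arm, (seg1, seg2) in (("B1HB2", ("B1H", "HB2")),
                              ("H1BH2", ("H1B", "BH2"))):
        vm = vms[arm]
        mt = movement_table(vm[["baseline", "crossover", "crossback"]],
                            set(by_seg[seg1].entries["re_id"]),
                            set(by_seg[seg2].entries["re_id"]))
        assert (mt["first"] == vm["first"]).all()
        assert (mt["second"] == vm["second"]).all()


def test_panel_coverage_separates_bad_samples():
    cfg = SimulationConfig(seed=7)
    tracks, panel, truth = simulate_panel_coverage(cfg)
    by_sample = {}
    for t in tracks:
        by_sample.setdefault(t.sample_id, []).append(t)
    results = [compute_tii(ts, panel) for ts in by_sample.values()]
    kept, removed = filter_q4(results)
    assert sorted(r.sample_id for r in removed) == \
        sorted(truth.index[truth["bad"]])


def test_transcript_tracks_planted_integrity():
    cfg = SimulationConfig(seed=4)
    tracks, truth = simulate_transcript_tracks(cfg, n_samples=7)
    for tid, ts in tracks.items():
        call = call_integrity(ts)
        assert call.n_pass == truth.loc[tid, "n_pass"]


def test_classifier_recovers_all_planted_labels(sim_small):
    _, sperm, oocyte, zygote, truth = sim_small
    res = classify_res(sperm, oocyte, zygote, gene_map=truth["gene"])
    expected = truth["cls"].map(
        {"fivefold": "FIVEFOLD_PATERNAL", "twofold": TWOFOLD,
         "sperm_specific": TWOFOLD, "maternal": "NONE", "null": "NONE"}
    )
    assert (res["label"] == expected).all()
    ss = truth["cls"] == "sperm_specific"
    assert res.loc[ss, "sperm_specific"].all()
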