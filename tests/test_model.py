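import math

import numpy as np
import pytest

from fragrank.chem import PROTON_MASS
from fragrank.fraggraph import Fragment, FragmentationGraph
from fragrank.model import (
    FRAGMENT_TOLERANCE,
    ScoringModel,
    _BOND_INDEX,
    annotate,
    load_model,
    save_model,
    score,
    train,
)
from fragrank.spectra import Peak, Spectrum, assign_log_ranks


def _fg(frag_rows, edges, mol_id="toy", n_nodes=4):
    frags = [Fragment(*row) for row in frag_rows]
    return FragmentationGraph(
        molecule_id=mol_id, n_nodes=n_nodes, fragments=frags, edges=edges,
        rules_digest="test-rules",
    )


def chain_fg(masses=(300.0, 180.0, 90.0), bonds=("root", "OC", "NC")):
    """root -> A -> B chain."""
    return _fg(
        [
            (0b111, masses[0], 0, bonds[0], []),
            (0b011, masses[1], 1, bonds[1], [0]),
            (0b001, masses[2], 2, bonds[2], [1]),
        ],
        [(0, 1, bonds[1]), (1, 2, bonds[2])],
    )


def single_frag_fg(root_mass=200.0, frag_mass=100.0, bond="OC"):
    return _fg(
        [(0b11, root_mass, 0, "root", []), (0b01, frag_mass, 1, bond, [0])],
        [(0, 1, bond)],
    )


def _spectrum(mz_int_pairs, precursor=301.0):
    return assign_log_ranks(
        Spectrum(
            id="s", precursor_mz=precursor,
            peaks=tuple(Peak(m, i) for m, i in mz_int_pairs),
        )
    )


def _mz(mass):
    return mass + PROTON_MASS


def test_match_tolerance_boundary():
    fg = single_frag_fg(frag_mass=100.0)
    inside = _spectrum([(_mz(100.0) + 0.009, 100.0), (500.0, 10.0)])
    ann = annotate(fg, inside, seed=0)
    assert ann.log_rank[1] == 1 and ann.matched_peak[1] is not None

    outside = _spectrum([(_mz(100.0) + 0.011, 100.0), (500.0, 10.0)])
    ann = annotate(fg, outside, seed=0)
    assert ann.log_rank[1] == 7 and ann.matched_peak[1] is None


def test_lowest_depth_fragment_wins_conflicts():
    """Two fragments at depths 1 and 2 both within tolerance of one peak."""
    fg = _fg(
        [
            (0b111, 300.0, 0, "root", []),
            (0b011, 100.002, 1, "OC", [0]),
            (0b001, 100.000, 2, "NC", [1]),
        ],
        [(0, 1, "OC"), (1, 2, "NC")],
    )
    s = _spectrum([(_mz(100.001), 100.0), (500.0, 10.0)])
    ann = annotate(fg, s, seed=0)
    assert ann.log_rank[1] == 1  # depth-1 fragment takes the peak
    assert ann.log_rank[2] == 7


def test_each_peak_annotates_at_most_one_fragment():
    fg = _fg(
        [
            (0b111, 300.0, 0, "root", []),
            (0b011, 100.002, 1, "OC", [0]),
            (0b110, 100.000, 1, "CC", [0]),
        ],
        [(0, 1, "OC"), (0, 2, "CC")],
    )
    s = _spectrum([(_mz(100.001), 100.0), (500.0, 10.0)])
    for seed in (0, 1, 2, 3):
        ann = annotate(fg, s, seed=seed)
        matched = [i for i in (1, 2) if ann.matched_peak[i] is not None]
        assert len(matched) == 1  # seeded tie-break picks exactly one
        assert annotate(fg, s, seed=seed).matched_peak == ann.matched_peak


def test_parent_log_rank_propagation():
    fg = chain_fg(masses=(300.0, 180.0, 90.0))
    # A's peak has rank 2 -> logRank 2; B unmatched
    s = _spectrum([(500.0, 100.0), (_mz(180.0), 50.0), (499.0, 10.0)])
    ann = annotate(fg, s, seed=0)
    assert ann.log_rank_pa[1] == 0  # depth-1: parent is root
    assert ann.log_rank[1] == 2
    assert ann.log_rank_pa[2] == 2  # B conditions on A's logRank


def test_train_counts_toy_example():
    """OC cell at parent-logRank 0 observed with logRanks {1,1,7,7} and zero
    pseudocount gives P(1)=P(7)=0.5."""
    fg = single_frag_fg()
    hit = _spectrum([(_mz(100.0), 100.0), (500.0, 10.0)])
    miss = _spectrum([(400.0, 100.0), (500.0, 10.0)])
    m = train([(fg, hit), (fg, hit), (fg, miss), (fg, miss)], pseudocount=0.0)
    assert m.cond_prob("OC", 0, 1) == pytest.approx(0.5)
    assert m.cond_prob("OC", 0, 7) == pytest.approx(0.5)
    assert m.counts[_BOND_INDEX["OC"], 0].sum() == 4


def test_trained_rows_normalized(small_model):
    sums = small_model.cond.sum(axis=2)
    assert np.allclose(sums, 1.0, atol=1e-9)
    assert small_model.null.sum() == pytest.approx(1.0, abs=1e-9)
    assert (small_model.cond >= 0).all() and (small_model.null >= 0).all()


def test_train_requires_pairs():
    with pytest.raises(ValueError, match="empty training set"):
        train([])


def test_train_deterministic(sim_setup):
    from fragrank.fixtures import simulate_training_set

    config, cond, null, graphs = sim_setup
    pairs = simulate_training_set(graphs, cond, null, config, seed=5, n_spectra=40)
    a = train(pairs, seed=9)
    b = train(pairs, seed=9)
    assert np.array_equal(a.cond, b.cond) and np.array_equal(a.null, b.null)


def _uniform_model(null=None):
    nullrow = np.full(7, 1 / 7) if null is None else np.asarray(null)
    cond = np.tile(nullrow, (9, 8, 1))
    return ScoringModel(
        cond=cond, null=nullrow, counts=np.zeros((9, 8, 7)), pseudocount=1.0,
        rules_digest="test-rules",
    )


def test_cond_equal_null_scores_zero():
    fg = chain_fg()
    s = _spectrum([(_mz(180.0), 100.0), (500.0, 10.0)])
    assert score(fg, s, _uniform_model(), seed=0) == pytest.approx(0.0, abs=1e-12)


def test_single_fragment_score_is_log_ratio():
    fg = single_frag_fg(frag_mass=100.0, bond="OC")
    s = _spectrum([(_mz(100.0), 100.0), (500.0, 10.0)])
    m = _uniform_model(null=[0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.3])
    m.cond[_BOND_INDEX["OC"], 0, 0] = 0.4  # P(logRank 1 | OC, root) = 0.4
    assert score(fg, s, m, seed=0) == pytest.approx(math.log(2.0), abs=1e-12)


def test_three_fragment_score_matches_hand_sum():
    fg = _fg(
        [
            (0b1111, 400.0, 0, "root", []),
            (0b0111, 250.0, 1, "OC", [0]),
            (0b1000, 150.0, 1, "CC", [0]),
            (0b0011, 120.0, 2, "NC", [1]),
        ],
        [(0, 1, "OC"), (0, 2, "CC"), (1, 3, "NC")],
    )
    # peaks: fragment 1 -> rank 1, fragment 3 -> rank 2, fragment 2 absent
    s = _spectrum([(_mz(250.0), 100.0), (_mz(120.0), 50.0), (500.0, 10.0)])
    m = _uniform_model(null=[0.25, 0.15, 0.1, 0.1, 0.1, 0.1, 0.2])
    m.cond[_BOND_INDEX["OC"], 0, 0] = 0.5   # frag 1: l=1 | OC, pa=0
    m.cond[_BOND_INDEX["CC"], 0, 6] = 0.35  # frag 2: l=7 | CC, pa=0
    m.cond[_BOND_INDEX["NC"], 1, 1] = 0.3   # frag 3: l=2 | NC, pa=1
    expected = (
        math.log(0.5 / 0.25) + math.log(0.35 / 0.2) + math.log(0.3 / 0.15)
    )
    assert score(fg, s, m, seed=0) == pytest.approx(expected, abs=1e-12)


def test_score_additive_over_fragments():
    fg = chain_fg()
    s = _spectrum([(_mz(180.0), 100.0), (_mz(90.0), 50.0), (500.0, 10.0)])
    m = _uniform_model(null=[0.3, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1])
    m.cond[_BOND_INDEX["OC"], 0, 0] = 0.6
    m.cond[_BOND_INDEX["NC"], 1, 1] = 0.4
    ann = annotate(fg, s, FRAGMENT_TOLERANCE, seed=0)
    per_fragment = []
    for j in (1, 2):
        l = ann.log_rank[j]
        b = fg.fragments[j].bond_type
        per_fragment.append(
            math.log(m.cond_prob(b, ann.log_rank_pa[j], l) / m.null_prob(l))
        )
    assert score(fg, s, m, seed=0) == pytest.approx(sum(per_fragment), abs=1e-12)


def test_zero_null_probability_raises():
    fg = single_frag_fg()
    s = _spectrum([(_mz(100.0), 100.0), (500.0, 10.0)])
    m = _uniform_model(null=[0.0, 0.2, 0.2, 0.2, 0.2, 0.1, 0.1])
    with pytest.raises(ValueError, match="pseudocount"):
        score(fg, s, m, seed=0)


def test_model_io_roundtrip(tmp_path, small_model):
    path = tmp_path / "model.json"
    save_model(small_model, path)
    back = load_model(path, expected_rules_digest=small_model.rules_digest)
    assert np.allclose(back.cond, small_model.cond)
    assert np.allclose(back.null, small_model.null)
    with pytest.raises(ValueError, match="rule digest"):
        load_model(path, expected_rules_digest="something-else")
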