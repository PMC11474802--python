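"""Flanking windows, PFMs, motif search, structure depletion and ORA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isohyl.enrich import (
    AMINO_ACIDS,
    FlankWindow,
    StructureAnnotation,
    extract_flanks,
    motif_enrich,
    ora,
    position_frequency_matrix,
    read_gmt,
    structure_depletion,
    _hypergeom_directional,
)

RNG = np.random.default_rng(13)


def _random_window(w=6, center="K", fixed=None, rng=RNG):
    chars = list(rng.choice(list(AMINO_ACIDS), size=2 * w + 1))
    chars[w] = center
    for off, res in (fixed or {}).items():
        chars[w + off] = res
    return FlankWindow("".join(chars), "P", 10)


# ---------------------------------------------------------------- flanks


def test_flank_padding_at_n_terminus():
    flanks = extract_flanks([("P1", 2)], {"P1": "AKGGGGGGGG"}, w=6)
    assert flanks[0].window == "_____AKGGGGGG"
    assert flanks[0].center == "K"


def test_flank_padding_at_c_terminus():
    flanks = extract_flanks([("P1", 9)], {"P1": "GGGGGGGGK"}, w=6)
    assert flanks[0].window == "GGGGGGGGK______"[2:]  # 13 chars
    assert flanks[0].window.endswith("______")
    assert len(flanks[0].window) == 13


def test_flank_interior_site_exact():
    seq = "ACDEFGHIKLMNPQRSTVWY"
    flanks = extract_flanks([("P1", 9)], {"P1": seq}, w=3)
    assert flanks[0].window == seq[5:12]  # FGHIKLM
    assert flanks[0].center == "K"


def test_flank_wrong_center_raises():
    with pytest.raises(ValueError, match="expected K"):
        extract_flanks([("P1", 1)], {"P1": "AK"}, w=2)


def test_flank_out_of_range_raises():
    with pytest.raises(ValueError, match="outside"):
        extract_flanks([("P1", 99)], {"P1": "AK"}, w=2)


def test_flank_unknown_protein_raises():
    with pytest.raises(KeyError):
        extract_flanks([("NOPE", 1)], {"P1": "AK"}, w=2)


# ---------------------------------------------------------------- PFM


def test_pfm_columns_sum_to_window_count():
    wins = [_random_window() for _ in range(50)]
    pfm = position_frequency_matrix(wins)
    assert (pfm.sum(axis=0) == 50).all()
    assert list(pfm.columns) == list(range(-6, 7))


def test_pfm_center_column_is_all_k():
    wins = [_random_window() for _ in range(30)]
    pfm = position_frequency_matrix(wins)
    assert pfm.loc["K", 0] == 30
    assert pfm.drop(index="K")[0].sum() == 0


def test_pfm_records_padding():
    flanks = extract_flanks([("P1", 1)], {"P1": "KAAA"}, w=3)
    pfm = position_frequency_matrix(flanks)
    assert pfm.loc["_", -1] == 1 and pfm.loc["_", -3] == 1
    assert pfm.loc["A", 1] == 1


def test_pfm_planted_majority_residue():
    wins = [
        _random_window(fixed={-1: "P"} if i < 80 else None) for i in range(100)
    ]
    pfm = position_frequency_matrix(wins)
    assert pfm[-1].idxmax() == "P"
    assert pfm.loc["P", -1] >= 80


def test_pfm_empty_input_raises():
    with pytest.raises(ValueError):
        position_frequency_matrix([])


def test_pfm_mixed_width_raises():
    with pytest.raises(ValueError, match="mixed"):
        position_frequency_matrix(
            [_random_window(w=6), _random_window(w=3)]
        )


# ---------------------------------------------------------------- motifs


def test_motif_foreground_equals_background_finds_nothing():
    wins = [_random_window() for _ in range(200)]
    assert motif_enrich(wins, wins, p_threshold=1e-6) == []


def test_motif_planted_p_at_minus_one_recovered_first():
    """60% of foreground carries P at -1 vs ~5% of background: the first
    extracted motif is P.K."""
    rng = np.random.default_rng(21)
    bg = [
        _random_window(fixed={-1: "P"} if rng.random() < 0.05 else None, rng=rng)
        for _ in range(2000)
    ]
    fg = [
        _random_window(fixed={-1: "P"} if i < 120 else None, rng=rng)
        for i in range(200)
    ]
    motifs = motif_enrich(fg, fg + bg, p_threshold=1e-6, min_support=20)
    assert motifs, "expected at least one motif"
    first = motifs[0]
    assert (-1, "P") in first.pattern
    assert first.as_string(6)[5:7] == "PK"
    assert first.fold > 2
    assert first.n_foreground >= 100


def test_motif_min_support_blocks_small_signals():
    rng = np.random.default_rng(22)
    bg = [_random_window(rng=rng) for _ in range(500)]
    fg = [_random_window(fixed={-1: "P"}, rng=rng) for _ in range(10)]
    assert motif_enrich(fg, fg + bg, min_support=20) == []


def test_motif_foreground_larger_than_background_is_an_error():
    wins = [_random_window() for _ in range(5)]
    with pytest.raises(ValueError, match="foreground"):
        motif_enrich(wins, wins[:2])


def test_motif_empty_foreground_gives_no_motifs():
    assert motif_enrich([], [_random_window()]) == []


def test_motif_search_is_deterministic():
    rng = np.random.default_rng(23)
    bg = [_random_window(rng=rng) for _ in range(800)]
    fg = [
        _random_window(fixed={-1: "P", 2: "G"}, rng=rng) for _ in range(60)
    ] + bg[:40]
    a = motif_enrich(fg, fg + bg)
    b = motif_enrich(list(fg), list(fg) + list(bg))
    assert a == b


# ------------------------------------------------------- structure tests


def _sites_and_bg(n_bg=20, n_fg=5, helix_bg=10, helix_fg=0):
    """Background lysines on one protein; the first helix_bg of them sit in
    a helix; foreground takes helix_fg helix sites then fills from loops."""
    bg = [("P1", 10 * (i + 1)) for i in range(n_bg)]
    ann = StructureAnnotation(
        tuple(("P1", 10 * (i + 1), 10 * (i + 1), "HELIX") for i in range(helix_bg))
    )
    fg = bg[:helix_fg] + bg[helix_bg : helix_bg + (n_fg - helix_fg)]
    return fg, bg, ann


def test_structure_toy_example_exact_p():
    """5 of 20 background lysines modified, 10 background in helix, 0
    modified in helix: depletion p = C(10,5)/C(20,5) = 252/15504."""
    fg, bg, ann = _sites_and_bg(n_bg=20, n_fg=5, helix_bg=10, helix_fg=0)
    res = structure_depletion(fg, bg, ann).set_index("class")
    row = res.loc["HELIX"]
    assert row.direction == "depleted"
    assert row.p == pytest.approx(252 / 15504, rel=1e-12)
    assert row.site_fraction == 0.0 and row.background_fraction == 0.5


def test_structure_sites_equal_background_gives_p_one():
    fg, bg, ann = _sites_and_bg(n_bg=12, n_fg=12, helix_bg=6, helix_fg=6)
    res = structure_depletion(bg, bg, ann).set_index("class")
    assert res.loc["HELIX"].p == pytest.approx(1.0)
    assert res.loc["HELIX"].site_fraction == res.loc["HELIX"].background_fraction


def test_structure_planted_threefold_depletion_is_significant():
    """N=2000 background lysines, half in helices; 200 modified sites with
    helix fraction ~1/6 instead of 1/2 → p < 1e-4."""
    fg, bg, ann = _sites_and_bg(n_bg=2000, n_fg=200, helix_bg=1000, helix_fg=33)
    res = structure_depletion(fg, bg, ann).set_index("class")
    assert res.loc["HELIX"].direction == "depleted"
    assert res.loc["HELIX"].p < 1e-4


def test_structure_site_not_in_background_is_an_error():
    fg, bg, ann = _sites_and_bg()
    with pytest.raises(ValueError, match="not in background"):
        structure_depletion([("P9", 1)], bg, ann)


def test_structure_any_row_counts_all_classes():
    bg = [("P1", i) for i in (5, 15, 25, 35)]
    ann = StructureAnnotation(
        (("P1", 1, 9, "HELIX"), ("P1", 11, 19, "STRAND"), ("P1", 21, 29, "TURN"))
    )
    res = structure_depletion(bg[:2], bg, ann).set_index("class")
    assert res.loc["ANY"].K == 3 and res.loc["ANY"].N == 4


def test_structure_overlapping_intervals_rejected():
    with pytest.raises(ValueError, match="overlap"):
        StructureAnnotation((("P1", 1, 10, "HELIX"), ("P1", 5, 12, "TURN")))


def test_directional_hypergeom_matches_brute_force_enumeration():
    """For every (N,K,n,k) with N<=12 the one-sided p equals the explicit
    combinatorial sum."""
    for N in range(1, 13):
        for K in range(N + 1):
            for n in range(N + 1):
                lo, hi = max(0, n + K - N), min(n, K)
                for k in range(lo, hi + 1):
                    p, direction = _hypergeom_directional(k, N, K, n)
                    denom = math.comb(N, n)
                    if direction == "depleted":
                        ks = range(lo, k + 1)
                    else:
                        ks = range(k, hi + 1)
                    brute = sum(
                        math.comb(K, i) * math.comb(N - K, n - i) for i in ks
                    ) / denom
                    assert p == pytest.approx(brute, rel=1e-9), (N, K, n, k)


# ---------------------------------------------------------------- ORA


def test_ora_matches_brute_force_hypergeometric():
    bg = [f"g{i}" for i in range(30)]
    fg = bg[:8]
    sets = {"T": set(bg[4:16])}
    (res,) = ora(fg, bg, sets)
    # k=4 of n=8 in a K=12 / N=30 set
    brute = sum(
        math.comb(12, i) * math.comb(18, 8 - i) for i in range(4, 9)
    ) / math.comb(30, 8)
    assert (res.k, res.n, res.K, res.N) == (4, 8, 12, 30)
    assert res.p == pytest.approx(brute, rel=1e-9)
    assert res.q == pytest.approx(res.p)


def test_ora_disjoint_set_is_not_enriched():
    bg = [f"g{i}" for i in range(40)]
    res = ora(bg[:10], bg, {"T": set(bg[20:30])})
    assert res[0].k == 0
    assert res[0].p == pytest.approx(1.0) or res[0].p > 0.5


def test_ora_ids_outside_background_are_ignored():
    bg = ["a", "b", "c", "d"]
    (res,) = ora(["a", "zzz"], bg, {"T": {"a", "yyy"}})
    assert res.n == 1 and res.K == 1 and res.k == 1


def test_ora_q_values_bh_consistent():
    rng = np.random.default_rng(30)
    bg = [f"g{i}" for i in range(100)]
    fg = list(rng.choice(bg, size=20, replace=False))
    sets = {
        f"T{j}": set(rng.choice(bg, size=15, replace=False)) for j in range(10)
    }
    res = ora(fg, bg, sets)
    ps = [r.p for r in res]
    from statsmodels.stats.multitest import multipletests

    qs = multipletests(ps, method="fdr_bh")[1]
    # results are sorted by q; compare after aligning on p
    assert sorted(round(r.q, 12) for r in res) == sorted(round(q, 12) for q in qs)
    assert [r.q for r in res] == sorted(r.q for r in res)


def test_ora_empty_background_is_an_error():
    with pytest.raises(ValueError, match="background"):
        ora(["a"], [], {"T": {"a"}})


def test_read_gmt_roundtrip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("helix\tdesc\tA\tB\tC\n\nturn\t\tB\tD\n")
    sets = read_gmt(path)
    assert sets == {"helix": {"A", "B", "C"}, "turn": {"B", "D"}}
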