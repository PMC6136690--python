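import itertools

import pytest

from histack.align import GAP, HistoneSequence, align_to_reference
from histack.assessment import (
    Verdict,
    assess,
    classify_overall,
    complementarity,
    enumerate_stacking_pairs_view,
    score_dimer_interface_view,
    score_stacking_interface_view,
)
from histack.panel import load_panel


@pytest.mark.parametrize(
    "res_a, res_b, backbone, expected",
    [
        ("K", "E", False, "salt_bridge"),
        ("E", "K", False, "salt_bridge"),
        ("H", "D", False, "salt_bridge"),
        ("Q", "Q", False, "sidechain_hbond"),
        ("N", "D", False, "sidechain_hbond"),
        ("T", "K", False, "sidechain_hbond"),
        ("Y", "Q", False, "sidechain_hbond"),
        ("A", "L", False, None),
        ("A", "L", True, None),  # backbone route still needs a donor
        ("R", "V", True, "backbone_mediated"),
        ("R", "V", False, None),
        ("K", "A", True, "backbone_mediated"),
        ("K", "R", False, None),  # two donors, no acceptor
        ("D", "E", False, None),  # two acceptors, no donor
        ("W", "E", False, "sidechain_hbond"),  # Trp is donor-only
        ("W", "W", False, None),  # ...and never an acceptor
        (GAP, "E", False, None),
        ("K", GAP, True, None),
        ("X", "E", False, None),
    ],
)
def test_complementarity_rules(res_a, res_b, backbone, expected):
    assert complementarity(res_a, res_b, backbone) == expected


def test_complementarity_symmetric():
    for a, b in itertools.product("KRHDENQSTYWAVLIG", repeat=2):
        assert complementarity(a, b) == complementarity(b, a)


class TestDimerInterface:
    def test_canonical_interface_likely(self):
        score = score_dimer_interface_view({46: "L", 49: "H", 59: "D", 62: "L"})
        assert score.value is Verdict.LIKELY and score.defects == ()

    def test_weakened_hbond_uncertain(self):
        # H49N keeps H-bond chemistry but loses the salt-bridge-grade contact
        score = score_dimer_interface_view({46: "L", 49: "N", 59: "D", 62: "L"})
        assert score.value is Verdict.UNCERTAIN
        assert len(score.defects) == 1

    def test_negatively_charged_surface_unlikely(self):
        # H49D plus E62: broken H-bond, non-hydrophobic 62, like-charge surface
        score = score_dimer_interface_view({46: "L", 49: "D", 59: "D", 62: "E"})
        assert score.value is Verdict.UNLIKELY
        assert len(score.defects) >= 2

    def test_d59s_plus_missing_alpha3_unlikely(self):
        # substitution of the 59 partner and a truncated 62 are two defects
        score = score_dimer_interface_view({46: "L", 49: "H", 59: "S"})
        assert score.value is Verdict.UNLIKELY

    def test_basic_like_charge_counts(self):
        score = score_dimer_interface_view({46: "L", 49: "K", 59: "E", 62: "R"})
        # 49-59 K-E is salt-bridge-grade; 62=R non-hydrophobic + basic/basic
        assert score.value is Verdict.UNLIKELY


class TestStackingInterface:
    @pytest.mark.parametrize("res, verdict", [
        ("G", Verdict.LIKELY), ("A", Verdict.LIKELY), ("S", Verdict.LIKELY),
        ("T", Verdict.UNCERTAIN), ("N", Verdict.UNCERTAIN), ("P", Verdict.UNCERTAIN),
        ("W", Verdict.UNLIKELY), ("K", Verdict.UNLIKELY), ("E", Verdict.UNLIKELY),
    ])
    def test_volume_classes(self, res, verdict):
        assert score_stacking_interface_view({16: res}).value is verdict

    def test_truncated_loop_unlikely(self):
        assert score_stacking_interface_view({}).value is Verdict.UNLIKELY

    def test_neighbours_reported_but_not_classifying(self):
        score = score_stacking_interface_view({15: "W", 16: "G", 17: "W"})
        assert score.value is Verdict.LIKELY
        assert any("15" in n for n in score.notes)


class TestEnumerate:
    def test_printed_hmfb_map_gives_canonical_three(self, catalog, printed_identity_map):
        pairs = enumerate_stacking_pairs_view(printed_identity_map, catalog)
        assert {(p.pos_a, p.pos_b) for p in pairs} == {(30, 61), (34, 65), (14, 48)}
        assert {p.kind for p in pairs} == {"salt_bridge"}

    def test_poly_alanine_gives_nothing(self, catalog):
        view = {pos: "A" for pos in catalog.positions()}
        assert enumerate_stacking_pairs_view(view, catalog) == ()

    def test_residue_can_join_multiple_pairs(self, catalog):
        # one lysine at 14 pairing both 48 and 18, as in dual-contact rows
        view = {14: "K", 18: "E", 48: "E"}
        pairs = enumerate_stacking_pairs_view(view, catalog)
        got = {(p.pos_a, p.pos_b) for p in pairs}
        assert {(14, 18), (14, 48)} <= got

    def test_deduplicated_on_position_pair(self, catalog):
        view = {30: "K", 61: "E"}
        pairs = enumerate_stacking_pairs_view(view, catalog)
        assert len(pairs) == len({(p.pos_a, p.pos_b) for p in pairs})

    def test_catalog_order_preserved(self, catalog):
        view = {30: "K", 61: "E", 14: "D", 48: "R", 34: "E", 65: "R"}
        pairs = enumerate_stacking_pairs_view(view, catalog)
        order = [e.positions for e in catalog]
        idx = [order.index((p.pos_a, p.pos_b)) for p in pairs]
        assert idx == sorted(idx)

    def test_invariant_to_off_catalog_positions(self, catalog, printed_identity_map):
        noisy = dict(printed_identity_map)
        noisy.update({3: "W", 22: "K", 50: "E"})  # not catalog positions
        assert enumerate_stacking_pairs_view(noisy, catalog) == enumerate_stacking_pairs_view(
            printed_identity_map, catalog
        )

    def test_backbone_token_notation(self, catalog):
        view = {14: "V", 48: "R"}
        (pair,) = [p for p in enumerate_stacking_pairs_view(view, catalog) if p.pos_b == 48]
        assert pair.kind == "backbone_mediated"
        assert pair.token() == "V14(bb)-R48"


class TestClassifyOverall:
    @pytest.mark.parametrize(
        "dimer, stacking, count, expected",
        [
            (Verdict.LIKELY, Verdict.LIKELY, 3, Verdict.LIKELY),
            (Verdict.UNLIKELY, Verdict.LIKELY, 2, Verdict.UNLIKELY),
            (Verdict.LIKELY, Verdict.UNLIKELY, 4, Verdict.UNCERTAIN),
            (Verdict.LIKELY, Verdict.UNLIKELY, 3, Verdict.UNCERTAIN),
            (Verdict.UNCERTAIN, Verdict.LIKELY, 3, Verdict.UNCERTAIN),
            (Verdict.UNCERTAIN, Verdict.UNCERTAIN, 7, Verdict.UNCERTAIN),
            (Verdict.UNCERTAIN, Verdict.UNLIKELY, 2, Verdict.UNLIKELY),
        ],
    )
    def test_rule(self, dimer, stacking, count, expected):
        assert classify_overall(dimer, stacking, count) is expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            classify_overall(Verdict.LIKELY, Verdict.LIKELY, -1)

    def test_monotone_over_full_grid(self):
        """Upgrading any input never downgrades the overall verdict."""
        verdicts = list(Verdict)
        counts = range(0, 9)
        for d, s, c in itertools.product(verdicts, verdicts, counts):
            base = classify_overall(d, s, c)
            for d2 in verdicts:
                if d2.value >= d.value:
                    assert classify_overall(d2, s, c).value >= base.value
            for s2 in verdicts:
                if s2.value >= s.value:
                    assert classify_overall(d, s2, c).value >= base.value
            if c + 1 in counts:
                assert classify_overall(d, s, c + 1).value >= base.value

    def test_reproduces_published_panel(self):
        rows = load_panel()
        assert len(rows) == 33
        for row in rows:
            assert row.reclassify() is row.overall, row.histone


class TestAssess:
    def test_reference_self_assessment(self, reference, catalog, hmfb_query):
        rec = assess(hmfb_query, reference, catalog)
        assert rec.overall is Verdict.LIKELY
        assert rec.dimer_interface.value is Verdict.LIKELY
        assert rec.stacking_interface.value is Verdict.LIKELY
        assert {(30, 61), (34, 65), (14, 48)} <= {
            (p.pos_a, p.pos_b) for p in rec.stacking_pairs
        }
        assert rec.termini.flags == frozenset()

    def test_c_tail_leaves_interface_scores_unchanged(self, reference, catalog):
        tailed = HistoneSequence(id="t", residues=reference.sequence + "A" * 28)
        base = assess(HistoneSequence(id="b", residues=reference.sequence), reference, catalog)
        rec = assess(tailed, reference, catalog)
        assert rec.termini.c_tail_length == 28
        assert rec.dimer_interface.value is base.dimer_interface.value
        assert rec.stacking_interface.value is base.stacking_interface.value
        assert rec.stacking_count == base.stacking_count

    def test_broken_dimer_interface_drives_overall_down(self, reference, catalog):
        seq = list(reference.sequence)
        seq[48] = "D"  # H49D
        seq[61] = "E"  # L62E
        rec = assess(HistoneSequence(id="neg", residues="".join(seq)), reference, catalog)
        assert rec.dimer_interface.value is Verdict.UNLIKELY
        assert rec.overall.value <= Verdict.UNCERTAIN.value

    def test_record_consistency(self, reference, catalog, hmfb_query):
        rec = assess(hmfb_query, reference, catalog)
        assert rec.stacking_count == len(rec.stacking_pairs)
        assert rec.overall is classify_overall(
            rec.dimer_interface.value, rec.stacking_interface.value, rec.stacking_count
        )


def test_published_pairs_are_complementarity_positive(catalog):
    """Every stacking pair printed in the curated panel passes the rules."""
    backbone_ok = {e.positions for e in catalog if e.backbone_allowed}
    for row in load_panel():
        for pair in row.pairs:
            kind = complementarity(
                pair.res_a, pair.res_b, backbone_allowed=pair.positions in backbone_ok
            )
            assert kind is not None, f"{row.histone}: {pair}"
            assert pair.positions in catalog.position_pairs(), f"{row.histone}: {pair}"
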