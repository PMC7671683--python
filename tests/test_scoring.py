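"""JSD conservation, BLOSUM divergence, and top-percentile flagging."""

import math

import numpy as np
import pytest

from cladesubs.detect import SubstitutionCall, detect_foreground_substitutions
from cladesubs.msa import henikoff_weights
from cladesubs.records import STANDARD_RESIDUES
from cladesubs.scoring import (
    ColumnDistribution,
    ScoringConfig,
    background_distribution,
    column_distribution,
    jsd_conservation,
    mean_outgroup_blosum,
    rank_and_flag,
    score_substitutions,
)
from tests.conftest import make_msa

CONFIG = ScoringConfig()


def brute_force_jsd(p, q, lam=0.5, gap_fraction=0.0):
    """Independent direct-summation JSD in bits, with the linear gap penalty.

    Pure-python loops over plain floats; shares no code with the library path.
    """
    r = [lam * pi + (1 - lam) * qi for pi, qi in zip(p, q)]
    kl_pr = sum(pi * math.log2(pi / ri) for pi, ri in zip(p, r) if pi > 0)
    kl_qr = sum(qi * math.log2(qi / ri) for qi, ri in zip(q, r) if qi > 0)
    return (1 - gap_fraction) * (lam * kl_pr + (1 - lam) * kl_qr)


def dist(p_map: dict[str, float], gap: float = 0.0) -> ColumnDistribution:
    full = {a: 0.0 for a in STANDARD_RESIDUES}
    full.update(p_map)
    return ColumnDistribution(full, gap)


def point_mass(residue: str, gap: float = 0.0) -> ColumnDistribution:
    return dist({residue: 1.0}, gap)


UNIFORM = {a: 0.05 for a in STANDARD_RESIDUES}


class TestColumnDistribution:
    W = {"x": 0.25, "y": 0.25, "z": 0.5}

    def test_uniform_residue_gives_point_mass(self):
        cfg = ScoringConfig(pseudocount=0.0)
        d = column_distribution({"x": "A", "y": "A", "z": "A"}, self.W, cfg,
                                ["x", "y", "z"])
        assert d.p["A"] == pytest.approx(1.0)
        assert d.gap_fraction == 0.0

    def test_weighted_counts(self):
        cfg = ScoringConfig(pseudocount=0.0)
        d = column_distribution({"x": "A", "y": "A", "z": "C"}, self.W, cfg,
                                ["x", "y", "z"])
        assert d.p["A"] == pytest.approx(0.5)
        assert d.p["C"] == pytest.approx(0.5)

    def test_weights_renormalized_over_contributing_set(self):
        cfg = ScoringConfig(pseudocount=0.0)
        d = column_distribution({"x": "A", "y": "C", "z": "C"}, self.W, cfg,
                                ["y", "z"])
        assert d.p["C"] == pytest.approx(1.0)
        assert d.p["A"] == 0.0

    def test_all_gapped_contributors_is_error(self):
        with pytest.raises(ValueError):
            column_distribution({"x": "-", "y": "-", "z": "A"}, self.W, CONFIG,
                                ["x", "y"])

    def test_distribution_sums_to_one(self):
        d = column_distribution({"x": "A", "y": "-", "z": "W"}, self.W, CONFIG,
                                ["x", "y", "z"])
        assert sum(d.p.values()) == pytest.approx(1.0, abs=1e-9)
        assert d.gap_fraction == pytest.approx(0.25)


class TestJsdConservation:
    def test_zero_when_column_equals_background(self):
        q = background_distribution("blosum62")
        assert jsd_conservation(dist(q), CONFIG) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_vs_uniform_closed_form(self):
        expected = brute_force_jsd(
            [1.0] + [0.0] * 19, [0.05] * 20
        )
        got = jsd_conservation(point_mass("A"), CONFIG, background=UNIFORM)
        assert got == pytest.approx(expected, abs=1e-12)
        # the closed form: r = 0.525 on the residue, 0.025 elsewhere
        closed = 0.5 * math.log2(1 / 0.525) + 0.5 * (
            0.05 * math.log2(0.05 / 0.525) + 19 * 0.05 * math.log2(2)
        )
        assert got == pytest.approx(closed, abs=1e-12)

    def test_gap_penalty_is_linear(self):
        free = jsd_conservation(point_mass("A"), CONFIG, background=UNIFORM)
        half = jsd_conservation(point_mass("A", gap=0.5), CONFIG, background=UNIFORM)
        assert half == pytest.approx(free / 2)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.dirichlet(np.full(20, 0.3))
            d = dist(dict(zip(STANDARD_RESIDUES, p)), gap=float(rng.random()))
            s = jsd_conservation(d, CONFIG)
            assert 0.0 <= s <= 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            p = rng.dirichlet(np.full(20, float(rng.uniform(0.1, 5.0))))
            q = rng.dirichlet(np.full(20, float(rng.uniform(0.1, 5.0))))
            gap = float(rng.random())
            d = dist(dict(zip(STANDARD_RESIDUES, p)), gap=gap)
            bg = dict(zip(STANDARD_RESIDUES, q))
            got = jsd_conservation(d, CONFIG, background=bg)
            want = brute_force_jsd(list(p), list(q), gap_fraction=gap)
            worst = max(worst, abs(got - want))
        assert worst < 1e-10

    def test_maximized_by_point_mass_on_rarest_background_residue(self):
        q = background_distribution("blosum62")
        rarest = min(q, key=q.get)  # tryptophan in the BLOSUM62 background
        scores = {
            a: jsd_conservation(point_mass(a), CONFIG) for a in STANDARD_RESIDUES
        }
        assert max(scores, key=scores.get) == rarest
        rng = np.random.default_rng(3)
        best = scores[rarest]
        for _ in range(200):
            p = rng.dirichlet(np.full(20, 0.5))
            assert jsd_conservation(
                dist(dict(zip(STANDARD_RESIDUES, p))), CONFIG
            ) <= best + 1e-12

    def test_sharper_distribution_never_scores_lower(self):
        # mixing a point mass toward background is monotone in the mix weight
        q = background_distribution("blosum62")
        prev = -1.0
        for t in np.linspace(0.0, 1.0, 11):
            p = {a: (1 - t) * q[a] + t * (1.0 if a == "P" else 0.0)
                 for a in STANDARD_RESIDUES}
            s = jsd_conservation(dist(p), CONFIG)
            assert s >= prev - 1e-12
            prev = s

    def test_invalid_distribution_rejected(self):
        bad = {a: 0.0 for a in STANDARD_RESIDUES}
        bad["A"] = 0.5  # sums to 0.5
        with pytest.raises(ValueError):
            jsd_conservation(ColumnDistribution(bad, 0.0), CONFIG)


def call(fg="L", og="P" * 9, gene="G1", column=0):
    return SubstitutionCall(gene, column, fg, tuple(og), {"ags": 1, "itri": 1})


class TestMeanOutgroupBlosum:
    @pytest.mark.parametrize(
        "fg,og,expected",
        [
            ("L", "P" * 9, -3.0),
            ("A", "A" * 9, 4.0),
            ("L", "P" * 8 + "M", (8 * -3 + 2) / 9),
        ],
    )
    def test_mean_matrix_scores(self, fg, og, expected):
        assert mean_outgroup_blosum(call(fg, og), CONFIG) == pytest.approx(expected)

    def test_invariant_to_outgroup_order(self):
        a = mean_outgroup_blosum(call("L", "PPMWC"), CONFIG)
        b = mean_outgroup_blosum(call("L", "CWMPP"), CONFIG)
        assert a == b

    def test_foreground_residue_absent_from_outgroup_by_construction(self):
        c = call("L", "P" * 9)
        assert c.foreground_residue not in c.outgroup_residues

    def test_empty_outgroup_is_error(self):
        with pytest.raises(ValueError):
            mean_outgroup_blosum(call("L", ""), CONFIG)


class TestScoreSubstitutions:
    def test_conserved_column_scores(self, panel, panel_species):
        msa = make_msa(["LL" + "P" * 9], panel_species)
        calls = detect_foreground_substitutions(msa, panel)
        weights = henikoff_weights(msa)
        [scored] = score_substitutions(msa, calls, weights, CONFIG,
                                       species_config=panel)
        # outgroup-only conservation: the column is a pure-P point mass
        expected = jsd_conservation(
            column_distribution(
                msa.column(0), weights, CONFIG, list(panel.outgroup_species)
            ),
            CONFIG,
        )
        assert scored.jsd == pytest.approx(expected)
        assert scored.mean_blosum == pytest.approx(-3.0)

    def test_variable_outgroup_scores_below_point_mass(self, panel, panel_species):
        conserved = make_msa(["LL" + "P" * 9], panel_species)
        variable = make_msa(["LL" + "PGAWCMKRH"], panel_species)
        cfg = panel
        s_cons = score_substitutions(
            conserved, detect_foreground_substitutions(conserved, cfg),
            henikoff_weights(conserved), CONFIG, species_config=cfg)[0]
        s_var = score_substitutions(
            variable, detect_foreground_substitutions(variable, cfg),
            henikoff_weights(variable), CONFIG, species_config=cfg)[0]
        assert s_var.jsd < s_cons.jsd

    def test_empty_call_list_gives_empty_output(self, panel, panel_species):
        msa = make_msa(["AA" + "A" * 9], panel_species)
        assert score_substitutions(msa, [], None, CONFIG, species_config=panel) == []


class TestRankAndFlag:
    def scored(self, n, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            from cladesubs.scoring import ScoredSubstitution

            out.append(
                ScoredSubstitution(
                    call=call(gene=f"G{i:04d}", column=i),
                    jsd=float(rng.random()),
                    mean_blosum=float(rng.integers(-4, 5)),
                )
            )
        return out

    @pytest.mark.parametrize("n,expected_flags", [(200, 2), (50, 1), (1, 1)])
    def test_flag_count_is_ceiling_of_top_fraction(self, n, expected_flags):
        ranked = rank_and_flag(self.scored(n), ScoringConfig(top_fraction=0.01))
        assert sum(s.flagged for s in ranked) == expected_flags

    def test_flagged_set_invariant_to_input_order(self):
        items = self.scored(100, seed=5)
        a = rank_and_flag(items, CONFIG)
        b = rank_and_flag(list(reversed(items)), CONFIG)
        flags_a = {(s.call.gene_symbol, s.call.column_index) for s in a if s.flagged}
        flags_b = {(s.call.gene_symbol, s.call.column_index) for s in b if s.flagged}
        assert flags_a == flags_b

    def test_all_equal_composites_resolved_by_tie_break_chain(self):
        from cladesubs.scoring import ScoredSubstitution

        items = [
            ScoredSubstitution(call=call(gene=g, column=0), jsd=0.5, mean_blosum=-3.0)
            for g in ("GB", "GA", "GC")
        ]
        ranked = rank_and_flag(items, ScoringConfig(top_fraction=0.01))
        flagged = [s.call.gene_symbol for s in ranked if s.flagged]
        assert flagged == ["GA"]  # gene symbol breaks the tie, stably

    def test_composite_definition(self):
        ranked = rank_and_flag(self.scored(40, seed=9), CONFIG)
        for s in ranked:
            assert s.composite == pytest.approx(
                (s.jsd_percentile + (1 - s.blosum_percentile)) / 2
            )

    def test_quadrant_mode_uses_both_thresholds(self):
        items = self.scored(100, seed=1)
        ranked = rank_and_flag(items, ScoringConfig(top_fraction=0.1,
                                                    flag_mode="quadrant"))
        jsds = sorted(s.jsd for s in ranked)
        blos = sorted(s.mean_blosum for s in ranked)
        j_cut = float(np.quantile(jsds, 0.9))
        b_cut = float(np.quantile(blos, 0.1))
        for s in ranked:
            assert s.flagged == (s.jsd >= j_cut and s.mean_blosum <= b_cut)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            rank_and_flag([], CONFIG)
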