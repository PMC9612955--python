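"""Repeated-measures ANOVA, planned contrasts, within-subject error bars."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hypoalgesia.rm_anova import (
    planned_contrasts,
    rm_anova_2x2,
    within_subject_se,
)


def random_cells(rng, n=12, scale=1.0):
    cols = pd.MultiIndex.from_product([["LR", "2back"], [0, 1]], names=["task", "reward"])
    return pd.DataFrame(rng.normal(50, 10 * scale, (n, 4)), columns=cols,
                        index=pd.RangeIndex(1, n + 1, name="participant_id"))


def paired_t_oracle(cells):
    """Each 2x2 within-subject F is the square of a paired t statistic."""
    c = cells.to_numpy()
    lvl0 = sorted({k[0] for k in cells.columns})
    # marginal means by factor level
    f1 = {a: cells[a].mean(axis=1).to_numpy() for a in lvl0}
    d1 = f1[lvl0[1]] - f1[lvl0[0]]
    lvl1 = sorted({k[1] for k in cells.columns})
    f2 = {b: cells.xs(b, axis=1, level=1).mean(axis=1).to_numpy() for b in lvl1}
    d2 = f2[lvl1[1]] - f2[lvl1[0]]
    dd = (
        cells[(lvl0[1], lvl1[1])] - cells[(lvl0[1], lvl1[0])]
        - cells[(lvl0[0], lvl1[1])] + cells[(lvl0[0], lvl1[0])]
    ).to_numpy()
    out = {}
    for name, d in [("f1", d1), ("f2", d2), ("inter", dd)]:
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        out[name] = t * t
    return out


class TestRmAnova:
    def test_f_equals_squared_paired_t(self, rng):
        for _ in range(10):
            cells = random_cells(rng)
            res = {r.effect: r for r in rm_anova_2x2(cells)}
            oracle = paired_t_oracle(cells)
            assert res["task"].F == pytest.approx(oracle["f1"], abs=1e-8)
            assert res["reward"].F == pytest.approx(oracle["f2"], abs=1e-8)
            assert res["task:reward"].F == pytest.approx(oracle["inter"], abs=1e-8)

    def test_error_df_is_n_minus_one(self, rng):
        cells = random_cells(rng, n=57)
        for r in rm_anova_2x2(cells):
            assert r.df_num == 1 and r.df_den == 56

    def test_partial_eta_sq_matches_f_identity(self, rng):
        cells = random_cells(rng)
        for r in rm_anova_2x2(cells):
            assert r.partial_eta_sq == pytest.approx(r.F / (r.F + r.df_den))
            assert 0.0 <= r.partial_eta_sq <= 1.0

    def test_additive_offsets_change_nothing(self, rng):
        cells = random_cells(rng)
        offs = cells.add(rng.normal(0, 30, len(cells)), axis=0)
        for r1, r2 in zip(rm_anova_2x2(cells), rm_anova_2x2(offs)):
            assert r2.F == pytest.approx(r1.F, rel=1e-9)
        for c1, c2 in zip(planned_contrasts(cells), planned_contrasts(offs)):
            assert c2.t == pytest.approx(c1.t, rel=1e-9)

    def test_identical_cells_reported_as_zero(self):
        cols = pd.MultiIndex.from_product([["LR", "2back"], [0, 1]], names=["task", "reward"])
        cells = pd.DataFrame(np.full((8, 4), 5.0), columns=cols)
        for r in rm_anova_2x2(cells):
            assert r.F == 0.0 and r.p == 1.0 and "degenerate" in r.note

    def test_additive_main_effects_only_interaction_null(self, rng):
        n = 200
        cols = pd.MultiIndex.from_product([["LR", "2back"], [0, 1]], names=["task", "reward"])
        base = rng.normal(50, 5, n)
        cells = pd.DataFrame(
            {
                ("LR", 0): base,
                ("LR", 1): base + 4,
                ("2back", 0): base + 7,
                ("2back", 1): base + 11,  # exactly additive
            }
        )[cols.tolist()]
        cells.columns = cols
        cells += rng.normal(0, 0.5, cells.shape)
        res = {r.effect: r for r in rm_anova_2x2(cells)}
        assert res["task"].F > 100 and res["reward"].F > 100
        assert res["task:reward"].p > 0.01


class TestContrasts:
    def test_family_of_four_simple_effects(self, rng):
        res = planned_contrasts(random_cells(rng))
        assert len(res) == 4
        for c in res:
            assert c.p_holm >= c.p_raw - 1e-15

    def test_holm_matches_stepdown_enumeration(self, rng):
        res = planned_contrasts(random_cells(rng))
        praw = np.array([c.p_raw for c in res])
        order = np.argsort(praw)
        m = len(praw)
        adj = np.empty(m)
        running = 0.0
        for k, idx in enumerate(order):
            running = max(running, min(1.0, (m - k) * praw[idx]))
            adj[idx] = running
        assert np.allclose([c.p_holm for c in res], adj, atol=1e-15)

    def test_holm_is_monotone_in_raw_p(self, rng):
        # step-down adjustment preserves the ordering of the raw p-values
        res = planned_contrasts(random_cells(rng))
        by_raw = sorted(res, key=lambda c: c.p_raw)
        adj = [c.p_holm for c in by_raw]
        assert adj == sorted(adj)
        assert all(p <= 1.0 for p in adj)

    def test_identical_conditions_null_contrast(self):
        cols = pd.MultiIndex.from_product([["LR", "2back"], [0, 1]], names=["task", "reward"])
        cells = pd.DataFrame(np.tile(np.arange(6.0)[:, None], (1, 4)), columns=cols)
        for c in planned_contrasts(cells):
            assert c.t == 0.0 and c.p_holm == 1.0

    def test_holm_rejects_at_least_as_many_as_bonferroni(self, rng):
        for _ in range(20):
            res = planned_contrasts(random_cells(rng))
            praw = np.array([c.p_raw for c in res])
            alpha = 0.05
            bonf = (praw * len(praw) <= alpha).sum()
            holm = (np.array([c.p_holm for c in res]) <= alpha).sum()
            assert holm >= bonf

    def test_empty_family_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            planned_contrasts(random_cells(rng), family=[])


class TestWithinSubjectSE:
    def test_pure_offsets_give_zero_se(self, rng):
        base = np.array([10.0, 12.0, 14.0, 13.0])
        cols = pd.MultiIndex.from_product([["LR", "2back"], [0, 1]], names=["task", "reward"])
        cells = pd.DataFrame(
            np.tile(base, (9, 1)) + rng.normal(0, 5, 9)[:, None], columns=cols
        )
        se = within_subject_se(cells)
        assert np.allclose(se.to_numpy(), 0.0, atol=1e-12)

    def test_formula_on_numeric_fixture(self, rng):
        cells = random_cells(rng, n=10)
        centered = cells.sub(cells.mean(axis=1), axis=0) + cells.to_numpy().mean()
        expected = centered.std(ddof=1) * np.sqrt(4 / 3) / np.sqrt(10)
        assert np.allclose(within_subject_se(cells).to_numpy(), expected.to_numpy())

    def test_single_participant_rejected(self):
        cols = pd.MultiIndex.from_product([["LR", "2back"], [0, 1]], names=["task", "reward"])
        cells = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], columns=cols)
        with pytest.raises(ValueError):
            within_subject_se(cells)
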