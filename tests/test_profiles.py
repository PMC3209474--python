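"""Profile matrices, trough finding, Welch and Mann-Whitney tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import cyclenuc as cn
from cyclenuc.errors import ProfileError
from cyclenuc.profiles import ProfileMatrix


def welch_oracle(a, b):
    """Closed-form Welch t and Welch-Satterthwaite two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / n + vb / m
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / n) ** 2 / (n - 1) + (vb / m) ** 2 / (m - 1))
    return t, 2 * stats.t.sf(abs(t), df)


def mwu_enumeration_oracle(x, y):
    """Two-sided exact p over all C(n+m, n) group labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    center = n * m / 2
    target = abs(u_obs - center) - 1e-12
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        u = sum(ranks[i] for i in idx) - n * (n + 1) / 2
        count += abs(u - center) >= target
        total += 1
    return count / total


def _matrix(values, d_g=None, is_cyclic=None, flank=None):
    values = np.asarray(values, float)
    n, w = values.shape
    flank = (w - 1) // 2 if flank is None else flank
    meta = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(n)],
            "d_g": d_g if d_g is not None else np.zeros(n),
            "is_cyclic": is_cyclic if is_cyclic is not None else [True] * n,
            "offset": [-100] * n,
        }
    )
    return ProfileMatrix(values, np.arange(-flank, flank + 1), meta)


class TestBuild:
    def test_shape_and_constant_track(self, rng):
        track = cn.NucleosomeTrack({"c": np.ones(5000)}, normalized=True)
        hits = [
            cn.MotifHit("c", 1000 + i, 1006 + i, "+", "CGCGTC", gene=f"g{i}",
                        offset=-100, genomic_center=1003 + i, upstream_strand="+")
            for i in range(3)
        ]
        table = pd.DataFrame(
            {"peak_freq": 2, "peak_amplitude": 1.0, "d_g": [0.0, 1.0, 2.0],
             "is_cyclic": [True, True, False], "rank": [1, 2, 3]},
            index=["g0", "g1", "g2"],
        )
        per = cn.PeriodicityResult(table, f_cc=2, d_inflection=2.0)
        mat = cn.build_profile_matrix(track, hits, per, flank=300)
        assert mat.values.shape == (3, 601)
        assert np.all(mat.values == 1.0)
        assert list(mat.meta["d_g"]) == [0.0, 1.0, 2.0]

    def test_hit_without_periodicity_entry_is_dropped_with_warning(self):
        track = cn.NucleosomeTrack({"c": np.ones(2000)}, normalized=True)
        hits = [
            cn.MotifHit("c", 900, 906, "+", "CGCGTC", gene=g, offset=-100,
                        genomic_center=903, upstream_strand="+")
            for g in ("known", "unknown")
        ]
        table = pd.DataFrame(
            {"peak_freq": [2], "peak_amplitude": [1.0], "d_g": [0.0],
             "is_cyclic": [True], "rank": [1]}, index=["known"],
        )
        per = cn.PeriodicityResult(table, 2, 1.0)
        with pytest.warns(UserWarning, match="dropped"):
            mat = cn.build_profile_matrix(track, hits, per, flank=10)
        assert mat.n_rows() == 1

    def test_row_order_matches_periodicity_ranking(self, profile_a):
        d = profile_a.meta["d_g"].to_numpy()
        assert (np.diff(d) >= 0).all()

    def test_depleted_rows_dip_at_center_on_synthetic_data(self, study, norm_track,
                                                           profile_a):
        """Rows over planted-depleted motifs: center occupancy below the
        upstream shoulder for >= 95% of depleted rows."""
        depleted = set()
        for g in study.truth.genes_of("A"):
            for off, st in zip(g.motif_centers_offset, g.motif_nucleosome_state):
                if st == "depleted":
                    depleted.add((g.gene, off))
        keys = list(zip(profile_a.meta["gene"], profile_a.meta["offset"]))
        mask = np.array([k in depleted for k in keys])
        assert mask.sum() >= 10
        offs = profile_a.offsets
        center = np.nanmean(profile_a.values[mask][:, np.abs(offs) <= 50], axis=1)
        shoulder = np.nanmean(
            profile_a.values[mask][:, (offs >= -300) & (offs <= -200)], axis=1
        )
        assert np.mean(center < shoulder) >= 0.95

    def test_profile_is_invariant_under_coordinate_mirroring(self, rng):
        """Reversing the contig coordinate system (and flipping annotations)
        leaves the gene-oriented profile rows unchanged."""
        N = 3000
        v = rng.random(N)
        track_fwd = cn.NucleosomeTrack({"c": v}, normalized=True)
        track_rev = cn.NucleosomeTrack({"c": v[::-1].copy()}, normalized=True)
        table = pd.DataFrame(
            {"peak_freq": [2], "peak_amplitude": [1.0], "d_g": [0.0],
             "is_cyclic": [True], "rank": [1]}, index=["g"],
        )
        per = cn.PeriodicityResult(table, 2, 1.0)
        center = 1200
        hit_fwd = cn.MotifHit("c", center - 3, center + 3, "+", "CGCGTC",
                              gene="g", offset=-100, genomic_center=center,
                              upstream_strand="+")
        # mirrored: the gene flips to '-', the hit to the mirrored center
        mcenter = N - 1 - center
        hit_rev = cn.MotifHit("c", mcenter - 2, mcenter + 4, "-", "CGCGTC",
                              gene="g", offset=-100, genomic_center=mcenter,
                              upstream_strand="+")
        m_fwd = cn.build_profile_matrix(track_fwd, [hit_fwd], per, flank=50)
        m_rev = cn.build_profile_matrix(track_rev, [hit_rev], per, flank=50)
        assert np.allclose(m_fwd.values, m_rev.values)


class TestAverageAndTrough:
    def test_single_row_average_is_identity(self):
        m = _matrix([[1.0, 2.0, 3.0]])
        mean, n = cn.average_profile(m)
        assert np.array_equal(mean, [1, 2, 3]) and np.array_equal(n, [1, 1, 1])

    def test_two_row_average(self):
        m = _matrix([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        mean, _ = cn.average_profile(m)
        assert np.array_equal(mean, [2, 2, 2])

    def test_missing_cells_reduce_n_not_the_mean(self):
        m = _matrix([[np.nan, 2.0, 3.0], [4.0, 2.0, 1.0]])
        mean, n = cn.average_profile(m)
        assert np.array_equal(mean, [4, 2, 2]) and list(n) == [1, 2, 2]

    def test_empty_subset_is_an_error(self):
        with pytest.raises(ProfileError):
            cn.average_profile(_matrix([[1.0, 2.0, 3.0]]), rows=[])

    def test_v_shape_minimum(self):
        offsets = np.arange(-300, 301)
        avg = np.abs(offsets + 37).astype(float)  # min at -37
        assert cn.find_trough(avg, offsets) == -37

    def test_flat_profile_tie_breaks_to_zero_and_upstream_preferred(self):
        offsets = np.arange(-5, 6)
        assert cn.find_trough(np.ones(11), offsets) == 0
        avg = np.ones(11)
        avg[np.flatnonzero(offsets == -3)] = 0.0
        avg[np.flatnonzero(offsets == 3)] = 0.0
        assert cn.find_trough(avg, offsets) == -3

    def test_synthetic_pooled_trough_sits_on_the_motif_center(self, study,
                                                              profile_a):
        depleted_genes = {
            g.gene for g in study.truth.genes_of("A")
            if "depleted" in g.motif_nucleosome_state
        }
        mask = profile_a.meta["gene"].isin(depleted_genes).to_numpy()
        avg, _ = cn.average_profile(profile_a, np.flatnonzero(mask))
        assert abs(cn.find_trough(avg, profile_a.offsets)) <= 10


class TestWelch:
    def test_identical_groups_give_t_zero_p_one(self):
        m = _matrix([[1.0, 0.5, 1.0]] * 4)
        res = cn.trough_welch_test(m, m)
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.trough_offset == 0  # flat tie rule after pooling

    def test_separated_groups_with_tiny_jitter_are_significant(self, rng):
        jitter = 1e-6 * rng.standard_normal((4, 3))
        a = _matrix(np.zeros((4, 3)) + jitter)
        b = _matrix(np.ones((4, 3)) + 1e-6 * rng.standard_normal((4, 3)))
        res = cn.trough_welch_test(a, b)
        assert res.p_value < 1e-6

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(25):
            a = rng.normal(0.8, 0.1, 50)
            b = rng.normal(1.0, 0.1, 50)
            am = _matrix(np.repeat(a[:, None], 3, axis=1))
            bm = _matrix(np.repeat(b[:, None], 3, axis=1))
            res = cn.trough_welch_test(am, bm)
            t, p = welch_oracle(
                am.values[:, res.trough_offset + 1], bm.values[:, res.trough_offset + 1]
            )
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_group_relabeling_flips_t_and_keeps_p(self, rng):
        a = _matrix(rng.random((10, 3)))
        b = _matrix(rng.random((12, 3)))
        r1 = cn.trough_welch_test(a, b)
        r2 = cn.trough_welch_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestMannWhitney:
    def test_spec_example_u_zero_p_one_third(self):
        res = cn.mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)

    def test_exact_branch_matches_enumeration(self, rng):
        for n, m in [(2, 3), (4, 4), (5, 3), (6, 6), (8, 8)]:
            x = rng.normal(size=n)
            y = rng.normal(0.5, 1.0, size=m)
            res = cn.mann_whitney(x, y)
            assert res.p_value == pytest.approx(mwu_enumeration_oracle(x, y),
                                                abs=1e-12)

    def test_tied_data_still_matches_enumeration(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([2.0, 3.0, 3.0, 4.0, 4.0])
        res = cn.mann_whitney(x, y)
        assert res.p_value == pytest.approx(mwu_enumeration_oracle(x, y), abs=1e-12)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ProfileError):
            cn.mann_whitney([], [1.0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 5), min_size=1, max_size=6),
        y=st.lists(st.integers(0, 5), min_size=1, max_size=6),
    )
    def test_exact_p_equals_enumeration_for_arbitrary_tied_samples(self, x, y):
        res = cn.mann_whitney(x, y)
        assert res.p_value == pytest.approx(mwu_enumeration_oracle(x, y),
                                            abs=1e-12)


class TestAssociation:
    def test_synthetic_association_is_strong(self, profile_a):
        res = cn.periodicity_association_test(profile_a)
        assert res.p_value < 1e-3
        assert abs(res.trough_offset) <= 20

    def test_summary_window_alternative_also_detects(self, profile_a):
        res = cn.periodicity_association_test(profile_a, summary_window=50)
        assert res.p_value < 1e-3

    def test_single_class_rows_are_an_error(self):
        m = _matrix(np.ones((4, 3)), is_cyclic=[True] * 4)
        with pytest.raises(ProfileError, match="acyclic"):
            cn.periodicity_association_test(m)


class TestExport:
    def test_row_aligned_tables_round_trip(self, tmp_path, rng):
        m = _matrix(rng.random((5, 7)))
        expr = pd.DataFrame(
            rng.random((4, 6)),
            index=[f"g{i}" for i in range(4)],  # g4 missing from expression
            columns=[float(5 * i) for i in range(6)],
        )
        prof_path, expr_path = cn.export_figure_tables(m, expr, tmp_path / "fig1")
        prof, expr_out = cn.read_figure_tables(prof_path, expr_path)
        assert len(prof) == len(expr_out) == 4
        assert list(prof["gene"]) == list(expr_out["gene"])
        values = prof.drop(columns=["gene", "motif_offset"]).to_numpy()
        assert np.array_equal(values, m.values[:4])
        assert np.array_equal(
            expr_out.drop(columns="gene").to_numpy(), expr.loc[prof["gene"]].to_numpy()
        )

    def test_disjoint_gene_sets_are_an_error(self, rng):
        m = _matrix(rng.random((2, 3)))
        expr = pd.DataFrame(rng.random((2, 3)), index=["x", "y"],
                            columns=[0.0, 5.0, 10.0])
        with pytest.raises(ProfileError):
            cn.export_figure_tables(m, expr, "unused")
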