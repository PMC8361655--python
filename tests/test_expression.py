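"""Differential-expression module: moderated t, BH, probe collapse."""

import math
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from mirppin import (
    DERecord,
    ExpressionMatrix,
    bh_adjust,
    collapse_probes,
    moderated_t_test,
    select_de,
)


def brute_force_bh(p):
    """Step-up definition: adj_i = min over j >= i (rank order) of p_(j)*m/j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    sorted_p = np.asarray(p)[order]
    for i in range(m):
        adj[order[i]] = min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
    return adj


def ebayes_oracle(values, a_idx, b_idx):
    """Independent step-by-step re-derivation of the moderated t.

    Pooled per-feature variances -> closed-form moment matching of the
    scaled-F prior on log variances -> posterior variances -> t.
    Implemented from the model definition, separately from the package.
    """
    xa, xb = values[:, a_idx], values[:, b_idx]
    na, nb = len(a_idx), len(b_idx)
    df = na + nb - 2
    s2 = (xa.var(axis=1, ddof=1) * (na - 1) + xb.var(axis=1, ddof=1) * (nb - 1)) / df
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    ebar = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    # invert trigamma by bisection (method independent of the package's Newton)
    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if special.polygamma(1, mid) > evar:
            lo = mid
        else:
            hi = mid
    d0 = 2 * math.sqrt(lo * hi)
    s0 = math.exp(ebar + special.digamma(d0 / 2) - math.log(d0 / 2))
    s2_post = (d0 * s0 + df * s2) / (d0 + df)
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    t = diff / np.sqrt(s2_post * (1 / na + 1 / nb))
    return t, d0 + df


class TestModeratedT:
    def test_equal_means_gives_zero_t_unit_p(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, size=(5, 4))
        values = np.hstack([base, base])  # identical per-feature group profiles
        mat = ExpressionMatrix(
            [f"f{i}" for i in range(5)],
            [f"s{i}" for i in range(8)],
            values,
            {f"s{i}": ("a" if i < 4 else "b") for i in range(8)},
        )
        recs = moderated_t_test(mat, "a", "b")
        for r in recs:
            assert r.t_moderated == pytest.approx(0.0, abs=1e-12)
            assert r.p_raw == pytest.approx(1.0)

    def test_matches_independent_rederivation(self, two_group_matrix):
        mat, planted = two_group_matrix
        recs = moderated_t_test(mat, "case", "ctrl")
        a_idx = [i for i, s in enumerate(mat.sample_ids) if mat.group_of[s] == "case"]
        b_idx = [i for i, s in enumerate(mat.sample_ids) if mat.group_of[s] == "ctrl"]
        t_oracle, df_oracle = ebayes_oracle(mat.values, a_idx, b_idx)
        t_pkg = np.array([r.t_moderated for r in recs])
        assert np.allclose(t_pkg, t_oracle, atol=1e-10)
        p_oracle = 2 * stats.t.sf(np.abs(t_oracle), df_oracle)
        assert np.allclose([r.p_raw for r in recs], p_oracle, atol=1e-10)

    def test_prior_weight_zero_equals_ordinary_t(self, two_group_matrix):
        mat, _ = two_group_matrix
        recs = moderated_t_test(mat, "case", "ctrl", prior_df=0.0, prior_var=1.0)
        a = mat.values[:, :6]
        b = mat.values[:, 6:]
        df = 10
        s2 = (a.var(axis=1, ddof=1) * 5 + b.var(axis=1, ddof=1) * 5) / df
        t_ord = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(s2 * (2 / 6))
        assert np.allclose([r.t_moderated for r in recs], t_ord, atol=1e-12)

    def test_infinite_prior_shrinks_to_common_variance(self, two_group_matrix):
        mat, _ = two_group_matrix
        s0 = 0.3
        recs = moderated_t_test(mat, "case", "ctrl", prior_df=math.inf, prior_var=s0)
        a, b = mat.values[:, :6], mat.values[:, 6:]
        t_limit = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(s0 * (2 / 6))
        assert np.allclose([r.t_moderated for r in recs], t_limit, atol=1e-12)
        # growing prior df moves the estimated t continuously toward the limit
        t_seq = []
        for d0 in (1.0, 10.0, 1e4):
            t_seq.append(moderated_t_test(mat, "case", "ctrl", prior_df=d0,
                                          prior_var=s0)[0].t_moderated)
        gaps = [abs(t - t_limit[0]) for t in t_seq]
        assert gaps == sorted(gaps, reverse=True)

    def test_matches_limma_reference(self):
        """Cross-check t and p against the canonical R implementation."""
        rng = np.random.default_rng(7)
        values = rng.normal(6.0, 1.0, size=(60, 8))
        values[:5, :4] += 1.5
        np.savetxt("/tmp/_mirppin_limma_in.tsv", values, delimiter="\t")
        rcode = textwrap.dedent("""
            suppressMessages(library(limma))
            x <- as.matrix(read.table('/tmp/_mirppin_limma_in.tsv', sep='\\t'))
            design <- cbind(Intercept=1, case=c(1,1,1,1,0,0,0,0))
            fit <- eBayes(lmFit(x, design))
            out <- cbind(fit$t[, 'case'], fit$p.value[, 'case'])
            write.table(out, '/tmp/_mirppin_limma_out.tsv', sep='\\t',
                        row.names=FALSE, col.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        ref = np.loadtxt("/tmp/_mirppin_limma_out.tsv")
        mat = ExpressionMatrix(
            [f"f{i}" for i in range(60)],
            [f"s{i}" for i in range(8)],
            values,
            {f"s{i}": ("case" if i < 4 else "ctrl") for i in range(8)},
        )
        recs = moderated_t_test(mat, "case", "ctrl")
        assert np.allclose([r.t_moderated for r in recs], ref[:, 0], atol=1e-6)
        assert np.allclose([r.p_raw for r in recs], ref[:, 1], atol=1e-6)

    def test_small_group_rejected(self, two_group_matrix):
        mat, _ = two_group_matrix
        mat.group_of[mat.sample_ids[0]] = "lonely"
        with pytest.raises(ValueError, match=">= 2 samples"):
            moderated_t_test(mat, "lonely", "ctrl")

    def test_zero_variance_feature_is_shrunk_not_dropped(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, size=(50, 8))
        values[0] = 5.0  # flat feature
        mat = ExpressionMatrix(
            [f"f{i}" for i in range(50)],
            [f"s{i}" for i in range(8)],
            values,
            {f"s{i}": ("a" if i < 4 else "b") for i in range(8)},
        )
        recs = moderated_t_test(mat, "a", "b")
        assert math.isfinite(recs[0].t_moderated)
        assert recs[0].t_moderated == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_variance_errors(self):
        values = np.ones((5, 6))
        mat = ExpressionMatrix(
            [f"f{i}" for i in range(5)],
            [f"s{i}" for i in range(6)],
            values,
            {f"s{i}": ("a" if i < 3 else "b") for i in range(6)},
        )
        with pytest.raises(ValueError, match="zero variance"):
            moderated_t_test(mat, "a", "b")


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.05], [0.05]),
            ([0.05] * 6, [0.05] * 6),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_known_values(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_matches_step_up_definition_exhaustively(self, p):
        assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    def test_monotone_along_sort(self, p):
        p_sorted = sorted(p)
        adj = bh_adjust(p_sorted)
        assert all(adj[i] <= adj[i + 1] + 1e-15 for i in range(len(adj) - 1))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _rec(fid, p_adj, lfc=1.0):
    return DERecord(fid, lfc, 2.0, p_adj / 2, p_adj, "up" if lfc >= 0 else "down")


class TestCollapseAndSelect:
    def test_most_significant_probe_wins(self):
        recs = [_rec("p1", 0.04), _rec("p2", 0.20)]
        out = collapse_probes(recs, {"p1": "G", "p2": "G"})
        assert len(out) == 1 and out[0].feature_id == "G"
        assert out[0].p_adj == 0.04

    def test_single_probe_passthrough(self):
        out = collapse_probes([_rec("p1", 0.1)], {"p1": "G"})
        assert out[0].p_adj == 0.1 and out[0].feature_id == "G"

    def test_tie_break_order_invariant(self):
        a = _rec("pB", 0.05, lfc=1.0)
        b = _rec("pA", 0.05, lfc=2.0)  # equal p_adj, larger |logFC| wins
        for order in ([a, b], [b, a]):
            out = collapse_probes(order, {"pA": "G", "pB": "G"})
            assert out[0].log_fold_change == 2.0
        # full tie -> lexicographically smaller probe id wins
        c = _rec("pA", 0.05, lfc=1.0)
        for order in ([a, c], [c, a]):
            out = collapse_probes(order, {"pA": "G", "pB": "G"})
            assert out[0].p_adj == 0.05

    def test_unmapped_probes_dropped_size_is_distinct_genes(self, rng):
        recs = [_rec(f"p{i}", float(rng.uniform(0, 1))) for i in range(30)]
        mapping = {f"p{i}": f"G{i % 7}" for i in range(20)}
        out = collapse_probes(recs, mapping)
        assert len(out) == 7
        perm = list(recs)
        rng.shuffle(perm)
        assert collapse_probes(perm, mapping) == out

    def test_select_strict_boundary(self):
        recs = [_rec("a", 0.049), _rec("b", 0.051), _rec("c", 0.05)]
        kept = {r.feature_id for r in select_de(recs, 0.05)}
        assert kept == {"a"}

    def test_select_alpha_one_keeps_all(self):
        recs = [_rec("a", 0.5), _rec("b", 1.0)]
        assert len(select_de(recs, 1.0)) == 2
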