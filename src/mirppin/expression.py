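"""Differential expression with empirical-Bayes moderated t-statistics.

Two-group comparisons of log2-scale expression matrices (miRNA or mRNA).
Per-feature sample variances are shrunk toward a common prior variance
estimated by closed-form method of moments on the log sample variances,
raw p-values come from a t distribution with augmented degrees of freedom,
and multiple testing is controlled by Benjamini-Hochberg step-up FDR.
Matrices are assumed already normalised and log2-transformed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "DERecord",
    "moderated_t_test",
    "bh_adjust",
    "collapse_probes",
    "select_de",
]


@dataclass
class ExpressionMatrix:
    """Features x samples log2-intensity table with per-sample group labels.

    Parameters
    ----------
    feature_ids : sequence of str
        Probe or feature identifiers, one per row; must be unique.
    sample_ids : sequence of str
        Sample identifiers, one per column.
    values : ndarray of shape (n_features, n_samples)
        Finite log2 intensities.
    group_of : mapping sample_id -> group label
        Every sample must be labelled.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.group_of = dict(self.group_of)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_tsv(cls, expr_path, groups_path) -> "ExpressionMatrix":
        """Read an expression TSV (first column = feature id, header = sample
        ids) and a two-column sample -> group TSV."""
        df = pd.read_csv(expr_path, sep="\t", index_col=0)
        gmap = pd.read_csv(groups_path, sep="\t", header=None, comment="#")
        if gmap.shape[1] < 2:
            raise ValueError("group map must have two columns: sample, group")
        group_of = dict(zip(gmap.iloc[:, 0].astype(str), gmap.iloc[:, 1].astype(str)))
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            group_of=group_of,
        )


@dataclass(frozen=True)
class DERecord:
    """One feature's differential-expression summary."""

    feature_id: str
    log_fold_change: float
    t_moderated: float
    p_raw: float
    p_adj: float
    direction: str  # "up" | "down"


def records_to_frame(records: Iterable[DERecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(
        rows,
        columns=["feature_id", "log_fold_change", "t_moderated", "p_raw", "p_adj", "direction"],
    )
    return df.rename(columns={"log_fold_change": "logFC", "t_moderated": "t"})


def _trigamma_inverse(x: float) -> float:
    # Newton iteration for y with psi'(y) = x (monotone decreasing).
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F model for sample variances.

    Under the hierarchical model s2 ~ s0^2 * F(df_resid, d0), the statistic
    e = log(s2) - digamma(df/2) + log(df/2) has mean log(s0^2) +
    digamma(d0/2) - log(d0/2) and variance trigamma(df/2) + trigamma(d0/2).
    Matching the sample mean and variance of e gives closed-form d0 and s0^2.
    Zero variances carry no information about the prior and are excluded
    from the moment fit (they are still shrunk toward s0^2 afterwards).

    Returns
    -------
    (d0, s0_sq) : prior degrees of freedom (may be inf) and prior variance.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if not np.any(pos):
        raise ValueError("all features have zero variance; cannot estimate prior")
    z = np.log(s2[pos])
    half = df_resid / 2.0
    e = z - float(special.digamma(half)) + math.log(half)
    e_mean = float(np.mean(e))
    n = e.size
    if n < 2:
        return math.inf, float(math.exp(e_mean))
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1.0)) - float(special.polygamma(1, half))
    if e_var <= 0:
        return math.inf, float(math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s0_sq


def moderated_t_test(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> list[DERecord]:
    """Moderated two-sample t-test of ``group_a`` versus ``group_b``.

    log_fold_change is mean(group_a) - mean(group_b) in log2 units, so
    direction "up" means higher in ``group_a``.  Per-feature pooled
    variances are shrunk toward the prior: s~^2 = (d0*s0^2 + d*s^2)/(d0+d),
    and p-values come from a t distribution on d0 + d degrees of freedom.

    ``prior_df``/``prior_var`` override the method-of-moments estimates
    (prior_df=0 recovers the ordinary pooled t exactly).
    """
    a_idx = [i for i, s in enumerate(matrix.sample_ids) if matrix.group_of[s] == group_a]
    b_idx = [i for i, s in enumerate(matrix.sample_ids) if matrix.group_of[s] == group_b]
    n_a, n_b = len(a_idx), len(b_idx)
    if n_a < 2 or n_b < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {group_a}: {n_a}, {group_b}: {n_b})"
        )
    if matrix.n_features < 2:
        raise ValueError("need >= 2 features to pool variance information")

    xa = matrix.values[:, a_idx]
    xb = matrix.values[:, b_idx]
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    lfc = mean_a - mean_b
    df_resid = float(n_a + n_b - 2)
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None or prior_var is None:
        d0_est, s0_est = estimate_variance_prior(s2, df_resid)
        d0 = d0_est if prior_df is None else float(prior_df)
        s0_sq = s0_est if prior_var is None else float(prior_var)
    else:
        d0, s0_sq = float(prior_df), float(prior_var)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    if np.any(s2_post <= 0):
        raise ValueError("all features have zero variance; t undefined")

    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    t = lfc / se
    if math.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_adj = bh_adjust(p_raw)

    return [
        DERecord(
            feature_id=fid,
            log_fold_change=float(lfc[i]),
            t_moderated=float(t[i]),
            p_raw=float(p_raw[i]),
            p_adj=float(p_adj[i]),
            direction="up" if lfc[i] >= 0 else "down",
        )
        for i, fid in enumerate(matrix.feature_ids)
    ]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def collapse_probes(
    records: Sequence[DERecord], probe_to_gene: Mapping[str, str]
) -> list[DERecord]:
    """Collapse probe-level records to gene level.

    Each gene keeps the record of its most significant probe (smallest
    p_adj; ties broken by larger \\|logFC\\|, then lexicographic probe id, so
    the result is independent of input order).  Probes absent from the map
    are dropped.  The surviving record's feature_id becomes the gene symbol.
    """
    best: dict[str, DERecord] = {}
    best_probe: dict[str, str] = {}
    for rec in records:
        gene = probe_to_gene.get(rec.feature_id)
        if gene is None:
            continue
        cur = best.get(gene)
        if cur is None:
            best[gene] = rec
            best_probe[gene] = rec.feature_id
            continue
        key_new = (rec.p_adj, -abs(rec.log_fold_change), rec.feature_id)
        key_cur = (cur.p_adj, -abs(cur.log_fold_change), best_probe[gene])
        if key_new < key_cur:
            best[gene] = rec
            best_probe[gene] = rec.feature_id
    return [
        dataclasses.replace(best[g], feature_id=g) for g in sorted(best)
    ]


def select_de(records: Sequence[DERecord], alpha: float = 0.05) -> list[DERecord]:
    """Records with adjusted p strictly below ``alpha``.

    alpha = 1 keeps everything (adjusted p-values are capped at 1, so the
    strict inequality would otherwise silently drop p_adj == 1 records).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if alpha >= 1.0:
        return list(records)
    return [r for r in records if r.p_adj < alpha]
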