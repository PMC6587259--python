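"""Responder-signature analyses: differential expression, the APPM
signature, ssGSEA and signature-linked survival.

The antigen processing and presentation machinery (APPM) signature is
the intersection of responder-vs-non-responder differentially expressed
genes (unadjusted p < 0.05) with the union of APPM pathway gene sets.
Samples are scored by the median expression of the signature genes,
stratified into tertiles, and the top-vs-bottom tertile contrast is
linked to overall survival by the log-rank test and a univariate Cox
model.

Differential expression offers a Welch mode (one t-test per gene) and a
moderated mode using empirical-Bayes variance shrinkage: per-gene pooled
variances are shrunk toward a moment-matched scaled-inverse-chi-square
prior, with the prior degrees of freedom added to the residual ones.

ssGSEA follows the rank-weighted running-sum form: per sample, genes are
ranked by expression descending; in-set steps increase the running sum
by the gene's rank value raised to ``alpha`` (normalized over the set),
out-of-set steps decrease it uniformly; the enrichment score is the sum
of the running difference, normalized by the global ES range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

from . import stats
from .errors import (
    DesignError,
    ParameterError,
    SignatureError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named gene collection (GMT-style)."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ParameterError(f"gene set {self.name!r} has no members")


def read_gmt(path: str) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return sets


def write_gmt(sets: list[GeneSet], path: str) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_expression_matrix(path: str) -> pd.DataFrame:
    """Genes x samples TSV with a header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ParameterError("duplicate gene names in expression matrix")
    return df


def _fit_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match a scaled-inverse-chi-square prior to per-gene variances.

    Matches the mean and variance of log(s^2) to the marginal law of the
    hierarchical model; returns (d0, s0_squared).  A non-positive excess
    log-variance collapses to a near-infinite prior df (full shrinkage).
    """
    z = np.log(np.maximum(s2, 1e-300))
    var_z = float(np.var(z, ddof=1))
    excess = var_z - float(special.polygamma(1, df_resid / 2.0))
    if excess <= 1e-8:
        d0 = 1e6
    else:
        lo, hi = 1e-3, 1e6
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if special.polygamma(1, mid / 2.0) > excess:
                lo = mid
            else:
                hi = mid
        d0 = float(np.sqrt(lo * hi))
    mean_z = float(np.mean(z))
    log_s0 = (
        mean_z
        - float(special.digamma(df_resid / 2.0))
        + np.log(df_resid / 2.0)
        - np.log(d0 / 2.0)
        + float(special.digamma(d0 / 2.0))
    )
    return d0, float(np.exp(log_s0))


def differential_expression(
    matrix: pd.DataFrame,
    groups: pd.Series,
    method: str = "moderated",
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group differential expression.

    ``matrix`` is genes x samples; ``groups`` maps sample id to one of
    exactly two labels.  Effect = mean(group1) - mean(group2) with
    groups in sorted label order.  ``method``: "moderated" (empirical-
    Bayes shrunken pooled variance) or "welch".  Unadjusted p-values are
    reported by default; ``adjust`` adds Benjamini-Hochberg q-values.
    """
    groups = groups.dropna()
    labels = sorted(groups.unique(), key=str)
    if len(labels) != 2:
        raise DesignError(f"need exactly 2 groups, got {labels}")
    g1 = [s for s in matrix.columns if groups.get(s) == labels[0]]
    g2 = [s for s in matrix.columns if groups.get(s) == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise DesignError("each group needs >= 2 samples")
    x = matrix[g1].to_numpy(float)
    y = matrix[g2].to_numpy(float)
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    effect = m1 - m2

    if method == "welch":
        t, p = sps.ttest_ind(x, y, axis=1, equal_var=False)
        df = np.full(len(effect), np.nan)
    elif method == "moderated":
        v1 = x.var(axis=1, ddof=1)
        v2 = y.var(axis=1, ddof=1)
        d = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
        d0, s0sq = _fit_variance_prior(s2, d)
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = effect / se
        df_total = min(d0 + d, 1e6)
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
        df = np.full(len(effect), df_total)
    else:
        raise ParameterError(f"unknown method {method!r}")

    out = pd.DataFrame(
        {"gene": matrix.index, "effect": effect, "statistic": t, "p": p,
         "df": df}
    ).set_index("gene")
    if adjust:
        order = np.argsort(out["p"].to_numpy())
        n = len(out)
        q = np.empty(n)
        ranked = out["p"].to_numpy()[order] * n / (np.arange(n) + 1)
        q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        out["q"] = np.minimum(q, 1.0)
    return out


def derive_appm_signature(
    deg_table: pd.DataFrame,
    appm_sets: list[GeneSet],
    alpha: float = 0.05,
) -> list[str]:
    """Significant DEGs intersected with the APPM pathway gene union."""
    appm_union = set().union(*(set(s.genes) for s in appm_sets)) if appm_sets else set()
    significant = set(deg_table.index[deg_table["p"] < alpha])
    signature = sorted(significant & appm_union)
    if not signature:
        logger.warning("empty APPM signature: no significant DEG in APPM sets")
    return signature


def signature_score(matrix: pd.DataFrame, signature_genes: list[str]) -> pd.Series:
    """Per-sample median expression over the signature genes."""
    present = [g for g in signature_genes if g in matrix.index]
    missing = sorted(set(signature_genes) - set(present))
    if not present:
        raise SignatureError("no signature gene present in the matrix")
    if missing:
        logger.warning("%d signature genes missing from matrix: %s",
                       len(missing), missing[:5])
    return matrix.loc[present].median(axis=0)


def stratify_tertiles(scores: pd.Series) -> pd.Series:
    """Rank-based high/middle/low tertile labels.

    Group sizes differ by at most one, with the largest remainder
    assigned to the top tertile; ties in score break by sample id.
    """
    n = len(scores)
    if n < 3:
        raise ParameterError(f"need >= 3 samples to form tertiles, got {n}")
    base, rem = divmod(n, 3)
    n_high = base + (1 if rem >= 1 else 0)
    n_mid = base + (1 if rem >= 2 else 0)
    order = sorted(scores.index, key=lambda s: (-scores[s], str(s)))
    labels = {}
    for i, sample in enumerate(order):
        if i < n_high:
            labels[sample] = "high"
        elif i < n_high + n_mid:
            labels[sample] = "middle"
        else:
            labels[sample] = "low"
    return pd.Series(labels, name="tertile").reindex(scores.index)


def ssgsea(
    matrix: pd.DataFrame,
    gene_sets: list[GeneSet],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample GSEA normalized enrichment scores (sets x samples).

    Per sample, genes are ranked by expression descending and assigned
    rank values N..1.  Walking down the ranking, an in-set gene adds its
    rank value^alpha (normalized over in-set genes), an out-of-set gene
    subtracts 1/(N - set size); the ES is the sum of the running
    difference.  With ``normalize`` all ES are rescaled by the largest
    ES magnitude across sets and samples, bounding NES in [-1, 1].
    Sets with fewer than 2 genes in the matrix are skipped.
    """
    genes = matrix.index.to_numpy()
    n = len(genes)
    es = {}
    for s in gene_sets:
        members = set(s.genes) & set(genes)
        if len(members) < 2:
            logger.warning("gene set %s has <2 genes in matrix; skipped", s.name)
            continue
        es[s.name] = []
        for sample in matrix.columns:
            expr = matrix[sample]
            order = sorted(genes, key=lambda g: (-expr[g], g))
            rank_value = np.arange(n, 0, -1, dtype=float)
            in_set = np.array([g in members for g in order])
            w = np.where(in_set, rank_value**alpha, 0.0)
            w_sum = w.sum()
            inc = np.where(in_set, w / w_sum, 0.0)
            dec = np.where(~in_set, 1.0 / (n - len(members)), 0.0)
            running = np.cumsum(inc - dec)
            es[s.name].append(running.sum())
    if not es:
        raise ParameterError("no gene set overlaps the matrix")
    table = pd.DataFrame(es, index=matrix.columns).T
    if not normalize:
        return table
    scale = float(np.abs(table.to_numpy()).max())
    return table / scale if scale > 0 else table


def survival_by_signature(
    scores: pd.Series,
    records: list[stats.SurvivalRecord],
) -> dict:
    """Top-vs-bottom tertile survival contrast for a signature score.

    Returns tertile labels, the high-vs-low log-rank test, a univariate
    Cox fit on the high-vs-low indicator (high = 1) and Kaplan-Meier
    step tables for both groups.
    """
    by_sample = {r.sample: r for r in records}
    shared = [s for s in scores.index if s in by_sample]
    if not shared:
        raise ParameterError("scores and survival records share no samples")
    scores = scores.loc[shared]
    tertiles = stratify_tertiles(scores)
    contrast = tertiles[tertiles.isin(["high", "low"])]
    recs = [
        stats.SurvivalRecord(
            sample=s,
            time=by_sample[s].time,
            event=by_sample[s].event,
            group=contrast[s],
        )
        for s in contrast.index
    ]
    lr_stat, lr_p = stats.logrank(recs)
    cox_recs = [
        stats.SurvivalRecord(r.sample, r.time, r.event,
                             group=1.0 if r.group == "high" else 0.0)
        for r in recs
    ]
    cox = stats.cox_univariate(cox_recs)
    km = {
        label: stats.km_curve([r for r in recs if r.group == label])
        for label in ("high", "low")
    }
    return {
        "tertiles": tertiles,
        "logrank_stat": lr_stat,
        "logrank_p": lr_p,
        "cox": cox,
        "km": km,
    }


def compare_infiltration(
    cell_scores: pd.DataFrame,
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-cell-type two-group t-tests on infiltration scores.

    ``cell_scores`` is samples x cell types (xCell-style); ``groups``
    maps sample to "high"/"low" (other labels are ignored).  Cell types
    with fewer than 2 samples in either group are skipped.
    """
    labels = [l for l in ("high", "low") if (groups == l).any()]
    if len(labels) != 2:
        raise DesignError("need samples in both high and low groups")
    hi = [s for s in cell_scores.index if groups.get(s) == "high"]
    lo = [s for s in cell_scores.index if groups.get(s) == "low"]
    rows = []
    for cell_type in cell_scores.columns:
        x = cell_scores.loc[hi, cell_type].dropna()
        y = cell_scores.loc[lo, cell_type].dropna()
        if len(x) < 2 or len(y) < 2:
            logger.warning("cell type %s lacks samples in a group; skipped",
                           cell_type)
            continue
        t, df, p = stats.welch_t(x, y)
        rows.append({"cell_type": cell_type, "mean_high": x.mean(),
                     "mean_low": y.mean(), "t": t, "p": p})
    return pd.DataFrame(rows).set_index("cell_type")


def correlate_signature_gene(scores: pd.Series, gene_expr: pd.Series) -> dict:
    """Pearson correlation plus a least-squares trendline with 95% band.

    Returns r, p, slope, intercept and the pointwise confidence band of
    the fitted mean, evaluated at the observed score values.
    """
    shared = [s for s in scores.index if s in gene_expr.index]
    x = scores.loc[shared].to_numpy(float)
    y = gene_expr.loc[shared].to_numpy(float)
    r, p = stats.pearson(x, y)
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    resid = y - yhat
    s2 = (resid**2).sum() / (n - 2)
    sxx = ((x - x.mean()) ** 2).sum()
    tcrit = sps.t.ppf(0.975, n - 2)
    half = tcrit * np.sqrt(s2 * (1.0 / n + (x - x.mean()) ** 2 / sxx))
    order = np.argsort(x)
    return {
        "r": r,
        "p": p,
        "slope": float(slope),
        "intercept": float(intercept),
        "band_x": x[order],
        "band_lower": (yhat - half)[order],
        "band_upper": (yhat + half)[order],
    }
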