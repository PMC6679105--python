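"""Gene-body CG methylation (gbM) versus seasonal expression stability.

gbM is the pooled CG methylation level over a gene's span (introns
included, exon-only optional), averaged across sampling dates.  The
seasonal expression summary of a gene is the arithmetic mean of its
log2(RPM+1) values across dates (average) and the max − min of a centred
moving average of the date-ordered series (range).  Expressed genes
(average > 1) are split into gbM quintiles; group differences in average
and range are assessed with pairwise two-sided Mann-Whitney tests,
multiplicity-adjusted (Holm by default) and summarised as a compact letter
display: groups sharing a letter are not significantly different.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomeAnnotation, MethylomeSeries

log = logging.getLogger(__name__)


def gene_body_methylation(series: MethylomeSeries,
                          annotation: GenomeAnnotation,
                          context: str = "CG",
                          exon_only: bool = False) -> pd.DataFrame:
    """Per-gene pooled methylation level for one context.

    For each gene, the level is pooled over all sites of the context within
    the gene span (or its exons when ``exon_only``) per date, then averaged
    across dates with coverage.  Genes with no covered site are excluded
    (logged).  Columns: gene_id, gbm, n_sites, plus per-date gbm_<date>.
    """
    sub = series.for_context(context)
    which = "gene"
    hits = annotation.overlapping_feature(sub.sites, which)
    if exon_only and len(hits):
        keep = []
        for row in hits.itertuples(index=False):
            s = sub.sites.iloc[row.site_index]
            gene_exons = annotation.exons[
                annotation.exons["gene_id"] == row.feature_id]
            inside = ((gene_exons["start"] <= s["pos"]) &
                      (s["pos"] < gene_exons["end"])).any()
            keep.append(inside)
        hits = hits[np.asarray(keep, dtype=bool)]

    rows = []
    covered = set()
    for gid, grp in hits.groupby("feature_id"):
        idx = grp["site_index"].to_numpy()
        m = sub.meth[idx].sum(axis=0).astype(float)
        t = sub.total[idx].sum(axis=0).astype(float)
        if t.sum() == 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            by_date = np.where(t > 0, m / t, np.nan)
        rows.append((gid, float(np.nanmean(by_date)), len(idx), *by_date))
        covered.add(gid)
    skipped = set(annotation.genes["gene_id"]) - covered
    if skipped:
        log.info("%d gene(s) without covered %s sites excluded: %s",
                 len(skipped), context, sorted(skipped)[:5])
    cols = ["gene_id", "gbm", "n_sites"] + [f"gbm_{d}" for d in sub.dates]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def seasonal_summary(expression: pd.DataFrame,
                     smooth_window: int = 3) -> pd.DataFrame:
    """Seasonal average and range of expression per gene.

    ``expression`` is a genes × dates matrix of log2(RPM+1) (columns sorted
    by date).  average = mean across dates; range = max − min of the
    centred moving average of width ``smooth_window`` (window truncated at
    the edges; width 1 disables smoothing and gives the raw max − min).
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least two dates")
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    vals = expression.to_numpy(dtype=float)
    if (vals < 0).any():
        bad = expression.index[np.where(vals < 0)[0][0]]
        raise ValueError(
            f"negative expression value for gene {bad!r}: inputs are "
            f"log2(RPM+1) and must be >= 0")
    cols = sorted(expression.columns)
    expr = expression[cols]
    smooth = expr.T.rolling(window=smooth_window, center=True,
                            min_periods=1).mean().T
    out = pd.DataFrame({
        "gene_id": expr.index,
        "average": expr.mean(axis=1).to_numpy(),
        "range": (smooth.max(axis=1) - smooth.min(axis=1)).to_numpy(),
        "n_dates": expr.shape[1],
    })
    return out.reset_index(drop=True)


def quintile_bins(gbm_records: pd.DataFrame, summaries: pd.DataFrame,
                  expressed_min: float = 1.0) -> pd.Series:
    """gbM quintile (1..5, low to high) of each expressed gene.

    Genes whose seasonal average is ≤ ``expressed_min`` are removed; the
    remainder are split at the 20/40/60/80th percentiles of gbM, ties at a
    boundary going to the lower bin.  Fewer than 5 expressed genes, or an
    all-identical gbM vector (quintiles undefined), is an error.
    """
    merged = gbm_records.merge(summaries, on="gene_id", how="inner")
    expressed = merged[merged["average"] > expressed_min]
    if len(expressed) < 5:
        raise ValueError(
            f"only {len(expressed)} expressed genes; need at least 5 for "
            f"quintile binning")
    g = expressed["gbm"].to_numpy(dtype=float)
    if np.all(g == g[0]):
        raise ValueError("all gbm values identical: quintiles are undefined")
    cuts = np.quantile(g, [0.2, 0.4, 0.6, 0.8])
    bins = 1 + (g[:, None] > cuts[None, :]).sum(axis=1)
    return pd.Series(bins, index=expressed["gene_id"].to_numpy(),
                     name="bin")


def _exact_or_auto_mw(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 1.0  # fully degenerate pair: no evidence of any difference
    res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


def groupwise_tests(values_by_bin: dict, alpha: float = 0.01,
                    adjust: str = "holm"
                    ) -> tuple[pd.DataFrame, dict]:
    """All pairwise two-sided Mann-Whitney tests with a compact letter display.

    ``values_by_bin`` maps bin label → 1-d array of values (each with ≥2
    values).  P-values are adjusted for the C(k, 2) comparisons (Holm by
    default; 'bonferroni' and 'fdr_bh' available).  Letters are assigned so
    that two bins share a letter iff they are not significantly different
    at ``alpha`` after adjustment (maximal cliques of the non-significance
    graph, ordered by bin).  Returns (pairwise table, bin → letters dict).
    """
    bins = sorted(values_by_bin)
    if len(bins) < 2:
        raise ValueError("need at least two bins")
    for b in bins:
        if len(values_by_bin[b]) < 2:
            raise ValueError(f"bin {b!r} has fewer than 2 values")
    pairs, raw = [], []
    for i, bi in enumerate(bins):
        for bj in bins[i + 1:]:
            x = np.asarray(values_by_bin[bi], dtype=float)
            y = np.asarray(values_by_bin[bj], dtype=float)
            pairs.append((bi, bj))
            raw.append(_exact_or_auto_mw(x, y))
    method = {"holm": "holm", "bonferroni": "bonferroni",
              "fdr_bh": "fdr_bh"}[adjust]
    _, adj, _, _ = multipletests(raw, alpha=alpha, method=method)
    table = pd.DataFrame({
        "bin_a": [a for a, _ in pairs],
        "bin_b": [b for _, b in pairs],
        "p_raw": raw,
        "p_adjusted": adj,
        "significant": adj < alpha,
    })

    graph = nx.Graph()
    graph.add_nodes_from(bins)
    for (a, b), p in zip(pairs, adj):
        if p >= alpha:
            graph.add_edge(a, b)
    cliques = sorted((sorted(c) for c in nx.find_cliques(graph)),
                     key=lambda c: (bins.index(c[0]), c))
    letters: dict = {b: "" for b in bins}
    for letter_i, clique in enumerate(cliques):
        letter = chr(ord("a") + letter_i)
        for b in clique:
            letters[b] += letter
    return table, letters


def association_analysis(bins: pd.Series, summaries: pd.DataFrame,
                         gbm_records: pd.DataFrame, alpha: float = 0.01,
                         adjust: str = "holm") -> dict:
    """Distribution of seasonal average and range across gbM quintiles.

    Returns a dict with per-bin quartile summaries, the pairwise
    Mann-Whitney tables and letter displays for both statistics, and the
    gene-level Spearman rank correlation between gbM and seasonal range
    (the monotone-trend summary).  With a single populated bin the group
    tests are undefined and reported as None.
    """
    df = summaries.merge(gbm_records[["gene_id", "gbm"]], on="gene_id")
    df = df[df["gene_id"].isin(bins.index)]
    df["bin"] = bins.loc[df["gene_id"]].to_numpy()

    per_bin = (df.groupby("bin")[["average", "range"]]
               .describe(percentiles=[0.25, 0.5, 0.75]))
    populated = sorted(df["bin"].unique())
    # group tests need at least two values per bin
    testable = [b for b in populated
                if (df["bin"] == b).sum() >= 2]
    out: dict = {"per_bin": per_bin, "n_bins": len(populated)}
    if len(testable) >= 2:
        for stat in ("average", "range"):
            groups = {b: df.loc[df["bin"] == b, stat].to_numpy()
                      for b in testable}
            table, letters = groupwise_tests(groups, alpha=alpha,
                                             adjust=adjust)
            out[f"tests_{stat}"] = table
            out[f"letters_{stat}"] = letters
    else:
        log.info("fewer than two bins with >= 2 genes: group tests undefined")
        out["tests_average"] = out["tests_range"] = None
        out["letters_average"] = out["letters_range"] = None
    if df["gbm"].nunique() > 1 and df["range"].nunique() > 1 and len(df) > 2:
        rho, pval = spearmanr(df["gbm"], df["range"])
        out["spearman_gbm_range"] = float(rho)
        out["spearman_p"] = float(pval)
    else:
        out["spearman_gbm_range"] = float("nan")
        out["spearman_p"] = float("nan")
    return out


def feature_association(feature_series: pd.DataFrame,
                        expression_series: pd.Series) -> tuple[pd.DataFrame,
                                                               float]:
    """Pair one feature's seasonal methylation with one gene's expression.

    ``feature_series`` is a long table with 'date' and 'level' for a single
    feature; ``expression_series`` maps the same dates to expression.
    Returns the paired per-date table and the Pearson correlation between
    methylation level and expression (NaN, flagged in the table attrs, when
    either series is constant).  Date mismatch is an error.
    """
    meth = feature_series.set_index("date")["level"].sort_index()
    expr = expression_series.sort_index()
    if list(meth.index) != list(expr.index):
        raise ValueError(
            f"date mismatch between methylation ({list(meth.index)}) and "
            f"expression ({list(expr.index)})")
    if len(meth) < 3:
        raise ValueError("need at least 3 shared dates")
    paired = pd.DataFrame({"date": meth.index, "methylation": meth.to_numpy(),
                           "expression": expr.to_numpy()})
    if meth.nunique() <= 1 or expr.nunique() <= 1:
        paired.attrs["correlation_defined"] = False
        return paired, float("nan")
    r, _ = pearsonr(paired["methylation"], paired["expression"])
    paired.attrs["correlation_defined"] = True
    return paired, float(r)
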