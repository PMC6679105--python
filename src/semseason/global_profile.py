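"""Bulk, windowed and per-feature methylation summaries.

All levels are *pooled* ratios: Σ methylated calls / Σ total calls over the
site-date observations of a region, never a mean of per-site ratios.  A
level over a set of observations with zero total coverage is undefined and
reported as NaN, never as 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import CONTEXTS, GenomeAnnotation, MethylomeSeries

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000


def methylation_level(counts) -> float:
    """Pooled methylation level of a collection of (n_meth, n_unmeth) pairs.

    Returns NaN when every pair has zero total — the level is undefined for
    an uncovered region, not zero.
    """
    arr = np.asarray(list(counts), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected pairs of (n_meth, n_unmeth)")
    if (arr < 0).any():
        raise ValueError("negative counts")
    total = arr.sum()
    if total == 0:
        return float("nan")
    return float(arr[:, 0].sum() / total)


def bulk_levels(series: MethylomeSeries) -> pd.DataFrame:
    """Pooled methylation level per (context, date) over the whole series.

    Contexts absent from the series are absent from the result, not zero.
    """
    if series.n_sites == 0:
        raise ValueError("empty methylome series")
    rows = []
    ctx = series.sites["context"].to_numpy()
    for c in CONTEXTS:
        mask = ctx == c
        if not mask.any():
            continue
        m = series.meth[mask].sum(axis=0).astype(float)
        t = series.total[mask].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lvl = np.where(t > 0, m / t, np.nan)
        for d, x, nt in zip(series.dates, lvl, t):
            rows.append((c, d, x, int(mask.sum()), int(nt)))
    return pd.DataFrame(rows, columns=["context", "date", "level", "n_sites",
                                       "n_calls"])


def conversion_rate(series: MethylomeSeries, spike_in: str) -> pd.DataFrame:
    """Bisulfite conversion rate per date from the unmethylated spike-in.

    rate = 1 − pooled methylation level over all spike-in sites (any
    context).  The spike-in carries no true methylation, so residual
    methylated calls measure conversion failure.
    """
    sub = series.for_sequences([spike_in])
    if sub.n_sites == 0:
        raise ValueError(f"no spike-in sites on contig {spike_in!r}")
    m = sub.meth.sum(axis=0).astype(float)
    t = sub.total.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(t > 0, 1.0 - m / t, np.nan)
    return pd.DataFrame({"date": sub.dates, "conversion_rate": rate,
                         "n_calls": t.astype(int)})


def window_profiles(series: MethylomeSeries, annotation: GenomeAnnotation,
                    window_size: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Fixed-width tiling window profiles of methylation and repeat density.

    Windows tile each sequence as [k·w, (k+1)·w), last window truncated; a
    site belongs to the window containing its position, so sites are
    conserved exactly across windows.  Repeat density is merged-repeat
    covered bp divided by the window span.  Returns a long DataFrame with
    one row per (window, context, date); the level is NaN where the window
    has no covered site of that context.
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    # repeat density per window
    density: dict[tuple[str, int], float] = {}
    spans: dict[tuple[str, int], tuple[int, int]] = {}
    for seq_id, length in annotation.sequences.items():
        n_win = -(-length // window_size)
        merged = annotation.merged_repeats(seq_id)
        cov = np.zeros(n_win)
        for s, e in merged:
            for k in range(s // window_size, (e - 1) // window_size + 1):
                ws, we = k * window_size, min((k + 1) * window_size, length)
                cov[k] += max(0, min(e, we) - max(s, ws))
        for k in range(n_win):
            ws, we = k * window_size, min((k + 1) * window_size, length)
            spans[(seq_id, k)] = (ws, we)
            density[(seq_id, k)] = cov[k] / (we - ws)

    df = series.sites.copy()
    df["window"] = df["pos"] // window_size
    rows = []
    for (seq_id, k, ctx), idx in df.groupby(
            ["seq_id", "window", "context"]).groups.items():
        idx = np.asarray(idx)
        m = series.meth[idx].sum(axis=0).astype(float)
        t = series.total[idx].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lvl = np.where(t > 0, m / t, np.nan)
        ws, we = spans[(seq_id, k)]
        for d, x in zip(series.dates, lvl):
            rows.append((seq_id, ws, we, density[(seq_id, k)], ctx, d, x,
                         len(idx)))
    return pd.DataFrame(rows, columns=["seq_id", "start", "end",
                                       "repeat_density", "context", "date",
                                       "level", "n_sites"])


def window_correlation(profiles: pd.DataFrame, context: str,
                       date: str) -> float:
    """Pearson r between repeat density and methylation level across windows."""
    sub = profiles[(profiles["context"] == context) &
                   (profiles["date"] == date)].dropna(subset=["level"])
    if len(sub) < 3:
        raise ValueError(
            f"need at least 3 windows with a defined level, got {len(sub)}")
    x = sub["repeat_density"].to_numpy(float)
    y = sub["level"].to_numpy(float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance: window correlation is undefined")
    return float(np.corrcoef(x, y)[0, 1])


def feature_series(series: MethylomeSeries, annotation: GenomeAnnotation,
                   features: str = "repeat", context: str = "CHH",
                   families: list[str] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature pooled seasonal methylation series for one context.

    ``features`` selects gene or repeat intervals; for repeats, ``families``
    optionally restricts to e.g. ["LTR/Copia"].  Features with no site of
    the requested context are excluded (with a log line).  Returns the
    per-feature long table and the per-family summary whose statistic is the
    *median across features* of the pooled level, per date.
    """
    if features not in ("gene", "repeat"):
        raise ValueError(f"features must be 'gene' or 'repeat', got {features!r}")
    feat_df = annotation.repeats if features == "repeat" else annotation.genes
    id_col = "repeat_id" if features == "repeat" else "gene_id"
    if families is not None and features == "repeat":
        feat_df = feat_df[feat_df["family"].isin(families)]
    if not len(feat_df):
        raise ValueError("no features to profile")

    sub = series.for_context(context)
    hits = annotation.overlapping_feature(sub.sites, features)
    if features == "repeat" and families is not None:
        keep_ids = set(feat_df[id_col])
        hits = hits[hits["feature_id"].isin(keep_ids)]
    fam = (dict(zip(annotation.repeats["repeat_id"],
                    annotation.repeats["family"]))
           if features == "repeat" else {})

    rows = []
    seen = set()
    for fid, grp in hits.groupby("feature_id"):
        idx = grp["site_index"].to_numpy()
        m = sub.meth[idx].sum(axis=0).astype(float)
        t = sub.total[idx].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lvl = np.where(t > 0, m / t, np.nan)
        for d, x in zip(sub.dates, lvl):
            rows.append((fid, fam.get(fid, features), d, x, len(idx)))
        seen.add(fid)
    skipped = set(feat_df[id_col]) - seen
    if skipped:
        log.info("%d %s feature(s) without %s sites excluded: %s",
                 len(skipped), features, context,
                 sorted(skipped)[:5])
    per_feature = pd.DataFrame(
        rows, columns=["feature_id", "family", "date", "level", "n_sites"])
    if len(per_feature):
        med = (per_feature.groupby(["family", "date"], sort=True)["level"]
               .agg(median_level="median", n_features="count").reset_index())
    else:
        med = pd.DataFrame(columns=["family", "date", "median_level",
                                    "n_features"])
    return per_feature, med


def gene_repeat_comparison(series: MethylomeSeries,
                           annotation: GenomeAnnotation) -> pd.DataFrame:
    """Pooled level per context/date for repeat sites vs genic sites.

    Sites inside both a gene and a repeat (intragenic repeats) count as
    repeat only, so the genic class is not inflated by its heterochromatic
    islands.
    """
    in_rep = annotation.in_repeat(series.sites)
    gene_hits = annotation.overlapping_feature(series.sites, "gene")
    in_gene = np.zeros(series.n_sites, dtype=bool)
    if len(gene_hits):
        in_gene[gene_hits["site_index"].unique()] = True
    classes = {"repeat": in_rep, "gene": in_gene & ~in_rep}
    rows = []
    ctx = series.sites["context"].to_numpy()
    for cls, mask in classes.items():
        for c in CONTEXTS:
            sel = mask & (ctx == c)
            if not sel.any():
                continue
            m = series.meth[sel].sum(axis=0).astype(float)
            t = series.total[sel].sum(axis=0).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                lvl = np.where(t > 0, m / t, np.nan)
            for d, x in zip(series.dates, lvl):
                rows.append((cls, c, d, x, int(sel.sum())))
    return pd.DataFrame(rows, columns=["region", "context", "date", "level",
                                       "n_sites"])
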