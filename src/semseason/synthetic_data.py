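"""Synthetic multi-timepoint methylome, annotation and expression generator.

The generator emulates the statistical structure of a year-round
whole-genome bisulfite study of a clonal perennial plant: eight sampling
dates at ~1.5-month intervals, context-specific baseline methylation
(CG ≈ 0.45, CHG ≈ 0.20, CHH ≈ 0.06), repeat-dense heterochromatic blocks
with elevated methylation, a small fraction of seasonally methylated
cytosines (SeMCs) with a single seasonal peak, an unmethylated spike-in
contig for the bisulfite-conversion check, and gene expression whose
seasonal range shrinks with gene-body CG methylation (gbM).

Counts are Poisson-depth / binomial-methylation draws, under which Fisher's
exact test comparing two dates at one site is correctly calibrated; a
bisulfite conversion failure flips a truly unmethylated call to methylated
with a small probability.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation, MethylomeSeries, cytosine_sites

#: the eight leaf-sampling dates of the emulated study year
STUDY_DATES = (
    "2014-11-11", "2014-12-22", "2015-02-09", "2015-03-24",
    "2015-05-07", "2015-06-23", "2015-07-28", "2015-09-08",
)

REPEAT_FAMILIES = (
    "LTR/Copia", "LTR/Gypsy", "LINE/L1", "DNA/MULE-MuDR", "DNA/hAT",
    "RC/Helitron", "SINE/tRNA",
)

_DAYS_PER_YEAR = 365.25


def date_angle(dates: Sequence[str]) -> np.ndarray:
    """Circular position of each calendar date within the year, in radians."""
    out = np.empty(len(dates))
    for i, d in enumerate(dates):
        dt = datetime.date.fromisoformat(d)
        doy = dt.timetuple().tm_yday
        out[i] = 2.0 * np.pi * doy / _DAYS_PER_YEAR
    return out


def seasonal_bump(dates: Sequence[str], peak_date: str,
                  sharpness: float = 4.0) -> np.ndarray:
    """Unit-height single-peak seasonal bump evaluated at sampling dates.

    A von Mises-style cosine bump ``exp(κ(cos Δθ − 1))`` on the circle of the
    year: 1 at the peak date, decaying symmetrically with distance.  κ = 4
    separates adjacent 1.5-month sampling dates clearly (the bump drops to
    ≈ 0.35 one sampling interval away) while remaining a smooth single peak.
    """
    theta = date_angle(dates)
    peak = date_angle([peak_date])[0]
    return np.exp(sharpness * (np.cos(theta - peak) - 1.0))


def _default_baseline() -> dict[str, float]:
    return {"CG": 0.45, "CHG": 0.20, "CHH": 0.06}


def _default_boost() -> dict[str, float]:
    return {"CG": 0.35, "CHG": 0.35, "CHH": 0.15}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the emulated conditions."""

    seed: int = 0
    # genome shape
    n_sequences: int = 4
    seq_length: int = 150_000
    block_size: int = 25_000
    repeat_fraction_dense: float = 0.60
    repeat_fraction_sparse: float = 0.05
    gc_content: float = 0.36
    # methylation model
    baseline_level: dict[str, float] = field(default_factory=_default_baseline)
    repeat_boost: dict[str, float] = field(default_factory=_default_boost)
    regional_sd: float = 0.25
    regional_segment: int = 5_000
    dates: tuple[str, ...] = STUDY_DATES
    coverage_mean: float = 20.0
    semc_fraction: float = 0.005
    semc_amplitude: float = 0.4
    peak_sharpness: float = 4.0
    semc_contexts: tuple[str, ...] | None = None
    semc_placement: str = "any"  # any | repeat | repeat_intergenic
    semc_peak_date: str | None = None
    # genes and expression
    n_genes: int = 40
    gene_length_min: int = 1_500
    gene_length_max: int = 3_000
    max_exons: int = 6
    gbm_coupling: float = 1.0
    expr_amplitude_max: float = 2.0
    expr_mean_base: float = 2.0
    expr_mean_slope: float = 1.5
    expr_noise_sd: float = 0.3
    expression_dates: tuple[str, ...] | None = None
    # controls
    spike_in_length: int = 5_000
    spike_in_name: str = "lambda_spikein"
    conversion_failure_rate: float = 0.005

    def validate(self) -> list[str]:
        """Return a list of human-readable constraint violations (empty = ok)."""
        v = []
        for name in ("repeat_fraction_dense", "repeat_fraction_sparse",
                     "gc_content", "semc_fraction", "semc_amplitude",
                     "conversion_failure_rate", "gbm_coupling"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                v.append(f"{name} must be in [0, 1], got {x}")
        for ctx, p in {**self.baseline_level, **self.repeat_boost}.items():
            if not 0.0 <= p <= 1.0:
                v.append(f"level for context {ctx} must be in [0, 1], got {p}")
        if self.coverage_mean <= 0:
            v.append(f"coverage_mean must be > 0, got {self.coverage_mean}")
        if len(self.dates) < 2:
            v.append("at least two sampling dates are required")
        if list(self.dates) != sorted(set(self.dates)):
            v.append("dates must be strictly increasing")
        if self.semc_placement not in ("any", "repeat", "repeat_intergenic"):
            v.append(f"unknown semc_placement {self.semc_placement!r}")
        if self.semc_peak_date is not None and \
                self.semc_peak_date not in self.dates:
            v.append("semc_peak_date must be one of the sampling dates")
        for name in ("n_sequences", "seq_length", "block_size", "n_genes",
                     "spike_in_length"):
            if getattr(self, name) < 0 or (name != "n_genes"
                                           and getattr(self, name) == 0):
                v.append(f"{name} must be positive, got {getattr(self, name)}")
        return v

    def require_valid(self) -> "SimulationConfig":
        violations = self.validate()
        if violations:
            raise ValueError("invalid simulation config: " + "; ".join(violations))
        return self

    def rng(self, stage: str) -> np.random.Generator:
        """Independent deterministic stream per pipeline stage."""
        stage_id = {"genome": 1, "methylome": 2, "expression": 3}[stage]
        return np.random.default_rng(np.random.SeedSequence(
            entropy=int(self.seed), spawn_key=(stage_id,)))

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationTruth:
    """Planted ground truth: per-site seasonal model and per-gene couplings.

    ``sites`` columns: seq_id, pos (0-based), strand, context, in_repeat,
    in_gene, is_semc, peak_date.  ``probs`` is the realized per-site,
    per-date true methylation probability matrix aligned with ``sites``.
    ``genes`` columns: gene_id, gbm plus (after expression simulation)
    expr_mean, expr_amplitude, expr_phase, true_average, true_range.
    """

    sites: pd.DataFrame
    probs: np.ndarray
    genes: pd.DataFrame
    dates: tuple[str, ...]


def _random_sequence(rng: np.random.Generator, length: int,
                     gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def _place_repeats(rng, seq_id, block_start, block_end, fraction, rows):
    """Fill one block with non-overlapping repeats up to a target density."""
    target = fraction * (block_end - block_start)
    covered = 0
    cursor = block_start
    while covered < target:
        gap = int(rng.exponential(300.0)) + 1
        length = int(rng.integers(100, 2000))
        start = cursor + gap
        end = start + length
        if end > block_end:
            break
        family = REPEAT_FAMILIES[int(rng.integers(len(REPEAT_FAMILIES)))]
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((seq_id, start, end, family, strand))
        covered += length
        cursor = end


def _place_genes(rng, config, seq_ids, repeat_rows):
    """Place non-overlapping genes outside repeats, with exon/intron structure."""
    by_seq: dict[str, list[tuple[int, int]]] = {s: [] for s in seq_ids}
    for seq_id, start, end, _, _ in repeat_rows:
        by_seq[seq_id].append((start, end))
    free: list[tuple[str, int, int]] = []
    for seq_id in seq_ids:
        blocks = sorted(by_seq[seq_id])
        cursor = 0
        for s, e in blocks + [(config.seq_length, config.seq_length)]:
            if s - cursor >= config.gene_length_max + 200:
                free.append((seq_id, cursor, s))
            cursor = max(cursor, e)
    genes, exons = [], []
    order = rng.permutation(len(free))
    gi = 0
    for idx in order:
        if gi >= config.n_genes:
            break
        seq_id, lo, hi = free[idx]
        cursor = lo + 100
        while gi < config.n_genes:
            length = int(rng.integers(config.gene_length_min,
                                      config.gene_length_max + 1))
            if cursor + length + 100 > hi:
                break
            gid = f"g{gi + 1:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((gid, seq_id, cursor, cursor + length, strand))
            n_ex = int(rng.integers(2, config.max_exons + 1))
            w = rng.random(2 * n_ex - 1) + 0.25
            seg = np.floor(w / w.sum() * length).astype(int)
            seg[-1] = length - seg[:-1].sum()
            p = cursor
            for j, s in enumerate(seg):
                if j % 2 == 0:  # exon
                    exons.append((gid, seq_id, p, p + max(int(s), 1)))
                p += int(s)
            gi += 1
            cursor += length + int(rng.integers(200, 800))
    if gi < config.n_genes:
        raise ValueError(
            f"genome too small to place {config.n_genes} genes "
            f"(placed {gi}); increase seq_length or lower repeat density"
        )
    return genes, exons


def simulate_genome(config: SimulationConfig
                    ) -> tuple[dict[str, str], GenomeAnnotation]:
    """Toy annotated genome: alternating repeat-dense / genic blocks plus an
    unannotated, fully unmethylated spike-in contig."""
    config.require_valid()
    rng = config.rng("genome")
    genome: dict[str, str] = {}
    seq_ids = [f"scaffold_{i + 1}" for i in range(config.n_sequences)]
    repeat_rows: list[tuple] = []
    for si, seq_id in enumerate(seq_ids):
        genome[seq_id] = _random_sequence(rng, config.seq_length,
                                          config.gc_content)
        n_blocks = -(-config.seq_length // config.block_size)
        for b in range(n_blocks):
            dense = (b + si) % 2 == 0
            frac = (config.repeat_fraction_dense if dense
                    else config.repeat_fraction_sparse)
            _place_repeats(rng, seq_id, b * config.block_size,
                           min((b + 1) * config.block_size, config.seq_length),
                           frac, repeat_rows)
    genes, exons = _place_genes(rng, config, seq_ids, repeat_rows)
    genome[config.spike_in_name] = _random_sequence(
        rng, config.spike_in_length, 0.5)

    sequences = {s: len(seq) for s, seq in genome.items()}
    repeats_df = pd.DataFrame(
        [(f"rep{i:06d}", s, a, b, fam, st)
         for i, (s, a, b, fam, st) in enumerate(repeat_rows)],
        columns=["repeat_id", "seq_id", "start", "end", "family", "strand"],
    )
    genes_df = pd.DataFrame(
        genes, columns=["gene_id", "seq_id", "start", "end", "strand"])
    exons_df = pd.DataFrame(exons, columns=["gene_id", "seq_id", "start", "end"])
    return genome, GenomeAnnotation(sequences, genes_df, exons_df, repeats_df)


def sample_counts(probs: np.ndarray, coverage_mean: float,
                  conversion_failure_rate: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (meth, total) counts: depth ~ Poisson, methylated ~ Binomial.

    A truly unmethylated call reads as methylated with probability
    ``conversion_failure_rate`` (incomplete bisulfite conversion), so the
    observed probability is ``p + (1 − p)·failure``.
    """
    depth = rng.poisson(coverage_mean, size=probs.shape)
    p_obs = probs + (1.0 - probs) * conversion_failure_rate
    meth = rng.binomial(depth, p_obs)
    return meth, depth


def simulate_methylome(config: SimulationConfig, genome: Mapping[str, str],
                       annotation: GenomeAnnotation
                       ) -> tuple[dict[str, pd.DataFrame], SimulationTruth]:
    """T per-date cytosine count reports plus the planted ground truth.

    The per-site stable level is ``baseline[context] + repeat_boost`` inside
    repeats (gene-body CG sites instead take the gene's planted gbM level),
    scaled by a log-normal regional effect that is constant in time; SeMC
    sites add a seasonal bump of height ``semc_amplitude`` peaking at their
    assigned date.  The spike-in contig is fully unmethylated.
    """
    config.require_valid()
    rng = config.rng("methylome")
    dates = list(config.dates)

    frames = []
    for seq_id, seq in genome.items():
        df = cytosine_sites(seq, seq_id=seq_id)
        frames.append(df)
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.sort_values(["seq_id", "pos", "strand"],
                              kind="mergesort").reset_index(drop=True)
    n = len(sites)
    is_spike = (sites["seq_id"] == config.spike_in_name).to_numpy()

    in_repeat = np.zeros(n, dtype=bool)
    in_repeat[~is_spike] = annotation.in_repeat(sites[~is_spike])
    sites["in_repeat"] = in_repeat

    # stable (non-seasonal) level
    base = np.array([config.baseline_level[c] for c in sites["context"]])
    boost = np.array([config.repeat_boost[c] for c in sites["context"]])
    level = base + boost * in_repeat

    # planted per-gene gbM overrides the baseline of gene-body CG sites
    genes_df = annotation.genes.reset_index(drop=True).copy()
    gbm = rng.uniform(0.0, 0.9, size=len(genes_df))
    genes_df["gbm"] = gbm
    gene_hits = annotation.overlapping_feature(sites[~is_spike], "gene")
    site_gene = np.full(n, "", dtype=object)
    if len(gene_hits):
        abs_idx = np.flatnonzero(~is_spike)[gene_hits["site_index"].to_numpy()]
        site_gene[abs_idx] = gene_hits["feature_id"].to_numpy()
    sites["gene_id"] = site_gene
    gbm_by_gene = dict(zip(genes_df["gene_id"], genes_df["gbm"]))
    cg_in_gene = (site_gene != "") & (sites["context"].to_numpy() == "CG")
    level[cg_in_gene] = [gbm_by_gene[g] for g in site_gene[cg_in_gene]]

    # regional multiplicative heterogeneity (constant across dates);
    # gene-body CG sites keep their planted gbM level exactly
    if config.regional_sd > 0:
        seg_key = pd.Series(
            sites["seq_id"].astype(str) + ":" +
            (sites["pos"] // config.regional_segment).astype(str))
        codes, _ = pd.factorize(seg_key, sort=True)
        eta = rng.normal(0.0, config.regional_sd, size=codes.max() + 1)
        mult = np.exp(eta[codes] - config.regional_sd ** 2 / 2.0)
        mult[cg_in_gene] = 1.0
        level = level * mult
    level = np.clip(level, 0.0, 1.0)
    level[is_spike] = 0.0

    # choose SeMC sites among eligible positions
    eligible = ~is_spike & (level <= 1.0 - config.semc_amplitude)
    if config.semc_contexts is not None:
        eligible &= sites["context"].isin(config.semc_contexts).to_numpy()
    if config.semc_placement in ("repeat", "repeat_intergenic"):
        eligible &= in_repeat
    if config.semc_placement == "repeat_intergenic":
        eligible &= site_gene == ""
    n_semc = int(round(config.semc_fraction * (~is_spike).sum()))
    pool = np.flatnonzero(eligible)
    n_semc = min(n_semc, pool.size)
    semc_idx = rng.choice(pool, size=n_semc, replace=False) if n_semc else \
        np.empty(0, dtype=int)
    is_semc = np.zeros(n, dtype=bool)
    is_semc[semc_idx] = True
    peak_dates = np.full(n, "", dtype=object)
    if n_semc:
        if config.semc_peak_date is not None:
            peak_dates[semc_idx] = config.semc_peak_date
        else:
            peak_dates[semc_idx] = rng.choice(np.array(dates), size=n_semc)

    probs = np.repeat(level[:, None], len(dates), axis=1)
    if n_semc:
        bumps = {d: seasonal_bump(dates, d, config.peak_sharpness)
                 for d in dates}
        for i in semc_idx:
            probs[i] = np.clip(
                level[i] + config.semc_amplitude * bumps[peak_dates[i]],
                0.0, 1.0)

    meth, total = sample_counts(probs, config.coverage_mean,
                                config.conversion_failure_rate, rng)

    sites["is_semc"] = is_semc
    sites["peak_date"] = peak_dates
    reports = {}
    base_cols = sites[["seq_id", "pos", "strand", "context",
                       "trinucleotide"]].copy()
    base_cols["pos"] = base_cols["pos"] + 1  # report dialect is 1-based
    for t, date in enumerate(dates):
        rep = base_cols.copy()
        rep["n_meth"] = meth[:, t]
        rep["n_unmeth"] = total[:, t] - meth[:, t]
        reports[date] = rep[["seq_id", "pos", "strand", "n_meth", "n_unmeth",
                             "context", "trinucleotide"]]
    truth = SimulationTruth(
        sites=sites[["seq_id", "pos", "strand", "context", "in_repeat",
                     "gene_id", "is_semc", "peak_date"]].copy(),
        probs=probs, genes=genes_df, dates=tuple(dates))
    return reports, truth


def simulate_expression(config: SimulationConfig,
                        annotation: GenomeAnnotation,
                        truth: SimulationTruth) -> pd.DataFrame:
    """Per-gene seasonal expression (log2(RPM+1)) coupled to planted gbM.

    Each gene follows ``mean(g) + A(g)·cos(θ − phase) + noise`` with seasonal
    amplitude ``A(g) = A_max·max(0, 1 − coupling·g)`` decreasing in gbM and a
    weakly increasing mean; negative draws are clipped at 0 (the scale is
    log2(RPM+1) ≥ 0).  Updates ``truth.genes`` with the noiseless seasonal
    average and range, and returns the genes × dates expression matrix.
    """
    config.require_valid()
    rng = config.rng("expression")
    dates = list(config.expression_dates or config.dates)
    theta = date_angle(dates)
    genes = truth.genes
    if not len(genes):
        raise ValueError("no genes to simulate expression for")
    g = genes["gbm"].to_numpy()
    amp = config.expr_amplitude_max * np.clip(1.0 - config.gbm_coupling * g,
                                              0.0, None)
    mean = config.expr_mean_base + config.expr_mean_slope * g
    phase = rng.uniform(0.0, 2.0 * np.pi, size=len(genes))
    clean = mean[:, None] + amp[:, None] * np.cos(theta[None, :] -
                                                  phase[:, None])
    clean = np.clip(clean, 0.0, None)
    expr = clean + rng.normal(0.0, config.expr_noise_sd, size=clean.shape)
    expr = np.clip(expr, 0.0, None)
    genes["expr_mean"] = mean
    genes["expr_amplitude"] = amp
    genes["expr_phase"] = phase
    genes["true_average"] = clean.mean(axis=1)
    genes["true_range"] = clean.max(axis=1) - clean.min(axis=1)
    out = pd.DataFrame(expr, index=genes["gene_id"].to_numpy(), columns=dates)
    out.index.name = "gene_id"
    return out


def truth_series(truth: SimulationTruth, reports: Mapping[str, pd.DataFrame]
                 ) -> MethylomeSeries:
    """Assemble the simulated reports into a MethylomeSeries (fast path).

    Equivalent to writing the reports to disk and re-reading them through
    :func:`semseason.io_formats.build_series`; used when simulation and
    analysis run in one process.
    """
    from .io_formats import build_series

    dates = sorted(reports)
    return build_series([reports[d] for d in dates], dates)


def simulate_series(n_sites: int = 20_000, context: str = "CG",
                    baseline: float = 0.45, semc_fraction: float = 0.0,
                    amplitude: float = 0.4, coverage_mean: float = 20.0,
                    dates: Sequence[str] = STUDY_DATES,
                    peak_sharpness: float = 4.0,
                    conversion_failure_rate: float = 0.0,
                    seed: int = 0) -> tuple[MethylomeSeries, pd.DataFrame]:
    """Direct count-level simulator for calibration studies.

    Skips the genome layer entirely: ``n_sites`` independent sites of one
    context on a dummy contig, a fraction of which are planted SeMCs with a
    seasonal bump of the given amplitude and a random peak among the
    sampling dates.  Returns the series and a per-site truth table.
    """
    rng = np.random.default_rng(seed)
    dates = list(dates)
    t = len(dates)
    probs = np.full((n_sites, t), float(baseline))
    n_semc = int(round(semc_fraction * n_sites))
    idx = rng.choice(n_sites, size=n_semc, replace=False) if n_semc else \
        np.empty(0, dtype=int)
    peaks = np.full(n_sites, "", dtype=object)
    if n_semc:
        assigned = rng.choice(np.array(dates), size=n_semc)
        peaks[idx] = assigned
        bumps = {d: seasonal_bump(dates, d, peak_sharpness) for d in dates}
        for i, d in zip(idx, assigned):
            probs[i] = np.clip(baseline + amplitude * bumps[d], 0.0, 1.0)
    meth, total = sample_counts(probs, coverage_mean,
                                conversion_failure_rate, rng)
    sites = pd.DataFrame({
        "seq_id": "sim_contig", "pos": np.arange(n_sites) * 10,
        "strand": "+", "context": context,
    })
    truth = sites.copy()
    truth["is_semc"] = False
    truth.loc[idx, "is_semc"] = True
    truth["peak_date"] = peaks
    series = MethylomeSeries(sites, meth, total, dates)
    return series, truth
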