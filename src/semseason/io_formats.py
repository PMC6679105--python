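"""Readers, writers and core containers for the methylome pipeline.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open.  The two 1-based dialects
(per-cytosine count reports and GFF3) are converted at the I/O boundary and
converted back on write.

The per-cytosine count report is a 7-column TSV (comment lines start with
``#``)::

    seq_id  pos(1-based)  strand  n_meth  n_unmeth  context  trinucleotide

which is the Bismark "CX report" column layout with methylated/unmethylated
call counts in columns 4-5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REPORT_COLUMNS = [
    "seq_id",
    "pos",
    "strand",
    "n_meth",
    "n_unmeth",
    "context",
    "trinucleotide",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def classify_trinucleotide(tri: str) -> str | None:
    """Classify a 3-mer read 5'→3' on the cytosine's own strand.

    Returns ``CG``, ``CHG`` or ``CHH``; ``None`` if the 3-mer is incomplete
    or contains a non-ACGT base.  The first base must be C.
    """
    if len(tri) != 3 or any(b not in "ACGT" for b in tri):
        return None
    if tri[0] != "C":
        raise ValueError(f"trinucleotide {tri!r} does not start with C")
    if tri[1] == "G":
        return "CG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


def assign_context(sequence: str, seq_id: str, pos: int, strand: str) -> str | None:
    """Sequence context of the cytosine at 1-based ``pos`` on ``strand``.

    The context is read from the two bases downstream of the cytosine in the
    5'→3' direction of its own strand.  Returns ``None`` when the 3-mer runs
    off the sequence end or contains a non-ACGT base.
    """
    if strand not in STRANDS:
        raise ValueError(f"unknown strand {strand!r}")
    if pos < 1 or pos > len(sequence):
        raise ValueError(
            f"position {pos} out of bounds for sequence {seq_id!r} "
            f"of length {len(sequence)}"
        )
    i = pos - 1
    base = sequence[i].upper()
    expected = "C" if strand == "+" else "G"
    if base != expected:
        raise ValueError(
            f"{seq_id}:{pos}({strand}) is {base!r}, not a cytosine on that strand"
        )
    if strand == "+":
        tri = sequence[i : i + 3].upper()
        if len(tri) < 3:
            return None
    else:
        if i - 2 < 0:
            return None
        tri = revcomp(sequence[i - 2 : i + 1].upper())
    if any(b not in "ACGT" for b in tri):
        return None
    return classify_trinucleotide(tri)


# uint8 codes of the four bases as they appear in ASCII byte arrays
_A, _C, _G, _T = 65, 67, 71, 84


def cytosine_sites(sequence: str, seq_id: str = "") -> pd.DataFrame:
    """All cytosine sites of a sequence on both strands, with context.

    Returns a DataFrame with columns ``pos`` (0-based forward coordinate of
    the cytosine), ``strand``, ``context`` and ``trinucleotide``; sites whose
    context is undefined (edge of sequence, or an N in the 3-mer) are
    excluded.  Vectorised so that chromosome-scale sequences are cheap.
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    n = arr.size
    known = np.isin(arr, (_A, _C, _G, _T))

    frames = []
    # forward strand: C with two valid downstream bases
    fwd = np.flatnonzero(arr[: max(n - 2, 0)] == _C)
    if fwd.size:
        ok = known[fwd + 1] & known[fwd + 2]
        fwd = fwd[ok]
        ctx = np.where(
            arr[fwd + 1] == _G, "CG", np.where(arr[fwd + 2] == _G, "CHG", "CHH")
        )
        frames.append(
            pd.DataFrame({"pos": fwd, "strand": "+", "context": ctx})
        )
    # minus strand: forward-strand G with two valid upstream bases
    rev = np.flatnonzero(arr == _G)
    rev = rev[rev >= 2]
    if rev.size:
        ok = known[rev - 1] & known[rev - 2]
        rev = rev[ok]
        # downstream bases on the minus strand are complements of pos-1, pos-2
        ctx = np.where(
            arr[rev - 1] == _C, "CG", np.where(arr[rev - 2] == _C, "CHG", "CHH")
        )
        frames.append(
            pd.DataFrame({"pos": rev, "strand": "-", "context": ctx})
        )
    if not frames:
        return pd.DataFrame(
            {"pos": pd.Series(dtype=np.int64), "strand": pd.Series(dtype=object),
             "context": pd.Series(dtype=object),
             "trinucleotide": pd.Series(dtype=object)}
        )
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)
    tris = []
    for p, s in zip(df["pos"].to_numpy(), df["strand"].to_numpy()):
        if s == "+":
            tris.append(sequence[p : p + 3].upper())
        else:
            tris.append(revcomp(sequence[p - 2 : p + 1].upper()))
    df["trinucleotide"] = tris
    if seq_id:
        df.insert(0, "seq_id", seq_id)
    return df


@dataclass
class CytosineRecord:
    """One line of a per-cytosine count report (1-based position)."""

    seq_id: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int
    context: str
    trinucleotide: str


def read_cytosine_report(path, genome: Mapping[str, str] | None = None,
                         strict: bool = False) -> pd.DataFrame:
    """Read a 7-column per-cytosine count report into a DataFrame.

    Positions stay 1-based in the returned frame (this is the file dialect;
    :func:`build_series` converts to internal coordinates).  If ``genome`` is
    given, the stated context of every site is re-derived from the sequence;
    mismatching sites are reported in ``df.attrs['context_mismatches']`` and
    logged (raised if ``strict``).
    """
    with open(path) as fh:
        n_leading_comments = 0
        for line in fh:
            if line.startswith("#"):
                n_leading_comments += 1
            else:
                break
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=REPORT_COLUMNS,
            dtype={"seq_id": str, "strand": str, "context": str,
                   "trinucleotide": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed cytosine report {path}: {exc}") from exc

    def _line(i: int) -> int:
        return int(i) + n_leading_comments + 1

    for col in ("pos", "n_meth", "n_unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise ValueError(
                f"{path}: non-integer {col} at line {_line(bad.idxmax())}"
            )
        df[col] = vals.astype(np.int64)
    neg = (df["n_meth"] < 0) | (df["n_unmeth"] < 0) | (df["pos"] < 1)
    if neg.any():
        raise ValueError(f"{path}: negative count or position at line "
                         f"{_line(neg.idxmax())}")
    bad_strand = ~df["strand"].isin(STRANDS)
    if bad_strand.any():
        raise ValueError(
            f"{path}: unknown strand token "
            f"{df.loc[bad_strand.idxmax(), 'strand']!r} at line "
            f"{_line(bad_strand.idxmax())}"
        )
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        raise ValueError(
            f"{path}: unknown context token "
            f"{df.loc[bad_ctx.idxmax(), 'context']!r} at line "
            f"{_line(bad_ctx.idxmax())}"
        )

    if genome is not None:
        mism = []
        for row in df.itertuples(index=False):
            derived = assign_context(genome[row.seq_id], row.seq_id, row.pos,
                                     row.strand)
            if derived != row.context:
                mism.append((row.seq_id, row.pos, row.strand, row.context,
                             derived))
        mism_df = pd.DataFrame(
            mism, columns=["seq_id", "pos", "strand", "stated", "derived"]
        )
        df.attrs["context_mismatches"] = mism_df
        if len(mism_df):
            msg = (f"{path}: {len(mism_df)} site(s) whose stated context "
                   f"disagrees with the genome: "
                   f"{mism_df.head(10).to_dict('records')}")
            if strict:
                raise ValueError(msg)
            log.warning(msg)
    return df


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    """Write a report DataFrame (1-based positions) back to the TSV dialect."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(REPORT_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False,
                  columns=REPORT_COLUMNS)


@dataclass
class MethylomeSeries:
    """Per-cytosine methylated/total counts at each of T sampling dates.

    ``sites`` has columns ``seq_id, pos (0-based), strand, context`` and is
    row-aligned with the ``meth`` and ``total`` count matrices of shape
    ``(n_sites, T)``.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    dates: list[str]

    def __post_init__(self) -> None:
        if len(self.dates) < 2:
            raise ValueError("a methylome series needs at least two dates")
        if list(self.dates) != sorted(set(self.dates)):
            raise ValueError("dates must be strictly increasing")
        n, t = self.meth.shape
        if self.total.shape != (n, t) or len(self.sites) != n or t != len(self.dates):
            raise ValueError("sites/counts/dates shapes are inconsistent")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_dates(self) -> int:
        return len(self.dates)

    def ratios(self) -> np.ndarray:
        """Per-date methylation ratios; NaN where a site has no coverage."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / self.total, np.nan)

    def subset(self, mask) -> "MethylomeSeries":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return MethylomeSeries(
            self.sites.iloc[idx].reset_index(drop=True),
            self.meth[idx], self.total[idx], list(self.dates),
        )

    def for_context(self, context: str) -> "MethylomeSeries":
        return self.subset(self.sites["context"].to_numpy() == context)

    def for_sequences(self, seq_ids: Iterable[str],
                      invert: bool = False) -> "MethylomeSeries":
        mask = self.sites["seq_id"].isin(list(seq_ids)).to_numpy()
        return self.subset(~mask if invert else mask)


def build_series(reports: Sequence[pd.DataFrame],
                 dates: Sequence[str]) -> MethylomeSeries:
    """Join T per-date count reports into one :class:`MethylomeSeries`.

    Sites are the union over reports; absent (site, date) pairs get (0, 0)
    counts.  Site order is deterministic (seq_id, pos, strand).  Conflicting
    context annotations for one site, or duplicate sites within one report,
    are errors.
    """
    if len(reports) != len(dates):
        raise ValueError("one report per date is required")
    key = ["seq_id", "pos", "strand"]
    frames = []
    for date, rep in zip(dates, reports):
        dup = rep.duplicated(subset=key)
        if dup.any():
            row = rep.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate site {row['seq_id']}:{row['pos']}({row['strand']}) "
                f"in report for {date}"
            )
        sub = rep[key + ["context", "n_meth", "n_unmeth"]].copy()
        sub["date"] = date
        frames.append(sub)
    cat = pd.concat(frames, ignore_index=True)
    ctx = cat.groupby(key, sort=False)["context"].nunique()
    if (ctx > 1).any():
        bad = ctx.index[ctx.to_numpy() > 1][0]
        raise ValueError(f"conflicting context annotations for site {bad}")

    wide_m = cat.pivot_table(index=key + ["context"], columns="date",
                             values="n_meth", fill_value=0, aggfunc="sum")
    wide_u = cat.pivot_table(index=key + ["context"], columns="date",
                             values="n_unmeth", fill_value=0, aggfunc="sum")
    wide_m = wide_m.reindex(columns=list(dates), fill_value=0).sort_index()
    wide_u = wide_u.reindex(columns=list(dates), fill_value=0).sort_index()
    sites = wide_m.index.to_frame(index=False)
    sites["pos"] = sites["pos"].astype(np.int64) - 1  # to internal 0-based
    meth = wide_m.to_numpy(dtype=np.int64)
    unmeth = wide_u.to_numpy(dtype=np.int64)
    return MethylomeSeries(sites.reset_index(drop=True), meth, meth + unmeth,
                           list(dates))


LOCATION_CLASSES = ("exon", "intron", "intergenic")


@dataclass
class GenomeAnnotation:
    """Gene (with exons) and repeat intervals over named sequences.

    All intervals 0-based half-open.  ``genes`` columns: gene_id, seq_id,
    start, end, strand.  ``exons`` columns: gene_id, seq_id, start, end.
    ``repeats`` columns: repeat_id, seq_id, start, end, family, strand.
    """

    sequences: dict[str, int]
    genes: pd.DataFrame
    exons: pd.DataFrame
    repeats: pd.DataFrame
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name, df in (("gene", self.genes), ("exon", self.exons),
                         ("repeat", self.repeats)):
            for row in df.itertuples(index=False):
                length = self.sequences.get(row.seq_id)
                if length is None:
                    raise ValueError(
                        f"{name} on unknown sequence {row.seq_id!r}")
                if not (0 <= row.start < row.end <= length):
                    raise ValueError(
                        f"{name} interval [{row.start}, {row.end}) outside "
                        f"sequence {row.seq_id!r} of length {length}")

    def _tree(self, which: str, seq_id: str) -> IntervalTree:
        cache_key = (which, seq_id)
        if cache_key not in self._trees:
            df = {"gene": self.genes, "exon": self.exons,
                  "repeat": self.repeats}[which]
            sub = df[df["seq_id"] == seq_id]
            tree = IntervalTree()
            id_col = "repeat_id" if which == "repeat" else "gene_id"
            for row in sub.itertuples(index=False):
                tree.addi(row.start, row.end, getattr(row, id_col))
            self._trees[cache_key] = tree
        return self._trees[cache_key]

    def locate(self, seq_id: str, pos: int) -> str:
        """Classify a 0-based point as exon, intron or intergenic.

        Precedence for overlapping annotations: exon > intron > intergenic.
        """
        if self._tree("exon", seq_id).overlaps_point(pos):
            return "exon"
        if self._tree("gene", seq_id).overlaps_point(pos):
            return "intron"
        return "intergenic"

    def locate_sites(self, sites: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(sites), dtype=object)
        for i, (s, p) in enumerate(zip(sites["seq_id"].to_numpy(),
                                       sites["pos"].to_numpy())):
            out[i] = self.locate(s, p)
        return out

    def overlapping_feature(self, sites: pd.DataFrame,
                            which: str) -> pd.DataFrame:
        """All (site index, feature id) overlap pairs for gene or repeat."""
        rows = []
        for i, (s, p) in enumerate(zip(sites["seq_id"].to_numpy(),
                                       sites["pos"].to_numpy())):
            for iv in self._tree(which, s).at(p):
                rows.append((i, iv.data))
        return pd.DataFrame(rows, columns=["site_index", "feature_id"])

    def in_repeat(self, sites: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(sites), dtype=bool)
        for i, (s, p) in enumerate(zip(sites["seq_id"].to_numpy(),
                                       sites["pos"].to_numpy())):
            out[i] = self._tree("repeat", s).overlaps_point(p)
        return out

    def merged_repeats(self, seq_id: str) -> list[tuple[int, int]]:
        """Repeat intervals of one sequence, overlaps merged, sorted."""
        sub = self.repeats[self.repeats["seq_id"] == seq_id]
        ivs = sorted(zip(sub["start"].to_numpy(), sub["end"].to_numpy()))
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into a name → sequence dict."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_annotation(gff3_path, repeat_bed_path=None,
                    min_repeat_len: int = 50,
                    sequences: Mapping[str, int] | None = None) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from GFF3 genes/exons and BED repeats.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Repeats shorter than ``min_repeat_len`` bp are dropped (the default of
    50 bp mirrors the convention of keeping only repeats of at least 50 bp).
    ``sequences`` supplies sequence lengths; without it they are taken from
    ``##sequence-region`` pragmas, falling back to the right-most feature end.
    """
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes, exons = [], []
    for gene in db.features_of_type("gene"):
        gid = gene.id
        gstart, gend = gene.start - 1, gene.end
        genes.append((gid, gene.seqid, gstart, gend, gene.strand))
        for exon in db.children(gene, featuretype="exon"):
            estart, eend = exon.start - 1, exon.end
            if estart < gstart or eend > gend:
                raise ValueError(
                    f"exon [{exon.start}, {exon.end}] outside the span of "
                    f"gene {gid} [{gene.start}, {gene.end}]"
                )
            exons.append((gid, exon.seqid, estart, eend))
    genes_df = pd.DataFrame(
        genes, columns=["gene_id", "seq_id", "start", "end", "strand"]
    )
    exons_df = pd.DataFrame(exons, columns=["gene_id", "seq_id", "start", "end"])

    if repeat_bed_path is not None:
        try:
            bed = pd.read_csv(repeat_bed_path, sep="\t", header=None,
                              comment="#")
        except pd.errors.EmptyDataError:
            bed = pd.DataFrame()
    else:
        bed = pd.DataFrame()
    if len(bed):
        bed = bed.rename(columns={0: "seq_id", 1: "start", 2: "end",
                                  3: "family", 4: "score", 5: "strand"})
        if "family" not in bed.columns:
            bed["family"] = "unknown"
        if "strand" not in bed.columns:
            bed["strand"] = "."
        keep = (bed["end"] - bed["start"]) >= min_repeat_len
        bed = bed[keep].reset_index(drop=True)
        repeats_df = pd.DataFrame({
            "repeat_id": [f"rep{i:06d}" for i in range(len(bed))],
            "seq_id": bed["seq_id"].astype(str),
            "start": bed["start"].astype(np.int64),
            "end": bed["end"].astype(np.int64),
            "family": bed["family"].astype(str),
            "strand": bed["strand"].astype(str),
        })
    else:
        repeats_df = pd.DataFrame(columns=["repeat_id", "seq_id", "start",
                                           "end", "family", "strand"])

    if sequences is None:
        sequences = {}
        with open(gff3_path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, name, start, end = line.split()[:4]
                    sequences[name] = int(end)
        for df in (genes_df, repeats_df):
            for row in df.itertuples(index=False):
                sequences[row.seq_id] = max(sequences.get(row.seq_id, 0),
                                            int(row.end))
    return GenomeAnnotation(dict(sequences), genes_df, exons_df, repeats_df)


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Write genes and exons back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.sequences.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        exons_by_gene = dict(tuple(annotation.exons.groupby("gene_id", sort=False)))
        for g in annotation.genes.itertuples(index=False):
            fh.write(
                f"{g.seq_id}\tsemseason\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for j, e in enumerate(
                exons_by_gene.get(g.gene_id, pd.DataFrame()).itertuples(index=False), 1
            ):
                fh.write(
                    f"{e.seq_id}\tsemseason\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{j};Parent={g.gene_id}\n"
                )


def write_bed(annotation: GenomeAnnotation, path) -> None:
    """Write repeats as BED6 with the family label in the name column."""
    with open(path, "w") as fh:
        for r in annotation.repeats.itertuples(index=False):
            strand = r.strand if r.strand in STRANDS else "."
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.family}\t0\t{strand}\n")
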