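"""Weighted methylation levels, genome backgrounds, window tilings and
near-gene profiles.

The weighted methylation level of a region and context is the summed
methylated read count divided by the summed total read count over that
region's cytosines of the context; it is the standard read-weighted
estimator and lies in [0, 1] whenever any read covers the region.  A
region with zero covered sites has an *undefined* level (NaN), never 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mchh_islands.io import CONTEXTS, CytosineRecord, GeneModel, Methylome


@dataclass(frozen=True)
class ContextLevel:
    """Weighted methylation of one context over some region."""

    context: str
    level: float  # NaN when undefined
    n_sites: int
    n_meth_reads: int
    n_total_reads: int

    @property
    def defined(self) -> bool:
        return self.n_total_reads > 0


@dataclass
class GenomicWindow:
    """A tiling window; ``partial`` marks a short terminal window."""

    chrom: str
    start: int
    end: int
    partial: bool = False
    levels: dict[str, ContextLevel] = field(default_factory=dict)


@dataclass
class Background:
    """Genome-wide weighted levels per context — the binomial null rates."""

    levels: dict[str, ContextLevel]

    def p0(self, context: str) -> float:
        lvl = self.levels.get(context)
        return float("nan") if lvl is None else lvl.level


def _coerce_counts(records, context: str) -> tuple[int, int, int]:
    """Sum (n_sites, n_meth, n_total) over records of one context."""
    if isinstance(records, Methylome):
        records = records.df
    if isinstance(records, pd.DataFrame):
        sub = records[records["context"] == context]
        covered = int((sub["n_total"] > 0).sum())
        return covered, int(sub["n_meth"].sum()), int(sub["n_total"].sum())
    n_sites = n_meth = n_total = 0
    for r in records:
        if r.context != context:
            continue
        if r.n_total > 0:
            n_sites += 1
        n_meth += r.n_meth
        n_total += r.n_total
    return n_sites, n_meth, n_total


def weighted_level(records, context: str) -> ContextLevel:
    """Weighted methylation level of one context over a set of sites.

    Accepts an iterable of :class:`CytosineRecord`, a methylome DataFrame
    slice, or a :class:`Methylome`.  Empty input yields an undefined level.
    """
    n_sites, n_meth, n_total = _coerce_counts(records, context)
    level = n_meth / n_total if n_total > 0 else float("nan")
    return ContextLevel(context, level, n_sites, n_meth, n_total)


def call_site_methylation(record: CytosineRecord, error_rate: float,
                          alpha: float = 0.05) -> str:
    """Classify one cytosine as methylated / unmethylated / no_call.

    A site with fewer than two reads is a ``no_call``.  Otherwise the site
    is methylated when the one-sided binomial tail
    ``P[X >= n_meth | Bin(n_total, error_rate)]`` falls below ``alpha``,
    where ``error_rate`` is the bisulfite non-conversion rate.  For
    genome-scale calling apply :func:`call_sites`, which adds a
    Benjamini-Hochberg correction across sites.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must lie strictly in (0, 1)")
    if record.n_total < 2:
        return "no_call"
    p = stats.binom.sf(record.n_meth - 1, record.n_total, error_rate)
    return "methylated" if p < alpha else "unmethylated"


def call_sites(df: pd.DataFrame, error_rate: float, alpha: float = 0.05) -> pd.Series:
    """Vectorised per-site calls with BH FDR across testable sites."""
    from statsmodels.stats.multitest import multipletests

    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must lie strictly in (0, 1)")
    out = pd.Series("no_call", index=df.index, dtype=object)
    testable = df["n_total"] >= 2
    if testable.any():
        sub = df[testable]
        p = stats.binom.sf(sub["n_meth"] - 1, sub["n_total"], error_rate)
        reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        out.loc[testable] = np.where(reject, "methylated", "unmethylated")
    return out


def genome_background(methylome: Methylome) -> Background:
    """Per-context genome-wide weighted level over all covered cytosines."""
    import warnings

    levels = {}
    for ctx in CONTEXTS:
        lvl = weighted_level(methylome, ctx)
        if not lvl.defined:
            warnings.warn(f"no covered {ctx} sites: background undefined")
        levels[ctx] = lvl
    return Background(levels)


def tile_windows(chrom_lengths: Mapping[str, int], size: int = 100) -> list[GenomicWindow]:
    """Nonoverlapping windows [0,size),[size,2*size),...; a short terminal
    window is included and flagged ``partial``."""
    if size <= 0:
        raise ValueError("window size must be > 0")
    windows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        for start in range(0, length, size):
            end = min(start + size, length)
            windows.append(GenomicWindow(chrom, start, end, partial=end - start < size))
    return windows


def window_counts(methylome: Methylome, size: int = 100,
                  context: str = "CHH") -> pd.DataFrame:
    """Per-window site and read tallies for one context.

    Only windows containing at least one site of the context appear.
    Columns: chrom, start, n_sites (covered), n_meth_sites (sites with a
    methylated read), n_meth, n_total.
    """
    df = methylome.df
    sub = df[df["context"] == context]
    if sub.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "n_sites", "n_meth_sites", "n_meth", "n_total"]
        )
    widx = sub["pos"].to_numpy() // size
    grouped = (
        pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "start": widx * size,
                "covered": (sub["n_total"].to_numpy() > 0).astype(np.int64),
                "meth_site": (sub["n_meth"].to_numpy() > 0).astype(np.int64),
                "n_meth": sub["n_meth"].to_numpy(),
                "n_total": sub["n_total"].to_numpy(),
            }
        )
        .groupby(["chrom", "start"], sort=True)
        .sum()
        .reset_index()
        .rename(columns={"covered": "n_sites", "meth_site": "n_meth_sites"})
    )
    return grouped


# ---------------------------------------------------------------------------
# profiles


@dataclass
class Metaprofile:
    """Gene-anchored methylation profile: 10 upstream bins (200 bp), 20
    proportional gene-body bins, 10 downstream bins (200 bp); bin 0 is
    always 5'-most regardless of strand."""

    table: pd.DataFrame  # columns: bin, region, context, mean, n_genes
    n_genes: int


def _gene_bins(gene: GeneModel, sites: pd.DataFrame, flank: int,
               flank_bin: int, body_bins: int) -> np.ndarray:
    """Map site positions to oriented bin indices 0..(2*n_flank+body_bins-1);
    -1 for out of range."""
    n_flank = flank // flank_bin
    pos = sites["pos"].to_numpy()
    nbins = 2 * n_flank + body_bins
    bins = np.full(pos.shape, -1, dtype=np.int64)

    up = (pos >= gene.start - flank) & (pos < gene.start)
    body = (pos >= gene.start) & (pos < gene.end)
    down = (pos >= gene.end) & (pos < gene.end + flank)
    bins[up] = (pos[up] - (gene.start - flank)) // flank_bin
    glen = gene.end - gene.start
    bins[body] = n_flank + np.minimum(
        ((pos[body] - gene.start) * body_bins) // glen, body_bins - 1
    )
    bins[down] = n_flank + body_bins + (pos[down] - gene.end) // flank_bin
    if gene.strand == "-":
        valid = bins >= 0
        bins[valid] = nbins - 1 - bins[valid]
    return bins


def metaprofile(genes: Sequence[GeneModel], methylome: Methylome,
                flank: int = 2000, flank_bin: int = 200,
                body_bins: int = 20,
                chrom_lengths: Mapping[str, int] | None = None) -> Metaprofile:
    """Average per-gene methylation profile in 5'-oriented bins.

    Genes shorter than ``body_bins`` bases, or whose 2 kb flanks run off
    the chromosome, are excluded.  Within a gene, a bin with no covered
    sites of a context is skipped for that gene's average.
    """
    n_flank = flank // flank_bin
    nbins = 2 * n_flank + body_bins
    sums = {ctx: np.zeros(nbins) for ctx in CONTEXTS}
    counts = {ctx: np.zeros(nbins, dtype=np.int64) for ctx in CONTEXTS}
    n_used = 0
    for gene in genes:
        if gene.end - gene.start < body_bins:
            continue
        if gene.start - flank < 0:
            continue
        if chrom_lengths is not None and gene.end + flank > chrom_lengths.get(
            gene.chrom, np.inf
        ):
            continue
        sites = methylome.sites(gene.chrom, gene.start - flank, gene.end + flank)
        if sites.empty:
            continue
        bins = _gene_bins(gene, sites, flank, flank_bin, body_bins)
        n_used += 1
        for ctx in CONTEXTS:
            mask = (sites["context"].to_numpy() == ctx) & (bins >= 0)
            if not mask.any():
                continue
            b = bins[mask]
            m = np.bincount(b, weights=sites["n_meth"].to_numpy()[mask], minlength=nbins)
            t = np.bincount(b, weights=sites["n_total"].to_numpy()[mask], minlength=nbins)
            defined = t > 0
            sums[ctx][defined] += m[defined] / t[defined]
            counts[ctx][defined] += 1
    if n_used == 0:
        raise ValueError("no qualifying genes for metaprofile")
    region = (["upstream"] * n_flank + ["body"] * body_bins + ["downstream"] * n_flank)
    rows = []
    for ctx in CONTEXTS:
        with np.errstate(invalid="ignore"):
            means = np.where(counts[ctx] > 0, sums[ctx] / np.maximum(counts[ctx], 1), np.nan)
        for i in range(nbins):
            rows.append((i, region[i], ctx, means[i], int(counts[ctx][i])))
    table = pd.DataFrame(rows, columns=["bin", "region", "context", "mean", "n_genes"])
    return Metaprofile(table, n_used)


@dataclass
class EnrichmentResult:
    """Near-gene mCHH enrichment: upstream mean over random-window mean."""

    ratio: float
    upstream_mean: float
    random_mean: float
    n_genes: int
    n_random: int
    seed: int | None


def near_gene_enrichment(genes: Sequence[GeneModel], methylome: Methylome,
                         chrom_lengths: Mapping[str, int],
                         region: int = 1000, seed: int | None = None,
                         context: str = "CHH") -> EnrichmentResult:
    """Fold enrichment of upstream methylation over random genomic windows.

    Numerator: mean over genes of the weighted level in the ``region`` bp
    immediately 5' of the TSS (genes lacking the full flank on-chromosome
    are excluded).  Denominator: mean over an equal number of windows
    sampled uniformly without replacement from the genome-wide ``region``
    bp tiling, restricted to windows with at least one covered site of the
    context.
    """
    rng = np.random.default_rng(seed)
    per_gene = []
    for gene in genes:
        lo, hi = gene.flank5(region)
        if lo < 0 or hi > chrom_lengths.get(gene.chrom, np.inf):
            continue
        lvl = weighted_level(methylome.sites(gene.chrom, lo, hi), context)
        if lvl.defined:
            per_gene.append(lvl.level)
    if not per_gene:
        raise ValueError("no gene has a covered upstream region")

    wc = window_counts(methylome, size=region, context=context)
    wc = wc[wc["n_sites"] > 0]
    if wc.empty:
        raise ValueError("no covered random windows available")
    k = min(len(per_gene), len(wc))
    pick = rng.choice(len(wc), size=k, replace=False)
    sub = wc.iloc[pick]
    random_levels = sub["n_meth"].to_numpy() / sub["n_total"].to_numpy()
    up_mean = float(np.mean(per_gene))
    rnd_mean = float(np.mean(random_levels))
    if rnd_mean == 0:
        raise ZeroDivisionError("random-window mean methylation is zero")
    return EnrichmentResult(
        up_mean / rnd_mean, up_mean, rnd_mean, len(per_gene), k, seed
    )


def island_centered_profile(centers: Sequence[tuple[str, int]],
                            methylome: Methylome, span: int = 2000,
                            bin: int = 100) -> pd.DataFrame:
    """Per-context mean weighted levels in ``bin`` bp steps around island
    centers (one center per gene: the significant window nearest the TSS).

    Returns a table with columns offset (bp of bin start relative to the
    center), context, mean, n.
    """
    if not centers:
        raise ValueError("no island centers given")
    nbins = 2 * span // bin
    sums = {ctx: np.zeros(nbins) for ctx in CONTEXTS}
    counts = {ctx: np.zeros(nbins, dtype=np.int64) for ctx in CONTEXTS}
    for chrom, center in centers:
        sites = methylome.sites(chrom, center - span, center + span)
        if sites.empty:
            continue
        bins = (sites["pos"].to_numpy() - (center - span)) // bin
        for ctx in CONTEXTS:
            mask = sites["context"].to_numpy() == ctx
            if not mask.any():
                continue
            b = bins[mask]
            m = np.bincount(b, weights=sites["n_meth"].to_numpy()[mask], minlength=nbins)
            t = np.bincount(b, weights=sites["n_total"].to_numpy()[mask], minlength=nbins)
            defined = t > 0
            sums[ctx][defined] += m[defined] / t[defined]
            counts[ctx][defined] += 1
    rows = []
    for ctx in CONTEXTS:
        for i in range(nbins):
            mean = sums[ctx][i] / counts[ctx][i] if counts[ctx][i] else np.nan
            rows.append((i * bin - span, ctx, mean, int(counts[ctx][i])))
    return pd.DataFrame(rows, columns=["offset", "context", "mean", "n"])
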