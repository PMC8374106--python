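"""The core island-calling statistic.

Each chromosome is tiled into nonoverlapping 100 bp windows; a window with
more than five covered CHH cytosines is tested for CHH hypermethylation
with a one-sided binomial test against the genome-wide background rate,
p-values are Benjamini-Yekutieli adjusted across all tested windows
genome-wide, and a significant window (q < 0.01) becomes an mCHH island
when any of its bases falls within the strand-aware 2 kb 5' or 3' flank of
a gene.  An empirical-cutoff mode (weighted mCHH >= 25%) is provided as a
statistics-free alternative, together with an agreement metric between the
two calling modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mchh_islands.io import GeneModel, Methylome
from mchh_islands.methylation import Background, genome_background, window_counts


@dataclass
class IslandCall:
    """One tested 100 bp window and its island status."""

    chrom: str
    start: int
    end: int
    n_chh_sites: int
    n_meth_reads: int
    n_total_reads: int
    level: float
    p_value: float | None
    q_value: float | None
    is_island: bool = False
    #: (gene_id, side) pairs for genes whose 2 kb flank the window overlaps;
    #: side is "5p" or "3p".
    assoc: list[tuple[str, str]] = field(default_factory=list)

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneIslandStatus:
    """Per-gene island association after the near-gene coverage filter."""

    gene_id: str
    coverage_ok: bool
    has_5p_island: bool
    has_3p_island: bool
    nearest_island_distance: float  # bp from TSS to nearest 5' island edge; NaN if none


def test_window(n_meth: int, n_total: int, p0: float) -> float:
    """One-sided binomial tail P[X >= n_meth | X ~ Bin(n_total, p0)].

    ``n_total = 0`` gives p = 1.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("background rate p0 must lie strictly in (0, 1)")
    if n_total < 0 or not 0 <= n_meth <= max(n_total, 0):
        raise ValueError("require 0 <= n_meth <= n_total")
    return float(stats.binom.sf(n_meth - 1, n_total, p0))


def by_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted q-values, in input order.

    q_(i) = min_{j>=i}(p_(j) * m * c(m) / j) capped at 1, with
    c(m) = sum_{k=1..m} 1/k — valid under arbitrary dependence among tests.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_by")
    return q


def _flank_intervals(genes: Sequence[GeneModel], flank: int):
    """Yield (gene, side, lo, hi) half-open flank intervals."""
    for gene in genes:
        lo5, hi5 = gene.flank5(flank)
        lo3, hi3 = gene.flank3(flank)
        yield gene, "5p", max(lo5, 0), hi5
        yield gene, "3p", max(lo3, 0), hi3


def _annotate(calls_by_key: Mapping[tuple[str, int], IslandCall],
              genes: Sequence[GeneModel], size: int, flank: int,
              alpha_mask) -> list[IslandCall]:
    """Attach gene associations to significant windows; set is_island."""
    for gene, side, lo, hi in _flank_intervals(genes, flank):
        if hi <= lo:
            continue
        first = lo // size
        last = (hi - 1) // size
        for widx in range(first, last + 1):
            call = calls_by_key.get((gene.chrom, widx))
            if call is not None and alpha_mask(call):
                call.assoc.append((gene.gene_id, side))
                call.is_island = True
    return list(calls_by_key.values())


def call_islands(methylome: Methylome, genes: Sequence[GeneModel],
                 background: Background | None = None, size: int = 100,
                 min_sites: int = 5, flank: int = 2000, alpha: float = 0.01,
                 site_metric: str = "covered") -> list[IslandCall]:
    """Binomial-mode island calling over a whole methylome.

    Returns every tested window (strictly more than ``min_sites`` CHH
    cytosines by ``site_metric``: "covered" counts covered CHH sites,
    "methylated" counts sites with at least one methylated read).  BY
    adjustment spans all tested windows genome-wide; ``is_island`` is set
    for q < ``alpha`` windows overlapping a gene's 2 kb 5' or 3' flank.
    """
    if not genes:
        raise ValueError("no genes supplied")
    if site_metric not in ("covered", "methylated"):
        raise ValueError("site_metric must be 'covered' or 'methylated'")
    if background is None:
        background = genome_background(methylome)
    p0 = background.p0("CHH")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"degenerate CHH background {p0!r}")

    wc = window_counts(methylome, size=size, context="CHH")
    metric = wc["n_sites"] if site_metric == "covered" else wc["n_meth_sites"]
    tested = wc[metric > min_sites].reset_index(drop=True)
    if tested.empty:
        raise ValueError("no windows pass the site-count rule")

    n_meth = tested["n_meth"].to_numpy()
    n_total = tested["n_total"].to_numpy()
    p = stats.binom.sf(n_meth - 1, n_total, p0)
    q = by_adjust(p)

    calls: dict[tuple[str, int], IslandCall] = {}
    starts = tested["start"].to_numpy()
    chroms = tested["chrom"].to_numpy()
    sites = tested["n_sites"].to_numpy()
    with np.errstate(invalid="ignore"):
        levels = np.where(n_total > 0, n_meth / np.maximum(n_total, 1), np.nan)
    for i in range(len(tested)):
        call = IslandCall(
            chrom=str(chroms[i]), start=int(starts[i]), end=int(starts[i]) + size,
            n_chh_sites=int(sites[i]), n_meth_reads=int(n_meth[i]),
            n_total_reads=int(n_total[i]), level=float(levels[i]),
            p_value=float(p[i]), q_value=float(q[i]),
        )
        calls[(call.chrom, call.start // size)] = call
    return _annotate(calls, genes, size, flank, lambda c: c.q_value < alpha)


def empirical_cutoff_call(methylome: Methylome, genes: Sequence[GeneModel],
                          cutoff: float = 0.25, size: int = 100,
                          min_sites: int = 5, flank: int = 2000) -> list[IslandCall]:
    """Cutoff-mode island calling: a window is an island iff its weighted
    mCHH level is at least ``cutoff`` (closed lower bound); no p-values."""
    if not genes:
        raise ValueError("no genes supplied")
    wc = window_counts(methylome, size=size, context="CHH")
    tested = wc[wc["n_sites"] > min_sites].reset_index(drop=True)
    if tested.empty:
        raise ValueError("no windows pass the site-count rule")
    calls: dict[tuple[str, int], IslandCall] = {}
    for row in tested.itertuples(index=False):
        level = row.n_meth / row.n_total if row.n_total > 0 else float("nan")
        call = IslandCall(
            chrom=str(row.chrom), start=int(row.start), end=int(row.start) + size,
            n_chh_sites=int(row.n_sites), n_meth_reads=int(row.n_meth),
            n_total_reads=int(row.n_total), level=level,
            p_value=None, q_value=None,
        )
        calls[(call.chrom, call.start // size)] = call
    return _annotate(
        calls, genes, size, flank,
        lambda c: np.isfinite(c.level) and c.level >= cutoff,
    )


def coverage_filter(gene: GeneModel, methylome: Methylome, flank: int = 2000,
                    depth: int = 2, frac: float = 0.5) -> bool:
    """Near-gene coverage rule: among CHH cytosines in the 5' ``flank``
    region, at least ``frac`` of sites must have read depth > ``depth``.

    A flank with zero CHH sites fails the filter.
    """
    lo, hi = gene.flank5(flank)
    sub = methylome.sites(gene.chrom, max(lo, 0), hi, context="CHH")
    if sub.empty:
        return False
    return float((sub["n_total"] > depth).mean()) >= frac


def coverage_filter_all(genes: Sequence[GeneModel], methylome: Methylome,
                        flank: int = 2000, depth: int = 2,
                        frac: float = 0.5) -> dict[str, bool]:
    return {
        g.gene_id: coverage_filter(g, methylome, flank=flank, depth=depth, frac=frac)
        for g in genes
    }


def associate_genes(islands: Sequence[IslandCall], genes: Sequence[GeneModel],
                    coverage_ok: Mapping[str, bool] | None = None,
                    flank: int = 2000) -> list[GeneIslandStatus]:
    """Per-gene island association from a set of window calls.

    A gene has a 5' (3') island when >= 1 island window overlaps, by any
    base, the strand-aware 2 kb upstream of its TSS (downstream of its
    TTS).  Genes failing the coverage filter are reported with
    ``coverage_ok=False`` and no island flags, so downstream tallies can
    exclude them.
    """
    island_windows = [c for c in islands if c.is_island]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in island_windows:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    for chrom in by_chrom:
        by_chrom[chrom].sort()

    def overlapping(chrom, lo, hi):
        out = []
        for s, e in by_chrom.get(chrom, ()):
            if s < hi and e > lo:
                out.append((s, e))
        return out

    statuses = []
    for gene in genes:
        cov = True if coverage_ok is None else bool(coverage_ok.get(gene.gene_id, False))
        if not cov:
            statuses.append(GeneIslandStatus(gene.gene_id, False, False, False, float("nan")))
            continue
        lo5, hi5 = gene.flank5(flank)
        lo3, hi3 = gene.flank3(flank)
        up = overlapping(gene.chrom, max(lo5, 0), hi5)
        down = overlapping(gene.chrom, max(lo3, 0), hi3)
        dist = float("nan")
        if up:
            tss = gene.tss
            dist = float(min(min(abs(tss - s), abs(tss - (e - 1))) for s, e in up))
        statuses.append(
            GeneIslandStatus(gene.gene_id, True, bool(up), bool(down), dist)
        )
    return statuses


def method_agreement(status_a: Sequence[GeneIslandStatus],
                     status_b: Sequence[GeneIslandStatus]) -> float:
    """Fraction of genes with the same 5' island designation in two calling
    modes.  Both inputs must cover the identical gene universe."""
    a = {s.gene_id: s.has_5p_island for s in status_a}
    b = {s.gene_id: s.has_5p_island for s in status_b}
    if set(a) != set(b):
        raise ValueError("gene universes differ between the two callers")
    if not a:
        raise ValueError("empty gene universe")
    return sum(a[g] == b[g] for g in a) / len(a)


def select_tss_islands(islands: Sequence[IslandCall],
                       genes: Sequence[GeneModel],
                       flank: int = 2000) -> dict[str, IslandCall]:
    """Pick, per gene, the single 5' island window nearest the TSS (for
    island-centered profiles)."""
    by_gene: dict[str, IslandCall] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for call in islands:
        if not call.is_island:
            continue
        for gid, side in call.assoc:
            if side != "5p":
                continue
            gene = gene_by_id.get(gid)
            if gene is None:
                continue
            d = min(abs(gene.tss - call.start), abs(gene.tss - (call.end - 1)))
            best = by_gene.get(gid)
            if best is None:
                by_gene[gid] = call
            else:
                bd = min(abs(gene.tss - best.start), abs(gene.tss - (best.end - 1)))
                if d < bd:
                    by_gene[gid] = call
    return by_gene
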