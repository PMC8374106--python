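"""Genic predictors of island presence: TE distance, gene length,
expression quartile, and gene-body methylation (gbM).

All four predictors feed the logistic model through a common 0-1
standardisation ((x - min) / (max - min)); missing values (a gene with no
TE on its scaffold, a gene absent from the expression table) propagate as
NaN and are handled listwise by the model-fitting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mchh_islands.io import GeneModel, Methylome, RepeatFeature
from mchh_islands.methylation import Background
from mchh_islands.islands import GeneIslandStatus


def te_distance(gene: GeneModel, repeats: Sequence[RepeatFeature]) -> float:
    """Distance (bp) from the gene's TSS to the nearest TE edge on its
    chromosome, indiscriminate of strand.

    The distance is the minimum over repeats of min(|tss - start|,
    |tss - end|); it is 0 when a repeat's span overlaps the gene body, and
    NaN (missing) when the scaffold carries no repeat at all.
    """
    best = float("nan")
    tss = gene.tss
    for rep in repeats:
        if rep.chrom != gene.chrom:
            continue
        if rep.start < gene.end and rep.end > gene.start:
            return 0.0
        d = min(abs(tss - rep.start), abs(tss - rep.end))
        if not best <= d:  # best is NaN or larger
            best = float(d)
    return best


def te_distances(genes: Sequence[GeneModel],
                 repeats: Sequence[RepeatFeature]) -> dict[str, float]:
    """Vectorised :func:`te_distance` over many genes."""
    by_chrom: dict[str, list[RepeatFeature]] = {}
    for rep in repeats:
        by_chrom.setdefault(rep.chrom, []).append(rep)
    arrs = {
        c: (
            np.array([r.start for r in reps]),
            np.array([r.end for r in reps]),
        )
        for c, reps in by_chrom.items()
    }
    out = {}
    for gene in genes:
        if gene.chrom not in arrs:
            out[gene.gene_id] = float("nan")
            continue
        starts, ends = arrs[gene.chrom]
        overlap = (starts < gene.end) & (ends > gene.start)
        if overlap.any():
            out[gene.gene_id] = 0.0
            continue
        tss = gene.tss
        out[gene.gene_id] = float(
            np.minimum(np.abs(tss - starts), np.abs(tss - ends)).min()
        )
    return out


def expression_quartiles(expr: Mapping[str, float],
                         genes: Sequence[GeneModel] | Sequence[str],
                         include_zero: bool = False) -> dict[str, int]:
    """Assign each gene an expression quartile 1-4; quartile 0 for genes
    absent from the table (and, by default, genes with RPKM = 0, whose
    log2 is undefined).

    Breakpoints are the 25/50/75% linear-interpolation quantiles of
    log2(RPKM) over the expressed set.  A value equal to a breakpoint falls
    in the lower quartile, so a fully tied expressed set lands in
    quartile 1.
    """
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else g for g in genes]
    expressed = {
        gid: expr[gid]
        for gid in gene_ids
        if gid in expr and (include_zero or expr[gid] > 0)
    }
    if len(expressed) < 4:
        raise ValueError("need at least 4 expressed genes to form quartiles")
    logs = {gid: np.log2(v) if v > 0 else -np.inf for gid, v in expressed.items()}
    vals = np.array(list(logs.values()))
    breaks = np.quantile(vals, [0.25, 0.5, 0.75])
    out = {}
    for gid in gene_ids:
        if gid not in logs:
            out[gid] = 0
        else:
            out[gid] = 1 + int(np.searchsorted(breaks, logs[gid], side="left"))
    return out


def gene_length(gene: GeneModel) -> int:
    """Full annotated span (max minus min position, introns included)."""
    return gene.end - gene.start


def exon_length(gene: GeneModel) -> int:
    """Secondary length measure: summed exon length of the longest transcript."""
    return sum(e - s for s, e in gene.exons)


@dataclass
class GbmCall:
    gene_id: str
    exonic_mcg: float  # NaN when no exonic CG coverage
    gbm_binary: bool
    tested: bool  # False when the gene had no exonic CG coverage


def gbm_classify(genes: Sequence[GeneModel], methylome: Methylome,
                 background: Background, alpha: float = 0.05,
                 definition: str = "classic") -> list[GbmCall]:
    """Classify genes as gene-body methylated.

    ``exonic_mcg`` is the weighted CG level over the longest transcript's
    exons.  The binary call applies a one-sided binomial CG-hypermethylation
    test against the genome background with BH FDR < ``alpha`` across
    genes; under the "classic" definition a gene additionally must not be
    CHG- or CHH-hypermethylated at the same threshold ("cg_only" drops that
    exclusion).  Genes with zero exonic CG coverage are excluded
    (``tested=False``).
    """
    from statsmodels.stats.multitest import multipletests

    if definition not in ("classic", "cg_only"):
        raise ValueError("definition must be 'classic' or 'cg_only'")
    contexts = ("CG",) if definition == "cg_only" else ("CG", "CHG", "CHH")
    sums = {ctx: np.zeros((len(genes), 2), dtype=np.int64) for ctx in contexts}
    for i, gene in enumerate(genes):
        for s, e in gene.exons:
            sub = methylome.sites(gene.chrom, s, e)
            for ctx in contexts:
                csub = sub[sub["context"] == ctx]
                sums[ctx][i, 0] += int(csub["n_meth"].sum())
                sums[ctx][i, 1] += int(csub["n_total"].sum())

    hyper = {}
    for ctx in contexts:
        p0 = background.p0(ctx)
        m, t = sums[ctx][:, 0], sums[ctx][:, 1]
        testable = t > 0
        flags = np.zeros(len(genes), dtype=bool)
        if testable.any():
            if not 0.0 < p0 < 1.0:
                raise ValueError(f"degenerate {ctx} background {p0!r}")
            p = stats.binom.sf(m[testable] - 1, t[testable], p0)
            reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
            flags[testable] = reject
        hyper[ctx] = flags

    calls = []
    cg_m, cg_t = sums["CG"][:, 0], sums["CG"][:, 1]
    for i, gene in enumerate(genes):
        tested = cg_t[i] > 0
        mcg = cg_m[i] / cg_t[i] if tested else float("nan")
        gbm = bool(hyper["CG"][i]) and tested
        if definition == "classic" and gbm:
            gbm = not (bool(hyper["CHG"][i]) or bool(hyper["CHH"][i]))
        calls.append(GbmCall(gene.gene_id, mcg, gbm, tested))
    return calls


def standardize01(values) -> np.ndarray:
    """Scale to [0, 1]: (x - min) / (max - min); NaN propagates.

    Raises on a constant vector (undefined scaling) or fewer than two
    distinct finite values.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2 or finite.min() == finite.max():
        raise ValueError("standardize01 requires >= 2 distinct values")
    return (x - finite.min()) / (finite.max() - finite.min())


def build_feature_table(genes: Sequence[GeneModel],
                        statuses: Sequence[GeneIslandStatus],
                        repeats: Sequence[RepeatFeature],
                        expr: Mapping[str, float],
                        gbm_calls: Sequence[GbmCall]) -> pd.DataFrame:
    """Assemble the per-gene analysis table.

    Columns: gene_id (index), has_5p_island, has_3p_island, coverage_ok,
    te_distance, gene_length, exon_length, rpkm (NaN when absent),
    quartile, gbm_binary, exonic_mcg.  Genes failing the near-gene coverage
    filter are retained with coverage_ok=False so callers can subset.
    """
    status_by_id = {s.gene_id: s for s in statuses}
    gbm_by_id = {c.gene_id: c for c in gbm_calls}
    dists = te_distances(genes, repeats)
    quartiles = expression_quartiles(expr, genes)
    rows = []
    for gene in genes:
        st = status_by_id.get(gene.gene_id)
        gb = gbm_by_id.get(gene.gene_id)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "has_5p_island": bool(st.has_5p_island) if st else False,
                "has_3p_island": bool(st.has_3p_island) if st else False,
                "coverage_ok": bool(st.coverage_ok) if st else False,
                "te_distance": dists[gene.gene_id],
                "gene_length": gene_length(gene),
                "exon_length": exon_length(gene),
                "rpkm": expr.get(gene.gene_id, float("nan")),
                "quartile": quartiles[gene.gene_id],
                "gbm_binary": bool(gb.gbm_binary) if gb and gb.tested else (
                    False if gb else False
                ),
                "exonic_mcg": gb.exonic_mcg if gb else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
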