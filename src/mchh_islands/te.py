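"""TE-superfamily analyses: island enrichment per superfamily, the
Feltz-Miller test for equality of coefficients of variation,
coincident/dissonant classification of lineage-specific islands and TEs,
and best-hit e-value summaries of BLAST tabular output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mchh_islands.io import GeneModel, RepeatFeature
from mchh_islands.islands import IslandCall


@dataclass
class SuperfamilyEnrichment:
    superfamily: str
    n: int            # genes whose nearest upstream-within-2kb TE is this superfamily
    k: int            # of those, genes with a 5' island
    proportion: float
    p0: float         # pooled proportion across superfamilies
    p_value: float
    q_value: float
    label: str        # Enriched / Under / NS


def superfamily_enrichment(table: pd.DataFrame, alpha: float = 0.05,
                           alternative: str = "two-sided"
                           ) -> list[SuperfamilyEnrichment]:
    """Per-superfamily island enrichment against the pooled proportion.

    ``table`` needs one row per gene with columns ``superfamily`` (the
    nearest upstream-within-2kb TE's code) and ``has_island`` (bool).  Each
    superfamily's island count k of n is tested with an exact binomial
    test against p0 = pooled proportion over all superfamilies, BH-adjusted
    across the tested superfamilies.  Labels: Enriched when q < alpha and
    proportion > p0; Under when q < alpha and proportion < p0; else NS.
    Superfamilies with n = 0 are omitted.
    """
    from statsmodels.stats.multitest import multipletests

    grouped = table.groupby("superfamily")["has_island"].agg(["count", "sum"])
    grouped = grouped[grouped["count"] > 0]
    if grouped.empty:
        raise ValueError("no superfamilies with genes to test")
    total_n = int(grouped["count"].sum())
    total_k = int(grouped["sum"].sum())
    p0 = total_k / total_n
    pvals = []
    for fam, row in grouped.iterrows():
        n, k = int(row["count"]), int(row["sum"])
        if 0.0 < p0 < 1.0:
            pv = stats.binomtest(k, n, p0, alternative=alternative).pvalue
        else:
            pv = 1.0
        pvals.append(pv)
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out = []
    for (fam, row), pv, qv in zip(grouped.iterrows(), pvals, qvals):
        n, k = int(row["count"]), int(row["sum"])
        prop = k / n
        if qv < alpha and prop > p0:
            label = "Enriched"
        elif qv < alpha and prop < p0:
            label = "Under"
        else:
            label = "NS"
        out.append(
            SuperfamilyEnrichment(str(fam), n, k, prop, p0, float(pv), float(qv), label)
        )
    return out


def feltz_miller_cv_test(samples: Sequence[Sequence[float]]):
    """Feltz-Miller asymptotic test for equality of coefficients of
    variation across k groups.

    With per-group CV estimates c_i = s_i / mean_i and the pooled
    c = sum((n_i - 1) c_i) / sum(n_i - 1), the statistic
    sum((n_i - 1)(c_i - c)^2) / (c^2 (0.5 + c^2)) is referred to a
    chi-square with k - 1 degrees of freedom.  Requires every group to
    have n >= 2 and a positive mean.
    """
    cvs, dfs = [], []
    for grp in samples:
        x = np.asarray(grp, dtype=float)
        if len(x) < 2:
            raise ValueError("each group needs n >= 2")
        mean = x.mean()
        if mean <= 0:
            raise ValueError("group mean must be > 0")
        cvs.append(x.std(ddof=1) / mean)
        dfs.append(len(x) - 1)
    cvs = np.asarray(cvs)
    dfs = np.asarray(dfs, dtype=float)
    k = len(cvs)
    if k < 2:
        raise ValueError("need at least two groups")
    c = float(np.sum(dfs * cvs) / np.sum(dfs))
    if c == 0:
        return 0.0, 1.0
    statistic = float(np.sum(dfs * (cvs - c) ** 2) / (c**2 * (0.5 + c**2)))
    p_value = float(stats.chi2.sf(statistic, k - 1))
    return statistic, p_value


@dataclass
class CoincidenceRecord:
    ortholog_id: str
    island_species: str | None  # species carrying the lineage-specific island
    te_pattern: str             # neither / both / same-species / other-species
    klass: str                  # coincident / dissonant / excluded


@dataclass
class CoincidenceResult:
    records: list[CoincidenceRecord]
    n_coincident: int
    n_dissonant: int
    chi2: float
    p_value: float


def classify_coincidence(panel_pair: pd.DataFrame,
                         te_flags: pd.DataFrame) -> CoincidenceResult:
    """Classify lineage-specific islands as coincident or dissonant with
    lineage-specific TEs, for one species pair.

    ``panel_pair`` and ``te_flags``: DataFrames indexed by ortholog with the
    two species as boolean columns (island presence / TE-within-2kb).
    Orthologs with islands in both or neither species are excluded.  Among
    single-island orthologs, coincident means the lineage-specific TE is in
    the island-bearing species, dissonant means it is in the other; TE in
    both or neither species leaves the record classified by ``te_pattern``
    only.  The chi-square is a 1-df goodness-of-fit of (coincident,
    dissonant) against 50:50.
    """
    if panel_pair.shape[1] != 2 or te_flags.shape[1] != 2:
        raise ValueError("panel_pair and te_flags need exactly two species columns")
    sa, sb = panel_pair.columns
    common = panel_pair.dropna().index.intersection(te_flags.dropna().index)
    records = []
    n_co = n_dis = 0
    for oid in common:
        ia, ib = bool(panel_pair.at[oid, sa]), bool(panel_pair.at[oid, sb])
        ta, tb = bool(te_flags.at[oid, sa]), bool(te_flags.at[oid, sb])
        if ia == ib:
            records.append(CoincidenceRecord(str(oid), None, "n/a", "excluded"))
            continue
        isl_sp = sa if ia else sb
        te_in_island_sp = ta if ia else tb
        te_in_other_sp = tb if ia else ta
        if te_in_island_sp and te_in_other_sp:
            pattern, klass = "both", "excluded"
        elif not te_in_island_sp and not te_in_other_sp:
            pattern, klass = "neither", "excluded"
        elif te_in_island_sp:
            pattern, klass = "same-species", "coincident"
            n_co += 1
        else:
            pattern, klass = "other-species", "dissonant"
            n_dis += 1
        records.append(CoincidenceRecord(str(oid), isl_sp, pattern, klass))
    if n_co + n_dis == 0:
        raise ValueError("no classifiable orthologs (no single-lineage TE cases)")
    chi2_res = stats.chisquare([n_co, n_dis])
    return CoincidenceResult(
        records, n_co, n_dis, float(chi2_res.statistic), float(chi2_res.pvalue)
    )


def coincidence_by_superfamily(records: Sequence[CoincidenceRecord],
                               superfamilies: Mapping[str, str],
                               alpha: float = 0.05) -> pd.DataFrame:
    """Per-superfamily over/under-representation among coincident vs
    dissonant events: 2x2 contingency chi-square (superfamily vs rest),
    BH-adjusted.  ``superfamilies`` maps ortholog_id -> the code of the
    lineage-specific TE."""
    from statsmodels.stats.multitest import multipletests

    classed = [r for r in records if r.klass in ("coincident", "dissonant")]
    fams = sorted({superfamilies.get(r.ortholog_id, "unknown") for r in classed})
    rows = []
    for fam in fams:
        in_co = sum(
            1 for r in classed
            if r.klass == "coincident" and superfamilies.get(r.ortholog_id, "unknown") == fam
        )
        in_dis = sum(
            1 for r in classed
            if r.klass == "dissonant" and superfamilies.get(r.ortholog_id, "unknown") == fam
        )
        out_co = sum(1 for r in classed if r.klass == "coincident") - in_co
        out_dis = sum(1 for r in classed if r.klass == "dissonant") - in_dis
        table = np.array([[in_co, in_dis], [out_co, out_dis]])
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            p = 1.0
        else:
            p = float(stats.chi2_contingency(table, correction=False).pvalue)
        rows.append((fam, in_co, in_dis, p))
    df = pd.DataFrame(rows, columns=["superfamily", "coincident", "dissonant", "p_value"])
    _, q, _, _ = multipletests(df["p_value"], alpha=alpha, method="fdr_bh")
    df["q_value"] = q
    return df


def blast_evalue_summary(hits: pd.DataFrame, query_ids: Sequence[str]):
    """Best e-value per query over its HSPs; queries without hits get 1.0.

    Returns (per-query Series, summary dict) where the summary reports the
    fractions of queries below 1e-5 and 1e-40 and a log10 e-value
    histogram.  A hit whose query id is not in ``query_ids`` is an error.
    """
    qset = set(query_ids)
    if len(qset) != len(list(query_ids)):
        raise ValueError("duplicate query ids")
    unknown = set(hits["query_id"]) - qset
    if unknown:
        raise ValueError(f"hits for unknown query ids: {sorted(unknown)[:5]}")
    best = hits.groupby("query_id")["evalue"].min()
    per_query = pd.Series(1.0, index=pd.Index(sorted(qset), name="query_id"))
    if len(best):
        per_query.loc[best.index] = best.astype(float)
    per_query = per_query.astype(float)
    logs = np.log10(np.maximum(per_query.to_numpy(), 1e-200))
    edges = np.arange(-200, 1 + 10, 10, dtype=float)
    hist, _ = np.histogram(logs, bins=edges)
    summary = {
        "n_queries": len(per_query),
        "frac_below_1e-5": float((per_query < 1e-5).mean()),
        "frac_below_1e-40": float((per_query < 1e-40).mean()),
        "hist_log10_edges": edges.tolist(),
        "hist_counts": hist.tolist(),
    }
    return per_query, summary


@dataclass
class CvComparison:
    n: int
    tss_mean: float
    tss_cv: float
    te_edge_mean: float
    te_edge_cv: float
    statistic: float
    p_value: float


def island_te_distances(islands: Sequence[IslandCall],
                        tes: Sequence[RepeatFeature],
                        genes: Sequence[GeneModel]):
    """For islands whose window midpoint lies inside an annotated TE,
    measure the distance from the midpoint to the closest TE end and to
    the TSS of the nearest associated gene, then compare the two distance
    distributions' CVs with the Feltz-Miller test.

    Returns (per-island DataFrame with columns chrom, center, superfamily,
    dist_te_edge, dist_tss; CvComparison).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    te_by_chrom: dict[str, list[RepeatFeature]] = {}
    for te in tes:
        te_by_chrom.setdefault(te.chrom, []).append(te)
    rows = []
    for isl in islands:
        if not isl.is_island:
            continue
        center = isl.center
        containing = [
            te for te in te_by_chrom.get(isl.chrom, ())
            if te.start <= center < te.end
        ]
        if not containing:
            continue
        te = min(containing, key=lambda t: t.end - t.start)
        dist_edge = min(abs(center - te.start), abs(center - te.end))
        assoc_genes = [gene_by_id[g] for g, side in isl.assoc
                       if side == "5p" and g in gene_by_id]
        if not assoc_genes:
            continue
        dist_tss = min(abs(center - g.tss) for g in assoc_genes)
        rows.append((isl.chrom, center, te.superfamily, dist_edge, dist_tss))
    if not rows:
        raise ValueError("no island midpoints fall within an annotated TE")
    df = pd.DataFrame(
        rows, columns=["chrom", "center", "superfamily", "dist_te_edge", "dist_tss"]
    )
    tss_d = df["dist_tss"].to_numpy(dtype=float)
    edge_d = df["dist_te_edge"].to_numpy(dtype=float)
    # degenerate all-zero groups cannot enter the CV test
    if len(df) >= 2 and tss_d.mean() > 0 and edge_d.mean() > 0:
        statistic, p = feltz_miller_cv_test([tss_d, edge_d])
    else:
        statistic, p = float("nan"), float("nan")
    def _cv(x):
        return float(x.std(ddof=1) / x.mean()) if len(x) >= 2 and x.mean() > 0 else float("nan")

    cmp = CvComparison(
        n=len(df),
        tss_mean=float(tss_d.mean()), tss_cv=_cv(tss_d),
        te_edge_mean=float(edge_d.mean()), te_edge_cv=_cv(edge_d),
        statistic=statistic, p_value=p,
    )
    return df, cmp
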