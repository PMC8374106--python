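"""Synthetic multi-species methylome generator with known ground truth.

The generator emulates the study conditions of a grass WGBS panel: random
chromosome sequences with cytosine contexts derived from the sequence on
both strands; low genome-wide CHH background with higher CG and CHG
backgrounds; planted 5' islands (short tracts upstream of the TSS with
elevated methylation in all three contexts); gene-body-methylated genes
with elevated exonic CG; TEs placed within 2 kb of a subset of genes;
per-gene expression values; and a multi-species ortholog panel whose
island indicators have controllable marginal proportions and cross-species
correlation (a Gaussian copula).  Read counts are beta-binomial by default
to emulate biological overdispersion, with an exact-binomial mode for
distribution-theory tests.  All randomness flows from a single mandatory
seed; reruns are bit-identical.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mchh_islands.io import (
    CONTEXTS,
    GeneModel,
    Methylome,
    RepeatFeature,
)

_DEFAULT_BACKGROUND = {"CG": 0.60, "CHG": 0.40, "CHH": 0.05}
_DEFAULT_TE_MIX = {
    "DTT": 0.18, "DTM": 0.12, "DTH": 0.10, "DTA": 0.08, "DTC": 0.08,
    "DTX": 0.06, "DHH": 0.08, "RLC": 0.12, "RLG": 0.12, "RIX": 0.03,
    "RLX": 0.02, "RSX": 0.01,
}


@dataclass
class SimConfig:
    """Parameters of one simulated species (and, for panels, the species set).

    Defaults encode a grass-like regime: genome-wide weighted levels of
    0.60 (CG), 0.40 (CHG) and 0.05 (CHH) — CHH backgrounds in grasses sit
    at 12% or less — islands at 0.40 CHH with CG/CHG raised 0.2 over
    background (islands are elevated in all three contexts), island tracts
    of 100-300 bp ending 0-1500 bp upstream of the TSS, and mean 10x
    read depth.
    """

    seed: int
    n_chromosomes: int = 2
    chrom_length: int = 300_000
    n_genes: int = 60
    coverage_mean: float = 10.0
    background: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BACKGROUND)
    )
    island_fraction: float = 0.4
    island_chh_level: float = 0.40
    island_cg_boost: float = 0.2
    island_chg_boost: float = 0.2
    island_offset_max: int = 1500
    island_len_range: tuple[int, int] = (100, 300)
    gbm_fraction: float = 0.25
    gbm_cg_level: float = 0.85
    te_fraction: float = 0.6
    te_superfamily_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TE_MIX)
    )
    overdispersion: float = 50.0  # beta-binomial concentration
    binomial_counts: bool = False  # True: exact binomial counts
    gene_length_range: tuple[int, int] = (1000, 4000)
    expressed_fraction: float = 0.85
    flank: int = 2000
    n_species: int = 8
    rho: float = 0.0
    island_p_by_species: Sequence[float] | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for ctx, lvl in self.background.items():
            if not 0.0 < lvl < 1.0:
                raise ValueError(f"background {ctx} level must lie in (0,1)")
        for frac in (self.island_fraction, self.gbm_fraction, self.te_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")


@dataclass
class SimTruth:
    """Ground-truth labels emitted alongside the data."""

    genes: pd.DataFrame       # gene_id index: island_planted, island_start/end,
                              # gbm_planted, te_planted, te_superfamily, rpkm
    island_tracts: list[tuple[str, int, int]]  # (chrom, start, end)

    def island_windows(self, size: int = 100):
        """(full, any) window-start sets on the ``size`` lattice: windows
        fully inside a planted tract, and windows overlapping one at all."""
        full, any_overlap = set(), set()
        for chrom, a, b in self.island_tracts:
            first, last = a // size, (b - 1) // size
            for w in range(first, last + 1):
                s, e = w * size, w * size + size
                if s < b and e > a:
                    any_overlap.add((chrom, s))
                if s >= a and e <= b:
                    full.add((chrom, s))
        return full, any_overlap

    def to_frame(self) -> pd.DataFrame:
        return self.genes.copy()


@dataclass
class SimulatedSpecies:
    species: str
    config: SimConfig
    chrom_lengths: dict[str, int]
    methylome: Methylome
    genes: list[GeneModel]
    repeats: list[RepeatFeature]
    expression: dict[str, float]
    truth: SimTruth

    def write(self, outdir) -> dict[str, Path]:
        """Emit the five per-species files (cytosine report, GFF3, repeat
        BED, expression TSV, truth TSV); returns their paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        rep = outdir / f"{self.species}.cx_report.tsv"
        df = self.methylome.df
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": df["pos"] + 1,  # 1-based on disk
                "strand": df["strand"],
                "n_meth": df["n_meth"],
                "n_unmeth": df["n_total"] - df["n_meth"],
                "context": df["context"],
            }
        )
        out.to_csv(rep, sep="\t", header=False, index=False)
        paths["cytosine_report"] = rep

        gff = outdir / f"{self.species}.genes.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(
                    f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
                )
                tid = f"{g.gene_id}.t1"
                fh.write(
                    f"{g.chrom}\tsim\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
                )
                for s, e in g.exons:
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={tid}\n"
                    )
        paths["genes"] = gff

        bed = outdir / f"{self.species}.repeats.bed"
        with open(bed, "w") as fh:
            for r in sorted(self.repeats, key=lambda r: (r.chrom, r.start)):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.superfamily}\n")
        paths["repeats"] = bed

        expr = outdir / f"{self.species}.expression.tsv"
        with open(expr, "w") as fh:
            fh.write("gene_id\trpkm\n")
            for gid in sorted(self.expression):
                fh.write(f"{gid}\t{self.expression[gid]:.6g}\n")
        paths["expression"] = expr

        truth = outdir / f"{self.species}.truth.tsv"
        self.truth.to_frame().to_csv(truth, sep="\t")
        paths["truth"] = truth
        return paths


def _derive_contexts(seq: np.ndarray):
    """Cytosine positions, strands and contexts from an integer sequence
    (0=A, 1=C, 2=G, 3=T), both strands."""
    L = len(seq)
    # plus strand: C at i, context from i+1, i+2
    plus = np.flatnonzero(seq[: L - 2] == 1)
    nxt1, nxt2 = seq[plus + 1], seq[plus + 2]
    plus_ctx = np.where(nxt1 == 2, 0, np.where(nxt2 == 2, 1, 2))  # 0 CG, 1 CHG, 2 CHH
    # minus strand: G at i, context from i-1, i-2 complemented
    minus = np.flatnonzero(seq[2:] == 2) + 2
    prv1, prv2 = seq[minus - 1], seq[minus - 2]
    minus_ctx = np.where(prv1 == 1, 0, np.where(prv2 == 1, 1, 2))
    pos = np.concatenate([plus, minus])
    strand = np.concatenate(
        [np.zeros(len(plus), dtype=np.int8), np.ones(len(minus), dtype=np.int8)]
    )
    ctx = np.concatenate([plus_ctx, minus_ctx]).astype(np.int8)
    order = np.argsort(pos, kind="mergesort")
    return pos[order], strand[order], ctx[order]


_CTX_NAMES = np.array(["CG", "CHG", "CHH"])
_STRAND_NAMES = np.array(["+", "-"])


def simulate_species(config: SimConfig, species: str = "sim",
                     forced_islands: Sequence[bool] | None = None,
                     rng: np.random.Generator | None = None) -> SimulatedSpecies:
    """Simulate one species' methylome, annotations, expression and truth.

    ``forced_islands`` (one flag per gene) overrides the random
    island-gene draw — the hook the panel simulator uses to impose
    cross-species island correlation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_per = config.n_genes // config.n_chromosomes
    if n_per == 0:
        raise ValueError("need at least one gene per chromosome")
    slot = config.chrom_length // n_per
    need = config.gene_length_range[1] + 2 * (config.flank + 100)
    if slot < need:
        raise ValueError(
            f"infeasible packing: {n_per} genes need {need} bp each but slots are {slot} bp"
        )

    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)
    }
    chrom_names = sorted(chrom_lengths)

    # --- gene placement and truth labels -------------------------------
    genes: list[GeneModel] = []
    for chrom in chrom_names:
        for j in range(n_per):
            glen = int(rng.integers(*config.gene_length_range, endpoint=True))
            lo = j * slot + config.flank + 100
            hi = (j + 1) * slot - config.flank - 100 - glen
            start = int(rng.integers(lo, max(lo + 1, hi)))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"{species}_g{len(genes):04d}"
            # two exons separated by a 20% intron in the middle
            e1 = (start, start + int(glen * 0.4))
            e2 = (start + int(glen * 0.6), start + glen)
            genes.append(GeneModel(gid, chrom, start, start + glen, strand, [e1, e2]))

    n_genes = len(genes)
    if forced_islands is not None:
        if len(forced_islands) != n_genes:
            raise ValueError("forced_islands length must equal the gene count")
        island_flags = np.asarray(forced_islands, dtype=bool)
    else:
        island_flags = rng.random(n_genes) < config.island_fraction
    gbm_flags = rng.random(n_genes) < config.gbm_fraction
    te_flags = rng.random(n_genes) < config.te_fraction

    # --- island tracts and TEs ----------------------------------------
    tracts: list[tuple[str, int, int]] = []
    tract_per_gene: list[tuple[int, int] | None] = []
    for gene, has_island in zip(genes, island_flags):
        if not has_island:
            tract_per_gene.append(None)
            continue
        tlen = int(rng.integers(*config.island_len_range, endpoint=True))
        offset = int(rng.integers(0, max(1, config.island_offset_max - tlen + 1)))
        lo, hi = gene.flank5(config.flank)
        if gene.strand == "+":
            b = hi - offset
            a = b - tlen
        else:
            a = lo + offset
            b = a + tlen
        a, b = max(a, 0), min(b, chrom_lengths[gene.chrom])
        tracts.append((gene.chrom, a, b))
        tract_per_gene.append((a, b))

    fams = list(config.te_superfamily_weights)
    wts = np.array([config.te_superfamily_weights[f] for f in fams], dtype=float)
    wts = wts / wts.sum()
    repeats: list[RepeatFeature] = []
    te_fam_per_gene: list[str | None] = []
    for gene, has_te in zip(genes, te_flags):
        if not has_te:
            te_fam_per_gene.append(None)
            continue
        fam = fams[int(rng.choice(len(fams), p=wts))]
        tlen = int(rng.integers(500, 2500, endpoint=True))
        offset = int(rng.integers(0, config.island_offset_max))
        lo, hi = gene.flank5(config.flank)
        if gene.strand == "+":
            b = hi - offset
            a = b - tlen
        else:
            a = lo + offset
            b = a + tlen
        a = max(a, 0)
        b = min(b, chrom_lengths[gene.chrom])
        if b - a >= 50:
            repeats.append(RepeatFeature(gene.chrom, a, b, fam))
            te_fam_per_gene.append(fam)
        else:
            te_fam_per_gene.append(None)
    # a few intergenic background TEs per chromosome
    for chrom in chrom_names:
        for _ in range(max(1, n_per // 4)):
            tlen = int(rng.integers(500, 2500, endpoint=True))
            a = int(rng.integers(0, chrom_lengths[chrom] - tlen))
            fam = fams[int(rng.choice(len(fams), p=wts))]
            repeats.append(RepeatFeature(chrom, a, a + tlen, fam))

    # --- per-site methylation rates and counts -------------------------
    frames = []
    eps = 1e-6
    bg = np.array(
        [config.background["CG"], config.background["CHG"], config.background["CHH"]]
    )
    isl = np.array(
        [
            min(config.background["CG"] + config.island_cg_boost, 0.95),
            min(config.background["CHG"] + config.island_chg_boost, 0.95),
            config.island_chh_level,
        ]
    )
    for chrom in chrom_names:
        seq = rng.integers(0, 4, size=chrom_lengths[chrom], dtype=np.int8)
        pos, strand, ctx = _derive_contexts(seq)
        rate = bg[ctx].copy()
        for (tchrom, a, b) in tracts:
            if tchrom != chrom:
                continue
            lo, hi = np.searchsorted(pos, [a, b])
            rate[lo:hi] = isl[ctx[lo:hi]]
        for gene, gbm in zip(genes, gbm_flags):
            if gene.chrom != chrom or not gbm:
                continue
            for s, e in gene.exons:
                lo, hi = np.searchsorted(pos, [s, e])
                sel = slice(lo, hi)
                cg = ctx[sel] == 0
                seg = rate[sel]
                seg[cg] = config.gbm_cg_level
                rate[sel] = seg
        depth = rng.poisson(config.coverage_mean, size=len(pos))
        if config.binomial_counts:
            n_meth = rng.binomial(depth, rate)
        else:
            conc = config.overdispersion
            p_site = rng.beta(
                np.clip(rate, eps, 1 - eps) * conc,
                np.clip(1 - rate, eps, 1 - eps) * conc,
            )
            n_meth = rng.binomial(depth, p_site)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "strand": _STRAND_NAMES[strand],
                    "context": _CTX_NAMES[ctx],
                    "n_meth": n_meth.astype(np.int64),
                    "n_total": depth.astype(np.int64),
                }
            )
        )
    methylome = Methylome(pd.concat(frames, ignore_index=True))

    # --- expression -----------------------------------------------------
    expression: dict[str, float] = {}
    expressed = rng.random(n_genes) < config.expressed_fraction
    log2_rpkm = rng.normal(3.0, 2.0, size=n_genes)
    for gene, on, lv in zip(genes, expressed, log2_rpkm):
        if on:
            expression[gene.gene_id] = float(2.0 ** lv)

    truth_rows = []
    for i, gene in enumerate(genes):
        tract = tract_per_gene[i]
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "island_planted": bool(island_flags[i]),
                "island_start": tract[0] if tract else -1,
                "island_end": tract[1] if tract else -1,
                "gbm_planted": bool(gbm_flags[i]),
                "te_planted": te_fam_per_gene[i] is not None,
                "te_superfamily": te_fam_per_gene[i] or "",
                "rpkm": expression.get(gene.gene_id, float("nan")),
            }
        )
    truth = SimTruth(pd.DataFrame(truth_rows).set_index("gene_id"), tracts)
    return SimulatedSpecies(
        species, config, chrom_lengths, methylome, genes, repeats, expression, truth
    )


def simulate_island_matrix(p_by_species: Sequence[float], n_orthologs: int,
                           rho: float,
                           rng: np.random.Generator | None = None,
                           seed: int | None = None) -> np.ndarray:
    """Boolean ortholog x species island matrix with marginals ``p_s`` and
    pairwise latent correlation ``rho`` (equicorrelated Gaussian copula).

    ``rho = 0`` gives independent columns (the random regime); ``rho > 0``
    gives detectable cross-species conservation.
    """
    p = np.asarray(p_by_species, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("marginal proportions must lie strictly in (0,1)")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    k = p.size
    shared = rng.standard_normal((n_orthologs, 1))
    indep = rng.standard_normal((n_orthologs, k))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
    return z < stats.norm.ppf(p)


@dataclass
class SimulatedPanel:
    species: list[str]
    per_species: dict[str, SimulatedSpecies]
    ortholog_table: pd.DataFrame   # ortholog_id index, one gene-id column per species
    island_matrix: pd.DataFrame    # ortholog_id x species booleans (planted truth)
    tree_newick: str

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {sp: sim.write(outdir) for sp, sim in self.per_species.items()}
        ortho = outdir / "orthologs.tsv"
        self.ortholog_table.to_csv(ortho, sep="\t")
        tree = outdir / "species.nwk"
        tree.write_text(self.tree_newick + "\n")
        paths["orthologs"] = ortho
        paths["tree"] = tree
        return paths


def _random_tree(species: Sequence[str], seed: int) -> str:
    """Random coalescent-style species tree with branch lengths (newick)."""
    import dendropy
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace(list(species))
    tree = treesim.pure_kingman_tree(
        taxon_namespace=taxa, pop_size=1.0, rng=_pyrandom.Random(seed)
    )
    return tree.as_string(schema="newick").strip()


def simulate_panel(config: SimConfig) -> SimulatedPanel:
    """Simulate a multi-species ortholog panel with shared ortholog ids.

    Island indicators are drawn once from the Gaussian copula (marginals
    ``island_p_by_species`` or the common ``island_fraction``; correlation
    ``rho``) and imposed on each species' generator, so the planted island
    matrix is the panel's ground truth.
    """
    if config.n_species < 2:
        raise ValueError("a panel needs n_species >= 2")
    rng = np.random.default_rng(config.seed)
    species = [f"sp{i + 1}" for i in range(config.n_species)]
    if config.island_p_by_species is not None:
        p = list(config.island_p_by_species)
        if len(p) != config.n_species:
            raise ValueError("island_p_by_species length must equal n_species")
    else:
        p = [config.island_fraction] * config.n_species
    matrix = simulate_island_matrix(p, config.n_genes, config.rho, rng=rng)

    ortho_ids = [f"og{i:05d}" for i in range(config.n_genes)]
    per_species = {}
    table = {}
    for s_idx, sp in enumerate(species):
        child_seed = int(rng.integers(2**31))
        child_cfg = replace(config, seed=child_seed)
        sim = simulate_species(
            child_cfg, species=sp, forced_islands=matrix[:, s_idx],
            rng=np.random.default_rng(child_seed),
        )
        per_species[sp] = sim
        table[sp] = [g.gene_id for g in sim.genes]
    ortholog_table = pd.DataFrame(table, index=pd.Index(ortho_ids, name="ortholog_id"))
    island_df = pd.DataFrame(
        matrix, index=ortholog_table.index, columns=species
    )
    tree = _random_tree(species, seed=int(rng.integers(2**31)))
    return SimulatedPanel(species, per_species, ortholog_table, island_df, tree)
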