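"""Published summary values for the eight-species grass panel.

These are the printed per-species summaries from the comparative study of
upstream mCHH islands in Poaceae: genome sizes, the percentage of genes
and of 1-to-1 orthologs associated with a 5' island in each species, and,
for barley, rice and maize, the per-TE-superfamily counts of genes with a
nearest upstream TE within 2 kb together with the fraction of those genes
carrying an island.  They serve as inputs to the package's internal
consistency checks and worked examples (e.g. the random-model expected
species count is plain arithmetic on the ortholog proportions).
"""

from __future__ import annotations

SPECIES = (
    "Brachypodium distachyon",
    "Hordeum vulgare",
    "Oryza sativa",
    "Phyllostachys heterocycla",
    "Setaria italica",
    "Sorghum bicolor",
    "Triticum urartu",
    "Zea mays",
)

GENOME_SIZE_MB = {
    "Brachypodium distachyon": 355,
    "Hordeum vulgare": 5428,
    "Oryza sativa": 489,
    "Phyllostachys heterocycla": 2075,
    "Setaria italica": 513,
    "Sorghum bicolor": 734,
    "Triticum urartu": 4817,
    "Zea mays": 2655,
}

#: Percentage of genes associated with an mCHH island within the flanking
#: 5' or 3' 2.0 kb.
PCT_ISLAND_GENES = {
    "Brachypodium distachyon": 55.16,
    "Hordeum vulgare": 28.22,
    "Oryza sativa": 71.85,
    "Phyllostachys heterocycla": 17.27,
    "Setaria italica": 29.80,
    "Sorghum bicolor": 54.01,
    "Triticum urartu": 22.94,
    "Zea mays": 30.85,
}

#: Percentage of the 2,720 one-to-one orthologs associated with a 5' mCHH
#: island in each species.
PCT_ISLAND_ORTHOLOGS = {
    "Brachypodium distachyon": 58.20,
    "Hordeum vulgare": 41.34,
    "Oryza sativa": 76.61,
    "Phyllostachys heterocycla": 18.51,
    "Setaria italica": 34.31,
    "Sorghum bicolor": 59.91,
    "Triticum urartu": 28.29,
    "Zea mays": 38.73,
}

N_ORTHOLOGS = 2720

#: Per-superfamily counts for barley, rice and maize: for each Wicker
#: superfamily, (n genes whose closest upstream TE within 2 kb belongs to
#: the superfamily, fraction of those genes with a 5' island, published
#: enrichment label at BH FDR < 0.05 against the pooled proportion).
TE_SUPERFAMILY_TABLE = {
    "Hordeum vulgare": {
        "DHH": (69, 0.174, "NS"),
        "DTA": (21, 0.095, "NS"),
        "DTC": (3480, 0.280, "NS"),
        "DTH": (478, 0.460, "Enriched"),
        "DTM": (654, 0.378, "Enriched"),
        "DTT": (474, 0.430, "Enriched"),
        "DTX": (332, 0.497, "Enriched"),
        "RIX": (880, 0.227, "Under"),
        "RLC": (4896, 0.239, "Under"),
        "RLG": (4413, 0.213, "Under"),
        "RLX": (11356, 0.315, "Enriched"),
        "RSX": (76, 0.316, "NS"),
    },
    "Oryza sativa": {
        "DHH": (132, 0.417, "Under"),
        "DTA": (517, 0.768, "NS"),
        "DTC": (1243, 0.474, "Under"),
        "DTH": (40, 0.700, "NS"),
        "DTM": (1106, 0.806, "Enriched"),
        "DTT": (2143, 0.898, "Enriched"),
        "DTX": (6476, 0.882, "Enriched"),
        "RIX": (551, 0.611, "Under"),
        "RLC": (1433, 0.651, "Under"),
        "RLG": (2230, 0.580, "Under"),
        "RLX": (10753, 0.704, "Under"),
        "RSX": (796, 0.932, "Enriched"),
    },
    "Zea mays": {
        "DHH": (5235, 0.283, "Under"),
        "DTA": (653, 0.542, "Enriched"),
        "DTC": (184, 0.429, "Enriched"),
        "DTH": (2677, 0.536, "Enriched"),
        "DTM": (122, 0.623, "Enriched"),
        "DTT": (2307, 0.389, "Enriched"),
        "DTX": (299, 0.408, "Enriched"),
        "RIX": (87, 0.253, "NS"),
        "RLC": (3148, 0.280, "Under"),
        "RLG": (3891, 0.292, "Under"),
        "RLX": (2632, 0.224, "Under"),
        "RSX": (43, 0.302, "NS"),
    },
}

#: Printed pooled totals of the superfamily table: (total n, pooled
#: proportion of genes with both a TE within 2 kb and an island).
TE_SUPERFAMILY_TOTALS = {
    "Hordeum vulgare": (27129, 0.285),
    "Oryza sativa": (27420, 0.747),
    "Zea mays": (21278, 0.333),
}


def ortholog_island_proportions() -> list[float]:
    """Per-species ortholog island proportions (0-1), in species order."""
    return [PCT_ISLAND_ORTHOLOGS[s] / 100.0 for s in SPECIES]


def reconstruct_superfamily_counts(species: str):
    """Rebuild integer island counts k = round(n * proportion) per
    superfamily for one species, as a DataFrame suitable for
    :func:`mchh_islands.te.superfamily_enrichment` checks."""
    import pandas as pd

    rows = []
    for fam, (n, prop, label) in TE_SUPERFAMILY_TABLE[species].items():
        rows.append((fam, n, int(round(n * prop)), prop, label))
    return pd.DataFrame(
        rows, columns=["superfamily", "n", "k", "proportion", "published_label"]
    )
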