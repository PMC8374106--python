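"""Cross-species conservation of island status among 1-to-1 orthologs.

The ortholog panel is a DataFrame of booleans (ortholog x species; NaN
marks an ortholog failing the coverage filter in that species).  Pairwise
conservation is summarised as observed / expected counts of
island-in-both orthologs, with the expectation taken under independence
(N * p_i * p_j over the doubly-scored subset), and tested with a label
permutation.  A purely random model for the per-ortholog species count is
the independent-Bernoulli (Poisson-binomial) model whose mean is the sum
of the per-species proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from mchh_islands.regression import OlsFit, ols_fit


@dataclass
class PairEnrichment:
    species_i: str
    species_j: str
    n: int              # orthologs scored in both species
    p_i: float
    p_j: float
    observed: int       # island in both
    expected: float     # n * p_i * p_j
    enrichment: float   # observed / expected


def _pair_subset(panel: pd.DataFrame, species_i: str, species_j: str):
    for s in (species_i, species_j):
        if s not in panel.columns:
            raise KeyError(f"species {s!r} not in panel")
    sub = panel[[species_i, species_j]].dropna()
    return sub[species_i].astype(bool).to_numpy(), sub[species_j].astype(bool).to_numpy()


def pairwise_enrichment(panel: pd.DataFrame, species_i: str,
                        species_j: str) -> PairEnrichment:
    """Observed over expected count of orthologs carrying an island in both
    species; expectation under independence from the per-pair proportions."""
    a, b = _pair_subset(panel, species_i, species_j)
    n = len(a)
    p_i, p_j = a.mean() if n else 0.0, b.mean() if n else 0.0
    observed = int(np.sum(a & b))
    expected = n * p_i * p_j
    if expected == 0:
        raise ValueError(
            f"expected count is zero (p_{species_i}={p_i}, p_{species_j}={p_j})"
        )
    return PairEnrichment(
        species_i, species_j, n, float(p_i), float(p_j), observed,
        float(expected), observed / expected,
    )


def permutation_test(panel: pd.DataFrame, species_i: str, species_j: str,
                     n_perm: int = 10000, seed: int | None = None,
                     rng: np.random.Generator | None = None) -> float:
    """One-sided permutation p-value for excess island co-occurrence.

    Each permutation shuffles one species' island labels across orthologs
    (shuffling both is equivalent in distribution);
    p = (1 + #{perm observed >= real observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value")
    if rng is None:
        rng = np.random.default_rng(seed)
    a, b = _pair_subset(panel, species_i, species_j)
    observed = int(np.sum(a & b))
    perms = rng.permuted(np.tile(b, (n_perm, 1)), axis=1)
    perm_obs = perms[:, a].sum(axis=1)
    return float((1 + np.sum(perm_obs >= observed)) / (n_perm + 1))


def random_model_mean(p_by_species: Sequence[float]) -> float:
    """Expected per-ortholog species count under independent Bernoulli
    draws: the sum of the per-species island proportions."""
    p = np.asarray(p_by_species, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    return float(p.sum())


def monte_carlo_species_count(p_by_species: Sequence[float], n_orthologs: int,
                              observed_mean: float | None = None,
                              n_reps: int = 10000,
                              seed: int | None = None,
                              alternative: str = "two-sided"):
    """Monte-Carlo check of the random model.

    Simulates ``n_reps`` panels of ``n_orthologs`` orthologs with
    independent per-species Bernoulli island indicators, returning the
    simulated mean-of-means, its standard error, and (when
    ``observed_mean`` is given) a permutation-style p-value for the
    observed mean against the simulated distribution.
    """
    p = np.asarray(p_by_species, dtype=float)
    rng = np.random.default_rng(seed)
    means = np.empty(n_reps)
    for r in range(n_reps):
        draws = rng.random((n_orthologs, p.size)) < p
        means[r] = draws.sum(axis=1).mean()
    result = {
        "mc_mean": float(means.mean()),
        "mc_se": float(means.std(ddof=1) / np.sqrt(n_reps)),
        "mc_sd": float(means.std(ddof=1)),
    }
    if observed_mean is not None:
        center = p.sum()
        if alternative == "two-sided":
            extreme = np.abs(means - center) >= abs(observed_mean - center)
        elif alternative == "greater":
            extreme = means >= observed_mean
        elif alternative == "less":
            extreme = means <= observed_mean
        else:
            raise ValueError("alternative must be two-sided/greater/less")
        result["p_value"] = float((1 + extreme.sum()) / (n_reps + 1))
    return result


def count_distribution(panel: pd.DataFrame):
    """Histogram of per-ortholog island counts (0..n_species), with the
    observed mean and median.  Missing (NaN) entries count as no island
    for the tally but the ortholog must be scored in >= 1 species."""
    scored = panel.notna().sum(axis=1) > 0
    counts = panel.loc[scored].fillna(False).astype(bool).sum(axis=1)
    hist = counts.value_counts().reindex(
        range(panel.shape[1] + 1), fill_value=0
    ).sort_index()
    return hist, float(counts.mean()), float(counts.median())


def conservation_lm(panel: pd.DataFrame, variable: pd.DataFrame) -> OlsFit:
    """OLS of the per-ortholog island count on a genic variable averaged
    per ortholog across species (mean over species with data)."""
    counts = panel.fillna(False).astype(bool).sum(axis=1)
    avg = variable.mean(axis=1, skipna=True)
    common = counts.index.intersection(avg.index)
    return ols_fit(counts.loc[common].to_numpy(), avg.loc[common].to_numpy())
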