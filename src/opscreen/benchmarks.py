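"""Database-style benchmarking of perturbation profiles.

Validates screen profiles against external annotation resources:
within-protein-complex profile correlations versus the background of all
hit-gene pairs (CORUM-style), pairwise link-score distributions binned
by profile correlation (STRING-style), essential/nonessential signal
score split by gene-dependency threshold, and cosine-similarity
rankings consumable by preranked enrichment tools.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd

from .profiles import ProfileTable


def _gene_matrix(gene_profiles: ProfileTable) -> tuple[list[str], np.ndarray]:
    frame = gene_profiles.frame
    if "Metadata_gene" not in frame.columns:
        raise KeyError("profiles must carry Metadata_gene")
    genes = frame["Metadata_gene"].tolist()
    X = frame[gene_profiles.features].to_numpy(dtype=float)
    return genes, X


def complex_correlations(
    gene_profiles: ProfileTable,
    complexes: dict[str, list[str]],
    min_frac: Fraction | float = Fraction(1, 3),
):
    """Within-complex versus background profile correlations.

    A complex is retained if at least ``min_frac`` of its annotated
    subunits are among the profiled (hit) genes — compared with exact
    rational arithmetic, so 2 of 6 subunits meets the one-third rule.
    Returns (within, background): Pearson r over all profiled-member
    pairs of each retained complex, and over all profiled gene pairs.
    """
    genes, X = _gene_matrix(gene_profiles)
    pos = {g: i for i, g in enumerate(genes)}
    if not isinstance(min_frac, Fraction):
        min_frac = Fraction(min_frac).limit_denominator(10**6)
    within: list[float] = []
    for members in complexes.values():
        present = [g for g in members if g in pos]
        if Fraction(len(present), len(members)) < min_frac:
            continue
        for a, b in itertools.combinations(present, 2):
            r = np.corrcoef(X[pos[a]], X[pos[b]])[0, 1]
            within.append(float(r))
    background: list[float] = []
    if len(genes) >= 2:
        corr = np.corrcoef(X)
        iu = np.triu_indices(len(genes), k=1)
        background = corr[iu].tolist()
    return within, background


def binned_pair_scores(
    gene_profiles: ProfileTable,
    pair_scores: pd.DataFrame,
    n_bins: int = 8,
    bin_range: tuple[float, float] = (-1.0, 1.0),
) -> dict[int, list[int]]:
    """Distribution of link scores in equal-width profile-correlation
    bins.

    Correlation bins span ``bin_range`` (fixed to [-1, 1] by default for
    comparability across screens) and are right-closed; every scored
    pair with both profiles present falls in exactly one bin.
    """
    genes, X = _gene_matrix(gene_profiles)
    pos = {g: i for i, g in enumerate(genes)}
    lo, hi = bin_range
    edges = np.linspace(lo, hi, n_bins + 1)
    bins: dict[int, list[int]] = {b: [] for b in range(n_bins)}
    for gene_a, gene_b, score in pair_scores[["gene_a", "gene_b", "score"]].itertuples(
        index=False
    ):
        ia, ib = pos.get(gene_a), pos.get(gene_b)
        if ia is None or ib is None or ia == ib:
            continue
        r = float(np.corrcoef(X[ia], X[ib])[0, 1])
        b = int(np.digitize(r, edges[1:-1], right=True))
        bins[b].append(int(score))
    return bins


def essentiality_split(
    signal_scores: pd.Series,
    dependency: pd.Series,
    threshold: float = -0.5,
) -> tuple[pd.Series, pd.Series]:
    """Split signal scores by gene essentiality: a gene is essential iff
    its dependency score is strictly below ``threshold`` (the boundary
    value itself is nonessential). Only genes present in both inputs
    are considered."""
    common = signal_scores.index.intersection(dependency.index)
    dep = dependency.loc[common]
    ess = signal_scores.loc[common[dep < threshold]]
    non = signal_scores.loc[common[dep >= threshold]]
    return ess, non


def rank_by_similarity(gene_profiles: ProfileTable, query: str) -> pd.Series:
    """Genes ranked by descending cosine similarity to the query gene's
    profile (query excluded) — the input ranking for preranked
    enrichment analyses."""
    genes, X = _gene_matrix(gene_profiles)
    pos = {g: i for i, g in enumerate(genes)}
    if query not in pos:
        raise KeyError(f"unknown query gene {query!r}")
    q = X[pos[query]]
    qn = np.linalg.norm(q)
    if qn == 0.0:
        raise ValueError("query profile has zero norm")
    norms = np.linalg.norm(X, axis=1)
    norms[norms == 0.0] = np.nan
    sims = (X @ q) / (norms * qn)
    s = pd.Series(sims, index=genes).drop(index=query)
    return s.sort_values(ascending=False, kind="stable")


def write_rnk(ranking: pd.Series, path: str) -> None:
    """Write a two-column .rnk file (gene, score) for enrichment tools."""
    ranking.to_csv(path, sep="\t", header=False)
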