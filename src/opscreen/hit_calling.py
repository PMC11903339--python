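"""Per-feature rank tests, profile scores and empirical-null FDR hit calls.

For each gene, the distribution of every feature across the gene's guide
profiles is compared with the nontargeting control guides by a two-sided
Mann-Whitney U-test. The profile score counts features significant at
alpha (default 0.001); the morphological signal score sums -log10 p over
those features. Hit thresholds are order statistics of the profile-score
distribution of unexpressed (zero-TPM) genes — a second, empirical null
that absorbs nonspecific effects of CRISPR cutting — so that at FDR f at
most a fraction f of the null genes can sit strictly above the
threshold. Compartment hits repeat the procedure on each channel's
feature subset (texture, intensity, correlation, radial distribution and
granularity measures from that channel) against that channel's own
zero-TPM percentile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import CHANNELS, ProfileTable, channel_feature_mask
from .synthetic import NONTARGETING_GENE

DEFAULT_ALPHA = 1e-3
DEFAULT_FDR = 0.01


def feature_pvalues(
    gene_units: pd.DataFrame, control_units: pd.DataFrame
) -> pd.Series:
    """Two-sided Mann-Whitney U p-value per feature, comparing one
    gene's guide profiles with the nontargeting guide profiles.

    The exact null distribution is used when the smaller group has <= 8
    units and there are no ties; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    if list(gene_units.columns) != list(control_units.columns):
        raise ValueError("gene and control units must share one feature set")
    if len(gene_units) < 2:
        raise ValueError("need at least 2 gene units")
    if len(control_units) < 8:
        raise ValueError("need at least 8 control units")
    x = gene_units.to_numpy(dtype=float)
    y = control_units.to_numpy(dtype=float)
    res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided", method="auto")
    return pd.Series(res.pvalue, index=gene_units.columns, name="p")


@dataclass
class GeneScore:
    """Per-gene outcome of the feature-level rank tests."""

    gene: str
    p_values: pd.Series
    profile_score: int
    signal_score: float
    per_channel_scores: dict[str, int]
    n_units: int
    alpha: float


def score_gene(
    gene: str,
    p_values: pd.Series,
    alpha: float = DEFAULT_ALPHA,
    channel_masks: dict[str, np.ndarray] | None = None,
    n_units: int = 0,
) -> GeneScore:
    """Profile score (count of features with p < alpha), morphological
    signal score (sum of -log10 p over those features) and per-channel
    significant-feature counts."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    p = p_values.to_numpy(dtype=float)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    sig = p < alpha
    profile_score = int(sig.sum())
    signal_score = float(-np.log10(p[sig]).sum()) if profile_score else 0.0
    if channel_masks is None:
        channel_masks = {
            ch: channel_feature_mask(list(p_values.index), ch) for ch in CHANNELS
        }
    per_channel = {ch: int((sig & m).sum()) for ch, m in channel_masks.items()}
    return GeneScore(gene, p_values, profile_score, signal_score, per_channel, n_units, alpha)


def score_screen(
    guide_profiles: ProfileTable,
    alpha: float = DEFAULT_ALPHA,
    control_gene: str = NONTARGETING_GENE,
    channels: tuple[str, ...] = CHANNELS,
) -> dict[str, GeneScore]:
    """Score every targeting gene of a guide-level profile table against
    the nontargeting guides.

    Genes with fewer than two guide profiles cannot be tested and are
    skipped with a warning.
    """
    frame = guide_profiles.frame
    features = guide_profiles.features
    is_control = frame["Metadata_gene"] == control_gene
    controls = frame.loc[is_control, features]
    if len(controls) < 8:
        raise ValueError("need at least 8 nontargeting guide profiles")
    masks = {ch: channel_feature_mask(features, ch, channels) for ch in channels}
    scores: dict[str, GeneScore] = {}
    skipped = []
    for gene, sub in frame.loc[~is_control].groupby("Metadata_gene", sort=True):
        if len(sub) < 2:
            skipped.append(gene)
            continue
        p = feature_pvalues(sub[features], controls)
        scores[gene] = score_gene(gene, p, alpha, masks, n_units=len(sub))
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} genes with <2 guide profiles", stacklevel=2
        )
    return scores


def scores_frame(scores: dict[str, GeneScore], channels=CHANNELS) -> pd.DataFrame:
    """Tabulate GeneScores: one row per gene with profile, signal and
    per-channel scores."""
    rows = []
    for gene, s in scores.items():
        row = {
            "gene": gene,
            "profile_score": s.profile_score,
            "signal_score": s.signal_score,
            "n_units": s.n_units,
        }
        for ch in channels:
            row[f"score_{ch}"] = s.per_channel_scores.get(ch, 0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def empirical_threshold(null_scores, fdr: float = DEFAULT_FDR) -> float:
    """Order-statistic hit threshold from the empirical null: the null
    score at ascending rank ceil((1 - fdr) * m), no interpolation. Hits
    must fall strictly above it, which caps the flagged null fraction at
    fdr (plus at most one order-statistic step)."""
    arr = np.sort(np.asarray(list(null_scores), dtype=float))
    m = arr.size
    if m == 0:
        raise ValueError("empty null score set")
    if not (0.0 < fdr < 1.0):
        raise ValueError("fdr must be in (0, 1)")
    if m < math.ceil(1.0 / fdr):
        warnings.warn(
            f"only {m} null scores for fdr={fdr}; threshold is coarse", stacklevel=2
        )
    rank = math.ceil((1.0 - fdr) * m)  # 1-based
    rank = min(max(rank, 1), m)
    return float(arr[rank - 1])


@dataclass
class HitTable:
    """Hit calls at one FDR level: per-gene flags plus the thresholds
    and null set that produced them."""

    table: pd.DataFrame  # per gene: scores, whole_cell_hit, hit_<channel> flags
    thresholds: dict[str, float]  # "whole_cell" and one entry per channel
    fdr_level: float
    null_set: list[str] = field(default_factory=list)


def call_hits(
    scores: dict[str, GeneScore] | pd.DataFrame,
    null_genes,
    fdr: float = DEFAULT_FDR,
    channels: tuple[str, ...] = CHANNELS,
) -> HitTable:
    """Flag whole-cell and compartment hits against zero-TPM empirical
    null thresholds.

    Each channel uses its own null percentile, so a gene can be a
    compartment hit without being a whole-cell hit (and vice versa).
    ``null_genes`` must all carry scores; nontargeting controls are the
    test's control arm, never part of the null set.
    """
    df = scores if isinstance(scores, pd.DataFrame) else scores_frame(scores, channels)
    null_genes = list(null_genes)
    missing = [g for g in null_genes if g not in df.index]
    if missing:
        raise KeyError(f"null genes without scores: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    null_df = df.loc[null_genes]
    thresholds = {"whole_cell": empirical_threshold(null_df["profile_score"], fdr)}
    out = df.copy()
    out["whole_cell_hit"] = out["profile_score"] > thresholds["whole_cell"]
    for ch in channels:
        thresholds[ch] = empirical_threshold(null_df[f"score_{ch}"], fdr)
        out[f"hit_{ch}"] = out[f"score_{ch}"] > thresholds[ch]
    hit_cols = [f"hit_{ch}" for ch in channels]
    out["compartment_hit"] = out[hit_cols].any(axis=1)
    return HitTable(table=out, thresholds=thresholds, fdr_level=fdr, null_set=null_genes)


def call_hits_grid(
    scores: dict[str, GeneScore] | pd.DataFrame,
    null_genes,
    fdr_levels=(0.01, 0.02, 0.03, 0.04, 0.05),
    channels: tuple[str, ...] = CHANNELS,
) -> dict[float, HitTable]:
    """Hit calls across a grid of FDR stringencies (hit lists grow as
    the FDR is relaxed)."""
    return {f: call_hits(scores, null_genes, f, channels) for f in fdr_levels}


def channel_fractions(
    scores: dict[str, GeneScore] | list[GeneScore],
    feature_names: list[str],
    gene_set=None,
    channels: tuple[str, ...] = CHANNELS,
) -> pd.Series:
    """Average normalized fraction of significant features per channel
    for a gene set.

    Per gene, each channel's significant-feature count is divided by
    that channel's feature count, the five ratios are renormalized to
    sum to 1, and the resulting fractions are averaged over the set.
    Genes with zero significant features are excluded with a warning.
    """
    if isinstance(scores, dict):
        items = list(scores.values())
    else:
        items = list(scores)
    if gene_set is not None:
        gene_set = set(gene_set)
        items = [s for s in items if s.gene in gene_set]
    if not items:
        raise ValueError("empty gene set")
    sizes = {
        ch: max(int(channel_feature_mask(feature_names, ch, channels).sum()), 1)
        for ch in channels
    }
    rows = []
    excluded = 0
    for s in items:
        ratios = np.array(
            [s.per_channel_scores.get(ch, 0) / sizes[ch] for ch in channels], dtype=float
        )
        tot = ratios.sum()
        if tot == 0.0:
            excluded += 1
            continue
        rows.append(ratios / tot)
    if excluded:
        warnings.warn(
            f"excluded {excluded} genes with zero significant features", stacklevel=2
        )
    if not rows:
        raise ValueError("no gene in the set has significant features")
    mean = np.mean(rows, axis=0)
    return pd.Series(mean, index=list(channels), name="fraction")
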