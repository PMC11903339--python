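"""Single-feature genome-wide screens.

Each individual morphological feature defines a screen of its own: genes
are ranked by the feature's rank-test p-value (as produced during hit
calling), a "top 20+" most-perturbed list is cut at the 20th gene's
p-value (ties extend the list), and gene-set enrichment within that list
is assessed by a one-sided Fisher exact test with Benjamini-Hochberg
FDR control plus an additional Bonferroni column. Granularity spectra —
the ordered per-size granularity values of normalized (but not
feature-selected) gene profiles — expose compositional mass shifts such
as the loss at small erosion sizes with compensatory gains at larger
sizes characteristic of lysosomal-acidification perturbations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import ProfileTable, parse_feature_name


def top_gene_list(feature_pvals: pd.Series, rank_cut: int = 20) -> list[str]:
    """All genes with p-value <= that of the gene at ``rank_cut`` when
    sorted ascending; ties at the cutoff extend the list, so its size is
    at least ``rank_cut`` whenever that many genes were tested."""
    s = feature_pvals.sort_values(kind="stable")
    if len(s) < rank_cut:
        warnings.warn(
            f"only {len(s)} genes tested (< rank_cut={rank_cut}); returning all",
            stacklevel=2,
        )
        return s.index.tolist()
    cutoff = s.iloc[rank_cut - 1]
    return s[s <= cutoff].index.tolist()


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a tested-gene universe."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("universe contains duplicates")
        self.sets = {
            name: sorted(uni.intersection(members)) for name, members in self.sets.items()
        }


def set_enrichment(
    hits: list[str],
    collection: GeneSetCollection,
    bonferroni_alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of each gene set in a hit list.

    The 2x2 table per set counts (hit, in-set), (hit, out-of-set),
    (non-hit, in-set), (non-hit, out-of-set) over the universe.
    Benjamini-Hochberg adjusted p-values are reported alongside an
    additional Bonferroni-adjusted column and a flag at
    ``bonferroni_alpha``.
    """
    universe = set(collection.universe)
    if not universe:
        raise ValueError("empty universe")
    hit_set = set(hits)
    if not hit_set <= universe:
        raise ValueError("hits must be a subset of the universe")
    rows = []
    for name, members in collection.sets.items():
        mem = set(members)
        a = len(hit_set & mem)
        b = len(hit_set) - a
        c = len(mem) - a
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "set": name,
                "n_hit_in_set": a,
                "n_hit_out": b,
                "n_nonhit_in_set": c,
                "n_nonhit_out": d,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
        out["significant"] = out["p_bonferroni"] < bonferroni_alpha
        out = out.sort_values("p", kind="stable")
    return out


def granularity_spectrum(
    profiles: ProfileTable,
    channel: str,
    gene_group: list[str],
    object: str = "Cells",
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene granularity spectra and the group mean trace.

    Reads the ordered granularity features 1..G for (object, channel)
    from normalized, NOT feature-selected gene profiles. Returns a
    (gene x size) table and the mean trace over the group.
    """
    if profiles.feature_selected:
        raise ValueError("granularity spectra use non-feature-selected profiles")
    sizes: dict[int, str] = {}
    for name in profiles.features:
        try:
            meta = parse_feature_name(name)
        except ValueError:
            continue
        if (
            meta.feature_class == "Granularity"
            and meta.object == object
            and meta.channels == (channel,)
        ):
            sizes[int(meta.params[0])] = name
    if not sizes:
        raise KeyError(f"no granularity features for ({object}, {channel})")
    g_max = max(sizes)
    missing = [i for i in range(1, g_max + 1) if i not in sizes]
    if missing:
        raise KeyError(f"missing granularity size indices {missing} for {channel}")
    cols = [sizes[i] for i in range(1, g_max + 1)]
    frame = profiles.frame.set_index("Metadata_gene")
    absent = [g for g in gene_group if g not in frame.index]
    if absent:
        raise KeyError(f"genes without profiles: {absent[:5]}")
    spectra = frame.loc[gene_group, cols].astype(float)
    spectra.columns = pd.RangeIndex(1, g_max + 1, name="size")
    mean_trace = spectra.mean(axis=0)
    mean_trace.name = "mean"
    return spectra, mean_trace
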