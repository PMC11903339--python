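"""Image-based morphological profile processing.

Turns single-cell feature tables from an optical pooled screen into
guide- and gene-level profiles following the standard image-based
profiling recipe:

1. median-aggregate single-cell profiles by guide, per plate;
2. standardize each feature per plate (subtract mean, divide by
   population s.d. across that plate's guide profiles);
3. feature selection — drop features with missing values, near-zero
   variance, and redundant features (pairwise Pearson |r| > 0.9);
4. median-aggregate per-plate guide profiles to one profile per guide,
   then guide profiles to one profile per gene;
5. optionally PCA-reduce gene profiles to the smallest number of
   components explaining a target fraction of variance.

Tables follow the ``Metadata_`` column-prefix convention: any column
whose name starts with ``Metadata_`` is treated as annotation, every
other column is a morphological feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

METADATA_PREFIX = "Metadata_"

#: Default phenotyping channels: nucleus, endoplasmic reticulum, actin
#: cytoskeleton, mitochondria, Golgi/plasma membrane.
CHANNELS = ("DNA", "ER", "Actin", "Mito", "WGA")

OBJECTS = frozenset({"Cells", "Cytoplasm", "Nuclei", "Image"})

FEATURE_CLASSES = frozenset(
    {
        "AreaShape",
        "Correlation",
        "Granularity",
        "Intensity",
        "Neighbors",
        "RadialDistribution",
        "Texture",
        "Location",
    }
)

#: Feature classes measured per stain; used to form per-compartment
#: feature subsets for compartment-level hit calling.
CHANNEL_CLASSES = frozenset(
    {"Texture", "Intensity", "Correlation", "RadialDistribution", "Granularity"}
)

#: Classes that never carry a channel label.
CHANNEL_FREE_CLASSES = frozenset({"AreaShape", "Neighbors"})


class FeatureNameError(ValueError):
    """Raised when a feature name does not follow Object_Class_Params_Channel."""


@dataclass(frozen=True)
class FeatureMeta:
    """Parsed feature name: segmented object, feature class, parameter
    tokens (e.g. granularity size index, texture scale) and 0-2 channel
    labels."""

    raw_name: str
    object: str
    feature_class: str
    params: tuple[str, ...]
    channels: tuple[str, ...]


def parse_feature_name(name: str, channels: tuple[str, ...] = CHANNELS) -> FeatureMeta:
    """Parse an underscore-delimited feature name such as
    ``Cells_Granularity_1_WGA``.

    Tokens matching a channel label are collected as channels wherever
    they appear (CellProfiler puts them before or after numeric
    parameters depending on the measurement class); the remaining middle
    tokens are parameters.
    """
    tokens = name.split("_")
    if len(tokens) < 2:
        raise FeatureNameError(f"feature name {name!r} has fewer than 2 tokens")
    obj, fclass = tokens[0], tokens[1]
    if obj not in OBJECTS:
        raise FeatureNameError(f"unknown object token {obj!r} in {name!r}")
    if fclass not in FEATURE_CLASSES:
        raise FeatureNameError(f"unknown feature class token {fclass!r} in {name!r}")
    chans = tuple(t for t in tokens[2:] if t in channels)
    params = tuple(t for t in tokens[2:] if t not in channels)
    if fclass == "Correlation" and len(chans) != 2:
        raise FeatureNameError(
            f"Correlation feature {name!r} must carry exactly 2 channels, got {len(chans)}"
        )
    if fclass in CHANNEL_FREE_CLASSES and chans:
        raise FeatureNameError(
            f"{fclass} feature {name!r} must not carry a channel label"
        )
    return FeatureMeta(name, obj, fclass, params, chans)


def channel_feature_mask(
    feature_names: list[str],
    channel: str,
    channels: tuple[str, ...] = CHANNELS,
) -> np.ndarray:
    """Boolean mask of features belonging to one compartment's subset:
    texture, intensity, correlation, radial-distribution and granularity
    features measured in that channel.

    A two-channel Correlation feature belongs to a channel's subset if
    the channel appears in either slot. Names that do not parse are not
    assigned to any channel.
    """
    mask = np.zeros(len(feature_names), dtype=bool)
    for i, name in enumerate(feature_names):
        try:
            meta = parse_feature_name(name, channels)
        except FeatureNameError:
            continue
        if meta.feature_class in CHANNEL_CLASSES and channel in meta.channels:
            mask[i] = True
    return mask


# ---------------------------------------------------------------------------
# ProfileTable
# ---------------------------------------------------------------------------

_LEVELS = ("cell", "plate_guide", "guide", "gene")


@dataclass
class ProfileTable:
    """A profile matrix (one row per unit) with processing-state flags.

    ``frame`` holds ``Metadata_*`` annotation columns plus feature
    columns. ``level`` records the aggregation unit. Flags are monotone
    along the pipeline; once ``pca_reduced`` the feature columns are
    principal-component scores.
    """

    frame: pd.DataFrame
    level: str
    normalized: bool = False
    feature_selected: bool = False
    pca_reduced: bool = False
    explained_variance: np.ndarray | None = None
    flagged_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.level not in _LEVELS:
            raise ValueError(f"unknown profile level {self.level!r}")

    @property
    def features(self) -> list[str]:
        return [c for c in self.frame.columns if not c.startswith(METADATA_PREFIX)]

    @property
    def metadata_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith(METADATA_PREFIX)]

    def values(self) -> np.ndarray:
        return self.frame[self.features].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


_GROUP_KEYS = {
    "plate_guide": ["Metadata_plate", "Metadata_guide"],
    "guide": ["Metadata_guide"],
    "gene": ["Metadata_gene"],
}


def aggregate_profiles(
    cells: pd.DataFrame | ProfileTable, level: str = "plate_guide"
) -> ProfileTable:
    """Median-aggregate profiles to ``plate_guide``, ``guide`` or
    ``gene`` level.

    Carries along annotation columns that are constant within each group
    (e.g. the gene of a guide). Groups with zero rows simply do not
    appear.
    """
    if level not in _GROUP_KEYS:
        raise ValueError(f"unknown aggregation level {level!r}")
    if isinstance(cells, ProfileTable):
        frame, src = cells.frame, cells
    else:
        frame, src = cells, None
    keys = _GROUP_KEYS[level]
    for key in keys:
        if key not in frame.columns:
            raise KeyError(f"missing grouping column {key!r}")
    features = [c for c in frame.columns if not c.startswith(METADATA_PREFIX)]
    grouped = frame.groupby(keys, sort=True, observed=True)
    agg = grouped[features].median()
    # keep annotation columns that are nested within the grouping keys
    extra = [
        c
        for c in frame.columns
        if c.startswith(METADATA_PREFIX) and c not in keys
    ]
    if extra:
        nunique = grouped[extra].nunique()
        const_cols = [c for c in extra if (nunique[c] <= 1).all()]
        if const_cols:
            agg = grouped[const_cols].first().join(agg)
    out = agg.reset_index()
    return ProfileTable(
        frame=out,
        level=level,
        normalized=src.normalized if src is not None else False,
        feature_selected=src.feature_selected if src is not None else False,
    )


def normalize_profiles(table: ProfileTable) -> ProfileTable:
    """Standardize each feature within each plate: subtract the plate
    mean and divide by the plate population s.d. (ddof=0) across that
    plate's guide profiles.

    Features with zero variance within a plate are flagged and set
    missing for that plate (they carry no information and cannot be
    scaled).
    """
    if table.level != "plate_guide":
        raise ValueError("normalization operates on plate-level guide profiles")
    frame = table.frame
    features = table.features
    flagged: set[str] = set()
    chunks = []
    for plate, sub in frame.groupby("Metadata_plate", sort=True, observed=True):
        if len(sub) < 2:
            raise ValueError(
                f"plate {plate!r} has a single profile; cannot estimate scale"
            )
        vals = sub[features].to_numpy(dtype=float)
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=0)
        zero = sd == 0.0
        sd_safe = np.where(zero, 1.0, sd)
        normed = (vals - mean) / sd_safe
        normed[:, zero] = np.nan
        flagged.update(np.asarray(features)[zero].tolist())
        out = sub.copy()
        out[features] = normed
        chunks.append(out)
    new = pd.concat(chunks, axis=0).sort_index()
    return ProfileTable(
        frame=new,
        level=table.level,
        normalized=True,
        feature_selected=table.feature_selected,
        flagged_features=sorted(flagged),
    )


def select_features(
    table: ProfileTable,
    corr_threshold: float = 0.9,
    var_threshold: float = 1e-8,
    drop_missing: bool = True,
) -> ProfileTable:
    """Feature selection: drop features with missing values, features
    with near-zero variance, and redundant features until the retained
    set has max pairwise \\|Pearson r\\| <= ``corr_threshold``.

    Within each violating pair the feature with the larger mean absolute
    correlation to all other features is dropped (the convention of
    established profiling workflows). The operation is idempotent.
    """
    if len(table.frame) < 2:
        raise ValueError("feature selection requires at least 2 profiles")
    frame = table.frame
    features = table.features
    X = frame[features].to_numpy(dtype=float)
    keep = np.ones(len(features), dtype=bool)
    if drop_missing:
        keep &= ~np.isnan(X).any(axis=0)
    keep &= np.nanstd(X, axis=0, ddof=0) > var_threshold
    idx = np.flatnonzero(keep)
    if idx.size >= 2:
        corr = np.corrcoef(X[:, idx], rowvar=False)
        corr = np.abs(corr)
        np.fill_diagonal(corr, 0.0)
        alive = np.ones(idx.size, dtype=bool)
        while True:
            sub = corr[np.ix_(alive, alive)]
            if sub.size == 0 or sub.max() <= corr_threshold:
                break
            alive_idx = np.flatnonzero(alive)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            a, b = alive_idx[i], alive_idx[j]
            # drop whichever of the pair is on average more redundant
            mean_a = corr[a, alive].mean()
            mean_b = corr[b, alive].mean()
            drop = a if mean_a >= mean_b else b
            alive[drop] = False
        keep = np.zeros(len(features), dtype=bool)
        keep[idx[alive]] = True
    retained = [f for f, k in zip(features, keep) if k]
    new = frame[table.metadata_columns + retained].copy()
    return ProfileTable(
        frame=new,
        level=table.level,
        normalized=table.normalized,
        feature_selected=True,
        flagged_features=table.flagged_features,
    )


def reduce_pca(table: ProfileTable, var_fraction: float = 0.90) -> ProfileTable:
    """Project profiles onto the smallest number of principal components
    whose cumulative explained variance is at least ``var_fraction``.

    The per-component explained-variance ratios of the retained
    components are kept in ``explained_variance``.
    """
    if not (0.0 < var_fraction <= 1.0):
        raise ValueError("var_fraction must be in (0, 1]")
    X = table.values()
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values; run feature selection")
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_fraction - 1e-12) + 1)
    k = min(k, scores.shape[1])
    cols = [f"PC{i + 1}" for i in range(k)]
    new = table.frame[table.metadata_columns].copy().reset_index(drop=True)
    new[cols] = scores[:, :k]
    return ProfileTable(
        frame=new,
        level=table.level,
        normalized=table.normalized,
        feature_selected=table.feature_selected,
        pca_reduced=True,
        explained_variance=pca.explained_variance_ratio_[:k].copy(),
    )


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------


@dataclass
class ProcessedScreen:
    """All processing stages of one screen, as produced by
    :func:`process_cells`."""

    plate_guide: ProfileTable  # normalized per-plate guide profiles (all features)
    guide: ProfileTable  # feature-selected per-guide profiles
    gene: ProfileTable  # feature-selected per-gene profiles
    gene_full: ProfileTable  # normalized but NOT feature-selected gene profiles


def process_cells(
    cells: pd.DataFrame,
    corr_threshold: float = 0.9,
    var_threshold: float = 1e-8,
) -> ProcessedScreen:
    """Run the full profiling chain on a single-cell table.

    Aggregates cells to per-plate guide profiles, standardizes per
    plate, performs feature selection on the concatenated per-plate
    guide profiles, then median-aggregates to guide level and gene
    level. The un-selected gene-level table is kept as well (granularity
    spectra are read from it).
    """
    pg = aggregate_profiles(cells, "plate_guide")
    normed = normalize_profiles(pg)
    selected = select_features(normed, corr_threshold, var_threshold)
    guide = aggregate_profiles(selected, "guide")
    gene = aggregate_profiles(guide, "gene")
    gene_full = aggregate_profiles(aggregate_profiles(normed, "guide"), "gene")
    return ProcessedScreen(plate_guide=normed, guide=guide, gene=gene, gene_full=gene_full)
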