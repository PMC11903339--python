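"""Seeded synthetic optical pooled screens.

Generates single-cell morphological feature tables with the statistical
structure the analysis pipeline assumes, plus matching annotation sets
(protein-complex memberships, pairwise link scores, gene sets,
expression and dependency scores), so that every downstream stage can be
exercised and validated at desk scale.

The generator emulates, at configurable scale, the structure of a
genome-wide optical CRISPR knockout screen:

* ~4 guides per gene plus a pool of nontargeting control guides;
* strongly overdispersed cells-per-guide counts (a gene-shared Gamma
  frailty with per-guide Poisson sampling, giving marginal negative-
  binomial guide counts and matching gene-level mean/s.d. of roughly
  491/655 cells at the default dispersion);
* a fraction of unexpressed ("zero-TPM") genes whose guides behave
  exactly like nulls — the empirical null for FDR thresholding;
* planted gene effects concentrated in one labeled compartment
  (channel), with genes sharing a synthetic complex having highly
  aligned (or deliberately anti-aligned, for inhibitory members) effect
  directions;
* per-guide activity (models Cas9 editing efficiency ~60-90%);
* additive per-plate offsets removed by per-plate standardization;
* compositional granularity features: within one channel/object the
  granularity spectrum is a fixed total redistributed across erosion
  sizes, so any planted increase at one size is compensated at others.

Feature names follow the ``Object_Class_Params_Channel`` convention so
the profiling stage needs no special casing.
"""

from __future__ import annotations

import itertools
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import (
    CHANNELS,
    METADATA_PREFIX,
    ProfileTable,
    channel_feature_mask,
    parse_feature_name,
)

NONTARGETING_GENE = "nontargeting"

_DEFAULT_FEATURES_PER_CLASS = {
    "Intensity": 4,  # per channel
    "Texture": 8,  # per channel
    "Granularity": 8,  # per channel; 8 erosion sizes as measured per stain
    "RadialDistribution": 4,  # per channel
    "Correlation": 2,  # per channel pair
    "AreaShape": 8,  # total (channel-free)
    "Neighbors": 4,  # total (channel-free)
}

_INTENSITY_STATS = [
    "IntegratedIntensity",
    "MeanIntensity",
    "MaxIntensity",
    "StdIntensity",
    "MinIntensity",
    "MedianIntensity",
    "UpperQuartileIntensity",
    "MADIntensity",
]
_TEXTURE_STATS = [
    "Contrast",
    "Entropy",
    "Variance",
    "SumAverage",
    "InfoMeas1",
    "SumEntropy",
    "DifferenceVariance",
    "InverseDifferenceMoment",
]
_TEXTURE_SCALES = [3, 5]
_CORRELATION_STATS = ["Pearson", "Overlap", "K", "Manders"]
_AREASHAPE_STATS = [
    "Area",
    "Perimeter",
    "Eccentricity",
    "Solidity",
    "Extent",
    "FormFactor",
    "MajorAxisLength",
    "Compactness",
    "MinorAxisLength",
    "Orientation",
]
_NEIGHBORS_STATS = [
    "NumberOfNeighbors",
    "PercentTouching",
    "FirstClosestDistance",
    "AngleBetweenNeighbors",
]


def default_feature_names(
    channels: tuple[str, ...] = CHANNELS,
    counts: dict[str, int] | None = None,
) -> list[str]:
    """Build the synthetic feature-name list.

    ``counts`` maps feature class to the number of features per channel
    (single-channel classes), per channel pair (Correlation) or in total
    (AreaShape, Neighbors).
    """
    counts = dict(_DEFAULT_FEATURES_PER_CLASS, **(counts or {}))
    names: list[str] = []
    names += [f"Nuclei_AreaShape_{s}" for s in _AREASHAPE_STATS[: counts["AreaShape"]]]
    names += [f"Cells_Neighbors_{s}_Adjacent" for s in _NEIGHBORS_STATS[: counts["Neighbors"]]]
    texture = [f"{s}_{sc}" for sc, s in itertools.product(_TEXTURE_SCALES, _TEXTURE_STATS)]
    for ch in channels:
        names += [f"Cells_Intensity_{s}_{ch}" for s in _INTENSITY_STATS[: counts["Intensity"]]]
        for t in texture[: counts["Texture"]]:
            stat, scale = t.rsplit("_", 1)
            names.append(f"Cells_Texture_{stat}_{ch}_{scale}")
        names += [f"Cells_Granularity_{i}_{ch}" for i in range(1, counts["Granularity"] + 1)]
        names += [
            f"Cells_RadialDistribution_FracAtD_{ch}_{i}"
            for i in range(1, counts["RadialDistribution"] + 1)
        ]
    for a, b in itertools.combinations(channels, 2):
        names += [
            f"Cells_Correlation_{s}_{a}_{b}"
            for s in _CORRELATION_STATS[: counts["Correlation"]]
        ]
    return names


@dataclass
class ScreenConfig:
    """Parameters of a synthetic optical pooled screen.

    ``effect_size`` is the typical shift, in units of the cell-level
    noise s.d., applied to each affected feature of a planted hit gene
    (granularity features receive it as a logit shift of the
    compositional spectrum). ``compartment_specificity`` is the fraction
    of a hit gene's squared effect mass confined to its home channel.
    ``cells_per_guide_dispersion`` is the negative-binomial shape k
    (smaller = more overdispersed; var = m + m^2/k).
    """

    n_genes: int
    guides_per_gene: int = 4
    n_nontargeting: int = 601
    frac_zero_tpm: float = 0.25
    n_plates: int = 5
    cells_per_guide_mean: float = 125.0
    cells_per_guide_dispersion: float = 0.56
    channels: tuple[str, ...] = CHANNELS
    features_per_channel_by_class: dict[str, int] = field(default_factory=dict)
    effect_size: float = 1.0
    frac_hit_genes: float = 0.1
    compartment_specificity: float = 0.55
    guide_activity_prob: float = 0.9
    plate_effect_sd: float = 0.2
    noise_block_corr: float = 0.3
    frac_anticorrelated: float = 0.2
    frac_complexed: float = 0.6
    frac_essential: float = 0.2
    granularity_total: float = 100.0
    cutting_effect_size: float = 0.0
    n_vatpase_like: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "guides_per_gene", "n_nontargeting", "n_plates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "frac_zero_tpm",
            "frac_hit_genes",
            "compartment_specificity",
            "guide_activity_prob",
            "frac_anticorrelated",
            "frac_complexed",
            "frac_essential",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_zero_tpm + self.frac_hit_genes > 1.0:
            raise ValueError("frac_zero_tpm + frac_hit_genes must not exceed 1")
        if len(self.channels) != 5 or len(set(self.channels)) != 5:
            raise ValueError("channels must be 5 distinct labels")
        if self.cells_per_guide_dispersion <= 0:
            raise ValueError("cells_per_guide_dispersion must be positive")

    def feature_names(self) -> list[str]:
        return default_feature_names(self.channels, self.features_per_channel_by_class)


@dataclass
class Truth:
    """Planted ground truth of a synthetic screen."""

    genes: pd.DataFrame  # gene, is_hit, home_channel, complex, zero_tpm, essential, tpm, dependency
    effects: pd.DataFrame  # gene x feature planted effect vectors
    guide_active: pd.Series  # guide -> bool


@dataclass
class ScreenDataset:
    """A synthetic screen: single-cell table, guide library and truth."""

    cells: pd.DataFrame
    library: pd.DataFrame  # guide, gene, targeting
    truth: Truth
    config: ScreenConfig

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.cells.columns if not c.startswith(METADATA_PREFIX)]


@dataclass
class AnnotationSet:
    """Synthetic external annotations: complex memberships, pairwise
    link scores (integer 0-999), GMT-style gene sets, expression and
    dependency scores."""

    complexes: dict[str, list[str]]
    pair_scores: pd.DataFrame  # gene_a, gene_b, score
    gene_sets: dict[str, list[str]]
    expression: pd.Series  # gene -> TPM
    dependency: pd.Series  # gene -> dependency score


# ---------------------------------------------------------------------------
# Effect construction
# ---------------------------------------------------------------------------


def _granularity_blocks(feature_names: list[str], channels) -> list[np.ndarray]:
    """Column-index blocks of granularity features, one per
    (object, channel), ordered by erosion size."""
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for j, name in enumerate(feature_names):
        meta = parse_feature_name(name, tuple(channels))
        if meta.feature_class == "Granularity":
            size = int(meta.params[0])
            groups.setdefault((meta.object, meta.channels[0]), []).append((size, j))
    blocks = []
    for key in sorted(groups):
        items = sorted(groups[key])
        blocks.append(np.array([j for _, j in items]))
    return blocks


def _noise_blocks(feature_names: list[str], channels) -> list[np.ndarray]:
    """Channel-wise blocks for correlated noise; two-channel features
    join their first channel's block, channel-free features form their
    own block."""
    by_key: dict[str, list[int]] = {}
    for j, name in enumerate(feature_names):
        meta = parse_feature_name(name, tuple(channels))
        key = meta.channels[0] if meta.channels else "_cellwide"
        by_key.setdefault(key, []).append(j)
    return [np.array(v) for v in by_key.values()]


def _make_effect(
    rng: np.random.Generator,
    home_mask: np.ndarray,
    cfg: ScreenConfig,
    p_home: float = 0.6,
) -> np.ndarray:
    """Sparse prototype effect vector with the configured fraction of
    squared mass in the home channel."""
    n = home_mask.size
    n_home = int(home_mask.sum())
    n_other = n - n_home
    s = cfg.compartment_specificity
    if n_home == 0 or s <= 0:
        q_home, q_other = 0.0, 0.3
    elif n_other == 0 or s >= 1:
        q_home, q_other = p_home, 0.0
    else:
        q_home = p_home
        q_other = min(1.0, p_home * n_home * (1.0 - s) / (s * n_other))
    prob = np.where(home_mask, q_home, q_other)
    affected = rng.random(n) < prob
    if not affected.any():
        affected[rng.integers(n)] = True
    signs = rng.choice([-1.0, 1.0], size=n)
    mags = cfg.effect_size * rng.uniform(0.5, 1.5, size=n)
    return np.where(affected, signs * mags, 0.0)


def _member_effect(
    rng: np.random.Generator,
    prototype: np.ndarray,
    cfg: ScreenConfig,
    allow_flip: bool = True,
) -> np.ndarray:
    """A complex member's effect: the prototype plus small jitter on its
    support, possibly sign-flipped (inhibitory member)."""
    jitter = 0.15 * cfg.effect_size * rng.standard_normal(prototype.size)
    v = prototype + np.where(prototype != 0.0, jitter, 0.0)
    if allow_flip and rng.random() < cfg.frac_anticorrelated:
        v = -v
    return v


def _vatpase_prototype(
    feature_names: list[str], cfg: ScreenConfig, rng: np.random.Generator
) -> np.ndarray:
    """Effect pattern of a lysosomal-acidification-like perturbation: a
    strong loss of granularity mass at the smallest WGA erosion size,
    redistributed to the larger sizes, plus mild signal elsewhere in the
    WGA channel."""
    v = np.zeros(len(feature_names))
    wga_mask = channel_feature_mask(feature_names, "WGA", cfg.channels)
    for j, name in enumerate(feature_names):
        meta = parse_feature_name(name, cfg.channels)
        if meta.feature_class == "Granularity" and meta.channels == ("WGA",):
            size = int(meta.params[0])
            v[j] = -1.5 * cfg.effect_size if size == 1 else 0.35 * cfg.effect_size
        elif wga_mask[j] and rng.random() < 0.3:
            v[j] = 0.5 * cfg.effect_size * rng.choice([-1.0, 1.0])
    return v


# ---------------------------------------------------------------------------
# Screen generation
# ---------------------------------------------------------------------------


def generate_screen(config: ScreenConfig) -> ScreenDataset:
    """Generate a seeded synthetic screen.

    Cell feature vectors are plate offset + (active-guide gene effect) +
    channel-block-correlated unit-variance noise; granularity features
    are produced compositionally by passing their entries through a
    softmax scaled to ``granularity_total`` per channel/object.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    feature_names = cfg.feature_names()
    n_feat = len(feature_names)
    channels = tuple(cfg.channels)

    genes = [f"GENE{i + 1:05d}" for i in range(cfg.n_genes)]
    guide_rows = []
    for g in genes:
        for k in range(cfg.guides_per_gene):
            guide_rows.append((f"{g}_g{k + 1}", g, True))
    for k in range(cfg.n_nontargeting):
        guide_rows.append((f"NT_{k + 1:04d}", NONTARGETING_GENE, False))
    library = pd.DataFrame(guide_rows, columns=["guide", "gene", "targeting"])

    # --- planted truth -----------------------------------------------------
    n_hits = int(round(cfg.frac_hit_genes * cfg.n_genes))
    n_hits = max(n_hits, cfg.n_vatpase_like)
    perm = rng.permutation(cfg.n_genes)
    hit_idx = perm[:n_hits]
    n_zero = int(round(cfg.frac_zero_tpm * cfg.n_genes))
    zero_idx = perm[n_hits : n_hits + n_zero]

    effects = np.zeros((cfg.n_genes, n_feat))
    home_channel = np.array([""] * cfg.n_genes, dtype=object)
    complex_id = np.array([""] * cfg.n_genes, dtype=object)

    hit_list = list(hit_idx)
    # reserved acidification-like group
    vat = hit_list[: cfg.n_vatpase_like]
    if vat:
        proto = _vatpase_prototype(feature_names, cfg, rng)
        for gi in vat:
            # loss of function of any subunit acts in the same direction
            effects[gi] = _member_effect(rng, proto, cfg, allow_flip=False)
            home_channel[gi] = "WGA"
            complex_id[gi] = "VATPASE_LIKE"
    rest = hit_list[cfg.n_vatpase_like :]
    n_complexed = int(round(cfg.frac_complexed * len(rest)))
    pos = 0
    cplx = 0
    home_masks = {
        ch: channel_feature_mask(feature_names, ch, channels) for ch in channels
    }
    while pos < n_complexed:
        size = int(rng.integers(3, 7))
        members = rest[pos : pos + size]
        if len(members) < 2:
            break
        cplx += 1
        ch = channels[rng.integers(len(channels))]
        proto = _make_effect(rng, home_masks[ch], cfg)
        for gi in members:
            effects[gi] = _member_effect(rng, proto, cfg)
            home_channel[gi] = ch
            complex_id[gi] = f"CPX{cplx:03d}"
        pos += size
    for gi in rest[pos:]:
        ch = channels[rng.integers(len(channels))]
        effects[gi] = _make_effect(rng, home_masks[ch], cfg)
        home_channel[gi] = ch

    is_hit = np.zeros(cfg.n_genes, dtype=bool)
    is_hit[hit_idx] = True
    zero_tpm = np.zeros(cfg.n_genes, dtype=bool)
    zero_tpm[zero_idx] = True

    if cfg.cutting_effect_size > 0:
        cut_dir = rng.standard_normal(n_feat)
        cut_dir *= cfg.cutting_effect_size / np.linalg.norm(cut_dir) * np.sqrt(n_feat) * 0.2
        effects = effects + cut_dir  # every targeting guide cuts, incl. zero-TPM genes

    # expression and dependency
    tpm = rng.lognormal(mean=3.0, sigma=1.2, size=cfg.n_genes)
    tpm[zero_tpm] = 0.0
    essential = rng.random(cfg.n_genes) < cfg.frac_essential
    mag = np.linalg.norm(effects, axis=1)
    rel = mag / mag.max() if mag.max() > 0 else np.zeros_like(mag)
    dependency = rng.normal(0.0, 0.15, size=cfg.n_genes)
    dependency[essential] = (
        -0.55 - 0.6 * rel[essential] + rng.normal(0.0, 0.08, size=int(essential.sum()))
    )

    truth_genes = pd.DataFrame(
        {
            "gene": genes,
            "is_hit": is_hit,
            "home_channel": home_channel,
            "complex": complex_id,
            "zero_tpm": zero_tpm,
            "essential": essential,
            "tpm": tpm,
            "dependency": dependency,
        }
    )
    effects_df = pd.DataFrame(effects, index=pd.Index(genes, name="gene"), columns=feature_names)

    # guide activity (Cas9 efficiency); nontargeting guides do nothing anyway
    n_guides = len(library)
    active = rng.random(n_guides) < cfg.guide_activity_prob
    active[~library["targeting"].to_numpy()] = False
    guide_active = pd.Series(active, index=library["guide"], name="active")

    # --- cell counts: gene-shared Gamma frailty, per-guide Poisson ---------
    k = cfg.cells_per_guide_dispersion
    gene_gamma = rng.gamma(shape=k, scale=1.0 / k, size=cfg.n_genes)
    nt_gamma = rng.gamma(shape=k, scale=1.0 / k, size=cfg.n_nontargeting)
    lam = np.empty(n_guides)
    lam[: cfg.n_genes * cfg.guides_per_gene] = np.repeat(gene_gamma, cfg.guides_per_gene)
    lam[cfg.n_genes * cfg.guides_per_gene :] = nt_gamma
    totals = rng.poisson(lam * cfg.cells_per_guide_mean)
    n_empty = int((totals == 0).sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} guides drew 0 cells; they stay in the library with 0 rows",
            stacklevel=2,
        )
    per_plate = rng.multinomial(totals, np.full(cfg.n_plates, 1.0 / cfg.n_plates))

    plate_offsets = rng.normal(0.0, cfg.plate_effect_sd, size=(cfg.n_plates, n_feat))
    gran_blocks = _granularity_blocks(feature_names, channels)
    noise_blocks = _noise_blocks(feature_names, channels)
    rho = cfg.noise_block_corr
    gene_of_guide = library["gene"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    guide_eff = np.zeros((n_guides, n_feat))
    for i in range(n_guides):
        if active[i]:
            guide_eff[i] = effects[gene_pos[gene_of_guide[i]]]

    frames = []
    base_logits = {}
    for b in gran_blocks:
        base_logits[tuple(b)] = np.linspace(1.5, -1.5, b.size)
    for p in range(cfg.n_plates):
        counts = per_plate[:, p]
        n_cells = int(counts.sum())
        gidx = np.repeat(np.arange(n_guides), counts)
        X = rng.standard_normal((n_cells, n_feat))
        if rho > 0:
            for b in noise_blocks:
                shared = rng.standard_normal((n_cells, 1))
                X[:, b] = np.sqrt(1 - rho) * X[:, b] + np.sqrt(rho) * shared
        X += plate_offsets[p]
        X += guide_eff[gidx]
        for b in gran_blocks:
            logits = base_logits[tuple(b)] + X[:, b]
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            X[:, b] = cfg.granularity_total * e / e.sum(axis=1, keepdims=True)
        df = pd.DataFrame(X, columns=feature_names)
        df.insert(0, "Metadata_plate", f"P{p + 1}")
        df.insert(1, "Metadata_guide", library["guide"].to_numpy()[gidx])
        df.insert(2, "Metadata_gene", gene_of_guide[gidx])
        df.insert(3, "Metadata_targeting", library["targeting"].to_numpy()[gidx])
        frames.append(df)
    cells = pd.concat(frames, axis=0, ignore_index=True)

    return ScreenDataset(
        cells=cells,
        library=library,
        truth=Truth(genes=truth_genes, effects=effects_df, guide_active=guide_active),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def generate_annotations(
    screen: ScreenDataset,
    noise_sd: float = 0.05,
    n_random_pairs: int | None = None,
) -> AnnotationSet:
    """Derive a synthetic annotation set from the screen's planted truth.

    Pairwise link scores are a monotone noisy transform of the absolute
    cosine between truth effect vectors, scaled to the integer range
    0-999 (STRING-like). Complexes group genes sharing a planted effect
    direction (CORUM-like). The dependency score is negatively
    associated with effect magnitude for the essential subset.
    """
    cfg = screen.config
    rng = np.random.default_rng((cfg.seed + 987_654_321) % 2**31)
    truth = screen.truth
    genes = truth.genes["gene"].tolist()

    complexes: dict[str, list[str]] = {}
    for name, sub in truth.genes[truth.genes["complex"] != ""].groupby("complex"):
        members = sub["gene"].tolist()
        if len(members) >= 2:
            complexes[str(name)] = members

    E = truth.effects.to_numpy()
    norms = np.linalg.norm(E, axis=1)
    unit = np.zeros_like(E)
    nz = norms > 0
    unit[nz] = E[nz] / norms[nz, None]

    pairs: set[tuple[int, int]] = set()
    pos = {g: i for i, g in enumerate(genes)}
    for members in complexes.values():
        for a, b in itertools.combinations(sorted(members), 2):
            pairs.add((min(pos[a], pos[b]), max(pos[a], pos[b])))
    n_random = 5 * len(genes) if n_random_pairs is None else n_random_pairs
    target = min(len(pairs) + n_random, len(genes) * (len(genes) - 1) // 2)
    attempts = 0
    while len(pairs) < target and attempts < 50 * (n_random + 1):
        i, j = rng.integers(len(genes), size=2)
        if i != j:
            pairs.add((min(i, j), max(i, j)))
        attempts += 1
    pair_list = sorted(pairs)
    rows = []
    for i, j in pair_list:
        cos = abs(float(unit[i] @ unit[j]))
        noisy = cos + (noise_sd * rng.standard_normal() if noise_sd > 0 else 0.0)
        score = int(round(999 * min(1.0, max(0.0, noisy))))
        rows.append((genes[i], genes[j], score))
    pair_scores = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])

    gene_sets: dict[str, list[str]] = {}
    hits = truth.genes[truth.genes["is_hit"]]
    for ch in cfg.channels:
        members = hits.loc[hits["home_channel"] == ch, "gene"].tolist()
        if members:
            gene_sets[f"compartment_{ch}"] = members
    for name, members in complexes.items():
        gene_sets[f"complex_{name}"] = list(members)
    if len(hits):
        gene_sets["all_hits"] = hits["gene"].tolist()

    expression = pd.Series(truth.genes["tpm"].to_numpy(), index=genes, name="tpm")
    dependency = pd.Series(
        truth.genes["dependency"].to_numpy(), index=genes, name="dependency"
    )
    return AnnotationSet(
        complexes=complexes,
        pair_scores=pair_scores,
        gene_sets=gene_sets,
        expression=expression,
        dependency=dependency,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_gmt(gene_sets: dict[str, list[str]], path: str) -> None:
    """Write gene sets in GMT format: name<TAB>description<TAB>genes..."""
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, name] + list(members)) + "\n")


def read_gmt(path: str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_screen(
    screen: ScreenDataset, out_dir: str, annotations: AnnotationSet | None = None
) -> dict[str, str]:
    """Write a screen (and optionally its annotations) as delimited text.

    Emits ``cells.csv``, ``library.csv``, ``truth.csv`` (per-gene truth
    with ``effect_``-prefixed planted effect columns), ``gene_meta.csv``
    (expression/dependency, the pipeline-facing annotation input) and,
    when annotations are given, ``complexes.tsv``, ``pair_scores.tsv``
    and ``sets.gmt``. All tables round-trip losslessly through
    :func:`read_screen` / :func:`read_annotations`.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    screen.cells.to_csv(_p("cells.csv"), index=False, float_format="%.17g")
    screen.library.to_csv(_p("library.csv"), index=False)
    truth = screen.truth.genes.copy()
    eff = screen.truth.effects.add_prefix("effect_").reset_index(drop=True)
    truth = pd.concat([truth, eff], axis=1)
    truth["guide_active"] = [
        ";".join(
            screen.truth.guide_active[screen.library.loc[screen.library["gene"] == g, "guide"]]
            .astype(int)
            .astype(str)
        )
        for g in truth["gene"]
    ]
    truth.to_csv(_p("truth.csv"), index=False, float_format="%.17g")
    gene_meta = screen.truth.genes[["gene", "tpm", "dependency"]]
    gene_meta.to_csv(_p("gene_meta.csv"), index=False, float_format="%.17g")
    if annotations is not None:
        with open(_p("complexes.tsv"), "w") as fh:
            fh.write("complex_name\tmembers\n")
            for name, members in annotations.complexes.items():
                fh.write(f"{name}\t{','.join(members)}\n")
        annotations.pair_scores.to_csv(_p("pair_scores.tsv"), sep="\t", index=False)
        write_gmt(annotations.gene_sets, _p("sets.gmt"))
    return paths


def read_cells(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def read_screen(out_dir: str) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read back ``cells.csv``, ``library.csv`` and ``truth.csv``."""
    cells = read_cells(os.path.join(out_dir, "cells.csv"))
    library = pd.read_csv(os.path.join(out_dir, "library.csv"))
    truth = pd.read_csv(os.path.join(out_dir, "truth.csv"))
    return cells, library, truth


def read_annotations(out_dir: str) -> AnnotationSet:
    complexes: dict[str, list[str]] = {}
    cpath = os.path.join(out_dir, "complexes.tsv")
    with open(cpath) as fh:
        next(fh)
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, members = line.split("\t")
            complexes[name] = members.split(",") if members else []
    pair_scores = pd.read_csv(os.path.join(out_dir, "pair_scores.tsv"), sep="\t")
    gene_sets = read_gmt(os.path.join(out_dir, "sets.gmt"))
    meta = pd.read_csv(os.path.join(out_dir, "gene_meta.csv"))
    expression = pd.Series(meta["tpm"].to_numpy(), index=meta["gene"], name="tpm")
    dependency = pd.Series(
        meta["dependency"].to_numpy(), index=meta["gene"], name="dependency"
    )
    return AnnotationSet(complexes, pair_scores, gene_sets, expression, dependency)


# ---------------------------------------------------------------------------
# Small seeded matrices for isolated stage tests
# ---------------------------------------------------------------------------


def correlated_profile_matrix(
    n_profiles: int,
    n_features: int,
    block_size: int = 10,
    within_corr: float = 0.95,
    seed: int = 0,
) -> ProfileTable:
    """A standardized profile matrix whose features form equicorrelated
    blocks — the redundancy structure the correlation filter must
    remove."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_profiles, n_features))
    for start in range(0, n_features, block_size):
        cols = slice(start, min(start + block_size, n_features))
        shared = rng.standard_normal((n_profiles, 1))
        X[:, cols] = np.sqrt(1 - within_corr) * X[:, cols] + np.sqrt(within_corr) * shared
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    frame = pd.DataFrame(X, columns=[f"f{i:04d}" for i in range(n_features)])
    frame.insert(0, "Metadata_guide", [f"g{i:04d}" for i in range(n_profiles)])
    return ProfileTable(frame=frame, level="guide", normalized=True)


def anisotropic_profile_matrix(
    n_profiles: int,
    n_features: int,
    decay: float = 0.97,
    seed: int = 0,
) -> ProfileTable:
    """Gene-level profiles with a geometrically decaying variance
    spectrum (anisotropic covariance), for dimensionality-reduction
    tests."""
    rng = np.random.default_rng(seed)
    scales = decay ** np.arange(n_features)
    X = rng.standard_normal((n_profiles, n_features)) * scales
    frame = pd.DataFrame(X, columns=[f"f{i:04d}" for i in range(n_features)])
    frame.insert(0, "Metadata_gene", [f"GENE{i + 1:05d}" for i in range(n_profiles)])
    return ProfileTable(frame=frame, level="gene", normalized=True, feature_selected=True)
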