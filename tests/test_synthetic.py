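"""Structure and invariants of the synthetic screen generator."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import opscreen as op


def _quiet_screen(cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return op.generate_screen(cfg)


class TestGenerateScreen:
    def test_library_size_arithmetic(self):
        cfg = op.ScreenConfig(n_genes=50, guides_per_gene=4, n_nontargeting=20, seed=0)
        screen = _quiet_screen(
            op.ScreenConfig(
                n_genes=50, guides_per_gene=4, n_nontargeting=20,
                cells_per_guide_mean=5, n_plates=2, seed=0,
            )
        )
        assert len(screen.library) == 220
        assert cfg.guides_per_gene * cfg.n_genes + cfg.n_nontargeting == 220

    def test_seeded_determinism(self):
        cfg = dict(n_genes=20, n_nontargeting=10, cells_per_guide_mean=10, n_plates=2, seed=3)
        a = _quiet_screen(op.ScreenConfig(**cfg))
        b = _quiet_screen(op.ScreenConfig(**cfg))
        pd.testing.assert_frame_equal(a.cells, b.cells)
        pd.testing.assert_frame_equal(a.truth.effects, b.truth.effects)

    def test_nulls_have_zero_effect_vectors(self, demo_screen, demo_truth):
        eff = demo_screen.truth.effects
        for gene in demo_truth.index[demo_truth.zero_tpm]:
            assert np.all(eff.loc[gene].to_numpy() == 0.0)
        assert (demo_truth.loc[demo_truth.zero_tpm, "tpm"] == 0.0).all()

    def test_cutting_effect_reaches_zero_tpm_genes(self):
        screen = _quiet_screen(
            op.ScreenConfig(
                n_genes=20, n_nontargeting=10, cells_per_guide_mean=5,
                n_plates=2, cutting_effect_size=0.5, seed=3,
            )
        )
        truth = screen.truth.genes.set_index("gene")
        zt = truth.index[truth.zero_tpm]
        assert np.abs(screen.truth.effects.loc[zt].to_numpy()).sum() > 0

    def test_every_cell_guide_in_library(self, demo_screen):
        assert set(demo_screen.cells["Metadata_guide"]) <= set(demo_screen.library["guide"])

    def test_overdispersed_guide_counts(self):
        """With >= 500 guides, sample variance exceeds sample mean."""
        screen = _quiet_screen(
            op.ScreenConfig(
                n_genes=150, n_nontargeting=20, cells_per_guide_mean=30,
                n_plates=2, seed=9,
            )
        )
        counts = (
            screen.cells.groupby("Metadata_guide")
            .size()
            .reindex(screen.library["guide"])
            .fillna(0)
        )
        assert len(counts) >= 500
        assert counts.var() > counts.mean()

    def test_granularity_mass_conserved_per_cell(self, demo_screen, demo_config):
        names = demo_screen.feature_names
        for ch in demo_config.channels:
            cols = [n for n in names if f"_Granularity_" in n and n.endswith(f"_{ch}")]
            totals = demo_screen.cells[cols].sum(axis=1).to_numpy()
            assert np.abs(totals - demo_config.granularity_total).max() < 1e-9

    def test_complex_members_share_effect_direction(self, demo_screen, demo_truth):
        eff = demo_screen.truth.effects
        found = 0
        for _, sub in demo_truth[demo_truth["complex"].str.startswith("CPX")].groupby("complex"):
            genes = sub.index.tolist()
            for i, a in enumerate(genes):
                for b in genes[i + 1 :]:
                    va, vb = eff.loc[a].to_numpy(), eff.loc[b].to_numpy()
                    cos = va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))
                    assert abs(cos) > 0.7
                    found += 1
        assert found > 0

    def test_compartment_specificity_of_effect_mass(self, demo_screen, demo_truth, demo_config):
        eff = demo_screen.truth.effects
        names = demo_screen.feature_names
        hits = demo_truth[demo_truth.is_hit & (demo_truth["complex"] == "")]
        fracs = []
        for gene, row in hits.iterrows():
            mask = op.channel_feature_mask(names, row.home_channel)
            v = eff.loc[gene].to_numpy()
            fracs.append((v[mask] ** 2).sum() / (v**2).sum())
        assert abs(np.mean(fracs) - demo_config.compartment_specificity) < 0.15

    def test_null_screen_hit_rate_bounded_by_fdr(self):
        """With no planted effects anywhere, flagged genes stay at or
        below the nominal FDR."""
        screen = _quiet_screen(
            op.ScreenConfig(
                n_genes=200, n_nontargeting=60, cells_per_guide_mean=20,
                n_plates=2, effect_size=0.0, frac_hit_genes=0.0,
                frac_zero_tpm=0.5, seed=13,
            )
        )
        proc = op.process_cells(screen.cells)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = op.score_screen(proc.guide)
        sf = op.scores_frame(scores)
        truth = screen.truth.genes.set_index("gene")
        nulls = [g for g in truth.index[truth.zero_tpm] if g in sf.index]
        hits = op.call_hits(sf, nulls, fdr=0.05)
        assert hits.table["whole_cell_hit"].mean() <= 0.05 + 1.0 / len(nulls)


class TestAnnotations:
    def test_identical_vectors_score_999_without_noise(self):
        screen = _quiet_screen(
            op.ScreenConfig(
                n_genes=12, n_nontargeting=10, cells_per_guide_mean=5,
                n_plates=2, frac_hit_genes=0.5, frac_zero_tpm=0.0, seed=17,
            )
        )
        truth = screen.truth.genes.set_index("gene")
        cpx = truth[truth["complex"].str.startswith("CPX")]
        assert len(cpx) >= 2, "fixture must contain a complex"
        a, b = cpx[cpx["complex"] == cpx["complex"].iloc[0]].index[:2]
        screen.truth.effects.loc[b] = screen.truth.effects.loc[a]  # identical vectors
        ann = op.generate_annotations(screen, noise_sd=0.0)
        ps = ann.pair_scores.set_index(["gene_a", "gene_b"])["score"]
        key = (a, b) if (a, b) in ps.index else (b, a)
        assert ps[key] == 999  # complex pairs are always scored

    def test_zero_noise_ranking_matches_truth_cosine(self):
        screen = _quiet_screen(
            op.ScreenConfig(
                n_genes=20, n_nontargeting=10, cells_per_guide_mean=5,
                n_plates=2, frac_hit_genes=0.5, seed=21,
            )
        )
        ann = op.generate_annotations(screen, noise_sd=0.0)
        eff = screen.truth.effects
        norms = np.linalg.norm(eff.to_numpy(), axis=1)
        unit = pd.DataFrame(
            np.where(norms[:, None] > 0, eff.to_numpy() / np.where(norms == 0, 1, norms)[:, None], 0.0),
            index=eff.index,
        )
        cosines = [
            abs(unit.loc[a].to_numpy() @ unit.loc[b].to_numpy())
            for a, b in ann.pair_scores[["gene_a", "gene_b"]].itertuples(index=False)
        ]
        rho = stats.spearmanr(cosines, ann.pair_scores["score"]).statistic
        assert rho > 0.999

    def test_annotations_closed_over_screen_genes(self, demo_screen, demo_annotations):
        genes = set(demo_screen.truth.genes["gene"])
        for members in demo_annotations.complexes.values():
            assert set(members) <= genes
        assert set(demo_annotations.pair_scores["gene_a"]) <= genes
        assert set(demo_annotations.pair_scores["gene_b"]) <= genes
        for members in demo_annotations.gene_sets.values():
            assert set(members) <= genes and len(members) > 0

    def test_pair_scores_in_range(self, demo_annotations):
        s = demo_annotations.pair_scores["score"]
        assert s.between(0, 999).all()

    def test_dependency_split_marks_essential_genes(self, demo_truth):
        ess = demo_truth[demo_truth.essential]
        non = demo_truth[~demo_truth.essential]
        assert ess["dependency"].mean() < non["dependency"].mean()


class TestIO:
    def test_round_trip(self, demo_screen, demo_annotations, tmp_path):
        op.write_screen(demo_screen, str(tmp_path), demo_annotations)
        cells, library, truth = op.read_screen(str(tmp_path))
        pd.testing.assert_frame_equal(cells, demo_screen.cells)
        pd.testing.assert_frame_equal(library, demo_screen.library)
        ann = op.read_annotations(str(tmp_path))
        assert ann.complexes == demo_annotations.complexes
        pd.testing.assert_frame_equal(ann.pair_scores, demo_annotations.pair_scores)
        assert ann.gene_sets == demo_annotations.gene_sets

    def test_gmt_format(self, tmp_path):
        path = str(tmp_path / "sets.gmt")
        op.write_gmt({"setA": ["g1", "g2"], "setB": ["g3"]}, path)
        lines = open(path).read().splitlines()
        assert lines[0] == "setA\tsetA\tg1\tg2"
        assert op.read_gmt(path) == {"setA": ["g1", "g2"], "setB": ["g3"]}

    def test_empty_screen_writes_headers_only(self, demo_screen, tmp_path):
        import copy

        empty = copy.copy(demo_screen)
        empty.cells = demo_screen.cells.iloc[0:0]
        paths = op.write_screen(empty, str(tmp_path))
        cells = pd.read_csv(paths["cells.csv"])
        assert len(cells) == 0
        assert list(cells.columns) == list(demo_screen.cells.columns)
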