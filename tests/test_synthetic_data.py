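import json

import numpy as np
import pytest

from notchtrunc import io as ntio
from notchtrunc.domain_expression import domain_ratio
from notchtrunc.synthetic_data import (
    CASE1_TRUTH,
    CASE2_TRUTH,
    SimConfig,
    make_gene_model,
    simulate_counts,
    simulate_exon_coverage,
    simulate_sv_callset,
    write_fixtures,
)
from notchtrunc.variant_filters import apply_filters


class TestSimConfig:
    def test_defaults_valid(self):
        SimConfig()

    @pytest.mark.parametrize(
        "kw",
        [
            {"truncated_fraction": 1.5},
            {"doublet_rate": -0.1},
            {"ren_fold": 0.5},
            {"exon_count": 29},
            {"nb_dispersion": 0.0},
            {"strand": "x"},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestSvCallset:
    def test_case1_single_record_with_truth(self, model):
        records = simulate_sv_callset(model, "case1", seed=3)
        assert len(records) == 1
        assert records[0].variant_class == "rearrangement"
        assert records[0].truth == CASE1_TRUTH

    def test_case2_truth_and_classes(self, model):
        records = simulate_sv_callset(model, "case2", seed=3)
        assert sorted(r.breakpoints.sv_class for r in records) == ["deletion", "inversion"]
        assert all(r.truth == CASE2_TRUTH for r in records)

    def test_case2_deletion_spans_regulator(self, model):
        records = simulate_sv_callset(model, "case2", seed=8)
        dele = next(r.breakpoints for r in records if r.breakpoints.sv_class == "deletion")
        g = model["NRARP"]
        assert dele.pos_a <= g.start and g.end <= dele.pos_b

    def test_artifacts_all_fail(self, model):
        for seed in range(10):
            records = simulate_sv_callset(model, "artifacts", seed=seed)
            assert apply_filters(records).n_pass == 0

    def test_unknown_scenario(self, model):
        with pytest.raises(ValueError, match="scenario"):
            simulate_sv_callset(model, "case3")

    def test_deletion_scale_is_08_mb(self, model):
        for seed in range(5):
            bp = simulate_sv_callset(model, "case1", seed=seed)[0].breakpoints
            assert 0.7e6 < bp.pos_b - bp.pos_a < 0.95e6


class TestExonCoverage:
    def test_p_zero_uniform_depth(self, model):
        track = simulate_exon_coverage(model, 0.0, depth=200.0, seed=1)
        per_base = track.counts / track.lengths
        assert per_base.std() / per_base.mean() < 0.1

    def test_p_one_zero_ecd(self, model):
        track = simulate_exon_coverage(model, 1.0, depth=100.0, seed=1)
        assert track.counts[:27].sum() == 0
        assert (track.counts[27:] > 0).all()

    def test_expected_half_coverage(self, model):
        ecd, icd = [], []
        for seed in range(60):
            t = simulate_exon_coverage(model, 0.5, depth=100.0, seed=seed)
            per_base = t.counts / t.lengths
            ecd.append(per_base[:27].mean())
            icd.append(per_base[27:].mean())
        assert np.mean(ecd) == pytest.approx(50.0, rel=0.03)
        assert np.mean(icd) == pytest.approx(100.0, rel=0.03)

    def test_invalid_fraction(self, model):
        with pytest.raises(ValueError):
            simulate_exon_coverage(model, 1.2, depth=10.0)

    def test_ratio_monotone_in_truncated_fraction(self, model):
        means = []
        for p in (0.0, 0.3, 0.6, 0.8):
            ratios = [
                domain_ratio(simulate_exon_coverage(model, p, 100.0, seed=s)).ratio
                for s in range(40)
            ]
            means.append(np.mean(ratios))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestCounts:
    def test_shapes_and_metadata(self, counts_matrix):
        assert counts_matrix.counts.shape == (len(counts_matrix.genes), len(counts_matrix.cells))
        assert {"sample", "truth", "label", "doublet_score"} <= set(counts_matrix.cells.columns)
        assert counts_matrix.genes["mito"].sum() == 5

    def test_determinism(self):
        cfg = SimConfig(seed=9, cells_per_type={"tumour": 40, "mesangial": 30, "endothelial": 20})
        a, b = simulate_counts(cfg), simulate_counts(cfg)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert a.cells.equals(b.cells)

    def test_zero_doublet_rate(self):
        cfg = SimConfig(
            seed=2, doublet_rate=0.0,
            cells_per_type={"tumour": 30, "mesangial": 20, "endothelial": 10},
        )
        cm = simulate_counts(cfg)
        assert (cm.cells["truth"] == "doublet").sum() == 0

    def test_ren_fold_recovered_in_count_space(self):
        cfg = SimConfig(
            seed=4, ren_fold=3.0, doublet_rate=0.0, lowq_rate=0.0,
            cells_per_type={"tumour": 600, "mesangial": 600, "endothelial": 50},
        )
        cm = simulate_counts(cfg)
        ren = cm.gene_row("REN").astype(float)
        truth = cm.cells["truth"].to_numpy()
        fold = ren[truth == "tumour"].mean() / ren[truth == "mesangial"].mean()
        assert fold == pytest.approx(3.0, rel=0.15)

    def test_doublet_scores_separate(self, counts_matrix):
        scores = counts_matrix.cells["doublet_score"]
        truth = counts_matrix.cells["truth"]
        assert scores[truth == "doublet"].min() > scores[truth != "doublet"].median()

    def test_invalid_cells_per_type(self):
        with pytest.raises(ValueError):
            simulate_counts(SimConfig(cells_per_type={"tumour": 0, "mesangial": 1, "endothelial": 1}))


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    cfg = SimConfig(seed=6, cells_per_type={"tumour": 25, "mesangial": 15, "endothelial": 10})
    model = make_gene_model(cfg)
    out = tmp_path_factory.mktemp("fx")
    fixtures = {
        "model": model,
        "sv_records": simulate_sv_callset(model, "case1", seed=6),
        "small_variants": simulate_sv_callset(model, "artifacts", seed=6),
        "coverage": simulate_exon_coverage(model, 0.5, 50.0, seed=6),
        "counts": simulate_counts(cfg),
        "truth": {"scenario": "case1"},
    }
    manifest = write_fixtures(fixtures, out, seed=6)
    return out, fixtures, manifest


class TestWriteFixtures:
    def test_manifest_seed(self, fixture_dir):
        out, _, manifest = fixture_dir
        assert manifest["seed"] == 6
        assert json.loads((out / "manifest.json").read_text())["seed"] == 6

    def test_model_round_trip(self, fixture_dir):
        out, fixtures, _ = fixture_dir
        assert ntio.read_model(out / "model.gff3") == fixtures["model"]

    def test_bedpe_round_trip(self, fixture_dir):
        out, fixtures, _ = fixture_dir
        assert ntio.read_bedpe(out / "sv.bedpe") == fixtures["sv_records"]

    def test_small_variant_round_trip(self, fixture_dir):
        out, fixtures, _ = fixture_dir
        back = ntio.read_variants_tsv(out / "variants.tsv")
        expected = [r for r in fixtures["small_variants"] if r.variant_class != "rearrangement"]
        assert back == expected

    def test_coverage_round_trip(self, fixture_dir):
        out, fixtures, _ = fixture_dir
        (track,) = ntio.read_coverage_tsv(out / "coverage.tsv")
        np.testing.assert_array_equal(track.counts, fixtures["coverage"].counts)
        assert track.library_size == fixtures["coverage"].library_size

    def test_counts_round_trip(self, fixture_dir):
        out, fixtures, _ = fixture_dir
        back = ntio.read_counts(out)
        np.testing.assert_array_equal(back.counts, fixtures["counts"].counts)
        assert list(back.cells.columns) == list(fixtures["counts"].cells.columns)
        np.testing.assert_allclose(
            back.cells["doublet_score"], fixtures["counts"].cells["doublet_score"]
        )

    def test_bedpe_is_zero_based_half_open(self, fixture_dir):
        out, fixtures, _ = fixture_dir
        lines = (out / "sv.bedpe").read_text().splitlines()
        header = lines[0].split("\t")
        row = dict(zip(header, lines[1].split("\t")))
        bp = fixtures["sv_records"][0].breakpoints
        assert int(row["start1"]) == bp.pos_a and int(row["end1"]) == bp.pos_a + 1

    def test_byte_identical_for_same_seed(self, tmp_path):
        cfg = SimConfig(seed=3, cells_per_type={"tumour": 20, "mesangial": 10, "endothelial": 10})
        outs = []
        for name in ("a", "b"):
            model = make_gene_model(cfg)
            fixtures = {
                "model": model,
                "sv_records": simulate_sv_callset(model, "case1", seed=cfg.seed),
                "counts": simulate_counts(cfg),
                "truth": {"seed": cfg.seed},
            }
            d = tmp_path / name
            write_fixtures(fixtures, d, seed=cfg.seed)
            outs.append(d)
        a, b = outs
        names = sorted(p.name for p in a.iterdir())
        assert names == sorted(p.name for p in b.iterdir())
        for n in names:
            assert (a / n).read_bytes() == (b / n).read_bytes(), n
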