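"""Prediction-job building, confidence parsing, ranking and heatmaps."""

import json

import numpy as np
import pytest

from legscan import library as lib
from legscan import screen as ls


@pytest.fixture(scope="module")
def design():
    return ls.ScreenDesign(
        enzyme_id="hLEG",
        enzyme_sequence="GACDEFGHIK" * 6,
        peptide_template="YVANXX",
        p1_prime_pos=5,
        catalytic_residue=189,
    )


# planted preference: Cys then Gly at P1', Arg/Lys at P2' — top hit YVANCR
PREF = {(5, "C"): 0.35, (5, "G"): 0.25, (6, "R"): 0.06, (6, "K"): 0.05}


@pytest.fixture(scope="module")
def small_screen(design, tmp_path_factory):
    """Mock screen over a reduced alphabet (5x5 grid) with planted truth."""
    out = tmp_path_factory.mktemp("screen")
    alphabet = ("A", "C", "G", "K", "R")
    library = lib.enumerate_combinatorial_library("YVANXX", alphabet)
    jobs = ls.build_jobs(design, library)
    truths = {}
    for job in jobs:
        truths[job.peptide_sequence] = ls.mock_predict(
            job, PREF, seed=7, out_dir=out / job.name, p1_prime_pos=5
        )
    scores = [ls.parse_prediction_output(out / job.name) for job in jobs]
    result = ls.ScreenResult(scores=scores, peptide_template="YVANXX", placeholder_positions=(5, 6))
    return out, jobs, truths, result


class TestBuildJobs:
    def test_full_prime_side_screen_is_400_jobs(self, design):
        library = lib.enumerate_combinatorial_library("YVANXX")
        assert len(ls.build_jobs(design, library)) == 400

    def test_single_placeholder_is_20_jobs(self, design):
        library = lib.enumerate_combinatorial_library("AAANX")
        d = ls.ScreenDesign(
            enzyme_id="AtLEGbeta", enzyme_sequence=design.enzyme_sequence, peptide_template="AAANX"
        )
        assert len(ls.build_jobs(d, library)) == 20

    def test_duplicates_collapse_with_warning(self, design):
        library = [
            lib.PeptideVariant(sequence="YVANCR", library_id="a"),
            lib.PeptideVariant(sequence="YVANCR", library_id="b"),
        ]
        with pytest.warns(UserWarning, match="duplicate"):
            jobs = ls.build_jobs(design, library)
        assert len(jobs) == 1

    def test_job_file_roundtrip_is_byte_identical(self, design, tmp_path):
        job = ls.build_jobs(design, [lib.PeptideVariant(sequence="YVANCR", library_id="x")])[0]
        p1 = ls.write_job(job, tmp_path / "job.json")
        rebuilt = ls.read_job(p1)
        p2 = ls.write_job(rebuilt, tmp_path / "job2.json")
        assert p1.read_bytes() == p2.read_bytes()


class TestParsePredictionOutput:
    def test_roundtrip_identity_on_planted_scores(self, small_screen):
        out, jobs, truths, result = small_screen
        for score in result.scores:
            truth = truths[score.peptide]
            assert score.iptm == truth["iptm"]
            assert score.plddt_mean == pytest.approx(truth["plddt_mean"], abs=1e-9)
            np.testing.assert_allclose(score.plddt_per_residue, truth["plddt_per_residue"])
            assert score.pae_mean_interchain == pytest.approx(
                truth["pae_mean_interchain"], abs=1e-9
            )

    def test_top_printed_score_parsed_exactly(self, small_screen):
        out, jobs, truths, result = small_screen
        # YVANCR: base 0.55 + 0.35 (P1' Cys) + 0.06 (P2' Arg) = 0.96
        score = next(s for s in result.scores if s.peptide == "YVANCR")
        assert score.iptm == 0.96

    def test_uniform_plddt_mean(self, tmp_path, design):
        job = ls.build_jobs(design, [lib.PeptideVariant(sequence="YVANGG", library_id="x")])[0]
        ls.mock_predict(job, {}, seed=1, out_dir=tmp_path / job.name)
        conf_path = tmp_path / job.name / f"{job.name}_confidences.json"
        conf = json.loads(conf_path.read_text())
        conf["atom_plddts"] = [50.0] * len(conf["atom_plddts"])
        conf_path.write_text(json.dumps(conf))
        score = ls.parse_prediction_output(tmp_path / job.name)
        assert score.plddt_mean == 50.0

    def test_missing_key_error_names_file_and_key(self, tmp_path, design):
        job = ls.build_jobs(design, [lib.PeptideVariant(sequence="YVANGG", library_id="x")])[0]
        ls.mock_predict(job, {}, seed=1, out_dir=tmp_path / job.name)
        sp = tmp_path / job.name / f"{job.name}_summary_confidences.json"
        sp.write_text(json.dumps({"ptm": 0.5}))
        with pytest.raises(ValueError, match="iptm"):
            ls.parse_prediction_output(tmp_path / job.name)

    def test_out_of_range_iptm_rejected(self, tmp_path, design):
        job = ls.build_jobs(design, [lib.PeptideVariant(sequence="YVANGG", library_id="x")])[0]
        ls.mock_predict(job, {}, seed=1, out_dir=tmp_path / job.name)
        sp = tmp_path / job.name / f"{job.name}_summary_confidences.json"
        sp.write_text(json.dumps({"iptm": 1.7}))
        with pytest.raises(ValueError, match="iptm"):
            ls.parse_prediction_output(tmp_path / job.name)


class TestRanking:
    def make_score(self, pep, iptm, plddt=70.0):
        return ls.ComplexScore(
            peptide=pep,
            iptm=iptm,
            plddt_mean=plddt,
            plddt_per_residue=np.full(len(pep), plddt),
            pae_mean_interchain=5.0,
        )

    def test_descending_iptm(self):
        res = ls.ScreenResult(
            scores=[self.make_score("AAANGG", 0.8), self.make_score("AAANCC", 0.9)],
            peptide_template="AAANXX",
            placeholder_positions=(5, 6),
        )
        ranked = ls.rank_screen(res)
        assert ranked.iloc[0]["peptide"] == "AAANCC"

    def test_plddt_breaks_ties(self):
        res = ls.ScreenResult(
            scores=[self.make_score("AAANGG", 0.8, 70.0), self.make_score("AAANCC", 0.8, 80.0)],
            peptide_template="AAANXX",
            placeholder_positions=(5, 6),
        )
        assert ls.rank_screen(res).iloc[0]["peptide"] == "AAANCC"

    def test_permutation_invariance(self, small_screen):
        _, _, _, result = small_screen
        ranked = ls.rank_screen(result)
        rng = np.random.default_rng(0)
        shuffled = ls.ScreenResult(
            scores=[result.scores[i] for i in rng.permutation(len(result.scores))],
            peptide_template=result.peptide_template,
            placeholder_positions=result.placeholder_positions,
        )
        assert list(ls.rank_screen(shuffled)["peptide"]) == list(ranked["peptide"])

    def test_planted_top_peptide_ranks_first(self, small_screen):
        _, _, truths, result = small_screen
        best = max(truths.values(), key=lambda t: t["iptm"])
        assert ls.rank_screen(result).iloc[0]["peptide"] == best["peptide"] == "YVANCR"


class TestClassifyConfidence:
    @pytest.mark.parametrize(
        "iptm,band",
        [(0.9, "high"), (0.96, "high"), (0.49, "low"), (0.7, "intermediate"), (0.6, "intermediate"), (0.8, "intermediate")],
    )
    def test_bands(self, iptm, band):
        assert ls.classify_confidence(iptm) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ls.classify_confidence(1.2)

    def test_monotone(self):
        order = {"low": 0, "intermediate": 1, "high": 2}
        grid = np.linspace(0, 1, 101)
        bands = [order[ls.classify_confidence(x)] for x in grid]
        assert all(b2 >= b1 for b1, b2 in zip(bands, bands[1:]))


class TestHeatmap:
    def test_complete_grid_has_no_blanks(self, design, tmp_path):
        # full 400-peptide screen, scores synthesized without files
        library = lib.enumerate_combinatorial_library("YVANXX")
        scores = [
            ls.ComplexScore(
                peptide=v.sequence,
                iptm=0.55,
                plddt_mean=70.0,
                plddt_per_residue=np.full(6, 70.0),
                pae_mean_interchain=5.0,
            )
            for v in library
        ]
        result = ls.ScreenResult(scores=scores, peptide_template="YVANXX", placeholder_positions=(5, 6))
        mat = ls.heatmap_matrix(result, 5, 6)
        assert mat.shape == (20, 20)
        assert not mat.isna().any().any()

    def test_planted_preference_peaks_at_cys_row(self, small_screen):
        _, _, _, result = small_screen
        mat = ls.heatmap_matrix(result, 5, 6)
        sub = mat.dropna(how="all").dropna(axis=1, how="all")
        assert sub.mean(axis=1).idxmax() == "C"

    def test_matrix_entries_equal_parsed_scores(self, small_screen):
        _, _, _, result = small_screen
        mat = ls.heatmap_matrix(result, 5, 6)
        for s in result.scores:
            assert mat.loc[s.peptide[4], s.peptide[5]] == s.iptm

    def test_fixed_placeholder_slices_consistently(self):
        library = lib.enumerate_combinatorial_library("XXAN", ("A", "C", "G"))
        scores = [
            ls.ComplexScore(
                peptide=v.sequence,
                iptm=round(0.5 + 0.01 * i, 3),
                plddt_mean=70.0,
                plddt_per_residue=np.full(4, 70.0),
                pae_mean_interchain=5.0,
            )
            for i, v in enumerate(library)
        ]
        result = ls.ScreenResult(scores=scores, peptide_template="XXAN", placeholder_positions=(1, 2))
        with pytest.raises(ValueError, match="row and column"):
            ls.heatmap_matrix(result, 1, 1)
        mat = ls.heatmap_matrix(result, 1, 2)
        direct = {(s.peptide[0], s.peptide[1]): s.iptm for s in scores}
        for (r, c), want in direct.items():
            assert mat.loc[r, c] == want

    def test_unfixed_extra_placeholder_is_error(self):
        library = lib.enumerate_combinatorial_library("XXXN", ("A", "C"))
        scores = [
            ls.ComplexScore(
                peptide=v.sequence,
                iptm=0.5,
                plddt_mean=70.0,
                plddt_per_residue=np.full(4, 70.0),
                pae_mean_interchain=5.0,
            )
            for v in library
        ]
        result = ls.ScreenResult(scores=scores, peptide_template="XXXN", placeholder_positions=(1, 2, 3))
        with pytest.raises(ValueError, match="fixed"):
            ls.heatmap_matrix(result, 1, 2)
        mat = ls.heatmap_matrix(result, 1, 2, fixed={3: "A"})
        assert mat.loc["A", "C"] == 0.5

    def test_render_heatmap_writes_image(self, small_screen, tmp_path):
        _, _, _, result = small_screen
        mat = ls.heatmap_matrix(result, 5, 6)
        out = ls.render_heatmap(mat, tmp_path / "m.svg")
        assert out.exists() and out.stat().st_size > 0


class TestMockPredict:
    def test_zero_contributions_give_base_everywhere(self, design, tmp_path):
        library = lib.enumerate_combinatorial_library("YVANXX", ("A", "G"))
        for job in ls.build_jobs(design, library):
            t = ls.mock_predict(job, {}, seed=3, out_dir=tmp_path / job.name)
            assert t["iptm"] == 0.55

    def test_same_seed_reproduces_output_bytes(self, design, tmp_path):
        job = ls.build_jobs(design, [lib.PeptideVariant(sequence="YVANCK", library_id="x")])[0]
        ls.mock_predict(job, PREF, seed=9, out_dir=tmp_path / "a", noise_sd=0.02, p1_prime_pos=5)
        ls.mock_predict(job, PREF, seed=9, out_dir=tmp_path / "b", noise_sd=0.02, p1_prime_pos=5)
        for name in (f"{job.name}_summary_confidences.json", f"{job.name}_confidences.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_planted_contribution_shifts_mean_iptm(self, design, tmp_path):
        pref = {(6, "K"): 0.15, (6, "R"): 0.15}
        library = lib.enumerate_combinatorial_library("YVANAX")
        vals = {}
        for job in ls.build_jobs(design, library):
            t = ls.mock_predict(job, pref, seed=5, out_dir=tmp_path / job.name, noise_sd=0.01)
            vals[t["peptide"][5]] = vals.get(t["peptide"][5], []) + [t["iptm"]]
        favored = np.mean([np.mean(vals[r]) for r in ("K", "R")])
        others = np.mean([np.mean(v) for r, v in vals.items() if r not in ("K", "R")])
        assert favored - others == pytest.approx(0.15, abs=0.02)
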