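"""Report assembly, cross-language comparison, and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from orthodepth.cli import main as cli_main
from orthodepth.errors import MeasureError
from orthodepth.report import (
    DEFAULT_MEASURES,
    compute_all,
    correlate_and_project,
)
from orthodepth.synthetic import GeneratorSpec, generate_lexicon, generate_orthography, write_fixture


def make_report(seed=1, n_words=400, **spec_kw):
    spec = GeneratorSpec(n_letters=14, n_words=n_words, seed=seed, **spec_kw)
    rules, config = generate_orthography(spec)
    lex, _ = generate_lexicon(rules, config, spec)
    return compute_all(lex, rules, seed=seed, sample_size=200)


class TestComputeAll:
    def test_shallow_lexicon_report(self):
        rep = make_report(seed=2)
        assert rep.rules.pct_irregular == 0.0
        assert rep.basic.pct_equal_length == 100.0
        assert all(p.efficiency == 1.0 for p in rep.efficiency.values())
        assert rep.opc.mean_opc == 1.0
        assert rep.skipped == {}

    def test_missing_rules_skips_rule_measures_only(self):
        spec = GeneratorSpec(n_letters=14, n_words=300, seed=3)
        rules, config = generate_orthography(spec)
        lex, _ = generate_lexicon(rules, config, spec)
        rep = compute_all(lex, None, seed=1, sample_size=100)
        assert "rules" in rep.skipped
        assert "graphemes" not in rep.efficiency
        assert rep.entropy is not None
        assert rep.opc is not None
        assert rep.vowel_consistency is not None

    def test_deterministic_json(self):
        a = make_report(seed=4, exception_rate=0.1)
        b = make_report(seed=4, exception_rate=0.1)
        assert a.to_json().encode() == b.to_json().encode()

    def test_measure_vector_covers_defaults(self):
        vec = make_report(seed=5).measure_vector()
        assert set(vec) == set(DEFAULT_MEASURES)
        assert vec["pct_irregular"] == 0.0
        assert vec["efficiency_graphemes"] == 1.0

    def test_report_roundtrips_through_json(self):
        from orthodepth.cli import _report_from_dict

        rep = make_report(seed=6, exception_rate=0.2, n_multiletter_graphemes=3)
        back = _report_from_dict(json.loads(rep.to_json()))
        assert back.measure_vector() == rep.measure_vector()


class TestCorrelateAndProject:
    def _reports(self):
        reports = []
        # one family varies only unpredictability, the other only unit size
        for i, eps in enumerate((0.0, 0.1, 0.25, 0.4)):
            spec = GeneratorSpec(n_letters=14, n_words=400, exception_rate=eps, seed=50 + i)
            rules, config = generate_orthography(spec)
            lex, _ = generate_lexicon(rules, config, spec, language_tag=f"eps{i}")
            reports.append(compute_all(lex, rules, seed=1, sample_size=150))
        for i, nm in enumerate((2, 5, 8)):
            spec = GeneratorSpec(
                n_letters=14, n_words=400, n_multiletter_graphemes=nm, seed=60 + i
            )
            rules, config = generate_orthography(spec)
            lex, _ = generate_lexicon(rules, config, spec, language_tag=f"multi{i}")
            reports.append(compute_all(lex, rules, seed=1, sample_size=150))
        return reports

    def test_needs_three_reports(self):
        with pytest.raises(MeasureError):
            correlate_and_project([make_report(seed=1), make_report(seed=2)])

    def test_correlation_matrix_properties(self):
        summary = correlate_and_project(self._reports())
        corr = summary.correlations.to_numpy()
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_loadings_orthonormal(self):
        summary = correlate_and_project(self._reports())
        L = summary.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(2), atol=1e-10)

    def test_duplicated_report_gets_identical_scores(self):
        reports = self._reports()
        dup = reports + [reports[0]]
        summary = correlate_and_project(dup)
        scores = summary.scores.to_numpy()
        assert np.allclose(scores[0], scores[-1])

    def test_reconstruction_error_equals_dropped_eigenvalues(self):
        summary = correlate_and_project(self._reports())
        mat = summary.matrix.drop(columns=list(summary.dropped_measures))
        z = ((mat - mat.mean()) / mat.std(ddof=1)).to_numpy()
        L = summary.loadings.to_numpy()
        resid = z - z @ L @ L.T
        err = (resid**2).sum() / (len(mat) - 1)
        assert err == pytest.approx(sum(summary.eigenvalues[2:]), abs=1e-8)

    def test_two_knob_families_load_on_different_components(self):
        summary = correlate_and_project(self._reports())
        load = summary.loadings

        def dominant(measure):
            row = load.loc[measure].abs()
            return row.idxmax()

        unpredictability = ["pct_irregular", "entropy_ci", "vowel_consistency", "mean_opc"]
        complexity = ["pct_equal_length", "n_multi"]
        u_comps = {dominant(m) for m in unpredictability if m in load.index}
        c_comps = {dominant(m) for m in complexity if m in load.index}
        assert len(u_comps) == 1
        assert len(c_comps) == 1
        assert u_comps != c_comps


class TestCli:
    def test_simulate_compute_compare_pipeline(self, tmp_path):
        runner = CliRunner()
        reports_dir = tmp_path / "reports"
        reports_dir.mkdir()
        for i, eps in enumerate((0.0, 0.15, 0.35)):
            fx = tmp_path / f"fx{i}"
            spec_file = tmp_path / f"spec{i}.yaml"
            spec_file.write_text(
                f"n_letters: 14\nn_words: 250\nexception_rate: {eps}\nseed: {70 + i}\n",
                encoding="utf-8",
            )
            res = runner.invoke(cli_main, ["simulate", "--spec", str(spec_file), "--out-dir", str(fx)])
            assert res.exit_code == 0, res.output
            res = runner.invoke(
                cli_main,
                [
                    "compute",
                    "--lexicon", str(fx / "lexicon.tsv"),
                    "--config", str(fx / "config.yaml"),
                    "--rules", str(fx / "rules.tsv"),
                    "--language-tag", f"lang{i}",
                    "--seed", "1",
                    "--sample-size", "100",
                    "--out", str(reports_dir / f"lang{i}.json"),
                ],
            )
            assert res.exit_code == 0, res.output
        out = tmp_path / "summary.json"
        res = runner.invoke(
            cli_main, ["compare", "--reports", str(reports_dir), "--out", str(out)]
        )
        assert res.exit_code == 0, res.output
        assert "descriptive only" in res.output
        summary = json.loads(out.read_text(encoding="utf-8"))
        assert summary["languages"] == ["lang0", "lang1", "lang2"]
        assert len(summary["variance_explained"]) == 2

    def test_compute_without_rules_still_reports(self, tmp_path):
        runner = CliRunner()
        fx = tmp_path / "fx"
        write_fixture(fx, GeneratorSpec(n_letters=12, n_words=120, seed=1))
        out = tmp_path / "rep.json"
        res = runner.invoke(
            cli_main,
            [
                "compute",
                "--lexicon", str(fx / "lexicon.tsv"),
                "--config", str(fx / "config.yaml"),
                "--out", str(out),
            ],
        )
        assert res.exit_code == 0, res.output
        rep = json.loads(out.read_text(encoding="utf-8"))
        assert "rules" in rep["skipped"]
        assert "entropy" in rep

    def test_bad_input_exits_2(self, tmp_path):
        runner = CliRunner()
        fx = tmp_path / "fx"
        write_fixture(fx, GeneratorSpec(n_letters=12, n_words=50, seed=1))
        bad = tmp_path / "bad.tsv"
        bad.write_text("orthography\tphonology\nqqQ\t##\n", encoding="utf-8")
        res = runner.invoke(
            cli_main,
            [
                "compute",
                "--lexicon", str(bad),
                "--config", str(fx / "config.yaml"),
                "--out", str(tmp_path / "r.json"),
            ],
        )
        assert res.exit_code == 2


def test_item_table_per_word_values(mint_lexicon):
    from orthodepth.report import item_table

    df = item_table(mint_lexicon, seed=0, sample_size=100)
    assert list(df.columns) == [
        "orthography", "phonology", "vowel_consistency", "body_consistency", "opc",
    ]
    row = df[df.orthography == "pint"].iloc[0]
    assert row.body_consistency == 0.25
    mint_row = df[df.orthography == "mint"].iloc[0]
    assert mint_row.opc == 1.2
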