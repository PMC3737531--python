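import numpy as np
import pandas as pd
import pytest

from apashift.apa_array import (
    DistalProximalTable,
    ExpressionMatrix,
    GeneRatioRecord,
    NormalizationConfig,
    call_apa_shift,
    candidate_genes,
    classify_last_exon_probes,
    curate_table,
    distal_proximal_ratios,
    filter_expressed,
    normalize_signals,
    read_expression,
    select_downregulated,
    write_expression,
)
from apashift.genome_model import GenomicInterval, ProbeSet
from apashift.synthetic_data import SimConfig, simulate_dataset

from conftest import make_gene


def make_matrix(signals: dict, conditions: dict, calls=None, scale="linear"):
    sig = pd.DataFrame(signals).T  # probe x sample
    samples = pd.DataFrame(
        {
            "condition": {k: v[0] for k, v in conditions.items()},
            "experiment": {k: v[1] for k, v in conditions.items()},
        }
    ).loc[sig.columns]
    if calls is None:
        calls = sig.map(lambda _: "P")
    return ExpressionMatrix(sig, calls, samples, scale=scale)


TWO_BY_TWO = {  # (condition, experiment) per sample
    "c1": ("control", 1),
    "c2": ("control", 2),
    "k1": ("kd", 1),
    "k2": ("kd", 2),
}


class TestNormalization:
    def test_shift_pins_percentile_to_reference(self, rng):
        sig = pd.DataFrame(
            rng.lognormal(5, 1, size=(100, 3)),
            index=[f"p{i}" for i in range(100)],
            columns=["c1", "c2", "k1"],
        )
        m = ExpressionMatrix(
            sig,
            sig.map(lambda _: "P"),
            pd.DataFrame(
                {"condition": ["control", "control", "kd"], "experiment": [1, 2, 1]},
                index=sig.columns,
            ),
        )
        out = normalize_signals(m, NormalizationConfig(reference_value=1.5))
        pct = out.signals.quantile(0.75, axis=0)
        assert np.allclose(pct, 1.5, atol=1e-12)
        assert out.scale == "log2"

    def test_matches_sort_based_percentile_oracle(self, rng):
        """Independent oracle: sorted-array linear interpolation at rank
        0.75*(n-1), computed longhand per sample."""
        sig = pd.DataFrame(
            rng.lognormal(6, 0.8, size=(100, 3)), columns=["a", "b", "c"]
        )
        m = ExpressionMatrix(
            sig,
            sig.map(lambda _: "P"),
            pd.DataFrame(
                {"condition": ["control", "kd", "kd"], "experiment": [1, 1, 2]},
                index=sig.columns,
            ),
        )
        out = normalize_signals(m)
        for col in sig.columns:
            logged = np.sort(np.log2(sig[col].to_numpy()))
            h = 0.75 * (len(logged) - 1)
            lo, frac = int(np.floor(h)), h - int(np.floor(h))
            q = logged[lo] * (1 - frac) + logged[min(lo + 1, len(logged) - 1)] * frac
            expected = np.log2(sig[col]) - q
            assert np.allclose(out.signals[col], expected, atol=1e-12)

    def test_scale_equivariance(self, rng):
        """Multiplying one sample's linear signals by any constant leaves its
        normalized output unchanged."""
        base = rng.lognormal(5, 1, size=(50, 4))
        m1 = make_matrix(
            {f"p{i}": dict(zip(TWO_BY_TWO, row)) for i, row in enumerate(base)},
            TWO_BY_TWO,
        )
        scaled = base.copy()
        scaled[:, 2] *= 37.5
        m2 = make_matrix(
            {f"p{i}": dict(zip(TWO_BY_TWO, row)) for i, row in enumerate(scaled)},
            TWO_BY_TWO,
        )
        out1, out2 = normalize_signals(m1), normalize_signals(m2)
        assert np.allclose(out1.signals, out2.signals, atol=1e-12)

    def test_rejects_nonpositive_signal(self):
        with pytest.raises(ValueError, match="nonpositive"):
            make_matrix(
                {"p0": {"c1": 1.0, "c2": -2.0, "k1": 1.0, "k2": 1.0}}, TWO_BY_TWO
            )


class TestFilterExpressed:
    def test_absent_everywhere_excluded_present_everywhere_kept(self):
        calls = pd.DataFrame(
            {"c1": ["A", "P"], "c2": ["A", "P"], "k1": ["A", "P"], "k2": ["A", "P"]},
            index=["dead", "alive"],
        )
        sig = pd.DataFrame(100.0, index=calls.index, columns=calls.columns)
        m = ExpressionMatrix(
            sig,
            calls,
            pd.DataFrame(
                {
                    "condition": ["control", "control", "kd", "kd"],
                    "experiment": [1, 2, 1, 2],
                },
                index=calls.columns,
            ),
        )
        assert filter_expressed(m) == {"alive"}

    def test_silent_probe_recovery_on_simulated_data(self):
        cfg = SimConfig(seed=13, frac_silent_probes=0.1)
        _genes, probes, expr, truth = simulate_dataset(cfg)
        expressed = filter_expressed(expr)
        silent = set(truth.silent_probes)
        all_ids = {p.probe_id for p in probes}
        correct = len(expressed - silent) + len((all_ids - expressed) & silent)
        assert correct / len(all_ids) >= 0.99


class TestSelectDownregulated:
    def test_no_change_probe_excluded(self):
        m = make_matrix(
            {"p": {"c1": 100.0, "c2": 100.0, "k1": 100.0, "k2": 100.0}}, TWO_BY_TWO
        )
        res = select_downregulated(normalize_signals(m), "kd")
        assert res.loc["p", "log2_fc"] == 0
        assert not res.loc["p", "passes_filter"]

    def test_exact_twofold_zero_variance_is_included(self):
        """'At least 2-fold' is inclusive; with zero variance the t statistic
        is infinite and p = 0, so the boundary probe passes.  The matrix is
        already on the normalized log2 scale (the screen's contract)."""
        m = make_matrix(
            {
                "p": {"c1": 8.0, "c2": 8.0, "k1": 7.0, "k2": 7.0},
                "q": {"c1": 9.0, "c2": 9.0, "k1": 9.0, "k2": 9.0},
            },
            TWO_BY_TWO,
            scale="log2",
        )
        res = select_downregulated(m, "kd")
        assert res.loc["p", "log2_fc"] == pytest.approx(-1.0)
        assert res.loc["p", "passes_filter"]
        assert not res.loc["q", "passes_filter"]

    def test_single_experiment_is_indeterminate(self):
        m = make_matrix(
            {"p": {"c1": 200.0, "k1": 100.0}},
            {"c1": ("control", 1), "k1": ("kd", 1)},
        )
        res = select_downregulated(normalize_signals(m), "kd")
        assert np.isnan(res.loc["p", "p_value"])
        assert not res.loc["p", "passes_filter"]
        assert res.loc["p", "indeterminate"]

    def test_screen_sensitivity_on_simulated_targets(self, rng):
        """200 probes, 40 true 2.5-fold-down targets, log2 noise sd 0.15,
        2 experiments on the normalized scale: the screen recovers >= 90%
        of the targets."""
        n, n_true = 200, 40
        base = rng.normal(8, 1.4, n)  # log2 baseline
        shift = np.zeros(n)
        shift[:n_true] = -np.log2(2.5)
        sig = {}
        for i in range(n):
            e = rng.normal(0, 0.15, 4)
            sig[f"p{i}"] = {
                "c1": base[i] + e[0],
                "c2": base[i] + e[1],
                "k1": base[i] + shift[i] + e[2],
                "k2": base[i] + shift[i] + e[3],
            }
        m = make_matrix(sig, TWO_BY_TWO, scale="log2")
        res = select_downregulated(m, "kd")
        hits = res.iloc[:n_true]["passes_filter"].mean()
        assert hits >= 0.9
        false_hits = res.iloc[n_true:]["passes_filter"].mean()
        assert false_hits <= 0.05
        gene_map = {f"p{i}": f"g{i}" for i in range(n)}
        assert len(candidate_genes(res, gene_map)) >= 0.9 * n_true


class TestClassifyLastExonProbes:
    def _probe(self, pid, start, end, strand="+"):
        return ProbeSet(pid, "g1", GenomicInterval("chr1", start, end, strand))

    def test_five_prime_most_probe_is_proximal_then_downstream_order(self):
        """Mirrors the canonical worked example: the probe set nearest the
        last exon's 5' end is proximal, the two downstream ones distal in
        proximal-to-distal order."""
        g = make_gene(exons=((0, 100), (2000, 6000)))
        probes = [
            self._probe("dist_far", 5000, 5200),
            self._probe("prox", 2100, 2300),
            self._probe("dist_near", 3500, 3700),
            self._probe("upstream_exon", 10, 60),  # outside the last exon
        ]
        prox, distal = classify_last_exon_probes(probes, g)
        assert prox.probe_id == "prox" and prox.apa_class == "proximal"
        assert [d.probe_id for d in distal] == ["dist_near", "dist_far"]
        assert all(d.apa_class == "distal" for d in distal)

    def test_minus_strand_reflection(self):
        g = make_gene(strand="-", exons=((1000, 5000), (7000, 8000)))
        probes = [
            self._probe("a", 1200, 1400, "-"),
            self._probe("b", 4500, 4700, "-"),
        ]
        prox, distal = classify_last_exon_probes(probes, g)
        assert prox.probe_id == "b"  # largest start = most 5' on minus strand
        assert [d.probe_id for d in distal] == ["a"]

    def test_single_probe_degenerate(self):
        g = make_gene(exons=((0, 100), (2000, 6000)))
        prox, distal = classify_last_exon_probes([self._probe("only", 2100, 2300)], g)
        assert prox.probe_id == "only" and distal == []

    def test_no_last_exon_probe_raises(self):
        g = make_gene(exons=((0, 100), (2000, 6000)))
        with pytest.raises(ValueError, match="no probe"):
            classify_last_exon_probes([self._probe("up", 10, 60)], g)


def two_probe_matrix(ctrl_prox, ctrl_dist, kd_prox, kd_dist):
    return make_matrix(
        {
            "gp": {"c1": ctrl_prox, "c2": ctrl_prox, "k1": kd_prox, "k2": kd_prox},
            "gd": {"c1": ctrl_dist, "c2": ctrl_dist, "k1": kd_dist, "k2": kd_dist},
        },
        TWO_BY_TWO,
    )


def two_probe_classification():
    g = make_gene(exons=((0, 100), (2000, 6000)))
    prox = ProbeSet("gp", "g1", GenomicInterval("chr1", 2100, 2300, "+"))
    dist = ProbeSet("gd", "g1", GenomicInterval("chr1", 4000, 4200, "+"))
    return {"g1": (prox, [dist])}


class TestDistalProximalRatios:
    def test_identical_pattern_gives_unity(self):
        m = two_probe_matrix(100, 70, 350, 245)  # kd is control scaled by 3.5
        t = distal_proximal_ratios(m, two_probe_classification(), ["kd"])
        assert t.genes["g1"].dp_ratios["kd"]["gd"] == pytest.approx(1.0)

    def test_halved_distal_gives_half(self):
        m = two_probe_matrix(100, 100, 100, 50)
        t = distal_proximal_ratios(m, two_probe_classification(), ["kd"])
        assert t.genes["g1"].dp_ratios["kd"]["gd"] == pytest.approx(0.5)
        assert t.genes["g1"].proximal_ratio["kd"] == pytest.approx(1.0)

    def test_matches_arithmetic_oracle_on_random_tables(self, rng):
        for _ in range(50):
            cp, cd, kp, kd_ = rng.lognormal(5, 1, 4)
            m = two_probe_matrix(cp, cd, kp, kd_)
            t = distal_proximal_ratios(m, two_probe_classification(), ["kd"])
            expected = (kd_ / kp) / (cd / cp)
            assert t.genes["g1"].dp_ratios["kd"]["gd"] == pytest.approx(
                expected, abs=1e-12 * expected
            )

    def test_invariant_to_per_sample_rescaling(self, rng):
        m = two_probe_matrix(120, 80, 90, 30)
        t1 = distal_proximal_ratios(m, two_probe_classification(), ["kd"])
        m.signals["k1"] *= 13.7  # per-sample scale cancels in the double ratio
        m.signals["c2"] *= 0.21
        t2 = distal_proximal_ratios(m, two_probe_classification(), ["kd"])
        assert t1.genes["g1"].dp_ratios["kd"]["gd"] == pytest.approx(
            t2.genes["g1"].dp_ratios["kd"]["gd"]
        )


def toy_table(dp, prox=1.1, gene="g1", probes=("d1",)):
    rec = GeneRatioRecord(
        gene_id=gene,
        proximal_probe="p1",
        distal_probes=list(probes),
        dp_ratios={"kd": dict(zip(probes, dp))},
        proximal_ratio={"kd": prox},
    )
    return DistalProximalTable(genes={gene: rec}, conditions=["kd"])


class TestCurationAndCalls:
    def test_unexpressed_distal_drops_gene_and_is_logged(self):
        t = toy_table([0.5])
        out = curate_table(t, expressed={"p1"})
        assert out.genes == {}
        assert out.curation_log["n_genes_dropped_curation"] == 1

    def test_clean_table_unchanged(self):
        t = toy_table([0.5, 0.6], probes=("d1", "d2"))
        out = curate_table(t, expressed={"p1", "d1", "d2"})
        assert out.genes["g1"].distal_probes == ["d1", "d2"]
        assert out.curation_log["n_distal_probes_dropped_unexpressed"] == 0

    def test_injected_silent_probes_yield_exact_survivor_set(self):
        cfg = SimConfig(seed=21, n_genes=60, frac_silent_probes=0.15, log2_noise_sd=0.0)
        genes, probes, expr, truth = simulate_dataset(cfg)
        by_gene = {}
        for p in probes:
            by_gene.setdefault(p.gene_id, []).append(p)
        cls = {
            g.gene_id: classify_last_exon_probes(by_gene[g.gene_id], g)
            for g in genes
        }
        t = distal_proximal_ratios(expr, cls, ["kd1"])
        silent = set(truth.silent_probes)
        out = curate_table(t, expressed={p.probe_id for p in probes} - silent)
        expected_survivors = {
            g.gene_id
            for g in genes
            if f"{g.gene_id}_prox" not in silent
            and any(
                p.probe_id not in silent
                for p in by_gene[g.gene_id]
                if p.probe_id.endswith(tuple("123456789"))
            )
        }
        assert set(out.genes) == expected_survivors

    def test_strict_margin_call_examples(self):
        t = toy_table([0.5, 0.6], prox=1.1, probes=("d1", "d2"))
        assert call_apa_shift(t, "kd", margin=0.0)["g1"] == "distal_selective"
        t2 = toy_table([0.5, 1.2], prox=1.1, probes=("d1", "d2"))
        assert call_apa_shift(t2, "kd", margin=0.0)["g1"] == "not_shifted"

    def test_proximal_decrease_blocks_distal_selective(self):
        t = toy_table([0.4], prox=0.5)
        assert call_apa_shift(t, "kd", margin=0.2)["g1"] == "not_shifted"

    def test_call_monotone_in_distal_signal(self):
        """Decreasing a distal probe's knockdown signal can never flip
        distal_selective to not_shifted."""
        for r in np.linspace(0.75, 0.05, 15):
            call = call_apa_shift(toy_table([r]), "kd", margin=0.2)["g1"]
            assert call == "distal_selective"


def test_expression_table_round_trip(tmp_path, noisy_dataset):
    _cfg, _genes, _probes, expr, _truth = noisy_dataset
    write_expression(
        expr, tmp_path / "s.tsv", tmp_path / "c.tsv", tmp_path / "m.tsv"
    )
    back = read_expression(
        tmp_path / "s.tsv", tmp_path / "c.tsv", tmp_path / "m.tsv"
    )
    assert np.allclose(back.signals, expr.signals)
    assert (back.calls == expr.calls).all().all()
    assert list(back.samples["condition"]) == list(expr.samples["condition"])
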