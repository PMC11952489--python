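"""Coverage binning, background regularization, NB support tests, trimming, JCC."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom, poisson

from isodeg.annotation import AnnotationBundle, Transcript
from isodeg.annotation_qc import (
    estimate_dispersion,
    flag_unsupported_isoforms,
    gene_background,
    jcc_score,
    make_bins,
    nb_upper_tail,
    regularize_intronic,
    score_exonic_bins,
    trim_and_flag,
)
from isodeg.io import AbundanceTable
from isodeg.simulate import simulate_gene_models


def _bundle(*transcripts):
    return AnnotationBundle({t.transcript_id: t for t in transcripts})


def _abundance(tpms, samples=("s1",)):
    rows = []
    for s in samples:
        for (tx, gene, tpm) in tpms:
            rows.append((s, tx, gene, tpm, 100.0))
    return AbundanceTable(
        pd.DataFrame(
            rows, columns=["sample", "transcript_id", "gene_id", "TPM", "expected_count"]
        )
    )


class TestMakeBins:
    def test_exon_tiling_with_partial_terminal_bin(self):
        b = _bundle(Transcript("t", "g", "c", "+", [(0, 500)]))
        bins = make_bins(b)
        ex = bins[bins["kind"] == "exonic"]
        assert list(ex["length"]) == [200, 200, 100]
        assert len(bins[bins["kind"] == "intronic"]) == 0

    def test_union_rule_for_alternative_exons(self):
        full = Transcript("full", "g", "c", "+", [(0, 100), (200, 300)])
        skip = Transcript("skip", "g", "c", "+", [(0, 100)])
        bins = make_bins(_bundle(full, skip))
        ex = bins[bins["kind"] == "exonic"]
        # the alternative exon region [200, 300) is exonic (union rule)
        assert any((s == 200) and (e == 300) for s, e in zip(ex["start"], ex["end"]))
        intr = bins[bins["kind"] == "intronic"]
        assert list(zip(intr["start"], intr["end"])) == [(100, 200)]

    def test_every_base_in_exactly_one_bin_kind(self):
        # per-base oracle on simulated gene models
        bundle = simulate_gene_models(5, seed=3)
        bins = make_bins(bundle)
        for gene in bundle.genes:
            span_s, span_e = bundle.gene_span(gene)
            union = bundle.exonic_union(gene)
            gb = bins[bins["gene"] == gene]
            covered = np.zeros(span_e - span_s, dtype=int)
            kind_of = np.empty(span_e - span_s, dtype=object)
            for r in gb.itertuples():
                covered[r.start - span_s : r.end - span_s] += 1
                kind_of[r.start - span_s : r.end - span_s] = r.kind
            assert (covered == 1).all()
            for pos in range(span_s, span_e, 7):
                exonic = any(s <= pos < e for s, e in union)
                assert kind_of[pos - span_s] == ("exonic" if exonic else "intronic")

    def test_intron_bins_respect_max_size(self):
        bundle = simulate_gene_models(4, seed=5)
        bins = make_bins(bundle)
        assert (bins[bins["kind"] == "intronic"]["length"] <= 600).all()
        assert (bins[bins["kind"] == "exonic"]["length"] <= 200).all()


class TestRegularizeIntronic:
    @staticmethod
    def _stats(rng, n=100, noise=0.0):
        ex = rng.lognormal(2, 1, n)
        intr = 0.1 * ex * np.exp(rng.normal(0, noise, n))
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "exonic_rpkm": ex,
                "intronic_rpkm": intr,
                "intronic_reads": np.full(n, 50.0),
            }
        )

    def test_on_trend_gene_stays_near_observation(self, rng):
        stats = self._stats(rng, noise=0.0)
        out = regularize_intronic(stats)
        np.testing.assert_allclose(
            out["background_rpkm"], stats["intronic_rpkm"], rtol=0.05
        )

    def test_zero_intronic_gene_pulled_to_trend(self, rng):
        stats = self._stats(rng)
        stats.loc[0, "intronic_rpkm"] = 0.0
        stats.loc[0, "intronic_reads"] = 0.0
        out = regularize_intronic(stats)
        assert out["background_rpkm"].iloc[0] > 0

    def test_shrunk_estimates_beat_raw_in_rmse(self, rng):
        n = 200
        ex = rng.lognormal(2, 1, n)
        true_rate = 0.1 * ex  # on-trend truth
        obs_reads = rng.poisson(true_rate * 5)
        stats = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "exonic_rpkm": ex,
                "intronic_rpkm": obs_reads / 5.0,
                "intronic_reads": obs_reads.astype(float),
            }
        )
        out = regularize_intronic(stats)
        err_shrunk = np.log(out["background_rpkm"] / true_rate)
        raw = np.clip(stats["intronic_rpkm"], 1e-3, None)
        err_raw = np.log(raw / true_rate)
        assert np.sqrt((err_shrunk**2).mean()) < np.sqrt((err_raw**2).mean())

    def test_degenerate_trend_falls_back_with_warning(self):
        stats = pd.DataFrame(
            {
                "gene": ["a", "b"],
                "exonic_rpkm": [1.0, 1.0],
                "intronic_rpkm": [0.1, 0.1],
                "intronic_reads": [10.0, 10.0],
            }
        )
        with pytest.warns(UserWarning, match="trend"):
            out = regularize_intronic(stats)
        assert (out["background_rpkm"] > 0).all()


class TestNBBinTest:
    def test_count_at_null_mean_is_not_significant(self):
        p = nb_upper_tail(np.array([10.0]), np.array([10.0]), dispersion=0.1)
        assert 0.3 < p[0] < 0.7

    def test_poisson_limit(self):
        p_nb = nb_upper_tail(np.array([15.0]), np.array([5.0]), dispersion=1e-12)
        p_pois = poisson.sf(14, 5.0)
        assert abs(p_nb[0] - p_pois) < 1e-6

    def test_null_calibration(self, rng):
        mu, phi, n = 50.0, 0.05, 10_000
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu), n)
        p = nb_upper_tail(counts.astype(float), np.full(n, mu), phi)
        rate = float((p < 0.05).mean())
        # compare against the exact attainable size of the discrete test
        grid = np.arange(0, 500)
        sf = nbinom.sf(grid - 1, r, r / (r + mu))
        exact = float(nbinom.sf(grid[sf <= 0.05][0] - 1, r, r / (r + mu)))
        mc_se = np.sqrt(exact * (1 - exact) / n)
        assert abs(rate - exact) < 3 * mc_se
        assert rate < 0.05 + 3 * mc_se

    def test_dispersion_moment_estimate_recovers_truth(self, rng):
        mu, phi = 30.0, 0.2
        r = 1 / phi
        rows = []
        for g in range(50):
            counts = rng.negative_binomial(r, r / (r + mu), 20)
            for i, c in enumerate(counts):
                rows.append((f"g{g}", f"g{g}:I{i}", "intronic", 600, "s1", int(c)))
        bc = pd.DataFrame(
            rows, columns=["gene", "bin", "kind", "length", "sample", "count"]
        )
        est = estimate_dispersion(bc)
        assert 0.5 * phi < est < 2.0 * phi


def _toy_support(gene, entries):
    """entries: (start, end, supported)"""
    return pd.DataFrame(
        {
            "gene": gene,
            "bin": [f"{gene}:E{i}" for i in range(len(entries))],
            "kind": "exonic",
            "start": [e[0] for e in entries],
            "end": [e[1] for e in entries],
            "length": [e[1] - e[0] for e in entries],
            "sample": "s1",
            "count": 0,
            "p": 1.0,
            "padj": 1.0,
            "supported": [e[2] for e in entries],
        }
    )


class TestTrimAndFlag:
    TX = Transcript("t", "g", "c", "+", [(0, 400), (600, 800), (1000, 1400)])

    def test_unsupported_terminal_tail_is_trimmed(self):
        support = _toy_support(
            "g",
            [
                (0, 200, True),
                (200, 400, True),
                (600, 800, True),
                (1000, 1200, True),
                (1200, 1400, False),  # 3' tail
            ],
        )
        trimmed, flags = trim_and_flag(_bundle(self.TX), support)
        assert flags.iloc[0]["trimmed"] and not flags.iloc[0]["problematic"]
        assert trimmed.transcripts["t"].exons == [(0, 400), (600, 800), (1000, 1200)]

    def test_internal_unsupported_bin_flags_problematic_untrimmed(self):
        support = _toy_support(
            "g",
            [
                (0, 200, True),
                (200, 400, True),
                (600, 800, False),  # middle exon
                (1000, 1200, True),
                (1200, 1400, True),
            ],
        )
        trimmed, flags = trim_and_flag(_bundle(self.TX), support)
        assert flags.iloc[0]["problematic"] and not flags.iloc[0]["trimmed"]
        assert trimmed.transcripts["t"].exons == self.TX.exons

    def test_fully_supported_untouched(self):
        support = _toy_support(
            "g", [(0, 400, True), (600, 800, True), (1000, 1400, True)]
        )
        trimmed, flags = trim_and_flag(_bundle(self.TX), support)
        assert not flags.iloc[0]["trimmed"] and not flags.iloc[0]["problematic"]

    def test_fully_unsupported_flagged_not_deleted(self):
        support = _toy_support(
            "g", [(0, 400, False), (600, 800, False), (1000, 1400, False)]
        )
        trimmed, flags = trim_and_flag(_bundle(self.TX), support)
        assert flags.iloc[0]["problematic"]
        assert trimmed.transcripts["t"].exons == self.TX.exons

    def test_whole_terminal_exon_removal_is_refused(self):
        # removing the entire first exon would delete a junction
        support = _toy_support(
            "g",
            [
                (0, 200, False),
                (200, 400, False),
                (600, 800, True),
                (1000, 1400, True),
            ],
        )
        _, flags = trim_and_flag(_bundle(self.TX), support)
        assert flags.iloc[0]["problematic"]

    def test_five_prime_trimming(self):
        support = _toy_support(
            "g",
            [
                (0, 200, False),
                (200, 400, True),
                (600, 800, True),
                (1000, 1400, True),
            ],
        )
        trimmed, flags = trim_and_flag(_bundle(self.TX), support)
        assert flags.iloc[0]["trimmed"]
        assert trimmed.transcripts["t"].exons[0] == (200, 400)

    @pytest.mark.parametrize(
        "entries",
        [
            [(0, 200, True), (200, 400, True), (600, 800, True), (1000, 1200, True), (1200, 1400, False)],
            [(0, 200, False), (200, 400, True), (600, 800, True), (1000, 1400, True)],
        ],
    )
    def test_trimming_preserves_junction_set(self, entries):
        trimmed, _ = trim_and_flag(_bundle(self.TX), _toy_support("g", entries))
        assert trimmed.transcripts["t"].junctions == self.TX.junctions


class TestFlagUnsupportedIsoforms:
    FULL = Transcript("full", "g", "c", "+", [(0, 200), (400, 600)])
    DEAD = Transcript("dead", "g", "c", "+", [(0, 200), (800, 1000)])

    def _support(self, dead_exon_supported):
        return _toy_support(
            "g",
            [
                (0, 200, True),
                (400, 600, True),
                (800, 1000, dead_exon_supported),
            ],
        )

    def test_all_exons_supported_not_flagged(self):
        ab = _abundance([("full", "g", 10.0), ("dead", "g", 10.0)])
        out = flag_unsupported_isoforms(
            _bundle(self.FULL, self.DEAD), self._support(True), ab
        )
        assert not out["unsupported"].any()

    def test_dead_exon_flags_isoform(self):
        ab = _abundance([("full", "g", 10.0), ("dead", "g", 10.0)])
        out = flag_unsupported_isoforms(
            _bundle(self.FULL, self.DEAD), self._support(False), ab
        )
        out = out.set_index("transcript")
        assert bool(out.loc["dead", "unsupported"])
        assert not bool(out.loc["full", "unsupported"])
        assert bool(out.loc["dead", "in_report"])

    def test_low_tpm_isoform_excluded_from_report(self):
        ab = _abundance([("full", "g", 10.0), ("dead", "g", 0.5)])
        out = flag_unsupported_isoforms(
            _bundle(self.FULL, self.DEAD), self._support(False), ab
        ).set_index("transcript")
        assert bool(out.loc["dead", "unsupported"])
        assert not bool(out.loc["dead", "in_report"])


class TestJCCScore:
    FULL = Transcript("full", "g", "c", "+", [(0, 100), (200, 300), (400, 500)])
    SKIP = Transcript("skip", "g", "c", "+", [(0, 100), (400, 500)])

    def test_single_isoform_perfect_prediction_scores_zero(self):
        b = _bundle(self.FULL)
        ab = _abundance([("full", "g", 10.0)])
        obs = pd.DataFrame(
            {"gene": ["g", "g"], "start": [100, 300], "end": [200, 400], "count": [50, 50]}
        )
        out = jcc_score(obs, ab, b)
        assert out["jcc"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_maximum_discrepancy(self):
        # obs = (100, 0) on junctions predicted (50, 50) -> JCC = 1.0
        b = _bundle(self.FULL)
        ab = _abundance([("full", "g", 10.0)])
        obs = pd.DataFrame(
            {"gene": ["g", "g"], "start": [100, 300], "end": [200, 400], "count": [100, 0]}
        )
        assert jcc_score(obs, ab, b)["jcc"].iloc[0] == pytest.approx(1.0)

    def test_invariant_to_junction_order(self):
        b = _bundle(self.FULL, self.SKIP)
        ab = _abundance([("full", "g", 60.0), ("skip", "g", 40.0)])
        obs = pd.DataFrame(
            {
                "gene": ["g"] * 3,
                "start": [100, 300, 100],
                "end": [200, 400, 400],
                "count": [60, 55, 45],
            }
        )
        j1 = jcc_score(obs, ab, b)["jcc"].iloc[0]
        j2 = jcc_score(obs.iloc[::-1].reset_index(drop=True), ab, b)["jcc"].iloc[0]
        assert j1 == pytest.approx(j2)

    def test_no_junction_reads_gives_na(self):
        b = _bundle(self.FULL)
        ab = _abundance([("full", "g", 10.0)])
        obs = pd.DataFrame({"gene": [], "start": [], "end": [], "count": []})
        assert np.isnan(jcc_score(obs, ab, b)["jcc"].iloc[0])

    def test_unannotated_junction_inflates_score_with_warning(self):
        b = _bundle(self.FULL)
        ab = _abundance([("full", "g", 10.0)])
        obs = pd.DataFrame(
            {
                "gene": ["g"] * 3,
                "start": [100, 300, 95],
                "end": [200, 400, 405],
                "count": [50, 50, 20],
            }
        )
        with pytest.warns(UserWarning, match="absent"):
            out = jcc_score(obs, ab, b)
        assert out["jcc"].iloc[0] > 0


class TestGeneBackgroundPipeline:
    def test_background_positive_for_intronless_gene(self):
        intronless = Transcript("t1", "g1", "c", "+", [(0, 400)])
        spliced = [
            Transcript(f"t{i}", f"g{i}", "c", "+", [(0, 300), (900, 1200)])
            for i in range(2, 30)
        ]
        bundle = _bundle(intronless, *spliced)
        bins = make_bins(bundle)
        rng = np.random.default_rng(1)
        bc = bins.copy()
        bc["sample"] = "s1"
        rate = np.where(bc["kind"] == "exonic", 0.5, 0.05)
        bc["count"] = rng.poisson(rate * bc["length"].to_numpy())
        bg = gene_background(bc)
        assert (bg["background_rpkm"] > 0).all()
        assert "g1" in set(bg["gene"])

    def test_supported_called_from_counts(self):
        # one strongly covered exonic bin among background-level ones
        txs = [
            Transcript(f"t{i}", f"g{i}", "c", "+", [(0, 200), (800, 1000)])
            for i in range(25)
        ]
        bundle = _bundle(*txs)
        bins = make_bins(bundle)
        rng = np.random.default_rng(2)
        bc = bins.copy()
        bc["sample"] = "s1"
        base = np.where(bc["kind"] == "exonic", 0.02, 0.02)
        bc["count"] = rng.poisson(base * bc["length"].to_numpy())
        hot = bc[(bc["gene"] == "g0") & (bc["kind"] == "exonic")].index[0]
        bc.loc[hot, "count"] = 500
        bg = gene_background(bc)
        res = score_exonic_bins(bc, bg, dispersion=0.05)
        res = res.set_index("bin")
        assert bool(res.loc[bc.loc[hot, "bin"], "supported"])
        frac_supported = res["supported"].mean()
        assert frac_supported < 0.5
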