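"""Motif alteration, enrichment statistics, and regulon activity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sepqtl.regdrivers import (
    ActivityMatrix,
    activity_cell_correlation,
    alteration_matrix,
    differential_activity,
    ld_proxies,
    load_jaspar_pwms,
    motif_enrichment,
    read_gmt,
    regulon_activity,
    scan_motif_alteration,
    set_enrichment,
)

# a sharp 4-position motif with consensus ACGT
SHARP_PWM = np.array([
    # A   C   G   T  (columns = positions)
    [97, 1, 1, 1],
    [1, 97, 1, 1],
    [1, 1, 97, 1],
    [1, 1, 1, 97],
], dtype=float).T.reshape(4, 4)


def _consensus_pwm():
    pwm = np.full((4, 4), 1.0)
    for pos, base in enumerate("ACGT"):
        pwm["ACGT".index(base), pos] = 97.0
    return pwm


class TestMotifScan:
    def test_ref_consensus_alt_broken_is_interrupted(self):
        pwm = _consensus_pwm()
        #        0123456789
        seq = "TTTACGTTTT"  # consensus at 3..6; SNP at index 4 (the C)
        call = scan_motif_alteration(seq, 4, "C", "A", pwm)
        assert call == "interrupted"

    def test_alt_creates_consensus_is_introduced(self):
        pwm = _consensus_pwm()
        seq = "TTTAAGTTTT"  # A at index 4; C would complete ACGT
        call = scan_motif_alteration(seq, 4, "A", "C", pwm)
        assert call == "introduced"

    def test_neither_allele_hits_is_none(self):
        pwm = _consensus_pwm()
        seq = "TTTTTTTTTT"
        call = scan_motif_alteration(seq, 4, "T", "G", pwm)
        assert call == "none"

    def test_reverse_complement_strand_symmetry(self):
        pwm = _consensus_pwm()
        seq = "TTTACGTTTT"
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        call_fwd = scan_motif_alteration(seq, 4, "C", "A", pwm)
        call_rev = scan_motif_alteration(rc, len(seq) - 5, "G", "T", pwm)
        assert call_fwd == call_rev == "interrupted"

    def test_short_flank_rejected(self):
        with pytest.raises(ValueError):
            scan_motif_alteration("ACG", 0, "A", "C", _consensus_pwm())

    def test_wrong_ref_rejected(self):
        with pytest.raises(ValueError):
            scan_motif_alteration("TTTACGTTTT", 4, "G", "A", _consensus_pwm())


class TestJasparAndGmt:
    def test_jaspar_parse_roundtrip(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(
            ">MA0001.1 TESTTF\n"
            "A  [ 10  0  5 ]\n"
            "C  [  0 10  0 ]\n"
            "G  [  0  0  5 ]\n"
            "T  [  0  0  0 ]\n"
        )
        pwms = load_jaspar_pwms(p)
        assert "TESTTF" in pwms
        assert pwms["TESTTF"].shape == (4, 3)
        assert pwms["TESTTF"][0, 0] == 10

    def test_gmt_reader(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg4\n")
        sets = read_gmt(p)
        assert sets == {"setA": {"g1", "g2", "g3"}, "setB": {"g4"}}


class TestLdProxiesAndCollapse:
    def test_proxies_include_lead_and_copies(self, small_geno):
        lead = small_geno.snp_ids[1]
        proxies = ld_proxies(small_geno, lead, r2_min=0.8)
        assert lead in proxies

    def test_alteration_collapse_is_proxy_invariant(self):
        sigs = ["sig1", "sig2"]
        calls = {
            "snpA": {"m1": "introduced"},
            "snpB": {"m1": "none", "m2": "interrupted"},
        }
        m_via_a = alteration_matrix(
            sigs, {"sig1": ["snpA"], "sig2": []}, calls, ["m1", "m2"]
        )
        m_via_both = alteration_matrix(
            sigs, {"sig1": ["snpA", "snpB"], "sig2": []}, calls, ["m1", "m2"]
        )
        assert m_via_a.loc["sig1", "m1"] == m_via_both.loc["sig1", "m1"] == 1
        assert m_via_both.loc["sig1", "m2"] == 1  # any proxy suffices


class TestEnrichmentStats:
    def test_fisher_one_sided_hand_enumeration(self):
        """2x2 [[4,1],[1,4]]: one-sided p equals the hypergeometric tail."""
        _, p = stats.fisher_exact([[4, 1], [1, 4]], alternative="greater")
        # N=10, draw 5 'altered', 5 with interaction: P(X>=4) = 26/252
        assert p == pytest.approx(26 / 252, rel=1e-9)

    def test_motif_enrichment_detects_planted_signal(self, rng):
        n = 400
        flags = pd.Series(
            np.r_[np.ones(120, int), np.zeros(280, int)],
            index=[f"s{i}" for i in range(n)],
        )
        alt = pd.DataFrame(index=flags.index)
        alt["m_enriched"] = np.r_[
            rng.random(120) < 0.4, rng.random(280) < 0.05
        ].astype(int)
        for j in range(5):
            alt[f"m_null{j}"] = (rng.random(n) < 0.1).astype(int)
        tab, perm_p, _ = motif_enrichment(alt, flags, n_perm=200, seed=0)
        row = tab.set_index("motif").loc["m_enriched"]
        assert row["q"] < 0.05 and row["odds_ratio"] > 1
        assert perm_p < 0.05

    def test_equal_rates_not_enriched(self):
        flags = pd.Series([1] * 10 + [0] * 10,
                          index=[f"s{i}" for i in range(20)])
        alt = pd.DataFrame(
            {"m": [1] * 5 + [0] * 5 + [1] * 5 + [0] * 5}, index=flags.index
        )
        tab, _, _ = motif_enrichment(alt, flags, n_perm=10, seed=0)
        row = tab.iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["p"] >= 0.5

    def test_never_altered_motif_skipped(self):
        flags = pd.Series([1, 1, 0, 0], index=list("abcd"))
        alt = pd.DataFrame({"m0": [0, 0, 0, 0], "m1": [1, 0, 1, 0]},
                           index=flags.index)
        tab, _, _ = motif_enrichment(alt, flags, n_perm=5, seed=0)
        assert list(tab["motif"]) == ["m1"]

    def test_set_enrichment_hits_equal_universe(self):
        enr, p = set_enrichment({"a", "b"}, {"a", "b"}, {"a"},
                                method="hypergeometric")
        assert enr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_set_enrichment_fisher_matches_hypergeom(self):
        hits = {f"h{i}" for i in range(5)}
        universe = hits | {f"u{i}" for i in range(5)}
        ann = {f"h{i}" for i in range(4)} | {"u0"}
        e1, p1 = set_enrichment(hits, universe, ann, "hypergeometric")
        e2, p2 = set_enrichment(hits, universe, ann, "fisher_one_sided")
        assert p1 == pytest.approx(p2, rel=1e-9)
        assert p1 == pytest.approx(26 / 252, rel=1e-9)

    def test_binomial_tail_enumeration(self):
        """8 of 10 hits in annotation at null rate 0.5: p = 56/1024."""
        _, p = set_enrichment(
            {f"h{i}" for i in range(10)},
            {f"h{i}" for i in range(10)},
            {f"h{i}" for i in range(8)},
            method="binomial",
            null_rate=0.5,
        )
        assert p == pytest.approx(56 / 1024, rel=1e-9)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            set_enrichment({"a"}, set(), {"a"})
        with pytest.raises(ValueError):
            set_enrichment({"x"}, {"a"}, {"a"})


def _toy_activity(rng, n_genes=60, n_samples=40, shift=None, groups=None):
    expr_vals = rng.normal(size=(n_genes, n_samples))
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    import sepqtl.io as io

    gm = pd.DataFrame({"chrom": "1", "tss": 1}, index=pd.Index(genes))
    return io.ExpressionMatrix(
        pd.DataFrame(expr_vals, index=genes, columns=samples), gm
    )


class TestRegulonActivity:
    def test_constructed_target_pattern_scores_high(self, rng):
        expr = _toy_activity(rng)
        targets = expr.genes[:10]
        reg = pd.DataFrame({
            "tf": "TF1", "target": targets, "mode": 1, "evidence": "A",
        })
        expr.values.loc[targets, :] += 3.0  # up-shift all targets
        acts = regulon_activity(expr, reg)
        assert (acts.values.loc["TF1"] > 2).all()

    def test_negating_modes_negates_activity(self, rng):
        expr = _toy_activity(rng)
        reg = pd.DataFrame({
            "tf": "TF1", "target": expr.genes[:8],
            "mode": [1, 1, 1, 1, -1, -1, -1, -1], "evidence": "A",
        })
        a1 = regulon_activity(expr, reg)
        reg2 = reg.assign(mode=-reg["mode"])
        a2 = regulon_activity(expr, reg2)
        assert np.allclose(a1.values.to_numpy(), -a2.values.to_numpy())

    def test_random_modes_give_null_activity(self, rng):
        expr = _toy_activity(rng, n_genes=200)
        tstats = []
        for k in range(50):
            reg = pd.DataFrame({
                "tf": "TF", "target": rng.choice(expr.genes, 10,
                                                 replace=False),
                "mode": 1, "evidence": "A",
            })
            tstats.append(regulon_activity(expr, reg).values.to_numpy())
        frac_large = np.mean(np.abs(np.concatenate(tstats)) >= 3)
        assert frac_large < 0.01

    def test_small_regulons_excluded(self, rng):
        expr = _toy_activity(rng)
        reg = pd.DataFrame({
            "tf": ["TFsmall"] * 3 + ["TFok"] * 6,
            "target": expr.genes[:3] + expr.genes[3:9],
            "mode": 1, "evidence": "A",
        })
        acts = regulon_activity(expr, reg)
        assert list(acts.values.index) == ["TFok"]


class TestDifferentialActivity:
    def _frame(self, rng, n=80):
        return pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(n)],
            "individual_id": [f"i{j // 2}" for j in range(n)],
            "time_point": [1, 3] * (n // 2),
            "srs1": np.repeat(rng.integers(0, 2, n // 2), 2),
        })

    def test_planted_shift_recovered_and_null_calibrated(self, rng):
        samples = self._frame(rng)
        n = len(samples)
        vals = rng.normal(size=(30, n))
        srs = samples["srs1"].to_numpy()
        vals[:6] += 1.5 * srs  # planted differential TFs
        acts = ActivityMatrix(
            pd.DataFrame(vals, index=[f"TF{i}" for i in range(30)],
                         columns=samples["sample_id"]),
            pd.DataFrame(),
        )
        tab, expected = differential_activity(
            acts, samples, n_perm=20, seed=0
        )
        sig = set(tab.loc[tab["q"] < 0.05, "tf"])
        assert {f"TF{i}" for i in range(6)} <= sig
        assert len(sig - {f"TF{i}" for i in range(6)}) <= 2
        assert expected < 2  # permuted labels yield almost nothing

    def test_single_group_rejected(self, rng):
        samples = self._frame(rng)
        samples["srs1"] = 1
        acts = ActivityMatrix(
            pd.DataFrame(rng.normal(size=(3, len(samples))),
                         index=["a", "b", "c"],
                         columns=samples["sample_id"]),
            pd.DataFrame(),
        )
        with pytest.raises(ValueError):
            differential_activity(acts, samples)


class TestActivityCellCorrelation:
    def test_monotone_transform_gives_rho_one_first_sample_only(self, rng):
        samples = pd.DataFrame({
            "sample_id": ["i0_t1", "i0_t3", "i1_t1", "i2_t1", "i3_t1",
                          "i4_t1", "i5_t1", "i6_t1"],
            "individual_id": ["i0", "i0", "i1", "i2", "i3", "i4", "i5", "i6"],
            "time_point": [1, 3, 1, 1, 1, 1, 1, 1],
        })
        x = rng.normal(size=8)
        acts = ActivityMatrix(
            pd.DataFrame([x], index=["TF1"], columns=samples["sample_id"]),
            pd.DataFrame(),
        )
        cells = pd.DataFrame(
            {"neut": np.exp(x)}, index=samples["sample_id"]
        )
        # corrupt the later time point: it must not be used
        cells.loc["i0_t3", "neut"] = -999
        tab = activity_cell_correlation(acts, samples, cells)
        assert tab["rho"].iloc[0] == pytest.approx(1.0)
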