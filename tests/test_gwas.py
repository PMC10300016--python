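import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lethascan.gwas import (
    MarkerAssociation,
    annotate_windows,
    cross_trait_overlap,
    dosage_matrix,
    haplotype_association,
    snp_association,
)


class TestSingleMarkerOls:
    def test_worked_fixture_matches_closed_form(self):
        """Six-animal fixture agrees with textbook OLS (scipy.linregress)."""
        x = np.array([0, 0, 1, 1, 2, 2], float)
        y = np.array([0.1, -0.1, 0.2, 0.0, 0.4, 0.2])
        ref = stats.linregress(x, y)
        r = MarkerAssociation().fit(pd.DataFrame({"m": x}), y).results_[0]
        assert r.effect == pytest.approx(ref.slope, rel=1e-10)
        assert r.se == pytest.approx(ref.stderr, rel=1e-10)
        assert r.t_value == pytest.approx(ref.slope / ref.stderr, rel=1e-10)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_random_fixtures_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = rng.integers(5, 60)
            x = rng.integers(0, 3, n).astype(float)
            if len(set(x)) < 2:
                continue
            y = rng.normal(size=n)
            ref = stats.linregress(x, y)
            r = MarkerAssociation().fit(pd.DataFrame({"m": x}), y).results_[0]
            assert r.effect == pytest.approx(ref.slope, abs=1e-10)
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_monomorphic_not_testable(self):
        r = MarkerAssociation().fit(
            pd.DataFrame({"m": [1.0, 1, 1, 1]}), np.array([1.0, 2, 3, 4])
        ).results_[0]
        assert not r.testable and r.p_value == 1.0 and not r.significant

    def test_p_monotone_in_t_and_flag_consistent(self):
        rng = np.random.default_rng(1)
        rows = []
        for _ in range(40):
            x = rng.integers(0, 3, 50).astype(float)
            y = rng.normal(size=50) + 0.2 * x * rng.random()
            r = MarkerAssociation(threshold=1.3).fit(pd.DataFrame({"m": x}), y).results_[0]
            if r.testable:
                rows.append(r)
        rows.sort(key=lambda r: abs(r.t_value))
        ps = [r.p_value for r in rows]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))
        for r in rows:
            assert r.significant == (r.minus_log10_p > 1.3)

    def test_normal_tail_variant(self):
        x = np.array([0, 1, 2, 0, 1, 2], float)
        y = np.array([0.0, 0.5, 1.1, 0.1, 0.6, 0.9])
        rt = MarkerAssociation(tail="t").fit(pd.DataFrame({"m": x}), y).results_[0]
        rn = MarkerAssociation(tail="normal").fit(pd.DataFrame({"m": x}), y).results_[0]
        assert rn.p_value < rt.p_value  # normal tail is lighter than t with 4 df

    def test_null_p_values_uniform(self):
        """Under the null, single-marker p-values pass a KS uniformity test."""
        rng = np.random.default_rng(17)
        n, m = 300, 800
        X = pd.DataFrame(
            rng.integers(0, 3, size=(n, m)).astype(float),
            columns=[f"s{i}" for i in range(m)],
        )
        y = rng.normal(size=n)
        frame = MarkerAssociation().fit(X, y).frame_
        ps = frame.loc[frame["testable"], "p_value"]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestHaplotypeAssociation:
    def test_power_at_configured_effect(self):
        """A carrier liability effect of 0.5 SD at 10% carrier frequency and
        2,000 scored animals is detected at -log10(p) > 6."""
        rng = np.random.default_rng(5)
        n, delta = 2000, 0.5
        carrier = rng.random(n) < 0.10
        debv = pd.DataFrame(
            {
                "animal": [f"a{i}" for i in range(n)],
                "debv": delta * carrier + rng.normal(size=n),
            }
        )
        r = haplotype_association(debv, [f"a{i}" for i in np.flatnonzero(carrier)])
        assert r.effect > 0
        assert r.significant and r.minus_log10_p > 6

    def test_type_i_rate_under_permutation(self):
        """With labels permuted, the significant fraction at alpha=0.05 is
        near the nominal level."""
        rng = np.random.default_rng(6)
        n = 500
        carrier_ids = [f"a{i}" for i in range(50)]
        hits = 0
        reps = 200
        for _ in range(reps):
            debv = pd.DataFrame(
                {"animal": [f"a{i}" for i in rng.permutation(n)], "debv": rng.normal(size=n)}
            )
            r = haplotype_association(debv, carrier_ids)
            hits += r.p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 4 * se

    def test_degenerate_inputs_not_testable(self):
        debv = pd.DataFrame({"animal": ["a", "b", "c"], "debv": [0.0, 0.0, 0.0]})
        assert not haplotype_association(debv, ["a"]).testable  # zero-variance y
        debv2 = pd.DataFrame({"animal": ["a", "b", "c"], "debv": [0.1, 0.2, 0.3]})
        assert not haplotype_association(debv2, ["a", "b", "c"]).testable
        assert not haplotype_association(debv2, []).testable

    def test_positive_effect_in_integrated_pipeline(self):
        """With calves of carrier x carrier matings penalised on the PNM
        liability (penalty 3 SD, 15% incidence), carriers' deregressed EBVs
        shift upward: the haplotype effect is positive in every replicate and
        nominally significant in most."""
        from lethascan import SimConfig, simulate_population
        from lethascan.liability import GibbsThresholdModel, deregress, prepare_traits

        n_nominal = 0
        for seed in (1, 2, 3):
            cfg = SimConfig(
                n_founders=900, n_generations=3, n_sires_per_gen=45,
                lethal_founder_frequency=0.10, lethal_pnm_penalty=3.0,
                heritabilities={"PNM": 0.41}, trait_incidences={"PNM": 0.15},
                n_contemporary_groups=10, seed=seed,
            )
            pop = simulate_population(cfg)
            df = prepare_traits(pop.traits[["animal", "value", "cg"]])
            m = GibbsThresholdModel(n_iter=3000, burn_in=800, thin=5, seed=60 + seed).fit(
                df, pop.pedigree
            )
            d = deregress(m.result_, pop.pedigree, h2=m.h2_, min_acc=0.4)
            r = haplotype_association(d, pop.truth.true_carrier_ids, name="lethal")
            assert r.testable and r.effect > 0
            n_nominal += r.p_value < 0.05
        assert n_nominal >= 2


class TestAnnotation:
    def test_boundary_inclusive_at_window(self):
        res = pd.DataFrame(
            {"marker": ["s"], "chrom": ["1"], "pos": [500_000], "significant": [True]}
        )
        genes = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "start": [600_000, 600_001],
                "end": [650_000, 650_001],
                "gene": ["at_100kb", "beyond"],
            }
        )
        hits = annotate_windows(res, genes, window=100_000)
        assert list(hits["gene"]) == ["at_100kb"]
        assert hits.loc[0, "distance"] == 100_000

    def test_overlapping_gene_distance_zero(self):
        res = pd.DataFrame(
            {"marker": ["s"], "chrom": ["1"], "pos": [1000], "significant": [True]}
        )
        genes = pd.DataFrame(
            {"chrom": ["1"], "start": [900], "end": [1100], "gene": ["g"]}
        )
        assert annotate_windows(res, genes)["distance"].tolist() == [0]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(12)
        genes = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2"], 1000),
                "start": rng.integers(1, 10_000_000, 1000),
                "gene": [f"g{i}" for i in range(1000)],
            }
        )
        genes["end"] = genes["start"] + rng.integers(100, 50_000, 1000)
        res = pd.DataFrame(
            {
                "marker": [f"s{i}" for i in range(40)],
                "chrom": rng.choice(["1", "2"], 40),
                "pos": rng.integers(1, 10_000_000, 40),
                "significant": True,
            }
        )
        hits = annotate_windows(res, genes, window=100_000)
        got = set(zip(hits["marker"], hits["gene"]))
        brute = set()
        for _, r in res.iterrows():
            for _, g in genes.iterrows():
                if str(g["chrom"]) != str(r["chrom"]):
                    continue
                if g["start"] <= r["pos"] <= g["end"]:
                    d = 0
                elif r["pos"] < g["start"]:
                    d = g["start"] - r["pos"]
                else:
                    d = r["pos"] - g["end"]
                if d <= 100_000:
                    brute.add((r["marker"], g["gene"]))
        assert got == brute

    def test_chromosome_mismatch_raises(self):
        res = pd.DataFrame(
            {"marker": ["s"], "chrom": ["1"], "pos": [100], "significant": [True]}
        )
        genes = pd.DataFrame({"chrom": ["9"], "start": [1], "end": [2], "gene": ["g"]})
        with pytest.raises(ValueError, match="chromosome"):
            annotate_windows(res, genes)


class TestOverlap:
    def _frame(self, markers, sig):
        return pd.DataFrame(
            {"marker": markers, "significant": [m in sig for m in markers]}
        )

    def test_identical_lists_all_shared(self):
        f = self._frame(["a", "b"], {"a", "b"})
        ov = cross_trait_overlap({"HR": f, "STAY": f})
        assert ov["shared"]["HR&STAY"] == ["a", "b"]
        assert ov["specific"] == {"HR": [], "STAY": []}

    def test_disjoint_nothing_shared(self):
        ov = cross_trait_overlap(
            {
                "HR": self._frame(["a", "b"], {"a"}),
                "STAY": self._frame(["a", "b"], {"b"}),
            }
        )
        assert ov["shared"]["HR&STAY"] == []
        assert ov["specific"] == {"HR": ["a"], "STAY": ["b"]}

    def test_counts_match_set_algebra_on_random_sets(self):
        rng = np.random.default_rng(4)
        markers = [f"m{i}" for i in range(100)]
        sig = {
            t: set(rng.choice(markers, rng.integers(5, 40), replace=False))
            for t in ("HR", "PNM", "STAY")
        }
        ov = cross_trait_overlap(
            {t: self._frame(markers, s) for t, s in sig.items()}
        )
        assert set(ov["shared"]["HR&PNM&STAY"]) == sig["HR"] & sig["PNM"] & sig["STAY"]
        assert set(ov["shared"]["HR&STAY"]) == sig["HR"] & sig["STAY"]
        assert set(ov["specific"]["PNM"]) == sig["PNM"] - sig["HR"] - sig["STAY"]

    def test_single_trait_rejected(self):
        with pytest.raises(ValueError):
            cross_trait_overlap({"HR": self._frame(["a"], set())})


def test_dosage_matrix_counts_alt_copies(sim_pop):
    dos = dosage_matrix(sim_pop.panel)
    assert dos.shape == (sim_pop.panel.n_animals, sim_pop.panel.n_markers)
    np.testing.assert_array_equal(
        dos.to_numpy(), sim_pop.panel.haplotypes.sum(axis=1)
    )


def test_snp_association_intersects_animals(sim_pop):
    rng = np.random.default_rng(0)
    dos = dosage_matrix(sim_pop.panel).iloc[:, :5]
    some = list(dos.index[:500])
    debv = pd.DataFrame({"animal": some, "debv": rng.normal(size=500)})
    out = snp_association(debv, dos, sim_pop.panel.marker_map)
    assert (out["n"] == 500).all()
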