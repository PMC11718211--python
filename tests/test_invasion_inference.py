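import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tecascade.invasion_inference import (
    ContactGraph,
    InvasionWindow,
    StrainSample,
    cooccurrence,
    geographic_patchiness,
    infer_invasion_window,
    reconstruct_cascade,
    samples_from_frames,
    shared_te_snps,
)
from tecascade.shortread_quant import CopyNumberEstimate, TESnp
from tecascade.synthetic_data import SimulationConfig, SpeciesPlan, simulate_cohort


def mk_sample(strain, species, year, cn, te="Spoink", loc="main"):
    return StrainSample(
        strain, species, year, loc,
        {te: CopyNumberEstimate(strain, te, cn, 0.0, [])},
    )


class TestInvasionWindow:
    def test_simple_absent_then_present(self):
        samples = [mk_sample("a", "sim", 1961, 0.0), mk_sample("b", "sim", 2012, 8.0)]
        w = infer_invasion_window(samples, "Spoink")
        assert (w.last_absent_year, w.first_present_year) == (1961, 2012)
        assert w.status == "invaded"

    def test_all_absent_not_invaded(self):
        samples = [mk_sample(f"s{y}", "sim", y, 0.0) for y in (1970, 1990, 2010)]
        w = infer_invasion_window(samples, "Spoink")
        assert w.status == "not_invaded"
        assert w.last_absent_year is None and w.first_present_year is None

    def test_contamination_outlier_flagged(self):
        samples = [
            mk_sample("early", "sim", 1975, 5.0),
            mk_sample("a80", "sim", 1980, 0.0),
            mk_sample("a85", "sim", 1985, 0.0),
            mk_sample("a90", "sim", 1990, 0.0),
            mk_sample("p95", "sim", 1995, 6.0),
        ]
        w = infer_invasion_window(samples, "Spoink")
        assert w.outliers == ["early"]
        assert (w.last_absent_year, w.first_present_year) == (1990, 1995)

    def test_order_invariance_and_monotonicity(self):
        samples = [
            mk_sample("a", "sim", 1980, 0.0),
            mk_sample("b", "sim", 2000, 4.0),
            mk_sample("c", "sim", 2010, 9.0),
        ]
        rng = np.random.default_rng(0)
        base = infer_invasion_window(samples, "Spoink")
        for _ in range(5):
            perm = list(samples)
            rng.shuffle(perm)
            w = infer_invasion_window(perm, "Spoink")
            assert (w.last_absent_year, w.first_present_year) == (
                base.last_absent_year, base.first_present_year
            )
        # adding an earlier present sample can only move first_present earlier
        more = samples + [mk_sample("d", "sim", 1995, 3.0)]
        w2 = infer_invasion_window(more, "Spoink")
        assert w2.first_present_year <= base.first_present_year

    def test_single_year_undated(self):
        samples = [mk_sample("a", "sim", 2000, 0.0), mk_sample("b", "sim", 2000, 5.0)]
        with pytest.warns(UserWarning):
            w = infer_invasion_window(samples, "Spoink")
        assert w.status == "undated"

    def test_cohort_windows_bracket_true_invasion_year(self):
        """Over 100 seeded cohorts the inferred window contains the true
        invasion year in >= 95%; planted contaminants are flagged."""
        hits = 0
        flagged = 0
        n_cohorts = 100
        for seed in range(n_cohorts):
            rng = np.random.default_rng(seed)
            inv = int(rng.integers(1985, 2005))
            years = sorted(rng.choice(np.arange(1950, inv), 3, replace=False).tolist()) + \
                sorted(rng.choice(np.arange(inv + 1, 2024), 3, replace=False).tolist())
            plan = SpeciesPlan("sim", years=years, invasion_year=inv)
            res = simulate_cohort([plan], SimulationConfig(seed=seed),
                                  contaminant=("sim", int(years[0])))
            samples = [
                mk_sample(s, "sim", int(res.samples.set_index("strain_id").loc[s, "year"]),
                          res.truth.copy_numbers[s])
                for s in res.samples["strain_id"]
            ]
            w = infer_invasion_window(samples, "Spoink")
            if (
                w.status == "invaded"
                and w.last_absent_year is not None
                and w.last_absent_year <= inv <= w.first_present_year
            ):
                hits += 1
            if set(w.outliers) == res.truth.contaminants:
                flagged += 1
        assert hits >= 95
        assert flagged >= 95


class TestCooccurrence:
    def test_identical_vectors(self):
        df = pd.DataFrame({"A": [1, 1, 0, 0], "B": [1, 1, 0, 0]}, dtype=bool)
        conc, p = cooccurrence(df, "A", "B")
        assert conc == 1.0

    def test_complementary_vectors(self):
        df = pd.DataFrame({"A": [1, 1, 0, 0], "B": [0, 0, 1, 1]}, dtype=bool)
        conc, _p = cooccurrence(df, "A", "B")
        assert conc == 0.0

    def test_constant_te_p_undefined(self):
        df = pd.DataFrame({"A": [1, 1, 1, 1], "B": [1, 0, 1, 0]}, dtype=bool)
        conc, p = cooccurrence(df, "A", "B")
        assert p is None and conc == 0.5

    def test_perfect_six_six_table(self):
        df = pd.DataFrame({"A": [1] * 6 + [0] * 6, "B": [1] * 6 + [0] * 6}, dtype=bool)
        _c, p = cooccurrence(df, "A", "B")
        assert p == pytest.approx(2 / 924, rel=1e-9)

    def test_matches_hypergeometric_enumeration(self):
        """Fisher two-sided p equals exhaustive enumeration of tables with the
        same margins, summing probabilities <= the observed one."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(4, 21))
            a = rng.random(n) < 0.5
            b = rng.random(n) < 0.5
            df = pd.DataFrame({"A": a, "B": b})
            if df["A"].nunique() < 2 or df["B"].nunique() < 2:
                continue
            _c, p = cooccurrence(df, "A", "B")
            x11 = int((a & b).sum())
            r1, c1 = int(a.sum()), int(b.sum())

            def table_prob(k):
                return (
                    math.comb(r1, k) * math.comb(n - r1, c1 - k) / math.comb(n, c1)
                )

            obs = table_prob(x11)
            total = sum(
                table_prob(k)
                for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
                if table_prob(k) <= obs * (1 + 1e-9)
            )
            assert p == pytest.approx(total, rel=1e-7)


class TestSharedSnps:
    def _snp(self, pos, minor="G", te="Shellder"):
        return TESnp(te, pos, "A", minor, 0.2)

    def test_same_position_shared(self):
        assert len(shared_te_snps([self._snp(100)], [self._snp(100)])) == 1

    def test_different_positions_not_shared(self):
        assert shared_te_snps([self._snp(100)], [self._snp(250, "T")]) == []

    def test_self_intersection_identity(self):
        snps = [self._snp(p) for p in (10, 20, 30)]
        assert len(shared_te_snps(snps, snps)) == 3

    def test_allele_match_option(self):
        a, b = [self._snp(100, "G")], [self._snp(100, "T")]
        assert len(shared_te_snps(a, b)) == 1
        assert shared_te_snps(a, b, require_allele_match=True) == []

    def test_different_te_rejected(self):
        with pytest.raises(ValueError):
            shared_te_snps([self._snp(1, te="A")], [self._snp(1, te="B")])


def _win(sp, te, lo, hi):
    return ((sp, te), InvasionWindow(sp, te, lo, hi, status="invaded"))


class TestCascade:
    @pytest.fixture
    def paper_like_inputs(self):
        windows = dict([
            _win("D.melanogaster", "Spoink", 1983, 1993),
            _win("D.simulans", "Spoink", 1995, 2005),
            _win("D.mauritiana", "Spoink", 2000, 2006),
            _win("D.sechellia", "Spoink", 2000, 2012),
            _win("D.simulans", "Shellder", 1995, 2004),
            _win("D.mauritiana", "Shellder", 2000, 2006),
            _win("D.sechellia", "Shellder", 2000, 2012),
            _win("D.teissieri", "Shellder", 2000, 2009),
        ])
        contacts = ContactGraph.from_edges([
            ("D.melanogaster", "D.simulans", "range_overlap"),
            ("D.melanogaster", "D.mauritiana", "range_overlap"),
            ("D.melanogaster", "D.sechellia", "range_overlap"),
            ("D.simulans", "D.mauritiana", "hybridization"),
            ("D.simulans", "D.sechellia", "hybridization"),
            ("D.simulans", "D.teissieri", "range_overlap"),
        ])
        shared = {
            ("D.simulans", "D.mauritiana", "Shellder"): 5,
            ("D.simulans", "D.sechellia", "Shellder"): 4,
            ("D.mauritiana", "D.sechellia", "Shellder"): 1,
        }
        return windows, contacts, shared

    def test_reproduces_reference_edge_set(self, paper_like_inputs):
        events, unresolved = reconstruct_cascade(*paper_like_inputs)
        edges = {(e.te, e.donor, e.recipient) for e in events}
        assert edges == {
            ("Spoink", "D.melanogaster", "D.simulans"),
            ("Spoink", "D.simulans", "D.mauritiana"),
            ("Spoink", "D.simulans", "D.sechellia"),
            ("Shellder", "D.simulans", "D.mauritiana"),
            ("Shellder", "D.simulans", "D.sechellia"),
            ("Shellder", "D.simulans", "D.teissieri"),
        }
        # cascade roots (donors outside the sampled set) are unresolved
        assert set(unresolved) == {("D.melanogaster", "Spoink"), ("D.simulans", "Shellder")}

    def test_teissieri_is_single_origin(self, paper_like_inputs):
        events, _ = reconstruct_cascade(*paper_like_inputs)
        (teis,) = [e for e in events if e.recipient == "D.teissieri"]
        assert "shared_snps" not in teis.evidence
        assert "hybridization" not in teis.evidence

    def test_hybridization_evidence_on_island_edges(self, paper_like_inputs):
        events, _ = reconstruct_cascade(*paper_like_inputs)
        for e in events:
            if e.recipient in ("D.mauritiana", "D.sechellia"):
                assert "hybridization" in e.evidence
                if e.te == "Shellder":
                    assert "shared_snps" in e.evidence

    def test_acyclic_and_donor_before_recipient(self, paper_like_inputs):
        windows, contacts, shared = paper_like_inputs
        events, _ = reconstruct_cascade(windows, contacts, shared)
        for e in events:
            don = windows[(e.donor, e.te)]
            rec = windows[(e.recipient, e.te)]
            assert don.first_present_year <= rec.first_present_year
        # no directed cycles within a TE
        for te in ("Spoink", "Shellder"):
            edges = [(e.donor, e.recipient) for e in events if e.te == te]
            nodes = {n for e in edges for n in e}
            order = {}
            for n in nodes:
                order[n] = windows[(n, te)].first_present_year
            assert all(order[d] <= order[r] for d, r in edges)

    def test_no_contact_unresolved(self):
        windows = dict([
            _win("A", "te", 1980, 1990),
            _win("B", "te", 1995, 2000),
        ])
        events, unresolved = reconstruct_cascade(windows, ContactGraph())
        assert events == [] and ("B", "te") in unresolved


class TestPatchiness:
    def test_patchy_islands(self):
        samples = [mk_sample(f"p{i}", "sech", 2000, 5.0, loc="Praslin") for i in range(3)]
        samples += [mk_sample(f"m{i}", "sech", 2000, 0.0, loc="Mahe") for i in range(3)]
        classes, patchy = geographic_patchiness(samples, "Spoink")
        assert patchy and classes == {"Praslin": "fixed_present", "Mahe": "fixed_absent"}

    def test_uniform_presence_not_patchy(self):
        samples = [mk_sample(f"s{i}", "sim", 2000, 5.0, loc=l) for i, l in
                   enumerate(["a", "a", "b", "b"])]
        _classes, patchy = geographic_patchiness(samples, "Spoink")
        assert not patchy

    def test_simulated_island_cohort(self):
        rng = np.random.default_rng(4)
        islands = [f"isl{i}" for i in range(5)]
        invaded = set(rng.choice(islands, 2, replace=False).tolist())
        samples = []
        for i, isl in enumerate(islands):
            for k in range(3):
                cn = 6.0 if isl in invaded else 0.0
                samples.append(mk_sample(f"{isl}_{k}", "sech", 2000, cn, loc=isl))
        classes, patchy = geographic_patchiness(samples, "Spoink")
        assert patchy
        assert {l for l, c in classes.items() if c == "fixed_present"} == invaded


class TestSamplesFromFrames:
    def test_join_roundtrip(self):
        sheet = pd.DataFrame({
            "strain_id": ["s1", "s2"], "species": ["sim", "sim"],
            "year": [1990, 2000], "location": ["x", "y"],
        })
        cn = pd.DataFrame({
            "strain": ["s1", "s2"], "te": ["Spoink", "Spoink"],
            "copy_number": [0.0, 7.5],
        })
        samples = samples_from_frames(sheet, cn)
        assert not samples[0].present("Spoink") and samples[1].present("Spoink")
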