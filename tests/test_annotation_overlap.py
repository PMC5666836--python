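import numpy as np
import pytest

from phytamyloid import (
    ProteinRecord,
    Region,
    ar_distribution_over_cbrs,
    feature_overlap_fractions,
    pfam_summary,
)
from phytamyloid.annotation_overlap import (
    UNANNOTATED,
    add_unannotated,
    overlap_length,
    pfam_summary_frame,
)


class TestOverlapLength:
    @pytest.mark.parametrize(
        "region,feature,expected",
        [
            (Region(5, 25, "AR"), (0, 100), 20),   # containment
            (Region(0, 10, "AR"), (10, 20), 0),    # adjacent half-open
            (Region(0, 15, "AR"), (10, 20), 5),    # partial
        ],
    )
    def test_cases(self, region, feature, expected):
        assert overlap_length(region, feature) == expected


class TestFeatureOverlapFractions:
    def test_fraction_of_feature_covered(self):
        regions = {"p1": [Region(10, 40, "AR")]}
        features = {"p1": [("Transmembrane", 0, 100)]}
        fractions = feature_overlap_fractions(regions, features)
        assert fractions["Transmembrane"] == 0.30

    def test_untouched_type_zero_and_full_coverage_one(self):
        regions = {"p1": [Region(0, 20, "AR")]}
        features = {"p1": [("Signal", 0, 20), ("Domain", 50, 80)]}
        fractions = feature_overlap_fractions(regions, features)
        assert fractions["Signal"] == 1.0
        assert fractions["Domain"] == 0.0

    def test_same_type_intervals_unioned_in_denominator(self):
        regions = {"p1": [Region(0, 10, "AR")]}
        features = {"p1": [("D", 0, 30), ("D", 20, 50)]}  # union = 50 residues
        fractions = feature_overlap_fractions(regions, features)
        assert fractions["D"] == 10 / 50

    def test_overlap_mass_conservation(self, rng):
        """Sum of per-type overlaps equals total region∩annotated length when
        feature types partition the protein."""
        for trial in range(10):
            length = 200
            rec = ProteinRecord("p", "A" * length)
            cut1, cut2 = sorted(rng.integers(1, length, size=2).tolist())
            if cut1 == cut2:
                continue
            features = {"p": [("X", 0, cut1), ("Y", cut1, cut2)]}
            features = add_unannotated(features, [rec])
            regions = {}
            s = int(rng.integers(0, length - 20))
            regions["p"] = [Region(s, s + 20, "AR")]
            fractions = feature_overlap_fractions(regions, features["p"] and features)
            totals = {"X": cut1, "Y": cut2 - cut1, UNANNOTATED: length - cut2}
            mass = sum(fractions[t] * totals[t] for t in totals if totals[t] > 0)
            assert mass == pytest.approx(20)

    def test_bitmap_oracle_equivalence(self, rng):
        """Overlap sums match a per-residue bitmap on random fixtures."""
        for trial in range(20):
            length = int(rng.integers(50, 300))
            n_feats = int(rng.integers(1, 6))
            feats = []
            for _ in range(n_feats):
                s = int(rng.integers(0, length - 1))
                e = int(rng.integers(s + 1, length + 1))
                feats.append((f"F{int(rng.integers(0, 3))}", s, e))
            regions = []
            for _ in range(int(rng.integers(0, 4))):
                s = int(rng.integers(0, length - 1))
                e = int(rng.integers(s + 1, length + 1))
                regions.append(Region(s, e, "AR"))
            got = feature_overlap_fractions({"p": regions}, {"p": feats})
            # bitmap: per feature type, residues in type and in any region
            region_mask = np.zeros(length, dtype=bool)
            for r in regions:
                region_mask[r.start:r.end] = True
            for ftype in {f[0] for f in feats}:
                type_mask = np.zeros(length, dtype=bool)
                for t, s, e in feats:
                    if t == ftype:
                        type_mask[s:e] = True
                expected = (type_mask & region_mask).sum() / type_mask.sum()
                assert got[ftype] == pytest.approx(expected)


class TestArOverCbrs:
    def test_ar_inside_hydrophobic_cbr(self):
        ars = {"p1": [Region(0, 12, "AR")]}
        cbrs = {"p1": [Region(0, 20, "CBR", "IWYF", -9.0)]}
        assert ar_distribution_over_cbrs(ars, cbrs) == {"IWYF": 0.6}

    def test_no_ars_all_zero(self):
        cbrs = {"p1": [Region(0, 20, "CBR", "QN", -9.0)]}
        assert ar_distribution_over_cbrs({}, cbrs) == {"QN": 0.0}

    def test_ar_spanning_two_cbrs_summed(self):
        ars = {"p1": [Region(5, 45, "AR")]}
        cbrs = {"p1": [Region(0, 20, "CBR", "QN", -9.0),
                       Region(30, 50, "CBR", "QN", -9.0)]}
        # overlaps 15 and 15 over total QN length 40
        assert ar_distribution_over_cbrs(ars, cbrs) == {"QN": 0.75}


class TestPfamSummary:
    def _build(self, spec):
        """spec: list of (acc, n_proteins, n_species, n_qn, n_species_qn)
        with disjoint protein sets per accession."""
        pfam, qn_flags, species_map = {}, {}, {}
        counter = 0
        for acc, n_prot, n_sp, n_qn, n_sp_qn in spec:
            for i in range(n_prot):
                pid = f"{acc}_{i}"
                pfam[pid] = {acc}
                species_map[pid] = f"sp{(i % n_sp)}_{acc}"
                counter += 1
            # qn-rich proteins spread over exactly n_sp_qn species
            for i in range(n_qn):
                qn_flags[f"{acc}_{(i % n_sp_qn) + n_sp_qn * (i // n_sp_qn)}"] = True
        return pfam, qn_flags, species_map

    def test_counts_and_percentages(self):
        pfam = {"a": {"PF1"}, "b": {"PF1"}, "c": {"PF1"}, "d": {"PF2"}}
        qn = {"a": True, "d": True}
        species = {"a": "s1", "b": "s1", "c": "s2", "d": "s2"}
        rows = pfam_summary({"a", "b", "c", "d"}, pfam, qn, species)
        by_id = {r.pfam_id: r for r in rows}
        pf1 = by_id["PF1"]
        assert (pf1.n_proteins, pf1.n_species, pf1.n_qn_rich,
                pf1.n_species_qn_rich) == (3, 2, 1, 1)
        assert pf1.pct_qn_rich == 33.33
        total = by_id["Total"]
        assert (total.n_proteins, total.n_qn_rich) == (4, 2)
        assert total.pct_qn_rich == 50.0

    def test_total_counts_distinct_proteins_once(self):
        # one protein carrying two domains contributes once to Total
        pfam = {"a": {"PF1", "PF2"}, "b": {"PF1"}}
        rows = pfam_summary({"a", "b"}, pfam, {"a": True}, {"a": "s", "b": "s"})
        total = next(r for r in rows if r.pfam_id == "Total")
        assert total.n_proteins == 2
        assert total.n_qn_rich == 1

    def test_non_storage_proteins_ignored(self):
        pfam = {"a": {"PF1"}, "zz": {"PF9"}}
        rows = pfam_summary({"a"}, pfam, {}, {"a": "s"})
        assert {r.pfam_id for r in rows} == {"PF1", "Total"}

    def test_rounding_half_up_two_decimals(self):
        # 1/3 -> 33.33; 2/3 -> 66.67; 1/8 = 12.5 exactly -> 12.50
        pfam = {f"p{i}": {"PF1"} for i in range(3)}
        rows = pfam_summary(set(pfam), pfam, {"p0": True},
                            {p: "s" for p in pfam})
        assert rows[0].pct_qn_rich == 33.33

    def test_frame_schema(self):
        pfam = {"a": {"PF1"}}
        rows = pfam_summary({"a"}, pfam, {}, {"a": "s"})
        frame = pfam_summary_frame(rows)
        assert list(frame.columns) == [
            "pfam_id", "description", "n_proteins", "n_species", "n_qn_rich",
            "n_species_qn_rich", "pct_qn_rich", "pct_species_qn_rich",
        ]
        assert frame.iloc[-1]["pfam_id"] == "Total"
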