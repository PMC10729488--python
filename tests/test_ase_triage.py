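"""ASE ratios / NMD contrast and unmapped-read triage."""

import numpy as np
import pandas as pd
import pytest

from noninvrna.ase import flag_outlier_donors, nmd_contrast, ref_ratio
from noninvrna.simulate import simulate_ase_sites
from noninvrna.triage import (
    classify_reads,
    highlight_species,
    repeated_sequence_sharing,
    replicate_concordance,
    species_abundance,
    top_fraction_species,
)


def _sites(rows):
    df = pd.DataFrame(rows, columns=["ref_count", "alt_count"])
    df["donor"] = "D01"
    df["tissue"] = "hair"
    df["collection"] = 1
    df["consequence"] = "synonymous"
    return df


class TestRefRatio:
    def test_total_boundary_sixteen_kept_fifteen_dropped(self):
        out = ref_ratio(_sites([(8, 8), (7, 8)]))
        assert len(out) == 1
        assert out.loc[0, "ratio"] == pytest.approx(0.5)

    def test_extreme_ratios(self):
        out = ref_ratio(_sites([(0, 20), (20, 0)]))
        assert list(out["ratio"]) == [0.0, 1.0]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ref_ratio(_sites([(-1, 20)]))

    def test_swap_symmetry(self):
        a = ref_ratio(_sites([(12, 30)]))
        b = ref_ratio(_sites([(30, 12)]))
        assert a.loc[0, "ratio"] == pytest.approx(1 - b.loc[0, "ratio"])

    def test_raising_threshold_only_removes(self):
        sites = simulate_ase_sites(50, 20.0, 0.6, seed=1)
        lo = ref_ratio(sites, min_total=10)
        hi = ref_ratio(sites, min_total=30)
        keys = lambda df: set(df["variant"])
        assert keys(hi) <= keys(lo)


class TestOutlierDonors:
    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(2)
        rows = []
        for d in range(10):
            p = 0.9 if d == 0 else 0.5
            for i in range(40):
                tot = 50
                ref = rng.binomial(tot, p)
                rows.append({"donor": f"D{d:02d}", "ref_count": ref, "alt_count": tot - ref})
        ratios = ref_ratio(pd.DataFrame(rows))
        assert flag_outlier_donors(ratios) == ["D00"]

    def test_null_donors_not_flagged(self):
        rng = np.random.default_rng(3)
        rows = [
            {"donor": f"D{d:02d}", "ref_count": rng.binomial(50, 0.5), "alt_count": 0}
            for d in range(12)
            for _ in range(30)
        ]
        df = pd.DataFrame(rows)
        df["alt_count"] = 50 - df["ref_count"]
        assert flag_outlier_donors(ref_ratio(df)) == []

    def test_degenerate_identical_donors_warn(self):
        df = ref_ratio(
            pd.DataFrame(
                {
                    "donor": ["D1", "D2", "D3"],
                    "ref_count": [10, 10, 10],
                    "alt_count": [10, 10, 10],
                }
            )
        )
        with pytest.warns(UserWarning):
            assert flag_outlier_donors(df) == []


class TestNmdContrast:
    def test_planted_imbalance_detected(self):
        sites = simulate_ase_sites(100, 50.0, 0.8, seed=4)
        out = nmd_contrast(ref_ratio(sites))
        assert out.p_value < 0.01
        assert out.median_difference > 0

    def test_contrast_invariant_to_allele_swap(self):
        sites = simulate_ase_sites(50, 50.0, 0.8, seed=5)
        swapped = sites.rename(columns={"ref_count": "alt_count", "alt_count": "ref_count"})
        a = nmd_contrast(ref_ratio(sites))
        b = nmd_contrast(ref_ratio(swapped))
        assert a.p_value == pytest.approx(b.p_value)

    def test_single_site_groups_computable(self):
        df = pd.DataFrame(
            {
                "donor": ["D1", "D1"],
                "ref_count": [30, 10],
                "alt_count": [2, 10],
                "consequence": ["stop_gained", "synonymous"],
            }
        )
        out = nmd_contrast(ref_ratio(df))
        assert 0 < out.p_value <= 1

    def test_empty_group_is_error(self):
        sites = simulate_ase_sites(10, 50.0, 0.8, seed=6)
        only_syn = sites[sites["consequence"] == "synonymous"]
        with pytest.raises(ValueError):
            nmd_contrast(ref_ratio(only_syn))

    def test_stratified_output(self):
        sites = simulate_ase_sites(80, 50.0, 0.8, seed=7)
        out = nmd_contrast(ref_ratio(sites), by=["tissue"])
        assert {"tissue", "p_value"} <= set(out.columns)
        assert len(out) == sites["tissue"].nunique()


class TestClassifyReads:
    def test_all_mapped(self):
        led = classify_reads("s", ["r1", "r2"], ["r1", "r2"], [], [])
        assert (led.n_mapped, led.n_remapped, led.n_repeated, led.n_unknown) == (2, 0, 0, 0)

    def test_disjoint_thirds(self):
        ids = [f"r{i}" for i in range(9)]
        led = classify_reads("s", ids, ids[:3], ids[3:6], ids[6:])
        assert (led.n_mapped, led.n_remapped, led.n_repeated, led.n_unknown) == (3, 3, 3, 0)

    def test_precedence_counts_once(self):
        led = classify_reads("s", ["r1", "r2"], [], ["r1"], ["r1"])
        assert led.n_remapped == 1 and led.n_repeated == 0
        assert led.n_precedence_overlaps == 1

    def test_foreign_ids_rejected(self):
        with pytest.raises(ValueError):
            classify_reads("s", ["r1"], ["rX"], [], [])


class TestSpeciesAbundance:
    def _table(self):
        return pd.DataFrame(
            {"genome_length": [1e6, 2e6], "s1": [100, 100], "s2": [0, 50]},
            index=["spA", "spB"],
        )

    def test_length_normalized_closed_form(self):
        ab = species_abundance(self._table())
        assert ab["s1"].to_numpy() == pytest.approx([2 / 3, 1 / 3])

    def test_single_species_is_one(self):
        ab = species_abundance(self._table())
        assert ab.loc["spB", "s2"] == 1.0

    def test_depth_scale_invariance_and_colsum(self):
        t = self._table()
        t2 = t.copy()
        t2[["s1", "s2"]] *= 10
        assert np.allclose(species_abundance(t), species_abundance(t2))
        assert np.allclose(species_abundance(t).sum(axis=0), 1.0)

    def test_all_zero_sample_warns_nan(self):
        t = self._table()
        t["s3"] = 0
        with pytest.warns(UserWarning):
            ab = species_abundance(t)
        assert ab["s3"].isna().all()


class TestTopFractionSpecies:
    def test_ceiling_arithmetic(self):
        rng = np.random.default_rng(8)
        ab = pd.DataFrame(
            rng.dirichlet(np.ones(200), size=3).T, index=[f"sp{i:03d}" for i in range(200)]
        )
        assert len(top_fraction_species(ab, frac=0.005)) == 1
        assert len(top_fraction_species(ab, frac=1.0)) == 200

    def test_planted_dominant_species_first(self):
        ab = pd.DataFrame(
            {"s1": [0.6, 0.2, 0.2], "s2": [0.7, 0.1, 0.2]}, index=["dom", "x", "y"]
        )
        assert top_fraction_species(ab, frac=0.34)[0] == "dom"

    def test_sample_duplication_stable(self):
        ab = pd.DataFrame({"s1": [0.6, 0.4], "s2": [0.2, 0.8]}, index=["a", "b"])
        dup = pd.concat([ab, ab.add_suffix("_copy", axis=1)], axis=1)
        assert top_fraction_species(ab, frac=0.5) == top_fraction_species(dup, frac=0.5)


class TestReplicateConcordance:
    def test_identical_and_reversed_replicates(self):
        rng = np.random.default_rng(9)
        base = rng.dirichlet(np.ones(4), size=5).T
        cols = {}
        for i in range(5):
            cols[f"p{i}_r1"] = base[:, i]
            cols[f"p{i}_r2"] = base[:, i]
        ab = pd.DataFrame(cols, index=[f"sp{j}" for j in range(4)])
        pairs = [(f"p{i}_r1", f"p{i}_r2") for i in range(5)]
        assert np.allclose(replicate_concordance(ab, pairs), 1.0)
        rev = [(f"p{i}_r1", f"p{4 - i}_r2") for i in range(5)]
        ab2 = ab.copy()
        for i in range(5):
            ab2[f"p{i}_r2"] = base[:, ::-1][:, i] * 0 + np.sort(base[:, i])[::-1]
        # direct anti-rank construction
        x = np.array([[1, 2, 3, 4, 5], [4, 3, 2, 1, 0]], dtype=float)
        abx = pd.DataFrame(
            {f"p{i}_r1": x[0, i] for i in range(5)} | {f"p{i}_r2": x[1, i] for i in range(5)},
            index=["only"],
        )
        assert replicate_concordance(abx, pairs)["only"] == pytest.approx(-1.0)

    def test_mismatched_pairing_rejected(self):
        ab = pd.DataFrame({"a": [1.0]}, index=["sp"])
        with pytest.raises(KeyError):
            replicate_concordance(ab, [("a", "missing")])


class TestHighlightSpecies:
    def test_strict_threshold_and_tissue_locality(self):
        ab = pd.DataFrame(
            {
                "b1": [0.05, 0.5, 0.45],
                "b2": [0.05, 0.55, 0.40],
                "h1": [0.05, 0.01, 0.94],
                "h2": [0.05, 0.03, 0.92],
            },
            index=["at_threshold", "buccal_only", "everywhere"],
        )
        tissues = pd.Series(["buccal", "buccal", "hair", "hair"], index=ab.columns)
        out = highlight_species(ab, tissues)
        assert "at_threshold" not in out["buccal"] and "at_threshold" not in out["hair"]
        assert out["buccal"] == ["buccal_only", "everywhere"]
        assert out["hair"] == ["everywhere"]


class TestRepeatedSequenceSharing:
    def test_all_everywhere(self):
        pres = pd.DataFrame(True, index=["s1", "s2"], columns=["g1", "g2", "g3"])
        out = repeated_sequence_sharing(pres)
        assert out["in_all_groups"] == 2 and out["in_one_group"] == 0

    def test_exclusive_only(self):
        pres = pd.DataFrame(
            [[True, False], [False, True]], index=["s1", "s2"], columns=["g1", "g2"]
        )
        out = repeated_sequence_sharing(pres)
        assert out["in_one_group"] == 2 and out["in_all_groups"] == 0

    def test_five_sequence_power_set_oracle(self):
        rng = np.random.default_rng(10)
        pres = pd.DataFrame(
            rng.random((5, 3)) < 0.6,
            index=[f"s{i}" for i in range(5)],
            columns=["a", "b", "c"],
        )
        out = repeated_sequence_sharing(pres)
        total = sum(out["regions"].values())
        assert total == out["n_sequences"]
        for membership, count in out["regions"].items():
            expected = sum(
                1
                for s in pres.index
                if tuple(pres.loc[s]) == membership and any(membership)
            )
            assert count == expected
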