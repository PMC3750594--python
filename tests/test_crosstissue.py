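import numpy as np
import pandas as pd
import pytest

from tdmr import (
    BetaMatrix,
    SimulationConfig,
    VariabilityParams,
    correlation_overlap,
    cross_tissue_correlation,
    filter_snp_probes,
    interindividual_mss,
    simulate_methylation,
)
from tdmr.io_formats import IntervalTrack, ProbeManifest


def manifest_one(pos, strand="+"):
    return ProbeManifest(
        pd.DataFrame(
            {"probe_id": ["p0"], "chromosome": "chr1", "position": [pos], "strand": [strand]}
        )
    )


class TestSnpFilter:
    def test_snp_on_cpg_removes_probe(self):
        retained, n = filter_snp_probes(manifest_one(1000), [("chr1", 1000)])
        assert n == 1 and len(retained) == 0
        # second base of the CpG dinucleotide counts too
        retained, n = filter_snp_probes(manifest_one(1000), [("chr1", 1001)])
        assert n == 1

    def test_probe_body_window_is_strand_aware(self):
        # + strand: body extends to lower coordinates
        _, n = filter_snp_probes(manifest_one(1000, "+"), [("chr1", 990)], window=50)
        assert n == 1
        _, n = filter_snp_probes(manifest_one(1000, "+"), [("chr1", 1010)], window=50)
        assert n == 0
        # - strand: body extends to higher coordinates
        _, n = filter_snp_probes(manifest_one(1000, "-"), [("chr1", 1010)], window=50)
        assert n == 1
        # unknown strand masks both sides
        _, n = filter_snp_probes(manifest_one(1000, "."), [("chr1", 990)], window=50)
        assert n == 1

    def test_distant_snp_retained(self):
        retained, n = filter_snp_probes(manifest_one(1000), [("chr1", 1500)], window=50)
        assert n == 0 and list(retained) == ["p0"]

    def test_interval_track_input(self):
        track = IntervalTrack.from_tuples("SNP", [("chr1", 999, 1000)])  # 1-based 1000
        _, n = filter_snp_probes(manifest_one(1000), track)
        assert n == 1


class TestInterindividualMss:
    def _matrix(self, means_by_individual):
        from tdmr.io_formats import SampleSheet

        indivs = list(means_by_individual)
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": [f"liver_{i}" for i in indivs],
                    "tissue": "liver",
                    "individual": indivs,
                }
            )
        )
        values = pd.DataFrame(
            [list(means_by_individual.values())],
            index=pd.Index(["p0"], name="probe_id"),
            columns=[f"liver_{i}" for i in indivs],
        )
        return BetaMatrix(values=values, manifest=manifest_one(1000), samples=sheet)

    @pytest.mark.parametrize(
        "means, expected",
        [
            ({"a": 0.3, "b": 0.5}, 0.01),
            ({"a": 0.2, "b": 0.6}, 0.04),
            ({"a": 0.4, "b": 0.4, "c": 0.4}, 0.0),
        ],
    )
    def test_worked_values(self, means, expected):
        mss = interindividual_mss(self._matrix(means), "liver")
        assert mss.loc["p0"] == pytest.approx(expected, rel=1e-9)

    def test_single_individual_is_missing(self):
        mss = interindividual_mss(self._matrix({"a": 0.3}), "liver")
        assert np.isnan(mss.loc["p0"])


class TestCrossTissueCorrelation:
    def test_affine_copy_of_reference_has_unit_correlation(self):
        cfg = SimulationConfig(
            n_probes=50, planted_dmrs=(), snp_fraction=0.0,
            individuals_per_tissue=5, individual_sd=0.05, seed=3,
        )
        ds = simulate_methylation(cfg)
        vals = ds.matrix.values.copy()
        sheet = ds.matrix.samples.table
        for tissue in ("liver",):
            t_cols = sheet.loc[sheet.tissue == tissue].sort_values("individual")
            b_cols = sheet.loc[sheet.tissue == "blood"].sort_values("individual")
            for tc, bc in zip(t_cols.sample_id, b_cols.sample_id):
                vals[tc] = np.clip(0.5 * vals[bc] + 0.2, 0, 1)
        m = BetaMatrix(values=vals, manifest=ds.manifest, samples=ds.matrix.samples)
        tab = cross_tissue_correlation(m, "liver")
        r = tab["r_with_reference"].dropna()
        np.testing.assert_allclose(r, 1.0, atol=1e-9)

    def test_negated_differences_give_minus_one(self):
        cfg = SimulationConfig(
            n_probes=30, planted_dmrs=(), snp_fraction=0.0,
            individuals_per_tissue=4, individual_sd=0.05, seed=4,
        )
        ds = simulate_methylation(cfg)
        vals = ds.matrix.values.copy()
        sheet = ds.matrix.samples.table
        t_cols = sheet.loc[sheet.tissue == "liver"].sort_values("individual")
        b_cols = sheet.loc[sheet.tissue == "blood"].sort_values("individual")
        for tc, bc in zip(t_cols.sample_id, b_cols.sample_id):
            vals[tc] = np.clip(1.0 - vals[bc], 0, 1)  # mirror flips differences
        m = BetaMatrix(values=vals, manifest=ds.manifest, samples=ds.matrix.samples)
        tab = cross_tissue_correlation(m, "liver")
        r = tab["r_with_reference"].dropna()
        np.testing.assert_allclose(r, -1.0, atol=1e-9)

    def test_shared_offsets_recovered_independent_rejected(self):
        shared = SimulationConfig(
            n_probes=500, planted_dmrs=(), snp_fraction=0.0,
            individuals_per_tissue=6, individual_sd=0.1, residual_sd=0.01,
            correlated_fraction=1.0, seed=5,
        )
        tab = cross_tissue_correlation(simulate_methylation(shared).matrix, "liver")
        assert (tab["r_with_reference"] > 0.8).mean() >= 0.99
        indep = SimulationConfig(
            n_probes=500, planted_dmrs=(), snp_fraction=0.0,
            individuals_per_tissue=6, individual_sd=0.1, residual_sd=0.01,
            correlated_fraction=0.0, seed=5,
        )
        tab0 = cross_tissue_correlation(simulate_methylation(indep).matrix, "liver")
        assert (tab0["r_with_reference"] > 0.8).mean() <= 0.10

    def test_selection_requires_both_thresholds(self):
        cfg = SimulationConfig(
            n_probes=300, planted_dmrs=(), snp_fraction=0.0,
            individuals_per_tissue=6, individual_sd=0.25, residual_sd=0.01,
            correlated_fraction=1.0, seed=6,
        )
        tab = cross_tissue_correlation(simulate_methylation(cfg).matrix, "liver")
        sel = tab["selected"]
        man = (tab["mss_individual"] > 0.025) & (tab["r_with_reference"] > 0.8)
        assert (sel == man.fillna(False)).all()
        assert sel.any()  # offsets this large must select something

    def test_probe_subset_restricts_output(self):
        cfg = SimulationConfig(n_probes=40, planted_dmrs=(), snp_fraction=0.0, seed=7)
        ds = simulate_methylation(cfg)
        keep = pd.Index(ds.manifest.probe_ids[:10])
        tab = cross_tissue_correlation(ds.matrix, "liver", probes=keep)
        assert set(tab["probe_id"]) == set(keep)

    def test_reference_equal_to_target_rejected(self):
        cfg = SimulationConfig(n_probes=10, planted_dmrs=(), snp_fraction=0.0, seed=8)
        with pytest.raises(ValueError):
            cross_tissue_correlation(simulate_methylation(cfg).matrix, "blood")


class TestCorrelationOverlap:
    def _records(self, sel_by_tissue):
        out = {}
        probes = sorted({p for sel in sel_by_tissue.values() for p in sel} | {"pZ"})
        for tissue, sel in sel_by_tissue.items():
            out[tissue] = pd.DataFrame(
                {"probe_id": probes, "selected": [p in sel for p in probes]}
            )
        return out

    def test_membership_and_all_tissue_flag(self):
        recs = self._records(
            {"muscle": {"p1", "p3"}, "liver": {"p2", "p3"}, "fat": {"p3"}}
        )
        out = correlation_overlap(recs).set_index("probe_id")
        assert out.loc["p1", "tissues"] == "muscle"
        assert out.loc["p2", "tissues"] == "liver"
        assert out.loc["p3", "n_tissues"] == 3
        assert bool(out.loc["p3", "all_tissue_flag"])
        assert not bool(out.loc["p1", "all_tissue_flag"])

    def test_disjoint_memberships_partition_selected(self):
        recs = self._records({"muscle": {"p1"}, "liver": {"p2"}})
        out = correlation_overlap(recs)
        assert out["n_tissues"].sum() == 2
        assert len(out) == 2
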