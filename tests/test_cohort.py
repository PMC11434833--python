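"""Synthetic cohort generation and the long-format dataset interface."""

import io

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import peritopk as pk
from peritopk.cohort import DATASET_COLUMNS, REGIMEN_BY_CATEGORY


class TestGenerateCohort:
    def test_study_size_and_expected_category_counts(self, small_cohort,
                                                     pip_params, taz_params):
        design = pk.CohortDesign(n_patients=45)
        cohort = pk.generate_cohort(design, pip_params, taz_params, seed=5)
        assert len(cohort.subjects) == 45
        # multinomial mean 22/12/8/3; with one draw just check coverage and
        # that A dominates as designed
        counts = {c: 0 for c in "ABCD"}
        for s in cohort.subjects:
            counts[s.covariates.renal_category] += 1
        assert sum(counts.values()) == 45
        assert counts["A"] == max(counts.values())

    def test_regimen_assignment_follows_renal_category(self, pip_params,
                                                       taz_params):
        cohort = pk.generate_cohort(
            pk.CohortDesign(n_patients=40), pip_params, taz_params, seed=9
        )
        for s in cohort.subjects:
            cat = s.covariates.renal_category
            assert s.daily_dose["piperacillin"] == \
                REGIMEN_BY_CATEGORY[cat]["piperacillin"]
            assert s.daily_dose["tazobactam"] == \
                REGIMEN_BY_CATEGORY[cat]["tazobactam"]

    def test_same_seed_gives_byte_identical_dataset(self, pip_params,
                                                    taz_params):
        design = pk.CohortDesign(n_patients=10)
        out = []
        for _ in range(2):
            c = pk.generate_cohort(design, pip_params, taz_params, seed=77)
            buf = io.StringIO()
            pk.write_dataset(pk.cohort_to_dataset(c), buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_noiseless_t1_plasma_equals_closed_form_css(self, pip_noiseless,
                                                        taz_noiseless):
        # all-reference-category cohort so every subject has fully settled
        # kinetics within the 48-72 h window
        design = pk.CohortDesign(n_patients=8, category_probs=(1, 0, 0, 0))
        cohort = pk.generate_cohort(design, pip_noiseless, taz_noiseless,
                                    seed=2)
        pops = {"piperacillin": pip_noiseless, "tazobactam": taz_noiseless}
        for s in cohort.subjects:
            for r in s.records:
                if r.matrix == "plasma" and r.occasion == 2:
                    p = pk.individual_params(pops[r.drug], s.covariates)
                    css1, _ = pk.steady_state(p, s.daily_dose[r.drug] / 24)
                    assert r.value == pytest.approx(css1, rel=1e-6)

    def test_sampling_times_within_design_window(self, small_cohort):
        for s in small_cohort.subjects:
            assert 48.0 <= s.t1 <= 72.0

    def test_blq_frequency_increases_with_lloq(self, pip_params, taz_params):
        design_lo = pk.CohortDesign(n_patients=60)
        design_hi = replace(design_lo,
                            lloq={"piperacillin": 10.0, "tazobactam": 10.0})
        n_blq = []
        for design in (design_lo, design_hi):
            c = pk.generate_cohort(design, pip_params, taz_params, seed=4)
            n_blq.append(sum(r.below_lloq for r in c.records))
        assert n_blq[1] > n_blq[0]


class TestFluidCollections:
    def test_urine_recovers_renal_clearance_at_steady_state(
        self, pip_noiseless, taz_noiseless
    ):
        # noiseless, with a collection window long enough that the
        # loading-dose transient is a negligible share of the pooled
        # amount: the ratio formula recovers Cl1 within 5%
        design = pk.CohortDesign(n_patients=6, category_probs=(1, 0, 0, 0),
                                 t1_window=(140.0, 160.0))
        cohort = pk.generate_cohort(design, pip_noiseless, taz_noiseless,
                                    seed=6)
        for s in cohort.subjects:
            p = pk.individual_params(pip_noiseless, s.covariates)
            css1, _ = pk.steady_state(p, s.daily_dose["piperacillin"] / 24)
            uri = [r for r in s.records
                   if r.drug == "piperacillin" and r.matrix == "urine"][0]
            fc = pk.FluidCollection(
                matrix="urine", volume_l=s.urine_volume,
                concentration=uri.value, duration_h=s.t1 - 0.5,
                serum_css=css1,
            )
            assert pk.calculated_clearance(fc) == pytest.approx(p.Cl1, rel=0.05)

    def test_vac_recovers_effective_peritoneal_clearance(
        self, pip_noiseless, taz_noiseless
    ):
        # with full capture the calculated VAC clearance referenced to
        # plasma equals Cl2 * Q/(Q+Cl2)
        design = pk.CohortDesign(n_patients=6, category_probs=(1, 0, 0, 0),
                                 t1_window=(140.0, 160.0),
                                 vac_capture_fraction=1.0)
        cohort = pk.generate_cohort(design, pip_noiseless, taz_noiseless,
                                    seed=6)
        for s in cohort.subjects:
            p = pk.individual_params(pip_noiseless, s.covariates)
            css1, _ = pk.steady_state(p, s.daily_dose["piperacillin"] / 24)
            vac = [r for r in s.records
                   if r.drug == "piperacillin" and r.matrix == "vac_fluid"][0]
            fc = pk.FluidCollection(
                matrix="vac_fluid", volume_l=s.vac_volume,
                concentration=vac.value, duration_h=s.t1 - 0.5,
                serum_css=css1,
            )
            expected = p.Cl2 * p.Q / (p.Q + p.Cl2)
            assert pk.calculated_clearance(fc) == pytest.approx(expected,
                                                                rel=0.05)

    def test_capture_fraction_scales_vac_concentration(self, pip_noiseless,
                                                       taz_noiseless):
        full = pk.CohortDesign(n_patients=4, vac_capture_fraction=1.0)
        part = replace(full, vac_capture_fraction=0.13)
        c_full = pk.generate_cohort(full, pip_noiseless, taz_noiseless, seed=8)
        c_part = pk.generate_cohort(part, pip_noiseless, taz_noiseless, seed=8)
        for sf, sp in zip(c_full.subjects, c_part.subjects):
            vf = [r.value for r in sf.records if r.matrix == "vac_fluid"]
            vp = [r.value for r in sp.records if r.matrix == "vac_fluid"]
            np.testing.assert_allclose(vp, np.array(vf) * 0.13, rtol=1e-12)


class TestDataset:
    def test_schema_and_row_structure(self, small_cohort):
        df = pk.cohort_to_dataset(small_cohort)
        assert list(df.columns) == DATASET_COLUMNS
        for (sid, drug), g in df.groupby(["ID", "DRUG"]):
            assert (g["EVID"] == 1).sum() == 2            # load + continuous
            assert (g["EVID"] == 0).sum() >= 3            # T0 + T1 pair + fluids

    def test_round_trip(self, tmp_path, small_cohort):
        df = pk.cohort_to_dataset(small_cohort)
        path = tmp_path / "cohort.csv"
        pk.write_dataset(df, path)
        back = pk.read_dataset(path)
        pd.testing.assert_frame_equal(back, df, check_dtype=False)

    def test_empty_cohort_gives_header_only(self, small_cohort):
        empty = pk.Cohort(design=small_cohort.design, subjects=(), seed=0)
        df = pk.cohort_to_dataset(empty)
        assert list(df.columns) == DATASET_COLUMNS and len(df) == 0

    def test_schema_violations_reported_with_rows(self, tmp_path,
                                                  small_cohort):
        df = pk.cohort_to_dataset(small_cohort)
        bad = df.copy()
        bad.loc[bad["EVID"] == 0, "DV"] = -1.0
        path = tmp_path / "bad.csv"
        pk.write_dataset(bad, path)
        with pytest.raises(ValueError, match="negative DV"):
            pk.read_dataset(path)
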