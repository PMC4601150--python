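"""Reader merging, approach summarization, reference and cohort filters."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stenoquant import (
    CohortSpec,
    KidneyRecord,
    SegmentSummary,
    filter_cohort,
    generate_cohort,
    measurability_stats,
    merge_readers,
    records_from_cohort,
    resolve_reference,
    summarize_kidney,
)
from stenoquant.summarize import positive_fraction


def summary(min_d=2.0, max_d=5.0, dred=None, ared=None):
    import math

    min_a = math.pi * (min_d / 2) ** 2
    max_a = math.pi * (max_d / 2) ** 2
    return SegmentSummary(
        min_d_mm=min_d,
        min_a_mm2=min_a,
        max_d_mm=max_d,
        max_a_mm2=max_a,
        dred_pct=(1 - min_d / max_d) * 100 if dred is None else dred,
        ared_pct=(1 - min_a / max_a) * 100 if ared is None else ared,
    )


class TestMergeReaders:
    def test_mean_of_absolute_measures(self):
        merged = merge_readers(summary(min_d=2.0), summary(min_d=3.0))
        assert merged.min_d_mm == pytest.approx(2.5)
        assert merged.dred_pct == pytest.approx((1 - 2.5 / 5.0) * 100)

    def test_single_reader_passes_through(self):
        r1 = summary(min_d=2.2)
        assert merge_readers(r1, None) == r1
        assert merge_readers(None, r1) == r1

    def test_idempotent_on_identical_readers(self):
        r = summary(min_d=1.7, max_d=4.4)
        merged = merge_readers(r, r)
        assert merged.min_d_mm == pytest.approx(r.min_d_mm)
        assert merged.dred_pct == pytest.approx(r.dred_pct)

    @given(
        a=st.floats(0.5, 4.0), b=st.floats(0.5, 4.0),
        ma=st.floats(4.5, 8.0), mb=st.floats(4.5, 8.0),
    )
    def test_commutes_with_reader_order(self, a, b, ma, mb):
        r1, r2 = summary(min_d=a, max_d=ma), summary(min_d=b, max_d=mb)
        assert merge_readers(r1, r2) == merge_readers(r2, r1)

    def test_both_absent_non_measurable(self):
        assert not merge_readers(None, None).measurable

    def test_percentage_averaging_mode(self):
        r1 = summary(min_d=2.0, dred=60.0, ared=80.0)
        r2 = summary(min_d=3.0, dred=40.0, ared=60.0)
        merged = merge_readers(r1, r2, mode="average_pct")
        assert merged.dred_pct == pytest.approx(50.0)
        assert merged.ared_pct == pytest.approx(70.0)


def make_record(segment_map, cer="negative", ctest=None, patient=0, side="L", kidney=0):
    rec = KidneyRecord(kidney_id=kidney, patient=patient, side=side, cer=cer, ctest=ctest)
    for (modality, artery, seg), s in segment_map.items():
        rec.readers.setdefault((modality, artery, seg), {})[1] = s
    return rec


class TestSummarizeKidney:
    def test_single_segment_all_approaches_agree(self):
        rec = make_record({("CTA", 1, 1): summary(min_d=2.0)})
        for approach in ("First", "Tightest", "Main"):
            res = summarize_kidney(rec, approach, "CTA")
            assert (res.artery, res.segment) == (1, 1)

    def test_accessory_artery_distinguishes_tightest_from_main(self):
        """An 80 % stenosed accessory first segment wins Tightest, while
        Main follows the large artery's 40 % stenosis."""
        rec = make_record(
            {
                ("CTA", 1, 1): summary(min_d=3.0, max_d=5.0),  # main artery, Dred 40
                ("CTA", 1, 2): summary(min_d=2.8, max_d=4.0),  # Dred 30
                ("CTA", 2, 1): summary(min_d=0.7, max_d=3.5),  # accessory, Dred 80
            }
        )
        tightest = summarize_kidney(rec, "Tightest", "CTA")
        main = summarize_kidney(rec, "Main", "CTA")
        first = summarize_kidney(rec, "First", "CTA")
        assert tightest.dred_pct == pytest.approx(80.0)
        assert tightest.artery == 2
        assert main.artery == 1 and main.dred_pct == pytest.approx(40.0)
        assert first.dred_pct == pytest.approx(80.0)  # accessory seg 1 included

    def test_first_excludes_second_segments(self):
        rec = make_record(
            {
                ("CTA", 1, 1): summary(min_d=4.0, max_d=5.0),  # Dred 20
                ("CTA", 1, 2): summary(min_d=1.0, max_d=4.0),  # Dred 75
            }
        )
        assert summarize_kidney(rec, "First", "CTA").dred_pct == pytest.approx(20.0)
        assert summarize_kidney(rec, "Tightest", "CTA").dred_pct == pytest.approx(75.0)

    def test_empty_candidate_set_returns_none(self):
        rec = make_record({("MRA", 1, 2): summary()})
        assert summarize_kidney(rec, "First", "MRA") is None

    def test_tightest_dominates_other_approaches_on_simulated_kidneys(self):
        cohort = generate_cohort(CohortSpec(n_kidneys=60, seed=21))
        for rec in records_from_cohort(cohort):
            for modality in ("CTA", "MRA"):
                t = summarize_kidney(rec, "Tightest", modality)
                for other in ("First", "Main"):
                    o = summarize_kidney(rec, other, modality)
                    if t is not None and o is not None:
                        assert t.dred_pct >= o.dred_pct - 1e-9


class TestReference:
    @pytest.mark.parametrize(
        "cer,ctest,expected",
        [
            ("positive", None, "positive"),
            ("negative", None, "negative"),
            ("intermediate", "positive", "positive"),
            ("intermediate", "negative", "negative"),
        ],
    )
    def test_resolution_table(self, cer, ctest, expected):
        assert resolve_reference(cer, ctest) == expected

    def test_intermediate_without_ctest_rejected(self):
        with pytest.raises(ValueError, match="captopril"):
            resolve_reference("intermediate", None)


class TestFilterCohort:
    def toy_records(self):
        # patient 0: bilateral negative; patient 1: positive left kidney;
        # patient 2: positive left kidney that is itself non-measurable on MRA
        def seg(modality="CTA"):
            return {("CTA", 1, 1): summary(), ("MRA", 1, 1): summary()}

        recs = [
            make_record(seg(), patient=0, side="L", kidney=0),
            make_record(seg(), patient=0, side="R", kidney=1),
            make_record(seg(), cer="positive", patient=1, side="L", kidney=2),
            make_record(seg(), patient=1, side="R", kidney=3),
            make_record({("CTA", 1, 1): summary()}, cer="positive", patient=2, side="L", kidney=4),
            make_record(seg(), patient=2, side="R", kidney=5),
        ]
        return recs

    def test_three_rules_applied_by_hand(self):
        kept, accounting = filter_cohort(self.toy_records())
        kept_ids = {r.kidney_id for r in kept}
        # kidney 4 dropped (non-measurable on MRA); kidneys 3 and 5 dropped as
        # contralateral to positives (even the dropped positive 4)
        assert kept_ids == {0, 1, 2}
        assert accounting["n_after"].iloc[-1] == 3
        assert accounting.loc[accounting.step == "measurable_both_modalities", "n_dropped"].item() == 1
        assert accounting.loc[accounting.step == "contralateral_to_positive", "n_dropped"].item() == 2

    def test_nothing_dropped_when_all_negative_measurable(self):
        recs = self.toy_records()[:2]
        kept, accounting = filter_cohort(recs)
        assert len(kept) == 2
        assert (accounting["n_dropped"] == 0).all()

    def test_idempotent(self):
        kept, _ = filter_cohort(self.toy_records())
        again, accounting = filter_cohort(kept)
        assert {r.kidney_id for r in again} == {r.kidney_id for r in kept}
        assert (accounting["n_dropped"] == 0).all()

    def test_missing_investigation_dropped(self):
        recs = self.toy_records()[:2]
        recs[0].has_cta = False
        kept, accounting = filter_cohort(recs)
        assert len(kept) == 1
        assert accounting.loc[accounting.step == "complete_investigations", "n_dropped"].item() == 1

    def test_positive_fraction_on_constructed_analysis_set(self):
        records = [
            make_record({("CTA", 1, 1): summary()}, cer=c, ctest=t, kidney=i)
            for i, (c, t) in enumerate(
                [("positive", None)] * 9
                + [("intermediate", "positive")] * 2
                + [("negative", None)] * 53
                + [("intermediate", "negative")] * 4
            )
        ]
        pct, n_pos, n = positive_fraction(records)
        assert (n_pos, n) == (11, 68)
        assert round(pct, 1) == 16.2


class TestMeasurability:
    def test_counts_and_percentages(self):
        import pandas as pd

        rows = []
        for i in range(104):  # CTA first segments: 96 of 104 by both readers
            for reader in (1, 2):
                rows.append(
                    {
                        "kidney": i, "artery": 1, "segment": 1, "modality": "CTA",
                        "reader": reader, "measurable": reader == 1 or i < 96,
                    }
                )
        stats = measurability_stats(pd.DataFrame(rows))
        row = stats.iloc[0]
        assert (row["n_measurable_any"], row["n_measurable_both"]) == (104, 96)
        assert row["pct_both"] == 92

    def test_empty_group_reported_missing(self):
        import pandas as pd

        df = pd.DataFrame(
            [{"kidney": 0, "artery": 1, "segment": 1, "modality": "CTA", "reader": 1, "measurable": False},
             {"kidney": 0, "artery": 1, "segment": 1, "modality": "CTA", "reader": 2, "measurable": False}]
        )
        stats = measurability_stats(df)
        assert stats.iloc[0]["n_measurable_any"] == 0
        assert np.isnan(stats.iloc[0]["pct_both"])
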