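import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tauquant import srm_quant as sq
from tauquant.tau_model import FLEX_TAG, Peptide


def pep(seq="TPSLPTPPTR", start=212, end=221, spec="shared"):
    return Peptide(sequence=seq, start=start, end=end, specificity=spec)


def records(sample, peptide, light, heavy, modification=""):
    out = []
    for i, a in enumerate(light):
        out.append(
            sq.TransitionRecord(
                sample_id=sample, peptide=peptide, label="light",
                transition_id=f"y{i}", area=a, modification=modification,
            )
        )
    for i, a in enumerate(heavy):
        out.append(
            sq.TransitionRecord(
                sample_id=sample, peptide=peptide, label="heavy",
                transition_id=f"y{i}", area=a,
            )
        )
    return out


class TestReadTransitionReport:
    def test_six_row_fixture(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "sample_id,peptide,label,transition_id,area\n"
            "s1,TPSLPTPPTR,light,y3,1000\n"
            "s1,TPSLPTPPTR,light,y4,2000\n"
            "s1,TPSLPTPPTR,heavy,y3,2000\n"
            "s1,TPSLPTPPTR,heavy,y4,4000\n"
            "s1,SGYSSPGSPGTPGSR,light,y3,10\n"
            "s1,SGYSSPGSPGTPGSR,heavy,y3,100\n"
        )
        result = sq.read_transition_report(path)
        assert len(result.records) == 6
        assert result.n_rejected == 0

    def test_column_map_dialect(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "Replicate,Sequence,Isotope,Fragment,Area\n"
            "s1,TPSLPTPPTR,light,y3,1000\n"
        )
        result = sq.read_transition_report(
            path,
            column_map={
                "sample_id": "Replicate", "peptide": "Sequence",
                "label": "Isotope", "transition_id": "Fragment", "area": "Area",
            },
        )
        assert len(result.records) == 1
        assert result.records[0].area == 1000.0

    def test_negative_area_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "sample_id,peptide,label,transition_id,area\n"
            "s1,TPSLPTPPTR,light,y3,-5\n"
            "s1,TPSLPTPPTR,heavy,y3,100\n"
        )
        result = sq.read_transition_report(path)
        assert len(result.records) == 1
        assert result.n_rejected == 1

    def test_missing_column_is_hard_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample_id,peptide,label,area\ns1,X,light,5\n")
        with pytest.raises(ValueError, match="transition_id"):
            sq.read_transition_report(path)


class TestPeptideLhRatio:
    def test_proportional_transitions(self):
        q = sq.peptide_lh_ratio(
            records("s1", "TPSLPTPPTR", [1000, 2000, 3000], [2000, 4000, 6000]), pep()
        )
        assert q.lh_ratio == pytest.approx(0.5)
        assert (q.n_transitions_light, q.n_transitions_heavy) == (3, 3)

    def test_identical_areas_give_unity(self):
        q = sq.peptide_lh_ratio(
            records("s1", "TPSLPTPPTR", [10, 20, 30], [10, 20, 30]), pep()
        )
        assert q.lh_ratio == pytest.approx(1.0)

    def test_zero_heavy_flagged_undefined(self):
        q = sq.peptide_lh_ratio(records("s1", "TPSLPTPPTR", [100, 200], [0, 0]), pep())
        assert math.isnan(q.lh_ratio)
        assert "undefined_ratio" in q.flags
        assert not q.defined

    def test_no_light_is_zero_with_flag(self):
        q = sq.peptide_lh_ratio(records("s1", "TPSLPTPPTR", [], [50, 60, 70]), pep())
        assert q.lh_ratio == 0.0
        assert "no_light" in q.flags

    def test_transition_count_warning_flag(self):
        q = sq.peptide_lh_ratio(records("s1", "TPSLPTPPTR", [1] * 7, [1] * 7), pep())
        assert "transition_count_out_of_bounds" in q.flags

    def test_mixed_samples_rejected(self):
        recs = records("s1", "TPSLPTPPTR", [1], [1]) + records(
            "s2", "TPSLPTPPTR", [1], [1]
        )
        with pytest.raises(ValueError):
            sq.peptide_lh_ratio(recs, pep())


class TestStandardConcentration:
    def flex_quant(self, lh):
        return sq.PeptideQuant(
            sample_id="s1",
            peptide=Peptide(sequence=FLEX_TAG, start=0, end=0, specificity="flex_tag"),
            lh_ratio=lh, n_transitions_light=3, n_transitions_heavy=3,
        )

    def test_unity_ratio(self):
        assert sq.standard_concentration_from_flex(self.flex_quant(1.0), 15.0) == 15.0

    def test_ratio_three(self):
        assert sq.standard_concentration_from_flex(self.flex_quant(3.0), 15.0) == pytest.approx(5.0)

    def test_zero_ratio_errors(self):
        with pytest.raises(ValueError):
            sq.standard_concentration_from_flex(self.flex_quant(0.0), 15.0)

    def test_non_flex_peptide_rejected(self):
        q = sq.PeptideQuant(
            sample_id="s1", peptide=pep(), lh_ratio=1.0,
            n_transitions_light=3, n_transitions_heavy=3,
        )
        with pytest.raises(ValueError):
            sq.standard_concentration_from_flex(q, 15.0)


def quant(seq, lh, spec="shared", start=1, end=10):
    return sq.PeptideQuant(
        sample_id="s1", peptide=pep(seq, start, end, spec), lh_ratio=lh,
        n_transitions_light=3, n_transitions_heavy=3,
    )


class TestAbsoluteAbundance:
    def meta(self, **kw):
        base = dict(sample_id="s1", model="P301S", tissue_mass=1.0,
                    processed_volume=10.0)
        base.update(kw)
        return sq.SampleMeta(**base)

    def test_arithmetic(self):
        quants = [quant("AAAAAK", 2.0), quant("CCCCCK", 1.0)]
        res = sq.absolute_tau_abundance(self.meta(), quants, standard_conc=10.0)
        assert res.fmol_per_mg == pytest.approx(200.0)
        assert res.reference_peptide == "AAAAAK"

    def test_all_zero_ratios(self):
        res = sq.absolute_tau_abundance(
            self.meta(), [quant("AAAAAK", 0.0)], standard_conc=10.0
        )
        assert res.fmol_per_mg == 0.0

    def test_reference_class_respected(self):
        quants = [quant("AAAAAK", 9.0, spec="shared"),
                  quant("CCCCCK", 2.0, spec="human_specific")]
        human = self.meta(model="human_P301L")
        res = sq.absolute_tau_abundance(human, quants, standard_conc=10.0)
        assert res.reference_class == "human_specific"
        assert res.reference_peptide == "CCCCCK"

    def test_missing_class_errors(self):
        with pytest.raises(ValueError, match="human_specific"):
            sq.absolute_tau_abundance(
                self.meta(model="human_control"),
                [quant("AAAAAK", 1.0, spec="shared")],
                standard_conc=10.0,
            )


class TestUnmodifiedFraction:
    def test_reference_is_exactly_one(self):
        fr, refs, _ = sq.unmodified_fraction(
            [quant("AAAAAK", 0.8), quant("CCCCCK", 0.2)]
        )
        assert fr["AAAAAK"] == 1.0
        assert fr["CCCCCK"] == pytest.approx(0.25)
        assert refs["shared"] == "AAAAAK"

    def test_clipping_logged(self):
        # noise inverted the max within another class
        fr, _, events = sq.unmodified_fraction(
            [
                quant("AAAAAK", 0.8),
                quant("CCCCCK", 0.2),
            ]
        )
        assert not [e for e in events if e.startswith("clipped")]
        fr2, _, events2 = sq.unmodified_fraction(
            [
                quant("AAAAAK", 0.8, spec="shared"),
                quant("DDDDDK", 0.9, spec="human_specific"),
                quant("EEEEEK", 0.8, spec="human_specific"),
            ]
        )
        assert all(v <= 1.0 for v in fr2.values())

    def test_conservation(self):
        fr, _, _ = sq.unmodified_fraction(
            [quant("AAAAAK", 0.7), quant("CCCCCK", 0.35), quant("DDDDDK", 0.14)]
        )
        for v in fr.values():
            extent = 1.0 - v
            assert 0.0 <= v <= 1.0
            assert v + extent == pytest.approx(1.0)

    def test_zero_class_max_flagged(self):
        fr, refs, events = sq.unmodified_fraction(
            [quant("AAAAAK", 0.0), quant("CCCCCK", 0.0)]
        )
        assert all(math.isnan(v) for v in fr.values())
        assert "class_max_undefined:shared" in events

    def test_undefined_ratio_propagates_as_nan(self):
        q_nan = sq.PeptideQuant(
            sample_id="s1", peptide=pep("CCCCCK", 1, 6, "shared"),
            lh_ratio=float("nan"), n_transitions_light=3, n_transitions_heavy=3,
            flags=("undefined_ratio",),
        )
        fr, _, _ = sq.unmodified_fraction([quant("AAAAAK", 0.8), q_nan])
        assert math.isnan(fr["CCCCCK"])
        assert fr["AAAAAK"] == 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(min_value=1e-6, max_value=1e6),
        st.lists(
            st.floats(min_value=0.01, max_value=10.0), min_size=2, max_size=8
        ),
    )
    def test_scale_invariance_of_raw_areas(self, k, lights):
        # multiplying every area in a sample by k > 0 leaves fractions unchanged
        heavy = [100.0, 200.0, 300.0]

        def fractions(scale):
            quants = []
            for i, light in enumerate(lights):
                seq = "A" * (i + 6) + "K"
                recs = records(
                    "s1", seq,
                    [scale * light * h for h in heavy],
                    [scale * h for h in heavy],
                )
                quants.append(sq.peptide_lh_ratio(recs, pep(seq, 1, i + 7, "shared")))
            fr, _, _ = sq.unmodified_fraction(quants)
            return fr

        fr1, fr2 = fractions(1.0), fractions(k)
        for seq in fr1:
            assert fr2[seq] == pytest.approx(fr1[seq], rel=1e-9)


def test_lh_ratio_scale_invariance():
    # multiplying every raw area by k > 0 leaves the ratio unchanged
    rng = np.random.default_rng(5)
    light = list(rng.uniform(10, 1000, size=4))
    heavy = list(rng.uniform(10, 1000, size=4))
    q1 = sq.peptide_lh_ratio(records("s1", "TPSLPTPPTR", light, heavy), pep())
    for k in (1e-3, 7.3, 1e4):
        q2 = sq.peptide_lh_ratio(
            records("s1", "TPSLPTPPTR", [k * a for a in light], [k * a for a in heavy]),
            pep(),
        )
        assert q2.lh_ratio == pytest.approx(q1.lh_ratio, rel=1e-12)


class TestPhosphopeptide:
    def test_arithmetic(self):
        light = records("s1", "TPSLPTPPTR", [500], [], modification="phospho")
        heavy = records("s1", "TPSLPTPPTR", [], [1000])
        assert sq.phosphopeptide_relative_abundance(light, heavy) == pytest.approx(0.5)

    def test_zero_signal(self):
        light = records("s1", "TPSLPTPPTR", [0, 0], [], modification="phospho")
        heavy = records("s1", "TPSLPTPPTR", [], [1000])
        assert sq.phosphopeptide_relative_abundance(light, heavy) == 0.0

    def test_missing_counterpart_errors(self):
        light = records("s1", "TPSLPTPPTR", [500], [], modification="phospho")
        with pytest.raises(ValueError):
            sq.phosphopeptide_relative_abundance(light, [])


def test_read_sample_meta_roundtrip(tmp_path):
    path = tmp_path / "samples.csv"
    path.write_text(
        "sample_id,model,region,age,replicate,tissue_mass,standard_amount,"
        "flex_light_spike,processed_volume,fraction\n"
        "s1,P301S,cortex,2.0,1,10.0,500.0,15.0,50.0,insoluble\n"
    )
    metas = sq.read_sample_meta(path)
    assert metas["s1"].model == "P301S"
    assert metas["s1"].reference_class == "shared"
    assert metas["s1"].age == 2.0
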