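"""Fragment prediction, O-acetyl localization, isobar intensity splitting."""

import numpy as np
import pytest

import oracle
from ganglio.annotate import Annotation, Candidate, Spectrum, match_peaks
from ganglio.chem import (
    AdductState,
    CeramideSpec,
    IonSpecies,
    ValidationError,
    composition_of,
)
from ganglio.msms import (
    localize_acetyl,
    predict_fragments,
    split_isobaric_intensity,
)

PROTON = 1.00728
WATER = 18.01056


def make_ion(name, acyl="16:0", n_dehyd=0, acetyl_pos=None):
    species = composition_of(name)
    adduct = AdductState(
        n_dehydrations=n_dehyd,
        n_acetyl=1 if acetyl_pos else 0,
        acetyl_position=acetyl_pos,
    )
    return IonSpecies.create(species, CeramideSpec.parse(acyl), adduct)


def frag_by(fragments, kind, node):
    (hit,) = [f for f in fragments if f.kind == kind
              and f.cleavage_node == node and not f.satellite]
    return hit


class TestPredictFragments:
    def test_terminal_neu5ac_b1_of_gd3(self):
        frags = predict_fragments(make_ion("GD3"))
        b1 = frag_by(frags, "B", "neu2")
        assert b1.mz == pytest.approx(290.088, abs=1e-3)
        assert b1.mz == pytest.approx(
            oracle.glycan_b_ion({"Neu5Ac": 1}), abs=1e-4)

    def test_ceramide_y0(self):
        frags = predict_fragments(make_ion("GD3"))
        y0 = frag_by(frags, "Y", "glc")
        assert y0.label == "Y0"
        assert y0.mz == pytest.approx(536.505, abs=1e-3)
        assert y0.mz == pytest.approx(oracle.ceramide_y0(16), abs=1e-4)

    def test_acetylated_b1_of_oacgd3(self):
        frags = predict_fragments(make_ion("GD3", acetyl_pos="terminal"))
        b1 = frag_by(frags, "B", "neu2")
        assert b1.contains_acetyl
        assert b1.mz == pytest.approx(290.088 + 42.0106, abs=1e-3)

    def test_c_equals_b_plus_water_and_y_equals_z_plus_water(self):
        frags = predict_fragments(make_ion("GT2", acyl="24:0"))
        for node in {f.cleavage_node for f in frags}:
            assert frag_by(frags, "C", node).mz - frag_by(
                frags, "B", node).mz == pytest.approx(WATER, abs=1e-9)
            assert frag_by(frags, "Y", node).mz - frag_by(
                frags, "Z", node).mz == pytest.approx(WATER, abs=1e-9)

    @pytest.mark.parametrize("name, acyl, pos", [
        ("GM1", "16:0", None),
        ("GD3", "24:0", "inner"),
        ("GD2", "16:0", "terminal"),
        ("GT3", "24:0", "middle"),
        ("LacNAcGM1", "16:0", None),
    ])
    def test_complementarity_b_plus_y(self, name, acyl, pos):
        """mz(B)+mz(Y) = mz([M-H]-) - proton for every cleavage edge."""
        ion = make_ion(name, acyl=acyl, acetyl_pos=pos)
        frags = predict_fragments(ion)
        for node in {f.cleavage_node for f in frags}:
            b, y = frag_by(frags, "B", node), frag_by(frags, "Y", node)
            c, z = frag_by(frags, "C", node), frag_by(frags, "Z", node)
            assert b.mz + y.mz == pytest.approx(ion.mz - PROTON, abs=1e-4)
            assert c.mz + z.mz == pytest.approx(ion.mz - PROTON, abs=1e-4)

    def test_acetyl_on_exactly_one_side_of_each_cleavage(self):
        frags = predict_fragments(make_ion("GT3", acetyl_pos="middle"))
        for node in {f.cleavage_node for f in frags}:
            b, y = frag_by(frags, "B", node), frag_by(frags, "Y", node)
            assert b.contains_acetyl != y.contains_acetyl

    def test_lactone_opened_before_prediction(self):
        plain = predict_fragments(make_ion("GD3"))
        lactone = predict_fragments(make_ion("GD3", n_dehyd=1))
        assert [f.mz for f in plain] == [f.mz for f in lactone]

    def test_water_loss_satellites_for_oligosialyl_fragments(self):
        frags = predict_fragments(make_ion("GD3"), include_water_loss=True)
        sats = [f for f in frags if f.satellite]
        assert sats, "disialyl B2/C2 side should produce -H2O satellites"
        for sat in sats:
            assert sat.label.endswith("-H2O")


def spectrum_from(frags, intensity=100.0):
    mz = np.array([f.mz for f in frags])
    return Spectrum("ms2", mz, np.full(mz.size, float(intensity)))


def annotation_for(ion):
    return Annotation(ion.mz, 100.0, [Candidate(ion, 0.0)])


class TestLocalizeAcetyl:
    def test_terminal_call_from_acetylated_b1(self):
        ion = make_ion("GD3", acetyl_pos="terminal")
        sp = Spectrum("ms2", [290.088 + 42.011], [50.0])
        res = localize_acetyl(annotation_for(ion), sp)
        assert res.call == "terminal"
        assert res.margin == float("inf")

    def test_inner_call_from_plain_b1_plus_acetylated_y(self):
        ion = make_ion("GD3", acetyl_pos="inner")
        frags = predict_fragments(ion)
        keep = [f for f in frags if f.cleavage_node == "neu2"]
        res = localize_acetyl(annotation_for(ion), spectrum_from(keep))
        assert res.call == "inner"

    @pytest.mark.parametrize("name", ["GD3", "GD2", "GT3", "GT2"])
    def test_full_coverage_recovers_every_position(self, name):
        for pos in composition_of(name).neu5ac_positions:
            ion = make_ion(name, acetyl_pos=pos)
            sp = spectrum_from(predict_fragments(ion))
            res = localize_acetyl(annotation_for(ion), sp)
            assert res.call == pos, (name, pos, res.scores)
            assert res.margin >= 2.0

    def test_no_overlap_is_ambiguous(self):
        ion = make_ion("GD3", acetyl_pos="terminal")
        sp = Spectrum("ms2", [800.0], [10.0])  # matches nothing diagnostic
        res = localize_acetyl(annotation_for(ion), sp)
        assert res.call == "ambiguous"
        assert "matched" in res.status

    def test_requires_acetylated_candidate_and_fragments(self):
        plain = make_ion("GD3")
        sp = Spectrum("ms2", [290.088], [10.0])
        with pytest.raises(ValidationError):
            localize_acetyl(annotation_for(plain), sp)
        oac = make_ion("GD3", acetyl_pos="inner")
        with pytest.raises(ValidationError):
            localize_acetyl(annotation_for(oac),
                            Spectrum("ms2", [], []))


class TestSplitIsobaric:
    def _isobar_1670(self, default_library):
        sp = Spectrum("s", [1670.0], [80.0])
        (ann,) = match_peaks(sp, default_library, tolerance=0.3)
        assert ann.status == "isobaric"
        return ann

    def test_gm1_only_fragments_give_full_share(self, default_library):
        ann = self._isobar_1670(default_library)
        oacgm1 = make_ion("GM1", acyl="24:0", acetyl_pos="inner")
        shares, fallback = split_isobaric_intensity(
            ann, spectrum_from(predict_fragments(oacgm1)))
        assert not fallback
        assert shares["OAcGM1 d18:1/24:0 [M-H]-"] == pytest.approx(1.0)
        assert shares["OAcGD2 d18:1/16:0 [M-H2O-H]-"] == pytest.approx(0.0)

    def test_shares_proportional_to_unique_intensity(self, default_library):
        ann = self._isobar_1670(default_library)
        gd2 = make_ion("GD2", acyl="16:0", acetyl_pos="inner")
        gm1 = make_ion("GM1", acyl="24:0", acetyl_pos="inner")
        mixed = Spectrum(
            "ms2",
            np.concatenate([spectrum_from(predict_fragments(gd2), 30).mz,
                            spectrum_from(predict_fragments(gm1), 10).mz]),
            np.concatenate([np.full(len(predict_fragments(gd2)), 30.0),
                            np.full(len(predict_fragments(gm1)), 10.0)]),
        )
        shares, fallback = split_isobaric_intensity(ann, mixed)
        assert not fallback
        assert sum(shares.values()) == pytest.approx(1.0)
        assert shares["OAcGD2 d18:1/16:0 [M-H2O-H]-"] > \
            shares["OAcGM1 d18:1/24:0 [M-H]-"]

    def test_no_unique_match_falls_back_to_equal_split(self, default_library):
        ann = self._isobar_1670(default_library)
        sp = Spectrum("ms2", [700.0], [5.0])
        shares, fallback = split_isobaric_intensity(ann, sp)
        assert fallback
        n = len(ann.candidates)
        assert all(v == pytest.approx(1.0 / n) for v in shares.values())

    def test_permutation_equivariance(self, default_library):
        ann = self._isobar_1670(default_library)
        gm1 = make_ion("GM1", acyl="24:0", acetyl_pos="inner")
        sp = spectrum_from(predict_fragments(gm1))
        shares, _ = split_isobaric_intensity(ann, sp)
        flipped = Annotation(ann.peak_mz, ann.intensity,
                             list(reversed(ann.candidates)))
        shares_flipped, _ = split_isobaric_intensity(flipped, sp)
        assert shares == shares_flipped

    def test_requires_isobaric_precursor(self, default_library):
        sp = Spectrum("s", [1151.7], [10.0])
        (ann,) = match_peaks(sp, default_library, tolerance=0.3)
        with pytest.raises(ValidationError):
            split_isobaric_intensity(ann, Spectrum("ms2", [290.0], [1.0]))

    def test_known_mixture_recovered_with_noise(self, default_library):
        """A 60/40 two-species mixture is recovered within +-0.1 under 5%
        fragment-intensity noise."""
        ann = self._isobar_1670(default_library)
        gd2 = make_ion("GD2", acyl="16:0", acetyl_pos="inner")
        gm1 = make_ion("GM1", acyl="24:0", acetyl_pos="inner")
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(20):
            fr_a = predict_fragments(gd2)
            fr_b = predict_fragments(gm1)
            mz = np.array([f.mz for f in fr_a] + [f.mz for f in fr_b])
            inten = np.concatenate([
                np.full(len(fr_a), 60.0), np.full(len(fr_b), 40.0)
            ]) * (1 + rng.normal(0, 0.05, len(fr_a) + len(fr_b)))
            shares, _ = split_isobaric_intensity(
                ann, Spectrum("ms2", mz, np.clip(inten, 0, None)))
            errs.append(abs(shares["OAcGD2 d18:1/16:0 [M-H2O-H]-"] - 0.6))
        assert max(errs) < 0.1
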