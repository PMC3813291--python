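"""ΔG→pKi conversion, LE/BEI indices, normalization and ΔE series."""

import math
import random

import pytest
from scipy import stats

from fragrank import (
    BindingRecord,
    DescriptorSet,
    ThermoConstants,
    binding_efficiency_index,
    delta_e_series,
    delta_g_to_pki,
    ligand_efficiency,
    normalize_series,
    score_fragments,
)
from fragrank.efficiency import DegenerateRangeError


class TestThermo:
    def test_conversion_factor_near_1364(self):
        assert ThermoConstants().c == pytest.approx(1.364, abs=0.001)

    def test_pki_definition(self):
        assert delta_g_to_pki(0.0) == 0.0
        c = ThermoConstants().c
        assert delta_g_to_pki(-c) == pytest.approx(1.0)
        assert delta_g_to_pki(-10.55) == pytest.approx(7.73, abs=0.005)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            ThermoConstants(T=0.0)


class TestIndices:
    @pytest.mark.parametrize(
        "delta_g, hac, le",
        [(-10.55, 28, 0.377), (-10.96, 28, 0.391), (-1.0, 1, 1.0)],
    )
    def test_ligand_efficiency(self, delta_g, hac, le):
        assert ligand_efficiency(delta_g, hac) == pytest.approx(le, abs=5e-4)

    @pytest.mark.parametrize(
        "delta_g, mw, bei",
        [(-10.55, 374.2, 20.67), (-11.84, 374.2, 23.20)],
    )
    def test_binding_efficiency_index(self, delta_g, mw, bei):
        pki = delta_g_to_pki(delta_g)
        assert binding_efficiency_index(pki, mw) == pytest.approx(bei, abs=5e-3)

    def test_plain_bei(self):
        assert binding_efficiency_index(5.0, 500.0) == pytest.approx(10.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ligand_efficiency(-1.0, 0)
        with pytest.raises(ValueError):
            binding_efficiency_index(5.0, 0.0)

    def test_le_decreasing_in_hac_bei_in_mw(self):
        les = [ligand_efficiency(-10.0, h) for h in range(5, 40)]
        assert all(a > b for a, b in zip(les, les[1:]))
        beis = [binding_efficiency_index(7.0, mw) for mw in range(100, 600, 50)]
        assert all(a > b for a, b in zip(beis, beis[1:]))


class TestScoreFragments:
    def test_le_times_hac_recovers_energy(self):
        recs = [BindingRecord(f"m{i}", -2.0 - i) for i in range(5)]
        descs = {f"m{i}": DescriptorSet(10 + i, 140.0 + 10 * i, 0, 0, 0)
                 for i in range(5)}
        scores = score_fragments(recs, descs)
        for r in recs:
            assert scores[r.id].le * descs[r.id].hac == pytest.approx(-r.delta_g)

    def test_spreadsheet_oracle(self):
        """Hand-recomputed pKi/LE/BEI for 10 rows (independent arithmetic)."""
        rng = random.Random(4)
        recs, descs = [], {}
        for i in range(10):
            recs.append(BindingRecord(f"f{i}", -rng.uniform(3, 12)))
            descs[f"f{i}"] = DescriptorSet(
                rng.randint(8, 35), rng.uniform(100, 500), 0, 0, 0
            )
        c = math.log(10) * 0.001987 * 298.15
        scores = score_fragments(recs, descs)
        for r in recs:
            pki = -r.delta_g / c
            assert scores[r.id].pki == pytest.approx(pki)
            assert scores[r.id].le == pytest.approx(-r.delta_g / descs[r.id].hac)
            assert scores[r.id].bei == pytest.approx(pki / (descs[r.id].mw / 1000))

    def test_positive_scores_for_favourable_binding(self):
        scores = score_fragments(
            [BindingRecord("a", -5.0)], {"a": DescriptorSet(10, 150.0, 0, 0, 0)}
        )["a"]
        assert scores.pki > 0 and scores.le > 0 and scores.bei > 0

    def test_missing_descriptor_lists_ids(self):
        with pytest.raises(KeyError, match="orphan"):
            score_fragments([BindingRecord("orphan", -5.0)], {})

    def test_empty_input(self):
        assert score_fragments([], {}) == {}

    def test_rank_agreement_cno_only_breaks_with_sulfur(self):
        """LE and BEI rank near-identically when per-atom mass is uniform
        (C/N/O), and disagree once heavy sulfur-rich fragments are mixed in."""
        rng = random.Random(8)
        recs, descs = [], {}
        for i in range(30):
            hac = rng.randint(10, 30)
            recs.append(BindingRecord(f"c{i}", -rng.uniform(4, 11)))
            descs[f"c{i}"] = DescriptorSet(hac, hac * rng.uniform(13.0, 13.8),
                                           0, 0, 0)
        scores = score_fragments(recs, descs)
        le = [scores[r.id].le for r in recs]
        bei = [scores[r.id].bei for r in recs]
        tau_cno = stats.kendalltau(le, bei).statistic
        assert tau_cno >= 0.8
        for i in range(10):  # sulfur-rich: much heavier per heavy atom
            hac = rng.randint(10, 30)
            recs.append(BindingRecord(f"s{i}", -rng.uniform(4, 11)))
            descs[f"s{i}"] = DescriptorSet(hac, hac * rng.uniform(17.0, 19.0),
                                           0, 0, 0)
        scores = score_fragments(recs, descs)
        le = [scores[r.id].le for r in recs]
        bei = [scores[r.id].bei for r in recs]
        tau_mixed = stats.kendalltau(le, bei).statistic
        assert tau_mixed < tau_cno


class TestNormalization:
    def test_minmax(self):
        assert normalize_series([1.0, 2.0, 3.0]) == [0.0, 0.5, 1.0]

    def test_binding_energy_on_magnitude(self):
        out = normalize_series([-10.55, -10.96, -11.84], magnitude=True)
        assert out[0] == 0.0
        assert out[1] == pytest.approx(0.318, abs=1e-3)
        assert out[2] == 1.0

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateRangeError):
            normalize_series([5.0])
        with pytest.raises(DegenerateRangeError):
            normalize_series([2.0, 2.0, 2.0])


class TestDeltaE:
    def test_identical_series_all_zero(self):
        s = [0.1, 0.5, 0.9]
        assert delta_e_series(s, s) == [0.0, 0.0, 0.0]

    def test_hand_computed(self):
        assert delta_e_series([1.0, 0.5, 0.0], [0.0, 0.5, 1.0]) == [1.0, 0.0, -1.0]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            delta_e_series([1.0], [1.0, 2.0])

    def test_sulfur_rich_fragments_show_largest_gap(self):
        """With equal energies, the mass-weighted index penalizes the
        heavy-atom-mass outlier most: the S-rich fragment has the largest
        |ΔE| in a mixed set."""
        ids = ["cno1", "cno2", "cno3", "s2frag"]
        recs = [
            BindingRecord("cno1", -6.0),
            BindingRecord("cno2", -8.0),
            BindingRecord("cno3", -10.0),
            BindingRecord("s2frag", -8.0),  # mid-range energy, heavy mass
        ]
        descs = {
            "cno1": DescriptorSet(20, 270.0, 0, 0, 0),
            "cno2": DescriptorSet(20, 270.0, 0, 0, 0),
            "cno3": DescriptorSet(20, 270.0, 0, 0, 0),
            "s2frag": DescriptorSet(20, 364.0, 0, 0, 0),  # two sulfurs
        }
        scores = score_fragments(recs, descs)
        le_n = normalize_series([scores[i].le for i in ids])
        bei_n = normalize_series([scores[i].bei for i in ids])
        de = delta_e_series(bei_n, le_n)
        assert max(range(4), key=lambda k: abs(de[k])) == 3
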