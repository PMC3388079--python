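"""3C quantification: normalization algebra, efficiency cancellation,
linearity and digestion controls."""

import numpy as np
import pandas as pd
import pytest

from fcs3c.errors import DomainError, SchemaError
from fcs3c.synthetic import gen_band_table
from fcs3c.threec import (
    condition_ratio,
    contact_frequency,
    digestion_efficiency,
    linearity_check,
    validate_band_table,
)


def make_table(rows):
    return pd.DataFrame(
        rows,
        columns=["condition", "primer_pair", "template_mass_ng", "replicate",
                 "intensity"],
    )


@pytest.fixture
def paper_like_table():
    """Intensities implying contact frequencies 1.9 (+T7) and 2.7 (-T7)."""
    rows = []
    for rep in range(1, 4):
        rows += [
            ("plus_T7", "a:c", 30.0, rep, 1.9),
            ("plus_T7", "a:b", 30.0, rep, 1.0),
            ("minus_T7", "a:c", 30.0, rep, 2.7),
            ("minus_T7", "a:b", 30.0, rep, 1.0),
        ]
    return make_table(rows)


class TestContactFrequency:
    def test_identity_when_intensities_equal(self):
        rows = [("plus_T7", p, 30.0, r, 5.0) for p in ("a:c", "a:b")
                for r in (1, 2, 3)]
        cf = contact_frequency(make_table(rows), "plus_T7", "a:c", "a:b")
        assert cf.value == pytest.approx(1.0)
        assert cf.sd == pytest.approx(0.0)

    def test_paper_plus_t7_value(self, paper_like_table):
        cf = contact_frequency(paper_like_table, "plus_T7", "a:c", "a:b")
        assert cf.value == pytest.approx(1.9, rel=1e-12)

    def test_global_scaling_of_condition_cancels(self, paper_like_table):
        scaled = paper_like_table.copy()
        mask = scaled["condition"] == "plus_T7"
        scaled.loc[mask, "intensity"] *= 5.0
        cf0 = contact_frequency(paper_like_table, "plus_T7", "a:c", "a:b")
        cf1 = contact_frequency(scaled, "plus_T7", "a:c", "a:b")
        assert cf1.value == pytest.approx(cf0.value, rel=1e-12)

    def test_zero_control_is_division_error(self):
        rows = [("plus_T7", "a:c", 30.0, 1, 2.0), ("plus_T7", "a:b", 30.0, 1, 0.0)]
        with pytest.raises(ZeroDivisionError, match="a:b"):
            contact_frequency(make_table(rows), "plus_T7", "a:c", "a:b")

    def test_missing_pair_is_schema_error(self, paper_like_table):
        with pytest.raises(SchemaError):
            contact_frequency(paper_like_table, "plus_T7", "a:c", "d:e")


class TestConditionRatio:
    def test_paper_ratio_near_one_by_its_errors(self, paper_like_table):
        ratio = condition_ratio(paper_like_table, "a:c", "a:b")
        assert ratio.value == pytest.approx(1.9 / 2.7, rel=1e-12)

    def test_swapping_conditions_gives_reciprocal(self, paper_like_table):
        fwd = condition_ratio(paper_like_table, "a:c", "a:b")
        rev = condition_ratio(
            paper_like_table, "a:c", "a:b",
            numerator_condition="minus_T7", denominator_condition="plus_T7",
        )
        assert rev.value == pytest.approx(1.0 / fwd.value, rel=1e-12)

    def test_per_primer_efficiency_cancels(self, paper_like_table):
        base = condition_ratio(paper_like_table, "a:c", "a:b").value
        bumped = paper_like_table.copy()
        bumped.loc[bumped["primer_pair"] == "a:c", "intensity"] *= 7.0
        assert condition_ratio(bumped, "a:c", "a:b").value == pytest.approx(
            base, rel=1e-12
        )

    def test_metamorphic_random_multipliers(self, rng):
        """Arbitrary per-primer efficiencies (applied across conditions) and
        per-condition scales never change the condition ratio."""
        table = gen_band_table(true_ratio=0.7, noise_cv=0.02, seed=11)
        base = condition_ratio(table, "a:c", "a:b").value
        for _ in range(20):
            t = table.copy()
            for pair in ("a:c", "a:b"):
                t.loc[t["primer_pair"] == pair, "intensity"] *= 10 ** rng.uniform(-2, 2)
            for cond in ("plus_T7", "minus_T7"):
                t.loc[t["condition"] == cond, "intensity"] *= 10 ** rng.uniform(-2, 2)
            assert condition_ratio(t, "a:c", "a:b").value == pytest.approx(
                base, rel=1e-12
            )

    def test_recovers_known_ratio_from_noisy_synthetic_table(self):
        table = gen_band_table(
            true_ratio=0.7,
            primer_efficiencies={"a:c": 12.0, "a:b": 0.3},
            condition_scales={"plus_T7": 2.0, "minus_T7": 0.5},
            noise_cv=0.05,
            seed=7,
        )
        ratio = condition_ratio(table, "a:c", "a:b")
        # within the noise-propagated interval (3 sd)
        assert abs(ratio.value - 0.7) < 3 * ratio.sd + 1e-12


class TestLinearity:
    def test_exact_proportionality_passes(self):
        rows = [("plus_T7", "a:c", m, 1, 3.0 * m) for m in (15.0, 30.0, 60.0)]
        slope, intercept, r2, ok = linearity_check(make_table(rows), "a:c")
        assert r2 == pytest.approx(1.0)
        assert ok

    def test_saturated_intensities_fail(self):
        rows = [("plus_T7", "a:c", m, 1, 8.0) for m in (15.0, 30.0, 60.0)]
        *_, ok = linearity_check(make_table(rows), "a:c")
        assert not ok

    def test_noisy_proportional_data_passes(self, rng):
        masses = np.repeat([15.0, 30.0, 60.0], 3)
        rows = [
            ("plus_T7", "a:c", m, i % 3 + 1, 2.0 * m * (1 + rng.normal(0, 0.05)))
            for i, m in enumerate(masses)
        ]
        *_, r2, ok = linearity_check(make_table(rows), "a:c")
        assert ok and r2 >= 0.95

    def test_insufficient_masses_rejected(self):
        rows = [("plus_T7", "a:c", m, 1, m) for m in (15.0, 30.0)]
        with pytest.raises(DomainError):
            linearity_check(make_table(rows), "a:c")


class TestDigestionEfficiency:
    @pytest.mark.parametrize(
        "digested,undigested,expected",
        [(0.8, 0.8, 0.0), (0.0, 0.8, 1.0), (0.2, 0.8, 0.75)],
    )
    def test_values(self, digested, undigested, expected):
        assert digestion_efficiency(digested, undigested) == pytest.approx(expected)

    def test_out_of_range_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert digestion_efficiency(1.2, 0.8) == 0.0

    def test_nonpositive_undigested_rejected(self):
        with pytest.raises(DomainError):
            digestion_efficiency(0.2, 0.0)


class TestSchema:
    def test_duplicate_rows_rejected(self):
        rows = [("plus_T7", "a:c", 30.0, 1, 1.0)] * 2
        with pytest.raises(SchemaError, match="duplicate"):
            validate_band_table(make_table(rows))

    def test_negative_intensity_rejected(self):
        rows = [("plus_T7", "a:c", 30.0, 1, -1.0)]
        with pytest.raises(SchemaError):
            validate_band_table(make_table(rows))

    def test_missing_column_rejected(self):
        df = pd.DataFrame({"condition": ["x"], "intensity": [1.0]})
        with pytest.raises(SchemaError, match="missing"):
            validate_band_table(df)
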