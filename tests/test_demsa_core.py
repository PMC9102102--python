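import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demsa import (
    SEGMENTS,
    NicheRange,
    ValidationError,
    between_resemblance,
    common_with_control,
    compute_niche_range,
    decompose,
    dominance_codominance,
    functional_alteration,
    guild_association,
    guild_segment_table,
    segment_index,
    segment_indices,
    within_resemblance,
)
from demsa.ecoplate_io import DesignTable

from conftest import CODES, make_profile
from _printed_tables import GUILD_MEANS, PRINTED_GUILD_PAIRS, TIED_CELLS


def constant_niche(lower, center, upper):
    """A niche range with the same limits on all 31 substrates."""
    idx = pd.Index(CODES)
    return NicheRange(
        lower=pd.Series(lower, index=idx),
        center=pd.Series(center, index=idx),
        upper=pd.Series(upper, index=idx),
        n_control=3,
    )


def segment_oracle(x, lo, mid, up):
    """Brute-force decomposition: integrate an indicator over the interval
    between the niche center and the observation, split at the outer limit.
    """
    grid = np.linspace(min(x, mid), max(x, mid), 200001)
    dv = grid[1] - grid[0] if len(grid) > 1 and x != mid else 0.0
    if x >= mid:
        inten = np.sum((grid >= mid) & (grid <= up)) * dv
        expan = np.sum(grid > up) * dv
        return inten, 0.0, expan, 0.0
    narro = np.sum((grid >= lo) & (grid <= mid)) * dv
    contr = np.sum(grid < lo) * dv
    return 0.0, narro, 0.0, contr


# ---------------------------------------------------------------------------
# Niche range
# ---------------------------------------------------------------------------

class TestNicheRange:
    def test_min_mean_max(self):
        profiles = [make_profile([v] * 31, f"c{i}", "V1", i + 1)
                    for i, v in enumerate((0.2, 0.5, 0.8))]
        niche = compute_niche_range(profiles)
        assert niche.lower.iloc[0] == pytest.approx(0.2)
        assert niche.center.iloc[0] == pytest.approx(0.5)
        assert niche.upper.iloc[0] == pytest.approx(0.8)

    def test_identical_replicates_collapse(self):
        profiles = [make_profile([1.1] * 31, f"c{i}", "V1", i + 1) for i in range(4)]
        niche = compute_niche_range(profiles)
        assert (niche.lower == niche.center).all()
        assert (niche.center == niche.upper).all()

    def test_all_zero_substrate(self):
        profiles = [make_profile([0.0, 1.0], f"c{i}", "V1", i + 1) for i in range(4)]
        niche = compute_niche_range(profiles)
        code = CODES[0]
        assert niche.lower[code] == niche.center[code] == niche.upper[code] == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError, match=">= 2"):
            compute_niche_range([make_profile([1] * 31)])


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

class TestDecompose:
    def test_at_center_all_zero(self):
        niche = constant_niche(0.2, 0.5, 0.8)
        d = decompose(make_profile([0.5] * 31), niche)
        for seg in SEGMENTS:
            assert d.segment(seg).abs().sum() == 0.0

    def test_above_upper(self):
        niche = constant_niche(0.2, 0.5, 0.8)
        d = decompose(make_profile([1.1] * 31), niche)
        code = CODES[0]
        assert d.intensification[code] == pytest.approx(0.3)
        assert d.expansion[code] == pytest.approx(0.3)
        assert d.narrowing[code] == d.contraction[code] == 0.0

    def test_below_lower(self):
        niche = constant_niche(0.2, 0.5, 0.8)
        d = decompose(make_profile([0.1] * 31), niche)
        code = CODES[0]
        assert d.narrowing[code] == pytest.approx(0.3)
        assert d.contraction[code] == pytest.approx(0.1)
        assert d.intensification[code] == d.expansion[code] == 0.0

    def test_matches_integral_oracle(self, rng):
        for _ in range(100):
            a, b, c = np.sort(rng.uniform(0, 2, 3))
            x = float(rng.uniform(-0.5, 3.0))
            niche = constant_niche(a, b, c)
            d = decompose(make_profile([max(x, 0.0)] * 31), niche)
            code = CODES[0]
            xx = max(x, 0.0)
            o_int, o_nar, o_exp, o_con = segment_oracle(xx, a, b, c)
            assert d.intensification[code] == pytest.approx(o_int, abs=1e-4)
            assert d.narrowing[code] == pytest.approx(o_nar, abs=1e-4)
            assert d.expansion[code] == pytest.approx(o_exp, abs=1e-4)
            assert d.contraction[code] == pytest.approx(o_con, abs=1e-4)

    @settings(max_examples=200, derandomize=True)
    @given(
        limits=st.tuples(*[st.floats(0, 3)] * 3).map(sorted),
        x=st.floats(0, 4),
    )
    def test_identity_and_exclusivity(self, limits, x):
        """int + exp - nar - con == x - center, and a substrate is never both
        above and below the center."""
        lo, mid, up = limits
        niche = constant_niche(lo, mid, up)
        d = decompose(make_profile([x] * 31), niche)
        code = CODES[0]
        i, e = d.intensification[code], d.expansion[code]
        n, c = d.narrowing[code], d.contraction[code]
        assert min(i, e, n, c) >= 0.0
        assert i + e - n - c == pytest.approx(x - mid, abs=1e-9)
        assert (i + e) * (n + c) == pytest.approx(0.0, abs=1e-12)
        if e > 0:
            assert i == pytest.approx(up - mid)
        if c > 0:
            assert n == pytest.approx(mid - lo)

    def test_monotone_in_x(self, rng):
        niche = constant_niche(0.3, 0.6, 1.0)
        code = CODES[0]
        xs = np.sort(rng.uniform(0, 2, 20))
        ups, downs = [], []
        for x in xs:
            d = decompose(make_profile([x] * 31), niche)
            ups.append(d.intensification[code] + d.expansion[code])
            downs.append(d.narrowing[code] + d.contraction[code])
        assert all(b >= a - 1e-12 for a, b in zip(ups, ups[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(downs, downs[1:]))

    def test_control_self_decomposition(self, experiment):
        """Control replicates against their own range never expand or
        contract; the range-attaining replicate intensifies by upper-center."""
        profiles, design, _ = experiment
        controls = [p for p in profiles if p.treatment == design.control]
        niche = compute_niche_range(controls)
        mat = pd.DataFrame([p.as_series() for p in controls])
        for p in controls:
            d = decompose(p, niche)
            assert d.expansion.sum() == 0.0
            assert d.contraction.sum() == 0.0
        by_id = {p.sample_id: p for p in controls}
        for code in CODES:
            top = mat[code].idxmax()
            d = decompose(by_id[top], niche)
            assert d.intensification[code] == pytest.approx(
                niche.upper[code] - niche.center[code]
            )

    def test_substrate_mismatch_rejected(self):
        niche = constant_niche(0.1, 0.2, 0.3)
        bad = niche.center.copy()
        bad.index = [f"Z{i}" for i in range(31)]
        with pytest.raises(ValidationError, match="match"):
            decompose(
                make_profile([0.5] * 31),
                NicheRange(bad, bad, bad, 3),
            )


# ---------------------------------------------------------------------------
# Indices and functional alteration
# ---------------------------------------------------------------------------

class TestIndices:
    def test_zero_decomposition(self):
        niche = constant_niche(0.5, 0.5, 0.5)
        p = make_profile([0.5] * 31)
        idx = segment_indices(decompose(p, niche), p)
        assert all(idx.index(s) == 0.0 for s in SEGMENTS)

    def test_index_formula(self):
        assert segment_index(7.46, 59.9) == pytest.approx(12.4541, abs=1e-3)
        assert segment_index(7.25, 45.4) == pytest.approx(15.9692, abs=1e-3)

    def test_zero_total_errors(self):
        with pytest.raises(ValidationError):
            segment_index(1.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.01, 3.0), min_size=31, max_size=31))
    def test_index_identity(self, values):
        """I_int + I_exp - I_nar - I_con == 100 (S - S_center) / S."""
        niche = constant_niche(0.2, 0.5, 0.9)
        p = make_profile(values)
        idx = segment_indices(decompose(p, niche), p)
        lhs = idx.intensification + idx.expansion - idx.narrowing - idx.contraction
        rhs = 100.0 * (p.total - niche.total_center) / p.total
        assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_functional_alteration_values(self):
        assert functional_alteration(45.4, 50.7) == pytest.approx(-10.454, abs=1e-3)
        assert functional_alteration(54.2, 50.7) == pytest.approx(6.903, abs=1e-3)
        assert functional_alteration(50.7, 50.7) == 0.0

    def test_functional_alteration_from_profile_and_range(self):
        niche = constant_niche(0.4, 0.5, 0.6)  # S_c = 15.5
        p = make_profile([1.0] * 31)           # S = 31
        assert functional_alteration(p, niche) == pytest.approx(100.0)

    def test_zero_baseline_errors(self):
        with pytest.raises(ValidationError):
            functional_alteration(10.0, 0.0)


# ---------------------------------------------------------------------------
# Associations
# ---------------------------------------------------------------------------

class TestAssociations:
    def test_expansion_row_organic(self):
        row = GUILD_MEANS["expansion"]["V2"]
        assert str(guild_association(row)) == "CH–P"

    def test_intensification_row_mineral(self):
        row = GUILD_MEANS["intensification"]["V4"]
        assert str(guild_association(row)) == "AA–CX"

    def test_full_tie_alphabetical_flagged(self):
        assoc = guild_association({g: 1.0 for g in ("AA", "AM", "CH", "CX", "P")})
        assert (assoc.first, assoc.second, assoc.tie) == ("AA", "AM", True)

    def test_exact_tie_broken_by_guild_totals(self):
        row = GUILD_MEANS["intensification"]["V3"]  # AA == CX == 1.23
        totals = {
            g: sum(GUILD_MEANS[seg]["V3"][g] for seg in GUILD_MEANS) for g in row
        }
        assoc = guild_association(row, totals)
        assert str(assoc) == "CX–AA"
        assert assoc.tie

    def test_all_16_printed_pairs(self):
        """The ranking reproduces every published guild pair; the two cells
        tied at printed precision are accepted in either order."""
        for treatment, by_seg in PRINTED_GUILD_PAIRS.items():
            totals = {
                g: sum(GUILD_MEANS[seg][treatment][g] for seg in GUILD_MEANS)
                for g in GUILD_MEANS["expansion"][treatment]
            }
            for segment, printed in by_seg.items():
                assoc = guild_association(GUILD_MEANS[segment][treatment], totals)
                if (treatment, segment) in TIED_CELLS:
                    assert assoc.tie
                    options = {printed, "–".join(reversed(printed.split("–")))}
                    assert str(assoc) in options
                else:
                    assert str(assoc) == printed, (treatment, segment)

    def test_dominance_pair(self):
        means = {c: 0.0 for c in CODES}
        means["CH9"], means["CH1"] = 0.4, 0.2
        assert str(dominance_codominance(means)) == "CH9–CH1"

    def test_dominance_single_nonzero_flagged(self):
        means = {c: 0.0 for c in CODES}
        means["P3"] = 0.9
        assoc = dominance_codominance(means)
        assert (assoc.first, assoc.second, assoc.tie) == ("P3", "", True)

    def test_dominance_all_zero_empty_flagged(self):
        assoc = dominance_codominance({c: 0.0 for c in CODES})
        assert (str(assoc), assoc.tie) == ("", True)


# ---------------------------------------------------------------------------
# Guild aggregation
# ---------------------------------------------------------------------------

class TestGuildSegmentTable:
    def _design(self, profiles):
        rows = tuple((p.sample_id, p.treatment, p.replicate) for p in profiles)
        return DesignTable(rows, "V1")

    def test_single_expansion_entry(self, catalog):
        niche = constant_niche(0.5, 0.5, 0.5)
        values = {c: 0.5 for c in CODES}
        values["CH3"] = 1.0
        p = make_profile([values[c] for c in CODES], "s1", "V2", 1)
        p2 = make_profile([values[c] for c in CODES], "s2", "V2", 2)
        d = [decompose(p, niche), decompose(p2, niche)]
        table = guild_segment_table(d, catalog)
        means = table.guild_means("V2", "expansion")
        assert means["CH"] == pytest.approx(0.5)
        assert sum(means.values()) == pytest.approx(0.5)

    def test_guild_sums_partition_total(self, catalog, experiment):
        profiles, design, _ = experiment
        controls = [p for p in profiles if p.treatment == design.control]
        niche = compute_niche_range(controls)
        decomps = [decompose(p, niche) for p in profiles if p.treatment != design.control]
        table = guild_segment_table(decomps, catalog)
        for d in decomps:
            for seg in SEGMENTS:
                per_guild = table.per_sample[
                    (table.per_sample["sample_id"] == d.sample_id)
                    & (table.per_sample["segment"] == seg)
                ]["value"].sum()
                assert per_guild == pytest.approx(float(d.segment(seg).sum()))


# ---------------------------------------------------------------------------
# Sharing and resemblance
# ---------------------------------------------------------------------------

class TestSharingResemblance:
    def test_common_above_center_is_center(self):
        niche = constant_niche(0.2, 0.5, 0.8)
        shared = common_with_control(make_profile([1.0] * 31), niche)
        assert (shared == 0.5).all()

    def test_common_elementwise_min(self):
        niche = constant_niche(0.2, 0.5, 0.8)
        shared = common_with_control(make_profile([0.4] * 31), niche)
        assert shared.iloc[0] == pytest.approx(0.4)

    def test_within_identical_is_100(self):
        profiles = [make_profile([1.0] * 31, f"s{i}", "T", i + 1) for i in range(3)]
        assert (within_resemblance(profiles) == 100.0).all()

    def test_within_disjoint_is_0(self):
        a = make_profile([1.0, 0.0], "a", "T", 1)
        b = make_profile([0.0, 1.0], "b", "T", 2)
        assert (within_resemblance([a, b]) == 0.0).all()

    def test_within_hand_value(self):
        a = make_profile([2.0, 2.0], "a", "T", 1)
        b = make_profile([2.0, 0.0], "b", "T", 2)
        # 200 * 2 / (4 + 2)
        assert within_resemblance([a, b])["a"] == pytest.approx(200 * 2 / 6)

    def test_between_hand_value(self):
        profiles = [
            make_profile([1.0, 1.0], "t1", "T", 1),
            make_profile([1.0, 1.0], "t2", "T", 2),
            make_profile([1.0, 0.0], "u1", "U", 1),
            make_profile([1.0, 0.0], "u2", "U", 2),
        ]
        design = DesignTable(tuple((p.sample_id, p.treatment, p.replicate)
                                   for p in profiles), "T")
        between = between_resemblance(profiles, design)
        assert between["t1"] == pytest.approx(50.0)  # min-sum 1 over total 2
        assert between["u1"] == pytest.approx(100.0)

    def test_between_identical_everywhere_is_100(self):
        profiles = [
            make_profile([1.0] * 31, f"{t}{r}", t, r)
            for t in ("A", "B") for r in (1, 2)
        ]
        design = DesignTable(tuple((p.sample_id, p.treatment, p.replicate)
                                   for p in profiles), "A")
        assert (between_resemblance(profiles, design) == 100.0).all()
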