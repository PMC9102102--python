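"""Niche-segmentation model for community-level physiological profiles.

The model treats the control community's per-substrate variation as the
native functional ecological niche: for every substrate the control
replicates define a lower limit (minimum), a center (mean) and an upper
limit (maximum).  A treated sample's deviation from the center on each
substrate is then split into four complementary, non-negative segments:

* intensification - increase from the center up to the upper limit;
* expansion       - increase beyond the upper limit;
* narrowing       - decrease from the center down to the lower limit;
* contraction     - decrease below the lower limit.

By construction ``int + exp - nar - con = x - center`` for every substrate,
and a sample is never simultaneously above and below the center, so at most
one of the pairs (int, exp) and (nar, con) is nonzero.

On top of the decomposition the module computes:

* guild-level segment sums (substrates grouped into the five chemical
  guilds CH, CX, AA, P, AM) with treatment means, s.e. and LSD letters;
* the four synthetic segment indices, each segment's summed activity as a
  percent of the sample's own total activity;
* functional alteration, the signed percent change of a sample's total
  activity relative to the control mean total;
* guild association and functional-group dominance-codominance: the two
  top-ranked guilds (or substrate codes) per treatment and segment;
* the community shared with the control (per-substrate minimum against the
  niche center) and within/between-community functional resemblance
  percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .ecoplate_io import (
    GUILDS,
    DesignTable,
    SampleProfile,
    SubstrateCatalog,
    ValidationError,
    builtin_catalog,
)
from .group_stats import lsd_letters, one_way_anova

__all__ = [
    "SEGMENTS",
    "EN_DASH",
    "NicheRange",
    "SegmentDecomposition",
    "SegmentIndices",
    "Association",
    "GuildSegmentTable",
    "compute_niche_range",
    "decompose",
    "guild_segment_table",
    "segment_index",
    "segment_indices",
    "functional_alteration",
    "guild_association",
    "dominance_codominance",
    "common_with_control",
    "within_resemblance",
    "between_resemblance",
]

#: Segment names, in the conventional reporting order.
SEGMENTS = ("intensification", "narrowing", "expansion", "contraction")

#: Pair separator used in association strings (ASCII "-" accepted on input).
EN_DASH = "–"


# ---------------------------------------------------------------------------
# Niche range
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NicheRange:
    """Per-substrate [lower, center, upper] limits from control replicates."""

    lower: pd.Series
    center: pd.Series
    upper: pd.Series
    n_control: int

    @property
    def total_center(self) -> float:
        """Control mean total activity, the functional-alteration baseline."""
        return float(self.center.sum())

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.center.index)


def compute_niche_range(control_profiles: Sequence[SampleProfile]) -> NicheRange:
    """Estimate the niche range as the min/mean/max of control replicates."""
    if len(control_profiles) < 2:
        raise ValidationError(
            f"niche range needs >= 2 control replicates, got {len(control_profiles)}"
        )
    mat = pd.DataFrame([p.as_series() for p in control_profiles])
    return NicheRange(
        lower=mat.min(axis=0),
        center=mat.mean(axis=0),
        upper=mat.max(axis=0),
        n_control=len(control_profiles),
    )


# ---------------------------------------------------------------------------
# Segment decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentDecomposition:
    """Non-negative per-substrate segment components of one sample (OD)."""

    sample_id: str
    treatment: str
    intensification: pd.Series
    narrowing: pd.Series
    expansion: pd.Series
    contraction: pd.Series

    def segment(self, name: str) -> pd.Series:
        if name not in SEGMENTS:
            raise KeyError(name)
        return getattr(self, name)

    def segment_sums(self) -> dict[str, float]:
        return {s: float(self.segment(s).sum()) for s in SEGMENTS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({s: self.segment(s) for s in SEGMENTS})


def decompose(profile: SampleProfile, niche: NicheRange) -> SegmentDecomposition:
    """Split a sample's deviations from the niche center into the four
    complementary segments.

    Above the center, increases are intensification up to the upper limit
    and expansion beyond it; below the center, decreases are narrowing down
    to the lower limit and contraction beyond it.
    """
    x = profile.as_series()
    if set(x.index) != set(niche.codes):
        raise ValidationError(
            f"sample {profile.sample_id!r} substrates do not match the niche range"
        )
    x = x.reindex(niche.center.index)
    lo, mid, up = niche.lower, niche.center, niche.upper
    above = x >= mid
    inten = np.where(above, np.minimum(x, up) - mid, 0.0)
    expan = np.where(above, np.maximum(0.0, x - up), 0.0)
    narro = np.where(above, 0.0, mid - np.maximum(x, lo))
    contr = np.where(above, 0.0, np.maximum(0.0, lo - x))
    idx = niche.center.index
    return SegmentDecomposition(
        sample_id=profile.sample_id,
        treatment=profile.treatment,
        intensification=pd.Series(inten, index=idx),
        narrowing=pd.Series(narro, index=idx),
        expansion=pd.Series(expan, index=idx),
        contraction=pd.Series(contr, index=idx),
    )


# ---------------------------------------------------------------------------
# Guild-level segment table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuildSegmentTable:
    """Guild x segment sums per sample plus treatment-level summary.

    ``per_sample`` is long-format (sample_id, treatment, guild, segment,
    value); ``summary`` has one row per (treatment, guild, segment) with
    mean, se and LSD letter; ``anova`` one row per (guild, segment) with
    F and p.
    """

    per_sample: pd.DataFrame
    summary: pd.DataFrame
    anova: pd.DataFrame

    def guild_means(self, treatment: str, segment: str) -> dict[str, float]:
        """Guild -> mean segment value for one treatment (one table cell row)."""
        sub = self.summary[
            (self.summary["treatment"] == treatment)
            & (self.summary["segment"] == segment)
        ]
        return dict(zip(sub["guild"], sub["mean"]))

    def guild_totals(self, treatment: str) -> dict[str, float]:
        """Guild -> summed mean value across all four segments (tie-break key)."""
        sub = self.summary[self.summary["treatment"] == treatment]
        return sub.groupby("guild")["mean"].sum().to_dict()


def guild_segment_table(decomps: Sequence[SegmentDecomposition],
                        catalog: SubstrateCatalog | None = None,
                        design: DesignTable | None = None,
                        alpha: float = 0.05) -> GuildSegmentTable:
    """Aggregate decompositions to guild level and summarize per treatment.

    Per sample, the guild value of a segment is the sum of the segment
    component over the guild's substrates; treatment-level cells are
    mean +/- s.e. over replicates with LSD letters per guild x segment.
    """
    catalog = catalog or builtin_catalog()
    guild_of = catalog.guild_of
    rows = []
    for d in decomps:
        for seg in SEGMENTS:
            series = d.segment(seg)
            unknown = set(series.index) - set(guild_of)
            if unknown:
                raise ValidationError(f"substrates without a guild: {sorted(unknown)}")
            sums = series.groupby(series.index.map(guild_of)).sum()
            for guild in GUILDS:
                rows.append(
                    (d.sample_id, d.treatment, guild, seg, float(sums.get(guild, 0.0)))
                )
    per_sample = pd.DataFrame(
        rows, columns=["sample_id", "treatment", "guild", "segment", "value"]
    )

    summary_rows, anova_rows = [], []
    treatments = list(dict.fromkeys(per_sample["treatment"]))
    for guild in GUILDS:
        for seg in SEGMENTS:
            cell = per_sample[(per_sample["guild"] == guild) & (per_sample["segment"] == seg)]
            groups = {
                t: cell.loc[cell["treatment"] == t, "value"].to_list() for t in treatments
            }
            multi = {t: v for t, v in groups.items() if len(v) >= 2}
            letters = lsd_letters(multi, alpha=alpha) if len(multi) >= 2 else {}
            if len(multi) >= 2:
                res = one_way_anova(list(multi.values()))
                anova_rows.append((guild, seg, res.F, res.p))
            for t in treatments:
                v = np.asarray(groups[t], dtype=float)
                se = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")
                summary_rows.append(
                    (t, guild, seg, float(v.mean()), se, letters.get(t, ""))
                )
    summary = pd.DataFrame(
        summary_rows, columns=["treatment", "guild", "segment", "mean", "se", "letter"]
    )
    anova = pd.DataFrame(anova_rows, columns=["guild", "segment", "F", "p"])
    return GuildSegmentTable(per_sample, summary, anova)


# ---------------------------------------------------------------------------
# Synthetic indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentIndices:
    """The four segment indices of one sample, percent of its own total
    activity, plus (optionally) the signed functional alteration percent."""

    sample_id: str
    intensification: float
    narrowing: float
    expansion: float
    contraction: float
    functional_alteration: float | None = None

    def index(self, name: str) -> float:
        if name not in SEGMENTS:
            raise KeyError(name)
        return getattr(self, name)


def segment_index(segment_sum: float, total_activity: float) -> float:
    """A segment index: the segment's summed activity as a percent of the
    sample's own total activity S."""
    if total_activity <= 0:
        raise ValidationError("segment index undefined for zero total activity")
    return 100.0 * segment_sum / total_activity


def segment_indices(decomp: SegmentDecomposition,
                    profile: SampleProfile) -> SegmentIndices:
    """Compute all four segment indices for one sample."""
    S = profile.total
    sums = decomp.segment_sums()
    return SegmentIndices(
        sample_id=profile.sample_id,
        **{seg: segment_index(sums[seg], S) for seg in SEGMENTS},
    )


def functional_alteration(sample: Union[SampleProfile, float],
                          baseline: Union[NicheRange, float]) -> float:
    """Signed percent change of total activity against the control baseline.

    ``sample`` may be a profile or its total activity S; ``baseline`` may be
    a niche range (its center total is used) or the control mean total S_c.
    FA = 100 * (S - S_c) / S_c.
    """
    S = sample.total if isinstance(sample, SampleProfile) else float(sample)
    S_c = baseline.total_center if isinstance(baseline, NicheRange) else float(baseline)
    if S_c <= 0:
        raise ValidationError("functional alteration undefined for zero control total")
    return 100.0 * (S - S_c) / S_c


# ---------------------------------------------------------------------------
# Association and dominance ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Association:
    """An ordered dominant-codominant pair, e.g. ``CH–CX``.

    ``tie`` is set when values tied at the reporting precision make the
    membership or order of the pair ambiguous."""

    first: str
    second: str
    tie: bool = False

    def __str__(self) -> str:
        if not self.first:
            return ""
        if not self.second:
            return self.first
        return f"{self.first}{EN_DASH}{self.second}"


def _rank_top_two(values: Mapping[str, float],
                  totals: Mapping[str, float] | None,
                  precision: int,
                  empty_on_zero: bool = True) -> Association:
    items = {k: float(v) for k, v in values.items()}
    nonzero = {k for k, v in items.items() if v > 0}
    if not nonzero and empty_on_zero:
        return Association("", "", True)

    def key(label: str) -> tuple:
        # Descending value at full precision, then descending all-segment
        # total, then ascending label.
        total = float(totals.get(label, 0.0)) if totals else 0.0
        return (-items[label], -total, label)

    ordered = sorted(items, key=key)
    if len(nonzero) == 1:
        return Association(ordered[0], "", True)
    ranked_vals = [round(items[g], precision) for g in ordered]
    tie = ranked_vals[0] == ranked_vals[1] or (
        len(ranked_vals) > 2 and ranked_vals[1] == ranked_vals[2]
    )
    return Association(ordered[0], ordered[1], tie)


def guild_association(guild_values: Mapping[str, float],
                      guild_totals: Mapping[str, float] | None = None,
                      precision: int = 2) -> Association:
    """The two top-ranked guilds for one treatment x segment.

    Ranking is by descending value; exact ties fall back to the guild's
    summed mean across all four segments (``guild_totals``), then to
    alphabetical order.  The tie flag is raised whenever values rounded to
    ``precision`` decimals cannot distinguish the pair or its order.
    """
    if set(guild_values) != set(GUILDS):
        raise ValidationError(
            f"expected the five guilds {GUILDS}, got {sorted(guild_values)}"
        )
    return _rank_top_two(guild_values, guild_totals, precision, empty_on_zero=False)


def dominance_codominance(substrate_means: Mapping[str, float],
                          substrate_totals: Mapping[str, float] | None = None,
                          precision: int = 2) -> Association:
    """The dominant-codominant functional-group (substrate) pair for one
    treatment x segment, from per-substrate treatment mean segment values.

    An all-zero segment yields an empty, flagged pair; a single active
    substrate yields a flagged singleton."""
    if len(substrate_means) != 31:
        raise ValidationError(
            f"expected 31 substrate means, got {len(substrate_means)}"
        )
    return _rank_top_two(substrate_means, substrate_totals, precision)


# ---------------------------------------------------------------------------
# Community sharing and resemblance
# ---------------------------------------------------------------------------

def common_with_control(profile: SampleProfile, niche: NicheRange) -> pd.Series:
    """Per-substrate activity shared with the control community:
    min(x_s, center_s).  Rows over samples form the sharing matrix used for
    ordination."""
    x = profile.as_series().reindex(niche.center.index)
    return np.minimum(x, niche.center)


def _percentage_similarity(a: pd.Series, b: pd.Series) -> float:
    """Czekanowski percentage similarity: 200 * sum min / (sum a + sum b)."""
    denom = float(a.sum() + b.sum())
    if denom == 0:
        return 100.0  # two empty communities are identical
    return 200.0 * float(np.minimum(a, b).sum()) / denom


def within_resemblance(treatment_profiles: Sequence[SampleProfile]) -> pd.Series:
    """Within-community functional resemblance, percent, one value per
    replicate: the mean Czekanowski percentage similarity of that replicate
    to each other replicate of the same treatment."""
    if len(treatment_profiles) < 2:
        raise ValidationError("within-resemblance needs >= 2 replicates")
    series = [p.as_series() for p in treatment_profiles]
    vals = {}
    for i, p in enumerate(treatment_profiles):
        sims = [
            _percentage_similarity(series[i], series[j])
            for j in range(len(series))
            if j != i
        ]
        vals[p.sample_id] = float(np.mean(sims))
    return pd.Series(vals, name="within_resemblance")


def between_resemblance(profiles: Sequence[SampleProfile], design: DesignTable,
                        include_control: bool = True) -> pd.Series:
    """Between-community functional resemblance, percent, one value per
    sample: the share of the sample's activity also present in the other
    treatments' mean profiles, averaged over those treatments.

    For sample r of treatment t and another treatment u with mean profile
    m_u, coverage is 100 * sum_s min(x_rs, m_us) / sum_s x_rs; the sample's
    value averages coverage over all u != t (the control included by
    default, ``include_control=False`` restricts to fertilized treatments).
    """
    by_treatment: dict[str, list[pd.Series]] = {}
    for p in profiles:
        by_treatment.setdefault(p.treatment, []).append(p.as_series())
    if len(by_treatment) < 2:
        raise ValidationError("between-resemblance needs >= 2 treatments")
    mean_profiles = {t: pd.concat(v, axis=1).mean(axis=1) for t, v in by_treatment.items()}
    vals = {}
    for p in profiles:
        x = p.as_series()
        S = float(x.sum())
        if S == 0:
            warnings.warn(
                f"sample {p.sample_id!r} has zero total activity; skipped",
                stacklevel=2,
            )
            continue
        others = [
            u for u in mean_profiles
            if u != p.treatment and (include_control or u != design.control)
        ]
        if not others:
            continue
        coverages = [
            100.0 * float(np.minimum(x, mean_profiles[u].reindex(x.index)).sum()) / S
            for u in others
        ]
        vals[p.sample_id] = float(np.mean(coverages))
    return pd.Series(vals, name="between_resemblance")
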