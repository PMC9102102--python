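"""Conventional community-level physiological profile (CLPP) metrics.

Per sample: total activity S, average well color development (AWCD = S/31),
Shannon diversity (natural log) and Gini-Simpson diversity over the
substrate-use proportions.  Per treatment: mean +/- standard error with
LSD compact letters, the classic summary table of an EcoPlate study.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ecoplate_io import SampleProfile, ValidationError
from .group_stats import lsd_letters, one_way_anova

__all__ = ["DiversitySummary", "awcd", "shannon", "simpson", "summarize",
           "summarize_treatments"]

N_SUBSTRATES = 31


class UndefinedDiversityError(ValidationError):
    """Diversity indices are undefined for an all-zero profile."""


@dataclass(frozen=True)
class DiversitySummary:
    sample_id: str
    treatment: str
    S: float      # total activity (OD sum over 31 substrates)
    awcd: float   # S / 31
    H: float      # Shannon, nats
    D: float      # Gini-Simpson


def awcd(profile: SampleProfile) -> float:
    """Average well color development: mean blank-corrected response."""
    return profile.total / N_SUBSTRATES


def _proportions(profile: SampleProfile) -> np.ndarray:
    x = np.array(list(profile.responses.values()), dtype=float)
    S = x.sum()
    if S <= 0:
        raise UndefinedDiversityError(
            f"sample {profile.sample_id!r} has zero total activity; "
            "diversity is undefined"
        )
    return x / S

def shannon(profile: SampleProfile) -> float:
    """Shannon index H = -sum p ln p over substrate-use proportions (nats).

    Zero-response substrates contribute nothing (0 * ln 0 := 0)."""
    p = _proportions(profile)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(profile: SampleProfile) -> float:
    """Gini-Simpson index D = 1 - sum p^2 (0 for a single-substrate profile)."""
    p = _proportions(profile)
    return float(1.0 - (p ** 2).sum())


def summarize(profile: SampleProfile) -> DiversitySummary:
    return DiversitySummary(
        sample_id=profile.sample_id,
        treatment=profile.treatment,
        S=profile.total,
        awcd=awcd(profile),
        H=shannon(profile),
        D=simpson(profile),
    )


def _mean_se(values: Sequence[float]) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float(v.mean()), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


def summarize_treatments(profiles: Iterable[SampleProfile],
                         alpha: float = 0.05) -> pd.DataFrame:
    """Treatment-level summary of S, AWCD, H and D.

    Returns a table with one row per treatment and, for each metric, its
    mean, standard error and LSD compact letter, plus a trailing block of
    per-metric omnibus F and p values (rows ``F`` and ``p``).
    Treatments with a single replicate get a missing s.e. and a warning.
    """
    per_sample = pd.DataFrame([summarize(p).__dict__ for p in profiles])
    if per_sample.empty:
        raise ValidationError("no profiles to summarize")
    metrics = ["S", "awcd", "H", "D"]
    treatments = list(dict.fromkeys(per_sample["treatment"]))
    out: dict[str, dict[str, float | str]] = {t: {} for t in treatments}
    stats_rows: dict[str, dict[str, float]] = {"F": {}, "p": {}}
    for metric in metrics:
        groups = {
            t: per_sample.loc[per_sample["treatment"] == t, metric].to_list()
            for t in treatments
        }
        for t, vals in groups.items():
            mean, se = _mean_se(vals)
            if np.isnan(se):
                warnings.warn(
                    f"treatment {t!r} has a single replicate; s.e. undefined",
                    stacklevel=2,
                )
            out[t][f"{metric}_mean"] = mean
            out[t][f"{metric}_se"] = se
        multi = {t: v for t, v in groups.items() if len(v) >= 2}
        if len(multi) >= 2:
            letters = lsd_letters(multi, alpha=alpha)
            anova = one_way_anova(list(multi.values()))
            stats_rows["F"][f"{metric}_mean"] = anova.F
            stats_rows["p"][f"{metric}_mean"] = anova.p
        else:
            letters = {}
        for t in treatments:
            out[t][f"{metric}_letter"] = letters.get(t, "")
    table = pd.DataFrame.from_dict(out, orient="index")
    table.index.name = "treatment"
    table.attrs["anova"] = pd.DataFrame(stats_rows).T
    return table
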