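"""Seeded synthetic EcoPlate experiments with known ground truth.

The generator emulates a long-term fertilization trial read out by
community-level physiological profiling: five treatments (one of them the
unfertilized control) in four field replicates, one blank-corrected
31-substrate profile per replicate.  Control responses are truncated-normal
draws around a per-substrate baseline mu_s; a treatment multiplies every
substrate of guild g by its effect multiplier kappa[t][g] before noise is
added.  Because the effects are guild-structured, the expected direction of
every guild under every treatment — and hence the expected association and
dominance outcomes — is known by construction.

The default parameters emulate the magnitudes typical of a plateau-phase
EcoPlate read-out of grassland soil: baselines uniform on 0.3-2.5 OD (total
activity near 45-60 OD), replicate noise at 10 % of the baseline, and a
kappa matrix contrasting an organic treatment (carbohydrate/polymer boost),
a mineral treatment (overall reduction) and two intermediate organo-mineral
treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
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

__all__ = ["SimulationConfig", "GroundTruth", "generate_experiment", "write_fixture",
           "DEFAULT_KAPPA"]

#: Default guild effect multipliers: an organic treatment inflating
#: carbohydrates and polymers, a mild organo-mineral treatment, a mineral
#: treatment deflating most guilds, and a high organo-mineral treatment
#: with a slight overall reduction.  The control (first treatment) is
#: all-ones by definition.
DEFAULT_KAPPA: dict[str, dict[str, float]] = {
    "V1": {"AA": 1.00, "AM": 1.00, "CH": 1.00, "CX": 1.00, "P": 1.00},
    "V2": {"AA": 1.05, "AM": 1.00, "CH": 1.30, "CX": 1.15, "P": 1.35},
    "V3": {"AA": 1.10, "AM": 1.00, "CH": 1.05, "CX": 1.10, "P": 1.00},
    "V4": {"AA": 1.05, "AM": 0.90, "CH": 0.80, "CX": 0.95, "P": 0.80},
    "V5": {"AA": 0.95, "AM": 0.95, "CH": 0.95, "CX": 1.00, "P": 0.90},
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic EcoPlate experiment.

    ``mu_range`` bounds the uniform draw of per-substrate control baselines
    (OD); ``sigma_frac`` sets replicate noise as a fraction of the baseline;
    ``kappa`` maps treatment -> guild -> multiplicative effect (> 0).
    """

    treatments: tuple[str, ...] = ("V1", "V2", "V3", "V4", "V5")
    control: str = "V1"
    n_replicates: int = 4
    mu_range: tuple[float, float] = (0.3, 2.5)
    sigma_frac: float = 0.1
    kappa: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {t: dict(g) for t, g in DEFAULT_KAPPA.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control not in self.treatments:
            raise ValidationError(f"control {self.control!r} not among treatments")
        if self.n_replicates < 2:
            raise ValidationError("need >= 2 replicates")
        lo, hi = self.mu_range
        if not (0 < lo <= hi):
            raise ValidationError(f"invalid mu_range {self.mu_range}")
        if self.sigma_frac < 0:
            raise ValidationError("sigma_frac must be >= 0")
        for t in self.treatments:
            if t == self.control:
                continue
            effects = self.kappa.get(t)
            if effects is None:
                raise ValidationError(f"kappa missing treatment {t!r}")
            for g in GUILDS:
                k = effects.get(g)
                if k is None or k <= 0:
                    raise ValidationError(f"kappa[{t!r}][{g!r}] must be > 0, got {k!r}")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator built into the data.

    ``direction`` marks each treatment x guild as inflated / deflated /
    neutral according to its kappa; ``expected_expansion_guild`` and
    ``expected_contraction_guild`` name, per non-control treatment, the
    guild with the largest expected activity beyond the control maximum
    (respectively below the control minimum), or None when no guild is
    pushed in that direction.
    """

    mu: pd.Series
    kappa: dict[str, dict[str, float]]
    direction: dict[str, dict[str, str]]
    expected_expansion_guild: dict[str, str | None]
    expected_contraction_guild: dict[str, str | None]


def _truth(config: SimulationConfig, mu: pd.Series,
           catalog: SubstrateCatalog) -> GroundTruth:
    guild_of = catalog.guild_of
    guild_mu = mu.groupby(mu.index.map(guild_of)).sum()
    kappa = {t: {g: float(config.kappa[t][g]) for g in GUILDS}
             for t in config.treatments if t != config.control}
    direction, exp_guild, con_guild = {}, {}, {}
    for t, effects in kappa.items():
        direction[t] = {
            g: "inflated" if k > 1 else ("deflated" if k < 1 else "neutral")
            for g, k in effects.items()
        }
        # Expected mass shifted beyond the control mean, per guild.
        shift = {g: (effects[g] - 1.0) * float(guild_mu[g]) for g in GUILDS}
        up = {g: v for g, v in shift.items() if v > 0}
        down = {g: -v for g, v in shift.items() if v < 0}
        exp_guild[t] = max(up, key=up.get) if up else None
        con_guild[t] = max(down, key=down.get) if down else None
    return GroundTruth(mu, kappa, direction, exp_guild, con_guild)


def generate_experiment(config: SimulationConfig | None = None,
                        catalog: SubstrateCatalog | None = None
                        ) -> tuple[list[SampleProfile], DesignTable, GroundTruth]:
    """Draw one synthetic experiment.

    Control replicate responses are max(0, Normal(mu_s, sigma_s)); treated
    responses are max(0, Normal(kappa[t][g(s)] * mu_s, sigma_s)).  The draw
    is fully reproducible from ``config.seed``.
    """
    config = config or SimulationConfig()
    catalog = catalog or builtin_catalog()
    rng = np.random.default_rng(config.seed)
    codes = list(catalog.codes)
    guild_of = catalog.guild_of
    lo, hi = config.mu_range
    mu = pd.Series(rng.uniform(lo, hi, size=len(codes)), index=codes)
    sigma = config.sigma_frac * mu

    profiles: list[SampleProfile] = []
    design_rows: list[tuple[str, str, int]] = []
    for t in config.treatments:
        for rep in range(1, config.n_replicates + 1):
            sid = f"{t}-r{rep}"
            means = np.array([
                mu[c] if t == config.control else config.kappa[t][guild_of[c]] * mu[c]
                for c in codes
            ])
            draw = np.maximum(0.0, rng.normal(means, sigma.to_numpy()))
            profiles.append(
                SampleProfile(sid, t, rep, dict(zip(codes, draw.astype(float))))
            )
            design_rows.append((sid, t, rep))
    design = DesignTable(tuple(design_rows), config.control)
    return profiles, design, _truth(config, mu, catalog)


def write_fixture(profiles: Sequence[SampleProfile], design: DesignTable,
                  out_dir: Union[str, Path]) -> tuple[Path, Path]:
    """Write a generated experiment as the package's canonical CSVs:
    ``profiles.csv`` (long format) and ``design.csv``.  Round-trips
    losslessly through :func:`demsa.ecoplate_io.read_profiles`."""
    from .ecoplate_io import write_profiles

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles_path = out_dir / "profiles.csv"
    design_path = out_dir / "design.csv"
    write_profiles(profiles, profiles_path)
    design.to_frame().to_csv(design_path, index=False)
    return profiles_path, design_path
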