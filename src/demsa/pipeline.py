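"""End-to-end analysis: profiles + design in, report bundle out.

Runs the full chain — niche range from the control, per-sample segment
decomposition, guild tables, synthetic indices, associations, community
comparison, conventional metrics and ordinations — and renders it as the
set of CSV tables and a JSON report the command line writes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import clpp_metrics, demsa_core, group_stats
from .ecoplate_io import (
    DesignTable,
    SampleProfile,
    SubstrateCatalog,
    ValidationError,
    builtin_catalog,
)

__all__ = ["DemsaReport", "run_demsa", "write_report"]


def _mean_se(values: Sequence[float]) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    se = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")
    return float(v.mean()), se


@dataclass
class DemsaReport:
    """Everything one analysis run produces."""

    table1: pd.DataFrame                 # conventional metrics per treatment
    niche: demsa_core.NicheRange
    guild_table: demsa_core.GuildSegmentTable
    indices_per_sample: pd.DataFrame     # sample-level indices + FA
    indices_summary: pd.DataFrame        # treatment-level indices + letters
    associations: pd.DataFrame           # guild + group pairs per treatment x segment
    community: pd.DataFrame              # FA / within / between per treatment
    resemblance_per_sample: pd.DataFrame
    sharing: pd.DataFrame                # samples x substrates, min(x, center)
    pca: dict[str, group_stats.PcaSummary]
    alpha: float


def _summary_block(per_sample: pd.DataFrame, value_cols: Sequence[str],
                   treatments: Sequence[str], alpha: float) -> pd.DataFrame:
    """Treatment-level mean/se/letter summary of sample-level columns."""
    rows = {}
    for col in value_cols:
        groups = {
            t: per_sample.loc[per_sample["treatment"] == t, col].dropna().to_list()
            for t in treatments
        }
        groups = {t: v for t, v in groups.items() if v}
        multi = {t: v for t, v in groups.items() if len(v) >= 2}
        letters = group_stats.lsd_letters(multi, alpha=alpha) if len(multi) >= 2 else {}
        for t, vals in groups.items():
            mean, se = _mean_se(vals)
            rows.setdefault(t, {})[f"{col}_mean"] = mean
            rows[t][f"{col}_se"] = se
            rows[t][f"{col}_letter"] = letters.get(t, "")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "treatment"
    return out.loc[[t for t in treatments if t in out.index]]


def run_demsa(profiles: Sequence[SampleProfile], design: DesignTable,
              catalog: SubstrateCatalog | None = None, alpha: float = 0.05,
              between_include_control: bool = True,
              pca_scale: str = "none") -> DemsaReport:
    """Run the complete analysis on blank-corrected profiles."""
    catalog = catalog or builtin_catalog()
    by_id = {p.sample_id: p for p in profiles}
    if set(by_id) != {sid for sid, _, _ in design.rows}:
        raise ValidationError("profiles and design cover different samples")

    control_profiles = [p for p in profiles if p.treatment == design.control]
    if len(control_profiles) < 2:
        raise ValidationError(
            f"control treatment {design.control!r} needs >= 2 profiles"
        )
    treated = [t for t in design.treatments if t != design.control]

    # Conventional block (all treatments, control included).
    table1 = clpp_metrics.summarize_treatments(profiles, alpha=alpha)

    # Niche range and decomposition (every sample, control included).
    niche = demsa_core.compute_niche_range(control_profiles)
    decomps = {p.sample_id: demsa_core.decompose(p, niche) for p in profiles}

    # Guild x segment table over treated samples (the model's main matrix).
    treated_decomps = [decomps[p.sample_id] for p in profiles if p.treatment != design.control]
    guild_table = demsa_core.guild_segment_table(
        treated_decomps, catalog, design, alpha=alpha
    )

    # Synthetic indices and functional alteration per sample.
    idx_rows = []
    for p in profiles:
        if p.treatment == design.control:
            continue
        idx = demsa_core.segment_indices(decomps[p.sample_id], p)
        idx_rows.append({
            "sample_id": p.sample_id,
            "treatment": p.treatment,
            **{seg: idx.index(seg) for seg in demsa_core.SEGMENTS},
            "functional_alteration": demsa_core.functional_alteration(p, niche),
        })
    indices_per_sample = pd.DataFrame(idx_rows)
    indices_summary = _summary_block(
        indices_per_sample,
        list(demsa_core.SEGMENTS) + ["functional_alteration"],
        treated, alpha,
    )

    # Associations: guild pairs from treatment guild means, group pairs from
    # treatment substrate means, per segment, with all-segment tie-break keys.
    assoc_rows = []
    substrate_means: dict[tuple[str, str], pd.Series] = {}
    for t in treated:
        samples = [p.sample_id for p in profiles if p.treatment == t]
        seg_means = {
            seg: pd.concat([decomps[s].segment(seg) for s in samples], axis=1).mean(axis=1)
            for seg in demsa_core.SEGMENTS
        }
        substrate_totals = sum(seg_means.values())
        guild_totals = guild_table.guild_totals(t)
        for seg in demsa_core.SEGMENTS:
            guild_pair = demsa_core.guild_association(
                guild_table.guild_means(t, seg), guild_totals
            )
            group_pair = demsa_core.dominance_codominance(
                seg_means[seg].to_dict(), substrate_totals.to_dict()
            )
            substrate_means[(t, seg)] = seg_means[seg]
            assoc_rows.append({
                "treatment": t,
                "segment": seg,
                "guild_pair": str(guild_pair),
                "guild_tie": guild_pair.tie,
                "group_pair": str(group_pair),
                "group_tie": group_pair.tie,
            })
    associations = pd.DataFrame(assoc_rows)

    # Community comparison: FA, within- and between-resemblance.
    within_parts = []
    for t in design.treatments:
        t_profiles = [p for p in profiles if p.treatment == t]
        if len(t_profiles) >= 2:
            within_parts.append(demsa_core.within_resemblance(t_profiles))
    within = pd.concat(within_parts) if within_parts else pd.Series(dtype=float)
    between = demsa_core.between_resemblance(
        profiles, design, include_control=between_include_control
    )
    resemblance_per_sample = pd.DataFrame({
        "treatment": {p.sample_id: p.treatment for p in profiles},
        "within": within,
        "between": between,
    }).dropna(subset=["treatment"])
    resemblance_per_sample.index.name = "sample_id"
    community_per_sample = resemblance_per_sample.reset_index().merge(
        indices_per_sample[["sample_id", "functional_alteration"]],
        on="sample_id", how="left",
    )
    community = _summary_block(
        community_per_sample,
        ["functional_alteration", "within", "between"],
        treated, alpha,
    )

    # Sharing matrix and ordinations.
    sharing = pd.DataFrame({
        p.sample_id: demsa_core.common_with_control(p, niche) for p in profiles
    }).T
    sharing.index.name = "sample_id"

    pca: dict[str, group_stats.PcaSummary] = {}
    profile_matrix = pd.DataFrame({p.sample_id: p.as_series() for p in profiles}).T
    matrices: dict[str, pd.DataFrame] = {
        "profiles": profile_matrix,
        "sharing": sharing,
    }
    seg_frames = {}
    for seg in demsa_core.SEGMENTS:
        seg_frames[seg] = pd.DataFrame({
            sid: d.segment(seg) for sid, d in decomps.items()
        }).T
        matrices[seg] = seg_frames[seg]
    matrices["segments_combined"] = pd.concat(
        [f.add_suffix(f"_{seg[:3]}") for seg, f in seg_frames.items()], axis=1
    )
    for name, mat in matrices.items():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pca[name] = group_stats.pca_summary(mat, scale=pca_scale)
        except ValueError as err:
            warnings.warn(f"PCA of {name!r} skipped: {err}", stacklevel=2)

    return DemsaReport(
        table1=table1,
        niche=niche,
        guild_table=guild_table,
        indices_per_sample=indices_per_sample,
        indices_summary=indices_summary,
        associations=associations,
        community=community,
        resemblance_per_sample=resemblance_per_sample,
        sharing=sharing,
        pca=pca,
        alpha=alpha,
    )


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report(report: DemsaReport, out_dir: str | Path) -> list[Path]:
    """Write the report bundle; returns the list of files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _csv(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out_dir / name
        df.to_csv(path, index=index)
        written.append(path)

    _csv(report.table1, "table1.csv")
    _csv(report.guild_table.summary, "table2_guilds.csv", index=False)
    _csv(report.indices_summary, "table2_indices.csv")
    _csv(report.associations, "table2_associations.csv", index=False)
    _csv(report.community, "table2_community.csv")
    niche_df = pd.DataFrame({
        "lower": report.niche.lower,
        "center": report.niche.center,
        "upper": report.niche.upper,
    })
    niche_df.index.name = "substrate_code"
    _csv(niche_df, "niche_range.csv")
    _csv(report.sharing, "sharing_matrix.csv")
    for name, summary in report.pca.items():
        _csv(summary.scores, f"pca_{name}_scores.csv")
        _csv(summary.loadings, f"pca_{name}_loadings.csv")
        var = pd.DataFrame({"variance_pct": summary.variance_pct},
                           index=summary.scores.columns)
        var.index.name = "axis"
        _csv(var, f"pca_{name}_variance.csv")

    payload = {
        "alpha": report.alpha,
        "n_control": report.niche.n_control,
        "control_total": report.niche.total_center,
        "indices_per_sample": report.indices_per_sample.to_dict(orient="records"),
        "indices_summary": report.indices_summary.reset_index().to_dict(orient="records"),
        "associations": report.associations.to_dict(orient="records"),
        "community": report.community.reset_index().to_dict(orient="records"),
        "resemblance_per_sample": report.resemblance_per_sample.reset_index()
            .to_dict(orient="records"),
        "pca_variance": {k: list(v.variance_pct) for k, v in report.pca.items()},
    }
    path = out_dir / "report.json"
    with open(path, "w") as fh:
        json.dump(_json_safe(payload), fh, indent=2, sort_keys=True)
    written.append(path)
    return written
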