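"""End-to-end orchestration: counts -> QC -> statistics -> calls.

Thin glue over the analysis modules for the common experiment layout: per
experiment one T0 sample plus replicated treatment-arm Trelapse samples,
with the untreated (NT) arm as the reference for fold variations, fitness,
competitive index and resistant-clone calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import qc as qc_mod
from . import selection, stats
from .selection import CoreSet


@dataclass
class AnalysisResult:
    """Everything the standard analysis computes from one count matrix."""

    profiles: pd.DataFrame  # barcode x profile frequencies (QC output)
    qc_report: qc_mod.QCReport
    profile_meta: pd.DataFrame  # parsed profile metadata
    diversity: pd.DataFrame  # per profile: shannon H, richness, norm. richness
    folds: dict = field(default_factory=dict)  # condition -> experiment -> table
    fitness: dict = field(default_factory=dict)  # experiment -> Series
    competitive_index: dict = field(default_factory=dict)  # cond -> exp -> Series
    call_tables: dict = field(default_factory=dict)  # cond -> exp -> DataFrame
    resistant_sets: dict = field(default_factory=dict)  # cond -> exp -> frozenset
    cores: dict = field(default_factory=dict)  # condition -> CoreSet


def _parse_profile_meta(profiles: pd.DataFrame) -> pd.DataFrame:
    meta = []
    for pid in profiles.columns:
        cell_line, condition, experiment, bio_rep, timepoint = pid.split(":")
        meta.append(
            {
                "profile_id": pid,
                "cell_line": cell_line,
                "condition": condition,
                "experiment": experiment,
                "bio_rep": bio_rep,
                "timepoint": timepoint,
            }
        )
    return pd.DataFrame(meta).set_index("profile_id")


def analyze_profiles(
    profiles: pd.DataFrame,
    nt_label: str = "NT",
    t0_label: str = "T0",
    trelapse_label: str = "Trelapse",
    alpha: float = 0.05,
    top_k: int = 3,
) -> AnalysisResult:
    """Run the full clonal-dynamics analysis on QC'd profiles.

    Expects profile ids of the form cell_line:condition:experiment:bio_rep:
    timepoint (the output of the QC pipeline).  Per experiment, fold
    variations compare each Trelapse profile with that experiment's T0;
    fitness is the mean NT fold; resistant sets and cross-experiment cores
    are computed per treatment condition.
    """
    meta = _parse_profile_meta(profiles)
    experiments = sorted(meta["experiment"].unique())
    conditions = sorted(meta["condition"].unique())
    nt_trelapse = meta[
        (meta["condition"] == nt_label) & (meta["timepoint"] == trelapse_label)
    ].index

    # Per-profile diversity and richness (normalized to the NT Trelapse mean)
    nt_profiles = [profiles[c] for c in nt_trelapse]
    rows = []
    for pid in profiles.columns:
        profile = profiles[pid]
        entry = {
            "profile_id": pid,
            "shannon_h": stats.shannon_index(profile),
            "richness": int((profile > 0).sum()),
        }
        if len(nt_profiles) > 0:
            entry["normalized_richness"] = stats.barcode_richness(
                profile, nt_profiles
            )
        top_ids, top_sum = stats.top_clones_summary(profile, top_k)
        entry["top_clones"] = ",".join(top_ids)
        entry["top_clones_frequency"] = top_sum
        rows.append(entry)
    diversity = pd.DataFrame(rows).set_index("profile_id")

    result = AnalysisResult(
        profiles=profiles,
        qc_report=None,  # attached by analyze_counts
        profile_meta=meta,
        diversity=diversity,
    )

    # Fold tables per condition and experiment
    for cond in conditions:
        result.folds[cond] = {}
        for exp in experiments:
            t0_cols = meta[
                (meta["experiment"] == exp) & (meta["timepoint"] == t0_label)
            ].index
            rep_cols = meta[
                (meta["experiment"] == exp)
                & (meta["condition"] == cond)
                & (meta["timepoint"] == trelapse_label)
            ].index
            if len(t0_cols) == 0 or len(rep_cols) == 0:
                continue
            result.folds[cond][exp] = stats.fold_change_table(
                profiles, t0_cols[0], list(rep_cols)
            )

    for exp in experiments:
        nt_folds = result.folds.get(nt_label, {}).get(exp)
        if nt_folds is None:
            continue
        result.fitness[exp] = stats.fitness(nt_folds)

    # Resistant calling per treatment arm, plus competitive index
    for cond in conditions:
        if cond == nt_label:
            continue
        result.call_tables[cond] = {}
        result.resistant_sets[cond] = {}
        result.competitive_index[cond] = {}
        for exp, treat_folds in result.folds.get(cond, {}).items():
            nt_folds = result.folds.get(nt_label, {}).get(exp)
            if nt_folds is None:
                continue
            rep_cols = meta[
                (meta["experiment"] == exp)
                & (meta["condition"] == cond)
                & (meta["timepoint"] == trelapse_label)
            ].index
            trelapse = profiles[list(rep_cols)]
            resistant, table = selection.call_resistant_set(
                treat_folds, nt_folds, treatment_trelapse=trelapse, alpha=alpha
            )
            result.call_tables[cond][exp] = table
            result.resistant_sets[cond][exp] = resistant
            result.competitive_index[cond][exp] = stats.competitive_index(
                treat_folds, nt_folds
            )
        sets = [
            result.resistant_sets[cond][exp]
            for exp in sorted(result.resistant_sets[cond])
        ]
        if len(sets) >= 2:
            result.cores[cond] = selection.core_overlap(
                sets, labels=sorted(result.resistant_sets[cond])
            )
    return result


def analyze_counts(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    qc_config: qc_mod.QCConfig | None = None,
    **kwargs,
) -> AnalysisResult:
    """QC a raw count matrix and run the full analysis on the survivors."""
    profiles, report = qc_mod.run_qc(counts, sheet, qc_config)
    result = analyze_profiles(profiles, **kwargs)
    result.qc_report = report
    return result
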