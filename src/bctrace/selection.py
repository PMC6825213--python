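"""Identification of chemoresistant barcode clones.

A clone is called for each barcode by comparing its T0 -> Trelapse fold
variations under a treatment against the matching untreated (NT) folds with
a per-barcode two-sample test.  Clones whose folds are NOT significantly
decreased relative to NT ("equal or increased") are classed resistant; the
consistently resistant core is the intersection of per-experiment resistant
sets, mirroring the Venn analysis of multi-experiment relapse data.

Default test: Welch's unequal-variance t on log2-transformed folds, with a
pseudocount of half the smallest positive fold in the comparison so that
eliminated clones (fold 0) remain testable.  No multiplicity correction is
applied by default (the calling rule is per-barcode P < alpha);
Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class SelectionError(ValueError):
    pass


CLASS_DECREASED = "decreased"
CLASS_EQUAL = "equal"
CLASS_INCREASED = "increased"


@dataclass
class CoreSet:
    """Intersection of per-experiment resistant sets, with provenance."""

    barcodes: frozenset[str]
    source_sets: list[frozenset[str]] = field(default_factory=list)
    source_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.source_sets:
            if not self.barcodes <= s:
                raise SelectionError("core is not a subset of a source set")

    def __len__(self) -> int:
        return len(self.barcodes)

    def to_text(self) -> str:
        lines = ["# core set"]
        for lab, s in zip(self.source_labels, self.source_sets):
            lines.append(f"# source {lab}: {len(s)} barcodes")
        lines.extend(sorted(self.barcodes))
        return "\n".join(lines) + "\n"


def _welch_log2(
    treatment: np.ndarray, nt: np.ndarray
) -> tuple[float, float]:
    """Welch t statistic and two-sided p on log2(fold + pseudocount).

    The pseudocount is half the minimum positive fold across both arms;
    if every fold is zero the comparison carries no information (p = 1).
    Degenerate zero-variance cases are resolved exactly: equal constant
    arms give p = 1, distinct constant arms give p = 0.
    """
    pooled = np.concatenate([treatment, nt])
    positive = pooled[pooled > 0]
    if positive.size == 0:
        return 0.0, 1.0
    pseudo = positive.min() / 2.0
    a = np.log2(treatment + pseudo)
    b = np.log2(nt + pseudo)
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        return (0.0, 1.0) if a[0] == b[0] else (np.inf * np.sign(a[0] - b[0]), 0.0)
    with warnings.catch_warnings():
        # near-constant arms trigger a scipy precision warning; the exactly
        # constant cases are resolved above
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, equal_var=False)  # Welch
    return float(t), float(p)


def _student_raw(treatment: np.ndarray, nt: np.ndarray) -> tuple[float, float]:
    if np.ptp(treatment) == 0.0 and np.ptp(nt) == 0.0:
        d = treatment[0] - nt[0]
        return (0.0, 1.0) if d == 0 else (np.inf * np.sign(d), 0.0)
    t, p = sps.ttest_ind(treatment, nt, equal_var=True)
    return float(t), float(p)


def classify_barcode(
    treatment_folds: Sequence[float],
    nt_folds: Sequence[float],
    alpha: float = 0.05,
    method: str = "welch_log2",
) -> dict:
    """Classify one barcode's treatment folds against its NT folds.

    Returns a dict with the mean folds, test statistic, p-value, one of the
    classes decreased / equal / increased, and the resistant flag (class is
    not decreased).  Requires >= 2 defined folds per arm.
    """
    t_arr = np.asarray(treatment_folds, dtype=float)
    n_arr = np.asarray(nt_folds, dtype=float)
    t_arr = t_arr[~np.isnan(t_arr)]
    n_arr = n_arr[~np.isnan(n_arr)]
    if t_arr.size < 2 or n_arr.size < 2:
        raise SelectionError(
            "insufficient replication: need >= 2 defined folds per arm"
        )
    if method == "welch_log2":
        stat, p = _welch_log2(t_arr, n_arr)
    elif method == "student_raw":
        stat, p = _student_raw(t_arr, n_arr)
    else:
        raise SelectionError(f"unknown test method {method!r}")
    mean_t = float(t_arr.mean())
    mean_n = float(n_arr.mean())
    if p < alpha and mean_t < mean_n:
        cls = CLASS_DECREASED
    elif p < alpha and mean_t > mean_n:
        cls = CLASS_INCREASED
    else:
        cls = CLASS_EQUAL
    return {
        "mean_treatment_fold": mean_t,
        "mean_nt_fold": mean_n,
        "statistic": stat,
        "p_value": p,
        "class": cls,
        "resistant": cls != CLASS_DECREASED,
    }


def call_resistant_set(
    treatment_folds: pd.DataFrame,
    nt_folds: pd.DataFrame,
    treatment_trelapse: pd.DataFrame | None = None,
    alpha: float = 0.05,
    method: str = "welch_log2",
    bh_correct: bool = False,
) -> tuple[frozenset[str], pd.DataFrame]:
    """Resistant ("equal or increased") barcode set for one experiment.

    ``treatment_folds`` and ``nt_folds`` are barcode x replicate fold
    tables; barcodes undetected at T0 carry NaN and are never classified.
    When ``treatment_trelapse`` (barcode x replicate frequency table) is
    given, a resistant call additionally requires a nonzero mean Trelapse
    frequency in the treatment arm, so clones never observed in relapses
    cannot be called "equal".

    Returns the resistant set and the full per-barcode call table.
    """
    shared = treatment_folds.index.intersection(nt_folds.index)
    rows = []
    for bc in shared:
        t_arr = treatment_folds.loc[bc].to_numpy(dtype=float)
        n_arr = nt_folds.loc[bc].to_numpy(dtype=float)
        # classified barcodes must be detected at T0 in both arms
        if np.isnan(t_arr).all() or np.isnan(n_arr).all():
            continue
        t_def = t_arr[~np.isnan(t_arr)]
        n_def = n_arr[~np.isnan(n_arr)]
        if t_def.size < 2 or n_def.size < 2:
            raise SelectionError(
                f"insufficient replication for barcode {bc!r}: "
                f"{t_def.size} treatment / {n_def.size} NT folds"
            )
        row = classify_barcode(t_def, n_def, alpha=alpha, method=method)
        row["barcode_id"] = bc
        rows.append(row)
    if not rows:
        raise SelectionError("no barcode is classifiable (none detected at T0)")
    table = pd.DataFrame(rows).set_index("barcode_id")

    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        reject, q, _, _ = multipletests(
            table["p_value"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        table["q_value"] = q
        sig = reject
        lower = table["mean_treatment_fold"] < table["mean_nt_fold"]
        higher = table["mean_treatment_fold"] > table["mean_nt_fold"]
        table["class"] = np.where(
            sig & lower, CLASS_DECREASED, np.where(sig & higher, CLASS_INCREASED, CLASS_EQUAL)
        )
        table["resistant"] = table["class"] != CLASS_DECREASED

    if treatment_trelapse is not None:
        mean_freq = treatment_trelapse.reindex(table.index).mean(axis=1)
        table["detected_trelapse"] = mean_freq > 0
        table.loc[~table["detected_trelapse"], "resistant"] = False
    resistant = frozenset(table.index[table["resistant"]].astype(str))
    return resistant, table


def core_overlap(
    resistant_sets: Sequence[frozenset[str] | set[str]],
    labels: Sequence[str] | None = None,
) -> CoreSet:
    """Intersection of per-experiment resistant sets (the Venn core).

    Also used one level up to intersect treatment cores (e.g. the Doxo core
    with the Doxo+Cyta core).  Requires at least two sets.
    """
    if len(resistant_sets) < 2:
        raise SelectionError("core overlap requires >= 2 resistant sets")
    sets = [frozenset(s) for s in resistant_sets]
    core = frozenset.intersection(*sets)
    if labels is None:
        labels = [f"set_{i + 1}" for i in range(len(sets))]
    return CoreSet(core, sets, list(labels))
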