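"""Clone-level descriptive statistics for barcode-tracing experiments.

Covers Shannon-Weaver diversity of a clonal profile, Pearson correlation of
clonal architectures, barcode richness normalized to untreated controls,
per-clone T0 -> Trelapse fold variation, fitness (fold variation under no
treatment), competitive index (treatment fold normalized to fitness),
top-clone summaries and the IC50 resistance ratio.

All profiles are frequency vectors (pandas Series indexed by barcode id)
summing to 1.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_SUM_TOL = 1e-6


class StatsError(ValueError):
    pass


def _check_normalized(profile: pd.Series, what: str = "profile") -> None:
    total = float(profile.sum())
    if abs(total - 1.0) > _SUM_TOL:
        raise StatsError(f"{what} is not normalized (sums to {total:.6g})")
    if (profile < 0).any():
        raise StatsError(f"{what} contains negative frequencies")


def shannon_index(profile: pd.Series) -> float:
    """Shannon-Weaver diversity H = -sum(x_i * ln(x_i)) in nats.

    Zero frequencies contribute 0 by the usual x*ln(x) -> 0 convention.
    H ranges from 0 (single clone) to ln(N) (N clones, uniform).
    """
    _check_normalized(profile)
    x = profile.to_numpy(dtype=float)
    x = x[x > 0]
    return float(-(x * np.log(x)).sum())


def architecture_correlation(
    profile_a: pd.Series, profile_b: pd.Series, log_transform: bool = False
) -> float:
    """Pearson r between two clonal architectures.

    Profiles are aligned on the union of their barcode sets, with missing
    barcodes treated as frequency 0.  Returns NaN when either vector has
    zero variance (r undefined).
    """
    union = profile_a.index.union(profile_b.index)
    a = profile_a.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    b = profile_b.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    if log_transform:
        a = np.log10(a * 1e5 + 1.0)
        b = np.log10(b * 1e5 + 1.0)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def barcode_richness(
    profile: pd.Series, nt_profiles: Sequence[pd.Series]
) -> float:
    """Number of detected barcodes, normalized to the untreated mean.

    Richness is the count of barcodes with frequency > 0; the result is that
    count divided by the mean richness across the untreated (NT) reference
    profiles.
    """
    if len(nt_profiles) == 0:
        raise StatsError("empty NT reference set")
    detected = int((profile > 0).sum())
    nt_mean = float(np.mean([(p > 0).sum() for p in nt_profiles]))
    if nt_mean == 0:
        raise StatsError("NT references detect no barcodes")
    return detected / nt_mean


def fold_change(
    t0: pd.Series,
    trelapse: pd.Series,
    zero_t0_policy: str = "exclude",
) -> pd.Series:
    """Per-barcode frequency fold variation between T0 and Trelapse.

    fold_i = freq_i(Trelapse) / freq_i(T0) for barcodes detected at T0.
    Barcodes absent at T0 are NaN under the default ``exclude`` policy; the
    ``pseudocount`` policy substitutes half the smallest positive T0
    frequency so late-appearing clones can be examined in sensitivity
    analyses.
    """
    _check_normalized(t0, "T0 profile")
    _check_normalized(trelapse, "Trelapse profile")
    union = t0.index.union(trelapse.index)
    t0u = t0.reindex(union, fill_value=0.0)
    t1u = trelapse.reindex(union, fill_value=0.0)
    if zero_t0_policy == "exclude":
        denom = t0u.where(t0u > 0)
    elif zero_t0_policy == "pseudocount":
        positive = t0u[t0u > 0]
        if positive.empty:
            raise StatsError("T0 profile has no detected barcodes")
        denom = t0u.where(t0u > 0, positive.min() / 2.0)
    else:
        raise StatsError(f"unknown zero_t0_policy {zero_t0_policy!r}")
    folds = t1u / denom
    folds.name = "fold"
    return folds


def fitness(nt_folds: pd.DataFrame) -> pd.Series:
    """Per-clone fitness: mean T0->Trelapse fold across untreated replicates.

    ``nt_folds`` is a barcode x replicate table of fold variations (NaN for
    barcodes undefined in a replicate).  A barcode with no defined fold in
    any replicate is NaN (not applicable).
    """
    if nt_folds.shape[1] < 1:
        raise StatsError("fitness requires at least one NT fold column")
    return nt_folds.mean(axis=1, skipna=True).rename("fitness")


def competitive_index(
    treatment_folds: pd.DataFrame,
    nt_folds: pd.DataFrame,
    geometric: bool = False,
) -> pd.Series:
    """Competitive index: mean treatment fold / mean NT fold (fitness).

    CI = 1 means the clone's T0->Trelapse behaviour under treatment matches
    its behaviour without treatment; CI > 1 means the treatment favoured it.
    NaN where either mean is undefined; +/-inf never returned -- a zero
    fitness yields NaN (flagged undefined).
    """
    if geometric:
        with np.errstate(divide="ignore"):
            t_mean = np.exp(np.log(treatment_folds).mean(axis=1, skipna=True))
            n_mean = np.exp(np.log(nt_folds).mean(axis=1, skipna=True))
    else:
        t_mean = treatment_folds.mean(axis=1, skipna=True)
        n_mean = nt_folds.mean(axis=1, skipna=True)
    ci = t_mean / n_mean.where(n_mean > 0)
    return ci.rename("competitive_index")


def top_clones_summary(
    profile: pd.Series, k: int = 3
) -> tuple[list[str], float]:
    """The k most dominant clones and their summed frequency.

    Ties at the boundary are broken by lexicographic barcode id, so the
    selection is deterministic.
    """
    if k < 1:
        raise StatsError("k must be >= 1")
    order = sorted(profile.items(), key=lambda kv: (-kv[1], str(kv[0])))
    top = order[: min(k, len(order))]
    ids = [str(bc) for bc, _ in top]
    return ids, float(sum(f for _, f in top))


def set_frequency(barcodes: Iterable[str], profile: pd.Series) -> float:
    """Summed frequency of a barcode set within a profile."""
    ids = list(barcodes)
    unknown = sorted(set(ids) - set(profile.index))
    if unknown:
        raise StatsError(f"barcodes absent from profile: {unknown}")
    return float(profile.loc[ids].sum()) if ids else 0.0


def resistance_ratio(ic50_condition: float, ic50_nt: float) -> float:
    """IC50 of a treated sample relative to the untreated control.

    Both inputs must be positive and in the same concentration units; the
    result is rounded half-up to two decimals, the convention used for
    reporting drug-resistance ratios.
    """
    if ic50_condition <= 0 or ic50_nt <= 0:
        raise StatsError("IC50 values must be positive")
    ratio = Decimal(repr(ic50_condition)) / Decimal(repr(ic50_nt))
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def fold_change_table(
    profiles: pd.DataFrame,
    t0_column: str,
    replicate_columns: Sequence[str],
    zero_t0_policy: str = "exclude",
) -> pd.DataFrame:
    """Fold variations of every barcode for several replicates of one arm.

    Convenience wrapper building a barcode x replicate fold table from a
    profile matrix: each listed replicate column is compared with the shared
    T0 column.
    """
    cols = {
        rep: fold_change(profiles[t0_column], profiles[rep], zero_t0_policy)
        for rep in replicate_columns
    }
    table = pd.DataFrame(cols)
    table.index.name = "barcode_id"
    return table
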