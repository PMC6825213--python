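"""Quality control of barcode count data.

Implements the three-gate QC used for barcoded-clone sequencing: a read-depth
gate on the mean of the two technical replicates, a Pearson-concordance gate
between technical replicates, and zeroing of "singleton" barcodes seen in
only one technical replicate.  Surviving replicate pairs are normalized and
averaged into one clonal frequency profile per biological replicate.

Gate semantics: a pair is dropped when mean depth is strictly below
``min_depth`` (default 1e4) and when Pearson r is strictly below ``min_r``
(default 0.8); the boundary values keep the sample.  Frequencies sum to 1
internally; the conventional normalized-count scale (1e5 reads per sample)
exists only at file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

NORMALIZED_TOTAL = 100_000  # export scale for normalized counts


class QCError(ValueError):
    pass


@dataclass
class QCConfig:
    min_depth: float = 10_000.0
    min_r: float = 0.8
    #: "mask_first" applies singleton masking before the concordance gate
    #: (default); "concordance_first" computes r on unmasked frequencies.
    order: str = "mask_first"
    #: compute Pearson on log10(x + 1)-transformed normalized counts
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.order not in ("mask_first", "concordance_first"):
            raise QCError(f"unknown QC order {self.order!r}")


@dataclass
class QCRecord:
    """QC outcome for one biological replicate (one A/B pair)."""

    profile_id: str
    sample_a: str
    sample_b: str
    depth_a: int
    depth_b: int
    mean_depth: float
    depth_pass: bool
    pearson_r: float | None  # None when r is undefined (zero variance)
    concordance_pass: bool
    masked_barcodes: list[str] = field(default_factory=list)
    excluded_reason: str | None = None  # primary reason, at most one

    @property
    def passed(self) -> bool:
        return self.excluded_reason is None


@dataclass
class QCReport:
    config: QCConfig
    records: list[QCRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "profile_id": r.profile_id,
                "sample_a": r.sample_a,
                "sample_b": r.sample_b,
                "mean_depth": r.mean_depth,
                "depth_pass": r.depth_pass,
                "pearson_r": np.nan if r.pearson_r is None else r.pearson_r,
                "concordance_pass": r.concordance_pass,
                "n_masked": len(r.masked_barcodes),
                "excluded_reason": r.excluded_reason or "",
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [
            f"# qc report (min_depth={self.config.min_depth:g}, "
            f"min_r={self.config.min_r:g}, order={self.config.order}, "
            f"log_transform={self.config.log_transform})"
        ]
        for r in self.records:
            status = "pass" if r.passed else f"EXCLUDED ({r.excluded_reason})"
            rtxt = "undefined" if r.pearson_r is None else f"{r.pearson_r:.6f}"
            lines.append(
                f"{r.profile_id}\t{status}\tmean_depth={r.mean_depth:.1f}\t"
                f"r={rtxt}\tmasked={len(r.masked_barcodes)}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Individual gates
# ---------------------------------------------------------------------------


def filter_low_depth(
    total_a: float, total_b: float, min_depth: float = 10_000.0
) -> bool:
    """Keep a technical-replicate pair iff mean total depth >= min_depth."""
    if total_a is None or total_b is None:
        raise QCError("unpaired technical replicate")
    return (total_a + total_b) / 2.0 >= min_depth


def mask_singleton_barcodes(
    rep_a: pd.Series, rep_b: pd.Series
) -> tuple[pd.Series, pd.Series, list[str]]:
    """Zero barcodes detected in exactly one technical replicate.

    A positive count in one replicate with zero in the other indicates low
    confidence; such barcodes are set to 0 in both replicates and reported.
    """
    if not rep_a.index.equals(rep_b.index):
        raise QCError("technical replicates indexed by different barcode sets")
    singleton = (rep_a > 0) != (rep_b > 0)
    masked = list(rep_a.index[singleton])
    rep_a = rep_a.where(~singleton, 0)
    rep_b = rep_b.where(~singleton, 0)
    return rep_a, rep_b, masked


def normalize_profile(counts: pd.Series) -> pd.Series:
    """Convert counts to frequencies summing to 1 (zeros retained)."""
    total = counts.sum()
    if total <= 0:
        raise QCError("empty sample: all counts are zero")
    if (counts < 0).any():
        raise QCError("negative counts")
    return counts / total


def concordance_filter(
    freq_a: pd.Series,
    freq_b: pd.Series,
    min_r: float = 0.8,
    log_transform: bool = False,
) -> tuple[bool, float | None]:
    """Pearson-concordance gate between technical replicates.

    Returns (pass, r); r is None (and the gate fails) when either vector has
    zero variance.
    """
    if not freq_a.index.equals(freq_b.index):
        raise QCError("technical replicates indexed by different barcode sets")
    a = freq_a.to_numpy(dtype=float)
    b = freq_b.to_numpy(dtype=float)
    if log_transform:
        a = np.log10(a * NORMALIZED_TOTAL + 1.0)
        b = np.log10(b * NORMALIZED_TOTAL + 1.0)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return False, None
    r = float(np.corrcoef(a, b)[0, 1])
    return r >= min_r, r


def average_replicates(freq_a: pd.Series, freq_b: pd.Series) -> pd.Series:
    """Mean of two normalized technical-replicate profiles, renormalized."""
    mean = (freq_a + freq_b) / 2.0
    total = mean.sum()
    if total <= 0:
        raise QCError("cannot average: both replicates empty")
    return mean / total


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def profile_key(row: pd.Series) -> str:
    return (
        f"{row['cell_line']}:{row['condition']}:{row['experiment']}"
        f":{row['bio_rep']}:{row['timepoint']}"
    )


def run_qc(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    config: QCConfig | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Run the full QC pipeline over a count matrix.

    Per biological replicate (an A/B technical-replicate pair), applies in
    order: depth gate -> singleton masking -> normalization -> concordance
    gate -> averaging (the alternative order runs the concordance gate on
    unmasked frequencies).  Returns a barcode x profile frequency matrix
    (columns sum to 1) and a :class:`QCReport` recording every decision.
    """
    config = config or QCConfig()
    report = QCReport(config=config)
    profiles: dict[str, pd.Series] = {}

    groups = sheet.groupby(
        ["cell_line", "condition", "experiment", "bio_rep", "timepoint"],
        sort=True,
    )
    for _, grp in groups:
        reps = {row["tech_rep"]: row["sample_id"] for _, row in grp.iterrows()}
        if set(reps) != {"A", "B"}:
            # unpaired replicates cannot pass the pairwise gates
            continue
        pid = profile_key(grp.iloc[0])
        a_raw = counts[reps["A"]]
        b_raw = counts[reps["B"]]
        depth_a, depth_b = int(a_raw.sum()), int(b_raw.sum())
        mean_depth = (depth_a + depth_b) / 2.0
        rec = QCRecord(
            profile_id=pid,
            sample_a=reps["A"],
            sample_b=reps["B"],
            depth_a=depth_a,
            depth_b=depth_b,
            mean_depth=mean_depth,
            depth_pass=filter_low_depth(depth_a, depth_b, config.min_depth),
            pearson_r=None,
            concordance_pass=False,
        )
        report.records.append(rec)
        if not rec.depth_pass:
            rec.excluded_reason = "low_depth"
            continue

        if config.order == "mask_first":
            a_masked, b_masked, masked = mask_singleton_barcodes(a_raw, b_raw)
            rec.masked_barcodes = masked
            if a_masked.sum() == 0 or b_masked.sum() == 0:
                rec.excluded_reason = "empty_after_masking"
                continue
            fa, fb = normalize_profile(a_masked), normalize_profile(b_masked)
            ok, r = concordance_filter(fa, fb, config.min_r, config.log_transform)
            rec.pearson_r, rec.concordance_pass = r, ok
            if not ok:
                rec.excluded_reason = "discordant"
                continue
        else:  # concordance_first
            fa0, fb0 = normalize_profile(a_raw), normalize_profile(b_raw)
            ok, r = concordance_filter(fa0, fb0, config.min_r, config.log_transform)
            rec.pearson_r, rec.concordance_pass = r, ok
            if not ok:
                rec.excluded_reason = "discordant"
                continue
            a_masked, b_masked, masked = mask_singleton_barcodes(a_raw, b_raw)
            rec.masked_barcodes = masked
            if a_masked.sum() == 0 or b_masked.sum() == 0:
                rec.excluded_reason = "empty_after_masking"
                continue
            fa, fb = normalize_profile(a_masked), normalize_profile(b_masked)

        profiles[pid] = average_replicates(fa, fb)

    if not profiles:
        raise QCError("no samples survived QC")
    out = pd.DataFrame(profiles)
    out.index.name = "barcode_id"
    return out, report


def write_profiles(profiles: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write profiles as normalized counts on the conventional 1e5 scale."""
    (profiles * NORMALIZED_TOTAL).to_csv(path, sep="\t", index_label="barcode_id")


def load_profiles(path: Union[str, Path]) -> pd.DataFrame:
    """Read a profile table written by :func:`write_profiles`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "barcode_id"
    return df / NORMALIZED_TOTAL
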