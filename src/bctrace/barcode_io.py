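"""Reading, writing and validation of barcode-tracing data.

Handles the reference barcode library, FASTQ read streams, barcode x sample
read-count matrices and the sample sheet that ties samples to conditions,
experiments, replicate pairs and timepoints.  Reads are assigned to library
barcodes by locating a common anchor (annealing-region) sequence and matching
the 15 nt that immediately follow it exactly against the library's 15-nt
barcode prefixes.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import pandas as pd
from Bio import SeqIO

PREFIX_LEN = 15
DNA_ALPHABET = frozenset("ACGT")

#: Condition labels recognised in sample sheets.  Extra labels are allowed
#: when explicitly passed to :func:`load_sample_sheet`.
DEFAULT_CONDITIONS = (
    "NT",
    "DAC",
    "Cyta",
    "Doxo",
    "Doxo+Cyta",
    "Doxo+Cyta+DAC",
)

SHEET_COLUMNS = (
    "sample_id",
    "cell_line",
    "condition",
    "experiment",
    "bio_rep",
    "tech_rep",
    "timepoint",
)


class BarcodeIOError(ValueError):
    """Raised for malformed or mutually inconsistent input files."""


# ---------------------------------------------------------------------------
# Barcode library
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BarcodeLibrary:
    """Reference set of barcode identifiers and sequences.

    Barcode identity of a read is decided by the first ``PREFIX_LEN``
    nucleotides of the barcode, so the 15-nt prefixes must be pairwise
    distinct across the library.
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    prefix_to_id: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise BarcodeIOError("ids and sequences differ in length")
        if len(self.ids) == 0:
            raise BarcodeIOError("empty library")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise BarcodeIOError(f"duplicate barcode ids: {dupes}")
        prefix_map: dict[str, str] = {}
        collisions: dict[str, list[str]] = {}
        for bc_id, seq in zip(self.ids, self.sequences):
            seq = seq.upper()
            if len(seq) < PREFIX_LEN:
                raise BarcodeIOError(
                    f"barcode {bc_id!r}: sequence shorter than {PREFIX_LEN} nt"
                )
            if not set(seq) <= DNA_ALPHABET:
                raise BarcodeIOError(
                    f"barcode {bc_id!r}: sequence contains non-ACGT characters"
                )
            prefix = seq[:PREFIX_LEN]
            if prefix in prefix_map:
                collisions.setdefault(prefix, [prefix_map[prefix]]).append(bc_id)
            else:
                prefix_map[prefix] = bc_id
        if collisions:
            detail = "; ".join(
                f"{p}: {', '.join(ids)}" for p, ids in sorted(collisions.items())
            )
            raise BarcodeIOError(f"duplicate {PREFIX_LEN}-nt prefixes: {detail}")
        object.__setattr__(self, "prefix_to_id", prefix_map)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, bc_id: str) -> bool:
        return bc_id in set(self.ids)


def load_library(path: Union[str, Path]) -> BarcodeLibrary:
    """Load a two-column (id, sequence) tab-delimited barcode library."""
    path = Path(path)
    ids: list[str] = []
    seqs: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise BarcodeIOError(
                    f"{path}: malformed library line {lineno}: {line!r}"
                )
            ids.append(parts[0])
            seqs.append(parts[1].upper())
    if not ids:
        raise BarcodeIOError(f"{path}: empty library")
    return BarcodeLibrary(tuple(ids), tuple(seqs))


def write_library(library: BarcodeLibrary, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for bc_id, seq in zip(library.ids, library.sequences):
            fh.write(f"{bc_id}\t{seq}\n")


# ---------------------------------------------------------------------------
# FASTQ barcode extraction
# ---------------------------------------------------------------------------


@dataclass
class ExtractionReport:
    """Per-sample tally of barcode extraction outcomes."""

    total_reads: int = 0
    assigned: int = 0
    unassigned: int = 0
    rescued: int = 0  # assigned via Hamming-1 rescue (off by default)

    @property
    def conserved(self) -> bool:
        return self.assigned + self.unassigned == self.total_reads


def _open_maybe_gzip(path: Union[str, Path]) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _hamming1_candidates(prefix: str) -> Iterable[str]:
    for i, base in enumerate(prefix):
        for sub in "ACGT":
            if sub != base:
                yield prefix[:i] + sub + prefix[i + 1 :]


def extract_barcode_counts(
    reads: Union[str, Path, Iterable],
    library: BarcodeLibrary,
    anchor: str,
    hamming_rescue: bool = False,
) -> tuple[pd.Series, ExtractionReport]:
    """Count reads per library barcode from a FASTQ stream.

    Each read is scanned for the first exact occurrence of ``anchor``; the
    15 nt following it are matched exactly against library barcode prefixes.
    Reads with no anchor, a truncated barcode window, or an unknown prefix
    are tallied as unassigned.  With ``hamming_rescue`` a prefix within
    Hamming distance 1 of exactly one library prefix is rescued and counted
    separately in the report.

    Returns a counts Series indexed by every library barcode id (zeros kept)
    and an :class:`ExtractionReport`.
    """
    anchor = anchor.upper()
    if not anchor:
        raise BarcodeIOError("anchor must be non-empty")
    if isinstance(reads, (str, Path)):
        handle = _open_maybe_gzip(reads)
        records = SeqIO.parse(handle, "fastq")
    else:
        handle = None
        records = SeqIO.parse(reads, "fastq") if hasattr(reads, "read") else reads

    counts: dict[str, int] = dict.fromkeys(library.ids, 0)
    report = ExtractionReport()
    try:
        for idx, rec in enumerate(records):
            try:
                seq = str(rec.seq).upper()
            except Exception as exc:  # pragma: no cover - malformed record
                raise BarcodeIOError(f"unreadable FASTQ record {idx}") from exc
            report.total_reads += 1
            if len(anchor) > len(seq):
                raise BarcodeIOError(
                    f"anchor ({len(anchor)} nt) longer than read {idx} "
                    f"({len(seq)} nt)"
                )
            pos = seq.find(anchor)
            if pos < 0:
                report.unassigned += 1
                continue
            start = pos + len(anchor)
            prefix = seq[start : start + PREFIX_LEN]
            if len(prefix) < PREFIX_LEN:
                report.unassigned += 1
                continue
            bc_id = library.prefix_to_id.get(prefix)
            if bc_id is None and hamming_rescue:
                hits = {
                    library.prefix_to_id[c]
                    for c in _hamming1_candidates(prefix)
                    if c in library.prefix_to_id
                }
                if len(hits) == 1:
                    bc_id = hits.pop()
                    report.rescued += 1
            if bc_id is None:
                report.unassigned += 1
            else:
                counts[bc_id] += 1
                report.assigned += 1
    finally:
        if handle is not None:
            handle.close()
    series = pd.Series(counts, name="count", dtype=int)
    return series, report


# ---------------------------------------------------------------------------
# Count matrices and sample sheets
# ---------------------------------------------------------------------------


def load_counts(path: Union[str, Path]) -> pd.DataFrame:
    """Load a barcode x sample count matrix (first column barcode_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "barcode_id"
    for col in df.columns:
        vals = df[col]
        if not (vals == vals.astype(int)).all():
            raise BarcodeIOError(f"{path}: non-integer count in sample {col!r}")
        if (vals < 0).any():
            bad = vals[vals < 0].index[0]
            raise BarcodeIOError(
                f"{path}: negative count for barcode {bad!r} in sample {col!r}"
            )
    return df.astype(int)


def write_counts(counts: pd.DataFrame, path: Union[str, Path]) -> None:
    counts.to_csv(path, sep="\t", index_label="barcode_id")


def load_sample_sheet(
    path: Union[str, Path],
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    extra_conditions: Iterable[str] = (),
) -> pd.DataFrame:
    """Load and validate a sample sheet.

    Checks unique sample ids, the declared condition vocabulary, and that
    every biological replicate comes as an (A, B) technical-replicate pair;
    unpaired replicates are tolerated only when flagged with tech_rep
    ``unpaired``.
    """
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise BarcodeIOError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dupes = sorted(sheet.loc[sheet["sample_id"].duplicated(), "sample_id"])
        raise BarcodeIOError(f"{path}: duplicate sample ids {dupes}")
    vocab = set(conditions) | set(extra_conditions)
    bad = sorted(set(sheet["condition"]) - vocab)
    if bad:
        raise BarcodeIOError(f"{path}: unknown condition labels {bad}")
    for key, grp in sheet.groupby(
        ["cell_line", "condition", "experiment", "bio_rep", "timepoint"]
    ):
        reps = sorted(grp["tech_rep"])
        if reps not in (["A", "B"], ["unpaired"]):
            raise BarcodeIOError(
                f"{path}: biological replicate {key} has technical replicates "
                f"{reps}; expected ['A', 'B'] or ['unpaired']"
            )
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: Union[str, Path]) -> None:
    sheet.to_csv(path, sep="\t", index=False, columns=list(SHEET_COLUMNS))


def load_experiment(
    counts_path: Union[str, Path],
    sheet_path: Union[str, Path],
    library: BarcodeLibrary | None = None,
    **sheet_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load a count matrix and its sample sheet, cross-validated.

    Every matrix column must have a sample-sheet row and vice versa; with a
    library given, every matrix barcode must belong to it.
    """
    counts = load_counts(counts_path)
    sheet = load_sample_sheet(sheet_path, **sheet_kwargs)
    matrix_samples = set(counts.columns)
    sheet_samples = set(sheet["sample_id"])
    only_matrix = sorted(matrix_samples - sheet_samples)
    only_sheet = sorted(sheet_samples - matrix_samples)
    if only_matrix or only_sheet:
        raise BarcodeIOError(
            "count matrix and sample sheet disagree: "
            f"matrix-only samples {only_matrix}, sheet-only samples {only_sheet}"
        )
    if library is not None:
        unknown = sorted(set(counts.index) - set(library.ids))
        if unknown:
            raise BarcodeIOError(
                f"count matrix contains barcodes absent from library: {unknown[:10]}"
            )
    return counts, sheet
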