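"""Per-sample consensus barcode calling from amplicon reads.

Each sequencing sample holds reads from (ideally) a single transgenic
F1 fly, whose integrated construct carries one fixed-length DNA barcode
between a known forward-primer core and a trailing flank.  Calling
proceeds in two stages:

1. **Trim** — locate the forward-primer core near the 5' end of each
   read, trying the known frameshift-pad offsets in order and allowing a
   bounded number of substitutions (Hamming distance, no indels), and
   keep the ``barcode_length`` bases immediately 3' of the core.
2. **Call** — samples with fewer than ``min_reads`` trimmed reads are
   excluded (``insufficient_reads``); otherwise a per-position base
   composition is tallied over the trimmed reads and the sample is
   ``called`` with the modal sequence only if, at *every* position, the
   modal base fraction strictly exceeds ``consensus_threshold`` (default
   >80%); any position failing the rule makes the sample ``mixed``.

Ambiguous bases (N etc.) count toward each position's denominator but
can never be the modal base, so heavy ambiguity pushes a sample toward
``mixed`` rather than toward a spurious call.  Base qualities are read
but ignored: the consensus rule uses base identity only.
"""

from __future__ import annotations

import enum
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

if TYPE_CHECKING:  # pragma: no cover
    from tagem.synthetic_data import ConstructLayout

logger = logging.getLogger(__name__)

__all__ = [
    "SampleReadSet",
    "CallingParams",
    "CallStatus",
    "BarcodeCall",
    "locate_and_trim",
    "trim_reads",
    "call_sample",
    "call_plate",
    "read_fastq",
    "write_fastq",
    "calls_to_frame",
    "write_calls_tsv",
]

#: Row order of the composition matrix.
COMPOSITION_ROWS = ("A", "C", "G", "T", "other")

# byte value -> composition row index; anything not ACGT maps to row 4
_BASE_ROW = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_ROW[_b] = _i


@dataclass
class SampleReadSet:
    """Reads belonging to one demultiplexed sample."""

    sample_id: str
    reads: List[Tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def sequences(self) -> List[str]:
        return [seq for seq, _ in self.reads]


@dataclass(frozen=True)
class CallingParams:
    """Tunable thresholds of the trimming and consensus rules."""

    min_reads: int = 500
    consensus_threshold: float = 0.80
    barcode_length: int = 14
    primer_max_mismatches: int = 2
    pad_search_offsets: Tuple[int, ...] = (0, 2, 4, 6)
    require_flank: bool = False  # strict mode: also check the trailing flank prefix
    flank_check_length: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.consensus_threshold < 1.0:
            raise ValueError("consensus_threshold must be in (0, 1)")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")


class CallStatus(str, enum.Enum):
    CALLED = "called"
    MIXED = "mixed"
    INSUFFICIENT_READS = "insufficient_reads"


@dataclass
class BarcodeCall:
    """Calling outcome for one sample.

    ``composition`` is a 5 x barcode_length count matrix (rows A, C, G,
    T, other) over the trimmed reads; its column sums equal
    ``n_reads_trimmed``.
    """

    sample_id: str
    status: CallStatus
    barcode: Optional[str]
    n_reads_total: int
    n_reads_trimmed: int
    composition: np.ndarray

    @property
    def modal_fractions(self) -> np.ndarray:
        """Per-position fraction of the modal A/C/G/T base among trimmed reads."""
        if self.n_reads_trimmed == 0:
            return np.zeros(self.composition.shape[1])
        return self.composition[:4].max(axis=0) / self.n_reads_trimmed


def locate_and_trim(
    read: str, layout: "ConstructLayout", params: CallingParams
) -> Optional[str]:
    """Extract the barcode from one read, or return None (rejection).

    The forward-primer core is sought at each frameshift-pad offset in
    the order given by ``params.pad_search_offsets``; the first offset at
    which the core matches with at most ``primer_max_mismatches``
    substitutions wins.  The barcode is the ``barcode_length`` bases
    immediately 3' of the core; reads with no acceptable primer hit or
    too few remaining bases are rejected.
    """
    core = layout.forward_primer_core
    lc = len(core)
    bl = params.barcode_length
    for off in params.pad_search_offsets:
        end = off + lc
        if len(read) < end + bl:
            continue
        window = read[off:end]
        mismatches = sum(a != b for a, b in zip(window, core))
        if mismatches > params.primer_max_mismatches:
            continue
        if params.require_flank:
            k = params.flank_check_length
            flank = read[end + bl : end + bl + k]
            expected = layout.trailing_flank[:k]
            if len(flank) < len(expected) or sum(
                a != b for a, b in zip(flank, expected)
            ) > params.primer_max_mismatches:
                continue
        return read[end : end + bl]
    return None


def _encode_reads(sequences: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    """Pack variable-length reads into a zero-padded uint8 matrix."""
    lengths = np.fromiter((len(s) for s in sequences), dtype=np.int64, count=len(sequences))
    width = int(lengths.max()) if len(sequences) else 0
    mat = np.zeros((len(sequences), width), dtype=np.uint8)
    for i, s in enumerate(sequences):
        mat[i, : lengths[i]] = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    return mat, lengths


def trim_reads(
    reads: SampleReadSet, layout: "ConstructLayout", params: CallingParams
) -> np.ndarray:
    """Trim all reads of a sample at once.

    Returns an ``(n_trimmed, barcode_length)`` uint8 matrix of barcode
    bases, vectorised but offset-order-equivalent to calling
    :func:`locate_and_trim` on each read.
    """
    if not reads.reads:
        return np.zeros((0, params.barcode_length), dtype=np.uint8)
    mat, lengths = _encode_reads(reads.sequences())
    core = np.frombuffer(layout.forward_primer_core.encode("ascii"), dtype=np.uint8)
    lc = core.size
    bl = params.barcode_length
    chosen = np.full(mat.shape[0], -1, dtype=np.int64)
    for off in params.pad_search_offsets:
        end = off + lc
        if end + bl > mat.shape[1]:
            continue
        candidate = (chosen < 0) & (lengths >= end + bl)
        if not candidate.any():
            continue
        mism = (mat[:, off:end] != core).sum(axis=1)
        ok = candidate & (mism <= params.primer_max_mismatches)
        if params.require_flank:
            k = min(params.flank_check_length, len(layout.trailing_flank))
            expected = np.frombuffer(
                layout.trailing_flank[:k].encode("ascii"), dtype=np.uint8
            )
            if end + bl + k <= mat.shape[1]:
                fl_ok = (lengths >= end + bl + k) & (
                    (mat[:, end + bl : end + bl + k] != expected).sum(axis=1)
                    <= params.primer_max_mismatches
                )
            else:
                fl_ok = np.zeros(mat.shape[0], dtype=bool)
            ok &= fl_ok
        chosen[ok] = off
    trimmed = []
    for off in params.pad_search_offsets:
        rows = np.nonzero(chosen == off)[0]
        if rows.size:
            trimmed.append(mat[rows, off + lc : off + lc + bl])
    if not trimmed:
        return np.zeros((0, bl), dtype=np.uint8)
    return np.concatenate(trimmed, axis=0)


def _composition(trimmed: np.ndarray, barcode_length: int) -> np.ndarray:
    comp = np.zeros((5, barcode_length), dtype=np.int64)
    if trimmed.size == 0:
        return comp
    rows = _BASE_ROW[trimmed]  # (n, bl) values 0..4
    for pos in range(barcode_length):
        comp[:, pos] = np.bincount(rows[:, pos], minlength=5)
    return comp


def call_sample(
    reads: SampleReadSet, layout: "ConstructLayout", params: Optional[CallingParams] = None
) -> BarcodeCall:
    """Apply the read-count filter and per-position consensus rule.

    A sample is ``called`` only when every barcode position has a single
    A/C/G/T base whose fraction of trimmed reads strictly exceeds
    ``consensus_threshold``; a position at exactly the threshold (e.g.
    800 of 1,000 reads with the default 0.80) leaves the sample
    ``mixed``.
    """
    params = params or CallingParams()
    trimmed = trim_reads(reads, layout, params)
    n_trimmed = trimmed.shape[0]
    comp = _composition(trimmed, params.barcode_length)
    if n_trimmed < params.min_reads:
        return BarcodeCall(
            reads.sample_id, CallStatus.INSUFFICIENT_READS, None,
            len(reads), n_trimmed, comp,
        )
    acgt = comp[:4]
    modal_counts = acgt.max(axis=0)
    # strict ">" on counts avoids rounding the fraction; a tied modal base
    # never counts as "a single base" regardless of threshold
    unique_modal = (acgt == modal_counts).sum(axis=0) == 1
    passes = unique_modal & (modal_counts > params.consensus_threshold * n_trimmed)
    if passes.all():
        modal_idx = acgt.argmax(axis=0)
        barcode = "".join("ACGT"[i] for i in modal_idx)
        return BarcodeCall(
            reads.sample_id, CallStatus.CALLED, barcode, len(reads), n_trimmed, comp
        )
    return BarcodeCall(
        reads.sample_id, CallStatus.MIXED, None, len(reads), n_trimmed, comp
    )


def call_plate(
    samples: Sequence[SampleReadSet],
    layout: "ConstructLayout",
    params: Optional[CallingParams] = None,
) -> List[BarcodeCall]:
    """Call every sample of a plate, preserving input order."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_ids: {dupes}")
    calls = []
    for sample in samples:
        call = call_sample(sample, layout, params)
        logger.info(
            "%s: %s (%d/%d reads trimmed)%s",
            call.sample_id,
            call.status.value,
            call.n_reads_trimmed,
            call.n_reads_total,
            f" barcode={call.barcode}" if call.barcode else "",
        )
        calls.append(call)
    return calls


def read_fastq(path: str | Path, sample_id: Optional[str] = None) -> SampleReadSet:
    """Load a Phred+33 FASTQ (optionally gzipped) into a SampleReadSet."""
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".gz").removesuffix(".fastq").removesuffix(".fq")
    opener = gzip.open if path.suffix == ".gz" else open
    reads: List[Tuple[str, str]] = []
    with opener(path, "rt") as handle:
        try:
            for _title, seq, qual in FastqGeneralIterator(handle):
                reads.append((seq.upper(), qual))
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record in {path} at record index {len(reads)}: {exc}"
            ) from exc
    return SampleReadSet(sample_id=sample_id, reads=reads)


def write_fastq(sample: SampleReadSet, path: str | Path) -> None:
    """Write a SampleReadSet as plain four-line FASTQ."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for i, (seq, qual) in enumerate(sample.reads):
            handle.write(f"@{sample.sample_id}_read{i}\n{seq}\n+\n{qual}\n")


def calls_to_frame(calls: Sequence[BarcodeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "status": [c.status.value for c in calls],
            "barcode": [c.barcode or "" for c in calls],
            "n_reads_total": [c.n_reads_total for c in calls],
            "n_reads_trimmed": [c.n_reads_trimmed for c in calls],
        }
    )


def write_calls_tsv(calls: Sequence[BarcodeCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
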