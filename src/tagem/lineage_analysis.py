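"""Per-lineage unique-insertion counting, controls, and rarefaction.

Aggregates per-sample barcode calls into the experiment's headline
quantities: how many distinct barcodes (independent germline
integration events) each injected G0 fly transmitted, the mean number
of insertions per transgenic-producing embryo, and the global
deduplicated count of unique transgenic lines.  Also provides a
sampling-saturation correction (`estimate_true_integrations`), control
validation, and rarefaction of the injected barcode library.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from tagem.barcode_calling import (
    BarcodeCall,
    CallingParams,
    CallStatus,
    SampleReadSet,
    trim_reads,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LineageTable",
    "LineageSummary",
    "ControlReport",
    "summarize_lineages",
    "validate_controls",
    "rarefaction_curve",
    "estimate_true_integrations",
]

ROLES = ("progeny", "duplicate_control", "blank")


@dataclass
class LineageTable:
    """Barcode calls grouped by G0 lineage, with sample roles."""

    lineages: Dict[str, List[BarcodeCall]] = field(default_factory=dict)
    roles: Dict[str, str] = field(default_factory=dict)  # lineage_id -> role

    @classmethod
    def from_calls(
        cls, calls: Sequence[BarcodeCall], sample_sheet: pd.DataFrame
    ) -> "LineageTable":
        """Group calls by the sample sheet's lineage assignment.

        ``sample_sheet`` needs columns sample_id, lineage_id, role; every
        call must appear in it exactly once.
        """
        required = {"sample_id", "lineage_id", "role"}
        missing = required - set(sample_sheet.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns {sorted(missing)}")
        bad_roles = set(sample_sheet["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles in sample sheet: {sorted(bad_roles)}")
        if sample_sheet["sample_id"].duplicated().any():
            dupes = sample_sheet.loc[
                sample_sheet["sample_id"].duplicated(), "sample_id"
            ].tolist()
            raise ValueError(f"duplicate sample_ids in sample sheet: {dupes}")
        meta = sample_sheet.set_index("sample_id")
        table = cls()
        for call in calls:
            if call.sample_id not in meta.index:
                raise ValueError(f"sample {call.sample_id!r} not in sample sheet")
            lineage = str(meta.at[call.sample_id, "lineage_id"])
            role = str(meta.at[call.sample_id, "role"])
            prev = table.roles.setdefault(lineage, role)
            if prev != role:
                raise ValueError(
                    f"lineage {lineage!r} mixes roles {prev!r} and {role!r}"
                )
            table.lineages.setdefault(lineage, []).append(call)
        return table

    def by_role(self, role: str) -> Dict[str, List[BarcodeCall]]:
        return {
            lid: calls
            for lid, calls in self.lineages.items()
            if self.roles.get(lid, "progeny") == role
        }


@dataclass
class ControlReport:
    n_duplicate_pairs: int
    n_matching_duplicates: int
    n_blanks: int
    n_blanks_called: int

    @property
    def blanks_pass(self) -> bool:
        return self.n_blanks_called == 0


@dataclass
class LineageSummary:
    """Derived per-experiment integration statistics.

    ``unique_barcode_counts`` maps each transgenic-producing lineage to
    the number of distinct called barcodes among its progeny;
    ``mean_insertions_per_embryo`` averages those counts;
    ``estimated_mean_insertions`` applies the saturation correction of
    :func:`estimate_true_integrations` lineage by lineage before
    averaging.  ``total_unique_insertions`` deduplicates globally, so it
    can be smaller than the sum of per-lineage counts when the same
    library barcode integrated in two embryos.
    """

    unique_barcode_counts: Dict[str, int]
    total_unique_insertions: int
    mean_insertions_per_embryo: float
    estimated_mean_insertions: float
    histogram: Dict[int, int]
    cross_lineage_collisions: Dict[str, List[str]]
    control_report: Optional[ControlReport] = None

    @property
    def n_transgenic_lineages(self) -> int:
        return len(self.unique_barcode_counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.unique_barcode_counts.items()),
            columns=["lineage_id", "unique_barcodes"],
        )


def summarize_lineages(table: LineageTable) -> LineageSummary:
    """Count distinct called barcodes per lineage and overall.

    Mixed and insufficient-read samples contribute nothing; lineages
    with zero called samples are excluded (with a warning for lineages
    that had no samples at all).  The mean is over lineages with at
    least one called barcode — i.e. per transgenic-producing embryo.
    """
    if not table.lineages:
        raise ValueError("empty lineage table")
    barcode_sets: Dict[str, set] = {}
    n_called: Dict[str, int] = {}
    for lineage_id, calls in table.by_role("progeny").items():
        if not calls:
            warnings.warn(f"lineage {lineage_id!r} has no samples; excluded")
            continue
        called = [c.barcode for c in calls if c.status is CallStatus.CALLED]
        if called:
            barcode_sets[lineage_id] = set(called)
            n_called[lineage_id] = len(called)
    counts = {lid: len(s) for lid, s in barcode_sets.items()}
    all_barcodes: Counter = Counter()
    owners: Dict[str, List[str]] = {}
    for lid, s in barcode_sets.items():
        for bc in s:
            all_barcodes[bc] += 1
            owners.setdefault(bc, []).append(lid)
    collisions = {bc: sorted(lids) for bc, lids in owners.items() if len(lids) > 1}
    if counts:
        mean = float(np.mean(list(counts.values())))
        corrected = []
        for lid, u in counts.items():
            n = n_called[lid]
            k_hat = estimate_true_integrations(u, n) if u < n else float("inf")
            # boundary (all sampled progeny distinct): fall back to the
            # observed count, a lower bound on the truth
            corrected.append(u if not np.isfinite(k_hat) else k_hat)
        est_mean = float(np.mean(corrected))
    else:
        mean = float("nan")
        est_mean = float("nan")
    try:
        control_report = validate_controls(table)
    except ValueError:
        control_report = None
    return LineageSummary(
        unique_barcode_counts=counts,
        total_unique_insertions=len(all_barcodes),
        mean_insertions_per_embryo=mean,
        estimated_mean_insertions=est_mean,
        histogram=dict(sorted(Counter(counts.values()).items())),
        cross_lineage_collisions=collisions,
        control_report=control_report,
    )


def validate_controls(table: LineageTable) -> ControlReport:
    """Check duplicate-control pairs and blank wells.

    A duplicate pair matches iff both halves were called with the same
    barcode; a blank passes iff its status is anything but ``called``.
    """
    dup = table.by_role("duplicate_control")
    n_matching = 0
    for lineage_id, calls in dup.items():
        if len(calls) != 2:
            raise ValueError(
                f"duplicate-control lineage {lineage_id!r} has {len(calls)} "
                "samples; expected a pair"
            )
        a, b = calls
        if (
            a.status is CallStatus.CALLED
            and b.status is CallStatus.CALLED
            and a.barcode == b.barcode
        ):
            n_matching += 1
    blanks = [c for calls in table.by_role("blank").values() for c in calls]
    n_blanks_called = sum(c.status is CallStatus.CALLED for c in blanks)
    return ControlReport(
        n_duplicate_pairs=len(dup),
        n_matching_duplicates=n_matching,
        n_blanks=len(blanks),
        n_blanks_called=n_blanks_called,
    )


def _collapse_one_mismatch(barcodes: np.ndarray, counts: np.ndarray) -> int:
    """Count barcode clusters after folding 1-mismatch neighbours.

    Each barcode within Hamming distance 1 of a strictly more abundant
    barcode (ties by order) is absorbed by it; returns the number of
    surviving cluster centres.
    """
    order = np.argsort(-counts, kind="stable")
    seqs = [barcodes[i] for i in order]
    mats = np.frombuffer(b"".join(seqs), dtype=np.uint8).reshape(len(seqs), -1)
    surviving = 0
    centre_rows: List[np.ndarray] = []
    for row in mats:
        absorbed = any((row != c).sum() <= 1 for c in centre_rows)
        if not absorbed:
            centre_rows.append(row)
            surviving += 1
    return surviving


def rarefaction_curve(
    reads: Union[SampleReadSet, Sequence[str]],
    levels: Sequence[int],
    n_reps: int = 10,
    seed: Optional[int] = None,
    layout=None,
    params: Optional[CallingParams] = None,
    collapse_1mm: bool = False,
) -> pd.DataFrame:
    """Unique-barcode count versus subsampled read depth.

    ``reads`` is either a sequence of already-trimmed barcode strings or
    a :class:`SampleReadSet` of the sequenced injected library (then
    ``layout`` is required and reads are trimmed first).  At each level,
    reads are subsampled without replacement ``n_reps`` times and the
    number of distinct barcodes counted; ``collapse_1mm`` optionally
    folds barcodes within one mismatch of a more abundant barcode before
    counting (crude sequencing-error denoising, off by default).

    Returns a DataFrame with columns level, mean_unique, sd_unique.
    """
    if isinstance(reads, SampleReadSet):
        if layout is None:
            raise ValueError("layout required to trim a SampleReadSet")
        params = params or CallingParams()
        mat = trim_reads(reads, layout, params)
        barcode_of_read = mat.view(f"S{mat.shape[1]}").ravel()
    else:
        barcode_of_read = np.asarray([s.encode("ascii") for s in reads])
    n_total = barcode_of_read.shape[0]
    codes, uniques = pd.factorize(barcode_of_read)
    rng = np.random.default_rng(seed)
    rows = []
    for level in levels:
        if level < 0 or level > n_total:
            raise ValueError(
                f"subsample level {level} outside [0, {n_total}] available reads"
            )
        uniq_counts = np.empty(n_reps)
        for rep in range(n_reps):
            if level == 0:
                uniq_counts[rep] = 0
                continue
            idx = rng.choice(n_total, size=level, replace=False)
            sub = codes[idx]
            if collapse_1mm:
                vals, cnts = np.unique(sub, return_counts=True)
                uniq_counts[rep] = _collapse_one_mismatch(
                    uniques[vals], cnts
                )
            else:
                uniq_counts[rep] = np.unique(sub).size
        rows.append(
            {
                "level": int(level),
                "mean_unique": float(uniq_counts.mean()),
                "sd_unique": float(uniq_counts.std(ddof=1)) if n_reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def estimate_true_integrations(observed_unique: float, n_progeny_sampled: int) -> float:
    """Invert the occupancy expectation to correct for sampling saturation.

    Sampling ``n`` progeny with replacement from ``K`` equally likely
    insertions yields ``E[U] = K * (1 - (1 - 1/K)**n)`` distinct
    barcodes in expectation; this solves that monotone relation for K
    given an observed U.  Returns 1 for U <= 1 and ``inf`` when U equals
    n (every sampled progeny distinct — no finite moment estimate).
    """
    u = float(observed_unique)
    n = int(n_progeny_sampled)
    if n < 1:
        raise ValueError("n_progeny_sampled must be >= 1")
    if u < 1 or u > n:
        raise ValueError(
            f"observed_unique must lie in [1, n_progeny_sampled={n}]; got {u}"
        )
    if u <= 1.0:
        return 1.0
    if u >= n:
        return float("inf")

    def expected_minus_u(k: float) -> float:
        return k * (1.0 - (1.0 - 1.0 / k) ** n) - u

    lo = u  # E[U] at K=u is < u for K=u>1, so the root lies above
    hi = max(2.0 * u, lo + 1.0)
    while expected_minus_u(hi) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - u==n already handled
            return float("inf")
    return float(brentq(expected_minus_u, lo, hi, xtol=1e-9))
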