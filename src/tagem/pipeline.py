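"""End-to-end convenience drivers tying simulation to analysis."""

from __future__ import annotations

from typing import List, Optional, Tuple

import pandas as pd

from tagem.barcode_calling import BarcodeCall, CallingParams, call_sample
from tagem.lineage_analysis import LineageSummary, LineageTable, summarize_lineages
from tagem.synthetic_data import (
    ConstructLayout,
    DEFAULT_LAYOUT,
    GermlineSimConfig,
    TruthTable,
    simulate_germline_experiment,
    synthesize_experiment_reads,
)

__all__ = [
    "sample_sheet_frame",
    "truth_frame",
    "call_simulated_experiment",
    "run_simulated_experiment",
]


def sample_sheet_frame(truth: TruthTable) -> pd.DataFrame:
    """Sample sheet (sample_id, lineage_id, role) of a simulated run."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in truth.samples],
            "lineage_id": [s.lineage_id for s in truth.samples],
            "role": [s.role for s in truth.samples],
        }
    )


def truth_frame(truth: TruthTable) -> pd.DataFrame:
    """Per-sample ground truth table (true template per sample)."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in truth.samples],
            "lineage_id": [s.lineage_id for s in truth.samples],
            "role": [s.role for s in truth.samples],
            "true_template": [s.true_template or "" for s in truth.samples],
        }
    )


def call_simulated_experiment(
    truth: TruthTable,
    config: GermlineSimConfig,
    layout: ConstructLayout = DEFAULT_LAYOUT,
    params: Optional[CallingParams] = None,
) -> List[BarcodeCall]:
    """Synthesize reads sample by sample and call each immediately.

    Reads are never held for more than one sample at a time, so memory
    stays flat even for thousands of samples.
    """
    params = params or CallingParams()
    return [
        call_sample(read_set, layout, params)
        for read_set in synthesize_experiment_reads(truth, layout, config)
    ]


def run_simulated_experiment(
    config: GermlineSimConfig,
    layout: ConstructLayout = DEFAULT_LAYOUT,
    params: Optional[CallingParams] = None,
) -> Tuple[TruthTable, List[BarcodeCall], LineageTable, LineageSummary]:
    """Simulate, sequence, call and summarize one whole experiment."""
    truth = simulate_germline_experiment(config)
    calls = call_simulated_experiment(truth, config, layout, params)
    table = LineageTable.from_calls(calls, sample_sheet_frame(truth))
    summary = summarize_lineages(table)
    return truth, calls, table, summary
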