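"""End-to-end orchestration: reads -> calls -> corrected matrices -> frequencies.

Glue over the junction caller and quantifier, kept thin so each stage
stays independently usable.  The per-animal order of operations is:
aggregate per-read calls into sites, fold signal crossover within each
animal, resolve cross-animal collisions, apply the min-count filter
(threshold = number of samples analyzed for that animal), then compute
per-sample frequencies.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .junction_caller import LtrIndexSet, ReferenceIndex, call_reads
from .vis_quantifier import (
    ClonalMatrix,
    FrequencyProfile,
    aggregate_sites,
    compute_frequencies,
    correct_collisions,
    correct_signal_crossover,
    filter_min_count,
)

__all__ = ["call_samples", "quantify", "run_pipeline"]


def call_samples(
    reads_by_sample: Mapping[str, Iterable[tuple[str, str]]],
    reference: ReferenceIndex,
    **call_kwargs,
) -> pd.DataFrame:
    """Run the junction caller per sample; returns the pooled per-read
    table with a ``sample_id`` column."""
    frames = []
    for sample_id, reads in reads_by_sample.items():
        calls = call_reads(reads, reference, **call_kwargs)
        calls.insert(0, "sample_id", sample_id)
        frames.append(calls)
    return pd.concat(frames, ignore_index=True)


def quantify(
    calls: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    merge_window: int = 5,
    crossover_ratio: float = 0.1,
    collision_ratio: float = 0.1,
) -> tuple[dict[str, ClonalMatrix], dict[str, FrequencyProfile]]:
    """Corrected per-animal count matrices and frequency profiles."""
    matrices: dict[str, ClonalMatrix] = {}
    for animal, meta in sample_sheet.groupby("animal"):
        sub = calls[calls["sample_id"].isin(meta.index)]
        m = aggregate_sites(sub, meta, merge_window=merge_window)
        matrices[animal] = correct_signal_crossover(m, ratio=crossover_ratio)
    matrices = correct_collisions(matrices, ratio=collision_ratio)
    matrices = {
        animal: filter_min_count(m, n_samples=m.n_samples)
        for animal, m in matrices.items()
    }
    freqs = {animal: compute_frequencies(m) for animal, m in matrices.items()}
    return matrices, freqs


def run_pipeline(
    reads_by_sample: Mapping[str, Iterable[tuple[str, str]]],
    reference: ReferenceIndex | Mapping[str, str],
    sample_sheet: pd.DataFrame,
    index_set: LtrIndexSet | None = None,
    merge_window: int = 5,
    crossover_ratio: float = 0.1,
    collision_ratio: float = 0.1,
) -> dict:
    """Reads to frequencies in one call.

    Returns ``{"calls": per-read table, "matrices": {animal: ClonalMatrix},
    "frequencies": {animal: FrequencyProfile}}``.
    """
    if not isinstance(reference, ReferenceIndex):
        reference = ReferenceIndex(reference)
    calls = call_samples(reads_by_sample, reference, index_set=index_set)
    matrices, freqs = quantify(
        calls,
        sample_sheet,
        merge_window=merge_window,
        crossover_ratio=crossover_ratio,
        collision_ratio=collision_ratio,
    )
    return {"calls": calls, "matrices": matrices, "frequencies": freqs}
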