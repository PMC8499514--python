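"""Aggregate validated junction calls into a clone x sample count matrix.

The unit of observation is an integration site (chrom, pos, strand,
index_label); its per-sample sequence counts s_i quantify clone abundance.
Before frequencies p_i = s_i / S are computed, three corrections run in
order:

1. signal crossover — reads from one LTR-index population appearing under
   another index at the same genomic coordinate (index hopping) are folded
   into the dominant label when the minor label is below a dominance ratio;
2. collisions — the same coordinate observed in more than one animal is
   kept only in the animal that dominates by count (or dropped everywhere
   when no animal dominates);
3. min-count filter — sites whose total count is below the number of
   samples analyzed for that animal are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SITE_KEY",
    "ClonalMatrix",
    "FrequencyProfile",
    "aggregate_sites",
    "correct_signal_crossover",
    "correct_collisions",
    "filter_min_count",
    "compute_frequencies",
    "merge_replicates",
    "read_sample_sheet",
]

SITE_KEY = ["chrom", "pos", "strand", "index_label"]
SAMPLE_COLUMNS = ["sample_id", "animal", "timepoint", "tissue", "replicate", "population"]


@dataclass
class ClonalMatrix:
    """VIS x sample integer count matrix with sample metadata.

    ``counts`` is indexed by the site key (chrom, pos, strand, index_label)
    with one column per sample_id; ``samples`` is indexed by sample_id.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate site keys")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def n_sites(self) -> int:
        return len(self.counts)

    @property
    def n_samples(self) -> int:
        return len(self.counts.columns)

    def site_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, samples_path: str | Path) -> "ClonalMatrix":
        df = pd.read_csv(matrix_path, sep="\t").set_index(SITE_KEY)
        samples = read_sample_sheet(samples_path)
        return cls(df[samples.index.tolist()], samples)


@dataclass
class FrequencyProfile:
    """Per-sample proportional abundances p_i = s_i / S."""

    p: pd.DataFrame
    empty_samples: tuple[str, ...] = ()

    def to_tsv(self, path: str | Path) -> None:
        self.p.reset_index().to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df.set_index("sample_id")


def _cluster_positions(positions: np.ndarray, window: int) -> np.ndarray:
    """Assign cluster ids to sorted positions chained by gaps <= window."""
    gaps = np.diff(positions) > window
    return np.concatenate([[0], np.cumsum(gaps)])


def aggregate_sites(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    merge_window: int = 5,
) -> ClonalMatrix:
    """Collapse accepted per-read calls into per-site, per-sample counts.

    ``calls`` must carry a ``sample_id`` column.  Reads on the same
    chromosome/strand/index whose positions lie within ``merge_window`` of
    the previous read position (after sorting) are merged into one site at
    the modal position (ties broken toward the smallest position).
    """
    calls = calls[calls["status"] == "accepted"].copy()
    if calls.empty:
        counts = pd.DataFrame(
            columns=list(samples.index),
            index=pd.MultiIndex.from_arrays([[], [], [], []], names=SITE_KEY),
        ).astype(int)
        return ClonalMatrix(counts, samples)
    calls["pos"] = calls["pos"].astype(int)

    rows = []
    for (chrom, strand, label), grp in calls.groupby(
        ["chrom", "strand", "index_label"], sort=True
    ):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        cluster = _cluster_positions(pos, merge_window)
        grp = grp.assign(_cluster=cluster)
        for _, sub in grp.groupby("_cluster"):
            vc = sub["pos"].value_counts()
            modal = int(min(vc.index[vc == vc.max()]))
            per_sample = sub.groupby("sample_id").size()
            rows.append(((chrom, modal, strand, label), per_sample))

    index = pd.MultiIndex.from_tuples([r[0] for r in rows], names=SITE_KEY)
    counts = pd.DataFrame(
        [r[1] for r in rows], index=index
    ).reindex(columns=samples.index, fill_value=0).fillna(0).astype(int)
    counts = counts.sort_index()
    return ClonalMatrix(counts, samples)


def correct_signal_crossover(m: ClonalMatrix, ratio: float = 0.1) -> ClonalMatrix:
    """Fold minor-index counts into the dominant index at each coordinate.

    For a genomic coordinate (chrom, pos, strand) observed under two or
    more index labels, any label whose total count is below
    ``ratio`` x the dominant label's total is treated as index hopping and
    its counts reassigned to the dominant label.
    """
    counts = m.counts.copy()
    totals = counts.sum(axis=1)
    grouped = totals.groupby(level=["chrom", "pos", "strand"])
    for coord, tot in grouped:
        if len(tot) < 2:
            continue
        major_total = tot.max()
        major_key = tot.idxmax()
        for key, t in tot.items():
            if key == major_key:
                continue
            if t < ratio * major_total:
                counts.loc[major_key] = counts.loc[major_key] + counts.loc[key]
                counts = counts.drop(index=key)
    return ClonalMatrix(counts.sort_index(), m.samples)


def correct_collisions(
    matrices: dict[str, ClonalMatrix], ratio: float = 0.1
) -> dict[str, ClonalMatrix]:
    """Resolve coordinates shared across animals by count dominance.

    A coordinate present in more than one animal is kept only in the
    animal whose total count dominates (every other animal's total is
    below ``ratio`` x the dominant total); with no dominant animal the
    coordinate is removed everywhere.
    """
    coord_totals: dict[tuple, dict[str, int]] = {}
    for animal, m in matrices.items():
        tot = m.counts.sum(axis=1).groupby(level=["chrom", "pos", "strand"]).sum()
        for coord, t in tot.items():
            coord_totals.setdefault(coord, {})[animal] = int(t)

    drop: dict[str, set] = {a: set() for a in matrices}
    for coord, per_animal in coord_totals.items():
        if len(per_animal) < 2:
            continue
        dominant = max(per_animal, key=per_animal.get)
        dom_count = per_animal[dominant]
        others = {a: c for a, c in per_animal.items() if a != dominant}
        if all(c < ratio * dom_count for c in others.values()):
            for a in others:
                drop[a].add(coord)
        else:
            for a in per_animal:
                drop[a].add(coord)

    out = {}
    for animal, m in matrices.items():
        if not drop[animal]:
            out[animal] = m
            continue
        coords = m.counts.index.droplevel("index_label")
        keep = ~coords.map(lambda c: c in drop[animal]).to_numpy()
        out[animal] = ClonalMatrix(m.counts[keep], m.samples)
    return out


def filter_min_count(m: ClonalMatrix, n_samples: int | None = None) -> ClonalMatrix:
    """Drop sites whose total count is below the number of samples analyzed."""
    if n_samples is None:
        n_samples = m.n_samples
    if n_samples <= 0:
        raise ValueError("invalid sample count")
    keep = m.site_totals() >= n_samples
    return ClonalMatrix(m.counts[keep], m.samples)


def compute_frequencies(m: ClonalMatrix) -> FrequencyProfile:
    """Per-sample proportional abundances p_i = s_i / S (S = column sum)."""
    totals = m.counts.sum(axis=0)
    empty = tuple(totals.index[totals == 0])
    safe = totals.replace(0, 1)
    return FrequencyProfile(m.counts / safe, empty_samples=empty)


def merge_replicates(
    m: ClonalMatrix,
    mode: Literal["sum_counts", "mean_frequency"] = "sum_counts",
):
    """Merge replicate columns per (animal, timepoint, tissue) group.

    ``sum_counts`` adds replicate count columns; ``mean_frequency``
    averages the per-replicate frequency vectors and renormalizes.
    """
    meta = m.samples
    if meta["replicate"].isna().any():
        bad = meta.index[meta["replicate"].isna()][0]
        raise ValueError(f"sample {bad} has no replicate id")
    group_cols = ["animal", "timepoint", "tissue"]
    merged_cols, merged_meta = [], []
    if mode == "sum_counts":
        for key, grp in meta.groupby(group_cols, sort=True):
            col = m.counts[grp.index].sum(axis=1)
            sample_id = "_".join(str(k) for k in key)
            col.name = sample_id
            merged_cols.append(col)
            merged_meta.append((sample_id, *key, "merged", grp["population"].iloc[0]))
        counts = pd.concat(merged_cols, axis=1)
        samples = pd.DataFrame(
            merged_meta,
            columns=["sample_id", *group_cols, "replicate", "population"],
        ).set_index("sample_id")
        return ClonalMatrix(counts, samples)
    if mode == "mean_frequency":
        freq = compute_frequencies(m).p
        out = {}
        for key, grp in meta.groupby(group_cols, sort=True):
            mean = freq[grp.index].mean(axis=1)
            s = mean.sum()
            out["_".join(str(k) for k in key)] = mean / s if s > 0 else mean
        return FrequencyProfile(pd.DataFrame(out))
    raise ValueError(f"unknown mode: {mode}")
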