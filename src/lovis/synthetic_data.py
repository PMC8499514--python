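"""Synthetic multi-omics fixtures with known clonal truth.

Generates everything the tracking workflow consumes — a genome seeded
with restriction motifs, gene annotation with biotypes and expression,
chromatin-feature peaks and coverage tracks, and LTR-junction reads from
a clone population with known integration sites and abundances — so the
whole pipeline is testable end to end without external data.

What is emulated, and how:

* genome: random sequence scrubbed of the CviQI/RsaI motif, then GTAC
  motifs placed as a Poisson process at a configurable per-kb rate (the
  assay can only recover junctions near a restriction site, so motif
  geometry matters);
* genes: non-overlapping bodies with a protein_coding/lncRNA/other
  biotype mix and log-normal FPKM draws; a gene is "active" above FPKM 1;
* peaks: H3K36me3 and H3K79me2 inside active gene bodies, H3K4me3 and
  other promoter marks at active TSS, H3K4me1 upstream (enhancer-like),
  H3K27me3 on inactive bodies, plus uniform background peaks; coverage
  tracks are elevated inside peaks over a flat baseline;
* clones: integration sites drawn from configurable bias weights
  (H3K36me3 peak / gene body / TSS-proximal / intergenic), each within
  1500 bp of a motif so the assay could see it; abundances are log-normal
  and evolve across timepoints by a multiplicative log-normal random walk
  so band/persistence structure exists;
* reads: LTR anchor carrying the clone's barcode + downstream host
  sequence, with per-base substitution errors, index hopping at a
  configured rate, negative-binomial overdispersion of per-sample counts
  (whole-genome-amplification noise), and a handful of clones copied into
  a second animal at low count (collisions).

Seeded runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .junction_caller import (
    DEFAULT_ANCHOR_PREFIX,
    DEFAULT_LTR_INDEXES,
    revcomp,
)

__all__ = [
    "SimulationConfig",
    "Reference",
    "TruthTable",
    "make_reference",
    "simulate_clones",
    "simulate_reads",
    "simulate",
    "write_reference",
    "write_fastqs",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the canonical fixture: a 2 Mb two-chromosome
    genome, 300 clones in one animal tracked in blood over four
    timepoints with MDA duplicates (8 samples, ~150k reads), plus a
    small second animal carrying collision copies.
    """

    seed: int = 0
    # reference
    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    motif: str = "GTAC"
    motif_rate_per_kb: float = 1.0
    n_genes: int = 150
    biotype_mix: tuple[float, float, float] = (0.70, 0.15, 0.15)
    gene_length_mean: float = 6000.0
    gene_length_sigma: float = 0.35
    fpkm_log_mean: float = 0.5
    fpkm_log_sigma: float = 2.0
    peak_width: int = 600
    n_background_peaks: int = 30
    # clones
    n_clones: int = 300
    wt_fraction: float = 0.12
    abundance_sigma: float = 1.0
    drift_sigma: float = 0.3
    bias_weights: dict = field(
        default_factory=lambda: {
            "h3k36me3": 0.50, "gene_body": 0.25, "tss": 0.05, "intergenic": 0.20,
        }
    )
    motif_max_dist: int = 1500
    # sampling design
    animal: str = "m1"
    timepoints: tuple[int, ...] = (13, 15, 17, 19)
    n_replicates: int = 2
    tissues: tuple[str, ...] = ("blood",)
    extra_tissues: tuple[str, ...] = ()  # sampled at the final timepoint
    depth: int = 18_750
    # reads
    host_read_len: int = 40
    error_rate: float = 0.002
    hop_rate: float = 0.01
    nb_dispersion: float = 0.02
    # second animal / collisions
    secondary_animal: str = "m2"
    n_secondary_clones: int = 40
    secondary_depth: int = 2000
    collision_clones: int = 5
    collision_mean_reads: float = 3.0

    def __post_init__(self) -> None:
        for rate in (self.error_rate, self.hop_rate, self.wt_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        total = sum(self.bias_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("bias weights must sum to 1")


@dataclass
class Reference:
    genome: dict[str, str]
    genes: pd.DataFrame  # gene_id, chrom, start, end (1-based incl), strand, biotype
    fpkm: pd.Series  # gene_id -> FPKM
    peaks: dict[str, pd.DataFrame]  # feature -> chrom/start/end (0-based half-open)
    coverage: dict[str, pd.DataFrame]  # feature -> bedGraph frame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


@dataclass
class TruthTable:
    """Known truth: clone sites, per-sample frequencies and emitted reads."""

    clones: pd.DataFrame  # clone_id -> animal, chrom, pos, strand, index_label
    freqs: pd.DataFrame  # clone_id x sample_id true frequencies
    sample_sheet: pd.DataFrame  # sample_id -> animal, timepoint, tissue, replicate
    emitted: pd.DataFrame | None = None  # clone_id x sample_id emitted read counts
    read_origin: pd.Series | None = None  # read_id -> clone_id

    def site_keys(self, animal: str) -> set:
        sub = self.clones[self.clones["animal"] == animal]
        return set(zip(sub["chrom"], sub["pos"], sub["strand"], sub["index_label"]))


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int, motif: str) -> str:
    seq = "".join(_BASES[rng.integers(0, 4, size=length)])
    # scrub natural motif occurrences so placement controls the rate
    while True:
        idx = seq.find(motif)
        if idx == -1:
            return seq
        repl = [b for b in "ACGT" if b != motif[1]]
        seq = seq[: idx + 1] + str(rng.choice(repl)) + seq[idx + 2 :]


def _place_motifs(
    rng: np.random.Generator, seq: str, motif: str, rate_per_kb: float
) -> str:
    n = rng.poisson(rate_per_kb * len(seq) / 1000.0)
    pos = np.sort(rng.integers(0, len(seq) - len(motif), size=n))
    keep = []
    last = -10
    for p in pos:
        if p - last >= len(motif):
            keep.append(int(p))
            last = p
    chars = list(seq)
    for p in keep:
        chars[p : p + len(motif)] = motif
    return "".join(chars)


def _place_genes(
    rng: np.random.Generator, cfg: SimulationConfig, chrom_lengths: dict[str, int]
) -> pd.DataFrame:
    chroms = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    rows: list[tuple] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(rows) < cfg.n_genes and attempts < cfg.n_genes * 200:
        attempts += 1
        chrom = chroms[
            rng.choice(len(chroms), p=[chrom_lengths[c] / total for c in chroms])
        ]
        length = int(rng.lognormal(np.log(cfg.gene_length_mean), cfg.gene_length_sigma))
        length = max(length, 500)
        if length + 2000 >= chrom_lengths[chrom]:
            continue
        start0 = int(rng.integers(1000, chrom_lengths[chrom] - length - 1000))
        end0 = start0 + length
        if any(start0 - 500 < e and end0 + 500 > s for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start0, end0))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = ["protein_coding", "lncRNA", "other"][
            rng.choice(3, p=cfg.biotype_mix)
        ]
        rows.append((f"G{len(rows):04d}", chrom, start0 + 1, end0, strand, biotype))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
    )


def _peak(chrom: str, center: int, width: int, chrom_len: int) -> tuple[str, int, int]:
    lo = max(0, center - width // 2)
    hi = min(chrom_len, lo + width)
    return chrom, lo, hi


def _make_peaks(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    genes: pd.DataFrame,
    fpkm: pd.Series,
    chrom_lengths: dict[str, int],
) -> dict[str, pd.DataFrame]:
    from .genomic_context import CHROMATIN_FEATURES

    active = genes[fpkm.loc[genes["gene_id"]].to_numpy() > 1.0]
    inactive = genes[fpkm.loc[genes["gene_id"]].to_numpy() <= 1.0]
    w = cfg.peak_width
    peaks: dict[str, list[tuple]] = {f: [] for f in CHROMATIN_FEATURES}

    for _, g in active.iterrows():
        clen = chrom_lengths[g["chrom"]]
        body_lo, body_hi = g["start"] - 1, g["end"]
        tss = body_lo if g["strand"] == "+" else body_hi - 1
        # gene-body marks of transcribed genes
        if body_hi - body_lo > w:
            c = int(rng.integers(body_lo + w // 2, body_hi - w // 2))
            peaks["H3K36me3"].append(_peak(g["chrom"], c, w, clen))
            if rng.random() < 0.6:
                c = int(rng.integers(body_lo + w // 2, body_hi - w // 2))
                peaks["H3K79me2"].append(_peak(g["chrom"], c, w, clen))
        # promoter / open-chromatin marks at the TSS
        for feat in ("H3K4me3", "ATAC", "H3K9ac", "H3K9cr", "H3K27ac", "RNApolII"):
            if rng.random() < 0.8:
                peaks[feat].append(_peak(g["chrom"], tss, w, clen))
        # enhancer-like mark upstream
        if rng.random() < 0.5:
            off = int(rng.integers(1000, 5000))
            c = tss - off if g["strand"] == "+" else tss + off
            if 0 < c < clen:
                peaks["H3K4me1"].append(_peak(g["chrom"], c, w, clen))
    for _, g in inactive.iterrows():
        body_lo, body_hi = g["start"] - 1, g["end"]
        if body_hi - body_lo > w and rng.random() < 0.7:
            c = int(rng.integers(body_lo + w // 2, body_hi - w // 2))
            peaks["H3K27me3"].append(_peak(g["chrom"], c, w, chrom_lengths[g["chrom"]]))

    chroms = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    for feat in CHROMATIN_FEATURES:
        for _ in range(cfg.n_background_peaks):
            chrom = chroms[
                rng.choice(len(chroms), p=[chrom_lengths[c] / total for c in chroms])
            ]
            c = int(rng.integers(0, chrom_lengths[chrom]))
            peaks[feat].append(_peak(chrom, c, w, chrom_lengths[chrom]))

    out = {}
    for feat, rows in peaks.items():
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        out[feat] = df
    return out


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for chrom, grp in df.groupby("chrom"):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _coverage_from_peaks(
    peaks: pd.DataFrame,
    chrom_lengths: dict[str, int],
    baseline: float = 1.0,
    peak_value: float = 10.0,
) -> pd.DataFrame:
    merged = _merge_intervals(peaks)
    rows = []
    for chrom, length in chrom_lengths.items():
        cursor = 0
        sub = merged[merged["chrom"] == chrom]
        for s, e in zip(sub["start"], sub["end"]):
            if s > cursor:
                rows.append((chrom, cursor, s, baseline))
            rows.append((chrom, s, e, peak_value))
            cursor = e
        if cursor < length:
            rows.append((chrom, cursor, length, baseline))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def make_reference(config: SimulationConfig) -> Reference:
    """Genome + annotation + expression + peaks + coverage, seeded."""
    rng = np.random.default_rng(config.seed)
    per_chrom = config.genome_length // config.n_chromosomes
    genome = {}
    for i in range(config.n_chromosomes):
        seq = _random_sequence(rng, per_chrom, config.motif)
        genome[f"chr{i + 1}"] = _place_motifs(
            rng, seq, config.motif, config.motif_rate_per_kb
        )
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    genes = _place_genes(rng, config, chrom_lengths)
    fpkm = pd.Series(
        rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sigma, size=len(genes)),
        index=genes["gene_id"].to_numpy(),
        name="fpkm",
    )
    if len(genes):
        peaks = _make_peaks(rng, config, genes, fpkm, chrom_lengths)
    else:
        peaks = {f: pd.DataFrame(columns=["chrom", "start", "end"]) for f in ()}
    coverage = {
        feat: _coverage_from_peaks(df, chrom_lengths) for feat, df in peaks.items()
    }
    return Reference(genome, genes, fpkm, peaks, coverage)


# ---------------------------------------------------------------------------
# Clone simulation
# ---------------------------------------------------------------------------


def _draw_site(
    rng: np.random.Generator,
    category: str,
    ref: Reference,
    cfg: SimulationConfig,
) -> tuple[str, int] | None:
    """One candidate (chrom, pos0) for a given placement bias category."""
    genes = ref.genes
    if category == "h3k36me3" and len(ref.peaks.get("H3K36me3", ())):
        df = ref.peaks["H3K36me3"]
        row = df.iloc[int(rng.integers(0, len(df)))]
        return row["chrom"], int(rng.integers(row["start"], row["end"]))
    if category == "gene_body" and len(genes):
        g = genes.iloc[int(rng.integers(0, len(genes)))]
        return g["chrom"], int(rng.integers(g["start"] - 1, g["end"]))
    if category == "tss" and len(genes):
        g = genes.iloc[int(rng.integers(0, len(genes)))]
        tss = g["start"] - 1 if g["strand"] == "+" else g["end"] - 1
        return g["chrom"], int(tss + rng.integers(-500, 501))
    # intergenic (also the fallback when the preferred category is empty)
    chroms = list(ref.genome)
    lengths = np.array([len(ref.genome[c]) for c in chroms], dtype=float)
    chrom = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
    pos0 = int(rng.integers(0, len(ref.genome[chrom])))
    if category == "intergenic" and len(genes):
        sub = genes[genes["chrom"] == chrom]
        if ((sub["start"] - 1 <= pos0) & (pos0 < sub["end"])).any():
            return None
    return chrom, pos0


def _sample_sites(
    rng: np.random.Generator,
    n: int,
    ref: Reference,
    cfg: SimulationConfig,
    taken: set[tuple[str, int]],
    min_sep: int = 50,
) -> list[tuple[str, int, str]]:
    from .genomic_context import _motif_distance, find_motif_positions

    motif_pos = {c: find_motif_positions(s, cfg.motif) for c, s in ref.genome.items()}
    categories = list(cfg.bias_weights)
    probs = np.array([cfg.bias_weights[c] for c in categories])
    margin = cfg.host_read_len + 5
    sites: list[tuple[str, int, str]] = []
    attempts = 0
    while len(sites) < n:
        attempts += 1
        if attempts > n * 10_000:
            raise RuntimeError("could not place clone sites under constraints")
        cat = categories[int(rng.choice(len(categories), p=probs))]
        cand = _draw_site(rng, cat, ref, cfg)
        if cand is None:
            continue
        chrom, pos0 = cand
        if not margin <= pos0 < len(ref.genome[chrom]) - margin:
            continue
        if _motif_distance(pos0, motif_pos[chrom], len(cfg.motif)) > cfg.motif_max_dist:
            continue
        if any(abs(pos0 - p) < min_sep for c, p in taken if c == chrom):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        taken.add((chrom, pos0))
        sites.append((chrom, pos0 + 1, strand))
    return sites


def _build_sample_sheet(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for tp in cfg.timepoints:
        for tissue in cfg.tissues:
            for rep in range(1, cfg.n_replicates + 1):
                rows.append((cfg.animal, tp, tissue, f"r{rep}"))
    for tissue in cfg.extra_tissues:
        for rep in range(1, cfg.n_replicates + 1):
            rows.append((cfg.animal, cfg.timepoints[-1], tissue, f"r{rep}"))
    if cfg.n_secondary_clones > 0:
        for rep in range(1, cfg.n_replicates + 1):
            rows.append((cfg.secondary_animal, cfg.timepoints[-1], "blood", f"r{rep}"))
    df = pd.DataFrame(rows, columns=["animal", "timepoint", "tissue", "replicate"])
    df["population"] = "mixed"
    df.index = pd.Index(
        [
            f"{a}_wk{t}_{ti}_{r}"
            for a, t, ti, r in zip(df["animal"], df["timepoint"], df["tissue"], df["replicate"])
        ],
        name="sample_id",
    )
    return df


def simulate_clones(config: SimulationConfig, ref: Reference) -> TruthTable:
    """Draw clone integration sites and per-sample true frequencies."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    labels = list(DEFAULT_LTR_INDEXES)
    taken: set[tuple[str, int]] = set()

    def assign_labels(n: int) -> list[str]:
        return ["WT" if rng.random() < config.wt_fraction else "H5" for _ in range(n)]

    rows = []
    prim = _sample_sites(rng, config.n_clones, ref, config, taken)
    for (chrom, pos, strand), label in zip(prim, assign_labels(config.n_clones)):
        rows.append((f"{config.animal}_c{len(rows):04d}", config.animal, chrom, pos, strand, label))
    n_prim = len(rows)
    if config.n_secondary_clones > 0:
        sec = _sample_sites(rng, config.n_secondary_clones, ref, config, taken)
        for (chrom, pos, strand), label in zip(sec, assign_labels(config.n_secondary_clones)):
            rows.append(
                (f"{config.secondary_animal}_c{len(rows) - n_prim:04d}",
                 config.secondary_animal, chrom, pos, strand, label)
            )
    clones = pd.DataFrame(
        rows, columns=["clone_id", "animal", "chrom", "pos", "strand", "index_label"]
    ).set_index("clone_id")

    sheet = _build_sample_sheet(config)
    freqs = pd.DataFrame(0.0, index=clones.index, columns=sheet.index)
    for animal, sub in clones.groupby("animal"):
        w = rng.lognormal(0.0, config.abundance_sigma, size=len(sub))
        per_tp: dict[int, np.ndarray] = {}
        for tp in config.timepoints:
            per_tp[tp] = w / w.sum()
            w = w * rng.lognormal(0.0, config.drift_sigma, size=len(sub))
        for sample_id, meta in sheet.iterrows():
            if meta["animal"] != animal:
                continue
            freqs.loc[sub.index, sample_id] = per_tp[meta["timepoint"]]
    return TruthTable(clones=clones, freqs=freqs, sample_sheet=sheet)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _host_sequence(ref: Reference, chrom: str, pos: int, strand: str, length: int) -> str:
    pos0 = pos - 1
    seq = ref.genome[chrom]
    if strand == "+":
        return seq[pos0 : pos0 + length]
    return revcomp(seq[pos0 - length + 1 : pos0 + 1])


def _mutate_batch(
    rng: np.random.Generator, template: str, count: int, error_rate: float
) -> list[str]:
    if count == 0:
        return []
    if error_rate == 0:
        return [template] * count
    arr = np.frombuffer(template.encode(), dtype="S1")
    mat = np.tile(arr, (count, 1))
    mask = rng.random(mat.shape) < error_rate
    if mask.any():
        subs = _BASES[rng.integers(0, 4, size=int(mask.sum()))].astype("S1")
        # force a real substitution (resample identical bases once; leftover
        # identities are a negligible fraction of an already-rare event)
        same = subs == mat[mask]
        if same.any():
            subs[same] = _BASES[rng.integers(0, 4, size=int(same.sum()))].astype("S1")
        mat[mask] = subs
    return [row.tobytes().decode() for row in mat]


def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    means = np.asarray(means, dtype=float)
    out = np.zeros(means.shape, dtype=np.int64)
    pos = means > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(means[pos])
        return out
    r = 1.0 / dispersion
    p = r / (r + means[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_reads(
    truth: TruthTable,
    ref: Reference,
    config: SimulationConfig,
) -> dict[str, list[tuple[str, str]]]:
    """Emit (read_id, sequence) pairs per sample; fills ``truth.emitted``
    and ``truth.read_origin`` in place.

    Per clone and sample, read counts are negative-binomial around
    depth x true frequency; each read is LTR anchor + barcode + host
    sequence with substitution errors, and with the configured
    index-hopping rate the barcode of another population is used.
    Collision clones from the primary animal additionally emit a low,
    fixed mean count into every secondary-animal sample.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    labels = list(DEFAULT_LTR_INDEXES)
    sheet = truth.sample_sheet
    emitted = pd.DataFrame(0, index=truth.clones.index, columns=sheet.index)
    origin: dict[str, str] = {}
    reads_by_sample: dict[str, list[tuple[str, str]]] = {}

    # Collision copies come from the most abundant primary clones: dominance
    # resolution presumes the true owner's count dwarfs the bleed-over, which
    # holds for clones large enough to bleed across animals in the first place.
    if config.collision_clones > 0:
        prim_cols = sheet.index[sheet["animal"] == config.animal]
        prim_clones = truth.clones.index[truth.clones["animal"] == config.animal]
        mean_freq = truth.freqs.loc[prim_clones, prim_cols].mean(axis=1)
        collision_ids = list(mean_freq.nlargest(config.collision_clones).index)
    else:
        collision_ids = []

    host_cache = {
        cid: _host_sequence(ref, c["chrom"], c["pos"], c["strand"], config.host_read_len)
        for cid, c in truth.clones.iterrows()
    }

    for sample_id, meta in sheet.iterrows():
        depth = config.depth if meta["animal"] == config.animal else config.secondary_depth
        own = truth.clones[truth.clones["animal"] == meta["animal"]]
        means = truth.freqs.loc[own.index, sample_id].to_numpy() * depth
        counts = _nb_counts(rng, means, config.nb_dispersion)
        batch: list[tuple[str, str]] = []
        clone_ids = list(own.index)
        clone_counts = list(counts)
        if meta["animal"] == config.secondary_animal:
            for cid in collision_ids:
                clone_ids.append(cid)
                clone_counts.append(int(rng.poisson(config.collision_mean_reads)))
        for cid, count in zip(clone_ids, clone_counts):
            if count == 0:
                continue
            emitted.loc[cid, sample_id] += count
            true_label = truth.clones.loc[cid, "index_label"]
            # index hopping: some reads carry another population's barcode
            hops = rng.random(count) < config.hop_rate
            n_hop = int(hops.sum())
            label_seq = []
            label_seq.extend([true_label] * (count - n_hop))
            for _ in range(n_hop):
                others = [l for l in labels if l != true_label]
                label_seq.append(others[int(rng.integers(0, len(others)))])
            host = host_cache[cid]
            by_label: dict[str, int] = {}
            for lab in label_seq:
                by_label[lab] = by_label.get(lab, 0) + 1
            i = 0
            for lab, n_lab in sorted(by_label.items()):
                template = DEFAULT_ANCHOR_PREFIX + DEFAULT_LTR_INDEXES[lab] + host
                for seq in _mutate_batch(rng, template, n_lab, config.error_rate):
                    read_id = f"{sample_id}:{cid}:{i}"
                    batch.append((read_id, seq))
                    origin[read_id] = cid
                    i += 1
        reads_by_sample[sample_id] = batch

    truth.emitted = emitted
    truth.read_origin = pd.Series(origin, dtype=object)
    return reads_by_sample


def simulate(config: SimulationConfig):
    """Full generation: reference, truth, and per-sample reads."""
    ref = make_reference(config)
    truth = simulate_clones(config, ref)
    reads = simulate_reads(truth, ref, config)
    return ref, truth, reads


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def write_reference(ref: Reference, outdir: str | Path) -> None:
    """Write genome FASTA, gene GTF, FPKM TSV, peak BEDs and bedGraphs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in ref.genome.items()
    ]
    SeqIO.write(records, str(outdir / "genome.fa"), "fasta")

    with open(outdir / "genes.gtf", "w") as fh:
        for _, g in ref.genes.iterrows():
            attrs = f'gene_id "{g["gene_id"]}"; gene_biotype "{g["biotype"]}";'
            fh.write(
                "\t".join(
                    [g["chrom"], "sim", "gene", str(g["start"]), str(g["end"]),
                     ".", g["strand"], ".", attrs]
                )
                + "\n"
            )
    ref.fpkm.rename_axis("gene_id").reset_index().to_csv(
        outdir / "fpkm.tsv", sep="\t", index=False
    )
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for feat, df in ref.peaks.items():
        df.to_csv(peak_dir / f"{feat}.bed", sep="\t", index=False, header=False)
    cov_dir = outdir / "coverage"
    cov_dir.mkdir(exist_ok=True)
    for feat, df in ref.coverage.items():
        df.to_csv(cov_dir / f"{feat}.bedGraph", sep="\t", index=False, header=False)


def write_fastqs(
    reads_by_sample: Mapping[str, list[tuple[str, str]]], outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample_id, reads in reads_by_sample.items():
        with open(outdir / f"{sample_id}.fastq", "w") as fh:
            for read_id, seq in reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_sample_sheet(truth: TruthTable, path: str | Path) -> None:
    truth.sample_sheet.reset_index().to_csv(path, sep="\t", index=False)
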