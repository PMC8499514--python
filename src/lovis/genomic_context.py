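"""Genomic and epigenomic context of integration sites.

Covers the motif-constrained random-integration null (sites uniformly
sampled subject to lying within a fixed distance of a restriction motif,
mimicking what a CviQI/RsaI-based junction assay can recover), nearest-gene
annotation with biotype and expression-activity calls, distances to
chromatin-feature peaks, distance histograms, the Yates-corrected
chi-squared enrichment test against the random null, and coverage
matrices around sites or scaled gene bodies for profile plots and a
variance-maximizing (PCA) feature separation.

All distances are unstranded base-pair offsets; a site inside an interval
has distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "CHROMATIN_FEATURES",
    "find_motif_positions",
    "generate_random_is",
    "annotate_nearest_gene",
    "classify_activity",
    "peak_distance",
    "bin_by_distance",
    "chisq_yates",
    "proximity_enrichment",
    "coverage_matrix",
    "feature_pca",
    "read_gtf_genes",
    "read_peaks_bed",
    "read_bedgraph",
]

CHROMATIN_FEATURES = (
    "ATAC", "H3K4me3", "H3K9ac", "H3K9cr", "H3K27ac",
    "H3K4me1", "H3K79me2", "H3K36me3", "H3K27me3", "RNApolII",
)

BIOTYPE_PRIORITY = {"protein_coding": 0, "lncRNA": 1, "other": 2}

DEFAULT_MOTIF = "GTAC"


# ---------------------------------------------------------------------------
# Random-integration null
# ---------------------------------------------------------------------------


def find_motif_positions(seq: str, motif: str = DEFAULT_MOTIF) -> np.ndarray:
    """Sorted 0-based start positions of ``motif`` on either strand.

    GTAC is its own reverse complement, so for the default motif a
    forward scan covers both strands; for asymmetric motifs the reverse
    complement is scanned too and positions are merged.
    """
    from .junction_caller import revcomp

    seq = seq.upper()
    motif = motif.upper()
    queries = {motif, revcomp(motif)}
    hits: list[int] = []
    for q in queries:
        start = seq.find(q)
        while start != -1:
            hits.append(start)
            start = seq.find(q, start + 1)
    return np.unique(np.asarray(hits, dtype=np.int64))


def _motif_distance(pos0: int, starts: np.ndarray, motif_len: int) -> int:
    """Distance in bp from a 0-based position to the nearest motif base."""
    if starts.size == 0:
        return np.iinfo(np.int64).max
    i = np.searchsorted(starts, pos0)
    best = np.iinfo(np.int64).max
    for j in (i - 1, i):
        if 0 <= j < starts.size:
            s = starts[j]
            if s <= pos0 < s + motif_len:
                return 0
            best = min(best, abs(pos0 - s) if pos0 < s else pos0 - (s + motif_len - 1))
    return int(best)


def generate_random_is(
    genome: Mapping[str, str],
    n: int = 1000,
    max_dist: int = 1500,
    motif: str = DEFAULT_MOTIF,
    seed: int = 0,
    max_attempts_per_site: int = 10_000,
) -> pd.DataFrame:
    """Motif-constrained random integration sites.

    Positions are drawn uniformly over the genome (chromosomes weighted by
    length, strand uniform) and kept only if they lie within ``max_dist``
    bp of an occurrence of ``motif``; rejection sampling continues until
    ``n`` sites are collected.  Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    motif_pos = {c: find_motif_positions(genome[c], motif) for c in chroms}
    if all(v.size == 0 for v in motif_pos.values()):
        raise ValueError("unsatisfiable constraint: motif absent from genome")

    weights = lengths / lengths.sum()
    rows = []
    attempts = 0
    budget = n * max_attempts_per_site
    while len(rows) < n:
        if attempts >= budget:
            raise ValueError("unsatisfiable constraint: attempt budget exhausted")
        attempts += 1
        ci = rng.choice(len(chroms), p=weights)
        chrom = chroms[ci]
        pos0 = int(rng.integers(0, len(genome[chrom])))
        if _motif_distance(pos0, motif_pos[chrom], len(motif)) <= max_dist:
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, pos0 + 1, strand))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """Gene records from a GTF: gene_id, chrom, start, end, strand, biotype.

    Coordinates stay 1-based inclusive as in the file.  Biotypes are
    collapsed onto {protein_coding, lncRNA, other}.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in f[8].rstrip(";").split(";")
                if kv.strip()
            )
            biotype = attrs.get("gene_biotype", attrs.get("gene_type", "other"))
            if biotype not in ("protein_coding", "lncRNA"):
                biotype = "other"
            rows.append(
                (attrs.get("gene_id", f"gene{len(rows)}"), f[0], int(f[3]),
                 int(f[4]), f[6], biotype)
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
    )


def _gene_distance(pos: int, start: int, end: int) -> int:
    """bp from a 1-based position to a 1-based inclusive interval (0 inside)."""
    if start <= pos <= end:
        return 0
    return start - pos if pos < start else pos - end


def annotate_nearest_gene(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 1000,
    mode: Literal["gene_body", "tss"] = "gene_body",
) -> pd.DataFrame:
    """Nearest-gene annotation with a distal cutoff.

    For each site the nearest gene is found (distance 0 inside the gene
    body, else bp to the nearest boundary; ``tss`` mode measures to the
    transcription start site instead).  The biotype class of the call is
    the nearest gene's biotype when the distance is <= ``window`` bp,
    otherwise ``distal``.  Exact distance ties are broken by biotype
    priority protein_coding > lncRNA > other, then gene_id order.
    """
    by_chrom = {c: g.reset_index(drop=True) for c, g in genes.groupby("chrom")}
    out = []
    for _, site in sites.iterrows():
        g = by_chrom.get(site["chrom"])
        if g is None or g.empty:
            out.append((None, np.nan, "distal"))
            continue
        if mode == "tss":
            tss = np.where(g["strand"] == "+", g["start"], g["end"])
            d = np.abs(tss - int(site["pos"]))
        else:
            d = np.array(
                [_gene_distance(int(site["pos"]), s, e)
                 for s, e in zip(g["start"], g["end"])]
            )
        order = sorted(
            range(len(g)),
            key=lambda i: (d[i], BIOTYPE_PRIORITY[g["biotype"][i]], g["gene_id"][i]),
        )
        best = order[0]
        dist = int(d[best])
        call = g["biotype"][best] if dist <= window else "distal"
        out.append((g["gene_id"][best], dist, call))
    ann = sites.copy()
    ann[["nearest_gene", "gene_distance", "biotype_class"]] = pd.DataFrame(
        out, index=sites.index
    )
    return ann


def classify_activity(
    annotation: pd.DataFrame,
    fpkm: pd.Series | Mapping[str, float],
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Flag genic calls whose nearest gene is expressed above ``threshold``.

    ``active`` is strictly FPKM > threshold; distal sites get a null flag.
    """
    fpkm = pd.Series(fpkm, dtype=float)
    ann = annotation.copy()
    active = []
    for _, row in ann.iterrows():
        if row["biotype_class"] == "distal" or row["nearest_gene"] is None:
            active.append(None)
        else:
            active.append(bool(fpkm.get(row["nearest_gene"], 0.0) > threshold))
    ann["active"] = active
    return ann


# ---------------------------------------------------------------------------
# Peak proximity
# ---------------------------------------------------------------------------


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    """BED/narrowPeak intervals as 0-based half-open chrom/start/end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def _interval_distance(pos0: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """bp from a 0-based position to sorted disjoint 0-based half-open intervals."""
    i = int(np.searchsorted(starts, pos0, side="right")) - 1
    best = np.iinfo(np.int64).max
    if i >= 0:
        if pos0 < ends[i]:
            return 0
        best = pos0 - (ends[i] - 1)
    if i + 1 < starts.size:
        best = min(best, int(starts[i + 1]) - pos0)
    return int(best)


def peak_distance(
    sites: pd.DataFrame,
    peaks: Mapping[str, pd.DataFrame],
    mode: Literal["edge", "center"] = "edge",
) -> pd.DataFrame:
    """Per-site distance to the nearest peak of each chromatin feature.

    Distance is 0 for a site inside a peak, else bp to the nearest peak
    edge (``center`` mode measures to peak midpoints instead).  A site on
    a chromosome with no peaks of a feature gets NaN.
    """
    out = sites.copy()
    for feature, df in peaks.items():
        prepared: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in df.groupby("chrom"):
            grp = grp.sort_values("start")
            prepared[chrom] = (
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
            )
        dists = []
        for _, site in sites.iterrows():
            iv = prepared.get(site["chrom"])
            if iv is None:
                dists.append(np.nan)
                continue
            pos0 = int(site["pos"]) - 1
            if mode == "center":
                centers = (iv[0] + iv[1]) // 2
                dists.append(int(np.abs(centers - pos0).min()))
            else:
                dists.append(_interval_distance(pos0, iv[0], iv[1]))
        out[f"dist_{feature}"] = dists
    return out


def bin_by_distance(
    distances,
    bin_width: int = 100,
    max_dist: int = 1000,
) -> pd.Series:
    """Histogram of absolute distances within [0, max_dist].

    Sites beyond ``max_dist`` (and NaN distances) are excluded; the last
    bin's right edge is inclusive.
    """
    d = np.abs(np.asarray(distances, dtype=float))
    d = d[~np.isnan(d)]
    edges = np.arange(0, max_dist + bin_width, bin_width)
    counts, _ = np.histogram(d[d <= max_dist], bins=edges)
    labels = [f"[{int(lo)},{int(hi)})" for lo, hi in zip(edges[:-2], edges[1:-1])]
    labels.append(f"[{int(edges[-2])},{int(edges[-1])}]")
    return pd.Series(counts, index=labels)


# ---------------------------------------------------------------------------
# Enrichment test
# ---------------------------------------------------------------------------


def chisq_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared test with Yates continuity correction on a 2x2 table.

    Table rows are (a, b) and (c, d).  The statistic is

        N * (max(|ad - bc| - N/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d))

    with N = a+b+c+d; the p-value comes from chi-squared with 1 df.
    """
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if n <= 0 or any(m == 0 for m in margins):
        raise ValueError("degenerate table")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    stat = n * num * num / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(scipy.stats.chi2.sf(stat, df=1))
    return float(stat), p


def proximity_enrichment(
    vis_distances,
    random_distances,
    max_dist: int = 1000,
) -> dict:
    """Test whether sites fall within ``max_dist`` of a feature more often
    than motif-matched random sites.  Returns counts, percentages and the
    Yates chi-squared statistic/p-value."""
    v = np.asarray(vis_distances, dtype=float)
    r = np.asarray(random_distances, dtype=float)
    v_in = int(np.nansum(v <= max_dist))
    r_in = int(np.nansum(r <= max_dist))
    v_out, r_out = len(v) - v_in, len(r) - r_in
    stat, p = chisq_yates(v_in, v_out, r_in, r_out)
    return {
        "vis_near": v_in, "vis_far": v_out,
        "random_near": r_in, "random_far": r_out,
        "vis_pct": 100.0 * v_in / len(v),
        "random_pct": 100.0 * r_in / len(r),
        "statistic": stat, "p_value": p,
    }


# ---------------------------------------------------------------------------
# Coverage matrices
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    return df


def _track_arrays(
    track: pd.DataFrame | str | Path,
    chrom_lengths: Mapping[str, int],
) -> dict[str, np.ndarray]:
    """Materialize a coverage track as per-chromosome float32 arrays."""
    if isinstance(track, (str, Path)) and str(track).endswith((".bw", ".bigwig")):
        import pyBigWig

        bw = pyBigWig.open(str(track))
        out = {}
        for chrom, length in chrom_lengths.items():
            vals = np.nan_to_num(
                np.asarray(bw.values(chrom, 0, length), dtype=np.float32)
            )
            out[chrom] = vals
        bw.close()
        return out
    if isinstance(track, (str, Path)):
        track = read_bedgraph(track)
    out = {c: np.zeros(l, dtype=np.float32) for c, l in chrom_lengths.items()}
    for chrom, start, end, value in track.itertuples(index=False):
        if chrom in out:
            out[chrom][start:end] = value
    return out


def _bin_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.linspace(0, len(values), n_bins + 1).astype(int)
    return np.array(
        [values[lo:hi].mean() if hi > lo else 0.0 for lo, hi in zip(edges[:-1], edges[1:])]
    )


@dataclass
class CoverageMatrix:
    matrix: np.ndarray  # anchors x bins
    clipped: np.ndarray  # bool per anchor: window hit a chromosome edge

    @property
    def profile(self) -> np.ndarray:
        """Per-bin mean over anchors (the profile-plot curve)."""
        return self.matrix.mean(axis=0)


def coverage_matrix(
    anchors: pd.DataFrame,
    track: pd.DataFrame | str | Path,
    chrom_lengths: Mapping[str, int],
    flank: int = 1000,
    n_bins: int = 40,
    mode: Literal["reference_point", "scale_regions"] = "reference_point",
    body_bins: int = 40,
) -> CoverageMatrix:
    """Coverage matrix around anchors for profile plots.

    ``reference_point``: the +-``flank`` bp window around each site's
    position, binned into ``n_bins`` mean-coverage bins.  Out-of-range
    parts of a window contribute 0 and flag the anchor as clipped.

    ``scale_regions``: each anchor is an interval (columns start/end,
    1-based inclusive); the body is rescaled to ``body_bins`` bins with
    unscaled ``flank`` bp flanks of ``n_bins`` bins each side (the
    TSS-to-TES metagene layout).
    """
    arrays = _track_arrays(track, chrom_lengths)
    rows, clipped = [], []
    for _, a in anchors.iterrows():
        arr = arrays.get(a["chrom"])
        if arr is None:
            rows.append(np.zeros(n_bins if mode == "reference_point" else 2 * n_bins + body_bins))
            clipped.append(True)
            continue
        if mode == "reference_point":
            center = int(a["pos"]) - 1
            lo, hi = center - flank, center + flank
            clip = lo < 0 or hi > len(arr)
            window = np.zeros(2 * flank, dtype=np.float32)
            src_lo, src_hi = max(lo, 0), min(hi, len(arr))
            window[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
            rows.append(_bin_means(window, n_bins))
            clipped.append(clip)
        else:
            start0, end0 = int(a["start"]) - 1, int(a["end"])
            up = np.zeros(flank, dtype=np.float32)
            dn = np.zeros(flank, dtype=np.float32)
            u_lo = max(start0 - flank, 0)
            up[u_lo - (start0 - flank):] = arr[u_lo:start0]
            d_hi = min(end0 + flank, len(arr))
            dn[: d_hi - end0] = arr[end0:d_hi]
            body = arr[start0:end0]
            rows.append(
                np.concatenate(
                    [_bin_means(up, n_bins), _bin_means(body, body_bins), _bin_means(dn, n_bins)]
                )
            )
            clipped.append(start0 - flank < 0 or end0 + flank > len(arr))
    return CoverageMatrix(np.vstack(rows), np.asarray(clipped, dtype=bool))


def feature_pca(
    profiles: Mapping[str, np.ndarray], n_components: int = 2
) -> pd.DataFrame:
    """Project per-feature mean coverage profiles onto principal components.

    Rows of the result are features, columns PC1..PCn; features whose
    coverage shape around sites differs (e.g. gene-body marks vs TSS
    marks) separate along the leading axes.
    """
    from sklearn.decomposition import PCA

    names = list(profiles)
    X = np.vstack([profiles[n] for n in names])
    n_components = min(n_components, len(names), X.shape[1])
    pcs = PCA(n_components=n_components).fit_transform(X)
    return pd.DataFrame(
        pcs, index=names, columns=[f"PC{i+1}" for i in range(pcs.shape[1])]
    )
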