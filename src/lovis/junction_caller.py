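"""Call vector-host junction coordinates from LTR-junction sequencing reads.

A valid junction read runs through the 3'-end U5 region of the lentiviral
LTR into flanking host DNA.  The last 16 nt of the U5 region carry the
LTR index (barcode) that distinguishes vector populations.  Calling a read
therefore proceeds in three steps:

1. locate the LTR terminal anchor inside the read (Hamming scan, no indels),
2. classify the 16-nt index window against the configured index set,
3. map the remaining host segment onto the reference genome and validate
   the placement (two-pass: global search, then local re-alignment around
   the best candidate window).

A read is accepted as a true integration-site read-out only if the host
segment aligns with >= 95% identity over >= 25 bases at a unique best
placement.  Coordinates are 0-based half-open internally; emitted tables
are 1-based inclusive.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LTR_INDEXES",
    "DEFAULT_LTR_ANCHOR",
    "LtrIndexSet",
    "JunctionRead",
    "IntegrationSite",
    "ReferenceIndex",
    "classify_ltr_index",
    "extract_host_junction",
    "validate_and_map",
    "call_reads",
    "write_calls",
]

# Vector LTR barcodes embedded at the 3' terminus of U5.  The WT entry is
# the unmodified U5 terminal sequence; H1 and H5 are barcoded variants.
DEFAULT_LTR_INDEXES: dict[str, str] = {
    "H1": "TGGAAAATCTCCAACA",
    "H5": "TGGAAAATATCCAACA",
    "WT": "TGGAAAATCTCTAGCA",
}

INDEX_LENGTH = 16

# U5 terminal anchor used to locate the LTR-host junction.  The final
# INDEX_LENGTH bases are the index window; anchor matching treats them as
# wildcards so that every barcode variant matches the same template.
DEFAULT_ANCHOR_PREFIX = "CCCTTTTAGTCAGTG"
DEFAULT_LTR_ANCHOR = DEFAULT_ANCHOR_PREFIX + DEFAULT_LTR_INDEXES["WT"]

DEFAULT_MIN_HOST_LEN = 25
DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_REALIGN_WINDOW = 500

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LtrIndexSet:
    """A set of LTR barcode sequences, all of equal length, unique labels."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate index labels")
        lengths = {len(seq) for _, seq in self.entries}
        if len(lengths) > 1:
            raise ValueError("all index sequences must have the same length")

    @property
    def index_length(self) -> int:
        return len(self.entries[0][1])

    @classmethod
    def default(cls) -> "LtrIndexSet":
        return cls(tuple(DEFAULT_LTR_INDEXES.items()))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LtrIndexSet":
        df = pd.read_csv(path, sep="\t", header=None, names=["label", "seq"])
        return cls(tuple(zip(df["label"], df["seq"].str.upper())))


@dataclass
class JunctionRead:
    """A read decomposed at the LTR-host junction."""

    read_id: str
    sequence: str
    status: str  # ok | short-host | no-LTR
    ltr_end_offset: int = -1
    index_window: str = ""
    host_segment: str = ""


@dataclass(frozen=True)
class IntegrationSite:
    """An accepted vector-host junction coordinate.

    ``pos`` is the 1-based coordinate of the first host base at the
    junction; ``strand`` is the orientation in which host sequence runs
    away from the vector.
    """

    chrom: str
    pos: int
    strand: str
    index_label: str
    identity: float
    matched_len: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def classify_ltr_index(
    window: str,
    index_set: LtrIndexSet | None = None,
    max_mismatch: int = 1,
) -> str:
    """Classify an index window against the barcode set.

    Returns the unique label whose barcode has minimal Hamming distance
    <= ``max_mismatch`` to the window and a strictly smaller distance than
    every other barcode; ties and windows shorter than the barcode length
    yield ``"unclassified"``.
    """
    index_set = index_set or LtrIndexSet.default()
    L = index_set.index_length
    if len(window) < L:
        return "unclassified"
    window = window[:L].upper()
    best_label, best_d, second_d = "unclassified", L + 1, L + 1
    for label, seq in index_set.entries:
        d = hamming(window, seq)
        if d < best_d:
            best_label, second_d, best_d = label, best_d, d
        elif d < second_d:
            second_d = d
    if best_d <= max_mismatch and best_d < second_d:
        return best_label
    return "unclassified"


def _mismatches_at(seq: str, pos: int, template: str, limit: int) -> int:
    """Mismatch count of ``template`` placed at ``pos`` (N = wildcard)."""
    n = 0
    for i, t in enumerate(template):
        if t != "N" and seq[pos + i] != t:
            n += 1
            if n > limit:
                return n
    return n


def extract_host_junction(
    read_id: str,
    sequence: str,
    anchor: str = DEFAULT_LTR_ANCHOR,
    index_offset: int | None = None,
    index_length: int = INDEX_LENGTH,
    max_anchor_mismatch: int = 2,
    min_host_len: int = DEFAULT_MIN_HOST_LEN,
) -> JunctionRead:
    """Split a read at the LTR terminal anchor.

    The anchor is located by a Hamming scan (no indels permitted inside
    the anchor); the ``index_length`` bases starting at ``index_offset``
    within the anchor (default: its 3' end) are treated as wildcards so
    that any barcode variant matches.  The host segment is everything
    downstream of the anchor.  Reads without an anchor match are flagged
    ``no-LTR``; reads whose host segment is shorter than ``min_host_len``
    are flagged ``short-host``.
    """
    sequence = sequence.upper()
    if index_offset is None:
        index_offset = len(anchor) - index_length
    template = (
        anchor[:index_offset].upper()
        + "N" * index_length
        + anchor[index_offset + index_length:].upper()
    )
    n_pos = len(sequence) - len(template)
    if n_pos < 0:
        return JunctionRead(read_id, sequence, "no-LTR")

    # Reads normally begin with the LTR; check offset 0 before scanning.
    best_pos, best_mm = -1, max_anchor_mismatch + 1
    for pos in range(n_pos + 1):
        mm = _mismatches_at(sequence, pos, template, max_anchor_mismatch)
        if mm < best_mm:
            best_pos, best_mm = pos, mm
            if mm == 0:
                break
    if best_mm > max_anchor_mismatch:
        return JunctionRead(read_id, sequence, "no-LTR")

    end = best_pos + len(template)
    window = sequence[best_pos + index_offset : best_pos + index_offset + index_length]
    host = sequence[end:]
    status = "ok" if len(host) >= min_host_len else "short-host"
    return JunctionRead(read_id, sequence, status, end, window, host)


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

SEED_LENGTH = 20


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class ReferenceIndex:
    """Reference genome held in memory with an exact-seed k-mer index.

    Loads either a FASTA path (via pyfaidx) or a chrom -> sequence mapping.
    The index maps every forward-strand ``SEED_LENGTH``-mer to its
    positions and drives the seed-and-verify placement search.
    """

    def __init__(self, source: str | Path | Mapping[str, str], seed_len: int = SEED_LENGTH):
        if isinstance(source, (str, Path)):
            from pyfaidx import Fasta

            fa = Fasta(str(source))
            self.seqs = {name: str(fa[name][:]).upper() for name in fa.keys()}
        else:
            self.seqs = {c: s.upper() for c, s in source.items()}
        self.lengths = {c: len(s) for c, s in self.seqs.items()}
        self.seed_len = seed_len
        self._build_index()

    def _build_index(self) -> None:
        k = self.seed_len
        hash_parts, chrom_parts, pos_parts = [], [], []
        self._chrom_names = list(self.seqs)
        for ci, chrom in enumerate(self._chrom_names):
            codes = _encode(self.seqs[chrom])
            n = len(codes) - k + 1
            if n <= 0:
                continue
            h = np.zeros(n, dtype=np.int64)
            valid = np.ones(n, dtype=bool)
            for j in range(k):
                h = (h << 2) | codes[j : j + n]
                valid &= codes[j : j + n] >= 0
            hash_parts.append(h[valid])
            pos_parts.append(np.nonzero(valid)[0].astype(np.int64))
            chrom_parts.append(np.full(int(valid.sum()), ci, dtype=np.int32))
        if hash_parts:
            hashes = np.concatenate(hash_parts)
            order = np.argsort(hashes, kind="stable")
            self._sorted_hashes = hashes[order]
            self._sorted_pos = np.concatenate(pos_parts)[order]
            self._sorted_chrom = np.concatenate(chrom_parts)[order]
        else:  # all chromosomes shorter than the seed
            self._sorted_hashes = np.empty(0, dtype=np.int64)
            self._sorted_pos = np.empty(0, dtype=np.int64)
            self._sorted_chrom = np.empty(0, dtype=np.int32)

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        """All forward-strand positions of an exact ``seed_len``-mer."""
        codes = _encode(kmer)
        if len(codes) != self.seed_len or (codes < 0).any():
            return []
        h = 0
        for c in codes:
            h = (h << 2) | int(c)
        lo = np.searchsorted(self._sorted_hashes, h, side="left")
        hi = np.searchsorted(self._sorted_hashes, h, side="right")
        return [
            (self._chrom_names[self._sorted_chrom[i]], int(self._sorted_pos[i]))
            for i in range(lo, hi)
        ]

    def items(self):
        return self.seqs.items()


def _seed_candidates(ref: "ReferenceIndex", query: str) -> set[tuple[str, int]]:
    """Candidate (chrom, start) placements from exact seed halves.

    With substitution-only divergence, any placement with at most one
    error-containing half is found; indel-shifted or doubly-errored
    placements fall through to the edlib search.
    """
    k = ref.seed_len
    cands: set[tuple[str, int]] = set()
    offsets = [0]
    if len(query) > k:
        offsets.append(len(query) - k)
    for offset in offsets:
        for chrom, hit in ref.seed_hits(query[offset : offset + k]):
            start = hit - offset
            if 0 <= start <= ref.lengths[chrom] - len(query):
                cands.add((chrom, start))
    return cands


def _hamming_limited(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def _edlib_placements(target: str, query: str, max_k: int):
    """(distance, [start positions]) of best infix alignments, or None."""
    res = edlib.align(query, target, mode="HW", task="locations", k=max_k)
    if res["editDistance"] == -1:
        return None
    starts = sorted({loc[0] for loc in res["locations"] if loc[0] is not None})
    return res["editDistance"], starts


def _dedupe_placements(starts: list[int], min_sep: int) -> list[int]:
    out: list[int] = []
    for s in sorted(starts):
        if not out or s - out[-1] >= min_sep:
            out.append(s)
    return out


def _alignment_identity(window: str, query: str):
    """Re-align query inside window; (identity, aligned_cols, start_in_window).

    Identity is the fraction of matching columns over all alignment columns
    (mismatches and indels both count against it).
    """
    res = edlib.align(query, window, mode="HW", task="path")
    if res["editDistance"] == -1:  # pragma: no cover - unbounded k never fails
        return 0.0, 0, 0
    start, end = res["locations"][0]
    cols = 0
    matches = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        cols += n
        if ch == "=":
            matches += n
    return matches / cols if cols else 0.0, cols, start


def validate_and_map(
    junction: JunctionRead | str,
    reference: ReferenceIndex,
    index_label: str = "",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_len: int = DEFAULT_MIN_HOST_LEN,
    realign_window: int = DEFAULT_REALIGN_WINDOW,
):
    """Place a host segment on the reference and validate the placement.

    Two-pass contract: first the best local placement of the host segment
    is searched on both strands of every chromosome (exact match, then
    exact 20-mer seeds with Hamming verification, then edlib infix
    alignment as fallback); second, the segment is re-aligned against the
    +-``realign_window`` bp window around the best candidate and accepted
    iff identity >= ``min_identity`` over >= ``min_len`` aligned bases and
    the best placement is unique (second-best strictly worse).

    Returns ``(IntegrationSite | None, status)`` where status is one of
    ``accepted``, ``unmapped``, ``multimapped``, ``low-identity``.
    """
    host = junction.host_segment if isinstance(junction, JunctionRead) else junction
    host = host.upper()
    L = len(host)
    if L < min_len:
        return None, "unmapped"
    max_k = max(int(np.ceil(L * (1.0 - min_identity))) + 1, 2)

    # placements: (distance, chrom, strand, start0_on_forward_ref)
    placements: list[tuple[int, str, str, int]] = []
    queries = {"+": host, "-": revcomp(host)}
    for strand, q in queries.items():
        for chrom, s in _seed_candidates(reference, q):
            d = _hamming_limited(reference.seqs[chrom][s : s + L], q, max_k)
            if d <= max_k:
                placements.append((d, chrom, strand, s))
    if not placements:
        # indels or errors in both seed halves: full edlib infix search
        for chrom, seq in reference.items():
            for strand, q in queries.items():
                hit = _edlib_placements(seq, q, max_k)
                if hit is not None:
                    d, starts = hit
                    placements.extend(
                        (d, chrom, strand, s) for s in _dedupe_placements(starts, L)
                    )
    if not placements:
        return None, "unmapped"

    placements.sort(key=lambda t: t[0])
    best_d = placements[0][0]
    best = [p for p in placements if p[0] == best_d]
    if len(best) > 1:
        return None, "multimapped"
    _, chrom, strand, start = best[0]

    # Second pass: re-align within the local candidate window.
    seq = reference.seqs[chrom]
    w_lo = max(0, start - realign_window)
    w_hi = min(len(seq), start + L + realign_window)
    identity, cols, in_window = _alignment_identity(seq[w_lo:w_hi], queries[strand])
    if cols < min_len or identity < min_identity:
        return None, "low-identity"
    ref_start0 = w_lo + in_window

    if strand == "+":
        pos0 = ref_start0  # first host base
    else:
        pos0 = ref_start0 + cols - 1  # junction base is the 3' end on the ref
    site = IntegrationSite(
        chrom=chrom,
        pos=pos0 + 1,
        strand=strand,
        index_label=index_label,
        identity=round(identity, 6),
        matched_len=cols,
    )
    return site, "accepted"


# ---------------------------------------------------------------------------
# Read-level driver
# ---------------------------------------------------------------------------


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq)


def call_reads(
    reads: Iterable[tuple[str, str]] | str | Path,
    reference: ReferenceIndex,
    index_set: LtrIndexSet | None = None,
    anchor: str = DEFAULT_LTR_ANCHOR,
    max_index_mismatch: int = 1,
    min_host_len: int = DEFAULT_MIN_HOST_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> pd.DataFrame:
    """Run the full per-read caller over a FASTQ file or (id, seq) pairs.

    Returns the per-read table with one row per input read:
    read_id, status, index_label, chrom, pos, strand, identity, matched_len.
    Results are cached per unique read sequence.
    """
    index_set = index_set or LtrIndexSet.default()
    if isinstance(reads, (str, Path)):
        reads = _iter_fastq(reads)

    cache: dict[str, tuple] = {}
    rows = []
    for read_id, seq in reads:
        hit = cache.get(seq)
        if hit is None:
            jr = extract_host_junction(
                "", seq, anchor=anchor, min_host_len=min_host_len
            )
            if jr.status != "ok":
                hit = (jr.status, "unclassified", "", 0, "", np.nan, 0)
            else:
                label = classify_ltr_index(jr.index_window, index_set, max_index_mismatch)
                site, status = validate_and_map(
                    jr, reference, index_label=label,
                    min_identity=min_identity, min_len=min_host_len,
                )
                if site is None:
                    hit = (status, label, "", 0, "", np.nan, 0)
                else:
                    hit = (
                        "accepted", label, site.chrom, site.pos, site.strand,
                        site.identity, site.matched_len,
                    )
            cache[seq] = hit
        rows.append((read_id, *hit))
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "status", "index_label", "chrom", "pos", "strand",
            "identity", "matched_len",
        ],
    )


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)
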