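"""Barcode extraction and counting from pooled-screen sequencing reads.

Each clone in a pooled competition experiment carries a random 10-bp DNA
barcode embedded in a fixed cassette, 5'-CTAGACTGCC-XXXXXXXXXX-GGATCACTCT-3'.
This module locates the cassette in raw (optionally paired-end) FASTQ reads,
extracts the barcode between the two flanks, and tallies per-sample counts
against a barcode map that links barcodes to variants and clone indices.

Reads are partitioned exhaustively into three bins per sample: *assigned*
(cassette found, barcode present in the map), *unassigned* (cassette found,
barcode unknown), and *no_context* (no cassette placement found), so that
assigned + unassigned + no_context always equals the number of read pairs
processed.
"""
from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BarcodeContext:
    """Fixed flanking context around the embedded barcode.

    Parameters
    ----------
    flank5, flank3
        Constant sequences immediately 5' and 3' of the barcode.
    barcode_length
        Number of bases between the flanks.
    max_flank_mismatches
        Maximum Hamming distance tolerated in *each* flank. Mismatches are
        never allowed inside the barcode itself: any 10-mer is a priori a
        valid barcode, so a sequencing error there is unrecoverable and the
        read falls into the unassigned bin instead.
    search_reverse_complement
        Also scan the reverse complement of each mate.
    min_barcode_quality
        Optional minimum mean Phred quality over the barcode window; reads
        below it are treated as no-context. Off by default.
    """

    flank5: str = "CTAGACTGCC"
    flank3: str = "GGATCACTCT"
    barcode_length: int = 10
    max_flank_mismatches: int = 0
    search_reverse_complement: bool = True
    min_barcode_quality: float | None = None

    def __post_init__(self) -> None:
        for name in ("flank5", "flank3"):
            flank = getattr(self, name)
            if not flank or set(flank) - _DNA:
                raise ValueError(f"{name} must be non-empty uppercase DNA over ACGT, got {flank!r}")
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")
        if not 0 <= self.max_flank_mismatches < min(len(self.flank5), len(self.flank3)):
            raise ValueError("max_flank_mismatches must be < min flank length and >= 0")

    @property
    def span(self) -> int:
        return len(self.flank5) + self.barcode_length + len(self.flank3)


class Extraction(NamedTuple):
    """A successful barcode placement within a read pair."""

    barcode: str
    mate: int  # 1 or 2
    strand: str  # "+" forward, "-" reverse complement
    start: int  # barcode start within the scanned orientation of the mate


def _scan_exact(seq: str, ctx: BarcodeContext) -> int | None:
    """Leftmost barcode start position for exact flank matches, or None."""
    f5, f3, blen = ctx.flank5, ctx.flank3, ctx.barcode_length
    pos = seq.find(f5)
    while pos != -1:
        bstart = pos + len(f5)
        bend = bstart + blen
        if bend + len(f3) <= len(seq) and seq[bend : bend + len(f3)] == f3:
            return bstart
        pos = seq.find(f5, pos + 1)
    return None


def _scan_hamming(seq: str, ctx: BarcodeContext) -> int | None:
    """Leftmost barcode start allowing <= k mismatches per flank, or None."""
    n = len(seq)
    if n < ctx.span:
        return None
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    f5 = np.frombuffer(ctx.flank5.encode("ascii"), dtype=np.uint8)
    f3 = np.frombuffer(ctx.flank3.encode("ascii"), dtype=np.uint8)
    mm5 = (sliding_window_view(arr, len(f5)) != f5).sum(axis=1)
    mm3 = (sliding_window_view(arr, len(f3)) != f3).sum(axis=1)
    k = ctx.max_flank_mismatches
    offset = len(ctx.flank5) + ctx.barcode_length
    starts = np.nonzero(mm5[: n - ctx.span + 1] <= k)[0]
    for pos in starts:  # ascending: leftmost placement wins
        if mm3[pos + offset] <= k:
            return int(pos) + len(ctx.flank5)
    return None


def extract_barcode(seq: str, ctx: BarcodeContext) -> int | None:
    """Return the leftmost barcode start position in ``seq``, or None.

    With ``max_flank_mismatches == 0`` this is a plain substring scan;
    otherwise every placement within the Hamming tolerance is considered and
    the leftmost one wins, keeping the result deterministic when a read
    happens to admit more than one placement.
    """
    if ctx.max_flank_mismatches == 0:
        return _scan_exact(seq, ctx)
    return _scan_hamming(seq, ctx)


def extract_from_pair(
    seq1: str,
    seq2: str | None,
    ctx: BarcodeContext,
) -> Extraction | None:
    """Scan mate 1 then mate 2, forward then reverse complement; first hit wins."""
    mates = [(1, seq1)] if seq2 is None else [(1, seq1), (2, seq2)]
    for mate, seq in mates:
        seq = seq.upper()
        orientations = [("+", seq)]
        if ctx.search_reverse_complement:
            orientations.append(("-", reverse_complement(seq)))
        for strand, oriented in orientations:
            start = extract_barcode(oriented, ctx)
            if start is not None:
                return Extraction(oriented[start : start + ctx.barcode_length], mate, strand, start)
    return None


@dataclass
class BarcodeMap:
    """Lookup from barcode to (variant, clone index), plus designated references.

    Every variant carries one to three independently barcoded clones; the
    clone index distinguishes them. ``reference_ids`` names the drug-inert
    scaling controls (KRAS_G12V in vitro, GFP in vivo).
    """

    entries: pd.DataFrame  # index: barcode; columns: variant_id, clone_index
    reference_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.entries.index.is_unique:
            dupes = self.entries.index[self.entries.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate barcodes in map: {dupes[:5]}")
        clones_per_variant = self.entries.groupby("variant_id").size()
        bad = clones_per_variant[(clones_per_variant < 1) | (clones_per_variant > 3)]
        if len(bad):
            raise ValueError(f"variants must have 1-3 clones, offending: {bad.index.tolist()[:5]}")
        missing = set(self.reference_ids) - set(self.entries["variant_id"])
        if missing:
            raise ValueError(f"reference_ids absent from map: {sorted(missing)}")

    @property
    def barcodes(self) -> pd.Index:
        return self.entries.index

    @property
    def variant_ids(self) -> list[str]:
        return self.entries["variant_id"].unique().tolist()

    @classmethod
    def from_tsv(cls, path: str | Path, reference_ids: Iterable[str] = ()) -> "BarcodeMap":
        df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "variant_id": str})
        required = {"barcode", "variant_id", "clone_index"}
        if not required.issubset(df.columns):
            raise ValueError(f"barcode map must have columns {sorted(required)}, got {list(df.columns)}")
        return cls(df.set_index("barcode")[["variant_id", "clone_index"]], frozenset(reference_ids))

    def to_tsv(self, path: str | Path) -> None:
        self.entries.reset_index(names="barcode").to_csv(path, sep="\t", index=False)


@dataclass
class CountTable:
    """Reads per barcode per sample, with the per-sample conservation tallies."""

    counts: pd.DataFrame  # index: barcode; columns: sample id
    unassigned: pd.Series  # per sample: cassette found, barcode unknown
    no_context: pd.Series  # per sample: no cassette placement
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)  # index: sample id

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total_reads(self) -> pd.Series:
        return self.counts.sum(axis=0) + self.unassigned + self.no_context

    def check_conservation(self, totals: Mapping[str, int]) -> None:
        for sample, total in totals.items():
            observed = int(self.total_reads[sample])
            if observed != total:
                raise AssertionError(
                    f"read conservation violated for {sample}: {observed} != {total}"
                )

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        self.counts.rename_axis("barcode").to_csv(path, sep="\t")
        if sidecar is not None:
            tallies = {
                sample: {
                    "assigned": int(self.counts[sample].sum()),
                    "unassigned": int(self.unassigned[sample]),
                    "no_context": int(self.no_context[sample]),
                }
                for sample in self.counts.columns
            }
            Path(sidecar).write_text(json.dumps(tallies, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path, sidecar: str | Path | None = None) -> "CountTable":
        counts = pd.read_csv(path, sep="\t", index_col="barcode")
        if sidecar is not None:
            tallies = json.loads(Path(sidecar).read_text())
            unassigned = pd.Series({s: t["unassigned"] for s, t in tallies.items()})
            no_context = pd.Series({s: t["no_context"] for s, t in tallies.items()})
        else:
            unassigned = pd.Series(0, index=counts.columns)
            no_context = pd.Series(0, index=counts.columns)
        return cls(counts, unassigned, no_context)


def _iter_read_pairs(
    r1: str | Path, r2: str | Path | None
) -> Iterator[tuple[int, str, str | None, str | None, str | None]]:
    """Yield (index, seq1, seq2, qual1, qual2) from FASTQ(.gz) file(s)."""
    with pysam.FastxFile(str(r1)) as fh1:
        if r2 is None:
            for i, rec in enumerate(fh1):
                if not rec.sequence:
                    raise ValueError(f"malformed FASTQ record at index {i} in {r1}")
                yield i, rec.sequence, None, rec.quality, None
        else:
            with pysam.FastxFile(str(r2)) as fh2:
                sentinel = object()
                it1, it2 = iter(fh1), iter(fh2)
                i = 0
                while True:
                    rec1 = next(it1, sentinel)
                    rec2 = next(it2, sentinel)
                    if rec1 is sentinel and rec2 is sentinel:
                        return
                    if rec1 is sentinel or rec2 is sentinel:
                        raise ValueError(
                            f"paired FASTQ files desynchronised at record index {i}"
                        )
                    if not rec1.sequence or not rec2.sequence:
                        raise ValueError(f"malformed FASTQ record at index {i}")
                    yield i, rec1.sequence, rec2.sequence, rec1.quality, rec2.quality
                    i += 1


def _mean_quality(qual: str | None, start: int, length: int) -> float:
    if qual is None:
        return float("inf")
    window = qual[start : start + length]
    if not window:
        return float("inf")
    return float(np.mean([ord(c) - 33 for c in window]))


def count_sample(
    r1: str | Path,
    r2: str | Path | None,
    ctx: BarcodeContext,
    bmap: BarcodeMap,
) -> tuple[pd.Series, int, int, int]:
    """Count one sample's reads against the barcode map.

    Returns (per-barcode counts over the map's barcodes, unassigned,
    no_context, total read pairs). Extracted barcodes that are not in the
    map are tallied as unassigned; reads without a cassette placement as
    no_context, so the three bins partition the input exactly.
    """
    if len(bmap.entries) == 0:
        raise ValueError("barcode map is empty")
    known = set(bmap.barcodes)
    tally: Counter[str] = Counter()
    unassigned = no_context = total = 0
    for i, seq1, seq2, q1, q2 in _iter_read_pairs(r1, r2):
        total += 1
        hit = extract_from_pair(seq1, seq2, ctx)
        if hit is None:
            no_context += 1
            continue
        if ctx.min_barcode_quality is not None:
            qual = q1 if hit.mate == 1 else q2
            if hit.strand == "-" and qual is not None:
                qual = qual[::-1]
            if _mean_quality(qual, hit.start, ctx.barcode_length) < ctx.min_barcode_quality:
                no_context += 1
                continue
        if hit.barcode in known:
            tally[hit.barcode] += 1
        else:
            unassigned += 1
    if total == 0:
        logger.warning("empty input file %s: emitting an all-zero column", r1)
    counts = pd.Series(tally, dtype=int).reindex(bmap.barcodes, fill_value=0)
    return counts, unassigned, no_context, total


def count_samples(
    fastqs: Mapping[str, tuple[str | Path, str | Path | None]],
    ctx: BarcodeContext,
    bmap: BarcodeMap,
    samples: pd.DataFrame | None = None,
) -> CountTable:
    """Build a CountTable from {sample_id: (r1_path, r2_path or None)}."""
    columns, unassigned, no_context = {}, {}, {}
    for sample_id, (r1, r2) in fastqs.items():
        col, un, nc, total = count_sample(r1, r2, ctx, bmap)
        columns[sample_id] = col
        unassigned[sample_id] = un
        no_context[sample_id] = nc
        assert int(col.sum()) + un + nc == total  # read conservation
    table = CountTable(
        pd.DataFrame(columns),
        pd.Series(unassigned, dtype=int),
        pd.Series(no_context, dtype=int),
        samples if samples is not None else pd.DataFrame(index=list(fastqs)),
    )
    return table


def count_reads_in_memory(
    reads: Sequence[tuple[str, str | None]],
    ctx: BarcodeContext,
    bmap: BarcodeMap,
) -> tuple[pd.Series, int, int]:
    """Count an in-memory list of (seq1, seq2) read pairs; used for testing
    and for piping simulated reads through without touching disk."""
    known = set(bmap.barcodes)
    tally: Counter[str] = Counter()
    unassigned = no_context = 0
    for seq1, seq2 in reads:
        hit = extract_from_pair(seq1, seq2, ctx)
        if hit is None:
            no_context += 1
        elif hit.barcode in known:
            tally[hit.barcode] += 1
        else:
            unassigned += 1
    return pd.Series(tally, dtype=int).reindex(bmap.barcodes, fill_value=0), unassigned, no_context
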