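"""Pause windows, gene bodies and per-gene density extraction.

The pause region of a gene is the 50 bp window with maximal summed signal
within a search region (200 bp for PRO-seq, 300 bp for GRO-seq) downstream
of the TSS; the pause density ``p`` is the summed signal in that window.
The gene body starts 500 bp past the pause window and ends at the TTS, or at
the distance an initiated polymerase can travel during the treatment at the
assumed elongation rate, whichever is shorter; the body density ``b`` is the
mean per-bp signal there.

Coordinates are 0-based half-open.  Minus-strand genes are processed on
flipped (sense) coordinates so "downstream of the TSS" is always increasing
offsets; recorded intervals are converted back to genomic coordinates.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .tracks import SignalTrack

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "PauseWindow",
    "DensityRecord",
    "read_bed6",
    "read_gene_list",
    "find_pause_window",
    "define_gene_body",
    "pause_sum",
    "body_mean",
    "sense_signal",
    "compute_densities",
    "DENSITY_COLUMNS",
]

DENSITY_COLUMNS = [
    "gene_id",
    "chrom",
    "strand",
    "pause_start",
    "pause_end",
    "pause_sum",
    "body_start",
    "body_end",
    "body_mean",
    "condition",
    "replicate",
]


@dataclass(frozen=True)
class GeneModel:
    """One annotated transcription unit.

    ``tss``/``tts`` are genomic 0-based positions with ``tss < tts``; for
    minus-strand genes the biological start site is at ``tts - 1`` and
    transcription proceeds toward ``tss``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidParameterError(f"strand must be + or -, got {self.strand!r}")
        if not self.tss < self.tts:
            raise InvalidParameterError(
                f"{self.gene_id}: tss must be < tts ({self.tss} >= {self.tts})"
            )

    @property
    def length(self) -> int:
        return self.tts - self.tss

    def sense_to_genomic(self, start_off: int, end_off: int) -> tuple[int, int]:
        """Map a sense-strand offset interval (0 = TSS) to genomic coordinates."""
        if self.strand == "+":
            return self.tss + start_off, self.tss + end_off
        anchor = self.tts - 1  # biological TSS base
        return anchor - end_off + 1, anchor - start_off + 1


@dataclass(frozen=True)
class PauseWindow:
    """Sense-strand half-open offset interval of the pause region."""

    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class DensityRecord:
    """Pause sum and body mean for one gene in one sample."""

    gene_id: str
    chrom: str
    strand: str
    pause_start: int
    pause_end: int
    pause_sum: float
    body_start: int
    body_end: int
    body_mean: float
    condition: str
    replicate: str


def read_bed6(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene annotations from a BED6 file (name field = gene id)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=range(6),
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    genes = [
        GeneModel(
            gene_id=row.name_,
            chrom=row.chrom,
            strand=row.strand,
            tss=int(row.start),
            tts=int(row.end),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise InvalidParameterError("duplicate gene ids in annotation")
    return genes


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Read a plain-text gene list, one id per line, '#' comments allowed."""
    with open(path) as fh:
        return [
            line.strip()
            for line in fh
            if line.strip() and not line.startswith("#")
        ]


def sense_signal(track: SignalTrack, gene: GeneModel, length: int | None = None) -> np.ndarray:
    """Per-base signal downstream of the TSS in the direction of transcription.

    Index 0 is the TSS base.  ``length`` defaults to the gene length; bases
    beyond the chromosome read as 0.
    """
    n = gene.length if length is None else length
    if gene.strand == "+":
        return track.values(gene.chrom, gene.tss, gene.tss + n)
    anchor = gene.tts - 1
    vals = track.values(gene.chrom, max(anchor - n + 1, 0), anchor + 1)
    if vals.size < n:  # TSS near chromosome start
        vals = np.concatenate([np.zeros(n - vals.size), vals])
    return vals[::-1]


def find_pause_window(
    signal: np.ndarray, search_len: int = 200, window: int = 50
) -> PauseWindow | None:
    """Maximal-sum window of width ``window`` within the first ``search_len`` bases.

    Ties break to the smallest offset (most TSS-proximal).  Returns None when
    the whole search region is zero (gene flagged and excluded downstream).
    """
    if search_len < window or window <= 0:
        raise InvalidParameterError("need search_len >= window > 0")
    region = np.zeros(search_len, dtype=float)
    region[: min(search_len, len(signal))] = signal[:search_len]
    if not region.any():
        return None
    # per-window sums (not a cumsum difference: exact equality with
    # brute-force enumeration matters for ties); argmax returns first maximum
    sums = np.lib.stride_tricks.sliding_window_view(region, window).sum(axis=1)
    start = int(np.argmax(sums))
    return PauseWindow(start=start, end=start + window)


def define_gene_body(
    pause: PauseWindow,
    gene: GeneModel,
    treatment_minutes: float | None = None,
    cap_rate: float = 2000.0,
    offset: int = 500,
) -> tuple[int, int] | None:
    """Sense-offset body interval: from pause end + offset to the TTS or the
    elongation-capped end, whichever is shorter.

    The cap is the distance a polymerase initiated at treatment onset can
    travel, ``treatment_minutes * cap_rate`` bp, measured from the start of
    the body.  Returns None for an empty body (gene dropped, reason logged).
    """
    body_start = pause.end + offset
    body_end = gene.length
    if treatment_minutes is not None:
        body_end = min(body_end, body_start + int(round(treatment_minutes * cap_rate)))
    if body_end <= body_start:
        logger.info(
            "%s: empty gene body (start %d >= end %d), dropped",
            gene.gene_id, body_start, body_end,
        )
        return None
    return body_start, body_end


def pause_sum(signal: np.ndarray, window: PauseWindow) -> float:
    """Summed signal over the pause window."""
    return float(np.sum(signal[window.start : window.end]))


def body_mean(signal: np.ndarray, body_start: int, body_end: int) -> float:
    """Mean per-bp signal over [body_start, body_end); gaps count as zero."""
    if body_end <= body_start:
        raise InvalidParameterError("empty body interval")
    total = float(np.sum(signal[body_start:body_end]))
    return total / (body_end - body_start)


def compute_densities(
    tracks: dict[str, SignalTrack],
    genes: Sequence[GeneModel],
    condition: str,
    replicate: str,
    search_len: int = 200,
    window: int = 50,
    treatment_minutes: float | None = None,
    cap_rate: float = 2000.0,
    body_offset: int = 500,
    pause_windows: dict[str, PauseWindow] | None = None,
) -> tuple[pd.DataFrame, dict[str, PauseWindow]]:
    """Per-gene pause sums and body means for one sample.

    ``tracks`` maps strand ('+'/'-') to its signal track.  If
    ``pause_windows`` is given (gene_id -> PauseWindow in sense offsets) those
    windows are reused instead of being recomputed — the default pipeline
    computes windows on pooled control signal and fixes them across
    conditions.  Genes with no pause signal or an empty body are dropped with
    a logged reason.

    Returns the density table and the pause windows actually used.
    """
    rows: list[DensityRecord] = []
    used: dict[str, PauseWindow] = {}
    for gene in genes:
        track = tracks[gene.strand]
        sig = sense_signal(track, gene)
        if pause_windows is not None and gene.gene_id in pause_windows:
            pw = pause_windows[gene.gene_id]
        else:
            pw = find_pause_window(sig, search_len=search_len, window=window)
        if pw is None:
            logger.info("%s: zero signal in pause search region, dropped", gene.gene_id)
            continue
        body = define_gene_body(
            pw, gene, treatment_minutes=treatment_minutes,
            cap_rate=cap_rate, offset=body_offset,
        )
        if body is None:
            continue
        used[gene.gene_id] = pw
        p_start, p_end = gene.sense_to_genomic(pw.start, pw.end)
        b_start, b_end = gene.sense_to_genomic(*body)
        rows.append(
            DensityRecord(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                pause_start=p_start,
                pause_end=p_end,
                pause_sum=pause_sum(sig, pw),
                body_start=b_start,
                body_end=b_end,
                body_mean=body_mean(sig, *body),
                condition=condition,
                replicate=replicate,
            )
        )
    df = pd.DataFrame([vars(r) for r in rows], columns=DENSITY_COLUMNS)
    return df, used


def pooled_tracks(track_sets: Iterable[dict[str, SignalTrack]]) -> dict[str, SignalTrack]:
    """Sum several in-memory strand->track dicts base-wise (for window pooling)."""
    from .tracks import ArrayTrack

    pooled: dict[str, dict[str, np.ndarray]] = {}
    for tracks in track_sets:
        for strand, track in tracks.items():
            if not isinstance(track, ArrayTrack):
                raise InvalidParameterError("pooling requires in-memory tracks")
            dest = pooled.setdefault(strand, {})
            for chrom, arr in track.arrays.items():
                if chrom in dest:
                    n = max(len(dest[chrom]), len(arr))
                    out = np.zeros(n)
                    out[: len(dest[chrom])] += np.abs(dest[chrom])
                    out[: len(arr)] += np.abs(arr)
                    dest[chrom] = out
                else:
                    dest[chrom] = np.abs(arr.copy())
    return {strand: ArrayTrack(arrays) for strand, arrays in pooled.items()}
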