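"""Per-base signal tracks: bedGraph and bigWig readers, bedGraph writer.

Nascent run-on assays (PRO-seq/GRO-seq) report the 3' end of each engaged
polymerase at base-pair resolution, one track per strand.  Minus-strand
tracks are conventionally stored with negative values; readers return
magnitudes.  All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["SignalTrack", "BedGraphTrack", "BigWigTrack", "ArrayTrack", "write_bedgraph"]


class SignalTrack:
    """Read-only per-base signal access for one strand of one sample."""

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal magnitudes over [start, end); missing bases are 0."""
        raise NotImplementedError

    def close(self) -> None:  # pragma: no cover - trivial
        pass

    def __enter__(self) -> "SignalTrack":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


class ArrayTrack(SignalTrack):
    """In-memory track backed by one dense numpy array per chromosome."""

    def __init__(self, arrays: Mapping[str, np.ndarray]):
        self.arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        if start < 0 or end < start:
            raise ValueError(f"bad interval [{start}, {end})")
        out = np.zeros(end - start, dtype=float)
        arr = self.arrays.get(chrom)
        if arr is None:
            return out
        lo, hi = min(start, len(arr)), min(end, len(arr))
        out[: hi - lo] = np.abs(arr[lo:hi])
        return out


class BedGraphTrack(ArrayTrack):
    """bedGraph (4-column, 0-based half-open) loaded into dense per-chrom arrays.

    Suited to the modest genomes this package targets directly (synthetic
    fixtures, single loci); genome-scale data should come in as bigWig.
    """

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        df = pd.read_csv(
            self.path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        # tolerate track definition lines
        df = df[pd.to_numeric(df["start"], errors="coerce").notna()]
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["value"] = df["value"].astype(float)
        arrays: dict[str, np.ndarray] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            arr = np.zeros(int(sub["end"].max()), dtype=float)
            for start, end, value in sub[["start", "end", "value"]].itertuples(
                index=False
            ):
                arr[start:end] = value
            arrays[chrom] = arr
        super().__init__(arrays)


class BigWigTrack(SignalTrack):
    """bigWig track accessed through pyBigWig."""

    def __init__(self, path: str | os.PathLike):
        import pyBigWig

        self.path = os.fspath(path)
        self._bw = pyBigWig.open(self.path)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self._bw.chroms():
            return np.zeros(end - start, dtype=float)
        chrom_len = self._bw.chroms(chrom)
        out = np.zeros(end - start, dtype=float)
        lo, hi = min(start, chrom_len), min(end, chrom_len)
        if hi > lo:
            vals = np.nan_to_num(
                np.asarray(self._bw.values(chrom, lo, hi), dtype=float)
            )
            out[: hi - lo] = np.abs(vals)
        return out

    def close(self) -> None:
        self._bw.close()


def open_track(path: str | os.PathLike) -> SignalTrack:
    """Open a signal file by extension (.bw/.bigwig -> bigWig, else bedGraph)."""
    ext = os.path.splitext(os.fspath(path))[1].lower()
    if ext in (".bw", ".bigwig"):
        return BigWigTrack(path)
    return BedGraphTrack(path)


def write_bedgraph(
    arrays: Mapping[str, np.ndarray] | Iterable[tuple[str, np.ndarray]],
    path: str | os.PathLike,
    negate: bool = False,
) -> None:
    """Write dense per-chromosome arrays as run-length-merged bedGraph.

    Zero runs are omitted.  ``negate`` writes values with flipped sign
    (minus-strand convention).
    """
    items = arrays.items() if isinstance(arrays, Mapping) else arrays
    sign = -1.0 if negate else 1.0
    with open(path, "w") as fh:
        for chrom, arr in items:
            arr = np.asarray(arr, dtype=float)
            if arr.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                val = sign * v
                txt = f"{val:g}" if val != int(val) else str(int(val))
                fh.write(f"{chrom}\t{s}\t{e}\t{txt}\n")
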