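"""Fragment-analyzer peak tables: reading, raw-peak filtering, fixed-width binning.

AFLP genotyping starts from size-called peak lists (fragment size in bp,
intensity in relative fluorescence units) exported per sample and per
primer-pair/dye channel. This module turns those lists into a per-channel
sample x bin intensity matrix using fixed-width, half-open bins anchored at
the window start, after discarding peaks outside the scoring window, below
the intensity threshold, or wider than the maximum peak width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "BinningConfig",
    "PeakTable",
    "BinnedMatrix",
    "PeakTableFormatError",
    "read_peak_table",
    "filter_raw_peaks",
    "bin_peaks",
    "bin_all_channels",
]


class PeakTableFormatError(ValueError):
    """Raised when a peak export cannot be parsed into a valid PeakTable."""


@dataclass(frozen=True)
class Peak:
    """A single size-called fragment observation."""

    sample_id: str
    channel: str
    size: float          # bp
    intensity: float     # RFU, >= 0
    width: float | None = None  # bp, optional

    def __post_init__(self) -> None:
        if not self.size > 0:
            raise ValueError(f"peak size must be > 0, got {self.size}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")
        if self.width is not None and not self.width > 0:
            raise ValueError(f"peak width must be > 0, got {self.width}")


@dataclass(frozen=True)
class BinningConfig:
    """Scoring window, bin width and raw-peak thresholds.

    Defaults are the standard automated-scoring settings for capillary AFLP:
    score fragments from 100 to 500 bp in 0.5 bp bins, require a peak height
    of at least 30 RFU, and reject peaks wider than 1.5 bp.
    """

    window_start: float = 100.0
    window_end: float = 500.0
    bin_width: float = 0.5
    min_intensity: float = 30.0
    max_peak_width: float = 1.5

    def __post_init__(self) -> None:
        if not self.window_start < self.window_end:
            raise ValueError("window_start must be < window_end")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be > 0")
        if self.min_intensity < 0:
            raise ValueError("min_intensity must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(math.ceil((self.window_end - self.window_start) / self.bin_width - 1e-9))

    def bin_index(self, size: float) -> int:
        """Index of the half-open bin [left, left + bin_width) containing ``size``."""
        return int(math.floor((size - self.window_start) / self.bin_width))


@dataclass
class PeakTable:
    """A collection of Peak records, held as a long-format DataFrame.

    Columns: sample, channel, size, intensity, width (NaN when not reported).
    Row order of the source file is preserved.
    """

    df: pd.DataFrame

    COLUMNS = ("sample", "channel", "size", "intensity", "width")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise PeakTableFormatError(f"peak table missing columns: {missing}")
        self.df = self.df.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        """Sample ids in first-appearance order."""
        return list(dict.fromkeys(self.df["sample"]))

    @property
    def channels(self) -> list[str]:
        return list(dict.fromkeys(self.df["channel"]))

    def peaks(self) -> list[Peak]:
        return [
            Peak(r.sample, r.channel, float(r.size), float(r.intensity),
                 None if pd.isna(r.width) else float(r.width))
            for r in self.df.itertuples(index=False)
        ]

    @classmethod
    def from_peaks(cls, peaks: list[Peak]) -> "PeakTable":
        rows = [(p.sample_id, p.channel, p.size, p.intensity,
                 np.nan if p.width is None else p.width) for p in peaks]
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


# Case-insensitive header synonyms for the generic long-format dialect.
_GENERIC_SYNONYMS = {
    "sample": ("sample", "sample_id", "sample file", "sample name"),
    "channel": ("channel", "dye", "marker", "primer", "primer_pair"),
    "size": ("size", "size (bp)", "fragment_size", "bp"),
    "intensity": ("intensity", "height", "rfu", "peak height", "signal"),
    "width": ("width", "peak width", "width (bp)"),
}


def _match_columns(header: list[str]) -> dict[str, str]:
    lowered = {h.strip().lower(): h for h in header}
    mapping: dict[str, str] = {}
    for canon, synonyms in _GENERIC_SYNONYMS.items():
        for syn in synonyms:
            if syn in lowered:
                mapping[canon] = lowered[syn]
                break
    for required in ("sample", "channel", "size", "intensity"):
        if required not in mapping:
            raise PeakTableFormatError(
                f"required column '{required}' not found in header {header}"
            )
    return mapping


def _coerce_numeric(df: pd.DataFrame, source_col: str, canon: str) -> pd.Series:
    """Coerce a column to float, reporting the 1-based file line of the first bad row."""
    raw = df[source_col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: header occupies line 1, data rows start on line 2
        raise PeakTableFormatError(
            f"non-numeric {canon} value {raw.iloc[idx]!r} on line {idx + 2}"
        )
    return out


def read_peak_table(path, dialect: str = "generic") -> PeakTable:
    """Read a fragment-analyzer peak export.

    Dialects:

    ``generic``
        Long-format CSV, one peak per row, header row with case-insensitive
        columns sample, channel/dye, size, height/intensity and optional width.
    ``genemapper``
        Wide genotypes-table export: one row per sample/dye with repeated
        "Size N" / "Height N" column pairs.
    """
    if dialect == "generic":
        # keep_default_na=False so tokens like "NA" surface as parse errors
        # with a line number instead of silently becoming missing values
        df = pd.read_csv(path, dtype=str, skip_blank_lines=False,
                         keep_default_na=False)
        mapping = _match_columns(list(df.columns))
        out = pd.DataFrame(
            {
                "sample": df[mapping["sample"]].astype(str),
                "channel": df[mapping["channel"]].astype(str),
                "size": _coerce_numeric(df, mapping["size"], "size"),
                "intensity": _coerce_numeric(df, mapping["intensity"], "intensity"),
                "width": _coerce_numeric(df, mapping["width"], "width")
                if "width" in mapping
                else np.nan,
            }
        )
        out = out[out["size"].notna()].reset_index(drop=True)
        return PeakTable(out)
    if dialect == "genemapper":
        return _read_genemapper(path)
    raise PeakTableFormatError(f"unknown peak-table dialect: {dialect!r}")


def _read_genemapper(path) -> PeakTable:
    """Adapter for the wide GeneMapper genotypes export (Size N / Height N pairs)."""
    df = pd.read_csv(path, dtype=str)
    lowered = {h.strip().lower(): h for h in df.columns}
    sample_col = next((lowered[k] for k in ("sample file", "sample name", "sample")
                       if k in lowered), None)
    dye_col = next((lowered[k] for k in ("dye", "dye/sample peak", "marker")
                    if k in lowered), None)
    if sample_col is None:
        raise PeakTableFormatError("required column 'sample' not found in GeneMapper export")
    if dye_col is None:
        raise PeakTableFormatError("required column 'channel' (Dye/Marker) not found")
    size_cols = sorted(
        (c for c in df.columns if c.strip().lower().startswith("size")),
        key=lambda c: int("".join(ch for ch in c if ch.isdigit()) or 0),
    )
    rows = []
    for _, rec in df.iterrows():
        for sc in size_cols:
            suffix = "".join(ch for ch in sc if ch.isdigit())
            hc = next((c for c in df.columns
                       if c.strip().lower() == f"height {suffix}"), None)
            if hc is None or pd.isna(rec[sc]) or str(rec[sc]).strip() == "":
                continue
            rows.append((str(rec[sample_col]), str(rec[dye_col]),
                         float(rec[sc]), float(rec[hc]), np.nan))
    return PeakTable(pd.DataFrame(rows, columns=list(PeakTable.COLUMNS)))


def filter_raw_peaks(
    peaks: PeakTable, cfg: BinningConfig
) -> tuple[PeakTable, dict[str, int]]:
    """Apply raw-peak quality filters; returns the retained table and removal counts.

    Retains peaks with window_start <= size < window_end, intensity >=
    min_intensity, and (only when a width was reported) width <= max_peak_width.
    Filters never fail on data values.
    """
    df = peaks.df
    in_window = (df["size"] >= cfg.window_start) & (df["size"] < cfg.window_end)
    intense = df["intensity"] >= cfg.min_intensity
    narrow = df["width"].isna() | (df["width"] <= cfg.max_peak_width)
    removed = {
        "window": int((~in_window).sum()),
        "intensity": int((in_window & ~intense).sum()),
        "width": int((in_window & intense & ~narrow).sum()),
    }
    keep = in_window & intense & narrow
    return PeakTable(df[keep].reset_index(drop=True)), removed


@dataclass
class BinnedMatrix:
    """Per-channel sample x bin intensity matrix (0 = no peak in that bin).

    ``bin_left`` holds the left edges of contiguous half-open bins
    [left, left + bin_width). Empty bins may have been dropped, so edges are
    ordered but not necessarily contiguous in value.
    """

    channel: str
    samples: list[str]
    bin_left: np.ndarray            # (n_bins,) left edges, bp
    bin_width: float
    intensity: np.ndarray           # (n_samples, n_bins) RFU
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_left = np.asarray(self.bin_left, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.samples), len(self.bin_left)):
            raise ValueError("intensity shape does not match samples x bins")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be >= 0")
        if len(self.bin_left) > 1 and not (np.diff(self.bin_left) > 0).all():
            raise ValueError("bin edges must be strictly increasing")

    def bin_labels(self) -> list[str]:
        return [_format_edge(x) for x in self.bin_left]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.intensity, index=self.samples,
                     columns=self.bin_labels()).to_csv(path, index_label="sample")

    @classmethod
    def from_csv(cls, path, channel: str = "", bin_width: float = 0.5) -> "BinnedMatrix":
        df = pd.read_csv(path, index_col="sample")
        return cls(
            channel=channel,
            samples=[str(s) for s in df.index],
            bin_left=np.array([float(c) for c in df.columns]),
            bin_width=bin_width,
            intensity=df.to_numpy(dtype=float),
        )


def _format_edge(x: float) -> str:
    return f"{x:.1f}" if abs(x - round(x, 1)) < 1e-9 else f"{x:.6f}"


def bin_peaks(
    peaks: PeakTable,
    cfg: BinningConfig,
    channel: str | None = None,
    drop_empty: bool = True,
    samples: list[str] | None = None,
) -> BinnedMatrix:
    """Assign filtered peaks of one channel to fixed-width bins.

    Each peak goes to bin floor((size - window_start) / bin_width); when one
    sample has several peaks in a bin, the maximum intensity is kept. With
    ``drop_empty`` (default) bins that hold no peak in any sample are removed.
    Peaks must already have passed :func:`filter_raw_peaks`.
    """
    df = peaks.df
    if channel is None:
        chans = peaks.channels
        if len(chans) != 1:
            raise ValueError(
                f"bin_peaks needs a single channel, table has {chans}; "
                "pass channel= or use bin_all_channels"
            )
        channel = chans[0]
    if samples is None:
        samples = peaks.samples  # union over all channels keeps matrices alignable
    sub = df[df["channel"] == channel]
    if ((sub["size"] < cfg.window_start) | (sub["size"] >= cfg.window_end)).any():
        raise RuntimeError("internal error: peak outside scoring window; "
                           "run filter_raw_peaks first")
    n_bins = cfg.n_bins
    sample_idx = {s: i for i, s in enumerate(samples)}
    grid = np.zeros((len(samples), n_bins))
    for rec in sub.itertuples(index=False):
        j = cfg.bin_index(rec.size)
        i = sample_idx[rec.sample]
        if rec.intensity > grid[i, j]:
            grid[i, j] = rec.intensity
    bin_left = cfg.window_start + cfg.bin_width * np.arange(n_bins)
    if drop_empty:
        keep = grid.any(axis=0)
        grid = grid[:, keep]
        bin_left = bin_left[keep]
    return BinnedMatrix(channel=channel, samples=list(samples), bin_left=bin_left,
                        bin_width=cfg.bin_width, intensity=grid)


def bin_all_channels(
    peaks: PeakTable, cfg: BinningConfig, drop_empty: bool = True
) -> dict[str, BinnedMatrix]:
    """Bin every channel of a multi-channel table against the shared sample list."""
    samples = peaks.samples
    return {
        ch: bin_peaks(peaks, cfg, channel=ch, drop_empty=drop_empty, samples=samples)
        for ch in peaks.channels
    }
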