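"""Three-state AFLP genotype calling.

Signal strength is first equalized among samples (sum-of-signal
normalization, per channel). Each bin is then called relative to the highest
normalized peak scored in that bin from any sample: a peak below 10% of that
maximum is absent (0), between 10% and 20% inclusive is ambiguous (?), and
above 20% is present (1). The two boundary ratios are assigned to the
ambiguous class, which is the conservative reading and makes the later
"delete bins with any 10-20% peak" filter exactly "delete bins with any ?".
Channels are scored independently and the per-channel matrices concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peak_io import BinnedMatrix

__all__ = [
    "ABSENT",
    "PRESENT",
    "AMBIGUOUS",
    "CallThresholds",
    "CallMatrix",
    "normalize_signals",
    "call_states",
    "combine_matrices",
    "score_channels",
]

# Cell codes in the states grid. AMBIGUOUS renders as '?' on disk.
ABSENT = 0
PRESENT = 1
AMBIGUOUS = -1

_STATE_TO_CHAR = {ABSENT: "0", PRESENT: "1", AMBIGUOUS: "?"}
_CHAR_TO_STATE = {v: k for k, v in _STATE_TO_CHAR.items()}


@dataclass(frozen=True)
class CallThresholds:
    """Intensity-ratio cutpoints, as fractions of the per-bin maximum."""

    ambiguous_low: float = 0.10
    present_low: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.ambiguous_low < self.present_low < 1:
            raise ValueError("need 0 < ambiguous_low < present_low < 1")


@dataclass
class CallMatrix:
    """samples x bins three-state genotype matrix.

    ``states`` is int8 over {0 absent, 1 present, -1 ambiguous}. Bin labels are
    channel-qualified ("channel:left-edge") and unique; ``channels`` records
    the channel of origin per bin.
    """

    samples: list[str]
    bins: list[str]
    states: np.ndarray
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.samples), len(self.bins)):
            raise ValueError("states shape does not match samples x bins")
        if not np.isin(self.states, [ABSENT, PRESENT, AMBIGUOUS]).all():
            raise ValueError("states must be in {0, 1, -1}")
        if len(set(self.bins)) != len(self.bins):
            raise ValueError("bin labels must be unique")
        if not self.channels:
            self.channels = [b.split(":", 1)[0] if ":" in b else "" for b in self.bins]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def row(self, sample: str) -> np.ndarray:
        return self.states[self.samples.index(sample)]

    def select_bins(self, keep: np.ndarray) -> "CallMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CallMatrix(
            samples=list(self.samples),
            bins=[self.bins[i] for i in idx],
            states=self.states[:, idx],
            thresholds=self.thresholds,
            channels=[self.channels[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        chars = np.vectorize(_STATE_TO_CHAR.get)(self.states) if self.states.size \
            else np.empty(self.states.shape, dtype="<U1")
        return pd.DataFrame(chars, index=self.samples, columns=self.bins)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="sample")

    @classmethod
    def from_csv(cls, path, thresholds: CallThresholds | None = None) -> "CallMatrix":
        df = pd.read_csv(path, index_col="sample", dtype=str)
        states = np.array(
            [[_CHAR_TO_STATE[c.strip()] for c in row] for row in df.to_numpy()],
            dtype=np.int8,
        ) if len(df.columns) else np.empty((len(df.index), 0), dtype=np.int8)
        return cls(
            samples=[str(s) for s in df.index],
            bins=[str(c) for c in df.columns],
            states=states,
            thresholds=thresholds or CallThresholds(),
        )

    def to_nexus(self, path) -> None:
        """Write a NEXUS DATA block (datatype=standard, symbols 0/1, missing ?),
        readable by split-network software."""
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN TAXA;\n")
            fh.write(f"    DIMENSIONS NTAX={self.n_samples};\n    TAXLABELS\n")
            for s in self.samples:
                fh.write(f"        '{s}'\n")
            fh.write("    ;\nEND;\n\nBEGIN CHARACTERS;\n")
            fh.write(f"    DIMENSIONS NCHAR={self.n_bins};\n")
            fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n')
            fh.write("    MATRIX\n")
            width = max((len(s) for s in self.samples), default=1) + 2
            for i, s in enumerate(self.samples):
                row = "".join(_STATE_TO_CHAR[int(x)] for x in self.states[i])
                fh.write(f"        '{s}'{' ' * (width - len(s))}{row}\n")
            fh.write("    ;\nEND;\n")


def normalize_signals(m: BinnedMatrix) -> BinnedMatrix:
    """Sum-of-signal normalization: scale each sample so per-sample totals are equal.

    The common target is the grand mean of the per-sample totals (downstream
    calls depend only on within-bin ratios, so any common constant would do).
    A sample with zero total signal cannot be normalized and is an error.
    """
    totals = m.intensity.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cannot normalize: sample(s) with zero total intensity: "
            f"{[m.samples[i] for i in zero]}"
        )
    factors = totals.mean() / totals
    return BinnedMatrix(
        channel=m.channel,
        samples=list(m.samples),
        bin_left=m.bin_left.copy(),
        bin_width=m.bin_width,
        intensity=m.intensity * factors[:, None],
        meta={**m.meta, "normalized": True},
    )


def call_states(m: BinnedMatrix, t: CallThresholds | None = None) -> CallMatrix:
    """Call three-state genotypes per bin against the per-bin maximum intensity.

    For each bin let M be the maximum (normalized) intensity over all samples
    and r = intensity / M: r < ambiguous_low -> 0; ambiguous_low <= r <=
    present_low -> ?; r > present_low -> 1. Bins with M = 0 carry no peak and
    are dropped. The sample holding the maximum is always called present.
    """
    t = t or CallThresholds()
    M = m.intensity.max(axis=0)
    keep = M > 0
    inten = m.intensity[:, keep]
    ratio = inten / M[keep]
    states = np.full(ratio.shape, ABSENT, dtype=np.int8)
    states[(ratio >= t.ambiguous_low) & (ratio <= t.present_low)] = AMBIGUOUS
    states[ratio > t.present_low] = PRESENT
    labels = [f"{m.channel}:{lab}" for lab, k in zip(m.bin_labels(), keep) if k]
    return CallMatrix(
        samples=list(m.samples),
        bins=labels,
        states=states,
        thresholds=t,
        channels=[m.channel] * len(labels),
    )


def combine_matrices(parts: list[CallMatrix]) -> CallMatrix:
    """Column-wise concatenation of per-channel call matrices.

    All parts must cover the same sample set (order may differ; the first
    part's order wins) and have disjoint channel-qualified bin labels.
    """
    if not parts:
        raise ValueError("combine_matrices needs at least one matrix")
    first = parts[0]
    ref = set(first.samples)
    for p in parts[1:]:
        if set(p.samples) != ref:
            diff = sorted(ref.symmetric_difference(p.samples))
            raise ValueError(f"sample sets differ between matrices: {diff}")
        if p.thresholds != first.thresholds:
            raise ValueError("cannot combine matrices called with different thresholds")
    bins: list[str] = []
    channels: list[str] = []
    blocks = []
    for p in parts:
        order = [p.samples.index(s) for s in first.samples]
        blocks.append(p.states[order])
        bins.extend(p.bins)
        channels.extend(p.channels)
    if len(set(bins)) != len(bins):
        raise ValueError("bin labels collide between matrices")
    return CallMatrix(
        samples=list(first.samples),
        bins=bins,
        states=np.hstack(blocks) if blocks else np.empty((len(first.samples), 0)),
        thresholds=first.thresholds,
        channels=channels,
    )


def score_channels(
    binned: dict[str, BinnedMatrix], t: CallThresholds | None = None
) -> CallMatrix:
    """Normalize, call and combine a set of per-channel binned matrices."""
    parts = [call_states(normalize_signals(m), t) for m in binned.values()]
    return combine_matrices(parts)
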