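"""Replicate-based AFLP scoring-error quantification and elimination.

Every DNA sample is amplified (at least) twice, so scoring error can be
measured as the fraction of comparable bins at which two replicates of the
same sample disagree (one scored present, the other absent; ambiguous calls
are excluded pairwise, matching the pairwise-deletion convention used for
p-distances downstream).

The error filter is a fixed two-step process:

1. delete every bin containing at least one ambiguous (?) call — i.e. every
   bin where some sample's peak fell in the 10-20% intensity band;
2. delete every remaining bin scored present in one replicate and absent in
   another replicate of any sample.

After both steps, all replicate pairs are scored identically by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .scoring import ABSENT, AMBIGUOUS, PRESENT, CallMatrix

__all__ = [
    "ReplicateMap",
    "ErrorReport",
    "FilterTrace",
    "replicate_difference_rates",
    "drop_ambiguous_bins",
    "drop_irreproducible_bins",
    "filter_scoring_errors",
    "collapse_replicates",
]

REPLICATION_LEVELS = ("extraction", "digestion_ligation", "preamp")


@dataclass
class ReplicateMap:
    """Grouping of sample entries into replicate sets.

    ``levels`` records, per group, the earliest wet-lab stage from which the
    members were replicated (extraction, digestion/ligation, or preamp only).
    Every sample belongs to exactly one group.
    """

    groups: dict[str, list[str]]
    levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for gid, members in self.groups.items():
            if len(members) < 1:
                raise ValueError(f"replicate group {gid!r} is empty")
            for s in members:
                if s in seen:
                    raise ValueError(
                        f"sample {s!r} appears in groups {seen[s]!r} and {gid!r}"
                    )
                seen[s] = gid
        for gid, lvl in self.levels.items():
            if lvl not in REPLICATION_LEVELS:
                raise ValueError(f"unknown replication level {lvl!r} for group {gid!r}")

    @property
    def samples(self) -> list[str]:
        return [s for members in self.groups.values() for s in members]

    def group_of(self, sample: str) -> str:
        for gid, members in self.groups.items():
            if sample in members:
                return gid
        raise KeyError(sample)

    @classmethod
    def from_csv(cls, path) -> "ReplicateMap":
        """Two-column CSV (sample_id, group_id) with optional third column level."""
        df = pd.read_csv(path, dtype=str)
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        groups: dict[str, list[str]] = {}
        levels: dict[str, str] = {}
        for rec in df.itertuples(index=False):
            groups.setdefault(str(rec.group_id), []).append(str(rec.sample_id))
            if "level" in cols and isinstance(getattr(rec, "level", None), str):
                levels[str(rec.group_id)] = rec.level
        return cls(groups=groups, levels=levels)

    def to_csv(self, path) -> None:
        rows = [
            (s, gid, self.levels.get(gid, ""))
            for gid, members in self.groups.items()
            for s in members
        ]
        pd.DataFrame(rows, columns=["sample_id", "group_id", "level"]).to_csv(
            path, index=False
        )


@dataclass
class ErrorReport:
    """Replicate difference rates, overall and per replication level."""

    pair_rates: dict[tuple[str, str], float | None]
    pair_comparable: dict[tuple[str, str], int]
    pair_level: dict[tuple[str, str], str]

    @property
    def defined_rates(self) -> list[float]:
        return [r for r in self.pair_rates.values() if r is not None]

    @property
    def min_rate(self) -> float | None:
        r = self.defined_rates
        return min(r) if r else None

    @property
    def max_rate(self) -> float | None:
        r = self.defined_rates
        return max(r) if r else None

    @property
    def mean_rate(self) -> float | None:
        r = self.defined_rates
        return float(np.mean(r)) if r else None

    def level_summary(self) -> dict[str, dict[str, float | int | None]]:
        out: dict[str, dict[str, float | int | None]] = {}
        for lvl in REPLICATION_LEVELS:
            rates = [
                r
                for pair, r in self.pair_rates.items()
                if r is not None and self.pair_level.get(pair) == lvl
            ]
            out[lvl] = {
                "n_pairs": len(rates),
                "mean": float(np.mean(rates)) if rates else None,
                "min": min(rates) if rates else None,
                "max": max(rates) if rates else None,
            }
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, self.pair_level.get((a, b), ""), self.pair_comparable[(a, b)], r)
            for (a, b), r in self.pair_rates.items()
        ]
        return pd.DataFrame(
            rows, columns=["sample_a", "sample_b", "level", "n_comparable", "rate"]
        )


@dataclass
class FilterTrace:
    """Fate of every input bin under the two-step filter.

    The three label lists partition the input bins: removed in step 1
    (ambiguity filter), removed in step 2 (reproducibility filter), retained.
    """

    step1_removed: list[str]
    step2_removed: list[str]
    retained: list[str]

    def __post_init__(self) -> None:
        sets = [set(self.step1_removed), set(self.step2_removed), set(self.retained)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("filter trace sets must be disjoint")

    @property
    def n_input(self) -> int:
        return len(self.step1_removed) + len(self.step2_removed) + len(self.retained)

    def merged_with(self, later: "FilterTrace") -> "FilterTrace":
        """Combine a step-1 trace with the step-2 trace run on its output."""
        return FilterTrace(
            step1_removed=self.step1_removed + later.step1_removed,
            step2_removed=self.step2_removed + later.step2_removed,
            retained=later.retained,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(b, "step1") for b in self.step1_removed]
            + [(b, "step2") for b in self.step2_removed]
            + [(b, "retained") for b in self.retained]
        )
        return pd.DataFrame(rows, columns=["bin", "fate"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def report_text(self) -> str:
        return (
            f"bins in: {self.n_input}\n"
            f"removed step 1 (ambiguity filter): {len(self.step1_removed)}\n"
            f"removed step 2 (reproducibility filter): {len(self.step2_removed)}\n"
            f"retained: {len(self.retained)}\n"
        )


def _pair_rate(a: np.ndarray, b: np.ndarray) -> tuple[float | None, int]:
    comparable = (a != AMBIGUOUS) & (b != AMBIGUOUS)
    n = int(comparable.sum())
    if n == 0:
        return None, 0
    mism = int((a[comparable] != b[comparable]).sum())
    return mism / n, n


def replicate_difference_rates(calls: CallMatrix, reps: ReplicateMap) -> ErrorReport:
    """Pairwise difference rates between replicate amplifications.

    rate = (# bins scored 0 in one replicate and 1 in the other) /
    (# bins where both calls are determinate). Groups of size 1 are skipped
    with a warning; a pair with zero comparable bins gets rate None.
    """
    pair_rates: dict[tuple[str, str], float | None] = {}
    pair_comp: dict[tuple[str, str], int] = {}
    pair_level: dict[tuple[str, str], str] = {}
    for gid, members in reps.groups.items():
        present = [s for s in members if s in calls.samples]
        if len(present) < 2:
            warnings.warn(f"replicate group {gid!r} has < 2 members in matrix; skipped")
            continue
        for a, b in combinations(present, 2):
            rate, n = _pair_rate(calls.row(a), calls.row(b))
            pair_rates[(a, b)] = rate
            pair_comp[(a, b)] = n
            pair_level[(a, b)] = reps.levels.get(gid, "preamp")
    return ErrorReport(pair_rates, pair_comp, pair_level)


def drop_ambiguous_bins(calls: CallMatrix) -> tuple[CallMatrix, FilterTrace]:
    """Step 1: remove every bin in which any sample was called ambiguous."""
    has_q = (calls.states == AMBIGUOUS).any(axis=0)
    trace = FilterTrace(
        step1_removed=[b for b, q in zip(calls.bins, has_q) if q],
        step2_removed=[],
        retained=[b for b, q in zip(calls.bins, has_q) if not q],
    )
    return calls.select_bins(~has_q), trace


def drop_irreproducible_bins(
    calls: CallMatrix, reps: ReplicateMap
) -> tuple[CallMatrix, FilterTrace]:
    """Step 2: remove bins scored present in one replicate and absent in another.

    Must run on the output of :func:`drop_ambiguous_bins` (no ? anywhere);
    afterwards all members of each replicate group carry identical profiles.
    """
    if (calls.states == AMBIGUOUS).any():
        raise ValueError(
            "drop_irreproducible_bins requires a matrix without ambiguous calls; "
            "run drop_ambiguous_bins first"
        )
    bad = np.zeros(calls.n_bins, dtype=bool)
    for members in reps.groups.values():
        rows = [calls.samples.index(s) for s in members if s in calls.samples]
        if len(rows) < 2:
            continue
        block = calls.states[rows]
        bad |= (block == PRESENT).any(axis=0) & (block == ABSENT).any(axis=0)
    trace = FilterTrace(
        step1_removed=[],
        step2_removed=[b for b, x in zip(calls.bins, bad) if x],
        retained=[b for b, x in zip(calls.bins, bad) if not x],
    )
    return calls.select_bins(~bad), trace


def filter_scoring_errors(
    calls: CallMatrix, reps: ReplicateMap
) -> tuple[CallMatrix, FilterTrace]:
    """Run the two-step filter in its fixed order and merge the traces."""
    step1, t1 = drop_ambiguous_bins(calls)
    step2, t2 = drop_irreproducible_bins(step1, reps)
    return step2, t1.merged_with(t2)


def collapse_replicates(calls: CallMatrix, reps: ReplicateMap) -> CallMatrix:
    """Collapse each replicate group to a single row labelled by its group id.

    Requires identical profiles within each group (true after the two-step
    filter); a discordant group is an error naming the first discordant bin.
    """
    rows = []
    labels = []
    for gid, members in reps.groups.items():
        idx = [calls.samples.index(s) for s in members if s in calls.samples]
        if not idx:
            continue
        block = calls.states[idx]
        disc = np.flatnonzero((block != block[0]).any(axis=0))
        if disc.size:
            raise ValueError(
                f"replicate group {gid!r} has discordant profiles at bin "
                f"{calls.bins[disc[0]]!r}; run the error filter first"
            )
        rows.append(block[0])
        labels.append(gid)
    return CallMatrix(
        samples=labels,
        bins=list(calls.bins),
        states=np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, calls.n_bins), dtype=np.int8),
        thresholds=calls.thresholds,
        channels=list(calls.channels),
    )
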