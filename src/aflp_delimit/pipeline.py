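"""Full-analysis orchestration: score -> replicate QC -> networks (+ sequences).

A single YAML config drives the run. Both network variants are produced when
requested — the full matrix with all scored polymorphisms and the reduced
matrix with reproducible polymorphisms only — mirroring the comparison of
interest: the two give essentially the same grouping, but the full matrix
exaggerates within-cluster variation relative to between-cluster variation.

All numeric results go to a machine-readable report (JSON); the log is for
humans and is never parsed. The report carries a reproducibility manifest
(package version, seed, config hash) and contains no timestamps, so the same
config and seed produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .network import extract_groups, neighbor_net, p_distance_matrix
from .peak_io import BinningConfig, bin_all_channels, filter_raw_peaks, read_peak_table
from .replicate_qc import (
    ReplicateMap,
    collapse_replicates,
    filter_scoring_errors,
    replicate_difference_rates,
)
from .scoring import CallThresholds, score_channels

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full AFLP run.

    ``variants`` selects which call matrices are taken through the network
    stage: "full" (all scored polymorphisms) and/or "reduced"
    (reproducible-only, after the two-step error filter).
    """

    peaks: str = ""
    replicates: str = ""
    out_dir: str = "run_out"
    binning: BinningConfig = field(default_factory=BinningConfig)
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    variants: tuple[str, ...] = ("full", "reduced")
    n_groups: int = 3
    collapse: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **cli_overrides) -> "RunConfig":
        """Load a config file; keyword overrides (from the CLI) win on conflict."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in cli_overrides.items() if v is not None})
        binning = BinningConfig(**raw.pop("binning", {}))
        thresholds = CallThresholds(**raw.pop("thresholds", {}))
        variants = tuple(raw.pop("variants", ("full", "reduced")))
        return cls(binning=binning, thresholds=thresholds, variants=variants, **raw)

    def to_dict(self) -> dict:
        return {
            "peaks": self.peaks,
            "replicates": self.replicates,
            "out_dir": self.out_dir,
            "binning": vars(self.binning).copy(),
            "thresholds": vars(self.thresholds).copy(),
            "variants": list(self.variants),
            "n_groups": self.n_groups,
            "collapse": self.collapse,
            "seed": self.seed,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _log(fh, msg: str) -> None:
    fh.write(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}\n")
    fh.flush()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in fixed order, writing artifacts and a report.

    Stages: peak_io (read + filter + bin), scoring, replicate_qc, network
    (per requested variant). Any stage error aborts with the stage name;
    artifacts written before the failure are retained. Returns the report
    dict (also written to ``out_dir/report.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "manifest": {
            "package": "aflp-delimit",
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "config_hash": cfg.digest(),
        },
        "stages": {},
    }
    with open(out / "run.log", "w") as log:
        stage = "peak_io"
        try:
            _log(log, f"stage {stage}: reading {cfg.peaks}")
            table = read_peak_table(cfg.peaks)
            filtered, removed = filter_raw_peaks(table, cfg.binning)
            binned = bin_all_channels(filtered, cfg.binning)
            for ch, bm in binned.items():
                bm.to_csv(out / f"binned_{ch}.csv")
            report["stages"][stage] = {
                "n_peaks_in": len(table),
                "n_peaks_kept": len(filtered),
                "removed": removed,
                "channels": {ch: len(bm.bin_left) for ch, bm in binned.items()},
            }

            stage = "scoring"
            _log(log, f"stage {stage}: calling three-state genotypes")
            calls = score_channels(binned, cfg.thresholds)
            calls.to_csv(out / "calls_full.csv")
            calls.to_nexus(out / "calls_full.nex")
            report["stages"][stage] = {
                "n_samples": calls.n_samples,
                "n_bins": calls.n_bins,
            }

            stage = "replicate_qc"
            _log(log, f"stage {stage}: replicate error rates and two-step filter")
            reps = ReplicateMap.from_csv(cfg.replicates)
            err = replicate_difference_rates(calls, reps)
            err.to_frame().to_csv(out / "replicate_rates_full.csv", index=False)
            reduced, trace = filter_scoring_errors(calls, reps)
            trace.to_csv(out / "filter_trace.csv")
            (out / "filter_trace.txt").write_text(trace.report_text())
            reduced.to_csv(out / "calls_reduced.csv")
            err_after = replicate_difference_rates(reduced, reps) \
                if reduced.n_bins else None
            report["stages"][stage] = {
                "rate_min": err.min_rate,
                "rate_max": err.max_rate,
                "rate_mean": err.mean_rate,
                "per_level": err.level_summary(),
                "bins_in": trace.n_input,
                "removed_step1": len(trace.step1_removed),
                "removed_step2": len(trace.step2_removed),
                "retained": len(trace.retained),
                "rate_max_after_filter": err_after.max_rate if err_after else None,
            }

            stage = "network"
            matrices = {"full": calls, "reduced": reduced}
            report["stages"][stage] = {}
            for variant in cfg.variants:
                _log(log, f"stage {stage}: NeighborNet for {variant} matrix")
                m = matrices[variant]
                if variant == "reduced" and cfg.collapse:
                    m = collapse_replicates(m, reps)
                if m.n_bins == 0 or m.n_samples < 2:
                    report["stages"][stage][variant] = {"skipped": "empty matrix"}
                    continue
                dm = p_distance_matrix(m)
                dm.to_phylip(out / f"pdist_{variant}.phy")
                dm.to_nexus(out / f"pdist_{variant}.nex")
                ss = neighbor_net(dm)
                ss.to_nexus(out / f"splits_{variant}.nex")
                ga = extract_groups(dm, k=min(cfg.n_groups, dm.n))
                report["stages"][stage][variant] = {
                    "n_taxa": dm.n,
                    "n_splits": len(ss.splits),
                    "fit_percent": round(ss.fit, 4),
                    "groups": {str(k): sorted(v) for k, v in ga.groups().items()},
                }
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            _log(log, f"stage {stage} FAILED: {exc}")
            with open(out / "report.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            raise PipelineError(stage, exc) from exc
        _log(log, "run complete")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
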