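"""End-to-end orchestration: read a cohort, run every stage, write tables.

The pipeline is deterministic given (cohort, config): a single master seed
fans out into per-K clustering streams and per-state permutation streams.
Outputs are delimited text tables — the machine-readable analogues of the
usual phase-locking-state figures: a p-value sweep across K, an effect-size
sweep, a signed FO-difference table, and a state summary with occupancy and
best reference-network match.
"""

from __future__ import annotations

import importlib.metadata
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import (
    CentroidPyramid,
    EigenvectorStack,
    fit_pyramid,
    rsn_overlap,
    stack_eigenvectors,
)
from .exceptions import ConfigurationError, ValidationError
from .metrics import StateOccupancyTable, occupancy_table
from .phase import DEFAULT_BAND, FILTER_ORDER, ParcelTimeSeries, eigenvector_series
from .stats import compare_all_states

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "read_cohort",
    "run_pipeline",
    "write_report_tables",
    "load_pipeline_config",
]

DEFAULT_GROUPS = ("A", "B")

_CONFIG_KEYS = {
    "k_min",
    "k_max",
    "replicates",
    "n_perm",
    "alpha",
    "band_low",
    "band_high",
    "seed",
    "rsn_references",
}


@dataclass
class PipelineConfig:
    """All analysis settings in one place.

    Defaults follow the standard protocol: K = 2..20 with 25 replicates per
    K, 5000 permutations per state, alpha = 0.05, 0.01-0.08 Hz band-pass.
    Set ``band=None`` for cohorts that are already band-limited.
    """

    k_min: int = 2
    k_max: int = 20
    replicates: int = 25
    n_perm: int = 5000
    alpha: float = 0.05
    band: tuple[float, float] | None = DEFAULT_BAND
    seed: int = 0
    rsn_references: str | Path | None = None

    def __post_init__(self) -> None:
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ConfigurationError("need 2 <= k_min <= k_max")
        if self.n_perm < 1 or self.replicates < 1:
            raise ConfigurationError("n_perm and replicates must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must be in (0, 1)")


@dataclass
class PipelineResult:
    """Everything one run produces."""

    pyramid: CentroidPyramid
    stack: EigenvectorStack
    fo_tables: dict[int, StateOccupancyTable]
    comparisons: pd.DataFrame
    state_summary: pd.DataFrame
    log: dict = field(default_factory=dict)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Parse a flat key-value YAML config; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a flat mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    band_low = raw.pop("band_low", DEFAULT_BAND[0])
    band_high = raw.pop("band_high", DEFAULT_BAND[1])
    band = None if band_low is None or band_high is None else (band_low, band_high)
    return PipelineConfig(band=band, **raw)


def _read_scan(path: Path, tr: float, scan_id: str) -> ParcelTimeSeries:
    if path.suffix == ".npy":
        data = np.load(path)
        return ParcelTimeSeries(data=data, tr=tr, scan_id=scan_id)
    frame = pd.read_csv(path, sep="\t")
    return ParcelTimeSeries(
        data=frame.to_numpy(dtype=float),
        tr=tr,
        region_labels=[str(c) for c in frame.columns],
        scan_id=scan_id,
    )


def read_cohort(
    manifest_path: str | Path,
    tr: float = 2.0,
    allowed_groups: tuple[str, ...] = DEFAULT_GROUPS,
) -> tuple[list[ParcelTimeSeries], list[str]]:
    """Load every scan referenced by a manifest (scan_id, group, path).

    Paths are resolved relative to the manifest's directory.  All scans
    must share the same region count; violations are reported with the
    offending scan named.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ValidationError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"scan_id", "group", "path"}
    if not required.issubset(manifest.columns):
        raise ValidationError(
            f"manifest must have columns {sorted(required)}, got "
            f"{list(manifest.columns)}"
        )
    scans: list[ParcelTimeSeries] = []
    groups: list[str] = []
    n_regions: int | None = None
    for row in manifest.itertuples(index=False):
        if row.group not in allowed_groups:
            raise ValidationError(
                f"scan {row.scan_id!r}: unknown group {row.group!r} "
                f"(expected one of {allowed_groups})"
            )
        scan_path = manifest_path.parent / row.path
        if not scan_path.exists():
            raise ValidationError(f"scan {row.scan_id!r}: file missing: {scan_path}")
        ts = _read_scan(scan_path, tr, row.scan_id)
        if n_regions is None:
            n_regions = ts.n_regions
        elif ts.n_regions != n_regions:
            raise ValidationError(
                f"scan {row.scan_id!r} has {ts.n_regions} regions; cohort has "
                f"{n_regions}"
            )
        scans.append(ts)
        groups.append(row.group)
    return scans, groups


def _load_references(path: str | Path) -> dict[str, np.ndarray]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return {str(name): row.to_numpy(dtype=float) for name, row in frame.iterrows()}


def run_pipeline(
    scans: list[ParcelTimeSeries],
    groups: list[str],
    config: PipelineConfig,
) -> PipelineResult:
    """Run the full analysis on an in-memory cohort.

    Stages: per-scan leading-eigenvector extraction, pooled multi-resolution
    cosine k-means, per-scan fractional occupancy, and per-state two-group
    permutation inference with the three-tier Bonferroni scheme.
    """
    series = [eigenvector_series(ts, band=config.band) for ts in scans]
    stack = stack_eigenvectors(series, groups)
    pyramid = fit_pyramid(
        stack, config.k_min, config.k_max, config.replicates, config.seed
    )
    fo_tables = {
        K: occupancy_table(sol, stack) for K, sol in pyramid.solutions.items()
    }
    comparisons = compare_all_states(
        fo_tables, n_perm=config.n_perm, seed=config.seed, alpha=config.alpha
    )

    references = (
        _load_references(config.rsn_references) if config.rsn_references else None
    )
    summary_rows = []
    for K in pyramid.k_values:
        sol = pyramid.solutions[K]
        occ = np.bincount(sol.labels - 1, minlength=K) / len(sol.labels)
        for state in range(1, K + 1):
            name, r = (
                rsn_overlap(sol.centroids[state - 1], references)
                if references
                else ("n/a", np.nan)
            )
            summary_rows.append(
                {
                    "K": K,
                    "state": state,
                    "occupancy": occ[state - 1],
                    "best_rsn": name,
                    "rsn_r": r,
                }
            )
    state_summary = pd.DataFrame(summary_rows)

    try:
        version = importlib.metadata.version("leida")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    log = {
        "leida_version": version,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "k_min": config.k_min,
        "k_max": config.k_max,
        "replicates": config.replicates,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "band": list(config.band) if config.band else None,
        "filter_order": FILTER_ORDER,
        "edge_volumes_trimmed": 2,
        "n_scans": len(scans),
        "n_rows": stack.n_rows,
        "total_states": pyramid.total_states,
        "p_estimator": "exhaustive-if-feasible, else Monte-Carlo add-one",
    }
    return PipelineResult(
        pyramid=pyramid,
        stack=stack,
        fo_tables=fo_tables,
        comparisons=comparisons,
        state_summary=state_summary,
        log=log,
    )


def write_report_tables(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write the comparison sweeps, FO tables, centroids and log to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.8g")
        written.append(path)

    comp = result.comparisons
    _write(comp[["K", "state", "p", "tier"]], "p_sweep.tsv")
    _write(comp[["K", "state", "g", "g_lo", "g_hi"]], "g_sweep.tsv")
    _write(
        comp[["K", "state", "mean_FO_A", "mean_FO_B", "diff"]], "fo_difference.tsv"
    )
    _write(comp, "comparisons.tsv")
    _write(result.state_summary, "state_summary.tsv")
    _write(
        pd.concat([t.to_frame() for t in result.fo_tables.values()]),
        "fo_long.tsv",
    )
    centroid_dir = out_dir / "centroids"
    centroid_dir.mkdir(exist_ok=True)
    for K, sol in result.pyramid.solutions.items():
        path = centroid_dir / f"centroids_K{K:02d}.tsv"
        np.savetxt(path, sol.centroids, delimiter="\t", fmt="%.8f")
        written.append(path)
    log_path = out_dir / "log.yaml"
    log_path.write_text(yaml.safe_dump(result.log, sort_keys=False))
    written.append(log_path)
    return written
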