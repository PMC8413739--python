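"""End-to-end orchestration: ingest -> normalize -> networks -> metrics ->
inference -> report files, with a serializable config and a run manifest.

Reports are plain TSV tables: the 13-row global comparison, the per-region
local betweenness comparison with FDR q-values, the fixed-density sweep for
one measure, and the clinical Pearson correlations.  The manifest records
the config (and its hash), seeds, group sizes and any warnings; a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import (
    CohortTable,
    default_atlas,
    normalize_volumes,
    read_cohort_csv,
    write_cohort_csv,
)
from .inference import (
    DEFAULT_DENSITIES,
    clinical_correlations,
    compare_all_global,
    compare_local_betweenness,
    density_sweep_comparison,
)
from .networks import DEFAULT_COVARIATES, partial_correlation_network
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger("scnet.pipeline")

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "config_digest",
    "REPORT_FILES",
]

REPORT_FILES: tuple[str, ...] = (
    "normalized_cohort.csv",
    "global_comparison.tsv",
    "local_betweenness.tsv",
    "density_sweep.tsv",
    "clinical_correlations.tsv",
    "metric_panels.tsv",
    "manifest.json",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def config_digest(obj) -> str:
    """Short stable hash of any JSON-serializable config object."""
    payload = json.dumps(_jsonable(obj), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs; fully serializable.

    Exactly one input source: ``input_csv`` (cohort table of absolute
    volumes unless ``input_normalized``) or ``synthetic`` (generator
    settings; the default synthetic cohort is used when both are None).
    """

    input_csv: str | None = None
    input_normalized: bool = False
    synthetic: SyntheticConfig | None = None
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    weight_policy: str = "zero_negative"
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    sweep_measure: str = "mean_clustering_coefficient"
    n_permutations: int = 1000
    n_null_graphs: int = 100
    clinical_vars: tuple[str, ...] = ("age",)
    group_a: str | None = None
    group_b: str | None = None
    seed: int = 0
    out_dir: str = "scnet_results"

    def digest(self) -> str:
        return config_digest(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in ("n_per_group", "group_names", "age_range",
                        "within_block_r"):
                if key in syn and isinstance(syn[key], list):
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = SyntheticConfig(**syn)
        for key in ("covariates", "densities", "clinical_vars"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_cohort(config: RunConfig) -> CohortTable:
    if config.input_csv is not None and config.synthetic is not None:
        raise PipelineError(
            "stage ingest: give either input_csv or synthetic, not both"
        )
    if config.input_csv is not None:
        return read_cohort_csv(config.input_csv, default_atlas(),
                               normalized=config.input_normalized)
    synthetic = config.synthetic or SyntheticConfig(seed=config.seed)
    return generate_cohort(synthetic)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name}: {exc}") from exc


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis and write the report files.

    Returns the manifest (also written as ``manifest.json``).  Any stage
    error aborts with a stage-tagged :class:`PipelineError` and no partial
    outputs are left behind (files are written only after every stage has
    succeeded).
    """
    out = Path(out_dir or config.out_dir)
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        cohort = _stage("ingest", _load_cohort, config)
        if not cohort.normalized:
            cohort = _stage("normalize", normalize_volumes, cohort)

        groups = cohort.group_names()
        group_a = config.group_a or groups[0]
        group_b = config.group_b or (groups[1] if len(groups) > 1 else None)
        if group_b is None:
            raise PipelineError("stage networks: cohort has a single group")

        panels = {}
        for g in (group_a, group_b):
            net = _stage("networks", partial_correlation_network,
                         cohort, g, config.covariates, config.weight_policy)
            from .metrics import compute_metric_panel
            panels[g] = _stage(
                "metrics", compute_metric_panel, net,
                {"n_null_graphs": config.n_null_graphs}, config.seed,
            )

        global_table = _stage(
            "global_comparison", compare_all_global, cohort,
            n_perm=config.n_permutations, seed=config.seed,
            group_a=group_a, group_b=group_b,
            covariates=config.covariates,
            weight_policy=config.weight_policy,
            n_null_graphs=config.n_null_graphs,
        )
        local_table = _stage(
            "local_comparison", compare_local_betweenness, cohort,
            n_perm=config.n_permutations, seed=config.seed,
            group_a=group_a, group_b=group_b,
            covariates=config.covariates,
            weight_policy=config.weight_policy,
        )
        sweep_table = _stage(
            "density_sweep", density_sweep_comparison, cohort,
            densities=config.densities, measure=config.sweep_measure,
            n_perm=config.n_permutations, seed=config.seed,
            group_a=group_a, group_b=group_b,
            covariates=config.covariates,
            weight_policy=config.weight_policy,
            n_null_graphs=config.n_null_graphs,
        )
        clinical_table = _stage(
            "clinical_correlations", clinical_correlations, cohort,
            clinical_vars=config.clinical_vars, group=group_a,
        )
        caught = sorted({f"{w.category.__name__}: {w.message}" for w in wrec})

    panel_rows = []
    for g, panel in panels.items():
        row = {"group": g}
        for name, value in panel.global_values().items():
            row[name] = np.nan if value is None else value
        panel_rows.append(row)
    panel_table = pd.DataFrame(panel_rows)

    manifest = {
        "package": "scnet",
        "version": __version__,
        "config": _jsonable(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "groups": {"a": group_a, "b": group_b},
        "group_sizes": cohort.group_sizes(),
        "n_regions": cohort.atlas.size,
        "units": {"volumes": "percent of TIV", "tiv": "mm^3",
                  "age": "years"},
        "n_permutations": config.n_permutations,
        "n_redrawn_permutations": {
            "global": int(global_table.attrs.get("n_redrawn", 0)),
            "local": int(local_table.attrs.get("n_redrawn", 0)),
            "density_sweep": int(sweep_table.attrs.get("n_redrawn", 0)),
        },
        "warnings": caught,
        "report_files": list(REPORT_FILES),
    }

    # all stages succeeded: write everything
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        write_cohort_csv(cohort, out / "normalized_cohort.csv")
        written.append(out / "normalized_cohort.csv")
        for fname, table in (
            ("global_comparison.tsv", global_table),
            ("local_betweenness.tsv", local_table),
            ("density_sweep.tsv", sweep_table),
            ("clinical_correlations.tsv", clinical_table),
            ("metric_panels.tsv", panel_table),
        ):
            path = out / fname
            table.to_csv(path, sep="\t", index=False, float_format="%.10g")
            written.append(path)
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                        + "\n")
        written.append(path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage report: {exc}") from exc
    return manifest
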