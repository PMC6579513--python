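"""Tabular dialects, configuration and the two end-to-end workflows.

All files are plain UTF-8 CSV (comma separated, "." decimal, header
required) or JSON/YAML; numbers are written with 6 significant digits.
The canonical uptake schema is one row per replicate observation:

    peptide_id, sequence, start, end, charge, condition, timepoint_s,
    replicate, percent_d

An optional ``experiment`` column pairs each compound with the vehicle arm
of its own differential run (screens acquired as N separate
compound-versus-control experiments); without it a single shared vehicle
arm is assumed.  A centroid-mode table replaces ``percent_d`` with
``undeut_mz``, ``obs_mz`` and ``dmax_mz``; %D is computed on read.  A small
alias shim maps common
HDX-Workbench-style export headers onto the canonical names.  The condition
id ``vehicle`` designates the control arm; a ``timepoint_s`` of 0 is the
undeuterated reference and is dropped from curves and statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import consolidation, differential, screening_stats
from .differential import SignificanceConfig
from .exchange_model import (
    ASSAYS,
    SimulationConfig,
    simulate_screen_study,
)
from .uptake import CentroidTriple, Peptide, percent_deuterium

log = logging.getLogger("hdxscreen")

__all__ = [
    "SchemaError",
    "WorkflowError",
    "RunConfig",
    "read_uptake_table",
    "write_uptake_table",
    "read_activity_table",
    "write_activity_table",
    "read_fasta",
    "load_config",
    "run_workflow",
]

UPTAKE_COLUMNS = [
    "peptide_id", "sequence", "start", "end", "charge",
    "condition", "timepoint_s", "replicate",
]
CENTROID_COLUMNS = ["undeut_mz", "obs_mz", "dmax_mz"]

# Maps HDX-Workbench-style export headers onto the canonical schema.
WORKBENCH_ALIASES = {
    "peptide": "sequence",
    "peptide sequence": "sequence",
    "charge state": "charge",
    "z": "charge",
    "start position": "start",
    "end position": "end",
    "exposure": "timepoint_s",
    "exposure (s)": "timepoint_s",
    "deut time (sec)": "timepoint_s",
    "sample": "condition",
    "state": "condition",
    "protein state": "condition",
    "file": "replicate",
    "%d": "percent_d",
    "percent d": "percent_d",
    "percentd": "percent_d",
}


class SchemaError(ValueError):
    """A table is missing columns or contains unparseable fields."""


class WorkflowError(RuntimeError):
    """A pipeline stage failed; the message carries a stage tag."""


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in WORKBENCH_ALIASES:
            renames[col] = WORKBENCH_ALIASES[key]
        elif key != col:
            renames[col] = key
    return df.rename(columns=renames)


def _require_numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(
                f"{path}: non-numeric value {df.loc[bad.idxmax(), col]!r} in "
                f"column {col!r} (line {row})"
            )
        df[col] = coerced
    return df


def read_uptake_table(path) -> tuple[pd.DataFrame, list[Peptide]]:
    """Read an uptake CSV; returns (observations, peptide list).

    Accepts percent-D or centroid columns (%D is computed on the fly via
    the Dmax-referenced formula in the latter case).  Schema and per-row
    validation errors carry the file line number.
    """
    path = Path(path)
    df = _canonicalize(pd.read_csv(path))
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    has_pct = "percent_d" in df.columns
    has_cent = all(c in df.columns for c in CENTROID_COLUMNS)
    if not has_pct and not has_cent:
        raise SchemaError(
            f"{path}: need either a 'percent_d' column or centroid columns "
            f"{CENTROID_COLUMNS}"
        )
    numeric = ["start", "end", "charge", "timepoint_s", "replicate"]
    numeric += ["percent_d"] if has_pct else CENTROID_COLUMNS
    df = _require_numeric(df, numeric, path)
    has_experiment = "experiment" in df.columns

    peptides: dict[str, Peptide] = {}
    for (pid, seq, start, end, charge), sub in df.groupby(
        ["peptide_id", "sequence", "start", "end", "charge"]
    ):
        if pid in peptides:
            raise SchemaError(
                f"{path}: peptide {pid!r} has inconsistent sequence/span/charge "
                f"(first offending line {int(sub.index[0]) + 2})"
            )
        try:
            peptides[pid] = Peptide(
                id=str(pid), sequence=str(seq),
                start=int(start), end=int(end), charge=int(charge),
            )
        except ValueError as exc:
            raise SchemaError(
                f"{path}: line {int(sub.index[0]) + 2}: {exc}"
            ) from exc

    if not has_pct:
        pct = np.empty(len(df))
        for i, row in enumerate(df.itertuples(index=False)):
            pct[i] = percent_deuterium(
                CentroidTriple(
                    undeuterated_mz=row.undeut_mz,
                    observed_mz=row.obs_mz,
                    dmax_mz=row.dmax_mz,
                    charge=int(row.charge),
                )
            )
        df = df.assign(percent_d=pct)
    cols = ["peptide_id", "condition", "timepoint_s", "replicate", "percent_d"]
    if has_experiment:
        cols.insert(2, "experiment")
    obs = df[cols].copy()
    obs["condition"] = obs["condition"].astype(str)
    if has_experiment:
        obs["experiment"] = obs["experiment"].astype(str)
    return obs, list(peptides.values())


def write_uptake_table(observations: pd.DataFrame, peptides, path) -> int:
    """Write the canonical uptake CSV; returns the row count."""
    info = pd.DataFrame(
        [
            {
                "peptide_id": p.id, "sequence": p.sequence,
                "start": p.start, "end": p.end, "charge": p.charge,
            }
            for p in peptides
        ]
    )
    value_cols = [
        c for c in ("percent_d", *CENTROID_COLUMNS) if c in observations.columns
    ]
    out = observations.merge(info, on="peptide_id", how="left")
    cols = list(UPTAKE_COLUMNS)
    if "experiment" in observations.columns:
        cols.insert(cols.index("timepoint_s"), "experiment")
    out = out[cols + value_cols]
    out.to_csv(path, index=False, float_format="%.6g")
    return len(out)


def read_activity_table(path) -> pd.DataFrame:
    """Read the compound/assay/value activity CSV."""
    path = Path(path)
    df = _canonicalize(pd.read_csv(path))
    missing = [c for c in ("compound", "assay", "value") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        warnings.warn(f"{path}: activity table is empty", stacklevel=2)
        return df
    unknown = set(df["assay"]) - set(ASSAYS)
    if unknown:
        raise SchemaError(f"{path}: unknown assay name(s) {sorted(unknown)}")
    dup = df.duplicated(subset=["compound", "assay"])
    if dup.any():
        raise SchemaError(
            f"{path}: duplicate (compound, assay) row at line {int(dup.idxmax()) + 2}"
        )
    df = _require_numeric(df, ["value"], path)
    return df[["compound", "assay", "value"]]


def write_activity_table(activities: pd.DataFrame, path) -> int:
    activities.to_csv(path, index=False, float_format="%.6g")
    return len(activities)


def read_fasta(path) -> tuple[str, str]:
    """First record of a FASTA file as (id, sequence)."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()


def write_fasta(name: str, sequence: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Run configuration and workflows
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative description of one pipeline run (YAML-loadable)."""

    workflow: str  # "timecourse" or "screen"
    out_dir: str
    uptake_path: str | None = None
    activity_path: str | None = None
    fasta_path: str | None = None
    vehicle: str = "vehicle"
    seed: int = 0
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    simulation: SimulationConfig | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.workflow not in ("timecourse", "screen"):
            raise ValueError("workflow must be 'timecourse' or 'screen'")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sig = SignificanceConfig(**raw.pop("significance", {}))
    sim = raw.pop("simulation", None)
    sim_cfg = SimulationConfig(**sim) if sim is not None else None
    return RunConfig(significance=sig, simulation=sim_cfg, **raw)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> int:
    df.to_csv(path, index=index, float_format="%.6g")
    return len(df)


def run_workflow(config: RunConfig) -> dict:
    """Execute a full workflow; returns (and writes) the artifact manifest.

    ``timecourse``: uptake curves, perturbation records, per-compound mean
    perturbation over timepoints, residue-level consolidation.

    ``screen``: perturbation records and wide matrix, significance filter,
    per-assay activity correlations, covariation grid + mask, Ward linkage
    table.

    Any stage failure raises :class:`WorkflowError` with a stage tag.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "workflow": config.workflow,
        "seed": config.seed,
        "vehicle": config.vehicle,
        "files": [],
    }

    def record(name: str, rows: int) -> None:
        manifest["files"].append({"file": name, "rows": rows})

    def stage(name):
        class _Stage:
            def __enter__(self):
                log.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise WorkflowError(f"[{name}] {exc}") from exc

        return _Stage()

    if config.workflow == "screen" and config.activity_path is None:
        raise WorkflowError("[config] screen workflow requires an activity table")
    if config.uptake_path is None:
        raise WorkflowError("[config] an uptake table is required")

    with stage("read"):
        obs, peptides = read_uptake_table(config.uptake_path)
        obs = obs[obs["timepoint_s"] > 0]  # 0 s rows are the undeuterated reference
        if config.fasta_path:
            _, sequence = read_fasta(config.fasta_path)
        else:
            sequence = None

    with stage("differential"):
        records = differential.compute_perturbations(
            obs, vehicle=config.vehicle, config=config.significance
        )
        record("perturbations.csv", _write_csv(records, out / "perturbations.csv"))

    if config.workflow == "timecourse":
        with stage("curves"):
            curves = (
                obs.groupby(["peptide_id", "condition", "timepoint_s"])["percent_d"]
                .agg(mean_percent_d="mean", sd=lambda v: v.std(ddof=1), n="count")
                .reset_index()
            )
            record("uptake_curves.csv", _write_csv(curves, out / "uptake_curves.csv"))
        with stage("consolidate"):
            means = differential.mean_perturbation_over_timepoints(records)
            record(
                "mean_perturbations.csv",
                _write_csv(means, out / "mean_perturbations.csv"),
            )
            for comp, sub in means.groupby("compound"):
                values = dict(
                    zip(sub["peptide_id"], sub["mean_delta_percent_d"])
                )
                rmap = consolidation.consolidate_to_residues(values, peptides)
                name = f"residues_{comp}.csv"
                record(name, _write_csv(rmap, out / name, index=True))
    else:
        with stage("filter"):
            kept, counts = differential.significance_filter(
                records, config.significance
            )
            record(
                "significance_counts.csv",
                _write_csv(counts, out / "significance_counts.csv"),
            )
            kept_df = pd.DataFrame(kept, columns=["peptide_id", "timepoint_s"])
            record("kept_cells.csv", _write_csv(kept_df, out / "kept_cells.csv"))
            matrix = differential.to_matrix(records)
            reduced = matrix.loc[:, kept] if kept else matrix
            record(
                "perturbation_matrix.csv",
                _write_csv(reduced, out / "perturbation_matrix.csv", index=True),
            )
        with stage("correlate"):
            activities = read_activity_table(config.activity_path)
            for assay in sorted(set(activities["assay"])):
                corr = screening_stats.activity_correlation(
                    reduced, activities, assay
                )
                name = f"correlation_{assay}.csv"
                record(name, _write_csv(corr, out / name))
        with stage("covariation"):
            cov = screening_stats.covariation(reduced)
            record(
                "covariation_r2.csv",
                _write_csv(cov.r_squared, out / "covariation_r2.csv", index=True),
            )
            record(
                "covariation_mask.csv",
                _write_csv(cov.mask, out / "covariation_mask.csv", index=True),
            )
            record(
                "covariation_pairs.csv",
                _write_csv(cov.pairs, out / "covariation_pairs.csv"),
            )
        with stage("cluster"):
            tree = screening_stats.cluster_compounds(reduced)
            link = tree.to_frame()
            link["leaf_order"] = pd.Series(tree.leaf_order)
            record("linkage.csv", _write_csv(link, out / "linkage.csv"))

    if sequence is not None:
        with stage("coverage"):
            first = min(p.start for p in peptides)
            manifest["sequence_coverage_percent"] = consolidation.sequence_coverage(
                peptides, len(sequence), first_index=first
            )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def simulate_to_files(
    out_dir,
    seed: int = 0,
    n_compounds: int = 38,
    n_replicates: int = 5,
    timecourse: bool = False,
    raw: bool = False,
) -> dict:
    """Simulate a study and write its input files (uptake, activities, FASTA).

    Ground-truth compound classes and planted effects go to ``truth.json``
    so downstream evaluations can score recovery.
    """
    from .exchange_model import FULL_TIMEPOINTS, SCREEN_TIMEPOINTS

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_screen_study(
        seed=seed,
        n_compounds=n_compounds,
        n_replicates=n_replicates,
        timepoints=FULL_TIMEPOINTS if timecourse else SCREEN_TIMEPOINTS,
        raw=raw,
    )
    manifest = {"seed": seed, "files": []}
    rows = write_uptake_table(study.observations, study.peptides, out / "uptake.csv")
    manifest["files"].append({"file": "uptake.csv", "rows": rows})
    rows = write_activity_table(study.activities, out / "activities.csv")
    manifest["files"].append({"file": "activities.csv", "rows": rows})
    write_fasta("construct", study.protein.sequence, out / "construct.fasta")
    manifest["files"].append({"file": "construct.fasta", "rows": 1})
    truth = {
        "classes": study.classes,
        "region_effects": {c.id: c.region_effects for c in study.compounds},
        "link_models": {
            a: {
                "score_region": s.score_region,
                "score_timepoint": s.score_timepoint,
                "intercept": s.intercept,
                "slope": s.slope,
                "noise_sd": s.noise_sd,
            }
            for a, s in study.link_model.links.items()
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    manifest["files"].append({"file": "truth.json", "rows": len(truth["classes"])})
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def dataclass_to_dict(obj) -> dict:
    return dataclasses.asdict(obj)
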