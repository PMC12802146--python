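"""Tabular readers/writers and the end-to-end pipeline.

All on-disk formats are UTF-8 comma-separated tables with a header row and
'.' decimals.  Files written by this package start with comment lines
(``# key: value``) recording the package version, the seed, and a hash of
the configuration, so every output is traceable to the run that produced
it; readers skip such lines.

Schemas (long formats keyed by ``cycle_id``):

* cycles:    cycle_id, lineage_id, well_id, role, generation,
             birth_time_min, division_time_min, birth_length_um, width_um,
             sibling_id
* series:    lineage_id, cycle_id, time_min, length_um
* transects: cycle_id, pixel_index, intensity_au, pixel_size_um
             (+ optional cell_length_um; inferred from the pixel count
             otherwise)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregates import DetectionParams, detect_aggregate, mean_fluorescence, partition_fluorescence
from .growth import fit_elongation_rate, InsufficientDataError
from .lineage import (
    CellCycleRecord,
    LineageTable,
    Role,
    TransectProfile,
    filter_complete_cycles,
    pair_divisions,
)
from .simulate import SimConfig, simulate_lineages
from .stats import ModelSpec, compare_models

__all__ = [
    "SchemaError",
    "PipelineError",
    "PipelineConfig",
    "read_lineage_table",
    "write_lineage_table",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

CYCLE_COLUMNS = [
    "cycle_id", "lineage_id", "well_id", "role", "generation",
    "birth_time_min", "division_time_min", "birth_length_um", "width_um",
    "sibling_id",
]
SERIES_COLUMNS = ["lineage_id", "cycle_id", "time_min", "length_um"]
TRANSECT_COLUMNS = ["cycle_id", "pixel_index", "intensity_au", "pixel_size_um"]


class SchemaError(ValueError):
    """An input table does not match the expected schema."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _numeric(frame: pd.DataFrame, col: str, path) -> pd.Series:
    # python's float() is correctly rounded (exact round trip of written
    # values), unlike the pandas fast parser
    values = np.empty(len(frame), dtype=float)
    for i, v in enumerate(frame[col].to_numpy()):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            values[i] = np.nan
            continue
        try:
            values[i] = float(v)
        except (TypeError, ValueError):
            # +2: one for the header row, one for 1-based line numbering
            raise SchemaError(
                f"{path}: malformed numeric value {v!r} in column {col!r} "
                f"near line {i + 2}"
            ) from None
    return pd.Series(values, index=frame.index)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype=str, keep_default_na=True)


def _header_lines(meta: Dict[str, str]) -> str:
    lines = [f"# {k}: {v}" for k, v in meta.items()]
    return "\n".join(lines) + "\n" if lines else ""


def _write_csv(frame: pd.DataFrame, path: Path, meta: Dict[str, str]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(meta))
        frame.to_csv(fh, index=False)


def read_lineage_table(
    cycles_path,
    series_path,
    transects_path=None,
) -> LineageTable:
    """Load a lineage table from its cycle, length-series, and transect CSVs."""
    cyc = _read_csv(cycles_path)
    _require_columns(cyc, CYCLE_COLUMNS, cycles_path)
    ser = _read_csv(series_path)
    _require_columns(ser, SERIES_COLUMNS, series_path)
    for col in ("generation", "birth_time_min", "division_time_min",
                "birth_length_um", "width_um"):
        cyc[col] = _numeric(cyc, col, cycles_path)
    for col in ("time_min", "length_um"):
        ser[col] = _numeric(ser, col, series_path)

    series_by_cycle: Dict[str, List] = {}
    for cid, grp in ser.groupby("cycle_id", sort=False):
        series_by_cycle[cid] = list(zip(grp["time_min"], grp["length_um"]))

    transects: Dict[str, TransectProfile] = {}
    if transects_path is not None:
        tra = _read_csv(transects_path)
        _require_columns(tra, TRANSECT_COLUMNS, transects_path)
        for col in ("pixel_index", "intensity_au", "pixel_size_um"):
            tra[col] = _numeric(tra, col, transects_path)
        has_length = "cell_length_um" in tra.columns
        if has_length:
            tra["cell_length_um"] = _numeric(tra, "cell_length_um", transects_path)
        for cid, grp in tra.groupby("cycle_id", sort=False):
            idx = grp["pixel_index"].to_numpy()
            if np.any(np.diff(idx) < 0):
                logger.warning(
                    "%s: pixel_index out of order for cycle %s; reordering",
                    transects_path, cid,
                )
                grp = grp.sort_values("pixel_index")
            px = float(grp["pixel_size_um"].iloc[0])
            intensities = grp["intensity_au"].to_numpy(dtype=float)
            if has_length and np.isfinite(grp["cell_length_um"].iloc[0]):
                length = float(grp["cell_length_um"].iloc[0])
            else:
                length = intensities.size * px
            transects[cid] = TransectProfile(intensities, px, length)

    records: List[CellCycleRecord] = []
    for _, row in cyc.iterrows():
        cid = row["cycle_id"]
        records.append(
            CellCycleRecord(
                lineage_id=row["lineage_id"],
                well_id=row["well_id"],
                role=Role(row["role"]),
                generation=int(row["generation"]),
                birth_time=float(row["birth_time_min"]),
                division_time=(None if pd.isna(row["division_time_min"])
                               else float(row["division_time_min"])),
                length_series=series_by_cycle.get(cid, []),
                width=float(row["width_um"]),
                cycle_id=cid,
                sibling_id=None if pd.isna(row["sibling_id"]) else row["sibling_id"],
                transect=transects.get(cid),
            )
        )
    return LineageTable(records=records)


def write_lineage_table(
    table: LineageTable,
    outdir,
    meta: Optional[Dict[str, str]] = None,
) -> Dict[str, Path]:
    """Write cycles/series/transects CSVs; returns the written paths."""
    outdir = Path(outdir)
    meta = meta or {}
    cyc = table.to_frame()

    ser_rows, tra_rows = [], []
    for rec in table.records:
        for t, length in rec.length_series:
            ser_rows.append(
                {"lineage_id": rec.lineage_id, "cycle_id": rec.cycle_id,
                 "time_min": t, "length_um": length}
            )
        if rec.transect is not None:
            tp = rec.transect
            for i, val in enumerate(tp.intensities):
                tra_rows.append(
                    {"cycle_id": rec.cycle_id, "pixel_index": i,
                     "intensity_au": val, "pixel_size_um": tp.pixel_size,
                     "cell_length_um": tp.cell_length}
                )
    paths = {
        "cycles": outdir / "cycles.csv",
        "series": outdir / "series.csv",
        "transects": outdir / "transects.csv",
    }
    _write_csv(cyc, paths["cycles"], meta)
    _write_csv(pd.DataFrame(ser_rows, columns=SERIES_COLUMNS), paths["series"], meta)
    _write_csv(
        pd.DataFrame(tra_rows, columns=TRANSECT_COLUMNS + ["cell_length_um"]),
        paths["transects"], meta,
    )
    return paths


# --------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end pipeline.

    With ``simulate=True`` the input tables are generated by the synthetic
    lineage model in :class:`SimConfig`; otherwise they are read from
    ``cycles_path``/``series_path``/``transects_path``.
    """

    outdir: str = "polagg_out"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    cycles_path: Optional[str] = None
    series_path: Optional[str] = None
    transects_path: Optional[str] = None
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        detection = DetectionParams(**raw.pop("detection", {}))
        cfg = cls(sim=sim, detection=detection, **raw)
        cfg.sim.seed = cfg.seed
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:10]

    def meta(self) -> Dict[str, str]:
        return {
            "package": f"polagg {__version__}",
            "seed": str(self.seed),
            "config": self.config_hash(),
        }


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run simulate (optional) → filter/pair → growth → detect/partition → stats.

    Writes every stage's table under ``config.outdir`` (header comments
    carry the package version, seed, and config hash) and returns a report
    dict of row counts and summary statistics.  A failing stage aborts the
    run with the stage named in the raised :class:`PipelineError`.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = config.meta()
    report: Dict[str, object] = {"seed": config.seed, "config_hash": meta["config"]}

    @_stage("ingest")
    def ingest():
        if config.simulate:
            config.sim.seed = config.seed
            table, log = simulate_lineages(config.sim)
            write_lineage_table(table, outdir, meta)
            _write_csv(log.frame, outdir / "truth.csv", meta)
            return table, log
        for name in ("cycles_path", "series_path"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"{name} not found: {p}")
        table = read_lineage_table(
            config.cycles_path, config.series_path, config.transects_path
        )
        return table, None

    table, log = ingest()
    report["n_input_cycles"] = len(table)

    @_stage("filter")
    def do_filter():
        filtered = filter_complete_cycles(table)
        pairs = pair_divisions(filtered)
        return filtered, pairs

    filtered, pairs = do_filter()
    report["filter_log"] = dict(filtered.filter_log)
    report["n_complete_cycles"] = len(filtered)
    report["n_pairs"] = len(pairs)
    report["n_unpaired"] = pairs.n_unpaired

    @_stage("growth")
    def do_growth():
        rows = []
        for rec in filtered:
            try:
                m = fit_elongation_rate(rec.length_series)
            except InsufficientDataError:
                continue
            rows.append(
                {"cycle_id": rec.cycle_id, "lineage_id": rec.lineage_id,
                 "role": rec.role.value, "generation": rec.generation,
                 "birth_time_min": rec.birth_time,
                 "elongation_rate_per_min": m.elongation_rate,
                 "division_interval_min": m.division_interval,
                 "birth_length_um": m.birth_length,
                 "fit_r_squared": m.fit_r_squared}
            )
        frame = pd.DataFrame(rows)
        _write_csv(frame, outdir / "growth.csv", meta)
        return frame

    growth = do_growth()
    report["n_growth_fits"] = len(growth)

    @_stage("detect")
    def do_detect():
        call_rows, part_rows = [], []
        for rec in filtered:
            if rec.transect is None:
                continue
            call = detect_aggregate(rec.transect, config.detection)
            part = partition_fluorescence(rec.transect, call)
            call_rows.append(
                {"cycle_id": rec.cycle_id, "role": rec.role.value,
                 "generation": rec.generation, "birth_time_min": rec.birth_time,
                 "present": call.present,
                 "start_px": call.pixel_span[0], "end_px": call.pixel_span[1],
                 "d_um": call.diameter, "delta_um": call.distance_to_old_pole,
                 "f_agg": call.mean_intensity, "f_peak": call.peak_intensity,
                 "rho": call.relative_length,
                 "mean_fluor_au": mean_fluorescence(rec.transect)}
            )
            part_rows.append(
                {"cycle_id": rec.cycle_id, "cell_mean_au": part.cell_mean,
                 "aggregated_mean_au": part.aggregated_mean,
                 "dispersed_mean_au": part.dispersed_mean,
                 "n_agg_pixels": part.n_agg_pixels,
                 "n_disp_pixels": part.n_disp_pixels}
            )
        calls = pd.DataFrame(call_rows)
        _write_csv(calls, outdir / "aggregate_calls.csv", meta)
        _write_csv(pd.DataFrame(part_rows), outdir / "partitions.csv", meta)
        return calls

    calls = do_detect()
    report["n_transects"] = len(calls)
    if len(calls):
        report["n_aggregate_calls"] = int(calls["present"].sum())

    @_stage("pairs")
    def do_pairs():
        rows = []
        d_by_cycle = {}
        if len(calls):
            d_by_cycle = calls.set_index("cycle_id")["d_um"].to_dict()
        for pair in pairs:
            rows.append(
                {"mother_cycle_id": pair.mother.cycle_id,
                 "daughter_cycle_id": pair.daughter.cycle_id,
                 "birth_time_min": pair.mother.birth_time,
                 "asymmetry": pair.asymmetry,
                 "mother_d_um": d_by_cycle.get(pair.mother.cycle_id, np.nan)}
            )
        frame = pd.DataFrame(rows)
        _write_csv(frame, outdir / "pairs.csv", meta)
        return frame

    do_pairs()

    @_stage("stats")
    def do_stats():
        if not len(growth) or not len(calls):
            return pd.DataFrame()
        data = growth.merge(
            calls[["cycle_id", "present", "rho"]], on="cycle_id", how="inner"
        )
        data = data.rename(columns={"elongation_rate_per_min": "rate"})
        data["time_h"] = data["birth_time_min"] / 60.0
        data["bearing"] = data["present"].astype(str)
        specs = [
            ModelSpec("rate~s(time)", "rate", smooth_terms={"time_h": 6}),
            ModelSpec("rate~s(time)+role", "rate",
                      factor_terms=["role"], smooth_terms={"time_h": 6}),
            ModelSpec("rate~s(time)+role+bearing", "rate",
                      factor_terms=["role", "bearing"], smooth_terms={"time_h": 6}),
            ModelSpec("rate~rho+role", "rate",
                      linear_terms=["rho"], factor_terms=["role"]),
        ]
        results = compare_models(data, specs)
        frame = pd.DataFrame(
            [{"model_id": r.model_id, "aic": r.aic, "delta_aic": r.delta_aic,
              "deviance_explained": r.deviance_explained,
              "substantially_better": r.substantially_better, "n": r.n_obs,
              "notes": r.notes}
             for r in results]
        )
        _write_csv(frame, outdir / "model_comparison.csv", meta)
        return frame

    comparison = do_stats()
    if len(comparison):
        report["best_model"] = str(comparison.iloc[0]["model_id"])

    if log is not None:
        report["n_truth_rows"] = len(log.frame)
        report["n_truncated"] = log.n_truncated

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=str)
    logger.info("pipeline complete: %s", report)
    return report
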