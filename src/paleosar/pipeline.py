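"""End-to-end orchestration: occurrences -> cells -> regions -> diversity ->
SAR fits and contrasts, with a manifest recording seeds and per-stage
record counts."""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import occurrences as occ_io
from .diversity import AbundanceVector, face_value_richness, richness_at_quorum
from .grid import EqualAreaGrid, bin_to_cells
from .regions import build_mst, enumerate_nested_regions, screen_regions, split_subtrees
from .sar import SpeciesAreaModel, compare_slopes, contrasts_to_frame

__all__ = ["RunConfig", "PipelineError", "build_sar_table", "fit_sar_tables",
           "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Single source of truth for one pipeline run."""

    input_path: str
    out_dir: str = "paleosar_out"
    column_map: dict = None
    groups: tuple = ()               # GroupRule names from DEFAULT_GROUPS, or rules
    scheme: occ_io.TimeBinScheme = None
    exclude_species: tuple = ()
    spacing_km: float = 100.0
    cutoff_km: float = 1000.0
    min_nodes: int = 10
    max_nn_km: float = 1000.0
    quorum: float = 0.8
    min_region_n: int = 10
    n_null_reps: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.scheme is None:
            self.scheme = occ_io.TimeBinScheme.stage_composite()
        for v, name in ((self.spacing_km, "spacing_km"), (self.cutoff_km, "cutoff_km"),
                        (self.min_nodes, "min_nodes"), (self.max_nn_km, "max_nn_km"),
                        (self.quorum, "quorum"), (self.min_region_n, "min_region_n")):
            if v <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        scheme = cfg.pop("scheme", None)
        if isinstance(scheme, str):
            scheme = {"stage_composite": occ_io.TimeBinScheme.stage_composite,
                      "substage_nalma": occ_io.TimeBinScheme.substage_nalma,
                      "single_bin": occ_io.TimeBinScheme.single_bin}[scheme]()
        elif isinstance(scheme, dict):
            scheme = occ_io.TimeBinScheme(
                bins=tuple((b["name"], tuple(b["members"])) for b in scheme["bins"]),
                resolution_tag=scheme.get("resolution_tag", "stage_composite"))
        return cls(scheme=scheme, **cfg)

    def digest(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("scheme",)}
        payload["scheme"] = [(n, list(m)) for n, m in self.scheme.bins]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _cell_abundances(df: pd.DataFrame, grid: EqualAreaGrid):
    """Per-cell species occurrence counts: (cell ids, species, counts matrix)."""
    cells = grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    tab = pd.crosstab(pd.Series(cells, name="cell_id"), df["species"])
    return list(tab.index), list(tab.columns), tab.to_numpy()


def build_sar_table(table: pd.DataFrame, *, spacing_km: float = 100.0,
                    cutoff_km: float = 1000.0, min_nodes: int = 10,
                    max_nn_km: float = 1000.0, quorum: float = 0.8,
                    min_region_n: int = 10, seed: int = 0,
                    by=("bin", "group")) -> pd.DataFrame:
    """Per-region SAR points for every bin x group in an occurrence table.

    Runs gridding, the global MST, contiguous-subtree extraction,
    nested-region enumeration, the nearest-neighbour screen, and both SQS and
    face-value richness per region.  Returns one row per retained region with
    columns: grouping keys, ``region_id``, ``n_cells``, ``mst_km``,
    ``max_nn_km``, ``n_occ``, ``s_obs``, ``richness_sqs``, ``richness_face``,
    ``mode``, ``usable``, ``cell_ids``.
    """
    grid = EqualAreaGrid(spacing_km)
    keys = [k for k in by if k in table.columns]
    groups = table.groupby(keys, observed=True) if keys else [((), table)]
    ss = np.random.SeedSequence(seed)
    rows = []
    for key, sub in groups:
        if not isinstance(key, tuple):
            key = (key,)
        key_dict = dict(zip(keys, key))
        cell_ids, species, counts = _cell_abundances(sub, grid)
        if len(cell_ids) < 2:
            continue
        mids = np.array([grid.midpoint(c) for c in cell_ids])
        pts = pd.DataFrame({"cell_id": cell_ids, "lon": mids[:, 0], "lat": mids[:, 1]})
        mst = build_mst(pts)
        subtrees, _ = split_subtrees(mst, cutoff_km=cutoff_km, min_nodes=min_nodes)
        row_of = {c: i for i, c in enumerate(cell_ids)}
        region_id = 0
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        for st in subtrees:
            regions = enumerate_nested_regions(st, seed=sub_seed)
            regions, _ = screen_regions(regions, max_nn_km=max_nn_km)
            for r in regions:
                idx = [row_of[c] for c in r.cells]
                pooled = counts[idx].sum(axis=0)
                ab = AbundanceVector(pooled)
                est = richness_at_quorum(ab, quorum, min_n=min_region_n)
                rows.append({**key_dict, "region_id": region_id,
                             "n_cells": r.n_cells, "mst_km": r.mst_km,
                             "max_nn_km": r.max_nn_km, "n_occ": ab.n,
                             "s_obs": ab.s_obs, "richness_sqs": est.value,
                             "richness_face": float(face_value_richness(ab)),
                             "mode": est.mode, "usable": est.usable,
                             "cell_ids": ";".join(sorted(r.cells))})
                region_id += 1
    return pd.DataFrame(rows)


def fit_sar_tables(points: pd.DataFrame, metric: str = "sqs",
                   by=("group", "bin")):
    """Fit one SAR per group x bin and contrast consecutive-bin slopes
    within each group.  Returns ``(fits_df, contrasts_df)``."""
    col = f"richness_{metric}"
    usable = points[points["usable"]] if metric == "sqs" else points
    keys = [k for k in by if k in usable.columns]
    fits, contrasts = [], []
    if keys:
        for key, sub in usable.groupby(keys, observed=True):
            if not isinstance(key, tuple):
                key = (key,)
            labels = dict(zip(keys, key))
            try:
                res = SpeciesAreaModel(sub["mst_km"], sub[col],
                                       bin_name=str(labels.get("bin", "")),
                                       group=str(labels.get("group", ""))).fit()
            except ValueError as exc:
                warnings.warn(f"SAR fit skipped for {labels}: {exc}", stacklevel=2)
                continue
            fits.append(res.to_dict())
        group_key = "group" if "group" in usable.columns else None
        for gname, gsub in (usable.groupby(group_key, observed=True)
                            if group_key else [("all", usable)]):
            if "bin" not in gsub.columns or gsub["bin"].nunique() < 2:
                continue
            try:
                cons = compare_slopes(gsub["mst_km"], gsub[col], gsub["bin"])
            except ValueError as exc:
                warnings.warn(f"contrasts skipped for {gname}: {exc}", stacklevel=2)
                continue
            frame = contrasts_to_frame(cons)
            frame.insert(0, "group", gname)
            contrasts.append(frame)
    else:
        res = SpeciesAreaModel(usable["mst_km"], usable[col]).fit()
        fits.append(res.to_dict())
    fits_df = pd.DataFrame(fits)
    contrasts_df = (pd.concat(contrasts, ignore_index=True)
                    if contrasts else pd.DataFrame())
    return fits_df, contrasts_df


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full empirical pipeline and write all artifacts.

    Writes ``occurrences.csv``, ``cells.csv``, ``sar_points.csv``,
    ``fits_sqs.csv``, ``fits_face.csv``, ``contrasts.csv``, optional null
    outputs, and ``manifest.json``.  Any stage failure raises
    :class:`PipelineError` naming the stage, after writing a partial
    manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_digest": config.digest(), "seed": config.seed,
                "stages": [], "counts": {}}

    def _finish_stage(name, **counts):
        manifest["stages"].append(name)
        manifest["counts"].update(counts)

    def _abort(stage, exc):
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, str(exc)) from exc

    try:
        table, report = occ_io.load_occurrences(
            config.input_path, column_map=config.column_map,
            exclude_species=config.exclude_species)
        _finish_stage("load_occurrences", load=report.as_dict())
    except Exception as exc:
        _abort("load_occurrences", exc)

    try:
        if config.groups:
            parts = []
            for g in config.groups:
                rule = g if isinstance(g, occ_io.GroupRule) else occ_io.DEFAULT_GROUPS[g]
                part = occ_io.filter_group(table, rule)
                part = part.copy()
                part["group"] = rule.name
                parts.append(part)
            table = pd.concat(parts, ignore_index=True)
        else:
            table = table.copy()
            table["group"] = "all"
        _finish_stage("filter_group", grouped_rows=len(table))
    except Exception as exc:
        _abort("filter_group", exc)

    try:
        table, bin_report = occ_io.assign_time_bins(table, config.scheme)
        if not len(table):
            raise ValueError("no records fall into any configured time bin")
        _finish_stage("assign_time_bins", binning=bin_report.as_dict())
        table.to_csv(out / "occurrences.csv", index=False)
    except Exception as exc:
        _abort("assign_time_bins", exc)

    try:
        cells = bin_to_cells(table, spacing_km=config.spacing_km)
        cells.to_csv(out / "cells.csv", index=False)
        _finish_stage("bin_to_cells", n_cells=len(cells))
    except Exception as exc:
        _abort("bin_to_cells", exc)

    try:
        points = build_sar_table(
            table, spacing_km=config.spacing_km, cutoff_km=config.cutoff_km,
            min_nodes=config.min_nodes, max_nn_km=config.max_nn_km,
            quorum=config.quorum, min_region_n=config.min_region_n,
            seed=config.seed)
        points.to_csv(out / "sar_points.csv", index=False)
        _finish_stage("build_regions", n_regions=len(points))
    except Exception as exc:
        _abort("build_regions", exc)

    try:
        fits_sqs, contrasts = fit_sar_tables(points, metric="sqs")
        fits_face, _ = fit_sar_tables(points, metric="face")
        fits_sqs.to_csv(out / "fits_sqs.csv", index=False)
        fits_face.to_csv(out / "fits_face.csv", index=False)
        contrasts.to_csv(out / "contrasts.csv", index=False)
        _finish_stage("fit_sar", n_fits=len(fits_sqs), n_contrasts=len(contrasts))
    except Exception as exc:
        _abort("fit_sar", exc)

    if config.n_null_reps > 0:
        from .nulls import null_slope_distribution, summarize_null_envelope
        try:
            runs = []
            for bin_name in sorted(table["bin"].unique()):
                for group in sorted(table["group"].unique()):
                    sub = table[(table["bin"] == bin_name) & (table["group"] == group)]
                    if not len(sub):
                        continue
                    r = null_slope_distribution(
                        sub, bin_name, n_reps=config.n_null_reps,
                        seed=config.seed, spacing_km=config.spacing_km,
                        cutoff_km=config.cutoff_km, min_nodes=config.min_nodes,
                        max_nn_km=config.max_nn_km, quorum=config.quorum,
                        min_region_n=config.min_region_n)
                    r.insert(0, "group", group)
                    r.insert(0, "bin", bin_name)
                    runs.append(r)
            null_df = pd.concat(runs, ignore_index=True) if runs else pd.DataFrame()
            null_df.to_csv(out / "null_runs.csv", index=False)
            summarize_null_envelope(null_df).to_csv(out / "null_envelope.csv",
                                                    index=False)
            _finish_stage("null_model", n_null_rows=len(null_df))
        except Exception as exc:
            _abort("null_model", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
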