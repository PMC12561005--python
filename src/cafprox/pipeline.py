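"""End-to-end orchestration: simulate/load → ROIs → counts → proximity.

`run_pipeline` takes a flat configuration mapping (all keys optional; see
:data:`DEFAULT_CONFIG`), runs every analysis stage, and returns a
:class:`PipelineReport` — a pydantic model, so the JSON report has a
published schema and validates structurally. The report carries full
provenance (config snapshot, seed, package version) and no timestamps,
so identical configs produce byte-identical reports.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any, Optional

from pydantic import BaseModel

from . import __version__
from .cells import CellTable, CellType, concat_tables
from .errors import CafproxError, StageError, UndefinedRatioError
from .geometry import TissueGeometry, make_interface
from .io import read_cell_table, read_geometry, write_cell_table, write_geometry
from .proximity import (
    fraction_within,
    proximity_between,
    radial_histogram,
    stratified_proximity,
)
from .roi import Stratum, count_cells, place_rois, pooled_caf_ratio
from .simulate import SimulationConfig, simulate_cafs, simulate_reference_cells

__all__ = ["DEFAULT_CONFIG", "PipelineReport", "run_pipeline"]

DEFAULT_CONFIG: dict[str, Any] = {
    # input mode: set both paths for file input, leave None to simulate
    "cells": None,
    "geometry": None,
    # simulation
    "seed": 0,
    "frame_width": 2000.0,
    "band_thickness": 150.0,
    "waviness_amplitude": 20.0,
    "osc_density": 5.2e-4,
    "oc_linear_density": 2.13e-2,
    "caf_density": 5.93e-3,
    "clustered_fraction": 0.75,
    "displacement_scale_sigma": 27.5,
    "spindle_fraction": 0.70,
    # ROI sampling
    "n_surface": 15,
    "n_deep": 15,
    "roi_side": 100.0,
    # proximity
    "direction": "caf_to_reference",  # or "reference_to_caf"
    "inner": 50.0,
    "outer": 100.0,
    "bin_width": 10.0,
    # optional stratified comparison: list of {label, band_thickness,
    # displacement_scale_sigma} mappings, simulated with the same seed
    "strata": None,
}


class ProvenanceModel(BaseModel):
    version: str
    seed: int
    mode: str  # "simulate" or "files"
    config: dict[str, Any]


class RatioModel(BaseModel):
    caf_per_oscc: Optional[float] = None
    caf_per_oscc_exact: Optional[float] = None
    caf_per_osteoclast: Optional[float] = None
    caf_per_osteoclast_exact: Optional[float] = None


class RoiModel(BaseModel):
    n_surface: int
    n_deep: int
    side: float
    pooled_counts_surface: dict[str, int]
    pooled_counts_deep: dict[str, int]
    ratios: RatioModel


class ProfileModel(BaseModel):
    target_type: str
    bin_edges_um: list[float]
    counts: list[int]
    density_per_100um2: Optional[list[float]] = None
    n_within_outer: int


class SummaryModel(BaseModel):
    target_type: str
    fraction_within: Optional[float] = None
    inner_um: float
    outer_um: float
    n_within_inner: int
    n_within_outer: int
    defined: bool
    stratum: Optional[str] = None


class PipelineReport(BaseModel):
    provenance: ProvenanceModel
    cell_counts: dict[str, int]
    roi: RoiModel
    profiles: list[ProfileModel]
    summaries: list[SummaryModel]
    strata: Optional[list[SummaryModel]] = None

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)


def _merge_config(config: Optional[dict[str, Any]]) -> dict[str, Any]:
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise CafproxError(f"unknown config keys: {sorted(unknown)}")
        cfg.update({k: v for k, v in config.items() if v is not None})
    return cfg


def _sim_config(cfg: dict[str, Any], seed: int, **overrides: Any) -> SimulationConfig:
    base = dict(
        band_thickness=cfg["band_thickness"],
        osc_density=cfg["osc_density"],
        oc_linear_density=cfg["oc_linear_density"],
        caf_density=cfg["caf_density"],
        clustered_fraction=cfg["clustered_fraction"],
        displacement_scale_sigma=cfg["displacement_scale_sigma"],
        spindle_fraction=cfg["spindle_fraction"],
        rng_seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def _simulate_field(
    cfg: dict[str, Any], band_thickness: float, sigma: float, seed: int
) -> tuple[TissueGeometry, CellTable]:
    geom = make_interface(
        cfg["frame_width"], band_thickness, cfg["waviness_amplitude"], seed
    )
    sim = _sim_config(
        cfg, seed, band_thickness=band_thickness, displacement_scale_sigma=sigma
    )
    refs = simulate_reference_cells(geom, sim)
    cafs = simulate_cafs(geom, refs, sim)
    return geom, concat_tables([refs, cafs])


def _summary_model(s, target_type: str) -> SummaryModel:
    return SummaryModel(
        target_type=target_type,
        fraction_within=None if not s.defined else s.fraction,
        inner_um=s.inner,
        outer_um=s.outer,
        n_within_inner=s.n_within_inner,
        n_within_outer=s.n_within_outer,
        defined=s.defined,
        stratum=s.stratum,
    )


def run_pipeline(
    config: Optional[dict[str, Any]] = None,
    outdir: Optional[str | Path] = None,
) -> PipelineReport:
    """Run the full quantification and proximity pipeline.

    With ``cells``/``geometry`` paths in the config, the inputs are read
    from disk; otherwise a synthetic invasive front is simulated. When
    ``outdir`` is given, the report JSON and supporting CSV/GeoJSON files
    are written there (cells + geometry only in simulation mode).
    """
    cfg = _merge_config(config)
    seed = int(cfg["seed"])

    # -- stage: load or simulate inputs --------------------------------
    try:
        if cfg["cells"] is not None and cfg["geometry"] is not None:
            mode = "files"
            geom = read_geometry(cfg["geometry"])
            cells = read_cell_table(cfg["cells"])
        elif cfg["cells"] is not None or cfg["geometry"] is not None:
            raise CafproxError("file mode needs both 'cells' and 'geometry'")
        else:
            mode = "simulate"
            geom, cells = _simulate_field(
                cfg, cfg["band_thickness"], cfg["displacement_scale_sigma"], seed
            )
    except Exception as exc:
        raise StageError("input", exc) from exc

    # -- stage: ROI quantification --------------------------------------
    try:
        rois = place_rois(
            geom, int(cfg["n_surface"]), int(cfg["n_deep"]), cfg["roi_side"], seed
        )
        counts = count_cells(rois, cells)
        ratios = RatioModel()
        try:
            r = pooled_caf_ratio(counts, CellType.OSCC, Stratum.DEEP)
            ratios.caf_per_oscc_exact = r
            ratios.caf_per_oscc = round(r, 1)
        except UndefinedRatioError:
            pass
        try:
            r = pooled_caf_ratio(counts, CellType.OSTEOCLAST, Stratum.SURFACE)
            ratios.caf_per_osteoclast_exact = r
            ratios.caf_per_osteoclast = round(r, 1)
        except UndefinedRatioError:
            pass
        roi_model = RoiModel(
            n_surface=len(rois.by_stratum(Stratum.SURFACE)),
            n_deep=len(rois.by_stratum(Stratum.DEEP)),
            side=cfg["roi_side"],
            pooled_counts_surface=counts.pooled(Stratum.SURFACE),
            pooled_counts_deep=counts.pooled(Stratum.DEEP),
            ratios=ratios,
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("roi", exc) from exc

    # -- stage: proximity ------------------------------------------------
    try:
        caf_first = cfg["direction"] == "caf_to_reference"
        if cfg["direction"] not in ("caf_to_reference", "reference_to_caf"):
            raise CafproxError(f"unknown direction {cfg['direction']!r}")
        profiles: list[ProfileModel] = []
        summaries: list[SummaryModel] = []
        for ref_type in (CellType.OSCC, CellType.OSTEOCLAST):
            src, tgt = (
                (CellType.CAF, ref_type) if caf_first else (ref_type, CellType.CAF)
            )
            if len(cells.select(src)) == 0 or len(cells.select(tgt)) == 0:
                continue
            result = proximity_between(cells, src, tgt)
            profile = radial_histogram(
                result,
                bin_width=cfg["bin_width"],
                outer=cfg["outer"],
                density=True,
                tissue=geom,
            )
            summary = fraction_within(result, cfg["inner"], cfg["outer"])
            profiles.append(
                ProfileModel(
                    target_type=ref_type.value,
                    bin_edges_um=profile.bin_edges.tolist(),
                    counts=profile.counts.tolist(),
                    density_per_100um2=(
                        None if profile.density is None else profile.density.tolist()
                    ),
                    n_within_outer=profile.n_within_outer,
                )
            )
            summaries.append(_summary_model(summary, ref_type.value))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("proximity", exc) from exc

    # -- stage: stratification (optional, simulation only) ---------------
    strata_models: Optional[list[SummaryModel]] = None
    if cfg["strata"]:
        try:
            tables = {}
            for spec in cfg["strata"]:
                label = spec["label"]
                _, tab = _simulate_field(
                    cfg,
                    spec.get("band_thickness", cfg["band_thickness"]),
                    spec.get(
                        "displacement_scale_sigma", cfg["displacement_scale_sigma"]
                    ),
                    seed,
                )
                tables[label] = tab
            strat = stratified_proximity(tables, inner=cfg["inner"], outer=cfg["outer"])
            strata_models = [
                _summary_model(s, s.target_type)
                for by_target in strat.per_stratum.values()
                for s in by_target.values()
            ]
        except StageError:
            raise
        except Exception as exc:
            raise StageError("stratify", exc) from exc

    report = PipelineReport(
        provenance=ProvenanceModel(
            version=__version__,
            seed=seed,
            mode=mode,
            config={k: v for k, v in cfg.items() if k not in ("cells", "geometry")}
            | {"cells": str(cfg["cells"]), "geometry": str(cfg["geometry"])},
        ),
        cell_counts=cells.counts_by_type(),
        roi=roi_model,
        profiles=profiles,
        summaries=summaries,
        strata=strata_models,
    )

    if outdir is not None:
        try:
            out = Path(outdir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "report.json").write_text(report.to_json() + "\n")
            rois.to_frame().to_csv(out / "rois.csv", index=False)
            counts.per_roi.to_csv(out / "roi_counts.csv", index=False)
            if mode == "simulate":
                write_cell_table(cells, out / "cells.csv")
                write_geometry(geom, out / "geometry.geojson")
        except Exception as exc:
            raise StageError("write", exc) from exc
    return report
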