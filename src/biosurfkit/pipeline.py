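"""End-to-end orchestration of the characterization stages.

A :class:`RunManifest` (read from a YAML file or built in code) names the
stages to run, their input files and a seed registry; ``run_pipeline``
executes them in a fixed dependency order, logs per-stage input hashes to
plain text, and aggregates the stage outputs — homologue table, MIC/MBC,
CMC fit, surface-energy table — into one report bundle.  All randomness
flows from the manifest's seed registry, so re-running an unchanged
manifest reproduces the deterministic outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotate, chem, cmc, fames, io as bio, surface, susceptibility

__all__ = ["RunManifest", "run_pipeline", "PipelineError", "STAGE_ORDER"]

STAGE_ORDER = ("annotate", "fames", "mic", "cmc", "surface")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass(frozen=True)
class RunManifest:
    """Declarative description of one pipeline run."""

    stages: tuple[str, ...]
    inputs: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    options: dict[str, Any] = field(default_factory=dict)
    out_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; known: {list(STAGE_ORDER)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            stages=tuple(cfg.get("stages", [])),
            inputs={k: str(v) for k, v in (cfg.get("inputs") or {}).items()},
            seeds={k: int(v) for k, v in (cfg.get("seeds") or {}).items()},
            options=cfg.get("options") or {},
            out_dir=str(cfg.get("out_dir", "pipeline_out")),
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "stages": list(self.stages),
                "inputs": self.inputs,
                "seeds": self.seeds,
                "options": self.options,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(manifest: RunManifest, stage: str, key: str) -> Path:
    if key not in manifest.inputs:
        raise PipelineError(f"stage {stage!r}: missing required input {key!r}")
    path = Path(manifest.inputs[key])
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: input file {path} does not exist")
    return path


def run_pipeline(manifest: RunManifest) -> dict[str, Any]:
    """Execute the manifest's stages in dependency order.

    Returns the report bundle (one entry per executed stage plus the run
    metadata) and writes it, together with a plain-text log, under
    ``manifest.out_dir``.  The first failing stage aborts the run with a
    :class:`PipelineError` naming the stage.
    """
    out_dir = Path(manifest.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config_hash={manifest.config_hash()}"]
    report: dict[str, Any] = {"config_hash": manifest.config_hash(), "stages": {}}

    for stage in STAGE_ORDER:
        if stage not in manifest.stages:
            continue
        try:
            result = _STAGE_RUNNERS[stage](manifest, out_dir, log)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        report["stages"][stage] = result

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return report


def _stage_annotate(manifest: RunManifest, out_dir: Path, log: list[str]) -> dict:
    peaks_path = _require(manifest, "annotate", "peaks")
    species_path = _require(manifest, "annotate", "species")
    log.append(f"annotate: peaks={peaks_path} sha={_file_hash(peaks_path)}")
    opts = manifest.options.get("annotate", {})
    polarity = opts.get("polarity", "negative")
    tol = float(opts.get("tol_da", annotate.DEFAULT_TOLERANCE_DA))
    species = bio.read_species_config(species_path)
    spectrum = bio.read_peaks(peaks_path, polarity=polarity, level=1)
    ladders = annotate.detect_ladder(spectrum, tolerance=tol)
    homologues = annotate.assign_homologues(ladders, species, polarity, tolerance=tol)
    table = [
        {
            "carbons": c,
            "observed_mz": round(a.peak.mz, 4),
            "theoretical_mz": round(a.ion.mz, 4),
            "nominal_mz": a.ion.nominal,
            "error_da": round(a.error_da, 4),
        }
        for c, a in homologues
    ]
    df = pd.DataFrame(table)
    df.to_csv(out_dir / "homologues.tsv", sep="\t", index=False)
    return {"n_ladders": len(ladders), "homologues": table}


def _stage_fames(manifest: RunManifest, out_dir: Path, log: list[str]) -> dict:
    path = _require(manifest, "fames", "fames")
    log.append(f"fames: input={path} sha={_file_hash(path)}")
    df = pd.read_csv(path, sep="\t")
    required = ["id", "rt", "peaks"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PipelineError(f"stage 'fames': missing columns {missing}")
    spectra = []
    for _, row in df.iterrows():
        pairs = tuple(
            (float(m), float(i))
            for m, i in (p.split(":") for p in str(row["peaks"]).split(","))
        )
        spectra.append(
            fames.FameSpectrum(float(row["rt"]), pairs, identifier=str(row["id"]))
        )
    opts = manifest.options.get("fames", {})
    std_name = opts.get("standard", spectra[0].identifier)
    standard = next(s for s in spectra if s.identifier == std_name)
    increment = float(opts.get("rt_increment", 1.0))
    calls = []
    for s in spectra:
        call = fames.classify_hydroxy(s)
        calls.append(
            {
                "id": s.identifier,
                "rt": s.retention_time,
                "hydroxyl": call.hydroxyl,
                "carbons": fames.assign_chain_length(s, standard, increment=increment),
                "reason": call.reason,
            }
        )
    pd.DataFrame(calls).to_csv(out_dir / "fame_calls.tsv", sep="\t", index=False)
    doublets = fames.detect_branching_doublet(
        spectra, window=float(opts.get("window", 0.2))
    )
    return {
        "calls": calls,
        "doublets": [[a.identifier, b.identifier] for a, b in doublets],
    }


def _stage_mic(manifest: RunManifest, out_dir: Path, log: list[str]) -> dict:
    plate_path = _require(manifest, "mic", "plate")
    log.append(f"mic: plate={plate_path} sha={_file_hash(plate_path)}")
    sub_path = manifest.inputs.get("subculture")
    plate = bio.read_plate(plate_path, sub_path)
    if plate.subculture is not None:
        res = susceptibility.determine_mbc(plate)
    else:
        res = susceptibility.determine_mic(plate)
    out = {"mic": res.mic, "mbc": res.mbc, "notes": list(res.notes)}
    (out_dir / "susceptibility.json").write_text(json.dumps(out, sort_keys=True) + "\n")
    return out


def _stage_cmc(manifest: RunManifest, out_dir: Path, log: list[str]) -> dict:
    curve_path = _require(manifest, "cmc", "curve")
    log.append(f"cmc: curve={curve_path} sha={_file_hash(curve_path)}")
    points = bio.read_tension_curve(curve_path)
    results = cmc.CmcModel(points).fit()
    fit = results.fit_result
    out: dict[str, Any] = {
        "cmc_mg_per_L": fit.breakpoint,
        "slope_pre": fit.slope_pre,
        "slope_post": fit.slope_post,
        "plateau": fit.plateau,
        "rss": fit.rss,
    }
    if fit.breakpoint is not None:
        seed = manifest.seeds.get("cmc", 0)
        lo, hi = results.bootstrap_ci(seed=seed)
        out["ci95"] = [lo, hi]
    (out_dir / "cmc.json").write_text(json.dumps(out, sort_keys=True) + "\n")
    return out


def _stage_surface(manifest: RunManifest, out_dir: Path, log: list[str]) -> dict:
    angles_path = _require(manifest, "surface", "angles")
    log.append(f"surface: angles={angles_path} sha={_file_hash(angles_path)}")
    liquids = surface.DEFAULT_LIQUIDS
    if "liquids" in manifest.inputs:
        liquids = bio.read_liquids(_require(manifest, "surface", "liquids"))
    data = bio.read_angles(angles_path)
    results = surface.ContactAngleModel(data, liquids).fit()
    summary = results.summary()
    summary.to_csv(out_dir / "surface_energy.tsv", sep="\t", index=False)
    compare = results.compare()
    if len(compare):
        compare.to_csv(out_dir / "surface_compare.tsv", sep="\t", index=False)
    return {
        "surfaces": summary.to_dict(orient="records"),
        "comparisons": compare.to_dict(orient="records"),
    }


_STAGE_RUNNERS = {
    "annotate": _stage_annotate,
    "fames": _stage_fames,
    "mic": _stage_mic,
    "cmc": _stage_cmc,
    "surface": _stage_surface,
}
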