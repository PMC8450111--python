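"""Simulate -> analyze -> report pipeline with a reproducibility manifest.

A run is described by a YAML config with one section per stage; stages are
executed in dependency order (simulate, coc, gamma, metrics,
missegregation). Numeric TSVs are the canonical outputs; the manifest
records the config snapshot, seeds, file digests, and package version, so a
rerun from the same manifest reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .interference import IntervalSpec, coc_curve, coc_pairs, fit_gamma
from .metrics import missegregation_frequency, strain_summary
from .simulate import SimulationConfig, simulate_focus_dataset, simulate_tetrads

log = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "simulate_tetrads", "coc", "gamma", "metrics", "missegregation"]

__all__ = ["PipelineError", "run_pipeline", "validate_focus_table", "STAGE_ORDER"]


class PipelineError(RuntimeError):
    pass


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve(base: Path, name: str) -> Path:
    p = Path(name)
    return p if p.is_absolute() else base / p


def run_pipeline(config_path, outdir=None) -> dict:
    """Execute the stages named in *config_path*; returns the manifest."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"{config_path}: unknown stage(s) {sorted(unknown)}")
    base = Path(outdir) if outdir is not None else config_path.parent
    base.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "meicoc",
        "version": __version__,
        "config_path": str(config_path),
        "config": cfg,
        "seeds": {},
        "inputs": {},
        "outputs": {},
    }

    def note_output(stage: str, path: Path) -> None:
        manifest["outputs"][stage] = {"path": str(path), "sha256": _digest(path)}

    def note_input(stage: str, path: Path) -> None:
        if not path.exists():
            raise PipelineError(f"stage {stage}: missing input {path}")
        manifest["inputs"][stage] = {"path": str(path), "sha256": _digest(path)}

    for stage in STAGE_ORDER:
        if stage not in cfg:
            continue
        sc = dict(cfg[stage] or {})
        if stage == "simulate":
            out = _resolve(base, sc.pop("out", "foci.tsv"))
            sim = SimulationConfig(**sc)
            manifest["seeds"]["simulate"] = sim.seed
            log.info("simulate: seed=%d n_nuclei=%d", sim.seed, sim.n_nuclei)
            io.write_focus_table(simulate_focus_dataset(sim), out)
            note_output("simulate", out)
        elif stage == "simulate_tetrads":
            out = _resolve(base, sc.pop("out", "tetrads.tsv"))
            manifest["seeds"]["simulate_tetrads"] = sc.get("seed", 0)
            io.write_tetrad_table(simulate_tetrads(**sc), out)
            note_output("simulate_tetrads", out)
        elif stage == "coc":
            foci = _resolve(base, sc.get("foci", "foci.tsv"))
            note_input("coc", foci)
            out = _resolve(base, sc.get("out", "coc_curve.tsv"))
            spec = IntervalSpec(n_intervals=int(sc.get("intervals", 30)))
            pairs = coc_pairs(io.read_focus_table(foci), spec)
            n_undef = int((~pairs["defined"]).sum())
            log.info("coc: %d undefined interval pairs excluded", n_undef)
            coc_curve(pairs).to_csv(out, sep="\t", index=False, float_format="%.6g")
            note_output("coc", out)
        elif stage == "gamma":
            foci = _resolve(base, sc.get("foci", "foci.tsv"))
            note_input("gamma", foci)
            out = _resolve(base, sc.get("out", "gamma_fit.tsv"))
            seed = int(sc.get("seed", 0))
            manifest["seeds"]["gamma"] = seed
            fit = fit_gamma(
                io.read_focus_table(foci),
                normalized=bool(sc.get("normalized", True)),
                n_boot=int(sc.get("bootstrap", 1000)),
                seed=seed,
                ci_method=sc.get("ci_method", "percentile"),
            )
            pd.DataFrame(
                [
                    {
                        "shape": fit.shape,
                        "scale": fit.scale,
                        "loglik": fit.log_likelihood,
                        "n": fit.n_distances,
                        "shape_lo": fit.shape_ci[0],
                        "shape_hi": fit.shape_ci[1],
                    }
                ]
            ).to_csv(out, sep="\t", index=False, float_format="%.6g")
            note_output("gamma", out)
        elif stage == "metrics":
            foci = _resolve(base, sc.get("foci", "foci.tsv"))
            note_input("metrics", foci)
            out = _resolve(base, sc.get("out", "strain_summary.tsv"))
            strain_summary(io.read_focus_table(foci)).to_csv(
                out, sep="\t", index=False, float_format="%.6g"
            )
            note_output("metrics", out)
        elif stage == "missegregation":
            tetrads = _resolve(base, sc.get("tetrads", "tetrads.tsv"))
            note_input("missegregation", tetrads)
            out = _resolve(base, sc.get("out", "missegregation.tsv"))
            freq, n_scored, n_excluded = missegregation_frequency(
                io.read_tetrad_table(tetrads)
            )
            log.info("missegregation: %d tetrads excluded (no fluorescent spores)", n_excluded)
            pd.DataFrame(
                [{"frequency": freq, "n_scored": n_scored, "n_excluded": n_excluded}]
            ).to_csv(out, sep="\t", index=False, float_format="%.6g")
            note_output("missegregation", out)
    manifest_path = base / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def validate_focus_table(path) -> list[dict]:
    """Row-level diagnostics for a focus table; empty list means clean."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    issues: list[dict] = []
    try:
        df = pd.read_csv(path, sep="\t", dtype={"strain": str, "nucleus_id": str, "chromosome_id": str})
    except Exception as err:  # unreadable / unparseable
        raise ValueError(f"{path}: cannot parse ({err})") from err
    missing = set(io.FOCUS_COLUMNS) - set(df.columns)
    if missing:
        return [{"row": None, "issue": f"missing columns {sorted(missing)}"}]
    if df.empty:
        raise ValueError(f"{path}: no records")
    for row in df.itertuples():
        i = row.Index + 2  # 1-based file line incl. header
        if not (row.axis_length_um > 0):
            issues.append({"row": i, "issue": f"non-positive axis length {row.axis_length_um}"})
            continue
        if pd.notna(row.focus_pos_um) and not (0 <= row.focus_pos_um <= row.axis_length_um):
            issues.append(
                {
                    "row": i,
                    "issue": f"focus position {row.focus_pos_um} outside [0, {row.axis_length_um}]",
                }
            )
    keys = ["strain", "nucleus_id", "chromosome_id"]
    for (strain, nid, cid), grp in df.groupby(keys):
        if grp["axis_length_um"].nunique() > 1:
            issues.append(
                {"row": None, "issue": f"inconsistent axis length for {strain}/{nid}/{cid}"}
            )
        dup = grp["focus_pos_um"].dropna().duplicated()
        if dup.any():
            issues.append(
                {"row": None, "issue": f"duplicate focus positions for {strain}/{nid}/{cid}"}
            )
        if grp["focus_pos_um"].isna().any() and len(grp) > 1:
            issues.append(
                {
                    "row": None,
                    "issue": f"zero-focus marker mixed with focus rows for {strain}/{nid}/{cid}",
                }
            )
    return issues
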