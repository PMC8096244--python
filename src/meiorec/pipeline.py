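"""Run configuration and the simulate → call → stats pipeline driver.

A run is described by a small YAML file with the sections ``sim`` (simulator
parameters), ``caller`` (caller thresholds) and top-level ``seed``,
``n_octads``, ``out_dir`` and ``log_level``.  Unknown keys are rejected.
Every run writes a key-value metadata sidecar (parameters, seeds, package
version, input digests) next to its outputs so results remain traceable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .caller import CallerParams, call_octad, events_table
from .errors import FormatError, StageError
from .io import write_genotype_table, write_truth_table
from .simulate import SimParams, make_marker_map, simulate_octad
from .stats import LengthSample, short_tract_fraction, summarize_lengths

logger = logging.getLogger("meiorec")

_TOP_KEYS = {"sim", "caller", "seed", "n_octads", "out_dir", "log_level"}


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run."""

    sim: SimParams = field(default_factory=SimParams)
    caller: CallerParams = field(default_factory=CallerParams)
    seed: int = 0
    n_octads: int = 2
    out_dir: str = "meiorec_out"
    log_level: str = "INFO"


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise FormatError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    sim_kw = raw.get("sim", {}) or {}
    caller_kw = raw.get("caller", {}) or {}
    _check_keys(sim_kw, {f.name for f in dataclasses.fields(SimParams)}, "sim")
    _check_keys(caller_kw, {f.name for f in dataclasses.fields(CallerParams)}, "caller")
    return RunConfig(
        sim=SimParams(**sim_kw),
        caller=CallerParams(**caller_kw),
        seed=int(raw.get("seed", 0)),
        n_octads=int(raw.get("n_octads", 2)),
        out_dir=str(raw.get("out_dir", "meiorec_out")),
        log_level=str(raw.get("log_level", "INFO")),
    )


def write_metadata(path: str | Path, entries: dict) -> None:
    """Write a flat key-value metadata sidecar."""
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}\t{value}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Simulate octads, call events, summarize lengths; write all outputs.

    Deterministic for a given config and seed: octad ``k`` uses seed
    ``seed + k``.  Returns paths and the summary tables.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_events = []
    lengths: list[float] = []
    hiconf_lengths: list[float] = []
    try:
        for k in range(config.n_octads):
            sim = dataclasses.replace(config.sim, seed=config.seed + k)
            marker_map = make_marker_map(
                sim.chrom_length, sim.mean_marker_spacing, seed=sim.seed
            )
            octad, truth = simulate_octad(marker_map, sim)
            write_genotype_table(octad, out / f"octad_{k}.genotypes.tsv")
            write_truth_table(truth, out / f"octad_{k}.truth.tsv")
            tracts, events = call_octad(octad, config.caller)
            tab = events_table(events)
            tab.insert(0, "octad", k)
            all_events.append(tab)
            lengths.extend(t.length_bp for t in tracts)
            hiconf_lengths.extend(t.length_bp for t in tracts if not t.low_confidence)
    except Exception as exc:
        raise StageError(f"simulate/call stage failed: {exc}") from exc

    try:
        events_df = (
            pd.concat(all_events, ignore_index=True)
            if all_events
            else pd.DataFrame()
        )
        events_path = out / "events.tsv"
        events_df.to_csv(events_path, sep="\t", index=False)

        summary_rows = []
        for label, values in (("all", lengths), ("high_confidence", hiconf_lengths)):
            if not values:
                continue
            sample = LengthSample("simulated", np.asarray(values), label, config.n_octads)
            s = summarize_lengths(sample)
            k, n, frac = short_tract_fraction(sample, config.caller.short_cutoff_bp)
            s["frac_short"] = frac
            summary_rows.append(s)
        summary = pd.DataFrame(summary_rows)
        summary_path = out / "summary.tsv"
        summary.to_csv(summary_path, sep="\t", index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stats stage failed: {exc}") from exc

    meta = {
        "meiorec_version": __version__,
        "seed": config.seed,
        "n_octads": config.n_octads,
    }
    meta.update({f"sim.{f.name}": getattr(config.sim, f.name) for f in dataclasses.fields(SimParams)})
    meta.update(
        {f"caller.{f.name}": getattr(config.caller, f.name) for f in dataclasses.fields(CallerParams)}
    )
    write_metadata(out / "run_metadata.tsv", meta)
    return {
        "events": events_path,
        "summary": summary_path,
        "events_df": events_df,
        "summary_df": summary,
        "out_dir": out,
    }
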