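"""One-command orchestration: simulate/load -> slice -> LDA -> events -> KIE/GKA.

The pipeline is a pure dataflow over immutable artifacts.  A single
:class:`PipelineConfig` (serializable to YAML) fully determines a run:
the same config and seed reproduce byte-identical outputs.  All
randomness flows from one top-level seed, fanned out deterministically
per dataset.  The run report echoes the full config so a run can be
re-executed from the report alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import datamodel as dm
from .datamodel import (
    DatasetMeta,
    Modality,
    Solvent,
    TRDataset,
    ValidationError,
    exclude_early_delays,
    get_region,
    read_dataset,
    slice_region,
    write_matrix,
)
from .dynamics import (
    SIGNIFICANCE_THRESHOLD,
    compute_dynamical_content,
    detect_peaks,
    normalize_content,
    summarize_events,
)
from .gka import compare_with_lda, gka_fit
from .kie import compute_kie, match_events
from .lda import build_lifetime_grid, fit_lda
from .synthetic import PRESET_NAMES, simulate_preset

logger = logging.getLogger("flavidyn")

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (reported before any compute)."""


@dataclass
class PipelineConfig:
    """Validated, fully serializable description of one pipeline run."""

    presets: list[str] = field(default_factory=list)
    inputs: list[dict] = field(default_factory=list)  # path/modality/solvent/sample
    regions: list[str] = field(default_factory=lambda: ["visTA"])
    tau_min: float = 1e-13
    tau_max: float = 1e-3
    points_per_decade: int = 41
    lambdas: list[float] | None = None
    prior_scale: float = 1e-6
    peak_threshold: float = SIGNIFICANCE_THRESHOLD
    noise_sigma: float = 0.01
    early_cutoff: float = dm.EARLY_DELAY_CUTOFF
    n_channels: int = 64
    run_gka: bool = False
    gka_components: int = 3
    seed: int = 0
    outdir: str = "flavidyn_run"

    def validate(self) -> None:
        if not self.presets and not self.inputs:
            raise ConfigError("config needs at least one preset or input file")
        for name in self.presets:
            if name not in PRESET_NAMES:
                raise ConfigError(
                    f"unknown preset {name!r}; valid: {', '.join(PRESET_NAMES)}"
                )
        for name in self.regions:
            if name not in dm.REGION_BOUNDS:
                raise ConfigError(
                    f"unknown region {name!r}; valid: {sorted(dm.REGION_BOUNDS)}"
                )
        for entry in self.inputs:
            if "path" not in entry:
                raise ConfigError("each input entry needs a 'path'")
        if not 0 < self.tau_min < self.tau_max:
            raise ConfigError("need 0 < tau_min < tau_max")
        if self.lambdas is not None and (
            len(self.lambdas) == 0 or any(l <= 0 for l in self.lambdas)
        ):
            raise ConfigError("lambdas must be a non-empty list of positives")
        if not 0 <= self.peak_threshold < 1:
            raise ConfigError("peak_threshold must lie in [0, 1)")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_inputs(config: PipelineConfig) -> list[tuple[str, TRDataset]]:
    datasets: list[tuple[str, TRDataset]] = []
    for i, name in enumerate(config.presets):
        ds, _ = simulate_preset(
            name,
            seed=config.seed + i,
            n_channels=config.n_channels,
            noise_sigma=config.noise_sigma,
        )
        datasets.append((name, ds))
    for j, entry in enumerate(config.inputs):
        meta = DatasetMeta(
            Modality(entry.get("modality", "TA")),
            Solvent(entry.get("solvent", "H2O")),
            entry.get("sample", f"input{j}"),
        )
        ds = read_dataset(entry["path"], meta)
        datasets.append((Path(entry["path"]).stem, ds))
    return datasets


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the machine-readable report.

    Any stage error marks the stage failed in the report and skips the
    later stages; the report is still written.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    report: dict = {
        "config": asdict(config),
        "stages": [],
        "datasets": {},
        "kie": {},
        "gka": {},
    }
    grid = build_lifetime_grid(config.tau_min, config.tau_max, config.points_per_decade)
    tables: dict[tuple[str, str, str], object] = {}  # (sample, solvent, region)

    def stage(name: str, status: str, **extra) -> None:
        report["stages"].append({"name": name, "status": status, **extra})

    try:
        datasets = _load_inputs(config)
        stage("load", "ok", n_datasets=len(datasets))
    except Exception as exc:  # noqa: BLE001 - report and stop
        stage("load", "failed", error=str(exc))
        _write_report(report, outdir)
        return report

    for name, ds in datasets:
        dsdir = outdir / name
        dsdir.mkdir(exist_ok=True)
        entry: dict = {"meta": {
            "modality": ds.meta.modality.value,
            "solvent": ds.meta.solvent.value,
            "sample": ds.meta.sample,
        }, "regions": {}}
        report["datasets"][name] = entry
        try:
            write_matrix(ds, dsdir / "input.tsv")
            ds_cut = exclude_early_delays(ds, config.early_cutoff)
        except Exception as exc:
            stage(f"prepare:{name}", "failed", error=str(exc))
            continue

        for region_name in config.regions:
            region = get_region(region_name, ds_cut.axis) if region_name == "raman_low_full" else get_region(region_name)
            if region.kind != ds_cut.axis.kind:
                entry["regions"][region_name] = {"status": "skipped_incompatible"}
                continue
            try:
                sliced = slice_region(ds_cut, region_name)
                amap, path = fit_lda(
                    sliced,
                    grid=grid,
                    lambdas=config.lambdas,
                    prior_scale=config.prior_scale,
                    seed=config.seed,
                )
                dc = normalize_content(compute_dynamical_content(amap))
                peaks = detect_peaks(dc, config.peak_threshold)
                table = summarize_events(
                    peaks,
                    sample=ds.meta.sample,
                    solvent=ds.meta.solvent.value,
                    region=region_name,
                )
                write_matrix(amap, dsdir / f"amplitudes_{region_name}.tsv")
                write_matrix(dc, dsdir / f"dynamical_content_{region_name}.tsv")
                table.to_frame().to_csv(
                    dsdir / f"events_{region_name}.tsv", sep="\t", index=False,
                    float_format="%.9g",
                )
                tables[(ds.meta.sample, ds.meta.solvent.value, region_name)] = (
                    table,
                    sliced,
                )
                entry["regions"][region_name] = {
                    "status": "ok",
                    "lambda_star": amap.lambda_used,
                    "n_channels_converged": int(np.sum(amap.converged)),
                    "events": [
                        {
                            "label": e.label,
                            "center_tau_s": e.center_tau,
                            "relative_area": e.relative_area,
                        }
                        for e in table.events
                    ],
                }
                stage(f"lda:{name}:{region_name}", "ok")
            except Exception as exc:
                entry["regions"][region_name] = {"status": "failed", "error": str(exc)}
                stage(f"lda:{name}:{region_name}", "failed", error=str(exc))

    # --- KIE: pair H2O/D2O tables of the same sample and region ------------
    samples = {(s, r) for (s, sol, r) in tables}
    for sample, region_name in sorted(samples):
        h = tables.get((sample, "H2O", region_name))
        d = tables.get((sample, "D2O", region_name))
        if h is None or d is None:
            continue
        key = f"{sample}:{region_name}"
        try:
            pairs, un_h, un_d = match_events(h[0], d[0])
            result = compute_kie(pairs, un_h, un_d)
            result.to_frame().to_csv(
                outdir / f"kie_{sample}_{region_name}.tsv", sep="\t", index=False,
                float_format="%.9g",
            )
            report["kie"][key] = [
                {"label": p.label, "tau_h_s": p.tau_h, "tau_d_s": p.tau_d,
                 "kie": k, "class": c}
                for p, k, c in zip(result.pairs, result.kie, result.classification)
            ]
            stage(f"kie:{key}", "ok")
        except Exception as exc:
            stage(f"kie:{key}", "failed", error=str(exc))

    # --- optional GKA on every analyzed dataset/region ----------------------
    if config.run_gka:
        for (sample, solvent, region_name), (table, sliced) in sorted(tables.items()):
            key = f"{sample}:{solvent}:{region_name}"
            try:
                init = [e.center_tau for e in table.events][: config.gka_components]
                while len(init) < config.gka_components:
                    init.append((init[-1] if init else 1e-9) * 30.0)
                eads = gka_fit(sliced, config.gka_components, init_lifetimes=init)
                gka_entry = {
                    "lifetimes_s": [float(t) for t in eads.lifetimes],
                    "chi2": eads.fit_chi2,
                    "reported_components": eads.reported_components,
                }
                if table.n_events:
                    disc = compare_with_lda(eads, table)
                    gka_entry["max_log10_discrepancy_vs_lda"] = float(disc.max())
                report["gka"][key] = gka_entry
                stage(f"gka:{key}", "ok")
            except Exception as exc:
                stage(f"gka:{key}", "failed", error=str(exc))

    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
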