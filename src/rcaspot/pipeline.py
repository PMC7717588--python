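"""End-to-end run orchestration with plain-file handoff and a manifest.

Stages: simulate (optional) → register → segment-expand → count →
annotate → analyze.  Every stage reads and writes ordinary TIFF/CSV/YAML
files so each is independently rerunnable; the manifest records the
package version, a hash of the configuration, per-stage timings and the
artifact list.  Identical config + seed reproduces identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import yaml

from . import __version__
from .annotate import MarkerPanel, ThresholdRule, annotate_by_panel, call_positivity
from .io import read_label_mask, read_stack
from .panel import GenePanel
from .registration import register_stack
from .segmentation import NucleusSet, expand_nuclei, filter_by_size
from .simulate import CellType, SimConfig, simulate_field, write_outputs
from .spots import assign_dots_to_cells, detect_all
from .stats import linkage_table, log_transform, ward_cluster


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run parameters.  Defaults mirror the published protocol:
    2-µm expansion, 2-SD size filter, 10%-of-max positivity with cap 3,
    0.1–2.0 µm² dot gates."""

    out_dir: str
    seed: int = 0
    # inputs (ignored when `simulate` block present)
    cycle_tiffs: list[str] = field(default_factory=list)
    nuclei_mask: str | None = None
    panel_csv: str | None = None
    pixel_size_um: float = 0.325
    # simulation block
    simulate: dict | None = None
    # stage parameters
    expansion_um: float = 2.0
    size_filter_k_sd: float = 2.0
    reference_cycle: int = 0
    max_shift_px: int = 20
    peak_threshold: float = 800.0
    min_area_um2: float = 0.1
    max_area_um2: float = 2.0
    threshold_fraction: float = 0.10
    threshold_cap: float = 3.0
    marker_panel_yaml: str | None = None
    n_clusters: int | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            cfg = cls(**raw)
        except TypeError as e:
            raise ConfigError(f"invalid run config: {e}") from e
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            missing = [
                name
                for name, val in [
                    ("cycle_tiffs", self.cycle_tiffs),
                    ("nuclei_mask", self.nuclei_mask),
                    ("panel_csv", self.panel_csv),
                ]
                if not val
            ]
            if missing:
                raise ConfigError(
                    f"without a 'simulate' block the config must set {missing}"
                )
        if self.expansion_um < 0 or self.max_shift_px < 0:
            raise ConfigError("expansion_um and max_shift_px must be >= 0")
        if self.peak_threshold <= 0:
            raise ConfigError("peak_threshold must be positive")
        # fail before any computation if the marker panel asks for unknown genes
        if self.marker_panel_yaml:
            panel_genes = self._panel().genes
            marker_panel = MarkerPanel.from_yaml(self.marker_panel_yaml)
            try:
                marker_panel.validate_against(panel_genes)
            except ValueError as e:
                raise ConfigError(str(e)) from e

    def _panel(self) -> GenePanel:
        if self.simulate is not None:
            return _sim_config(self).panel
        return GenePanel.from_csv(self.panel_csv)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sim_config(cfg: RunConfig) -> SimConfig:
    spec = dict(cfg.simulate or {})
    types = [CellType(**t) for t in spec.pop("cell_types", [])]
    panel = GenePanel(
        {g: tuple(slot) for g, slot in spec.pop("panel", {}).items()}
    )
    spec.setdefault("seed", cfg.seed)
    spec.setdefault("pixel_size_um", cfg.pixel_size_um)
    if "field_size_px" in spec:
        spec["field_size_px"] = tuple(spec["field_size_px"])
    if "cycle_shifts_px" in spec:
        spec["cycle_shifts_px"] = [tuple(s) for s in spec["cycle_shifts_px"]]
    if "nucleus_radius_um" in spec:
        spec["nucleus_radius_um"] = tuple(spec["nucleus_radius_um"])
    return SimConfig(cell_types=types, panel=panel, **spec)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the manifest (also written
    to ``manifest.json`` in the output directory)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }
    out = config.out_dir

    def _stage(name):
        t0 = time.perf_counter()

        def done(*files):
            manifest["stages"][name] = round(time.perf_counter() - t0, 3)
            manifest["outputs"].extend(files)

        return done

    try:
        if config.simulate is not None:
            done = _stage("simulate")
            sim_cfg = _sim_config(config)
            truth, stack = simulate_field(sim_cfg)
            sim_dir = os.path.join(out, "sim")
            write_outputs(sim_cfg, truth, stack, sim_dir)
            panel = sim_cfg.panel
            nuclei = NucleusSet(truth.nuclei.labels, sim_cfg.pixel_size_um)
            done("sim/")
        else:
            done = _stage("load")
            stack = read_stack(config.cycle_tiffs, config.pixel_size_um)
            panel = GenePanel.from_csv(config.panel_csv)
            nuclei = NucleusSet(
                read_label_mask(config.nuclei_mask), config.pixel_size_um
            )
            done()

        done = _stage("register")
        aligned, offsets = register_stack(
            stack, config.reference_cycle, config.max_shift_px
        )
        offsets.to_csv(os.path.join(out, "offsets.csv"))
        done("offsets.csv")

        done = _stage("segment")
        cells = expand_nuclei(nuclei, config.expansion_um)
        cells = filter_by_size(cells, config.size_filter_k_sd)
        cells.write(
            os.path.join(out, "cellmask.tif"), os.path.join(out, "cells_table.csv")
        )
        done("cellmask.tif", "cells_table.csv")

        done = _stage("count")
        dots = detect_all(
            aligned,
            panel,
            config.peak_threshold,
            min_area_um2=config.min_area_um2,
            max_area_um2=config.max_area_um2,
        )
        dots, counts = assign_dots_to_cells(dots, cells, genes=panel.genes)
        dots.to_csv(os.path.join(out, "dots_detected.csv"), index=False)
        counts.write(os.path.join(out, "counts.csv"))
        done("dots_detected.csv", "counts.csv")

        done = _stage("annotate")
        rule = ThresholdRule(config.threshold_fraction, config.threshold_cap)
        kept_counts = counts.counts
        if counts.kept is not None:
            kept_counts = counts.counts.loc[counts.kept.reindex(counts.counts.index,
                                                                fill_value=True)]
        positivity = call_positivity(kept_counts, rule)
        positivity.to_csv(os.path.join(out, "positivity.csv"))
        files = ["positivity.csv"]
        if config.marker_panel_yaml:
            marker_panel = MarkerPanel.from_yaml(config.marker_panel_yaml)
            labels = annotate_by_panel(positivity, kept_counts, marker_panel)
            labels.to_csv(os.path.join(out, "labels.csv"))
            files.append("labels.csv")
        done(*files)

        done = _stage("analyze")
        expr = log_transform(kept_counts)
        expr.to_csv(os.path.join(out, "expression_log2.csv"))
        files = ["expression_log2.csv"]
        if config.n_clusters and len(expr) >= max(2, config.n_clusters):
            Z, cluster_ids = ward_cluster(expr, n_clusters=config.n_clusters)
            linkage_table(Z).to_csv(os.path.join(out, "linkage.csv"), index=False)
            cluster_ids.to_csv(os.path.join(out, "clusters.csv"))
            files += ["linkage.csv", "clusters.csv"]
        done(*files)
    except Exception as e:
        manifest["failed"] = repr(e)
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
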