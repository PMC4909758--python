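"""End-to-end pipeline: inputs -> selection -> direct matrix -> tables -> maps.

All randomness funnels through two named seeds (phantom generation and track
subsampling), both recorded in ``report.json`` along with the track counts at
every stage (read, selected, subsampled, segments cut) so a run can be
audited the way the source analysis reports its own bookkeeping
(416,832 selected tracks, 9000 subsampled, 14,542 segments).

CSV outputs print percentages to one decimal (the precision of the source
tables) with '.' decimal separator; full-precision values go to a parallel
``tables.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .direct_connectivity import direct_matrix
from .errors import ConfigError
from .phantom import PhantomSpec, make_phantom, paper_like_spec
from .seed_connectivity import (
    apply_inclusion_threshold,
    seed_target_table,
    split_structure,
    structure_volume,
    voxel_projection_map,
)
from .streamline_io import LabelVolume, StructureSet, Tractogram, read_label_volume, read_tck
from .track_selection import select_seed_tracks

__all__ = ["PipelineConfig", "run_pipeline", "write_direct_csv", "write_table2_csv"]

log = logging.getLogger(__name__)

# acquisition/tracking parameters of the source data, recorded as provenance
# only — nothing in this package executes them
SOURCE_PROVENANCE = {
    "b_value_s_per_mm2": 2800,
    "lmax": 8,
    "step_mm": 0.05,
    "min_curvature_radius_mm": 0.1,
    "fod_cutoff": 0.3,
    "fod_cutoff_init": 0.01,
    "voxel_mm": 0.5,
}


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one input source: either the three real-input paths (``tck``,
    ``labels``, ``structures``) or a phantom (spec path / PhantomSpec /
    ``phantom_preset``).
    """

    tck: str | None = None
    labels: str | None = None
    structures: str | None = None
    phantom_spec: str | PhantomSpec | None = None
    phantom_preset: str | None = None
    phantom_n_tracks: int = 600
    phantom_seed: int = 0
    subsample_n: int | None = None
    subsample_seed: int = 0
    threshold: float = 1.0
    voxmaps: list[tuple[str, str]] = field(default_factory=list)
    split: list[str] = field(default_factory=list)
    out_dir: str = "bgconnect_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        real = all(x is not None for x in (self.tck, self.labels, self.structures))
        some_real = any(x is not None for x in (self.tck, self.labels, self.structures))
        phantom = self.phantom_spec is not None or self.phantom_preset is not None
        if some_real and phantom:
            raise ConfigError("config mixes real inputs with a phantom spec")
        if not (real or phantom):
            raise ConfigError("config needs either tck+labels+structures or a phantom")
        if some_real and not real:
            raise ConfigError("real inputs need all of tck, labels and structures")
        if not 0.0 <= self.threshold <= 100.0:
            raise ConfigError("threshold must be in [0, 100]")
        if self.subsample_n is not None and self.subsample_n < 0:
            raise ConfigError("subsample_n must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        voxmaps = [tuple(v) for v in raw.pop("voxmaps", [])]
        cfg = cls(**{k: v for k, v in raw.items() if k != "voxmaps"}, voxmaps=voxmaps)
        return cfg


def _fmt_pct(x: float) -> str:
    return "" if pd.isna(x) else f"{x:.1f}"


def write_direct_csv(counts: pd.DataFrame, percent: pd.DataFrame,
                     counts_path: Path, percent_path: Path) -> None:
    counts.to_csv(counts_path)
    # percent table mirrors the source layout: diagonal marked 'x',
    # one-decimal percentages, plus the Total row
    out = percent.copy().astype(object)
    for i, n in enumerate(out.index):
        for j, m in enumerate(out.columns):
            out.iloc[i, j] = "x" if n == m else f"{percent.iloc[i, j]:.1f}"
    totals = percent.sum(axis=0)
    out.loc["Total"] = [f"{t:.0f}" for t in totals]
    out.to_csv(percent_path)


def write_table2_csv(percent: pd.DataFrame, path: Path) -> None:
    percent.map(_fmt_pct).to_csv(path)


def _load_inputs(config: PipelineConfig):
    if config.phantom_preset is not None:
        if config.phantom_preset != "paper-like":
            raise ConfigError(f"unknown phantom preset {config.phantom_preset!r}")
        spec = paper_like_spec(n_tracks=config.phantom_n_tracks, rng_seed=config.phantom_seed)
        res = make_phantom(spec)
        return res.tractogram, res.volume, res.structures, res
    if config.phantom_spec is not None:
        spec = (
            config.phantom_spec
            if isinstance(config.phantom_spec, PhantomSpec)
            else PhantomSpec.from_yaml(config.phantom_spec)
        )
        res = make_phantom(spec)
        return res.tractogram, res.volume, res.structures, res
    tractogram = read_tck(config.tck)
    volume = read_label_volume(config.labels)
    structures = StructureSet.from_yaml(config.structures)
    return tractogram, volume, structures, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run select -> (subsample) -> cut/count/normalise -> tables -> maps.

    Writes ``direct_counts.csv``, ``direct_percent.csv``, ``table2.csv``,
    ``volumes.csv``, requested voxel maps, ``tables.json``, ``run.log`` and
    ``report.json`` into ``config.out_dir`` and returns the report dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("bgconnect")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    stage = "load"
    try:
        tractogram, volume, structures, phantom_res = _load_inputs(config)
        report: dict = {
            "stages": {"tracks_read": tractogram.count},
            "seeds": list(structures.seeds),
            "provenance": dict(SOURCE_PROVENANCE),
            "phantom_seed": config.phantom_seed if phantom_res is not None else None,
            "subsample_seed": config.subsample_seed,
            "threshold_percent": config.threshold,
        }

        stage = "split"
        for name in config.split:
            # the split structure's name becomes a composite of its two
            # halves, so it keeps its union semantics everywhere (including
            # as a core nucleus in the direct analysis)
            if name in structures.composites:
                raise ConfigError(f"cannot split composite structure {name!r}")
            lbl = structures.label(name)
            volume, la, lp = split_structure(volume, lbl)
            labels = dict(structures.as_dict()["labels"])
            del labels[name]
            labels[f"{name}_anterior"] = la
            labels[f"{name}_posterior"] = lp
            composites = {k: list(v) for k, v in structures.composites.items()}
            for comp in composites:
                if name in composites[comp]:
                    composites[comp] = [m for m in composites[comp] if m != name] + [
                        f"{name}_anterior", f"{name}_posterior",
                    ]
            composites[name] = [f"{name}_anterior", f"{name}_posterior"]
            core = tuple(structures.core_five)
            structures = StructureSet(
                labels, core_five=core, seeds=structures.seeds, composites=composites,
            )

        stage = "select"
        selected_ids, sequences = select_seed_tracks(tractogram, volume, structures)
        report["stages"]["tracks_selected"] = len(selected_ids)
        log.info("selected %d of %d tracks", len(selected_ids), tractogram.count)

        stage = "direct"
        matrix, segments = direct_matrix(
            sequences,
            structures,
            subsample_n=config.subsample_n,
            rng_seed=config.subsample_seed,
        )
        n_sub = (
            min(config.subsample_n, len(sequences))
            if config.subsample_n is not None
            else len(sequences)
        )
        report["stages"]["tracks_subsampled"] = n_sub
        report["stages"]["direct_segments"] = len(segments)
        write_direct_csv(
            matrix.counts, matrix.percent,
            out / "direct_counts.csv", out / "direct_percent.csv",
        )

        stage = "table"
        table = seed_target_table(sequences, structures)
        table = apply_inclusion_threshold(table, config.threshold)
        write_table2_csv(table.percent, out / "table2.csv")
        report["stages"]["table_targets_kept"] = int(len(table.percent.index))
        report["stages"]["table_targets_dropped"] = list(table.dropped_targets or [])

        stage = "volumes"
        vols = {
            name: structure_volume(volume, structures.label(name))
            for name in structures.names
        }
        pd.Series(vols, name="volume_mm3").rename_axis("structure").to_csv(
            out / "volumes.csv"
        )

        stage = "voxmap"
        selected_set = set(selected_ids)
        selected_streamlines = [s for s in tractogram if s.id in selected_set]
        for struct_name, target_name in config.voxmaps:
            vm = voxel_projection_map(
                selected_streamlines, volume, structures, struct_name, target_name
            )
            vm.to_nifti(out / f"voxmap_{struct_name}_to_{target_name}.nii.gz")

        stage = "report"
        full = {
            "direct_counts": matrix.counts.to_dict(),
            "direct_percent": matrix.percent.to_dict(),
            "table2_percent": json.loads(table.percent.to_json()),
            "seed_totals": table.totals.to_dict(),
            "volumes_mm3": vols,
        }
        (out / "tables.json").write_text(json.dumps(full, indent=1, sort_keys=True))
        if phantom_res is not None:
            report["ground_truth_matches"] = bool(
                matrix.counts.equals(phantom_res.ground_truth.direct_counts)
            ) if config.subsample_n is None else None
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        return report
    except Exception as e:
        (out / "FAILED").write_text(f"stage={stage}: {e}\n")
        raise type(e)(f"[stage {stage}] {e}") from e
    finally:
        root.removeHandler(handler)
        handler.close()
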