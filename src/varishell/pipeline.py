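"""End-to-end orchestration: scenes -> typing/QC -> shell densities ->
baskets + association -> NB mixed model -> report.

The report always carries the three cell-type contrasts per marker:
ChAT+/NOS- vs ChAT-/NOS+, ChAT+/NOS- vs ChAT+/NOS+, ChAT-/NOS+ vs
ChAT+/NOS+.  A single seed in the config fans out to per-stage seeds by
fixed offsets, so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as vio
from .baskets import BasketConfig, basket_summary, chisq_association, detect_baskets
from .celltypes import CellType, TypedCell, apply_exclusions, classify_cells, type_proportions
from .density_model import (
    ModelSettings,
    build_model_input,
    density_ratio,
    fit_nb_glmm,
    mean_density,
    morphometric_anova,
)
from .geometry import ShellConfig, attribute_spots, compute_densities
from .scene import CellLabelRecord, GanglionScene, MARKERS
from .synthetic import GeneratorParams, generate

__version__ = "0.1.0"

logger = logging.getLogger("varishell")

#: The three reported cell-type contrasts (numerator, denominator).
CONTRASTS = (
    (CellType.CHAT_ONLY.value, CellType.NOS_ONLY.value),
    (CellType.CHAT_ONLY.value, CellType.CHAT_NOS.value),
    (CellType.NOS_ONLY.value, CellType.CHAT_NOS.value),
)


@dataclass
class RunConfig:
    manifest: str | None = None  # scene manifest path (or pass scenes in-memory)
    shell: ShellConfig = field(default_factory=ShellConfig)
    baskets: BasketConfig = field(default_factory=BasketConfig)
    border_margin: float = 0.5
    chat_threshold: float = 100.0
    nos_threshold: float = 100.0
    model: ModelSettings = field(default_factory=ModelSettings)
    seed: int = 0
    out_dir: str | None = None
    fit_model: bool = True


@dataclass
class RunReport:
    config: dict
    seed: int
    version: str
    n_cells_reconstructed: int
    n_cells_excluded: int
    n_cells_analysed: int
    exclusion_reasons: dict
    type_proportions: dict
    density_records: list
    basket_calls: list
    basket_tables: dict
    chisq: dict
    mean_densities: list
    density_ratios: list
    morphometrics: dict
    diagnostics: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _stage(name, t0, **counts):
    logger.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, counts)


def run(
    config: RunConfig,
    scenes: list[GanglionScene] | None = None,
    labels: dict[str, list[CellLabelRecord]] | None = None,
) -> RunReport:
    """Run the full analysis and return the report.

    Scenes and labels may be passed in-memory (e.g. straight from the
    synthetic generator); otherwise they are read from ``config.manifest``.
    """
    t0 = time.time()
    if scenes is None:
        if config.manifest is None:
            raise ValueError("run requires either in-memory scenes or a manifest path")
        root = Path(config.manifest).parent
        scenes, labels = [], {}
        for entry in vio.read_manifest(config.manifest):
            scene, scene_labels = vio.read_scene(entry, root)
            scenes.append(scene)
            labels[f"{scene.subject_id}_{scene.ganglion_id}"] = scene_labels
    labels = labels or {}
    _stage("load", t0, scenes=len(scenes))

    # typing + exclusions, densities, baskets per scene
    all_typed: list[TypedCell] = []
    all_records = []
    all_calls = []
    ganglion_of: dict[str, tuple[str, str]] = {}
    for scene in scenes:
        key = f"{scene.subject_id}_{scene.ganglion_id}"
        scene_labels = labels.get(key)
        if not scene_labels:
            raise ValueError(f"scene {key}: no label records")
        typed = classify_cells(
            scene_labels,
            chat_threshold=config.chat_threshold,
            nos_threshold=config.nos_threshold,
        )
        typed = apply_exclusions(typed, scene, border_margin=config.border_margin)
        records = compute_densities(scene, typed, config.shell)
        attributed = {
            m: attribute_spots(scene.cells, scene.varicosities[m], config.shell)
            for m in sorted(scene.varicosities)
        }
        calls = detect_baskets(typed, scene, attributed, config.baskets)
        all_typed.extend(typed)
        all_records.extend(records)
        all_calls.extend(calls)
        for c in typed:
            ganglion_of[c.cell_id] = (scene.subject_id, scene.ganglion_id)
    n_total = len(all_typed)
    n_included = sum(tc.included for tc in all_typed)
    if n_included == 0:
        raise RuntimeError("no cells for analysis: every cell was excluded")
    reasons: dict[str, int] = {}
    for tc in all_typed:
        if not tc.included:
            reasons[tc.exclusion_reason or "unspecified"] = (
                reasons.get(tc.exclusion_reason or "unspecified", 0) + 1
            )
    _stage("quantify", t0, cells=n_total, included=n_included, records=len(all_records))

    props = type_proportions(all_typed)

    basket_tables = {}
    chisq = {}
    for marker in MARKERS:
        table, pct = basket_summary(all_calls, all_typed, marker)
        basket_tables[marker] = {
            "counts": table.counts.tolist(),
            "row_labels": table.row_labels,
            "col_labels": table.col_labels,
            "basket_pct_by_type": pct,
        }
        try:
            stat, dof, p = chisq_association(table)
            chisq[marker] = {"chi2": stat, "df": dof, "p": p}
        except ValueError as err:
            chisq[marker] = {"error": str(err)}
    _stage("baskets", t0, calls=len(all_calls))

    morph = {}
    for measure in ("surface_area", "volume"):
        try:
            res = morphometric_anova(
                all_typed, measure=measure, unit_of_analysis="ganglion", groups=ganglion_of
            )
            morph[measure] = dataclasses.asdict(res)
        except ValueError as err:
            morph[measure] = {"error": str(err)}

    mean_dens, ratios, diagnostics = [], [], {}
    if config.fit_model:
        rows = build_model_input(all_records)
        posterior = fit_nb_glmm(rows, config.model, seed=config.seed + 1)
        for ctype, marker in posterior.cells:
            md = mean_density(posterior, ctype, marker)
            md.pop("draws")
            mean_dens.append(md)
        for marker in MARKERS:
            for a, b in CONTRASTS:
                ratios.append(dataclasses.asdict(density_ratio(posterior, marker, a, b)))
        diagnostics = {
            "max_rhat": posterior.max_rhat,
            "divergences": posterior.divergences,
            "accept_rate": posterior.accept_rate,
            "n_rows": posterior.n_rows,
            "chains": config.model.chains,
            "warmup": config.model.warmup,
            "draws": config.model.draws,
        }
        _stage("model", t0, rows=len(rows), max_rhat=diagnostics["max_rhat"])

    report = RunReport(
        config=_config_dict(config),
        seed=config.seed,
        version=__version__,
        n_cells_reconstructed=n_total,
        n_cells_excluded=n_total - n_included,
        n_cells_analysed=n_included,
        exclusion_reasons=reasons,
        type_proportions=props,
        density_records=[dataclasses.asdict(r) for r in all_records],
        basket_calls=[dataclasses.asdict(c) for c in all_calls],
        basket_tables=basket_tables,
        chisq=chisq,
        mean_densities=mean_dens,
        density_ratios=ratios,
        morphometrics=morph,
        diagnostics=diagnostics,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vio.write_density_table(all_records, out / "densities.csv", overwrite=True)
        report.to_json(out / "report.json")
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def simulate(
    params: GeneratorParams = GeneratorParams(),
    out_dir: str | None = None,
    seed: int = 0,
):
    """Generate synthetic scenes; optionally write them plus a manifest and
    ground-truth JSON under ``out_dir``.  Returns (scenes, labels, truth)."""
    scenes, labels, truth = generate(params, seed=seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = [
            vio.write_scene(s, out, labels=labels[f"{s.subject_id}_{s.ganglion_id}"], overwrite=True)
            for s in scenes
        ]
        vio.write_manifest(entries, out, overwrite=True)
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth.to_dict(), fh, indent=2, default=_jsonable)
    return scenes, labels, truth
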