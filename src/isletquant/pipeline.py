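"""End-to-end orchestration of the islet quantification pipeline.

One field flows through: islet-region segmentation of the probability map
→ masking of the nuclear channel → nucleus detection → seed painting →
guide construction → seeded propagation of cell boundaries → per-cell
features → α/β classification → per-cell IGFBP7 colocalization.  A run
processes a set of fields (synthetic or from disk), pools the cell tables,
and computes the group summary with its Mann-Whitney comparisons.

Everything downstream of the master seed is deterministic: per-field seeds
are derived through a numpy SeedSequence, recorded in the manifest, and
sufficient to regenerate every output byte for byte (timings excepted).
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iqio
from .gridsearch import (
    CandidateScore,
    GridSpec,
    expand_grid,
    mask_similarity,
    nuclei_agreement,
    ranked,
    scores_to_frame,
    select_optimum,
)
from .imops import rescale_full_range
from .quantify import cell_features, classify_cells, per_cell_moc, summarize_by_donor, summarize_groups
from .segment import (
    IsletParams,
    NucleiParams,
    NucleusSet,
    PropagationParams,
    detect_nuclei,
    make_guide,
    mask_channel,
    paint_labels,
    propagate_cells,
    segment_islet,
)
from .synthgen import GeometryParams, IntensityModel, generate_cohort, render_probability_map

__version__ = "0.1.0"


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort layout and emulated probability-map imperfections."""

    n_nd: int = 6
    n_t2d: int = 3
    fields_per_donor: int = 1
    geometry: GeometryParams = field(default_factory=GeometryParams)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    probmap_blur_sigma_px: float = 5.0
    probmap_noise_sd: float = 8.0


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one run; YAML-round-trippable."""

    mode: str = "synthetic"  # "synthetic" | "files"
    output_dir: str = "isletquant_out"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    inputs: tuple = ()  # file mode: tuples/dicts with image, probmap, donor_id, group
    islet: IsletParams = field(default_factory=IsletParams)
    nuclei: NucleiParams = field(default_factory=NucleiParams)
    propagation: PropagationParams = field(default_factory=PropagationParams)
    classification_ratio: float = 1.5
    exclude_border_cells: bool = False
    per_image_rescale: bool = False
    donor_aggregation: bool = False
    write_images: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "synthetic" in kw and isinstance(kw["synthetic"], dict):
            syn = dict(kw["synthetic"])
            if "geometry" in syn and isinstance(syn["geometry"], dict):
                geo = dict(syn["geometry"])
                if "field_shape" in geo:
                    geo["field_shape"] = tuple(geo["field_shape"])
                syn["geometry"] = GeometryParams(**geo)
            if "intensity" in syn and isinstance(syn["intensity"], dict):
                syn["intensity"] = IntensityModel(**syn["intensity"])
            kw["synthetic"] = SyntheticConfig(**syn)
        for name, typ in (("islet", IsletParams), ("nuclei", NucleiParams),
                          ("propagation", PropagationParams)):
            if name in kw and isinstance(kw[name], dict):
                kw[name] = typ(**kw[name])
        if "inputs" in kw:
            kw["inputs"] = tuple(kw["inputs"])
        return cls(**kw)

    def echo(self) -> dict:
        d = asdict(self)
        # dict-valued IntensityModel fields carry tuple keys; stringify for JSON
        inten = d["synthetic"]["intensity"]
        for key in ("class_levels", "igfbp7_group_multiplier"):
            inten[key] = {"/".join(k): v for k, v in inten[key].items()}
        return d


@dataclass
class FieldResult:
    """All per-field artifacts produced by :func:`run_field`."""

    islet_mask: np.ndarray
    nuclei: NucleusSet
    seed_labels: np.ndarray
    cell_labels: np.ndarray
    table: pd.DataFrame


@dataclass
class RunManifest:
    """Audit record of one run: config echo, seeds, timings, outputs."""

    config: dict
    version: str
    seed_provenance: dict
    stage_timings_s: dict
    outputs: list
    warnings: list

    def to_dict(self) -> dict:
        return asdict(self)


def run_field(
    image: dict,
    prob_map: np.ndarray,
    donor_id: str = "donor0",
    group: str = "ND",
    islet: IsletParams = IsletParams(),
    nuclei_params: NucleiParams = NucleiParams(),
    propagation: PropagationParams = PropagationParams(),
    classification_ratio: float = 1.5,
    exclude_border_cells: bool = False,
) -> FieldResult:
    """Run the full single-field pipeline and return every intermediate."""
    mask = segment_islet(prob_map, islet)
    nuclear_in_islet = mask_channel(image["nuclear"], mask)
    nuclei = detect_nuclei(nuclear_in_islet, nuclei_params)
    seeds = paint_labels(nuclei)

    if len(nuclei) == 0:
        empty = cell_features(np.zeros_like(seeds), image, donor_id, group)
        empty = empty.assign(cell_class=pd.Series(dtype=object), moc=pd.Series(dtype=float),
                             median_igfbp7_rescaled=pd.Series(dtype=float))
        return FieldResult(mask, nuclei, seeds, np.zeros_like(seeds), empty)

    guide = make_guide(image)
    cells = propagate_cells(seeds, guide, propagation)
    if exclude_border_cells:
        border_labels = np.unique(np.concatenate(
            [cells[0], cells[-1], cells[:, 0], cells[:, -1]]))
        cells = np.where(np.isin(cells, border_labels[border_labels > 0]), 0, cells)

    table = cell_features(cells, image, donor_id, group)
    # raw medians drive classification; a per-image rescaled IGFBP7 median is
    # recorded alongside for cross-image comparability studies
    igf_rescaled = rescale_full_range(image["igfbp7"]) if np.ptp(image["igfbp7"]) > 0 else np.zeros_like(image["igfbp7"])
    rescaled_med = cell_features(cells, {"igfbp7_rescaled": igf_rescaled})
    table = table.merge(
        rescaled_med[["cell_id", "median_igfbp7_rescaled"]], on="cell_id", how="left"
    )
    table = classify_cells(table, ratio=classification_ratio)
    table = per_cell_moc(cells, image, table)
    return FieldResult(mask, nuclei, seeds, cells, table)


def run(config: PipelineConfig) -> RunManifest:
    """Execute a full run per the configuration; write artifacts; return manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict = {}
    outputs: list = []
    warnings_log: list = []
    seed_prov = {"master_seed": config.seed}

    t0 = time.perf_counter()
    fields = _collect_fields(config, seed_prov)
    timings["collect_fields"] = time.perf_counter() - t0

    tables = []
    t0 = time.perf_counter()
    for i, (name, image, prob_map, donor_id, group) in enumerate(fields):
        res = run_field(
            image, prob_map, donor_id=donor_id, group=group,
            islet=config.islet, nuclei_params=config.nuclei,
            propagation=config.propagation,
            classification_ratio=config.classification_ratio,
            exclude_border_cells=config.exclude_border_cells,
        )
        res.table.insert(0, "field", name)
        tables.append(res.table)
        if res.islet_mask.sum() == 0:
            warnings_log.append(f"{name}: empty islet mask")
        if config.write_images:
            for suffix, writer, obj in (
                ("channels.tif", iqio.write_multichannel_tiff, image),
                ("probmap.tif", iqio.write_probability_map, prob_map),
                ("islet_mask.tif", iqio.write_mask, res.islet_mask),
                ("seeds.tif", iqio.write_labels, res.seed_labels),
                ("cells.tif", iqio.write_labels, res.cell_labels),
            ):
                p = out / f"{name}_{suffix}"
                writer(p, obj)
                outputs.append(str(p))
    timings["segment_and_quantify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    value_col = "median_igfbp7_rescaled" if config.per_image_rescale else "median_igfbp7"
    summary = summarize_groups(table, value_col=value_col) if len(table) else summarize_groups(pd.DataFrame())
    timings["summarize"] = time.perf_counter() - t0

    cells_csv = out / "cells.csv"
    iqio.write_cell_table(cells_csv, table)
    outputs.append(str(cells_csv))
    summary_json = out / "summary.json"
    iqio.write_json(summary_json, {"summary": summary.to_dict(), "value_column": value_col})
    outputs.append(str(summary_json))
    if config.donor_aggregation and len(table):
        donor_csv = out / "donor_summary.csv"
        summarize_by_donor(table).to_csv(donor_csv, index=False)
        outputs.append(str(donor_csv))

    manifest = RunManifest(
        config=config.echo(), version=__version__, seed_provenance=seed_prov,
        stage_timings_s=timings, outputs=outputs, warnings=warnings_log,
    )
    iqio.write_json(out / "manifest.json", manifest.to_dict())
    missing = [p for p in outputs if not Path(p).exists()]
    if missing:
        raise RuntimeError(f"manifest incomplete; missing outputs: {missing}")
    return manifest


def _collect_fields(config: PipelineConfig, seed_prov: dict) -> list:
    """Resolve inputs to (name, image, prob_map, donor_id, group) tuples."""
    fields = []
    if config.mode == "synthetic":
        syn = config.synthetic
        cohort = generate_cohort(
            n_nd=syn.n_nd, n_t2d=syn.n_t2d, params=syn.geometry, model=syn.intensity,
            seed=config.seed, fields_per_donor=syn.fields_per_donor,
        )
        pm_seeds = np.random.SeedSequence((config.seed, 1)).spawn(len(cohort))
        seed_prov["probmap_seeds"] = []
        per_donor_count: dict = {}
        for i, (image, truth) in enumerate(cohort):
            pm_seed = int(pm_seeds[i].generate_state(1)[0] % (2**31))
            seed_prov["probmap_seeds"].append(pm_seed)
            prob_map = render_probability_map(
                truth, blur_sigma_px=syn.probmap_blur_sigma_px,
                noise_sd=syn.probmap_noise_sd, seed=pm_seed,
            )
            k = per_donor_count.get(truth.donor_id, 0)
            per_donor_count[truth.donor_id] = k + 1
            fields.append((f"{truth.donor_id}_f{k}", image, prob_map, truth.donor_id, truth.group))
    elif config.mode == "files":
        for entry in config.inputs:
            image = iqio.read_multichannel_tiff(entry["image"])
            prob_map = iqio.read_probability_map(entry["probmap"])
            name = entry.get("name", Path(entry["image"]).stem)
            fields.append((name, image, prob_map, entry.get("donor_id", name),
                           entry.get("group", "ND")))
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    return fields


def run_gridsearch(
    grid: GridSpec,
    testing_fields: list,
    annotations: list,
    task: str = "mask",
    output_dir: str | None = None,
    islet_template: IsletParams = IsletParams(),
    nuclei_template: NucleiParams = NucleiParams(),
) -> tuple[dict, pd.DataFrame]:
    """Exhaustively score a parameter grid against manual annotations.

    mask task: each combo overrides fields of the islet-segmentation
    parameters, runs on each testing field's probability map, and is scored
    by Jaccard against the manual mask.  nuclei task: combos override the
    nucleus-detection parameters and are scored by count error plus mean
    nearest-neighbor distance against the manual centroids.  Returns the
    winning combo and the full per-image + aggregate score table.
    """
    combos = expand_grid(grid)
    if len(testing_fields) != len(annotations):
        raise ValueError("need one annotation per testing field")
    per_image_rows = []
    agg_scores = []
    for gi, combo in enumerate(combos):
        per_img = []
        for (name, payload), ann in zip(testing_fields, annotations):
            if task == "mask":
                params = replace(islet_template, **combo)
                mask = segment_islet(payload, params)
                score = mask_similarity(mask, ann.manual_islet_mask)
                per_img.append(score)
                per_image_rows.append({"grid_index": gi, **combo, "image": name,
                                       "mask_jaccard": score})
            elif task == "nuclei":
                params = replace(nuclei_template, **combo)
                det = detect_nuclei(payload, params)
                ce, nn = nuclei_agreement(det.centroids, ann.manual_centroids)
                per_img.append((ce, nn))
                per_image_rows.append({"grid_index": gi, **combo, "image": name,
                                       "count_error": ce, "mean_nn_distance_px": nn})
            else:
                raise ValueError(f"unknown task {task!r}")
        if task == "mask":
            agg_scores.append(CandidateScore(combo=combo, grid_index=gi,
                                             mask_jaccard=float(np.mean(per_img))))
        else:
            ces = [c for c, _ in per_img]
            nns = [n for _, n in per_img]
            agg_scores.append(CandidateScore(combo=combo, grid_index=gi,
                                             count_error=float(np.mean(ces)),
                                             mean_nn_distance_px=float(np.mean(nns))))

    best = select_optimum(agg_scores, task=task)
    agg_frame = scores_to_frame(ranked(agg_scores, task=task)).assign(row_kind="aggregate")
    per_frame = pd.DataFrame(per_image_rows).assign(row_kind="per_image")
    full = pd.concat([per_frame, agg_frame], ignore_index=True)
    if output_dir is not None:
        outp = Path(output_dir)
        outp.mkdir(parents=True, exist_ok=True)
        full.to_csv(outp / f"gridsearch_{task}.csv", index=False)
        iqio.write_json(outp / f"gridsearch_{task}_best.json", {"combo": best.combo,
                                                                "grid_index": best.grid_index})
    return best.combo, full
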