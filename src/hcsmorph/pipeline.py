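"""End-to-end orchestration: simulate -> preprocess -> extract -> rank ->
select -> evaluate -> predict, with a manifest auditing every stage."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path


from .features.extract import ExtractionConfig, FeatureTable, extract_table
from .ibcga import GAConfig, run_ibcga
from .model_eval import jackknife, predict_independent, train
from .preprocess import PreprocessConfig, preprocess
from .selection import build_candidate_set, records_to_frame, ttest_all
from .synthetic import make_two_class_study, preset_params

__all__ = ["RunConfig", "run_pipeline", "report"]


@dataclass
class RunConfig:
    out_dir: str = "hcsmorph_run"
    cell_type: str = "astrocytes"
    preset: str = "astrocyte"
    n_per_class: int = 15
    n_independent: int = 0  # extra control-like images predicted independently
    rng_seed: int = 0
    image_width: int = 320
    image_height: int = 240
    quota: tuple = (15, 20, 5)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    ga: GAConfig = field(default_factory=lambda: GAConfig(
        r_end=5, n_pop=20, g_max=10, n_runs=5))
    jackknife_policy: str = "fixed"  # "fixed" uses the GA-selected gamma/C

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "preprocess" in d:
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "extraction" in d:
            d["extraction"] = ExtractionConfig(**d["extraction"])
        if "ga" in d:
            d["ga"] = GAConfig(**d["ga"])
        if "quota" in d:
            d["quota"] = tuple(d["quota"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    If a stage output already exists with a matching config hash it is
    reloaded instead of recomputed (resume support for the extraction
    stage, the expensive one).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"cell_type": config.cell_type, "stages": {}, "seed": config.rng_seed}

    def stage(name):
        t0 = time.time()
        manifest["stages"][name] = {"started": t0}
        return t0

    # --- simulate -----------------------------------------------------------
    t0 = stage("simulate")
    control, case = preset_params(
        config.preset, seed=config.rng_seed,
        width=config.image_width, height=config.image_height)
    study = make_two_class_study(control, case, config.n_per_class,
                                 seed=config.rng_seed)
    manifest["stages"]["simulate"].update(
        n_images=len(study.images), elapsed=time.time() - t0)

    # --- preprocess + extract (cached by config hash) -----------------------
    t0 = stage("extract")
    features_csv = out / "features.csv"
    manifest_json = out / "feature_manifest.json"
    cfg_blob = json.dumps({"extraction": config.extraction.to_dict(),
                           "seed": config.rng_seed,
                           "n_per_class": config.n_per_class,
                           "preset": config.preset}, sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_blob.encode()).hexdigest()
    hash_file = out / "extract.hash"
    if features_csv.exists() and hash_file.exists() and hash_file.read_text() == cfg_hash:
        table = FeatureTable.read_csv(features_csv, manifest_json)
        manifest["stages"]["extract"]["cached"] = True
    else:
        pres = [preprocess(img, config.preprocess) for img in study.images]
        table = extract_table(pres, study.labels, config.extraction)
        table.to_csv(features_csv, manifest_json)
        hash_file.write_text(cfg_hash)
        manifest["stages"]["extract"]["cached"] = False
    manifest["stages"]["extract"].update(
        n_features=len(table.feature_names), elapsed=time.time() - t0,
        features_sha256=_sha256(features_csv))

    # --- rank + candidate set ----------------------------------------------
    t0 = stage("rank")
    records = ttest_all(table)
    records_to_frame(records).to_csv(out / "ranked.csv", index=False)
    n1, n2, n3 = config.quota
    candidates = build_candidate_set(records, n1, n2, n3)
    cand_table = table.subset(candidates.names)
    cand_table.to_csv(out / "candidates.csv")
    manifest["stages"]["rank"].update(n_candidates=candidates.n,
                                      elapsed=time.time() - t0)

    # --- IBCGA select -------------------------------------------------------
    t0 = stage("select")
    ga = GAConfig(**{**config.ga.__dict__, "rng_seed": config.rng_seed})
    solutions = run_ibcga(cand_table, ga)
    solutions.to_json(out / "solutions.json")
    selected = solutions.selected_names()
    gamma = 2.0 ** solutions.robust.g
    cost = 2.0 ** solutions.robust.c
    manifest["stages"]["select"].update(
        selected_features=selected, fitness=solutions.robust.fitness,
        gamma=gamma, cost=cost, n_evaluations=solutions.n_evaluations,
        elapsed=time.time() - t0)

    # --- evaluate -----------------------------------------------------------
    t0 = stage("evaluate")
    if config.jackknife_policy == "fixed":
        ev = jackknife(table, selected, param_policy="fixed", gamma=gamma, cost=cost)
    else:
        ev = jackknife(table, selected, param_policy="grid")
    ev.per_sample.to_csv(out / "jackknife.csv")
    manifest["stages"]["evaluate"].update(
        accuracy=ev.accuracy, confusion=ev.confusion.tolist(),
        elapsed=time.time() - t0)

    # --- independent prediction --------------------------------------------
    if config.n_independent > 0:
        t0 = stage("predict")
        model = train(table, selected, gamma, cost)
        indep = make_two_class_study(control, control, config.n_independent,
                                     seed=config.rng_seed + 104729)
        pres = [preprocess(img, config.preprocess)
                for img in indep.images[:config.n_independent]]
        indep_table = extract_table(pres, ["unknown"] * len(pres), config.extraction)
        pred = predict_independent(model, indep_table)
        pred.per_image.to_csv(out / "independent.csv")
        manifest["stages"]["predict"].update(
            fraction_non_neuroinflammation=pred.fraction_non_neuroinflammation,
            elapsed=time.time() - t0)

    manifest["selected_features"] = selected
    manifest["jackknife_accuracy"] = manifest["stages"]["evaluate"]["accuracy"]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def report(manifest: dict) -> str:
    """Human-readable per-cell-type summary of a completed run manifest."""
    lines = [f"cell type: {manifest.get('cell_type', '?')}"]
    sel = manifest.get("selected_features")
    if sel is None:
        lines.append("warning: incomplete manifest (no selection stage)")
    else:
        lines.append(f"selected features ({len(sel)}): " + ", ".join(sel))
    acc = manifest.get("jackknife_accuracy")
    lines.append("jackknife accuracy: " +
                 (f"{acc:.4f}" if acc is not None else "absent"))
    pred = manifest.get("stages", {}).get("predict")
    if pred:
        lines.append("independent non-neuroinflammation fraction: "
                     f"{pred['fraction_non_neuroinflammation']:.2f}")
    else:
        lines.append("independent prediction: absent")
    return "\n".join(lines)
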