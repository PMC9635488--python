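"""Config-driven orchestration of the full analysis graph.

simulate -> train models -> searchlight RSA -> report.  A single top-level
seed is fanned out to named streams; every stage writes plain-text tables
(plus NIfTI volumes) under the configured output directory, and the final
report mirrors the reporting structure of the analysis: model accuracies,
the RDM correlation table, and one cluster table per requested analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .ann import (AnnConfig, hidden_representations, initialize_model,
                  read_nonwords, score_nonword, score_word, train,
                  training_accuracy)
from .errors import ConfigError
from .gpc import generate_rules, gpc_representation, read_rules_tsv, write_rules_tsv
from .lexicon import (encode_lexicon, read_lexicon_tsv, read_scheme_tsv,
                      write_lexicon_tsv, write_scheme_tsv)
from .rdm import (RDM, average_rdms, build_correlation_table, compute_rdm,
                  write_rdm_tsv, zscore_features)
from .searchlight import (BetaSeries, GroupInferenceConfig, SearchlightConfig,
                          VolumeGrid, group_inference, read_beta_series,
                          read_volume, searchlight_maps, write_beta_series,
                          write_volume)
from .synth import (PlantedRoiSpec, SyntheticDatasetSpec, SyntheticLexiconSpec,
                    make_dataset, nonword_orthography, nonword_targets,
                    read_nonwords_tsv, write_ground_truth, write_nonwords_tsv)

log = logging.getLogger(__name__)

KNOWN_SOURCES = ("orthography", "phonology", "ann_hidden", "gpc")


@dataclass(frozen=True)
class AnalysisSpec:
    name: str
    model: str
    control: str | None = None

    def __post_init__(self):
        if self.model not in KNOWN_SOURCES:
            raise ConfigError(f"unknown analysis model {self.model!r}; "
                              f"choose from {KNOWN_SOURCES}")
        if self.control is not None and self.control not in KNOWN_SOURCES:
            raise ConfigError(f"unknown control {self.control!r}")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    output_dir: str = "out"
    n_instantiations: int = 20
    table_method: str = "pearson"
    paths: dict[str, Any] = field(default_factory=dict)
    ann: AnnConfig = field(default_factory=AnnConfig)
    searchlight: SearchlightConfig = field(default_factory=SearchlightConfig)
    inference: GroupInferenceConfig = field(default_factory=GroupInferenceConfig)
    analyses: tuple[AnalysisSpec, ...] = ()
    simulate: SyntheticDatasetSpec | None = None


def _build_section(cls, data: Mapping[str, Any], section: str):
    import dataclasses
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}"
        )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section {section!r}: {exc}") from exc


def load_config(source) -> PipelineConfig:
    """Build a validated PipelineConfig from a YAML/JSON file or a dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    known = {"seed", "output_dir", "n_instantiations", "table_method",
             "paths", "ann", "searchlight", "inference", "analyses",
             "simulate"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    analyses = []
    for i, entry in enumerate(data.get("analyses", [])):
        analyses.append(_build_section(AnalysisSpec, entry, f"analyses[{i}]"))
    sim = None
    if "simulate" in data and data["simulate"] is not None:
        simdata = dict(data["simulate"])
        if "lexicon" in simdata:
            simdata["lexicon"] = _build_section(
                SyntheticLexiconSpec, simdata["lexicon"], "simulate.lexicon")
        if "rois" in simdata:
            simdata["rois"] = tuple(
                _build_section(PlantedRoiSpec,
                               {**r, "center": tuple(r.get("center", (0, 0, 0)))},
                               f"simulate.rois[{j}]")
                for j, r in enumerate(simdata["rois"]))
        if "grid_shape" in simdata:
            simdata["grid_shape"] = tuple(simdata["grid_shape"])
        if "mask_semi_axes" in simdata:
            simdata["mask_semi_axes"] = tuple(simdata["mask_semi_axes"])
        sim = _build_section(SyntheticDatasetSpec, simdata, "simulate")
    cfg = PipelineConfig(
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", "out")),
        n_instantiations=int(data.get("n_instantiations", 20)),
        table_method=str(data.get("table_method", "pearson")),
        paths=dict(data.get("paths", {})),
        ann=_build_section(AnnConfig, data.get("ann", {}), "ann"),
        searchlight=_build_section(SearchlightConfig,
                                   data.get("searchlight", {}), "searchlight"),
        inference=_build_section(GroupInferenceConfig,
                                 data.get("inference", {}), "inference"),
        analyses=tuple(analyses),
        simulate=sim,
    )
    for a in cfg.analyses:
        if a.control is None and cfg.searchlight.method == "partial_spearman":
            raise ConfigError(
                f"analysis {a.name!r}: partial method requires a control RDM")
    return cfg


def config_hash(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _log_stage(stage: str, t0: float, **kv) -> None:
    extras = " ".join(f"{k}={v}" for k, v in kv.items())
    log.info("stage=%s elapsed_s=%.2f %s", stage, time.monotonic() - t0, extras)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def simulate(config: PipelineConfig):
    """Generate the synthetic dataset configured in the `simulate` section
    and write every pipeline input format under <output_dir>/dataset."""
    if config.simulate is None:
        raise ConfigError("config has no `simulate` section")
    t0 = time.monotonic()
    spec = replace(config.simulate, seed=config.seed)
    ds = make_dataset(spec, ann_config=config.ann)
    out = Path(config.output_dir) / "dataset"
    out.mkdir(parents=True, exist_ok=True)
    write_lexicon_tsv(ds.lexicon, out / "lexicon.tsv")
    write_scheme_tsv(ds.lexicon.grapheme_scheme, out / "grapheme_scheme.tsv")
    write_scheme_tsv(ds.lexicon.phoneme_scheme, out / "phoneme_scheme.tsv")
    write_nonwords_tsv(ds.nonwords, out / "nonwords.tsv")
    write_rules_tsv(ds.ruleset, out / "rules.tsv")
    write_volume(ds.mask.astype(np.float32), ds.grid, out / "mask.nii.gz")
    for b in ds.betas:
        write_beta_series(b, out / f"{b.subject_id}_betas.nii.gz",
                          out / f"{b.subject_id}_labels.tsv")
    write_ground_truth(ds.regions, out / "ground_truth.json")
    _log_stage("simulate", t0, n_words=len(ds.lexicon),
               n_subjects=len(ds.betas))
    return ds


@dataclass
class ModelResults:
    rdms: dict[str, RDM]
    word_accuracy: float
    nonword_accuracy: dict[str, float]
    per_instantiation_word_accuracy: list[float]
    correlation_table: Any


def _dataset_dir(config: PipelineConfig) -> Path:
    return Path(config.output_dir) / "dataset"


def _load_inputs(config: PipelineConfig):
    paths = dict(config.paths)
    base = _dataset_dir(config)
    defaults = {
        "lexicon": base / "lexicon.tsv",
        "grapheme_scheme": base / "grapheme_scheme.tsv",
        "phoneme_scheme": base / "phoneme_scheme.tsv",
        "rules": base / "rules.tsv",
        "nonwords": base / "nonwords.tsv",
    }
    for key, val in defaults.items():
        paths.setdefault(key, val)
    gscheme = read_scheme_tsv(paths["grapheme_scheme"], "orthography")
    pscheme = read_scheme_tsv(paths["phoneme_scheme"], "phonology")
    lexicon = read_lexicon_tsv(paths["lexicon"], gscheme, pscheme)
    ruleset = (read_rules_tsv(paths["rules"]) if Path(paths["rules"]).exists()
               else generate_rules(lexicon))
    nonwords = (read_nonwords_tsv(paths["nonwords"])
                if Path(paths["nonwords"]).exists() else [])
    return lexicon, ruleset, nonwords


def run_models(config: PipelineConfig) -> ModelResults:
    """Train the network ensemble, score words and nonwords, build all RDMs."""
    t0 = time.monotonic()
    lexicon, ruleset, nonwords = _load_inputs(config)
    orth = encode_lexicon(lexicon, "orthography").values.astype(float)
    phon = encode_lexicon(lexicon, "phonology").values.astype(float)
    labels = lexicon.word_ids
    freqs = lexicon.frequencies
    cfg0 = replace(config.ann, n_input=orth.shape[1], n_output=phon.shape[1])

    nw_X = nonword_orthography(nonwords, lexicon.grapheme_scheme) if nonwords else None
    nw_targets = (nonword_targets(nonwords, lexicon.phoneme_scheme)
                  if nonwords else [])
    pool = [v for targets in nw_targets for v in targets]

    hidden_rdms = []
    word_accs = []
    nw_correct = {"jaccard": 0, "exact": 0}
    n_nw_scored = 0
    for i in range(config.n_instantiations):
        cfg = replace(cfg0, seed=config.seed + i)
        model, _ = train(initialize_model(cfg), orth, phon, freqs, cfg)
        word_accs.append(training_accuracy(model, orth, phon, freqs))
        H = hidden_representations(model, orth)
        hidden_rdms.append(compute_rdm(zscore_features(H), labels))
        if nw_X is not None:
            outputs = read_nonwords(model, nw_X)
            for out_vec, targets in zip(outputs, nw_targets):
                n_nw_scored += 1
                for crit in ("jaccard", "exact"):
                    if score_nonword(out_vec, targets, pool, crit):
                        nw_correct[crit] += 1
    mean_ann_rdm = average_rdms(hidden_rdms)

    gpc_feat = gpc_representation(lexicon, ruleset).astype(float)
    rdms = {
        "orthography": compute_rdm(zscore_features(orth), labels),
        "phonology": compute_rdm(zscore_features(phon), labels),
        "ann_hidden": mean_ann_rdm,
        "gpc": compute_rdm(zscore_features(gpc_feat), labels),
    }
    table = build_correlation_table(rdms, config.table_method)
    nw_acc = {crit: (nw_correct[crit] / n_nw_scored if n_nw_scored else float("nan"))
              for crit in ("jaccard", "exact")}
    results = ModelResults(
        rdms=rdms,
        word_accuracy=float(np.mean(word_accs)),
        nonword_accuracy=nw_acc,
        per_instantiation_word_accuracy=word_accs,
        correlation_table=table,
    )
    out = Path(config.output_dir) / "models"
    out.mkdir(parents=True, exist_ok=True)
    for name, r in rdms.items():
        write_rdm_tsv(r, out / f"rdm_{name}.tsv")
    table.to_frame().to_csv(out / "rdm_correlation_table.tsv", sep="\t",
                            index_label="model")
    with open(out / "accuracy.json", "w") as fh:
        json.dump({"word_accuracy": results.word_accuracy,
                   "nonword_accuracy": nw_acc,
                   "per_instantiation_word_accuracy": word_accs}, fh, indent=2)
    _log_stage("train-models", t0,
               n_instantiations=config.n_instantiations,
               word_accuracy=f"{results.word_accuracy:.4f}")
    return results


def _load_betas(config: PipelineConfig) -> tuple[list[BetaSeries], np.ndarray, VolumeGrid]:
    base = _dataset_dir(config)
    mask_path = config.paths.get("mask", base / "mask.nii.gz")
    mask_data, grid = read_volume(mask_path)
    mask = mask_data > 0.5
    betas = []
    specs = config.paths.get("betas")
    if specs:
        for entry in specs:
            betas.append(read_beta_series(entry["nii"], entry["labels"], mask,
                                          entry.get("subject", Path(entry["nii"]).stem)))
    else:
        for nii in sorted(base.glob("sub*_betas.nii.gz")):
            sid = nii.name.split("_betas")[0]
            betas.append(read_beta_series(nii, base / f"{sid}_labels.tsv",
                                          mask, sid))
    if not betas:
        raise ConfigError("no beta series found; run `simulate` or set paths.betas")
    return betas, mask, grid


def _load_rdms(config: PipelineConfig) -> dict[str, RDM]:
    from .rdm import read_rdm_tsv
    out = Path(config.output_dir) / "models"
    rdms = {}
    for name in KNOWN_SOURCES:
        path = out / f"rdm_{name}.tsv"
        if path.exists():
            rdms[name] = read_rdm_tsv(path)
    return rdms


def run_rsa(config: PipelineConfig, rdms: Mapping[str, RDM] | None = None,
            betas: list[BetaSeries] | None = None,
            mask: np.ndarray | None = None) -> dict[str, Any]:
    """Searchlight every requested analysis, then smooth / Fisher / t / cluster.

    All analyses share one searchlight pass per subject.  Returns, per
    analysis name, a dict with subject maps, the group map and the cluster
    table; cluster tables and group t volumes are also written to disk.
    """
    t0 = time.monotonic()
    if not config.analyses:
        log.info("no analyses requested; nothing to do")
        return {}
    if rdms is None:
        rdms = _load_rdms(config)
    if betas is None:
        betas, mask, _ = _load_betas(config)
    missing = {a.model for a in config.analyses} | \
              {a.control for a in config.analyses if a.control}
    missing -= set(rdms)
    if missing:
        raise ConfigError(f"missing RDMs for analyses: {sorted(missing)}; "
                          f"run `train-models` first")
    comparisons = [(a.name, rdms[a.model],
                    rdms[a.control] if a.control else None)
                   for a in config.analyses]
    subject_maps: dict[str, list] = {a.name: [] for a in config.analyses}
    for b in betas:
        maps = searchlight_maps(b, comparisons, config.searchlight)
        for name, m in maps.items():
            subject_maps[name].append(m)
    results = {}
    out = Path(config.output_dir) / "rsa"
    out.mkdir(parents=True, exist_ok=True)
    for a in config.analyses:
        gmap, table = group_inference(subject_maps[a.name],
                                      mask if mask is not None
                                      else betas[0].mask,
                                      config.inference)
        table.clusters.to_csv(out / f"clusters_{a.name}.tsv", sep="\t",
                              index=False)
        write_volume(np.nan_to_num(gmap.t, nan=0.0), gmap.grid,
                     out / f"group_t_{a.name}.nii.gz")
        results[a.name] = {"subject_maps": subject_maps[a.name],
                           "group": gmap, "clusters": table}
    _log_stage("rsa", t0, n_subjects=len(betas),
               n_analyses=len(config.analyses))
    return results


def write_report(config: PipelineConfig,
                 model_results: ModelResults | None = None,
                 rsa_results: Mapping[str, Any] | None = None) -> dict:
    """Assemble the run report (JSON) from in-memory or on-disk stage outputs."""
    out = Path(config.output_dir)
    report: dict[str, Any] = {
        "provenance": {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "package_version": __version__,
            "numpy_version": np.__version__,
        }
    }
    if model_results is not None:
        report["model_accuracy"] = {
            "word_accuracy": model_results.word_accuracy,
            "nonword_accuracy": model_results.nonword_accuracy,
        }
        tf = model_results.correlation_table.to_frame()
        report["rdm_correlation_table"] = {
            "labels": list(tf.columns),
            "values": tf.to_numpy().tolist(),
            "method": model_results.correlation_table.method,
        }
    elif (out / "models" / "accuracy.json").exists():
        with open(out / "models" / "accuracy.json") as fh:
            acc = json.load(fh)
        report["model_accuracy"] = {
            "word_accuracy": acc["word_accuracy"],
            "nonword_accuracy": acc["nonword_accuracy"],
        }
    if rsa_results is not None:
        report["cluster_tables"] = {
            name: res["clusters"].clusters.to_dict(orient="records")
            for name, res in rsa_results.items()}
    else:
        tables = {}
        for a in config.analyses:
            path = out / "rsa" / f"clusters_{a.name}.tsv"
            if path.exists():
                import pandas as pd
                tables[a.name] = pd.read_csv(path, sep="\t").to_dict(
                    orient="records")
        if tables:
            report["cluster_tables"] = tables
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_all(config: PipelineConfig) -> dict:
    """simulate -> train-models -> rsa -> report."""
    if config.simulate is not None:
        simulate(config)
    model_results = run_models(config)
    rsa_results = run_rsa(config, model_results.rdms)
    return write_report(config, model_results, rsa_results)
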