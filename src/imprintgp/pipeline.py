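"""One-command pipeline: simulate -> QC -> fit -> decompose -> evaluate.

A run is driven by a TOML config and a global seed.  The global seed
deterministically spawns per-stage seeds so each model fit is
independently reproducible.  Every stage writes its outputs before the
next starts, and a JSON manifest records the config echo, seeds, input
checksums, per-stage wall-clock and the output inventory.  A completed
run directory is never overwritten without ``overwrite=True``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluate import compare_models, h2_of_corrected_phenotype, split_by_date, validate_predictions
from .genotypes import qc_filter, read_phased_vcf, read_phenotypes
from .model import DEFAULT_MIXING, MODEL_EFFECTS, ModelSpec, SNPMixtureModel
from .simulate import SimulationConfig, simulate_population

__all__ = ["RunConfig", "RunManifest", "load_config", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    models: tuple[str, ...] = ("A", "AD", "AI", "ADI")
    simulate: SimulationConfig | None = None
    genotypes: Path | None = None
    phenotypes: Path | None = None
    cutoff_date: str | None = None
    chain_length: int = 50_000
    burn_in: int = 20_000
    thinning: int = 10
    mixing_proportions: tuple[float, ...] = DEFAULT_MIXING
    qc: dict = dataclasses.field(default_factory=dict)
    overwrite: bool = False
    simulate_only: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.models = tuple(self.models)
        if not self.models:
            raise ValueError("model list must be non-empty")
        bad = [m for m in self.models if m not in MODEL_EFFECTS]
        if bad:
            raise ValueError(f"unknown models {bad}; choose from {list(MODEL_EFFECTS)}")
        if self.simulate is None and (self.genotypes is None or self.phenotypes is None):
            raise ValueError("provide either a [simulate] section or genotype+phenotype paths")


@dataclasses.dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    input_checksums: dict
    stage_seconds: dict
    outputs: list[str]
    status: str = "complete"

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim = raw.pop("simulate", None)
    if sim is not None:
        if "target_variances" in sim:
            sim["target_variances"] = dict(sim["target_variances"])
        if "allele_freq_range" in sim:
            sim["allele_freq_range"] = tuple(sim["allele_freq_range"])
        if "mixing_proportions" in sim:
            sim["mixing_proportions"] = tuple(sim["mixing_proportions"])
        sim = SimulationConfig(**sim)
    for key in ("genotypes", "phenotypes"):
        if key in raw:
            raw[key] = Path(raw[key])
    if "mixing_proportions" in raw:
        raw["mixing_proportions"] = tuple(raw["mixing_proportions"])
    return RunConfig(simulate=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _spawn_seeds(seed: int, labels: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(labels))
    return {lab: int(c.generate_state(1)[0] & 0x7FFFFFFF)
            for lab, c in zip(labels, children)}


def run_pipeline(config: RunConfig) -> RunManifest:
    out = config.out_dir
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not config.overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; refusing to overwrite a completed run "
            "(set overwrite = true)")
    out.mkdir(parents=True, exist_ok=True)

    stage_labels = ["simulate"] + [f"fit_{m}" for m in config.models]
    seeds = _spawn_seeds(config.seed, stage_labels)
    timings: dict[str, float] = {}
    outputs: list[str] = []
    checksums: dict[str, str] = {}

    def _record(path: Path) -> Path:
        outputs.append(str(path.relative_to(out)))
        return path

    # -- stage: data (simulate or load) --------------------------------------
    t0 = time.perf_counter()
    cutoff = config.cutoff_date
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=seeds["simulate"])
        population = simulate_population(sim_cfg)
        paths = population.save(out / "data")
        for p in paths.values():
            _record(p)
        genotypes, phenotypes = population.genotypes, population.phenotypes
        if cutoff is None:
            cutoff = population.cutoff_date
    else:
        checksums["genotypes"] = _sha256(config.genotypes)
        checksums["phenotypes"] = _sha256(config.phenotypes)
        genotypes = read_phased_vcf(config.genotypes)
        phenotypes = read_phenotypes(config.phenotypes, genotypes=genotypes)
    timings["data"] = time.perf_counter() - t0

    config_echo = json.loads(json.dumps(dataclasses.asdict(config), default=str))
    manifest = RunManifest(config=config_echo, version=__version__, seeds=seeds,
                           input_checksums=checksums, stage_seconds=timings,
                           outputs=outputs, status="partial")
    manifest.save(manifest_path)
    if config.simulate_only:
        manifest.status = "complete"
        manifest.save(manifest_path)
        return manifest

    # -- stage: QC ------------------------------------------------------------
    t0 = time.perf_counter()
    genotypes, report = qc_filter(genotypes, **config.qc)
    report.to_frame().to_csv(_record(out / "qc_report.tsv"), sep="\t", index=False)
    phenotypes = phenotypes.aligned_to(genotypes.sample_ids)
    timings["qc"] = time.perf_counter() - t0
    manifest.save(manifest_path)

    # -- stage: split + fits ---------------------------------------------------
    if cutoff is None:
        raise ValueError("cutoff_date required (or provided by the simulation)")
    train_ids, val_ids = split_by_date(phenotypes, cutoff)
    id_pos = {s: i for i, s in enumerate(genotypes.sample_ids)}
    g_train = genotypes.subset(samples=np.array([id_pos[s] for s in train_ids]))
    g_val = genotypes.subset(samples=np.array([id_pos[s] for s in val_ids]))
    phen_train = phenotypes.aligned_to(train_ids)
    phen_val = phenotypes.aligned_to(val_ids)

    results = {}
    for code in config.models:
        t0 = time.perf_counter()
        model = SNPMixtureModel(phen_train, g_train, effects=code)
        spec = ModelSpec(effect_set=MODEL_EFFECTS[code],
                         mixing_proportions=config.mixing_proportions,
                         chain_length=config.chain_length, burn_in=config.burn_in,
                         thinning=config.thinning, seed=seeds[f"fit_{code}"])
        res = model.fit(spec=spec)
        results[code] = res
        fit_dir = out / "fits" / code
        fit_dir.mkdir(parents=True, exist_ok=True)
        res.variance_decomposition().to_frame().to_csv(
            _record(fit_dir / "posterior_summary.tsv"), sep="\t", index=False)
        res.effects_frame().to_csv(_record(fit_dir / "effects.tsv"), sep="\t", index=False)
        np.savez_compressed(_record(fit_dir / "samples.npz"),
                            class_var_samples=res.class_var_samples,
                            litter=res.component_samples["litter"],
                            residual=res.component_samples["residual"],
                            freqs=model.design.freqs,
                            mixing_proportions=np.asarray(spec.mixing_proportions))
        pd.DataFrame(res.trace, columns=["iteration", "var_litter", "var_residual"]
                     + [f"{e}_class{c + 1}" for e in model.effects for c in range(4)]
                     ).to_csv(_record(fit_dir / "trace.tsv"), sep="\t", index=False)
        with open(_record(fit_dir / "summary.txt"), "w") as fh:
            fh.write(res.summary() + "\n")
        timings[f"fit_{code}"] = time.perf_counter() - t0
        manifest.save(manifest_path)

    # -- stage: decomposition table (Table-1 layout across models) ------------
    frames = []
    for code, res in results.items():
        f = res.variance_decomposition().to_frame()
        f.insert(0, "model", code)
        frames.append(f)
    pd.concat(frames).to_csv(_record(out / "variance_components.tsv"),
                             sep="\t", index=False)

    # -- stage: evaluation -----------------------------------------------------
    t0 = time.perf_counter()
    cpos = {code: res.cpo for code, res in results.items()}
    baseline = "A" if "A" in results else config.models[0]
    comparison = compare_models(cpos, baseline=baseline)
    comparison.to_frame().to_csv(_record(out / "model_comparison.tsv"),
                                 sep="\t", index=False)

    ref = results[baseline].variance_components
    h2_yc = h2_of_corrected_phenotype(ref["additive"], ref["litter"], ref["residual"])
    predictions = {code: {"GBV": res.predict(g_val, scope="GBV"),
                          "GTV": res.predict(g_val, scope="GTV")}
                   for code, res in results.items()}
    report = validate_predictions(predictions, phen_val.frame["y_c"].to_numpy(float),
                                  h2_yc, cutoff, n_train=len(train_ids),
                                  baseline=baseline)
    report.reliability_table.to_csv(_record(out / "reliability.tsv"), sep="\t", index=False)
    report.bias_table.to_csv(_record(out / "bias.tsv"), sep="\t", index=False)
    timings["evaluate"] = time.perf_counter() - t0

    manifest.status = "complete"
    manifest.save(manifest_path)
    return manifest
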