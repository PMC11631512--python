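"""Pipeline orchestration: synth -> prep -> fit -> profile -> pcgsa -> perturb.

A single YAML/dict config drives all stages; every stage draws its
randomness from a named substream of one master seed, records its inputs,
outputs and timing, and the whole run is summarised in a manifest with
per-file checksums so deterministic stages can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataprep import assemble_dataset
from .dataset import ObservedDataset
from .estimation import GAConfig
from .params import PARAM_NAMES, HypoxiaParams, ParameterSet
from .sensitivity import singular_spectrum, variable_heatmap
from .synth import (
    SynthConfig,
    make_fraction_tables,
    make_observations,
    make_truth_counts,
    sample_ground_truth,
)
from .tme import TMEModel, TMEResults

__all__ = ["RunManifest", "run_all", "substream_seed"]

STAGE_ORDER = ("synth", "prep", "fit", "profile", "pcgsa", "perturb")


def substream_seed(master: int, name: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record of a pipeline run."""

    config_hash: str
    master_seed: int
    stage_seeds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # name -> {outputs, seconds, status}
    error: str | None = None

    def record(self, stage: str, outputs: list[Path], seconds: float):
        self.stages[stage] = {
            "outputs": {str(p): _checksum(p) for p in outputs},
            "seconds": round(seconds, 3),
            "status": "ok",
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "master_seed": self.master_seed,
            "stage_seeds": self.stage_seeds,
            "stages": self.stages,
            "error": self.error,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def run_all(config: dict | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the requested stages in order, short-circuiting on error."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir or config.get("out_dir", "tme_run"))
    out.mkdir(parents=True, exist_ok=True)

    master = int(config.get("seed", 0))
    stages = config.get("stages", list(STAGE_ORDER))
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        master_seed=master,
    )

    data: ObservedDataset | None = None
    results: TMEResults | None = None
    try:
        for stage in STAGE_ORDER:
            if stage not in stages:
                continue
            seed = substream_seed(master, stage)
            manifest.stage_seeds[stage] = seed
            t0 = time.perf_counter()
            outputs: list[Path] = []

            if stage == "synth":
                scfg_kw = dict(config.get("synth", {}))
                free = scfg_kw.pop("free", None)
                scfg = SynthConfig(seed=seed, sparsity=free, **scfg_kw)
                rng = np.random.default_rng(seed)
                truth = sample_ground_truth(scfg, rng=rng)
                noisy, ref = make_observations(truth, scfg, rng=rng)
                counts = make_truth_counts(scfg, rng=rng)
                tables = make_fraction_tables(counts)
                truth.to_json(out / "truth.json", HypoxiaParams())
                noisy.to_csv(out / "data.csv")
                ref.to_csv(out / "data_noiseless.csv")
                counts.to_csv(out / "truth_counts.csv", index=False)
                tables["fractions"].to_csv(out / "fractions.csv", index=False)
                tables["cytokines"].to_csv(out / "cytokines.csv", index=False)
                tables["totals"].to_csv(out / "totals.csv", index=False)
                data = noisy
                outputs = [
                    out / n for n in (
                        "truth.json", "data.csv", "data_noiseless.csv",
                        "truth_counts.csv", "fractions.csv", "cytokines.csv",
                        "totals.csv",
                    )
                ]

            elif stage == "prep":
                pcfg = config.get("prep", {})
                fr = pd.read_csv(pcfg.get("fractions", out / "fractions.csv"))
                cy = pd.read_csv(pcfg.get("cytokines", out / "cytokines.csv"))
                ds, counts = assemble_dataset(fr, cy, return_counts=True)
                counts.to_csv(out / "counts.csv", index=False)
                ds.to_csv(out / "nondim.csv")
                outputs = [out / "counts.csv", out / "nondim.csv"]

            elif stage == "fit":
                fcfg = dict(config.get("fit", {}))
                free = fcfg.pop("free", None)
                data_path = fcfg.pop("data", None)
                mice = fcfg.pop("mice", None)
                if data_path is not None:
                    data = ObservedDataset.from_csv(data_path)
                if data is None:
                    data = ObservedDataset.from_csv(out / "data.csv")
                if mice is not None:
                    data = data.select_mice(mice)
                ga = GAConfig(seed=seed, **fcfg)
                model = TMEModel(data, free_names=free)
                results = model.fit(ga)
                results.save(out / "fit.json")
                outputs = [out / "fit.json"]

            elif stage == "profile":
                if results is None:
                    raise RuntimeError("profile stage requires a fit")
                pcfg = config.get("profile", {})
                names = pcfg.get("params")
                prof = results.profile_all(
                    names,
                    grid_size=pcfg.get("grid_size", 11),
                    alpha=pcfg.get("alpha", 0.95),
                )
                payload = {
                    "labels": prof["labels"],
                    "counts": prof["counts"],
                    "curves": {
                        nm: {
                            "grid": c.grid.tolist(),
                            "values": c.values.tolist(),
                            "theta_hat": c.theta_hat,
                            "loss_hat": c.loss_hat,
                        }
                        for nm, c in prof["curves"].items()
                    },
                }
                (out / "profiles.json").write_text(json.dumps(payload, indent=1))
                outputs = [out / "profiles.json"]

            elif stage == "pcgsa":
                if results is None:
                    raise RuntimeError("pcgsa stage requires a fit")
                gcfg = config.get("pcgsa", {})
                n_grid = int(gcfg.get("grid", 151))
                t_grid = np.linspace(0.0, 150.0, n_grid)
                dec = results.sensitivity(t_grid=t_grid)
                cutoff = float(gcfg.get("cutoff", 0.2))
                n_pc = singular_spectrum(dec, cutoff)
                heat = variable_heatmap(dec, n_components=n_pc)
                payload = {
                    "singular_values": dec.sigma.tolist(),
                    "n_components": n_pc,
                    "cutoff": cutoff,
                    "S": dec.S[:n_pc].tolist(),
                    "param_names": list(dec.source.param_names),
                    "heatmap": heat,
                }
                (out / "pcgsa.json").write_text(json.dumps(payload, indent=1))
                outputs = [out / "pcgsa.json"]

            elif stage == "perturb":
                if results is None:
                    raise RuntimeError("perturb stage requires a fit")
                pcfg = config.get("perturb", {})
                name = pcfg.get("param", "lambda_VEN")
                delta = float(pcfg.get("delta", 0.1))
                exp = results.perturb(name, [-delta, 0.0, delta])
                rows = {"t_days": exp["t_grid"]}
                for d, series in exp["runs"].items():
                    rows[f"cancer_d{d:+g}"] = series["cancer"]
                    rows[f"immune_d{d:+g}"] = series["total_immune"]
                pd.DataFrame(rows).to_csv(out / "perturb.csv", index=False)
                outputs = [out / "perturb.csv"]

            manifest.record(stage, outputs, time.perf_counter() - t0)
    except Exception as exc:
        manifest.error = f"{type(exc).__name__}: {exc}"
    manifest.to_json(out / "manifest.json")
    return manifest
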