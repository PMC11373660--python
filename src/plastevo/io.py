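"""Serialization: parameters, genotypes, populations and run records.

Formats are all plain text: flat JSON for parameters and genotypes
(mirroring field names exactly), TSV for time series.  Floats are written
with ``repr`` so every round-trip is lossless.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .evolution import Population, RunRecord
from .genotype import Genotype
from .params import SimulationParams


def save_params(params: SimulationParams, path) -> None:
    with open(path, "w") as fh:
        fh.write(params.to_json())


def load_params(path) -> SimulationParams:
    with open(path) as fh:
        return SimulationParams.from_json(fh.read())


def save_genotype(genotype: Genotype, path, params_hash=None) -> None:
    with open(path, "w") as fh:
        fh.write(genotype.to_json(params_hash))


def load_genotype(path) -> Genotype:
    with open(path) as fh:
        return Genotype.from_json(fh.read())


def save_population(pop: Population, path) -> None:
    payload = {
        "n": pop.n,
        "generation": pop.generation,
        "current_env": pop.current_env,
        "rows": [[repr(float(v)) for v in row] for row in pop.rows],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_population(path) -> Population:
    with open(path) as fh:
        d = json.load(fh)
    rows = np.array([[float(v) for v in row] for row in d["rows"]])
    return Population(rows=rows, n=d["n"], generation=d["generation"],
                      current_env=d["current_env"])


def save_run_record(record: RunRecord, prefix, *,
                    include_population: bool = True) -> None:
    """Persist a run as ``<prefix>.tsv`` (generation, mean_w1, mean_w2),
    ``<prefix>.json`` (parameters and outcome) and optionally
    ``<prefix>.population.json`` (the final population)."""
    with open(f"{prefix}.tsv", "w") as fh:
        fh.write("generation\tmean_w1\tmean_w2\n")
        for g, a, b in zip(record.generations, record.mean_w1,
                           record.mean_w2):
            fh.write(f"{g}\t{float(a)!r}\t{float(b)!r}\n")
    sidecar = {
        "params": record.params.to_dict(),
        "params_hash": record.params_hash,
        "seed": list(record.seed) if isinstance(record.seed, tuple)
        else record.seed,
        "threshold": record.threshold,
        "window": record.window,
        "record_stride": record.record_stride,
        "success": record.success,
        "acquisition_generation": record.acquisition_generation,
        "final_generation": record.final_generation,
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    if include_population:
        save_population(record.final_population, f"{prefix}.population.json")


def load_run_record(prefix) -> RunRecord:
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    series = pd.read_csv(f"{prefix}.tsv", sep="\t",
                         float_precision="round_trip")
    pop_path = f"{prefix}.population.json"
    pop = load_population(pop_path) if os.path.exists(pop_path) else None
    seed = meta["seed"]
    return RunRecord(
        params=SimulationParams.from_dict(meta["params"]),
        seed=tuple(seed) if isinstance(seed, list) else seed,
        threshold=meta["threshold"],
        window=meta["window"],
        record_stride=meta["record_stride"],
        generations=series["generation"].to_numpy(),
        mean_w1=series["mean_w1"].to_numpy(),
        mean_w2=series["mean_w2"].to_numpy(),
        success=meta["success"],
        acquisition_generation=meta["acquisition_generation"],
        final_generation=meta["final_generation"],
        final_population=pop,
        snapshots=[],
    )
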