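"""Replicated parameter sweeps with resumable, atomically written output.

A sweep is the cartesian product of named axes over SimulationParams fields
(e.g. mu_c in {1e-6 .. 1e-4} x IT in {1, 10, 100, 1000, 10000}), each cell
run for a fixed number of replicates.  Per-cell results are written to
their own TSV named by the cell's parameter hash, so an interrupted sweep
resumes by skipping completed cells; cells are independent and may be run
concurrently by any scheduler.
"""

from __future__ import annotations

import dataclasses
import itertools
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import PlasticitySummary, success_proportion
from .evolution import run
from .params import SimulationParams

_COLUMNS = ("cell", "replicate", "seed", "success", "Tp",
            "final_generation", "error")


@dataclass
class SweepSpec:
    base_params: SimulationParams
    axes: dict = field(default_factory=dict)
    replicates: int = 1
    base_seed: int = 0

    def __post_init__(self):
        valid = {f.name for f in dataclasses.fields(SimulationParams)}
        for name in self.axes:
            if name not in valid:
                raise ValueError(f"axis {name!r} is not a parameter field")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def cells(self):
        """Cartesian product of the axes, in axis-declaration order."""
        names = list(self.axes)
        for values in itertools.product(*(self.axes[n] for n in names)):
            yield dict(zip(names, values))

    def cell_seed(self, cell_index: int, replicate: int):
        """Seed for one run: a pure function of (base_seed, cell, rep)."""
        return (self.base_seed, cell_index, replicate)


def _atomic_write(df: pd.DataFrame, path: str) -> None:
    tmp = path + ".tmp"
    df.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


def run_sweep(spec: SweepSpec, out_dir: str | None = None, *,
              threshold: float = 0.95, window: int = 100_000,
              engine: str = "fast") -> pd.DataFrame:
    """Execute every (cell, replicate); return the tidy result table.

    Columns: one per axis, plus cell index, replicate, seed, success, Tp,
    final_generation and error (empty unless the run raised; failed cells
    are recorded, never silently dropped).  With ``out_dir``, per-cell TSVs
    named ``cell_<params_hash>.tsv`` are written atomically and completed
    cells are skipped on re-run; the combined table is ``sweep.tsv``.
    """
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    frames = []
    for cell_index, cell in enumerate(spec.cells()):
        params = spec.base_params.with_overrides(**cell)
        cell_path = (os.path.join(out_dir, f"cell_{params.params_hash()}.tsv")
                     if out_dir else None)
        if cell_path and os.path.exists(cell_path):
            frames.append(pd.read_csv(cell_path, sep="\t"))
            continue
        rows = []
        for rep in range(spec.replicates):
            seed = spec.cell_seed(cell_index, rep)
            row = dict(cell)
            row.update(cell=cell_index, replicate=rep, seed=str(seed),
                       success=False, Tp=-1, final_generation=-1, error="")
            try:
                rec = run(params, seed=seed, threshold=threshold,
                          window=window, engine=engine)
                row.update(
                    success=rec.success,
                    Tp=(rec.acquisition_generation
                        if rec.acquisition_generation is not None else -1),
                    final_generation=rec.final_generation)
            except Exception as exc:  # noqa: BLE001 - recorded, not dropped
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
        frame = pd.DataFrame(rows)
        if cell_path:
            _atomic_write(frame, cell_path)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        _atomic_write(table, os.path.join(out_dir, "sweep.tsv"))
    return table


def summarize_sweep(table: pd.DataFrame, axes) -> pd.DataFrame:
    """Per-cell Sp and the Tp distribution of successful replicates."""
    axes = list(axes)
    out = []
    for key, grp in table.groupby(axes, sort=False):
        if not isinstance(key, tuple):
            key = (key,)
        summaries = [PlasticitySummary(None if t < 0 else int(t), bool(s))
                     for s, t in zip(grp["success"], grp["Tp"])]
        tps = sorted(int(t) for t in grp.loc[grp["success"], "Tp"])
        rec = dict(zip(axes, key))
        rec["Sp"] = success_proportion(summaries)
        rec["Tp_values"] = ",".join(str(t) for t in tps)
        rec["Tp_median"] = float(np.median(tps)) if tps else float("nan")
        out.append(rec)
    return pd.DataFrame(out)
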