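"""Reading and writing cohorts, traces and run configuration.

Cohorts travel as CSV with one column per subject field (plus an
optional ``true_label`` column for synthetic data); traces are written
as columnar delimited files (one column per scalar parameter, one row
per retained draw), a separate integer CSV for the allocation draws,
and a JSON sidecar with the run metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import COHORT_COLUMNS, Cohort
from .mixture import CONTINUOUS_VARS
from .sampler import Trace


def read_cohort(path: str | Path) -> Cohort:
    """Load a cohort CSV, validating every row (errors carry the first
    offending line numbers)."""
    frame = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    labels = frame.pop("true_label").to_numpy() if "true_label" in frame else None
    return Cohort(frame[COHORT_COLUMNS], labels)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    frame = cohort.frame[COHORT_COLUMNS].copy()
    if cohort.true_labels is not None:
        frame["true_label"] = cohort.true_labels
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trace serialisation

_CAT_LEVELS = {"p_job": 5, "p_mine": 2, "p_dur": 4}


def _param_columns(C: int) -> list[tuple[str, str, tuple]]:
    """(column name, trace attribute, index) triples in file order."""
    cols = []
    for c in range(C):
        cols.append((f"beta_{c + 1}", "beta", (c,)))
    for c in range(C):
        for v, name in enumerate(CONTINUOUS_VARS):
            cols.append((f"mu_{name}_{c + 1}", "mu", (c, v)))
            cols.append((f"sigma_{name}_{c + 1}", "sigma", (c, v)))
    for attr, L in _CAT_LEVELS.items():
        for c in range(C):
            for lvl in range(L):
                cols.append((f"{attr}{lvl + 1}_{c + 1}", attr, (c, lvl)))
    for c in range(C):
        cols.append((f"phi_{c + 1}", "phi", (c,)))
    cols.append(("alpha", "alpha", ()))
    for j in range(4):
        cols.append((f"lambda_{j + 1}", "lam", (j,)))
    return cols


def save_trace(trace: Trace, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    C = trace.n_components
    data = {}
    for name, attr, idx in _param_columns(C):
        arr = getattr(trace, attr)
        data[name] = arr[(slice(None),) + idx]
    pd.DataFrame(data).to_csv(outdir / "parameters.csv", index=False)
    np.savetxt(outdir / "allocations.csv", trace.alloc, fmt="%d", delimiter=",")
    meta = dict(trace.meta)
    meta["n_components"] = C
    meta["exposed_idx"] = [int(i) for i in trace.exposed_idx]
    meta["n_subjects"] = int(trace.n_subjects)
    with open(outdir / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_trace(outdir: str | Path) -> Trace:
    outdir = Path(outdir)
    with open(outdir / "meta.json") as fh:
        meta = json.load(fh)
    C = meta.pop("n_components")
    exposed_idx = np.array(meta.pop("exposed_idx"), dtype=int)
    n_subjects = meta.pop("n_subjects")
    params = pd.read_csv(outdir / "parameters.csv")
    alloc = np.loadtxt(outdir / "allocations.csv", dtype=int, delimiter=",", ndmin=2)
    D = len(params)
    arrays = {
        "beta": np.empty((D, C)), "mu": np.empty((D, C, 4)), "sigma": np.empty((D, C, 4)),
        "p_job": np.empty((D, C, 5)), "p_mine": np.empty((D, C, 2)),
        "p_dur": np.empty((D, C, 4)), "phi": np.empty((D, C)),
        "alpha": np.empty(D), "lam": np.empty((D, 4)),
    }
    for name, attr, idx in _param_columns(C):
        arrays[attr][(slice(None),) + idx] = params[name].to_numpy()
    return Trace(alloc=alloc, exposed_idx=exposed_idx, n_subjects=n_subjects,
                 meta=meta, **arrays)


def load_config(path: str | Path) -> dict:
    """Parse a JSON or YAML run configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
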