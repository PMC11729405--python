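"""Catalog persistence: CSV records + HDF5 trajectory store + JSON metadata.

A catalog directory contains:

* ``records.csv``        — intervention and descriptor columns + validity;
* ``meta.json``          — format version, behavior-space spec, provenance;
* ``trajectories.h5``    — optional per-record state matrices and time grid;
* ``perturbations.json`` — per-record perturbation specs and outcomes.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .explore import BehavioralCatalog, PerturbationRecord
from .perturb import PerturbationSpec
from .spaces import BehaviorSpace

__all__ = ["save_catalog", "load_catalog", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def save_catalog(catalog: BehavioralCatalog, path: str) -> dict:
    """Write a catalog directory; returns the manifest dict."""
    os.makedirs(path, exist_ok=True)
    N = len(catalog)
    I = catalog.intervention_matrix() if N else np.zeros((0, 0))
    Z = catalog.descriptor_matrix() if N else np.zeros((0, 0))
    cols = {}
    for j in range(I.shape[1] if I.ndim == 2 else 0):
        cols[f"i_{j}"] = I[:, j]
    for j in range(Z.shape[1] if Z.ndim == 2 else 0):
        cols[f"z_{j}"] = Z[:, j]
    cols["valid"] = catalog.valid_mask() if N else np.zeros(0, dtype=bool)
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(cols).to_csv(
        os.path.join(path, "records.csv"), index=False, float_format="%.17g"
    )

    stored = [k for k, t in enumerate(catalog.trajectories) if t is not None]
    with h5py.File(os.path.join(path, "trajectories.h5"), "w") as h5:
        for k in stored:
            t = catalog.trajectories[k]
            g = h5.create_group(f"record_{k}")
            g.create_dataset("times", data=t.times)
            g.create_dataset("states", data=t.states)

    perts = []
    for records in catalog.perturbations:
        perts.append(
            [
                {
                    "spec": json.loads(rec.spec.to_json()),
                    "descriptor": np.asarray(rec.descriptor).tolist(),
                    "valid": bool(rec.valid),
                }
                for rec in records
            ]
        )
    with open(os.path.join(path, "perturbations.json"), "w") as fh:
        json.dump(perts, fh)

    manifest = {
        "format_version": FORMAT_VERSION,
        "n_records": N,
        "space": {
            "kind": catalog.space.kind,
            "nodes": list(catalog.space.nodes),
            "n_bins": catalog.space.n_bins,
        },
        "provenance": catalog.provenance,
        "stored_trajectories": stored,
    }
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_catalog(path: str) -> BehavioralCatalog:
    with open(os.path.join(path, "meta.json")) as fh:
        meta = json.load(fh)
    if meta["format_version"] != FORMAT_VERSION:
        raise ValueError(
            f"catalog format version {meta['format_version']} != supported {FORMAT_VERSION}"
        )
    space = BehaviorSpace(
        kind=meta["space"]["kind"],
        nodes=tuple(meta["space"]["nodes"]),
        n_bins=meta["space"]["n_bins"],
    )
    catalog = BehavioralCatalog(space, meta.get("provenance", {}))
    df = pd.read_csv(os.path.join(path, "records.csv"), float_precision="round_trip")
    icols = sorted((c for c in df.columns if c.startswith("i_")), key=lambda c: int(c[2:]))
    zcols = sorted((c for c in df.columns if c.startswith("z_")), key=lambda c: int(c[2:]))
    trajs: dict = {}
    h5path = os.path.join(path, "trajectories.h5")
    if os.path.exists(h5path):
        with h5py.File(h5path, "r") as h5:
            for name in h5:
                k = int(name.split("_")[1])
                trajs[k] = Trajectory.from_states(h5[name]["times"][:], h5[name]["states"][:])
    for k in range(len(df)):
        catalog.append(
            df.loc[k, icols].to_numpy(dtype=float),
            df.loc[k, zcols].to_numpy(dtype=float),
            bool(df.loc[k, "valid"]),
            trajs.get(k),
        )
    pj = os.path.join(path, "perturbations.json")
    if os.path.exists(pj):
        with open(pj) as fh:
            perts = json.load(fh)
        for k, records in enumerate(perts):
            for rec in records:
                catalog.perturbations[k].append(
                    PerturbationRecord(
                        PerturbationSpec.from_json(json.dumps(rec["spec"])),
                        np.asarray(rec["descriptor"], dtype=float),
                        bool(rec["valid"]),
                    )
                )
    return catalog
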