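"""Delimited-text coordinate profiles.

A *coordinate profile* is the on-disk exchange format for tagged 3D
points: one row per object with columns ``cluster_id``, ``object_class``
(``soma`` or ``medulla_axon``), ``pd``, ``dv``, ``ap``.  It is both the
output format of the synthetic generator and the ingest path for real
cell-counter exports.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from dcnsim.synthetic_cluster import SomaCloud

__all__ = ["write_profile", "read_profile", "PROFILE_COLUMNS"]

PROFILE_COLUMNS = ("cluster_id", "object_class", "pd", "dv", "ap")
_CLASSES = ("soma", "medulla_axon")


def write_profile(
    path: str | os.PathLike,
    clouds: Iterable[SomaCloud],
    axons: Mapping[str, np.ndarray] | None = None,
    sep: str = "\t",
) -> None:
    """Write clouds (and optional axon termini) as a coordinate profile.

    ``axons`` maps cluster_id to an ``(m, 3)`` array of medulla-axon
    coordinates; axon rows follow the soma rows of their cluster.
    """
    frames = []
    for cloud in clouds:
        frames.append(
            pd.DataFrame(
                {
                    "cluster_id": cloud.cluster_id,
                    "object_class": "soma",
                    "pd": cloud.points[:, 0],
                    "dv": cloud.points[:, 1],
                    "ap": cloud.points[:, 2],
                }
            )
        )
        if axons and cloud.cluster_id in axons:
            pts = np.atleast_2d(np.asarray(axons[cloud.cluster_id], dtype=float))
            frames.append(
                pd.DataFrame(
                    {
                        "cluster_id": cloud.cluster_id,
                        "object_class": "medulla_axon",
                        "pd": pts[:, 0],
                        "dv": pts[:, 1],
                        "ap": pts[:, 2],
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, sep=sep, index=False)


def read_profile(
    path: str | os.PathLike, sep: str | None = None
) -> tuple[list[SomaCloud], dict[str, np.ndarray]]:
    """Read a coordinate profile into clouds and per-cluster axon arrays.

    The delimiter is sniffed (tab or comma) unless given.  Returns the
    clouds in file order plus a dict mapping cluster_id to ``(m, 3)``
    medulla-axon coordinates for clusters that have axon rows.
    """
    table = pd.read_csv(path, sep=sep if sep is not None else None, engine="python")
    missing = set(PROFILE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"profile missing required columns: {sorted(missing)}")
    bad = set(table["object_class"].unique()) - set(_CLASSES)
    if bad:
        raise ValueError(f"unknown object_class values: {sorted(bad)}")
    clouds: list[SomaCloud] = []
    axons: dict[str, np.ndarray] = {}
    for cid, group in table.groupby("cluster_id", sort=False):
        soma = group[group["object_class"] == "soma"]
        if len(soma):
            pts = soma[["pd", "dv", "ap"]].to_numpy(dtype=float)
            clouds.append(
                SomaCloud(
                    cluster_id=str(cid),
                    points=pts,
                    provenance="measured",
                    allow_single=True,
                )
            )
        axon = group[group["object_class"] == "medulla_axon"]
        if len(axon):
            axons[str(cid)] = axon[["pd", "dv", "ap"]].to_numpy(dtype=float)
    return clouds, axons
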