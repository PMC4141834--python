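"""OTU x array community matrices and the standardizations applied to them.

A :class:`CommunityMatrix` wraps a pandas DataFrame (rows: OTUs, columns:
replicate arrays) together with a *kind* tag that enforces the pipeline
order: raw intensities are relativized by column (general relativization,
exponent 1 — each value divided by its sample total), optionally arcsine
square-root transformed, and only relativized/arcsine matrices may enter the
distance computations.  Row z-scoring is a display transform for heat plots
and terminates the pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .otu_calling import PresenceProfile

KINDS = ("raw", "relativized", "arcsine", "row_z")


class MatrixError(ValueError):
    pass


@dataclass
class CommunityMatrix:
    values: pd.DataFrame  # index: otu_id, columns: array ids
    kind: str
    column_samples: dict[str, str] = field(default_factory=dict)
    column_groups: dict[str, str] = field(default_factory=dict)
    constant_rows: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise MatrixError(f"unknown matrix kind {self.kind!r}")
        if self.kind != "row_z" and (self.values.values < 0).any():
            raise MatrixError("negative values in a non-z-scored matrix")
        if self.kind == "relativized":
            sums = self.values.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise MatrixError("relativized columns must sum to 1")
        if self.kind == "arcsine" and (self.values.values > math.pi / 2 + 1e-12).any():
            raise MatrixError("arcsine values must lie in [0, pi/2]")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    def presence(self) -> pd.DataFrame:
        """Boolean presence per (otu, array): strictly positive abundance."""
        return self.values > 0


def build_matrix(
    profiles: Iterable[PresenceProfile],
    include_rule: str = "consensus_any",
) -> CommunityMatrix:
    """Assemble the raw intensity matrix from per-sample presence profiles.

    Columns are replicate arrays (``sample/replicate``); rows are the OTUs
    called present in at least one sample (by replicate consensus, the
    default) or on at least one array (``include_rule='any_array'``).  A cell
    holds the replicate array's hybridization score when the OTU was called
    present on that array, else 0.
    """
    profiles = list(profiles)
    if include_rule not in ("consensus_any", "any_array"):
        raise MatrixError(f"unknown include_rule {include_rule!r}")
    keep: list[str] = []
    for prof in profiles:
        if include_rule == "consensus_any":
            hits = prof.present_otus
        else:
            hits = [
                otu
                for calls in prof.replicate_calls.values()
                for otu, c in calls.items()
                if c.present
            ]
        for otu in hits:
            if otu not in keep:
                keep.append(otu)
    if not keep:
        raise MatrixError("no OTU is present in any sample")
    columns: dict[str, dict[str, float]] = {}
    column_samples: dict[str, str] = {}
    column_groups: dict[str, str] = {}
    for prof in profiles:
        for rep_id, calls in prof.replicate_calls.items():
            col = f"{prof.sample_id}/{rep_id}"
            columns[col] = {
                otu: (
                    calls[otu].hybridization_score
                    if otu in calls and calls[otu].present
                    else 0.0
                )
                for otu in keep
            }
            column_samples[col] = prof.sample_id
            column_groups[col] = prof.condition_label
    df = pd.DataFrame(columns, index=keep).astype(float)
    return CommunityMatrix(df, "raw", column_samples, column_groups)


def relativize_columns(m: CommunityMatrix) -> CommunityMatrix:
    """General relativization by columns: divide by the column total."""
    if m.kind not in ("raw", "relativized"):
        raise MatrixError(f"cannot relativize a {m.kind!r} matrix")
    sums = m.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise MatrixError(f"zero-sum sample column(s): {list(zero.index)}")
    return CommunityMatrix(
        m.values / sums, "relativized", m.column_samples, m.column_groups
    )


def arcsine_sqrt(m: CommunityMatrix) -> CommunityMatrix:
    """Elementwise arcsin(sqrt(v)); requires a relativized matrix."""
    if m.kind != "relativized":
        raise MatrixError(f"arcsine transform requires a relativized matrix, got {m.kind!r}")
    v = m.values.values
    if (v < 0).any() or (v > 1).any():
        raise MatrixError("arcsine sqrt requires values in [0, 1]")
    return CommunityMatrix(
        pd.DataFrame(np.arcsin(np.sqrt(v)), index=m.values.index, columns=m.values.columns),
        "arcsine",
        m.column_samples,
        m.column_groups,
    )


def row_zscore(m: CommunityMatrix) -> CommunityMatrix:
    """Center and scale each row (OTU) for heat-plot display.

    Constant rows cannot be scaled; they map to all-zero rows and are flagged
    in ``constant_rows`` rather than raising.
    """
    if m.values.shape[1] < 2:
        raise MatrixError("row z-scoring needs at least 2 columns")
    v = m.values.values.astype(float)
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0)
    sd[constant, 0] = 1.0
    z = (v - mean) / sd
    z[constant, :] = 0.0
    return CommunityMatrix(
        pd.DataFrame(z, index=m.values.index, columns=m.values.columns),
        "row_z",
        m.column_samples,
        m.column_groups,
        constant_rows=tuple(np.asarray(m.values.index)[constant]),
    )


def write_matrix(m: CommunityMatrix, path, sidecar_path=None) -> None:
    m.values.to_csv(path, sep="\t", index_label="otu_id")
    if sidecar_path is not None:
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "kind": m.kind,
                    "column_samples": m.column_samples,
                    "column_groups": m.column_groups,
                    "constant_rows": list(m.constant_rows),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def read_matrix(path, sidecar_path) -> CommunityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="otu_id")
    with open(sidecar_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    return CommunityMatrix(
        df,
        meta["kind"],
        meta.get("column_samples", {}),
        meta.get("column_groups", {}),
        tuple(meta.get("constant_rows", ())),
    )
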