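"""Shared in-memory containers for the pipeline.

All matrices are pandas DataFrames with explicit gene/sample labels; the
containers validate the structural invariants once at construction so that
downstream stages can rely on them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EcotypingError",
    "InputError",
    "SizingError",
    "AlignmentError",
    "ExpressionMatrix",
    "SignatureMatrix",
    "CellFractions",
    "PurifiedExpression",
    "SurvivalData",
    "SyntheticTruth",
]


class EcotypingError(Exception):
    """Base class for pipeline errors."""


class InputError(EcotypingError, ValueError):
    """Malformed or insufficient input."""


class SizingError(InputError):
    """A requested simulation or model size cannot be satisfied."""


class AlignmentError(InputError):
    """Two objects that must share an index do not."""


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise InputError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared scale.

    ``scale`` is ``"linear"`` (non-negative intensities/counts) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise InputError(f"unknown scale {self.scale!r}")
        if not isinstance(self.values, pd.DataFrame):
            raise InputError("values must be a DataFrame (genes x samples)")
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise InputError("expression matrix contains non-finite values")
        if self.scale == "linear" and arr.size and arr.min() < 0:
            raise InputError("linear-scale expression must be non-negative")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale copy (2**x - 1, floored at 0, for log2 input)."""
        if self.scale == "linear":
            return self
        lin = np.maximum(np.exp2(self.values.to_numpy()) - 1.0, 0.0)
        return ExpressionMatrix(
            pd.DataFrame(lin, index=self.values.index, columns=self.values.columns),
            scale="linear",
        )


@dataclass
class SignatureMatrix:
    """Reference expression profiles (genes x cell types) for deconvolution."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise InputError("signature needs at least 2 cell types")
        _check_unique(self.values.index, "signature gene ids")
        _check_unique(self.values.columns, "signature cell types")
        arr = self.values.to_numpy()
        if (arr < 0).any():
            raise InputError("signature values must be non-negative")
        if (arr.sum(axis=1) == 0).any():
            raise InputError("signature contains all-zero gene rows")

    @property
    def cell_types(self) -> list:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)


@dataclass
class CellFractions:
    """Samples x cell types simplex matrix (rows sum to 1)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size:
            if arr.min() < -1e-12:
                raise InputError("fractions must be non-negative")
            sums = arr.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise InputError("fraction rows must sum to 1")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def cell_types(self) -> list:
        return list(self.values.columns)


@dataclass
class PurifiedExpression:
    """Cell-type-specific expression imputed from a bulk mixture.

    ``fitted_levels`` holds the per-gene regression levels for *all* cell
    types (genes x types); ``values`` is the per-sample matrix for
    ``cell_type``; ``reliability`` flags genes whose imputation for this
    type is trustworthy (True = reliable). Unreliable genes are flagged,
    never silently dropped.
    """

    cell_type: str
    values: pd.DataFrame
    fitted_levels: pd.DataFrame
    reliability: pd.Series

    def __post_init__(self) -> None:
        if self.values.to_numpy().size and self.values.to_numpy().min() < 0:
            raise InputError("purified expression must be non-negative")
        if not self.values.index.equals(self.reliability.index):
            raise AlignmentError("reliability mask must align with gene index")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def reliable(self) -> pd.DataFrame:
        """Return the sub-matrix restricted to reliable genes."""
        return self.values.loc[self.reliability]


@dataclass
class SurvivalData:
    """Right-censored survival outcomes, optionally with response labels.

    ``table`` is indexed by sample id with columns ``time`` (positive),
    ``event`` (0/1) and optionally ``response`` in
    {"responder", "non_responder"} and ``group``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.table.columns:
                raise InputError(f"survival table missing column {col!r}")
        _check_unique(self.table.index, "survival sample ids")
        t = self.table["time"].to_numpy(dtype=float)
        if (t <= 0).any() or not np.isfinite(t).all():
            bad = self.table.index[(t <= 0) | ~np.isfinite(t)].tolist()[:5]
            raise InputError(f"non-positive survival times for samples {bad}")
        ev = self.table["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise InputError("event must be binary 0/1")
        if "response" in self.table.columns:
            ok = self.table["response"].isin(["responder", "non_responder"])
            ok |= self.table["response"].isna()
            if not ok.all():
                raise InputError("response must be responder/non_responder")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    @property
    def time(self) -> pd.Series:
        return self.table["time"]

    @property
    def event(self) -> pd.Series:
        return self.table["event"]

    def subset(self, samples) -> "SurvivalData":
        return SurvivalData(self.table.loc[list(samples)].copy())


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated cohort.

    Holds everything a recovery test needs: which states exist per cell
    type, their marker genes and effect sizes, the cross-type state
    communities, every sample's community and per-type state, the cell
    fractions, community hazard multipliers and therapy-benefit states.
    ``profile_seed`` pins the per-type baseline expression profiles so a
    validation cohort drawn later shares them with the discovery cohort.
    """

    cell_types: list
    states_per_type: dict
    marker_map: dict  # (cell_type, state) -> {gene: log2 effect}
    community_defs: dict  # community -> {cell_type: state}
    sample_community: dict  # sample -> community
    sample_states: dict  # (sample, cell_type) -> state
    fractions: pd.DataFrame  # samples x types, rows sum to 1
    hazard_multipliers: dict  # community -> positive float
    response_benefit_states: set  # {(cell_type, state)}
    noise_rate: float
    seed: int
    profile_seed: int = -1
    gene_ids: list = field(default_factory=list)
    # log2 down-shift of a marker gene's baseline in the *other* cell types:
    # state markers are modeled as cell-type-restricted genes
    marker_restriction_log2: float = 3.0

    def __post_init__(self) -> None:
        if self.profile_seed < 0:
            self.profile_seed = self.seed
        rows = self.fractions.to_numpy()
        if rows.size:
            if rows.min() < 0 or not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise InputError("fraction rows must be a simplex")
        for comm, defs in self.community_defs.items():
            if len(defs) < 3 or len(set(defs)) < 3:
                raise InputError(
                    f"community {comm} must span >= 3 distinct cell types"
                )
        # marker sets disjoint across states within a type
        for ct in self.cell_types:
            seen: set = set()
            for s in range(self.states_per_type[ct]):
                genes = set(self.marker_map.get((ct, s), {}))
                if genes & seen:
                    raise InputError(f"overlapping marker sets within {ct}")
                seen |= genes

    @property
    def sample_ids(self) -> list:
        return list(self.fractions.index)

    def n_states(self) -> int:
        return int(sum(self.states_per_type.values()))

    def states_of(self, cell_type: str) -> pd.Series:
        """Planted state of every sample for one cell type."""
        return pd.Series(
            {s: self.sample_states[(s, cell_type)] for s in self.sample_ids},
            name=cell_type,
        ).loc[self.sample_ids]

    def replace(self, **kw) -> "SyntheticTruth":
        return dataclasses.replace(self, **kw)
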