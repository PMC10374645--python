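"""Reference-based recovery of discovered cell states in new cohorts.

The discovery basis W is held fixed and only the abundance matrix H' is
re-estimated, jointly over all new samples, by the same multiplicative
updates — the new cohort is expressed in the coordinate system of the
discovery model rather than re-clustered. Recovery of each state is then
scored by how well its discovery marker fold-changes are reproduced under
the recovered assignments, with significance from a permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EcotypingError, InputError, PurifiedExpression
from .states import StateModel, _EPS

__all__ = [
    "RecoveryResult",
    "CoverageError",
    "recover_abundances",
    "recovery_significance",
    "recovery_rate",
]

Z_THRESHOLD = 1.65
P_THRESHOLD = 0.05


class CoverageError(EcotypingError):
    """Too few model genes present in the new cohort."""


@dataclass
class RecoveryResult:
    """Recovered abundances and per-state significance in a new cohort."""

    cell_type: str
    H_prime: pd.DataFrame  # states x new samples, columns sum to 1
    assignments: pd.Series  # sample -> state
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    # stats columns: R, null_mean, null_sd, z, p, significant, reason

    def significant_states(self) -> list:
        if self.stats.empty:
            return []
        return list(self.stats.index[self.stats["significant"]])


def _transform_like_discovery(new_values: pd.DataFrame, model: StateModel):
    """Apply the discovery z-transform to a new cohort's purified matrix.

    Returns the non-negative split feature matrix over shared genes plus
    the list of shared genes. Genes missing from the new cohort are
    dropped, never imputed.
    """
    genes = [g for g in model.features.genes if g in new_values.index]
    if len(genes) < 0.5 * len(model.features.genes):
        raise CoverageError(
            f"only {len(genes)}/{len(model.features.genes)} model genes in "
            "new cohort (< 50% coverage)"
        )
    logm = np.log2(new_values.loc[genes].to_numpy(dtype=float) + 1.0)
    mu = model.features.means.loc[genes].to_numpy()
    sd = model.features.sds.loc[genes].to_numpy()
    z = (logm - mu[:, None]) / sd[:, None]
    feats = np.concatenate([np.maximum(z, 0.0), np.maximum(-z, 0.0)], axis=0)
    rows = [f"{g}+" for g in genes] + [f"{g}-" for g in genes]
    return pd.DataFrame(feats, index=rows, columns=new_values.columns), genes


def recover_abundances(
    new_matrix, model: StateModel, tol: float = 1e-6, max_iter: int = 2000
) -> RecoveryResult:
    """Re-solve H' on a new cohort with the discovery W fixed.

    ``new_matrix`` is a PurifiedExpression or a genes x samples DataFrame
    on the linear scale. H' is initialized uniformly (deterministic) and
    updated jointly over all samples; columns are renormalized to sum 1
    and hard assignments taken by argmax (lowest-index ties).
    """
    values = (
        new_matrix.values if isinstance(new_matrix, PurifiedExpression) else new_matrix
    )
    V_df, _ = _transform_like_discovery(values, model)
    W = model.W.loc[V_df.index].to_numpy()
    V = V_df.to_numpy()
    K = W.shape[1]
    H = np.full((K, V.shape[1]), max(V.mean(), _EPS) / K)
    wtv = W.T @ V
    wtw = W.T @ W
    norm_v = np.linalg.norm(V)
    prev = None
    for _ in range(max_iter):
        H *= wtv / (wtw @ H + _EPS)
        err = np.linalg.norm(V - W @ H)
        if prev is not None and abs(prev - err) <= tol * max(norm_v, _EPS):
            break
        prev = err
    sums = H.sum(axis=0)
    H_norm = np.where(sums > 0, H / np.where(sums > 0, sums, 1.0), 1.0 / K)
    idx = H_norm.argmax(axis=0)
    states = model.states
    labels = pd.Series(
        [states[i] for i in idx], index=V_df.columns, name=model.cell_type
    )
    return RecoveryResult(
        cell_type=model.cell_type,
        H_prime=pd.DataFrame(H_norm, index=states, columns=V_df.columns),
        assignments=labels,
    )


def _state_log2fc(values: pd.DataFrame, genes, in_mask: np.ndarray) -> np.ndarray:
    expr = values.loc[genes].to_numpy(dtype=float)
    m_in = expr[:, in_mask].mean(axis=1)
    m_out = expr[:, ~in_mask].mean(axis=1)
    return np.log2(m_in + 1.0) - np.log2(m_out + 1.0)


def recovery_significance(
    new_matrix,
    model: StateModel,
    recovery: RecoveryResult,
    n_perm: int = 1000,
    seed: int = 0,
    min_markers: int = 3,
    min_samples: int = 2,
) -> RecoveryResult:
    """Permutation test of state recovery.

    For each state s, R_s is the Pearson correlation between the
    discovery marker log2 fold-changes and the fold-changes recomputed in
    the new cohort under the recovered assignments. The null shuffles the
    pairing of marker-gene labels; z = (R - null mean)/null sd and the
    one-sided empirical p use the (count >= observed + 1)/(n_perm + 1)
    rule. A state is significant iff z > 1.65 and p < 0.05.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    values = (
        new_matrix.values if isinstance(new_matrix, PurifiedExpression) else new_matrix
    )
    rng = np.random.default_rng([int(seed), 11])
    rows = []
    for state in model.states:
        disc = model.marker_vector(state)
        genes = [g for g in disc.index if g in values.index]
        in_mask = (recovery.assignments == state).to_numpy()
        row = {
            "R": np.nan, "null_mean": np.nan, "null_sd": np.nan,
            "z": np.nan, "p": np.nan, "significant": False, "reason": "",
        }
        if in_mask.sum() < min_samples or (~in_mask).sum() < 1:
            row["reason"] = f"{int(in_mask.sum())} assigned samples"
        elif len(genes) < min_markers:
            row["reason"] = f"{len(genes)} markers present"
        else:
            v_disc = disc.loc[genes].to_numpy()
            v_new = _state_log2fc(values, genes, in_mask)
            if v_disc.std() == 0 or v_new.std() == 0:
                row["reason"] = "degenerate fold-change vector"
            else:
                r_obs = float(np.corrcoef(v_disc, v_new)[0, 1])
                null = np.empty(n_perm)
                for b in range(n_perm):
                    null[b] = np.corrcoef(v_disc, rng.permutation(v_new))[0, 1]
                null_sd = float(null.std(ddof=1))
                if null_sd == 0:
                    row["reason"] = "zero-variance permutation null"
                else:
                    z = (r_obs - float(null.mean())) / null_sd
                    p = (int((null >= r_obs).sum()) + 1) / (n_perm + 1)
                    row.update(
                        R=r_obs, null_mean=float(null.mean()), null_sd=null_sd,
                        z=float(z), p=float(p),
                        significant=bool(z > Z_THRESHOLD and p < P_THRESHOLD),
                    )
        rows.append(pd.Series(row, name=state))
    recovery.stats = pd.DataFrame(rows)
    return recovery


def recovery_rate(recovery: RecoveryResult) -> float:
    """Fraction of new-cohort samples assigned to a significant state."""
    if recovery.stats.empty:
        raise InputError("run recovery_significance first")
    sig = set(recovery.significant_states())
    if len(recovery.assignments) == 0:
        return 0.0
    return float(recovery.assignments.isin(sig).mean())
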