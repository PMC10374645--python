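"""Ecotype (multicellular community) discovery from state co-occurrence.

Each patient is reduced to one state per cell type (binary assignment
matrix); pairwise state co-occurrence across patients is measured by the
Jaccard index, gated by a hypergeometric overlap test, and the gated
similarity matrix is clustered hierarchically with the cluster count
chosen by silhouette maximization. Sample-level ecotype abundance is the
mean abundance of the member states, renormalized across ecotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.metrics import silhouette_score

from .containers import EcotypingError, InputError

__all__ = [
    "BinaryAssignmentMatrix",
    "EcotypeModel",
    "build_assignment_matrix",
    "jaccard_matrix",
    "overlap_significance",
    "filter_jaccard",
    "cluster_states",
    "assign_ecotypes",
    "discover_ecotypes",
]


@dataclass
class BinaryAssignmentMatrix:
    """States x samples 0/1 matrix; row ids are (cell type, state) pairs."""

    A: pd.DataFrame  # index: "celltype::state"
    state_types: pd.Series  # row id -> cell type
    unassigned: dict = field(default_factory=dict)  # cell type -> [samples]

    @property
    def sample_ids(self) -> list:
        return list(self.A.columns)

    @property
    def state_ids(self) -> list:
        return list(self.A.index)


@dataclass
class EcotypeModel:
    """Ecotype clustering result and per-sample ecotype composition."""

    jaccard: pd.DataFrame
    gated_jaccard: pd.DataFrame
    pair_p: pd.DataFrame
    ecotype_map: pd.Series  # state id -> ecotype label (dismissed states NaN)
    silhouette_by_k: dict
    chosen_k: int
    abundance: pd.DataFrame = field(default_factory=pd.DataFrame)
    dominant: pd.Series = field(default_factory=pd.Series)
    dismissed: list = field(default_factory=list)

    @property
    def ecotypes(self) -> list:
        return sorted(self.ecotype_map.dropna().unique())


def _state_id(cell_type, state) -> str:
    return f"{cell_type}::{state}"


def build_assignment_matrix(assignments: dict) -> BinaryAssignmentMatrix:
    """Binary matrix A: A[i, j] = 1 iff state i is assigned to patient j.

    ``assignments`` maps cell type -> StateAssignment (or a plain Series
    of sample -> state). Samples are the union across types; a sample
    with no assignment for a type gets all-zero rows there, and this is
    recorded in ``unassigned``.
    """
    if len(assignments) < 2:
        raise InputError("need >= 2 cell types with retained states")
    labels = {
        ct: (a.labels if hasattr(a, "labels") else pd.Series(a))
        for ct, a in assignments.items()
    }
    samples: list = []
    for lab in labels.values():
        samples.extend(s for s in lab.index if s not in samples)
    if not samples:
        raise InputError("empty sample universe")
    shared = set(samples)
    for lab in labels.values():
        shared &= set(lab.index)
    if not shared:
        raise InputError("no sample is assigned in every cell type")

    rows, types, unassigned = {}, {}, {}
    for ct, lab in labels.items():
        states = sorted(lab.unique())
        missing = [s for s in samples if s not in lab.index]
        if missing:
            unassigned[ct] = missing
        for st in states:
            rid = _state_id(ct, st)
            assigned = set(lab.index[lab == st])
            rows[rid] = [1 if s in assigned else 0 for s in samples]
            types[rid] = ct
    A = pd.DataFrame.from_dict(rows, orient="index", columns=samples).astype(int)
    return BinaryAssignmentMatrix(
        A=A, state_types=pd.Series(types), unassigned=unassigned
    )


def jaccard_matrix(bam: BinaryAssignmentMatrix) -> pd.DataFrame:
    """Pairwise Jaccard index of the sample sets of every state pair."""
    A = bam.A.to_numpy(dtype=bool)
    inter = (A[:, None, :] & A[None, :, :]).sum(axis=2).astype(float)
    union = (A[:, None, :] | A[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(J, 1.0)
    return pd.DataFrame(J, index=bam.state_ids, columns=bam.state_ids)


def overlap_significance(bam: BinaryAssignmentMatrix) -> pd.DataFrame:
    """Upper-tail hypergeometric p for the co-occurrence of each state pair.

    For states i, k of different cell types: the population is the set of
    samples assigned in both types; drawing state i's samples, the
    overlap with state k is tested against the no-association null.
    Same-type pairs (mutually exclusive by construction) get p = 1.
    """
    A = bam.A.to_numpy(dtype=bool)
    ids = bam.state_ids
    types = bam.state_types
    type_any = {
        ct: A[[types[r] == ct for r in ids]].any(axis=0)
        for ct in types.unique()
    }
    P = np.ones((len(ids), len(ids)))
    warned = False
    for i in range(len(ids)):
        for k in range(i + 1, len(ids)):
            ti, tk = types[ids[i]], types[ids[k]]
            if ti == tk:
                continue
            pop = type_any[ti] & type_any[tk]
            N = int(pop.sum())
            if N == 0:
                if not warned:
                    warnings.warn("empty population for a state pair", stacklevel=2)
                    warned = True
                continue
            n_i = int((A[i] & pop).sum())
            n_k = int((A[k] & pop).sum())
            x = int((A[i] & A[k] & pop).sum())
            p = float(hypergeom.sf(x - 1, N, n_k, n_i))
            P[i, k] = P[k, i] = min(p, 1.0)
    return pd.DataFrame(P, index=ids, columns=ids)


def filter_jaccard(
    J: pd.DataFrame,
    pair_p: pd.DataFrame,
    state_types: pd.Series,
    alpha: float = 0.01,
    gate: str = "standard",
) -> pd.DataFrame:
    """Significance-gate the Jaccard matrix.

    ``gate="standard"`` zeroes non-significant pairs and keeps the Jaccard
    value of significant ones. ``gate="literal"`` reproduces the inverted
    published wording (non-significant pairs set to 1, significant to 0);
    it is provided for comparison only. Same-cell-type pairs are always
    zeroed and the diagonal forced to 1.
    """
    if not J.index.equals(pair_p.index):
        raise InputError("J and p matrices must align")
    if gate not in ("standard", "literal"):
        raise InputError(f"unknown gate {gate!r}")
    Jv = J.to_numpy(dtype=float).copy()
    Pv = pair_p.to_numpy(dtype=float)
    if gate == "standard":
        Jv[Pv > alpha] = 0.0
    else:
        sig = Pv <= alpha
        Jv = np.where(sig, 0.0, 1.0)
    t = state_types.loc[J.index].to_numpy()
    Jv[t[:, None] == t[None, :]] = 0.0
    np.fill_diagonal(Jv, 1.0)
    return pd.DataFrame(Jv, index=J.index, columns=J.columns)


def cluster_states(gated_J: pd.DataFrame, k_range=None):
    """Average-linkage clustering of states on 1 - gated Jaccard.

    Returns ``(ecotype_map, silhouette_by_k, chosen_k)`` where chosen_k
    maximizes the mean silhouette width (ties to smaller k). Candidate k
    producing fewer than 2 effective clusters are skipped.
    """
    n = gated_J.shape[0]
    if n < 4:
        raise InputError("need >= 4 states to cluster")
    if k_range is None:
        k_range = range(2, min(20, n - 1) + 1)
    D = 1.0 - gated_J.to_numpy(dtype=float)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    sil: dict = {}
    labels_by_k: dict = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        lab = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = float(silhouette_score(D, lab, metric="precomputed"))
        labels_by_k[k] = lab
    if not sil:
        raise InputError("no candidate k produced a valid clustering")
    chosen_k = min(sorted(sil), key=lambda k: (-sil[k], k))
    lab = labels_by_k[chosen_k]
    # stable ecotype labels: order clusters by first appearance
    order: dict = {}
    for c in lab:
        if c not in order:
            order[c] = f"E{len(order) + 1}"
    ecotype_map = pd.Series([order[c] for c in lab], index=gated_J.index)
    return ecotype_map, sil, chosen_k


def assign_ecotypes(
    ecotype_map: pd.Series,
    abundances: dict,
    min_states: int = 3,
) -> tuple:
    """Per-sample ecotype abundance and dominant ecotype.

    ``abundances`` maps cell type -> states x samples abundance frame
    (columns normalized). Ecotypes with fewer than ``min_states`` member
    states are dismissed and their states left unassigned. Sample
    abundance of an ecotype is the mean abundance of its member states,
    renormalized across retained ecotypes; dominant is the argmax with
    lowest-label ties.
    """
    counts = ecotype_map.value_counts()
    retained = sorted(counts.index[counts >= min_states])
    dismissed = [
        (e, f"only {int(counts[e])} states") for e in counts.index
        if e not in retained
    ]
    if not retained:
        raise EcotypingError(
            f"all ecotypes dismissed (min_states={min_states}): {dismissed}"
        )
    cleaned = ecotype_map.where(ecotype_map.isin(retained))

    samples: list = []
    for H in abundances.values():
        samples.extend(s for s in H.columns if s not in samples)
    rows = np.zeros((len(retained), len(samples)))
    for ei, eco in enumerate(retained):
        member_vals = []
        for rid in cleaned.index[cleaned == eco]:
            ct, st = rid.split("::", 1)
            H = abundances[ct]
            # state labels may be plain or stringified in the frame index
            key = st if st in H.index else type(H.index[0])(st)
            member_vals.append(H.loc[key].reindex(samples).fillna(0.0).to_numpy())
        rows[ei] = np.mean(member_vals, axis=0)
    totals = rows.sum(axis=0)
    zero = totals <= 0
    rows[:, ~zero] /= totals[~zero]
    rows[:, zero] = 1.0 / len(retained)
    abundance = pd.DataFrame(rows.T, index=samples, columns=retained)
    dominant = pd.Series(
        [retained[i] for i in rows.argmax(axis=0)], index=samples, name="ecotype"
    )
    return cleaned, abundance, dominant, dismissed


def discover_ecotypes(
    assignments: dict,
    abundances: dict | None = None,
    alpha: float = 0.01,
    gate: str = "standard",
    min_states: int = 3,
    k_range=None,
) -> EcotypeModel:
    """Full ecotype discovery from per-type state assignments.

    When ``abundances`` is omitted, one-hot abundance (1 for the assigned
    state) is used, which makes the dominant ecotype a pure vote over
    member states.
    """
    bam = build_assignment_matrix(assignments)
    J = jaccard_matrix(bam)
    P = overlap_significance(bam)
    gated = filter_jaccard(J, P, bam.state_types, alpha=alpha, gate=gate)
    ecotype_map, sil, chosen_k = cluster_states(gated, k_range=k_range)
    if abundances is None:
        abundances = {}
        for ct in bam.state_types.unique():
            rows = [r for r in bam.state_ids if bam.state_types[r] == ct]
            H = bam.A.loc[rows].astype(float)
            H.index = [r.split("::", 1)[1] for r in rows]
            abundances[ct] = H
    cleaned, abundance, dominant, dismissed = assign_ecotypes(
        ecotype_map, abundances, min_states=min_states
    )
    return EcotypeModel(
        jaccard=J,
        gated_jaccard=gated,
        pair_p=P,
        ecotype_map=cleaned,
        silhouette_by_k=sil,
        chosen_k=chosen_k,
        abundance=abundance,
        dominant=dominant,
        dismissed=dismissed,
    )
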