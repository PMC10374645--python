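"""Cell-state discovery by consensus non-negative matrix factorization.

Per cell type, purified expression is log-transformed, z-scored per gene
and split into positive/negative parts (NMF needs non-negative input but
the informative signal is relative). For each candidate rank the
factorization is restarted from multiple seeds; the stability of sample
co-clustering across restarts is summarized by the cophenetic coefficient
of the consensus matrix, and the rank whose coefficient is closest to
0.95 is retained. States are then characterized by marker genes (argmax
basis loading + log2 fold-change) and filtered: fewer than 10 markers, or
an abundance profile that merely tracks total purified signal (the
false-positive proxy), drops a state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .containers import EcotypingError, InputError, PurifiedExpression

__all__ = [
    "NonnegFeatures",
    "StateModel",
    "StateAssignment",
    "DegenerateStateModelError",
    "nonneg_transform",
    "run_nmf",
    "stability_scan",
    "consensus_matrix",
    "cophenetic_coefficient",
    "select_rank",
    "extract_markers",
    "filter_states",
    "assign_states",
    "discover_states",
]

COPHENETIC_TARGET = 0.95
_EPS = 1e-12


class DegenerateStateModelError(EcotypingError):
    """Every state of a cell type was filtered out."""


@dataclass
class NonnegFeatures:
    """Non-negative feature matrix plus the transform needed to reapply it.

    Rows come in pairs ``gene+`` / ``gene-`` holding the positive and
    negative parts of each z-scored gene; ``means``/``sds`` are the
    per-gene log2 statistics frozen at discovery time so a validation
    cohort can be transformed identically.
    """

    values: pd.DataFrame  # 2*genes x samples, >= 0
    means: pd.Series
    sds: pd.Series

    @property
    def genes(self) -> list:
        return list(self.means.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class StateModel:
    """Fitted consensus-NMF state model for one cell type."""

    cell_type: str
    rank: int
    W: pd.DataFrame  # features x states
    H: pd.DataFrame  # states x samples, columns sum to 1 after filtering
    cophenetic_by_rank: dict
    features: NonnegFeatures
    markers: dict = field(default_factory=dict)  # state -> [(gene, log2fc)]
    dropped_states: list = field(default_factory=list)  # [(state, reason)]
    restart_count: int = 0
    seed: int = 0

    @property
    def states(self) -> list:
        return list(self.H.index)

    def marker_vector(self, state) -> pd.Series:
        """Discovery log2 fold-changes of a state's markers, indexed by gene."""
        return pd.Series(dict(self.markers.get(state, [])), dtype=float)


@dataclass
class StateAssignment:
    """Hard per-sample state labels for one cell type (argmax of H)."""

    cell_type: str
    labels: pd.Series  # sample -> state label
    abundance: pd.DataFrame  # the H used


def nonneg_transform(
    purified: PurifiedExpression, max_genes: int = 1000
) -> NonnegFeatures:
    """z-score reliable genes on log2(x+1) and split into +/- parts.

    Zero-variance genes are dropped with a warning; when more than
    ``max_genes`` reliable genes remain, the most variable ones (log
    scale) are kept. The signed z-matrix is recovered exactly as
    (positive part) - (negative part).
    """
    mat = purified.reliable()
    if mat.shape[1] < 2:
        raise InputError("need >= 2 samples")
    if mat.shape[0] < 10:
        raise InputError(
            f"only {mat.shape[0]} reliable genes for {purified.cell_type!r}"
        )
    logm = np.log2(mat.to_numpy(dtype=float) + 1.0)
    sds = logm.std(axis=1, ddof=0)
    keep = sds > 0
    if not keep.any():
        raise InputError("all reliable genes have zero variance")
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance genes", stacklevel=2
        )
    genes = mat.index[keep]
    logm, sds = logm[keep], sds[keep]
    if len(genes) > max_genes:
        order = np.argsort(-sds, kind="stable")[:max_genes]
        order = np.sort(order)
        genes, logm, sds = genes[order], logm[order], sds[order]
    means = logm.mean(axis=1)
    z = (logm - means[:, None]) / sds[:, None]
    feats = np.concatenate([np.maximum(z, 0.0), np.maximum(-z, 0.0)], axis=0)
    index = [f"{g}+" for g in genes] + [f"{g}-" for g in genes]
    return NonnegFeatures(
        values=pd.DataFrame(feats, index=index, columns=mat.columns),
        means=pd.Series(means, index=genes),
        sds=pd.Series(sds, index=genes),
    )


def _mu_nmf(V, W, H, update_w, tol, max_iter):
    """Multiplicative updates for the Frobenius objective.

    Returns (W, H, error trace). The objective is non-increasing.
    """
    trace = []
    norm_v = np.linalg.norm(V)
    prev = None
    for it in range(max_iter):
        if update_w:
            W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        H *= (W.T @ V) / ((W.T @ W) @ H + _EPS)
        err = np.linalg.norm(V - W @ H)
        if not np.isfinite(err):
            raise FloatingPointError(f"non-finite NMF objective at iter {it}")
        trace.append(err)
        if prev is not None and abs(prev - err) <= tol * max(norm_v, _EPS):
            break
        prev = err
    return W, H, trace


def run_nmf(
    features,
    rank: int,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
):
    """Restarted multiplicative-update NMF of a non-negative matrix.

    Returns a list of ``(W, H, trace)`` per restart; restart r uses the
    deterministic sub-seed stream (seed, rank, r).
    """
    V = features.values.to_numpy() if hasattr(features, "values") else np.asarray(features)
    V = np.asarray(V, dtype=float)
    n_feat, n_samp = V.shape
    if rank >= min(n_feat, n_samp):
        raise InputError(f"rank {rank} >= min matrix dimension")
    if n_restarts < 1:
        raise InputError("need >= 1 restart")
    scale = np.sqrt(max(V.mean(), _EPS) / rank)
    fits = []
    for r in range(n_restarts):
        rng = np.random.default_rng([int(seed), int(rank), r])
        W = scale * rng.uniform(1e-3, 1.0, size=(n_feat, rank))
        H = scale * rng.uniform(1e-3, 1.0, size=(rank, n_samp))
        fits.append(_mu_nmf(V, W, H, True, tol, max_iter))
    return fits


def stability_scan(
    features,
    k_range,
    n_restarts: int = 20,
    seed: int = 0,
    sample_subsample: float = 0.8,
    feature_subsample: float = 0.8,
    perturb_sd: float = 1.75,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> dict:
    """Cophenetic stability of consensus clustering at each candidate rank.

    Each restart factorizes a randomly subsampled (samples and features)
    and noise-perturbed copy of the matrix; the consensus matrix over
    restarts summarizes how reproducible the argmax sample clustering is
    at that rank. ``perturb_sd`` is additive Gaussian noise on the
    z-score feature scale (clipped at 0). Its default, 1.75, is of the
    order of a typical state effect: structure weaker than a real state
    dissolves under the perturbation, so a stability near 1 is reachable
    only by rank choices that capture genuine states, and the selection
    target of 0.95 marks "as stable as true structure gets". With
    ``perturb_sd=0`` and unit subsampling fractions this reduces to
    plain restarted-NMF consensus.
    """
    V = features.values.to_numpy() if hasattr(features, "values") else np.asarray(features)
    V = np.asarray(V, dtype=float)
    n_feat, n_samp = V.shape
    if not 0 < sample_subsample <= 1 or not 0 < feature_subsample <= 1:
        raise InputError("subsample fractions must be in (0, 1]")
    coph: dict = {}
    for k in k_range:
        labels, col_sets = [], []
        for r in range(n_restarts):
            rng = np.random.default_rng([int(seed), int(k), 101, r])
            cols = np.sort(
                rng.choice(
                    n_samp,
                    size=max(k + 1, int(round(sample_subsample * n_samp))),
                    replace=False,
                )
            )
            rows = np.sort(
                rng.choice(
                    n_feat,
                    size=max(k + 1, int(round(feature_subsample * n_feat))),
                    replace=False,
                )
            )
            Vr = V[np.ix_(rows, cols)]
            if perturb_sd > 0:
                Vr = np.maximum(Vr + rng.normal(0.0, perturb_sd, Vr.shape), 0.0)
            scale = np.sqrt(max(Vr.mean(), _EPS) / k)
            W = scale * rng.uniform(1e-3, 1.0, size=(Vr.shape[0], k))
            H = scale * rng.uniform(1e-3, 1.0, size=(k, len(cols)))
            _, H, _ = _mu_nmf(Vr, W, H, True, tol, max_iter)
            labels.append(_argmax_labels(H))
            col_sets.append(cols)
        C = consensus_matrix(labels, sample_sets=col_sets, n_samples=n_samp)
        coph[k] = cophenetic_coefficient(C)
    return coph


def consensus_matrix(restart_assignments, sample_sets=None, n_samples=None) -> np.ndarray:
    """Co-clustering frequency across restarts.

    ``restart_assignments`` is a sequence of integer label vectors (one
    per restart, argmax of each restart's H). When restarts cover only a
    subset of samples, ``sample_sets`` gives the column indices used by
    each restart and entries are normalized by co-inclusion counts;
    pairs never co-included get 0.
    """
    labels = [np.asarray(a) for a in restart_assignments]
    if len(labels) < 2:
        raise InputError("need >= 2 restarts for a consensus matrix")
    if sample_sets is None:
        n = len(labels[0])
        C = np.zeros((n, n))
        for lab in labels:
            C += lab[:, None] == lab[None, :]
        C /= len(labels)
    else:
        if n_samples is None:
            n_samples = int(max(max(s) for s in sample_sets)) + 1
        conn = np.zeros((n_samples, n_samples))
        incl = np.zeros((n_samples, n_samples))
        for lab, cols in zip(labels, sample_sets):
            cols = np.asarray(cols)
            ix = np.ix_(cols, cols)
            conn[ix] += lab[:, None] == lab[None, :]
            incl[ix] += 1
        C = np.where(incl > 0, conn / np.maximum(incl, 1), 0.0)
    np.fill_diagonal(C, 1.0)
    return C


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of average-linkage clustering of 1 - consensus.

    Constant dissimilarities (perfectly stable clustering) are defined as
    1 by convention.
    """
    C = np.asarray(consensus, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-8):
        raise InputError("consensus must be square and symmetric")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    d = squareform(D, checks=False)
    if np.ptp(d) == 0:
        warnings.warn("constant consensus; cophenetic set to 1", stacklevel=2)
        return 1.0
    Z = average(d)
    c, _ = cophenet(Z, d)
    if not np.isfinite(c):
        return 1.0
    return float(min(max(c, 0.0), 1.0))


def select_rank(cophenetic_by_rank: dict, target: float = COPHENETIC_TARGET) -> int:
    """Rank whose cophenetic coefficient is closest to the target (0.95).

    Ties break toward the smaller rank.
    """
    if not cophenetic_by_rank:
        raise InputError("empty cophenetic map")
    return min(
        sorted(cophenetic_by_rank),
        key=lambda k: (abs(cophenetic_by_rank[k] - target), k),
    )


def _argmax_labels(H: np.ndarray) -> np.ndarray:
    # np.argmax breaks ties toward the lowest index, as required
    return H.argmax(axis=0)


def extract_markers(
    model: StateModel,
    purified: PurifiedExpression,
    assignment: "StateAssignment",
    min_log2fc: float = 1.0,
) -> dict:
    """Marker genes per state: argmax basis loading + fold-change gate.

    A gene is a marker of state s iff its row-normalized positive-part W
    loading is maximal in s and its log2 fold-change (mean purified
    linear expression in s vs all other states, pseudocount 1) is at
    least ``min_log2fc``. Marker sets are disjoint by the argmax rule.
    """
    genes = model.features.genes
    Wpos = model.W.loc[[f"{g}+" for g in genes]].to_numpy()
    row_sum = Wpos.sum(axis=1, keepdims=True)
    ok = row_sum[:, 0] > 0
    loading_state = np.full(len(genes), -1)
    loading_state[ok] = Wpos[ok].argmax(axis=1)

    labels = assignment.labels
    expr = purified.values.loc[genes, labels.index].to_numpy(dtype=float)
    markers: dict = {}
    for si, state in enumerate(model.states):
        in_mask = (labels == state).to_numpy()
        if not in_mask.any():
            warnings.warn(f"state {state} has no samples", stacklevel=2)
            markers[state] = []
            continue
        if in_mask.all():
            markers[state] = []
            continue
        m_in = expr[:, in_mask].mean(axis=1)
        m_out = expr[:, ~in_mask].mean(axis=1)
        lfc = np.log2(m_in + 1.0) - np.log2(m_out + 1.0)
        sel = (loading_state == si) & (lfc >= min_log2fc)
        order = np.argsort(-lfc[sel], kind="stable")
        chosen = np.flatnonzero(sel)[order]
        markers[state] = [(genes[g], float(lfc[g])) for g in chosen]
    return markers


def filter_states(
    model: StateModel,
    purified: PurifiedExpression,
    min_markers: int = 10,
    afi_threshold: float = 0.4,
    use_afi: bool = True,
) -> StateModel:
    """Drop low-evidence states and renormalize abundances.

    States with fewer than ``min_markers`` markers are removed; so are
    states whose *relative* abundance (H column-normalized to sum 1) is
    strongly correlated (|Spearman| > ``afi_threshold``) with per-sample
    total purified signal over *held-out* genes — genes the
    factorization never saw. A genuine state is defined by its feature
    genes and cannot drive the expression of genes outside them, whereas
    a component capturing a global signal-level artifact inflates every
    gene; the held-out total isolates the artifact case. When every gene
    was used as a feature the check is skipped with a warning. Remaining
    H columns are renormalized to sum 1.
    """
    if not model.markers:
        raise InputError("markers must be extracted before filtering")
    feature_genes = set(model.features.genes)
    held_out = [g for g in purified.values.index if g not in feature_genes]
    total = None
    if held_out:
        total = purified.values.loc[held_out, model.H.columns].sum(axis=0).to_numpy()
    elif use_afi:
        warnings.warn(
            "no held-out genes; artifact (AFI) check skipped", stacklevel=2
        )
    h_rel = model.H.to_numpy()
    h_rel = h_rel / np.maximum(h_rel.sum(axis=0, keepdims=True), _EPS)
    dropped = list(model.dropped_states)
    keep = []
    for state in model.states:
        n_mark = len(model.markers.get(state, []))
        if n_mark < min_markers:
            dropped.append((state, f"only {n_mark} markers (< {min_markers})"))
            continue
        if use_afi and total is not None:
            rho = spearmanr(h_rel[model.states.index(state)], total)[0]
            if np.isfinite(rho) and abs(rho) > afi_threshold:
                dropped.append(
                    (state, f"abundance tracks total signal (|rho|={abs(rho):.2f})")
                )
                continue
        keep.append(state)
    if not keep:
        raise DegenerateStateModelError(
            f"all states of {model.cell_type!r} filtered out: {dropped}"
        )
    H = model.H.loc[keep].copy()
    sums = H.sum(axis=0)
    zero = sums <= 0
    H.loc[:, ~zero.to_numpy()] = H.loc[:, ~zero.to_numpy()].div(sums[~zero], axis=1)
    if zero.any():
        H.loc[:, zero.to_numpy()] = 1.0 / len(keep)
    return StateModel(
        cell_type=model.cell_type,
        rank=len(keep),
        W=model.W[keep],
        H=H,
        cophenetic_by_rank=model.cophenetic_by_rank,
        features=model.features,
        markers={s: model.markers[s] for s in keep},
        dropped_states=dropped,
        restart_count=model.restart_count,
        seed=model.seed,
    )


def assign_states(model: StateModel) -> StateAssignment:
    """Hard assignment: most abundant state per sample (lowest-index ties)."""
    H = model.H.to_numpy()
    idx = _argmax_labels(H)
    labels = pd.Series(
        [model.states[i] for i in idx], index=model.H.columns, name=model.cell_type
    )
    return StateAssignment(
        cell_type=model.cell_type, labels=labels, abundance=model.H
    )


def discover_states(
    purified: PurifiedExpression,
    k_range=None,
    n_restarts: int = 20,
    seed: int = 0,
    max_genes: int = 1000,
    min_markers: int = 10,
    min_log2fc: float = 1.0,
    afi_threshold: float = 0.4,
    use_afi: bool = True,
    tol: float = 1e-6,
    max_iter: int = 2000,
    sample_subsample: float = 0.8,
    feature_subsample: float = 0.8,
    perturb_sd: float = 1.75,
):
    """End-to-end state discovery for one cell type.

    Scans ranks (default 2..min(20, n_samples-1)) with perturbed
    consensus restarts (see :func:`stability_scan`), selects the rank
    with cophenetic coefficient closest to 0.95, refits on the full
    unperturbed feature matrix at that rank (best reconstruction over
    restarts), extracts markers, filters states and assigns samples.
    Returns ``(StateModel, StateAssignment)``.
    """
    feats = nonneg_transform(purified, max_genes=max_genes)
    n_samples = len(feats.sample_ids)
    if k_range is None:
        k_range = range(2, min(20, n_samples - 1) + 1)
    k_range = [k for k in k_range if k < min(feats.values.shape)]
    if not k_range:
        raise InputError("no admissible rank to scan")

    coph = stability_scan(
        feats, k_range, n_restarts=n_restarts, seed=seed,
        sample_subsample=sample_subsample,
        feature_subsample=feature_subsample,
        perturb_sd=perturb_sd, tol=tol, max_iter=max_iter,
    )
    k_star = select_rank(coph)

    full = run_nmf(
        feats, k_star, n_restarts=n_restarts, seed=seed + 1,
        tol=tol, max_iter=max_iter,
    )
    best = min(full, key=lambda f: f[2][-1])
    W, H = best[0], best[1]
    state_ids = [f"S{i + 1:02d}" for i in range(k_star)]
    model = StateModel(
        cell_type=purified.cell_type,
        rank=k_star,
        W=pd.DataFrame(W, index=feats.values.index, columns=state_ids),
        H=pd.DataFrame(H, index=state_ids, columns=feats.values.columns),
        cophenetic_by_rank=coph,
        features=feats,
        restart_count=n_restarts,
        seed=seed,
    )
    assignment = assign_states(model)
    model.markers = extract_markers(model, purified, assignment, min_log2fc)
    model = filter_states(
        model, purified, min_markers=min_markers,
        afi_threshold=afi_threshold, use_afi=use_afi,
    )
    assignment = assign_states(model)
    return model, assignment
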