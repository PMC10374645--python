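"""Synthetic bulk cohorts with planted cell states, communities and outcomes.

The generator emulates the statistical structure of bulk tumor microarray
cohorts as the downstream analysis assumes it: a few cell types mixed with
Dirichlet fractions, discrete transcriptional states per type marked by
disjoint gene sets with log2 up-shifts, cross-type state co-occurrence
communities, multiplicative log-normal measurement noise, right-censored
exponential survival with community-dependent hazards and binary therapy
response. All randomness is driven by explicit integer seeds and every
draw is reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import (
    AlignmentError,
    ExpressionMatrix,
    InputError,
    SignatureMatrix,
    SizingError,
    SurvivalData,
    SyntheticTruth,
)

__all__ = [
    "generate_truth",
    "simulate_fractions",
    "simulate_bulk",
    "simulate_validation_cohort",
    "simulate_survival",
    "simulate_response",
    "true_signature",
]

# log2 mean / sd of per-gene per-type baseline expression: microarray-like
# dynamic range.
DEFAULT_BASELINE = (3.0, 1.5)


def _rng(*seeds: int) -> np.random.Generator:
    return np.random.default_rng(list(seeds))


def _community_definitions(
    cell_types, k_per_type, n_communities, rng
) -> dict:
    """Pick one state per cell type for each community.

    Construction guarantees that every state of every type appears in some
    community whenever ``n_communities >= max K``, and that community state
    vectors are pairwise distinct.
    """
    n_possible = int(np.prod([k_per_type[c] for c in cell_types]))
    if n_communities > n_possible:
        raise SizingError(
            f"cannot form {n_communities} distinct communities from "
            f"{n_possible} possible state combinations"
        )
    perms = {c: rng.permutation(k_per_type[c]) for c in cell_types}
    defs = {
        j: {c: int(perms[c][j % k_per_type[c]]) for c in cell_types}
        for j in range(n_communities)
    }
    # resolve duplicate vectors (possible when n_communities exceeds every
    # lcm-cycle) by nudging one coordinate to an unused combination
    seen = {tuple(sorted(defs[0].items()))}
    for j in range(1, n_communities):
        key = tuple(sorted(defs[j].items()))
        guard = 0
        while key in seen:
            ct = cell_types[guard % len(cell_types)]
            defs[j][ct] = int((defs[j][ct] + 1) % k_per_type[ct])
            key = tuple(sorted(defs[j].items()))
            guard += 1
            if guard > n_possible:
                raise SizingError("could not build distinct communities")
        seen.add(key)
    return defs


def generate_truth(
    n_genes: int,
    cell_types,
    k_per_type: dict,
    n_markers_per_state: int = 20,
    effect_size_log2: float = 2.0,
    n_communities: int = 3,
    community_noise_rate: float = 0.1,
    n_samples: int = 200,
    seed: int = 0,
    dirichlet_concentration: float = 5.0,
    hazard_multipliers: dict | None = None,
    response_benefit_states: set | None = None,
    marker_restriction_log2: float = 3.0,
) -> SyntheticTruth:
    """Plant the ground truth of a synthetic cohort.

    Marker gene sets are globally disjoint across all (cell type, state)
    pairs, and marker genes are cell-type-restricted: their baseline in
    every other cell type is shifted down by ``marker_restriction_log2``
    (state markers are expressed chiefly in their own lineage). Each
    sample gets a community label; its per-type state follows the
    community definition except for an independent per-(sample, type)
    reassignment to a uniformly random *other* state of that type with
    probability ``community_noise_rate``.
    """
    cell_types = list(cell_types)
    if len(cell_types) < 3:
        raise InputError("need >= 3 cell types to form communities")
    if any(k_per_type[c] < 2 for c in cell_types):
        raise InputError("every cell type needs >= 2 states")
    if not 0 <= community_noise_rate <= 0.5:
        raise InputError("community_noise_rate must be in [0, 0.5]")
    total_states = sum(k_per_type[c] for c in cell_types)
    needed = max(50 * total_states, n_markers_per_state * total_states)
    if n_genes < needed:
        raise SizingError(
            f"n_genes={n_genes} too small for {total_states} states: "
            f"need >= {needed} (deficit {needed - n_genes})"
        )

    rng = _rng(seed, 1)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    marker_pool = rng.permutation(n_genes)
    marker_map: dict = {}
    pos = 0
    for ct in cell_types:
        for s in range(k_per_type[ct]):
            genes = marker_pool[pos : pos + n_markers_per_state]
            pos += n_markers_per_state
            # per-marker effect heterogeneity (uniform 0.5-1.5x the nominal
            # effect): real state markers span a range of fold changes, and
            # a constant effect would make marker fold-change profiles
            # uninformative as state fingerprints
            marker_map[(ct, s)] = {
                gene_ids[g]: float(effect_size_log2 * rng.uniform(0.5, 1.5))
                for g in genes
            }

    community_defs = _community_definitions(
        cell_types, k_per_type, n_communities, rng
    )

    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    comm_labels = rng.integers(0, n_communities, size=n_samples)
    sample_community = dict(zip(sample_ids, (int(c) for c in comm_labels)))
    sample_states: dict = {}
    for sid, comm in sample_community.items():
        for ct in cell_types:
            state = community_defs[comm][ct]
            if rng.random() < community_noise_rate:
                others = [k for k in range(k_per_type[ct]) if k != state]
                state = int(rng.choice(others))
            sample_states[(sid, ct)] = int(state)

    fractions = pd.DataFrame(
        rng.dirichlet(
            np.full(len(cell_types), float(dirichlet_concentration)), n_samples
        ),
        index=sample_ids,
        columns=cell_types,
    )

    if hazard_multipliers is None:
        hazard_multipliers = {c: 1.0 for c in range(n_communities)}
        hazard_multipliers[0] = 2.0
        if n_communities > 1:
            hazard_multipliers[1] = 0.5

    return SyntheticTruth(
        cell_types=cell_types,
        states_per_type=dict(k_per_type),
        marker_map=marker_map,
        community_defs=community_defs,
        sample_community=sample_community,
        sample_states=sample_states,
        fractions=fractions,
        hazard_multipliers={int(k): float(v) for k, v in hazard_multipliers.items()},
        response_benefit_states=set(response_benefit_states or ()),
        noise_rate=float(community_noise_rate),
        seed=int(seed),
        gene_ids=gene_ids,
        marker_restriction_log2=float(marker_restriction_log2),
    )


def simulate_fractions(
    truth: SyntheticTruth, dirichlet_concentration=5.0, seed: int = 0
) -> pd.DataFrame:
    """Redraw the samples x types Dirichlet fraction matrix."""
    alpha = np.asarray(dirichlet_concentration, dtype=float)
    if alpha.ndim == 0:
        alpha = np.full(len(truth.cell_types), float(alpha))
    if alpha.shape != (len(truth.cell_types),):
        raise InputError("concentration must be scalar or one value per type")
    if (alpha <= 0).any():
        raise InputError("Dirichlet concentration must be positive")
    rng = _rng(seed, 2)
    vals = rng.dirichlet(alpha, len(truth.sample_ids))
    vals = vals / vals.sum(axis=1, keepdims=True)
    return pd.DataFrame(vals, index=truth.sample_ids, columns=truth.cell_types)


def _state_profiles(truth: SyntheticTruth, baseline_dist_params) -> dict:
    """Per-type, per-state linear expression profiles, pinned to profile_seed."""
    mu, sd = baseline_dist_params
    rng = _rng(truth.profile_seed, 3)
    genes = truth.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    base = np.exp2(rng.normal(mu, sd, size=(len(genes), len(truth.cell_types))))
    # markers are restricted to their own lineage: damp their baseline
    # in every other cell type
    if truth.marker_restriction_log2 > 0:
        damp = 2.0 ** (-truth.marker_restriction_log2)
        for (ct, _s), genes_eff in truth.marker_map.items():
            ci = truth.cell_types.index(ct)
            for g in genes_eff:
                row = gene_pos[g]
                for cj in range(len(truth.cell_types)):
                    if cj != ci:
                        base[row, cj] *= damp
    profiles: dict = {}
    for ci, ct in enumerate(truth.cell_types):
        for s in range(truth.states_per_type[ct]):
            prof = base[:, ci].copy()
            for g, eff in truth.marker_map[(ct, s)].items():
                prof[gene_pos[g]] *= 2.0**eff
            profiles[(ct, s)] = prof
    return profiles


def simulate_bulk(
    truth: SyntheticTruth,
    fractions: pd.DataFrame | None = None,
    baseline_dist_params=DEFAULT_BASELINE,
    noise_sd_log2: float = 0.5,
    seed: int = 0,
) -> ExpressionMatrix:
    """Mix per-state profiles into a linear-scale bulk matrix.

    bulk[g, s] = sum_c f[s, c] * x[g, c, state(s, c)], then multiplied by
    2**N(0, noise_sd_log2) measurement noise. With ``noise_sd_log2=0`` the
    mixture identity holds exactly.
    """
    if fractions is None:
        fractions = truth.fractions
    if list(fractions.index) != truth.sample_ids:
        raise AlignmentError("fractions rows must match truth samples")
    if not truth.gene_ids:
        raise InputError("truth carries no gene list")
    profiles = _state_profiles(truth, baseline_dist_params)
    n_g, n_s = len(truth.gene_ids), len(truth.sample_ids)
    bulk = np.zeros((n_g, n_s))
    f = fractions.to_numpy()
    for ci, ct in enumerate(truth.cell_types):
        states = np.array(
            [truth.sample_states[(sid, ct)] for sid in truth.sample_ids],
            dtype=int,
        )
        prof_mat = np.stack(
            [profiles[(ct, k)] for k in range(truth.states_per_type[ct])], axis=1
        )
        bulk += prof_mat[:, states] * f[:, ci]
    if noise_sd_log2 > 0:
        rng = _rng(seed, 4)
        bulk *= np.exp2(rng.normal(0.0, noise_sd_log2, size=bulk.shape))
    return ExpressionMatrix(
        pd.DataFrame(bulk, index=truth.gene_ids, columns=truth.sample_ids),
        scale="linear",
    )


def true_signature(
    truth: SyntheticTruth, baseline_dist_params=DEFAULT_BASELINE
) -> SignatureMatrix:
    """State-averaged per-type profiles: the oracle signature matrix."""
    profiles = _state_profiles(truth, baseline_dist_params)
    cols = {}
    for ct in truth.cell_types:
        cols[ct] = np.mean(
            [profiles[(ct, k)] for k in range(truth.states_per_type[ct])], axis=0
        )
    return SignatureMatrix(pd.DataFrame(cols, index=truth.gene_ids))


def simulate_validation_cohort(
    truth: SyntheticTruth,
    n_samples: int,
    seed: int = 1,
    baseline_dist_params=DEFAULT_BASELINE,
    noise_sd_log2: float = 0.5,
    dirichlet_concentration: float = 5.0,
):
    """Draw a held-out cohort from the same generative process.

    Returns ``(ExpressionMatrix, SyntheticTruth)``; the new truth shares
    the marker map, community definitions and baseline profiles
    (``profile_seed``) with the discovery truth but has fresh samples with
    disjoint ids (``V`` prefix).
    """
    rng = _rng(seed, 5)
    sample_ids = [f"V{i:04d}" for i in range(n_samples)]
    n_comm = len(truth.community_defs)
    comm = rng.integers(0, n_comm, size=n_samples)
    sample_community = dict(zip(sample_ids, (int(c) for c in comm)))
    sample_states = {}
    for sid, cj in sample_community.items():
        for ct in truth.cell_types:
            state = truth.community_defs[cj][ct]
            if rng.random() < truth.noise_rate:
                others = [
                    k for k in range(truth.states_per_type[ct]) if k != state
                ]
                state = int(rng.choice(others))
            sample_states[(sid, ct)] = int(state)
    alpha = np.full(len(truth.cell_types), float(dirichlet_concentration))
    fractions = pd.DataFrame(
        rng.dirichlet(alpha, n_samples) if n_samples else
        np.zeros((0, len(truth.cell_types))),
        index=sample_ids,
        columns=truth.cell_types,
    )
    val_truth = truth.replace(
        sample_community=sample_community,
        sample_states=sample_states,
        fractions=fractions,
        seed=int(seed),
        profile_seed=truth.profile_seed,
    )
    bulk = simulate_bulk(
        val_truth,
        baseline_dist_params=baseline_dist_params,
        noise_sd_log2=noise_sd_log2,
        seed=seed,
    )
    return bulk, val_truth


def _sample_hazards(truth: SyntheticTruth, baseline_hazard: float) -> np.ndarray:
    mult = np.array(
        [truth.hazard_multipliers.get(truth.sample_community[s], 1.0)
         for s in truth.sample_ids]
    )
    return baseline_hazard * mult


def _censoring_rate_for(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate whose marginal censoring fraction is target.

    For event rate h and censoring rate c, P(censored) = c / (h + c); the
    marginal fraction is the mean over samples, monotone in c, so the root
    is bracketed and unique.
    """

    def frac(c):
        return float(np.mean(c / (hazards + c))) - target

    lo, hi = 1e-12, float(hazards.max()) * 1e12
    return brentq(frac, lo, hi, xtol=1e-14, rtol=1e-12)


def simulate_survival(
    truth: SyntheticTruth,
    baseline_hazard: float = 0.05,
    censoring_rate: float = 0.2,
    seed: int = 0,
) -> SurvivalData:
    """Exponential survival with community-dependent hazard multipliers."""
    if baseline_hazard <= 0:
        raise InputError("baseline_hazard must be positive")
    if not 0 <= censoring_rate < 1:
        raise InputError("censoring_rate must be in [0, 1)")
    rng = _rng(seed, 6)
    hazards = _sample_hazards(truth, baseline_hazard)
    t_event = rng.exponential(1.0 / hazards)
    if censoring_rate > 0:
        c = _censoring_rate_for(hazards, censoring_rate)
        t_cens = rng.exponential(1.0 / c, size=len(hazards))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(hazards), dtype=int)
    tab = pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index(truth.sample_ids, name="sample_id"),
    )
    return SurvivalData(tab)


def simulate_response(
    truth: SyntheticTruth,
    benefit_hazard_reduction: float = 0.5,
    baseline_hazard: float = 0.05,
    censoring_rate: float = 0.0,
    seed: int = 0,
) -> SurvivalData:
    """Survival with 50/50 response labels and a planted treatment benefit.

    Response labels are assigned independently of states (no confounding);
    a responder whose planted state for some type is in
    ``truth.response_benefit_states`` has its hazard multiplied by
    ``benefit_hazard_reduction``.
    """
    if not 0 < benefit_hazard_reduction <= 1:
        raise InputError("benefit_hazard_reduction must be in (0, 1]")
    rng = _rng(seed, 7)
    n = len(truth.sample_ids)
    responder = rng.random(n) < 0.5
    hazards = _sample_hazards(truth, baseline_hazard)
    in_benefit = np.array(
        [
            any(
                (ct, truth.sample_states[(s, ct)])
                in truth.response_benefit_states
                for ct in truth.cell_types
            )
            for s in truth.sample_ids
        ]
    )
    hazards = np.where(
        responder & in_benefit, hazards * benefit_hazard_reduction, hazards
    )
    t_event = rng.exponential(1.0 / hazards)
    if censoring_rate > 0:
        c = _censoring_rate_for(hazards, censoring_rate)
        t_cens = rng.exponential(1.0 / c, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    tab = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "response": np.where(responder, "responder", "non_responder"),
        },
        index=pd.Index(truth.sample_ids, name="sample_id"),
    )
    if not in_benefit.any() and truth.response_benefit_states:
        warnings.warn("no sample falls in a benefit state", stacklevel=2)
    return SurvivalData(tab)
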