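"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (first column gene id, header sample
ids), gene sets as GMT, clinical tables as TSV, models and truth objects
as JSON + TSV sidecars. Write-then-read round-trips reproduce the
in-memory objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    InputError,
    SignatureMatrix,
    SurvivalData,
    SyntheticTruth,
)
from .enrichment import GeneSetCollection
from .states import NonnegFeatures, StateModel

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_signature_tsv",
    "read_gmt",
    "write_gmt",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "write_truth_json",
    "read_truth_json",
    "write_state_model",
    "read_state_model",
]

LOG2_MAX = 30.0  # matrices whose max value is below this look log-scaled

_FLOAT_FMT = "%.10g"


def read_expression_tsv(
    path, scale_hint: str | None = None, duplicate_genes: str = "max"
) -> ExpressionMatrix:
    """Read a genes x samples TSV expression matrix.

    Duplicate gene rows are collapsed (default: per-sample maximum, the
    usual multi-probe rule; ``duplicate_genes="mean"`` averages instead).
    Duplicate sample columns are rejected. Scale is auto-detected (max
    value < 30 => log2) unless ``scale_hint`` is given.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if pd.Index(header[1:]).has_duplicates:
        raise InputError(f"{path}: duplicate sample ids")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path} is empty") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise InputError(f"{path} has no data")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else "?"
            raise InputError(
                f"{path}: non-numeric value at gene {row!r}, sample {col!r}"
            )
    if df.index.has_duplicates:
        if duplicate_genes == "max":
            df = df.groupby(level=0, sort=False).max()
        elif duplicate_genes == "mean":
            df = df.groupby(level=0, sort=False).mean()
        else:
            raise InputError(f"unknown duplicate_genes rule {duplicate_genes!r}")
    if scale_hint is None:
        scale = "log2" if float(df.to_numpy().max()) < LOG2_MAX else "linear"
    else:
        scale = scale_hint
    return ExpressionMatrix(df.astype(float), scale=scale)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_signature_tsv(path) -> SignatureMatrix:
    expr = read_expression_tsv(path, scale_hint="linear")
    return SignatureMatrix(expr.values)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...)."""
    sets: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{ln}: GMT line has < 3 fields")
            name = fields[0]
            if name in sets:
                raise InputError(f"{path}:{ln}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(g for g in fields[2:] if g))
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


_RESPONSE_MAP = {
    "R": "responder", "NR": "non_responder",
    "1": "responder", "0": "non_responder",
    "responder": "responder", "non_responder": "non_responder",
}


def read_clinical_tsv(path) -> SurvivalData:
    """Read sample_id/time/event (+optional response, group) TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    df = df.set_index("sample_id")
    bad = df.index[(df["time"] <= 0) | df["time"].isna()]
    if len(bad):
        raise InputError(f"{path}: non-positive time for rows {list(bad[:5])}")
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])]
        raise InputError(f"{path}: non-binary event for rows {list(bad[:5])}")
    if "response" in df.columns:
        mapped = df["response"].astype(str).map(_RESPONSE_MAP)
        unknown = df.index[mapped.isna() & df["response"].notna()]
        if len(unknown):
            raise InputError(
                f"{path}: unrecognized response for rows {list(unknown[:5])}"
            )
        df["response"] = mapped
    return SurvivalData(df)


def write_clinical_tsv(survival: SurvivalData, path) -> None:
    df = survival.table.copy()
    if "response" in df.columns:
        df["response"] = df["response"].map(
            {"responder": "R", "non_responder": "NR"}
        )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_truth_json(truth: SyntheticTruth, path) -> None:
    payload = {
        "cell_types": truth.cell_types,
        "states_per_type": truth.states_per_type,
        "marker_map": {
            f"{ct}::{s}": eff for (ct, s), eff in truth.marker_map.items()
        },
        "community_defs": {
            str(c): d for c, d in truth.community_defs.items()
        },
        "sample_community": truth.sample_community,
        "sample_states": {
            f"{sid}::{ct}": st for (sid, ct), st in truth.sample_states.items()
        },
        "fractions": {
            "index": list(truth.fractions.index),
            "columns": list(truth.fractions.columns),
            "values": truth.fractions.to_numpy().tolist(),
        },
        "hazard_multipliers": {str(k): v for k, v in truth.hazard_multipliers.items()},
        "response_benefit_states": sorted(
            [list(x) for x in truth.response_benefit_states]
        ),
        "noise_rate": truth.noise_rate,
        "seed": truth.seed,
        "profile_seed": truth.profile_seed,
        "gene_ids": truth.gene_ids,
        "marker_restriction_log2": truth.marker_restriction_log2,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)


def read_truth_json(path) -> SyntheticTruth:
    with open(path) as fh:
        d = json.load(fh)
    fr = d["fractions"]
    return SyntheticTruth(
        cell_types=d["cell_types"],
        states_per_type={k: int(v) for k, v in d["states_per_type"].items()},
        marker_map={
            (k.split("::")[0], int(k.split("::")[1])): v
            for k, v in d["marker_map"].items()
        },
        community_defs={
            int(c): {ct: int(s) for ct, s in defs.items()}
            for c, defs in d["community_defs"].items()
        },
        sample_community={k: int(v) for k, v in d["sample_community"].items()},
        sample_states={
            (k.split("::")[0], k.split("::")[1]): int(v)
            for k, v in d["sample_states"].items()
        },
        fractions=pd.DataFrame(
            np.asarray(fr["values"], dtype=float).reshape(
                len(fr["index"]), len(fr["columns"])
            ),
            index=fr["index"],
            columns=fr["columns"],
        ),
        hazard_multipliers={int(k): float(v) for k, v in d["hazard_multipliers"].items()},
        response_benefit_states={(ct, int(s)) for ct, s in d["response_benefit_states"]},
        noise_rate=float(d["noise_rate"]),
        seed=int(d["seed"]),
        profile_seed=int(d["profile_seed"]),
        gene_ids=d["gene_ids"],
        marker_restriction_log2=float(d.get("marker_restriction_log2", 0.0)),
    )


def write_state_model(model: StateModel, prefix) -> None:
    """Serialize a StateModel as <prefix>.json / _W.tsv / _H.tsv."""
    prefix = Path(prefix)
    meta = {
        "cell_type": model.cell_type,
        "rank": model.rank,
        "cophenetic_by_rank": {str(k): v for k, v in model.cophenetic_by_rank.items()},
        "markers": {
            str(s): [[g, f] for g, f in lst] for s, lst in model.markers.items()
        },
        "dropped_states": [[str(s), r] for s, r in model.dropped_states],
        "restart_count": model.restart_count,
        "seed": model.seed,
        "feature_means": {g: float(v) for g, v in model.features.means.items()},
        "feature_sds": {g: float(v) for g, v in model.features.sds.items()},
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh, sort_keys=True, indent=1)
    W = model.W.copy()
    W.index.name = "feature"
    W.to_csv(f"{prefix}_W.tsv", sep="\t", float_format=_FLOAT_FMT)
    H = model.H.copy()
    H.index.name = "state"
    H.to_csv(f"{prefix}_H.tsv", sep="\t", float_format=_FLOAT_FMT)


def read_state_model(prefix) -> StateModel:
    prefix = Path(prefix)
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    W = pd.read_csv(f"{prefix}_W.tsv", sep="\t", index_col=0)
    H = pd.read_csv(f"{prefix}_H.tsv", sep="\t", index_col=0)
    means = pd.Series(meta["feature_means"], dtype=float)
    sds = pd.Series(meta["feature_sds"], dtype=float)
    feats = NonnegFeatures(
        values=pd.DataFrame(
            np.zeros((0, H.shape[1])), columns=H.columns
        ),
        means=means,
        sds=sds,
    )
    return StateModel(
        cell_type=meta["cell_type"],
        rank=int(meta["rank"]),
        W=W,
        H=H,
        cophenetic_by_rank={int(k): float(v) for k, v in meta["cophenetic_by_rank"].items()},
        features=feats,
        markers={
            s: [(g, float(f)) for g, f in lst]
            for s, lst in meta["markers"].items()
        },
        dropped_states=[(s, r) for s, r in meta["dropped_states"]],
        restart_count=int(meta["restart_count"]),
        seed=int(meta["seed"]),
    )
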