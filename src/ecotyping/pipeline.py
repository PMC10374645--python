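"""Pipeline configuration and end-to-end orchestration.

``run_pipeline`` wires the stages together: deconvolution -> per-type
state discovery -> ecotype discovery -> clinical screens -> enrichment,
with optional reference-based recovery on a validation cohort. Every
output is plain text and the run is reproducible: a manifest records the
configuration, seeds, input checksums and output checksums, and rerunning
the same configuration yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, clinical, deconvolution, ecotypes, enrichment, io
from .containers import EcotypingError, InputError
from .recovery import (
    CoverageError,
    recover_abundances,
    recovery_rate,
    recovery_significance,
)
from .states import DegenerateStateModelError, discover_states

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("ecotyping")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with defaults for every stage."""

    bulk: str = ""
    signature: str = ""
    output_dir: str = "ecotyping_out"
    clinical: str = ""
    gene_sets: str = ""
    validation_bulk: str = ""
    seed: int = 0
    scale_hint: str = ""
    duplicate_genes: str = "max"
    # deconvolution / purification
    min_mean_fraction: float = 0.005
    min_expression: float = 1.0
    min_specificity: float = 0.75
    # state discovery
    max_rank: int = 20
    n_restarts: int = 20
    max_genes: int = 1000
    min_markers: int = 10
    min_log2fc: float = 1.0
    afi_threshold: float = 0.4
    use_afi: bool = True
    # ecotypes
    jaccard_alpha: float = 0.01
    gate: str = "standard"
    min_states: int = 3
    # clinical
    min_group: int = 10
    # recovery / enrichment
    n_perm: int = 1000
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise InputError("config must be a mapping")
        return cls.from_dict(d)

    def validate(self) -> None:
        if not self.bulk:
            raise InputError("config must name a bulk expression matrix")
        if not self.signature:
            raise InputError("deconvolution enabled but no signature path")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path, index_name: str) -> None:
    df = df.copy()
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every configured stage; returns the output directory.

    A stage failure writes a FAILED marker naming the stage, keeps the
    partial outputs and re-raises.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    stage = "read_inputs"
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {},
        "outputs": {},
        "notes": [],
    }
    try:
        bulk = io.read_expression_tsv(
            config.bulk,
            scale_hint=config.scale_hint or None,
            duplicate_genes=config.duplicate_genes,
        )
        manifest["inputs"]["bulk"] = _sha256(config.bulk)
        signature = io.read_signature_tsv(config.signature)
        manifest["inputs"]["signature"] = _sha256(config.signature)
        log.info(
            "stage=%s genes=%d samples=%d", stage, bulk.n_genes, bulk.n_samples
        )

        stage = "deconvolution"
        fractions = deconvolution.estimate_fractions(bulk, signature)
        _write_tsv(fractions.values, out / "fractions.tsv", "sample_id")

        stage = "state_discovery"
        models: dict = {}
        assignments: dict = {}
        purified_by_type: dict = {}
        for ct in signature.cell_types:
            try:
                pur = deconvolution.purify_expression(
                    bulk,
                    fractions,
                    ct,
                    min_mean_fraction=config.min_mean_fraction,
                    min_expression=config.min_expression,
                    min_specificity=config.min_specificity,
                )
                model, assign = discover_states(
                    pur,
                    k_range=range(2, config.max_rank + 1),
                    n_restarts=config.n_restarts,
                    seed=config.seed,
                    max_genes=config.max_genes,
                    min_markers=config.min_markers,
                    min_log2fc=config.min_log2fc,
                    afi_threshold=config.afi_threshold,
                    use_afi=config.use_afi,
                )
            except (InputError, DegenerateStateModelError) as exc:
                manifest["notes"].append(f"{ct}: excluded ({exc})")
                log.warning("stage=%s type=%s excluded: %s", stage, ct, exc)
                continue
            models[ct] = model
            purified_by_type[ct] = pur
            io.write_state_model(model, out / f"state_model_{ct}")
            assignments[ct] = assign
            lab = assign.labels.to_frame("state")
            _write_tsv(lab, out / f"state_assignment_{ct}.tsv", "sample_id")
            log.info(
                "stage=%s type=%s states=%d samples=%d",
                stage, ct, model.rank, len(assign.labels),
            )
        if not models:
            raise EcotypingError("no cell type yielded a state model")

        stage = "ecotype_discovery"
        eco = None
        if len(models) >= 2:
            try:
                eco = ecotypes.discover_ecotypes(
                    assignments,
                    abundances={ct: m.H for ct, m in models.items()},
                    alpha=config.jaccard_alpha,
                    gate=config.gate,
                    min_states=config.min_states,
                )
            except (InputError, EcotypingError) as exc:
                manifest["notes"].append(f"ecotypes: skipped ({exc})")
                log.warning("stage=%s skipped: %s", stage, exc)
        if eco is not None:
            _write_tsv(eco.gated_jaccard, out / "jaccard_gated.tsv", "state")
            _write_tsv(
                eco.ecotype_map.to_frame("ecotype"), out / "ecotype_members.tsv",
                "state",
            )
            _write_tsv(eco.abundance, out / "ecotype_abundance.tsv", "sample_id")
            _write_tsv(
                eco.dominant.to_frame("ecotype"), out / "ecotype_dominant.tsv",
                "sample_id",
            )
            edges = []
            ids = list(eco.jaccard.index)
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    if eco.gated_jaccard.loc[a, b] > 0:
                        edges.append(
                            {
                                "state_i": a, "state_k": b,
                                "jaccard": eco.jaccard.loc[a, b],
                                "p": eco.pair_p.loc[a, b],
                            }
                        )
            pd.DataFrame(
                edges, columns=["state_i", "state_k", "jaccard", "p"]
            ).to_csv(out / "ecotype_edges.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)

        stage = "clinical_association"
        if config.clinical:
            surv = io.read_clinical_tsv(config.clinical)
            manifest["inputs"]["clinical"] = _sha256(config.clinical)
            shared = [s for s in bulk.sample_ids if s in set(surv.sample_ids)]
            surv = surv.subset(shared)
            for ct, assign in assignments.items():
                tab = clinical.state_survival_screen(
                    assign.labels.loc[shared], surv, min_group=config.min_group
                )
                _write_tsv(tab, out / f"survival_states_{ct}.tsv", "state")
            if eco is not None:
                tab = clinical.state_survival_screen(
                    eco.dominant.loc[shared], surv, min_group=config.min_group
                )
                _write_tsv(tab, out / "survival_ecotypes.tsv", "ecotype")
            if "response" in surv.table.columns:
                for ct, assign in assignments.items():
                    tab = clinical.therapy_benefit(assign.labels.loc[shared], surv)
                    _write_tsv(tab, out / f"benefit_states_{ct}.tsv", "state")
                if eco is not None:
                    tab = clinical.therapy_benefit(eco.dominant.loc[shared], surv)
                    _write_tsv(tab, out / "benefit_ecotypes.tsv", "ecotype")

        stage = "enrichment"
        if config.gene_sets:
            collection = io.read_gmt(config.gene_sets)
            manifest["inputs"]["gene_sets"] = _sha256(config.gene_sets)
            universe = bulk.gene_ids
            rows = []
            for ct, model in models.items():
                for state, lst in model.markers.items():
                    markers = [g for g, _ in lst]
                    if not markers:
                        continue
                    tab = enrichment.hypergeometric_enrichment(
                        markers, collection, universe
                    )
                    tab = tab.reset_index()
                    tab.insert(0, "state", state)
                    tab.insert(0, "cell_type", ct)
                    rows.append(tab)
            if rows:
                pd.concat(rows, ignore_index=True).to_csv(
                    out / "enrichment_states.tsv", sep="\t", index=False,
                    float_format=_FLOAT_FMT,
                )

        stage = "recovery"
        if config.validation_bulk:
            vbulk = io.read_expression_tsv(
                config.validation_bulk,
                scale_hint=config.scale_hint or None,
                duplicate_genes=config.duplicate_genes,
            )
            manifest["inputs"]["validation_bulk"] = _sha256(config.validation_bulk)
            vfrac = deconvolution.estimate_fractions(vbulk, signature)
            rows = []
            for ct, model in models.items():
                try:
                    vpur = deconvolution.purify_expression(
                        vbulk, vfrac, ct,
                        min_mean_fraction=config.min_mean_fraction,
                        min_expression=config.min_expression,
                        min_specificity=config.min_specificity,
                    )
                    rec = recover_abundances(vpur, model)
                    rec = recovery_significance(
                        vpur, model, rec, n_perm=config.n_perm, seed=config.seed
                    )
                except (CoverageError, InputError) as exc:
                    manifest["notes"].append(f"recovery {ct}: skipped ({exc})")
                    continue
                _write_tsv(
                    rec.assignments.to_frame("state"),
                    out / f"recovery_assignment_{ct}.tsv", "sample_id",
                )
                tab = rec.stats.reset_index(names="state")
                tab.insert(0, "cell_type", ct)
                tab["recovery_rate"] = recovery_rate(rec)
                rows.append(tab)
            if rows:
                pd.concat(rows, ignore_index=True).to_csv(
                    out / "recovery_stats.tsv", sep="\t", index=False,
                    float_format=_FLOAT_FMT,
                )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise

    stage = "manifest"
    for f in sorted(out.iterdir()):
        if f.name not in ("manifest.json", "FAILED") and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    if (out / "FAILED").exists():
        (out / "FAILED").unlink()
    return out
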