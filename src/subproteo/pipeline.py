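"""End-to-end pipeline: ingest -> qualify -> differential test -> aggregation
-> secretion (optional) -> live-cell array (optional), with a run manifest.

A single configuration object (loadable from YAML) carries the input paths,
the declared design, the qualification thresholds and test parameters, and a
seed that propagates to every stochastic stage; identical configuration and
seed give byte-identical outputs.  The manifest records the pipeline
version, a configuration hash, and per-stage row counts so filter attrition
is visible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as spio
from .aggregate import core_proteome, tally_by_group, total_altered
from .diffstat import TestConfig, differential_analysis, log_transform
from .lca import compute_tau, subtract_background, summarize_tau
from .qualify import call_presence, qualify_proteins
from .secretion import mislocalization_check, sec_proportion
from .simulate import CONDITIONS, CONTROL, INDUCED

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.message = message


@dataclass
class PipelineConfig:
    quant_path: str = ""
    localization_path: str | None = None
    sec_sp_path: str | None = None
    categories_path: str | None = None
    regulons_path: str | None = None
    plate_path: str | None = None
    strains: tuple[str, ...] = ("168", "midi")
    fractions: tuple[str, ...] = ("cytosolic", "membrane", "extracellular")
    n_replicates: int = 3
    intensities_log2: bool = False
    dialect: str = "strict"
    min_unique_peptides: int = 2
    min_replicates: int = 2
    strict_absence: bool = False
    s0: float = 0.1
    n_randomizations: int = 250
    fdr: float = 0.05
    fdr_method: str = "permutation"
    category_level: int = 2
    enable_secretion: bool = True
    enable_lca: bool = False
    outdir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("strains", "fractions"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        if not self.quant_path or not Path(self.quant_path).exists():
            raise PipelineError("config", f"quant table not found: {self.quant_path}")
        for name in ("localization", "sec_sp", "categories", "regulons", "plate"):
            p = getattr(self, f"{name}_path")
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"{name} map not found: {p}")
        if self.enable_secretion and self.sec_sp_path is None:
            raise PipelineError(
                "config", "secretion stage enabled but no signal-peptide map given"
            )
        if self.enable_lca and self.plate_path is None:
            raise PipelineError("config", "lca stage enabled but no plate series given")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages in order and write one TSV per stage plus a
    manifest; returns the manifest dictionary."""
    cfg = config
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = spio.config_hash(cfg.to_dict())
    manifest: dict = {
        "pipeline_version": spio.PIPELINE_VERSION,
        "config_hash": chash,
        "seed": cfg.seed,
        "stages": {},
    }
    design = spio.Design(
        strains=cfg.strains,
        conditions=CONDITIONS,
        fractions=cfg.fractions,
        n_replicates=cfg.n_replicates,
    )

    def _stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:  # surface the failing stage
            raise PipelineError(name, str(exc)) from exc

    # ingest
    def _ingest():
        table, report = spio.read_quant_table(
            cfg.quant_path,
            design=design,
            intensities_log2=cfg.intensities_log2,
            dialect=cfg.dialect,
            return_report=True,
        )
        maps = spio.read_annotation_maps(
            localization_path=cfg.localization_path,
            sec_sp_path=cfg.sec_sp_path,
            categories_path=cfg.categories_path,
            regulons_path=cfg.regulons_path,
        )
        manifest["stages"]["ingest"] = {
            "rows_in": report.n_input,
            "rows_kept": report.n_kept,
            "rows_rejected": report.n_rejected,
            "rows_zero_dropped": report.n_zero_dropped,
        }
        return table, maps

    table, maps = _stage("ingest", _ingest)

    # qualify
    def _qualify():
        qs = qualify_proteins(
            table,
            maps,
            min_unique_peptides=cfg.min_unique_peptides,
            min_replicates=cfg.min_replicates,
        )
        presence = call_presence(qs, strict_absence=cfg.strict_absence)
        spio.write_table(qs.counts, outdir / "qualified.tsv", cfg.to_dict())
        spio.write_table(presence, outdir / "presence.tsv", cfg.to_dict())
        manifest["stages"]["qualify"] = {
            "rows_observed": len(qs.counts),
            "rows_qualified": int(qs.counts["qualified"].sum()),
            "presence_calls": presence["call"].value_counts().to_dict(),
        }
        return qs, presence

    qs, presence = _stage("qualify", _qualify)

    # differential statistics
    def _diff():
        log2 = log_transform(table)
        tcfg = TestConfig(
            s0=cfg.s0,
            n_randomizations=cfg.n_randomizations,
            fdr=cfg.fdr,
            seed=cfg.seed,
            method=cfg.fdr_method,
        )
        classed = differential_analysis(
            log2, qs, presence, tcfg, n_replicates=cfg.n_replicates
        )
        spio.write_table(classed, outdir / "differential.tsv", cfg.to_dict())
        manifest["stages"]["diffstat"] = {
            "rows": len(classed),
            "classes": classed["class"].value_counts().to_dict(),
        }
        return log2, classed

    log2, classed = _stage("diffstat", _diff)

    # aggregation
    def _aggregate():
        tally = tally_by_group(classed, maps, grouping="category", level=cfg.category_level)
        spio.write_table(tally, outdir / "category_tally.tsv", cfg.to_dict())
        reg_tally = tally_by_group(classed, maps, grouping="regulon")
        spio.write_table(reg_tally, outdir / "regulon_tally.tsv", cfg.to_dict())
        sets = {
            f"{s}:{c}": qs.qualified_union(s, c)
            for s in cfg.strains
            for c in CONDITIONS
        }
        venn = core_proteome(sets)
        altered = total_altered(classed)
        import pandas as pd

        venn_df = pd.DataFrame(
            {"region": list(venn.regions), "count": list(venn.regions.values())}
        )
        spio.write_table(venn_df, outdir / "venn.tsv", cfg.to_dict())
        manifest["stages"]["aggregate"] = {
            "core_proteome": venn.core,
            "union": venn.union,
            "total_altered": altered,
        }
        return tally

    _stage("aggregate", _aggregate)

    # secretion
    if cfg.enable_secretion:

        def _secretion():
            import pandas as pd

            rows = []
            for strain in cfg.strains:
                try:
                    sp = sec_proportion(table, qs, maps, strain)
                except ValueError as exc:
                    logger.warning("secretion: %s", exc)
                    continue
                misloc = mislocalization_check(qs, maps, strain)
                rows.append(
                    {
                        "strain": strain,
                        "p_sec_mean": sp.mean,
                        "p_sec_sd": sp.sd,
                        "p_sec_pooled": sp.pooled,
                        "n_sec_quantified": sp.n_sec_quantified,
                        "n_mislocalized": len(misloc),
                        "mislocalized": ";".join(misloc),
                    }
                )
            summary = pd.DataFrame(rows)
            spio.write_table(summary, outdir / "secretion.tsv", cfg.to_dict())
            manifest["stages"]["secretion"] = {
                "strains": {r["strain"]: r["p_sec_mean"] for r in rows}
            }

        _stage("secretion", _secretion)

    # live-cell array
    if cfg.enable_lca:

        def _lca():
            series = spio.read_plate_series(cfg.plate_path)
            corrected = subtract_background(series)
            tau = compute_tau(corrected)
            profile, auc, ranking = summarize_tau(tau)
            spio.write_table(tau, outdir / "tau.tsv", cfg.to_dict())
            spio.write_table(profile, outdir / "tau_profile.tsv", cfg.to_dict())
            manifest["stages"]["lca"] = {"auc": auc, "ranking": ranking}

        _stage("lca", _lca)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
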