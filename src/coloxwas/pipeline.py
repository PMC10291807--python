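"""End-to-end orchestration: simulate -> train -> xwas -> cojo -> coloc ->
regions -> prioritize, with a manifest of content-hashed outputs.

The pipeline is resumable in the sense that every stage writes its outputs
in the package's on-disk dialects, so any stage can be re-run from the
files of the previous one via the CLI subcommands.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from coloxwas import cojo as cojo_mod
from coloxwas import io_formats as iof
from coloxwas.cis_models import CisTrainingConfig, fit_weights
from coloxwas.conditional_xwas import prioritize_region
from coloxwas.finemap_coloc import ColocConfig, conditional_coloc
from coloxwas.regions import (FeatureSpan, assemble_trait_support,
                              merge_regions, MHC_SPAN_DEFAULT,
                              PAD_BP_DEFAULT)
from coloxwas.synthetic import ScenarioSpec, make_scenario
from coloxwas.xwas_assoc import bonferroni_threshold, run_xwas_screen

logger = logging.getLogger(__name__)

STAGES = ("simulate", "train", "xwas", "cojo", "coloc", "regions",
          "prioritize")


class ConfigError(ValueError):
    """Pipeline configuration violates a documented range."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception,
                 manifest: dict[str, str]):
        self.stage = stage
        self.partial_manifest = manifest
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclasses.dataclass
class PipelineConfig:
    scenario: ScenarioSpec = dataclasses.field(default_factory=ScenarioSpec)
    alpha: float = 0.05
    p_entry: float = 5e-8
    collinearity: float = 0.1
    flank_bp: int = 250_000
    pad_bp: int = PAD_BP_DEFAULT
    pp4: float = 0.8
    out_dir: str = "coloxwas_run"
    train_models: bool = True  # False: use truth weights from the scenario

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if not (0 < self.p_entry < 1):
            raise ConfigError("p_entry must be in (0, 1)")
        if not (0 < self.collinearity < 1):
            raise ConfigError("collinearity must be in (0, 1)")
        if not (0 < self.pp4 < 1):
            raise ConfigError("pp4 must be in (0, 1)")
        if self.flank_bp < 0 or self.pad_bp < 0:
            raise ConfigError("flank_bp and pad_bp must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["scenario"]["maf_range"] = list(d["scenario"]["maf_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sc = d.pop("scenario", {})
        sc["maf_range"] = tuple(sc.get("maf_range", (0.05, 0.5)))
        return cls(scenario=ScenarioSpec(**sc), **d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Execute all stages on a synthetic scenario; return the manifest
    (relative path -> sha256) which is also written to ``manifest.json``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def record(path: Path) -> None:
        manifest[path.name] = _sha256(path)

    stage = "simulate"
    try:
        bundle = make_scenario(cfg.scenario)
        iof.write_ld_panel(bundle.panel, out / "panel")
        for t, ss in bundle.sumstats.items():
            iof.write_gwas_sumstats(ss, out / f"sumstats.{t}.tsv")
            record(out / f"sumstats.{t}.tsv")
        record(out / "panel.snps.tsv")
        record(out / "panel.dosage.tsv")
        logger.info("simulate: scenario=%s p=%d n_panel=%d traits=%d",
                    cfg.scenario.name, cfg.scenario.p_snps,
                    cfg.scenario.n_panel, len(bundle.sumstats))

        stage = "train"
        if cfg.train_models and bundle.features:
            span = (bundle.models[0].gene_span if bundle.models
                    else (cfg.scenario.chromosome,
                          int(bundle.panel.snps["position"].min()),
                          int(bundle.panel.snps["position"].max())))
            tc = CisTrainingConfig(seed=cfg.scenario.seed)
            models = []
            for fid, values in bundle.features.items():
                m = fit_weights(bundle.qtl_panel, values, span, tc,
                                feature_id=fid)
                if not m.untrainable:
                    models.append(m)
        else:
            models = bundle.models
        iof.write_weight_models(models, out / "weights.tsv")
        record(out / "weights.tsv")
        logger.info("train: %d trainable models", len(models))

        stage = "xwas"
        if models:
            xwas_results = run_xwas_screen(models, bundle.sumstats,
                                           bundle.panel, alpha=cfg.alpha)
        else:
            xwas_results = []
        iof.write_results_table(
            pd.DataFrame([r.as_row() for r in xwas_results]),
            out / "xwas.tsv")
        record(out / "xwas.tsv")
        logger.info("xwas: %d tests, %d significant", len(xwas_results),
                    sum(r.significant for r in xwas_results))

        stage = "cojo"
        cojo_rows = []
        signal_sets = {}
        for t, ss in bundle.sumstats.items():
            ms = cojo_mod.MarginalStats.from_sumstats(ss)
            sig = cojo_mod.cojo_slct(ms, bundle.panel,
                                     p_entry=cfg.p_entry,
                                     collinearity=cfg.collinearity)
            signal_sets[t] = sig
            for row in sig.joint.itertuples(index=False):
                cojo_rows.append({"trait_id": t, **row._asdict()})
        iof.write_results_table(
            pd.DataFrame(cojo_rows, columns=["trait_id", "snp_id",
                                             "b_joint", "se_joint",
                                             "p_joint"]),
            out / "cojo.tsv")
        record(out / "cojo.tsv")
        logger.info("cojo: leads per trait %s",
                    {t: len(s.lead_snps) for t, s in signal_sets.items()})

        stage = "coloc"
        ccfg = ColocConfig(pp4_report=cfg.pp4)
        coloc_rows = []
        coloc_by_trait: dict[str, dict[tuple[str, str], list]] = {}
        for model in models:
            qtl_ss = _feature_qtl_sumstats(bundle, model.feature_id)
            for t, ss in bundle.sumstats.items():
                res = conditional_coloc(
                    qtl_ss, ss, bundle.panel, model.gene_span, ccfg,
                    flank_bp=cfg.flank_bp, p_entry=cfg.p_entry,
                    collinearity=cfg.collinearity)
                key = (model.feature_id, model.tissue)
                coloc_by_trait.setdefault(t, {}).setdefault(
                    key, []).extend(res)
                for cr in res:
                    coloc_rows.append({"feature_id": model.feature_id,
                                       "tissue": model.tissue,
                                       "trait_id": t, **cr.as_row()})
        iof.write_results_table(
            pd.DataFrame(coloc_rows), out / "coloc.tsv")
        record(out / "coloc.tsv")
        logger.info("coloc: %d signal pairs, %d colocalized",
                    len(coloc_rows),
                    sum(r["colocalized"] for r in coloc_rows))

        stage = "regions"
        spans = [FeatureSpan(m.feature_id, m.tissue, *m.gene_span)
                 for m in models]
        region_list = merge_regions(spans, pad=cfg.pad_bp)
        gwas_regional_p = {
            t: {reg.region_id: _regional_min_p(ss, reg)
                for reg in region_list}
            for t, ss in bundle.sumstats.items()}
        support_df, overlap_df = assemble_trait_support(
            region_list, {t: xwas_results for t in bundle.sumstats},
            coloc_by_trait, gwas_regional_p, pp4=cfg.pp4)
        iof.write_results_table(support_df, out / "regions.tsv")
        iof.write_results_table(overlap_df, out / "overlap.tsv")
        record(out / "regions.tsv")
        record(out / "overlap.tsv")
        logger.info("regions: %d regions, %d supported pairs",
                    len(region_list),
                    int((support_df["support"] == "xwas_plus_coloc").sum()))

        stage = "prioritize"
        prio_rows = []
        if len(models) >= 2:
            uniq = {m.feature_id for m in models}
            thr = bonferroni_threshold(len(uniq), cfg.alpha)
            for t, ss in bundle.sumstats.items():
                for r in prioritize_region(models, ss, bundle.panel, thr):
                    prio_rows.append({"trait_id": t,
                                      **dataclasses.asdict(r)})
        iof.write_results_table(
            pd.DataFrame(prio_rows), out / "conditional_xwas.tsv")
        record(out / "conditional_xwas.tsv")
        logger.info("prioritize: %d conditional rows", len(prio_rows))
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(stage, exc, manifest) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def _feature_qtl_sumstats(bundle, feature_id: str):
    """Synthetic QTL summary statistics for one feature: marginal
    regression of the feature on each standardized dosage in the QTL panel."""
    from coloxwas.synthetic import feature_qtl_sumstats
    return feature_qtl_sumstats(bundle, feature_id)


def _regional_min_p(ss, region) -> float:
    from scipy import stats as sps
    df = ss.records
    sel = ((df["chromosome"].astype(str) == str(region.chromosome))
           & (df["position"] >= region.start)
           & (df["position"] <= region.stop))
    if not sel.any():
        return float("nan")
    z = df.loc[sel, "z"].to_numpy(float)
    return float(2.0 * sps.norm.sf(np.abs(z)).min())
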