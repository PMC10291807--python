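"""TWAS/PWAS association from summary statistics, weights, and LD.

The xWAS z-statistic is the standard weighted score

    z_xwas = w' z / sqrt(w' R w)

over the model SNPs that survive harmonization with the GWAS and the LD
panel, with R the ridge-stabilized panel correlation submatrix.  Multiple
testing is Bonferroni over *unique* features: a gene modelled in several
tissues, or an aptamer, counts once in the divisor.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coloxwas.io_formats import GwasSumstats, LdPanel, WeightModel

logger = logging.getLogger(__name__)

RIDGE = 0.01  # diagonal stabilization of reference LD before quadratic forms


class CoverageError(ValueError):
    """No model SNPs survive harmonization with GWAS and panel."""


class NumericalError(ArithmeticError):
    """The stabilized quadratic form w'Rw is non-positive."""


@dataclasses.dataclass
class XwasResult:
    feature_id: str
    tissue: str
    trait_id: str
    z_xwas: float
    p_xwas: float
    n_snps_used: int
    significant: bool = False
    degraded: bool = False  # < 50% of model weights survived harmonization
    modality: str = "expression"

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


def _orient_weights(model: WeightModel, gwas: GwasSumstats,
                    panel: LdPanel) -> tuple[list[str], np.ndarray]:
    """Intersect model SNPs with gwas and panel; flip weight signs where the
    model's A1 is the panel's A2.  GWAS is assumed already harmonized to the
    panel (see io_formats.harmonize_alleles)."""
    gwas_ids = set(gwas.snp_ids)
    panel_alleles = {r.snp_id: (r.A1, r.A2) for r in panel.snps.itertuples()}
    ids, ws = [], []
    for e in model.entries.itertuples(index=False):
        ref = panel_alleles.get(e.snp_id)
        if ref is None or e.snp_id not in gwas_ids:
            continue
        if (e.A1, e.A2) == ref:
            ids.append(e.snp_id); ws.append(e.weight)
        elif (e.A2, e.A1) == ref:
            ids.append(e.snp_id); ws.append(-e.weight)
        # irreconcilable allele pairs are dropped
    return ids, np.asarray(ws, dtype=float)


def xwas_z(model: WeightModel, gwas: GwasSumstats, panel: LdPanel,
           ridge: float = RIDGE) -> XwasResult:
    """Association z-score of one predicted feature with one trait."""
    ids, w = _orient_weights(model, gwas, panel)
    if not ids:
        raise CoverageError(
            f"no model SNPs of {model.feature_id!r} survive harmonization")
    z = gwas.records.set_index("snp_id").loc[ids, "z"].to_numpy(float)
    R = panel.correlation(ids, ridge=ridge)
    denom2 = float(w @ R @ w)
    if denom2 <= 0:
        raise NumericalError(
            f"w'Rw = {denom2:.3g} <= 0 for {model.feature_id!r}")
    zx = float(w @ z) / np.sqrt(denom2)
    p = float(2.0 * stats.norm.sf(abs(zx)))
    return XwasResult(
        feature_id=model.feature_id, tissue=model.tissue,
        trait_id=gwas.trait_id, z_xwas=zx, p_xwas=p, n_snps_used=len(ids),
        degraded=len(ids) < 0.5 * len(model.entries),
        modality=model.modality)


def bonferroni_threshold(n_unique_features: int, alpha: float = 0.05) -> float:
    """Bonferroni p-value threshold over unique features.

    Uniqueness is by feature identity: a gene modelled across several
    tissues counts once, as does an aptamer.  E.g. 12,893 unique genes at
    alpha 0.05 give 3.9e-6 (two significant figures) and 1342 unique
    aptamers give 3.7e-5.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_unique_features < 1:
        raise ValueError("n_unique_features must be >= 1")
    return alpha / n_unique_features


def run_xwas_screen(
    models: Sequence[WeightModel],
    gwas_by_trait: dict[str, GwasSumstats],
    panel: LdPanel,
    alpha: float = 0.05,
) -> list[XwasResult]:
    """Test every (feature x tissue, trait) pair; flag significance at the
    per-modality Bonferroni threshold over unique features."""
    if not models:
        raise ValueError("empty model manifest")
    thresholds: dict[str, float] = {}
    for modality in {m.modality for m in models}:
        uniq = {m.feature_id for m in models if m.modality == modality}
        thresholds[modality] = bonferroni_threshold(len(uniq), alpha)
    results: list[XwasResult] = []
    for model in models:
        if model.untrainable:
            continue
        for gwas in gwas_by_trait.values():
            try:
                res = xwas_z(model, gwas, panel)
            except (CoverageError, NumericalError) as exc:
                logger.warning("skipping %s x %s: %s", model.feature_id,
                               gwas.trait_id, exc)
                continue
            res.significant = res.p_xwas < thresholds[model.modality]
            results.append(res)
    results.sort(key=lambda r: r.p_xwas)
    return results


def classify_shared(results_trait1: Iterable[XwasResult],
                    results_trait2: Iterable[XwasResult]) -> pd.DataFrame:
    """Label each feature x tissue as trait1_only / trait2_only / shared by
    significance in each trait's own screen."""
    sig1 = {(r.feature_id, r.tissue) for r in results_trait1 if r.significant}
    sig2 = {(r.feature_id, r.tissue) for r in results_trait2 if r.significant}
    rows = []
    for key in sorted(sig1 | sig2):
        label = ("shared" if key in sig1 and key in sig2
                 else "trait1_only" if key in sig1 else "trait2_only")
        rows.append({"feature_id": key[0], "tissue": key[1], "label": label})
    return pd.DataFrame(rows, columns=["feature_id", "tissue", "label"])
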