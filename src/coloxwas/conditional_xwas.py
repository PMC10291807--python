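"""cis-regulated genetic correlations and pairwise conditional xWAS.

Two features' genetic components are imputed from their cis weights into a
common reference panel; their Pearson correlation rho is the cis-regulated
genetic correlation.  Conditioning one feature's xWAS z on another's then
follows the summary-statistic conditional form

    z_cond = (z_target - rho * z_conditioning) / sqrt(1 - rho^2)

When |rho| exceeds the collinearity bound (0.9 by default) the two
associations are statistically indistinguishable and a shared-signal
verdict is returned instead of a number.  Pairwise verdicts over a region:

* ``independent``       — both directions stay significant after
                          conditioning (two distinct signals);
* ``explained``         — one feature's signal drops below threshold while
                          the other's stands;
* ``shared_attenuated`` — both drop (one underlying association seen
                          through two correlated features);
* ``collinear_shared``  — |rho| at or above the bound.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from coloxwas.cis_models import impute_feature
from coloxwas.io_formats import GwasSumstats, LdPanel, WeightModel
from coloxwas.xwas_assoc import XwasResult, xwas_z

RHO_COLLINEAR_DEFAULT = 0.9


class DegenerateModelError(ValueError):
    """An imputed feature has zero variance in the reference panel."""


@dataclasses.dataclass
class CoregulationEstimate:
    feature_a: str
    feature_b: str
    rho: float
    n_ref: int


@dataclasses.dataclass
class ConditionalXwasRow:
    target: str
    conditioned_on: str
    rho: float
    z_marginal: float
    z_conditional: float  # NaN on collinearity
    p_conditional: float
    verdict: str


def cis_genetic_correlation(panel: LdPanel, model_a: WeightModel,
                            model_b: WeightModel) -> CoregulationEstimate:
    """Pearson correlation of the two imputed features in ``panel``."""
    ga = impute_feature(panel, model_a)
    gb = impute_feature(panel, model_b)
    for g, m in ((ga, model_a), (gb, model_b)):
        if g.std() == 0:
            raise DegenerateModelError(
                f"imputed feature {m.feature_id!r} has zero variance")
    rho = float(np.corrcoef(ga, gb)[0, 1])
    return CoregulationEstimate(model_a.feature_id, model_b.feature_id,
                                rho, panel.n_individuals)


def conditional_z(z_target: float, z_conditioning: float, rho: float,
                  rho_bound: float = RHO_COLLINEAR_DEFAULT) -> float:
    """Conditional z of the target feature given the conditioning feature.

    Raises :class:`CollinearSignals` when |rho| >= ``rho_bound``: the two
    instruments cannot be separated and the pair is one underlying
    association.
    """
    if abs(rho) >= rho_bound:
        raise CollinearSignals(rho)
    return float((z_target - rho * z_conditioning) / np.sqrt(1.0 - rho**2))


class CollinearSignals(ValueError):
    """|rho| at or above the collinearity bound: same underlying signal."""

    def __init__(self, rho: float):
        self.rho = rho
        super().__init__(
            f"|rho| = {abs(rho):.3f} at/above the collinearity bound; "
            "signals are statistically the same association")


def prioritize_region(
    candidate_models: Sequence[WeightModel],
    gwas: GwasSumstats,
    panel: LdPanel,
    sig_threshold: float,
    rho_bound: float = RHO_COLLINEAR_DEFAULT,
    xwas_by_feature: Mapping[str, XwasResult] | None = None,
) -> list[ConditionalXwasRow]:
    """All ordered pairwise conditional xWAS analyses within a region.

    ``sig_threshold`` is the modality's Bonferroni p threshold reused for
    the conditional verdicts.  Marginal xWAS results may be supplied to
    avoid recomputation.  Verdicts are assigned per unordered pair from the
    two conditional directions (see module docstring); the per-direction
    rows report the conditional statistics themselves.
    """
    if not candidate_models:
        raise ValueError("empty candidate set")
    from scipy import stats as sps

    models = {m.feature_id: m for m in candidate_models}
    zmarg: dict[str, float] = {}
    for fid, m in models.items():
        if xwas_by_feature and fid in xwas_by_feature:
            zmarg[fid] = xwas_by_feature[fid].z_xwas
        else:
            zmarg[fid] = xwas_z(m, gwas, panel).z_xwas
    z_threshold = float(sps.norm.isf(sig_threshold / 2.0))

    rows: list[ConditionalXwasRow] = []
    fids = sorted(models)
    for a in fids:
        for b in fids:
            if a == b:
                continue
            rho = cis_genetic_correlation(panel, models[a], models[b]).rho
            try:
                zc = conditional_z(zmarg[a], zmarg[b], rho, rho_bound)
                pc = float(2.0 * sps.norm.sf(abs(zc)))
                verdict = "pending"
            except CollinearSignals:
                zc, pc, verdict = float("nan"), float("nan"), "collinear_shared"
            rows.append(ConditionalXwasRow(
                target=a, conditioned_on=b, rho=rho,
                z_marginal=zmarg[a], z_conditional=zc, p_conditional=pc,
                verdict=verdict))

    by_pair = {(r.target, r.conditioned_on): r for r in rows}
    for i, a in enumerate(fids):
        for b in fids[i + 1:]:
            r_ab, r_ba = by_pair[(a, b)], by_pair[(b, a)]
            if "collinear_shared" in (r_ab.verdict, r_ba.verdict):
                r_ab.verdict = r_ba.verdict = "collinear_shared"
                continue
            a_stands = abs(r_ab.z_conditional) > z_threshold
            b_stands = abs(r_ba.z_conditional) > z_threshold
            if a_stands and b_stands:
                verdict = "independent"
            elif a_stands or b_stands:
                verdict = "explained"
            else:
                verdict = "shared_attenuated"
            r_ab.verdict = r_ba.verdict = verdict
    return rows
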