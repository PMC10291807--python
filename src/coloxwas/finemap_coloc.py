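"""Wakefield approximate Bayes factors, single-causal-variant PIPs, and
pairwise colocalization of independent signals.

Per SNP, with V = se^2, z = beta/se and effect-size prior N(0, W):

    log ABF = 0.5 * [ ln(V / (V + W)) + z^2 * W / (V + W) ]

Under a single causal variant the posterior inclusion probability of SNP k
is exp(labf_k - logsumexp(labf)).  For two traits measured over the same m
SNPs the five colocalization hypotheses receive unnormalized masses

    L0 = 1
    L1 = p1 * S1          S1 = sum_k e^{labf1_k}
    L2 = p2 * S2          S2 = sum_k e^{labf2_k}
    L3 = p1 p2 (S1 S2 - C)
    L4 = p12 * C          C  = sum_k e^{labf1_k + labf2_k}

(the S1*S2 - C term removes same-SNP configurations from the two-variant
hypothesis), evaluated in log space.  A region-trait pair colocalizes when
PP(H4) reaches the reporting threshold (0.8 by default).

When a region decomposes into several independent signals, each signal's
labfs are computed from its *conditional* (b, se) — marginal and
conditional statistics are never mixed within one signal — and every
(QTL signal x trait signal) pair is tested.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from coloxwas import cojo
from coloxwas.io_formats import GwasSumstats, LdPanel

logger = logging.getLogger(__name__)


class OverlapError(ValueError):
    """Fewer than one SNP shared between the two signals."""


@dataclasses.dataclass
class ColocConfig:
    """Priors of the five-hypothesis model.

    Defaults are the conventional single-variant colocalization priors for
    quantitative traits: effect prior SD 0.15 (W = 0.0225), per-SNP causal
    priors p1 = p2 = 1e-4, shared-causal prior p12 = 1e-5, and an H4
    reporting threshold of 0.8.
    """

    prior_var_W: float = 0.15**2
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    pp4_report: float = 0.8

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12", "pp4_report"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError("p12 must not exceed min(p1, p2)")
        if self.prior_var_W <= 0:
            raise ValueError("prior_var_W must be positive")


@dataclasses.dataclass
class SignalFineMap:
    snp_ids: list[str]
    labf: np.ndarray
    pip: np.ndarray


@dataclasses.dataclass
class ColocResult:
    qtl_signal: str
    trait_signal: str
    pp: dict[str, float]  # H0..H4
    n_snps_common: int
    colocalized: bool
    low_coverage: bool = False

    def as_row(self) -> dict:
        row = {"qtl_signal": self.qtl_signal,
               "trait_signal": self.trait_signal}
        row.update({f"pp_{h}": v for h, v in self.pp.items()})
        row.update({"n_snps_common": self.n_snps_common,
                    "colocalized": self.colocalized,
                    "low_coverage": self.low_coverage})
        return row


def wakefield_labf(beta: np.ndarray | float, se: np.ndarray | float,
                   prior_var_W: float) -> np.ndarray | float:
    """Log approximate Bayes factor for association at one or more SNPs."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if prior_var_W <= 0:
        raise ValueError("prior_var_W must be > 0")
    V = se**2
    z2 = (beta / se) ** 2
    out = 0.5 * (np.log(V / (V + prior_var_W)) + z2 * prior_var_W / (V + prior_var_W))
    return out if out.ndim else float(out)


def pip_from_labf(snp_ids: list[str], labfs: np.ndarray) -> SignalFineMap:
    """Posterior inclusion probabilities under one causal variant."""
    labfs = np.asarray(labfs, dtype=float)
    if labfs.size == 0:
        raise ValueError("empty labf vector")
    log_pip = labfs - logsumexp(labfs)
    return SignalFineMap(snp_ids=list(snp_ids), labf=labfs,
                         pip=np.exp(log_pip))


_HYP = ("H0", "H1", "H2", "H3", "H4")


def coloc_pair(fm1: SignalFineMap, fm2: SignalFineMap,
               cfg: ColocConfig | None = None,
               qtl_signal: str = "qtl", trait_signal: str = "trait",
               ) -> ColocResult:
    """Five-hypothesis colocalization of two signals over common SNPs.

    Inputs must already be restricted to the intersection SNP set in the
    same order; sums are evaluated in log space for stability.
    """
    cfg = cfg or ColocConfig()
    if fm1.snp_ids != fm2.snp_ids:
        raise OverlapError("signals must share an identical ordered SNP set")
    m = len(fm1.snp_ids)
    if m < 1:
        raise OverlapError("need at least one common SNP")
    l1, l2 = fm1.labf, fm2.labf
    logS1 = logsumexp(l1)
    logS2 = logsumexp(l2)
    logC = logsumexp(l1 + l2)
    logL = np.empty(5)
    logL[0] = 0.0
    logL[1] = np.log(cfg.p1) + logS1
    logL[2] = np.log(cfg.p2) + logS2
    # L3 = p1 p2 (S1 S2 - C); with one SNP the difference is exactly zero,
    # and rounding can push the ratio C/(S1 S2) to 1 — clamp mass to 0 then
    ratio = float(np.exp(min(logC - logS1 - logS2, 0.0)))
    if m == 1 or ratio >= 1.0:
        logL[3] = -np.inf
        if m > 1:
            logger.info("coloc %s x %s: H3 mass clamped to 0",
                        qtl_signal, trait_signal)
    else:
        logL[3] = (np.log(cfg.p1) + np.log(cfg.p2)
                   + logS1 + logS2 + np.log1p(-ratio))
    logL[4] = np.log(cfg.p12) + logC
    pp = np.exp(logL - logsumexp(logL))
    result = dict(zip(_HYP, (float(v) for v in pp)))
    return ColocResult(
        qtl_signal=qtl_signal, trait_signal=trait_signal, pp=result,
        n_snps_common=m,
        colocalized=result["H4"] >= cfg.pp4_report,
        low_coverage=m < 10)


# ---------------------------------------------------------------------------
# conditional colocalization of a gene region
# ---------------------------------------------------------------------------

FLANK_BP_DEFAULT = 250_000


def _signal_finemaps(
    stats_: cojo.MarginalStats,
    signals: cojo.SignalSet,
    W: float,
) -> dict[str, SignalFineMap]:
    """One fine-map per independent signal.

    With <= 1 lead, marginal statistics define a single signal; with >= 2
    leads each lead's signal uses the statistics conditioned on all other
    leads (the lead itself re-inserted with its joint estimate so the
    driving variant is part of its own signal).
    """
    if len(signals.lead_snps) <= 1:
        name = signals.lead_snps[0] if signals.lead_snps else "marginal"
        labf = wakefield_labf(stats_.b, stats_.se, W)
        return {name: SignalFineMap(stats_.snp_ids, np.asarray(labf),
                                    np.empty(0))}
    out: dict[str, SignalFineMap] = {}
    joint = signals.joint.set_index("snp_id")
    for lead in signals.lead_snps:
        cond = signals.conditional_stats[lead]
        ok = ~cond["masked"].to_numpy()
        ids = cond["snp_id"][ok].tolist()
        b = cond["b_cond"].to_numpy()[ok]
        se = cond["se_cond"].to_numpy()[ok]
        ids.append(lead)
        b = np.append(b, joint.loc[lead, "b_joint"])
        se = np.append(se, joint.loc[lead, "se_joint"])
        order = np.argsort([stats_.snp_ids.index(s) for s in ids])
        ids = [ids[i] for i in order]
        out[lead] = SignalFineMap(
            ids, np.asarray(wakefield_labf(b[order], se[order], W)),
            np.empty(0))
    return out


def conditional_coloc(
    qtl: GwasSumstats,
    trait: GwasSumstats,
    panel: LdPanel,
    gene_span: tuple[str, int, int],
    cfg: ColocConfig | None = None,
    flank_bp: int = FLANK_BP_DEFAULT,
    p_entry: float = cojo.P_ENTRY_DEFAULT,
    collinearity: float = cojo.COLLINEARITY_DEFAULT,
) -> list[ColocResult]:
    """Pairwise colocalization of independent QTL and trait signals.

    The analysis window is the gene span plus ``flank_bp`` on each side.
    Each dataset is decomposed with stepwise conditional selection; a
    dataset with one or no genome-wide-significant signal contributes its
    marginal statistics as a single signal.  Every (QTL signal x trait
    signal) combination is tested and all results returned.
    """
    cfg = cfg or ColocConfig()
    chrom, start, stop = gene_span
    window = (chrom, max(1, start - flank_bp), stop + flank_bp)
    ms_q = cojo.MarginalStats.from_sumstats(qtl, window)
    ms_t = cojo.MarginalStats.from_sumstats(trait, window)
    common = sorted(set(ms_q.snp_ids) & set(ms_t.snp_ids),
                    key=ms_q.snp_ids.index)
    if not common:
        raise OverlapError("no SNPs shared between QTL and trait in window")
    ms_q = ms_q.take([ms_q.snp_ids.index(s) for s in common])
    ms_t = ms_t.take([ms_t.snp_ids.index(s) for s in common])
    sig_q = cojo.cojo_slct(ms_q, panel, p_entry=p_entry,
                           collinearity=collinearity)
    sig_t = cojo.cojo_slct(ms_t, panel, p_entry=p_entry,
                           collinearity=collinearity)
    fms_q = _signal_finemaps(ms_q, sig_q, cfg.prior_var_W)
    fms_t = _signal_finemaps(ms_t, sig_t, cfg.prior_var_W)
    results = []
    for qname, fq in fms_q.items():
        for tname, ft in fms_t.items():
            shared = [s for s in fq.snp_ids if s in set(ft.snp_ids)]
            if not shared:
                continue
            qi = {s: i for i, s in enumerate(fq.snp_ids)}
            ti = {s: i for i, s in enumerate(ft.snp_ids)}
            fq_c = SignalFineMap(shared,
                                 fq.labf[[qi[s] for s in shared]], np.empty(0))
            ft_c = SignalFineMap(shared,
                                 ft.labf[[ti[s] for s in shared]], np.empty(0))
            results.append(coloc_pair(fq_c, ft_c, cfg,
                                      qtl_signal=f"{qtl.trait_id}:{qname}",
                                      trait_signal=f"{trait.trait_id}:{tname}"))
    return results
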