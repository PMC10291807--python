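"""Approximate conditional & joint analysis of a region from summary
statistics (COJO-style stepwise selection of independent signals).

The multiple-regression solution is reconstructed from marginal statistics
and a reference LD panel.  With f_k the effect-allele frequency, N_k the
per-SNP sample size, and s_k = sqrt(2 f_k (1-f_k)) the genotype SD under
Hardy-Weinberg:

* diagonal cross-products  D_kk = s_k^2 N_k  (~ x_k' x_k);
* off-diagonals            B_jk = r_jk s_j s_k min(N_j, N_k), with r_jk the
  reference correlation — the pairwise minimum sample size is the
  conservative reconciliation of per-SNP Ns;
* joint effects solve      B b_joint = D b_marginal;
* the phenotypic variance is estimated per SNP from the simple-regression
  identity var(y) ~ s_k^2 (N_k se_k^2 + b_k^2), region median taken.

Forward selection enters the SNP with the smallest conditional p below the
entry threshold whose reference r^2 with every selected SNP stays below the
collinearity cutoff; a backward pass drops any selected SNP whose joint p
rises above the threshold.  Conditional statistics for non-selected SNPs
subtract the LD-projected contribution of the selected joint effects; SNPs
in high LD with the conditioning set are masked rather than zeroed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from coloxwas.io_formats import GwasSumstats, LdPanel

P_ENTRY_DEFAULT = 5e-8
COLLINEARITY_DEFAULT = 0.1
RIDGE_DEFAULT = 0.01


class CollinearityError(ValueError):
    """The requested joint system is singular even after stabilization."""


@dataclasses.dataclass
class MarginalStats:
    """Region view of one trait's summary statistics, harmonized to a panel."""

    snp_ids: list[str]
    positions: np.ndarray
    b: np.ndarray
    se: np.ndarray
    freq: np.ndarray
    n: np.ndarray

    @property
    def z(self) -> np.ndarray:
        return self.b / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def __len__(self) -> int:
        return len(self.snp_ids)

    @classmethod
    def from_sumstats(cls, gwas: GwasSumstats,
                      window: tuple[str, int, int] | None = None,
                      ) -> "MarginalStats":
        df = gwas.records
        if window is not None:
            chrom, start, stop = window
            sel = ((df["chromosome"].astype(str) == str(chrom))
                   & (df["position"] >= start) & (df["position"] <= stop))
            df = df[sel]
        df = df.dropna(subset=["beta", "se", "freq_A1", "n"])
        return cls(
            snp_ids=df["snp_id"].tolist(),
            positions=df["position"].to_numpy(float),
            b=df["beta"].to_numpy(float),
            se=df["se"].to_numpy(float),
            freq=df["freq_A1"].to_numpy(float),
            n=df["n"].to_numpy(float),
        )

    def take(self, idx: np.ndarray) -> "MarginalStats":
        idx = np.asarray(idx, dtype=int)
        return MarginalStats(
            snp_ids=[self.snp_ids[i] for i in idx],
            positions=self.positions[idx], b=self.b[idx], se=self.se[idx],
            freq=self.freq[idx], n=self.n[idx])


@dataclasses.dataclass
class SignalSet:
    """Conditionally independent lead SNPs of one region."""

    lead_snps: list[str]
    joint: pd.DataFrame  # snp_id, b_joint, se_joint, p_joint
    conditional_stats: dict[str, pd.DataFrame]  # lead -> per-SNP table
    used_marginal: bool


def _var_y(stats_: MarginalStats) -> float:
    s2 = 2.0 * stats_.freq * (1.0 - stats_.freq)
    vp = s2 * (stats_.n * stats_.se**2 + stats_.b**2)
    return float(np.median(vp))


def _cross_products(stats_: MarginalStats, R: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(B, D_diag): reconstructed X'X and its exact diagonal."""
    s = np.sqrt(2.0 * stats_.freq * (1.0 - stats_.freq))
    n_pair = np.minimum.outer(stats_.n, stats_.n)
    B = R * np.outer(s, s) * n_pair
    D = s**2 * stats_.n
    np.fill_diagonal(B, D)
    return B, D


def approx_joint_fit(
    stats_: MarginalStats,
    snp_set: list[str],
    panel: LdPanel,
    ridge: float = RIDGE_DEFAULT,
) -> pd.DataFrame:
    """Joint (multiple-regression) effects of ``snp_set`` from marginals.

    Returns a DataFrame (snp_id, b_joint, se_joint, p_joint).  A single-SNP
    set returns the marginal statistics unchanged.
    """
    if not snp_set:
        raise ValueError("empty snp_set")
    pos = {s: i for i, s in enumerate(stats_.snp_ids)}
    idx = np.array([pos[s] for s in snp_set], dtype=int)
    sub = stats_.take(idx)
    if len(snp_set) == 1:
        z = sub.b / sub.se
        return pd.DataFrame({
            "snp_id": snp_set, "b_joint": sub.b, "se_joint": sub.se,
            "p_joint": 2.0 * stats.norm.sf(np.abs(z))})
    R = panel.correlation(snp_set, ridge=ridge)
    B, D = _cross_products(sub, R)
    rhs = D * sub.b
    try:
        bj = np.linalg.solve(B, rhs)
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(f"singular joint system: {exc}") from None
    var_y = _var_y(stats_)
    n_eff = float(np.min(sub.n))
    df_resid = max(n_eff - len(snp_set) - 1.0, 1.0)
    rss = var_y * n_eff - float(bj @ rhs)
    sigma2 = max(rss, 1e-12 * var_y * n_eff) / df_resid
    se_j = np.sqrt(sigma2 * np.diag(Binv))
    zj = bj / se_j
    return pd.DataFrame({
        "snp_id": snp_set, "b_joint": bj, "se_joint": se_j,
        "p_joint": 2.0 * stats.norm.sf(np.abs(zj))})


def conditional_stats(
    stats_: MarginalStats,
    condition_on: list[str],
    panel: LdPanel,
    collinearity: float = COLLINEARITY_DEFAULT,
    ridge: float = RIDGE_DEFAULT,
) -> pd.DataFrame:
    """Per-SNP statistics conditioned on the joint effects of ``condition_on``.

    Targets are all region SNPs outside the conditioning set.  A target
    whose reference r^2 with any conditioning SNP exceeds ``collinearity``
    is masked: emitted with NaN statistics, never a fabricated zero.
    """
    if not condition_on:
        raise ValueError("empty condition_on; use marginal statistics")
    joint = approx_joint_fit(stats_, condition_on, panel, ridge=ridge)
    bj = joint["b_joint"].to_numpy()
    cond_pos = {s: i for i, s in enumerate(stats_.snp_ids)}
    cidx = np.array([cond_pos[s] for s in condition_on], dtype=int)
    csub = stats_.take(cidx)
    tmask = np.ones(len(stats_), dtype=bool)
    tmask[cidx] = False
    tidx = np.flatnonzero(tmask)
    tsub = stats_.take(tidx)

    all_ids = [stats_.snp_ids[i] for i in np.concatenate([tidx, cidx])]
    R_all = panel.correlation(all_ids, ridge=0.0)
    nt = len(tidx)
    R_tc = R_all[:nt, nt:]

    var_y = _var_y(stats_)
    n_eff = float(np.min(csub.n))
    s_c = np.sqrt(2.0 * csub.freq * (1.0 - csub.freq))
    s_t = np.sqrt(2.0 * tsub.freq * (1.0 - tsub.freq))
    D_t = s_t**2 * tsub.n
    n_pair = np.minimum.outer(tsub.n, csub.n)
    B_tc = R_tc * np.outer(s_t, s_c) * n_pair

    D_c = s_c**2 * csub.n
    rss = var_y * n_eff - float(bj @ (D_c * csub.b))
    df_resid = max(n_eff - len(condition_on) - 1.0, 1.0)
    sigma2_c = max(rss, 1e-12 * var_y * n_eff) / df_resid

    b_cond = tsub.b - (B_tc @ bj) / D_t
    se_cond = np.sqrt(sigma2_c / D_t)
    masked = (R_tc**2 > collinearity).any(axis=1)
    b_cond[masked] = np.nan
    se_cond[masked] = np.nan
    z_cond = b_cond / se_cond
    return pd.DataFrame({
        "snp_id": tsub.snp_ids,
        "position": tsub.positions,
        "b_cond": b_cond,
        "se_cond": se_cond,
        "p_cond": 2.0 * stats.norm.sf(np.abs(z_cond)),
        "masked": masked,
    })


def cojo_slct(
    stats_: MarginalStats,
    panel: LdPanel,
    p_entry: float = P_ENTRY_DEFAULT,
    collinearity: float = COLLINEARITY_DEFAULT,
    ridge: float = RIDGE_DEFAULT,
    backward: bool = True,
    max_leads: int = 20,
) -> SignalSet:
    """Stepwise forward selection of conditionally independent lead SNPs.

    Seeds with the smallest marginal p below ``p_entry``; repeatedly adds
    the SNP with the smallest conditional p below ``p_entry`` whose
    reference r^2 with every selected SNP is at most ``collinearity``;
    after each addition a backward check drops leads whose joint p rises
    above the threshold.  Ties in minimal p break toward the smaller
    genomic position.  An empty region yields an empty, valid SignalSet.
    """
    empty = SignalSet(lead_snps=[], joint=pd.DataFrame(
        columns=["snp_id", "b_joint", "se_joint", "p_joint"]),
        conditional_stats={}, used_marginal=True)
    if len(stats_) == 0:
        return empty
    p_marg = stats_.p

    def _argmin_p(pvals: np.ndarray, positions: np.ndarray) -> int:
        best = np.nanmin(pvals)
        cand = np.flatnonzero(pvals == best)
        return int(cand[np.argmin(positions[cand])])

    i0 = _argmin_p(p_marg, stats_.positions)
    if not (p_marg[i0] < p_entry):
        return empty
    selected = [stats_.snp_ids[i0]]

    while len(selected) < max_leads:
        cond = conditional_stats(stats_, selected, panel,
                                 collinearity=collinearity, ridge=ridge)
        ok = ~cond["masked"].to_numpy() & np.isfinite(
            cond["p_cond"].to_numpy())
        if not ok.any():
            break
        pv = np.where(ok, cond["p_cond"].to_numpy(), np.nan)
        j = _argmin_p(pv, cond["position"].to_numpy())
        if not (pv[j] < p_entry):
            break
        candidate = cond["snp_id"].iloc[j]
        # pairwise collinearity among the would-be selected set
        R_sel = panel.correlation(selected + [candidate], ridge=0.0)
        off = R_sel[np.triu_indices(len(R_sel), k=1)]
        if (off**2 > collinearity).any():
            break
        selected.append(candidate)
        if backward and len(selected) > 1:
            joint = approx_joint_fit(stats_, selected, panel, ridge=ridge)
            keep = joint["p_joint"].to_numpy() < p_entry
            if not keep.all():
                selected = [s for s, k in zip(selected, keep) if k]
                if not selected:
                    return empty

    joint = approx_joint_fit(stats_, selected, panel, ridge=ridge)
    cond_tables: dict[str, pd.DataFrame] = {}
    for lead in selected:
        others = [s for s in selected if s != lead]
        if others:
            cond_tables[lead] = conditional_stats(
                stats_, others, panel, collinearity=collinearity,
                ridge=ridge)
    return SignalSet(
        lead_snps=selected, joint=joint, conditional_stats=cond_tables,
        used_marginal=len(selected) <= 1)
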