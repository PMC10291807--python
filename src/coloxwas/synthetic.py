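"""Synthetic LD panels, cis-heritable molecular features, and mediated GWAS
summary statistics with known ground truth.

The generator replaces consortium-scale GWAS and QTL panels with desk-scale
simulations that preserve the statistical structure the pipeline depends on:

* blockwise LD from a latent Gaussian AR(1) process thresholded at per-SNP
  minor-allele-frequency quantiles (two haplotype draws summed to a dosage);
* molecular features with 1-3 causal cis SNPs at a stated cis heritability;
* trait GWAS z-scores drawn from their asymptotic sampling distribution
  z ~ N(sqrt(N) R b_std, R), which reproduces the LD-induced correlation of
  marginal statistics without simulating individual phenotypes;
* named scenarios (null, single_shared, distinct_in_ld, two_signals,
  coregulated_pair) bundling a panel, weight truth, per-trait sumstats, and
  a TruthRecord oracle.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coloxwas.io_formats import GwasSumstats, LdPanel, WeightModel

SCENARIO_NAMES = (
    "null", "single_shared", "distinct_in_ld", "two_signals",
    "coregulated_pair",
)

#: accepted forms for per-SNP causal effects
CausalBetas = dict | np.ndarray | Sequence

#: alternating non-palindromic allele pairs assigned to simulated SNPs
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


class ParameterError(ValueError):
    """A simulation parameter is outside its valid range."""


@dataclasses.dataclass
class ScenarioSpec:
    """Knobs of one simulated study.

    Defaults are the package's standing study conditions: a 100-SNP cis
    block with moderate AR(1) LD, a 2,000-individual reference/QTL panel,
    GWAS effective N of 1e5, cis h2 of 0.2, and a mediated trait effect of
    0.15 SD per SD of feature.
    """

    name: str = "single_shared"
    p_snps: int = 100
    n_panel: int = 2000
    n_qtl: int = 2000
    n_gwas: float = 1e5
    ld_decay: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_cis: float = 0.2
    n_causal: int = 1
    alpha_mediation: float = 0.15
    rho_target: float = 0.9
    seed: int = 0
    chromosome: str = "1"
    start_bp: int = 1_000_000
    spacing_bp: int = 2_000

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ParameterError(f"unknown scenario {self.name!r}")
        if not (0 <= self.ld_decay < 1):
            raise ParameterError("ld_decay must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ParameterError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if not (0 < self.h2_cis < 1):
            raise ParameterError("h2_cis must be in (0, 1)")
        if self.n_causal > self.p_snps:
            raise ParameterError("n_causal exceeds p_snps")
        if self.n_gwas <= 0:
            raise ParameterError("n_gwas must be positive")


@dataclasses.dataclass
class TruthRecord:
    """Generating configuration exposed as an evaluation oracle."""

    causal_snps_by_feature: dict[str, list[str]]
    causal_snps_by_trait: dict[str, list[str]]
    true_rho: float | None
    expected_coloc: dict[tuple[str, str], str]  # (feature, trait) -> verdict


@dataclasses.dataclass
class ScenarioBundle:
    spec: ScenarioSpec
    panel: LdPanel
    qtl_panel: LdPanel
    models: list[WeightModel]
    features: dict[str, np.ndarray]  # per-individual values in qtl_panel
    sumstats: dict[str, GwasSumstats]
    truth: TruthRecord


# ---------------------------------------------------------------------------
# LD panel
# ---------------------------------------------------------------------------

def _draw_haplotypes(rng: np.random.Generator, n: int, mafs: np.ndarray,
                     decay: float) -> np.ndarray:
    """One haplotype per individual via AR(1) latent Gaussian thresholding."""
    p = len(mafs)
    latent = np.empty((n, p))
    latent[:, 0] = rng.standard_normal(n)
    if p > 1:
        innov = rng.standard_normal((n, p - 1)) * np.sqrt(1 - decay**2)
        for j in range(1, p):
            latent[:, j] = decay * latent[:, j - 1] + innov[:, j - 1]
    # allele is the minor allele iff the latent value is in the upper tail
    thresh = stats.norm.ppf(1 - mafs)
    return (latent > thresh[None, :]).astype(np.int8)


def simulate_ld_panel(spec: ScenarioSpec,
                      rng: np.random.Generator | None = None) -> LdPanel:
    """Simulate a genotype reference panel with AR(1)-patterned LD.

    Dosages are sums of two independent haplotype draws; the latent AR(1)
    coefficient ``ld_decay`` controls adjacent-SNP correlation (the realized
    dosage-scale r is attenuated by the dichotomization, see the orthant
    oracle in the tests).
    """
    if spec.p_snps < 2:
        raise ParameterError("p_snps must be >= 2")
    if spec.n_panel < 30:
        raise ParameterError("n_panel must be >= 30")
    lo, hi = spec.maf_range
    if lo >= hi:
        raise ParameterError("degenerate maf_range")
    rng = rng or np.random.default_rng(spec.seed)
    mafs = rng.uniform(lo, hi, spec.p_snps)
    hap1 = _draw_haplotypes(rng, spec.n_panel, mafs, spec.ld_decay)
    hap2 = _draw_haplotypes(rng, spec.n_panel, mafs, spec.ld_decay)
    dosages = (hap1 + hap2).astype(float)
    # resample monomorphic columns marginally so every SNP is usable
    const = dosages.std(axis=0) == 0
    for j in np.flatnonzero(const):
        dosages[:, j] = rng.binomial(2, max(mafs[j], lo), spec.n_panel)
        if dosages[:, j].std() == 0:
            dosages[0, j] = 2 - dosages[0, j]
    snps = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(spec.p_snps)],
        "chromosome": spec.chromosome,
        "position": spec.start_bp + spec.spacing_bp * np.arange(spec.p_snps),
        "A1": [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][0] for i in range(spec.p_snps)],
        "A2": [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][1] for i in range(spec.p_snps)],
        "freq_A1": mafs,
    })
    return LdPanel(snps, dosages)


def latent_to_dosage_r(decay: float, maf_i: float, maf_j: float,
                       lag: int = 1) -> float:
    """Expected dosage-scale correlation between two SNPs whose latent
    Gaussians correlate at ``decay**lag``, by bivariate-normal orthant mass.

    Serves as the independent oracle for the thresholding construction:
    cov(carrier indicators) = P(both latents in upper tails) - maf_i*maf_j,
    and the dosage correlation equals the indicator correlation because a
    dosage is a sum of two iid indicators per SNP.
    """
    rho = decay ** lag
    ti, tj = stats.norm.ppf(1 - maf_i), stats.norm.ppf(1 - maf_j)
    upper = stats.multivariate_normal(mean=[0, 0],
                                      cov=[[1, rho], [rho, 1]])
    # orthant mass P(X > ti, Y > tj) via the CDF of the lower quadrant
    both = upper.cdf([-ti, -tj])  # symmetry: P(X>ti,Y>tj)=P(X<-ti,Y<-tj)
    cov = both - maf_i * maf_j
    sd = np.sqrt(maf_i * (1 - maf_i) * maf_j * (1 - maf_j))
    return float(cov / sd)


# ---------------------------------------------------------------------------
# molecular features
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return (X - mu) / sd


def simulate_feature(
    panel: LdPanel,
    spec: ScenarioSpec,
    rng: np.random.Generator,
    causal_idx: Sequence[int] | None = None,
    betas: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one cis-heritable feature in the given panel.

    Returns (truth table with columns snp_id, beta for the causal SNPs,
    per-individual feature values).  Effects are on standardized dosage;
    they are rescaled so that the genetic component has variance ``h2_cis``
    in the panel, and the total feature variance is ~1.
    """
    if spec.n_causal < 1:
        raise ParameterError("n_causal must be >= 1")
    if not (0 < spec.h2_cis < 1):
        raise ParameterError("h2_cis must be in (0, 1)")
    if causal_idx is None:
        causal_idx = np.sort(rng.choice(panel.dosages.shape[1],
                                        size=spec.n_causal, replace=False))
    causal_idx = np.asarray(causal_idx, dtype=int)
    if betas is None:
        betas = rng.choice([-1.0, 1.0], size=len(causal_idx)) * \
            rng.uniform(0.5, 1.0, size=len(causal_idx))
    betas = np.asarray(betas, dtype=float)
    Xc = _standardize(panel.dosages[:, causal_idx])
    g = Xc @ betas
    gv = g.var()
    if gv > 0:
        scale = np.sqrt(spec.h2_cis / gv)
    else:
        scale = 0.0
    betas = betas * scale
    g = g * scale
    noise = rng.standard_normal(panel.n_individuals) * np.sqrt(1 - spec.h2_cis)
    feature = g + noise
    truth = pd.DataFrame({
        "snp_id": [panel.snp_ids[i] for i in causal_idx],
        "beta": betas,
    })
    return truth, feature


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas_sumstats(
    panel: LdPanel,
    causal_betas: CausalBetas,
    n_gwas: float,
    rng: np.random.Generator,
    trait_id: str = "trait",
) -> GwasSumstats:
    """Draw marginal GWAS statistics from their asymptotic distribution.

    With b_std the per-SNP causal effects on the standardized-trait,
    standardized-genotype scale and R the panel dosage correlation, the
    marginal z-vector is N(sqrt(N) R b_std, R).  beta, se, freq, and n are
    back-filled consistently: se = 1/sqrt(N * 2 f (1-f)) on the
    standardized-trait scale, beta = z * se.
    """
    if n_gwas <= 0:
        raise ParameterError("n_gwas must be positive")
    p = panel.dosages.shape[1]
    b = np.zeros(p)
    if isinstance(causal_betas, dict):
        lookup = {s: i for i, s in enumerate(panel.snp_ids)}
        for snp, eff in causal_betas.items():
            b[lookup[snp]] = eff
    else:
        b = np.asarray(causal_betas, dtype=float)
        if b.shape != (p,):
            raise ParameterError("causal_betas length must match panel SNPs")
    R = panel.correlation()
    mean = np.sqrt(n_gwas) * (R @ b)
    # draw via Cholesky with a small jitter for numerically semidefinite R
    jitter = 1e-10
    for _ in range(6):
        try:
            L = np.linalg.cholesky(R + jitter * np.eye(p))
            break
        except np.linalg.LinAlgError:
            jitter *= 100
    else:  # pragma: no cover
        raise np.linalg.LinAlgError("panel correlation not factorizable")
    z = mean + L @ rng.standard_normal(p)
    freq = panel.frequencies()
    se = 1.0 / np.sqrt(n_gwas * 2.0 * freq * (1.0 - freq))
    records = panel.snps[["snp_id", "chromosome", "position", "A1", "A2"]].copy()
    records["freq_A1"] = freq
    records["se"] = se
    records["z"] = z
    records["beta"] = z * se
    records["n"] = float(n_gwas)
    return GwasSumstats(trait_id, records[
        ["snp_id", "chromosome", "position", "A1", "A2",
         "freq_A1", "beta", "se", "z", "n"]
    ])


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _gene_span(panel: LdPanel, lo_frac: float = 0.3,
               hi_frac: float = 0.7) -> tuple[str, int, int]:
    pos = panel.snps["position"].to_numpy()
    p = len(pos)
    return (str(panel.snps["chromosome"].iloc[0]),
            int(pos[int(p * lo_frac)]), int(pos[int(p * hi_frac)]))


def _pick_low_ld_pair(panel: LdPanel, rng: np.random.Generator,
                      r2_max: float = 0.05, tries: int = 500) -> tuple[int, int]:
    """Rejection-sample two SNP indices with panel r^2 below ``r2_max``."""
    X = _standardize(panel.dosages)
    n = X.shape[0]
    for _ in range(tries):
        i, j = rng.choice(X.shape[1], size=2, replace=False)
        r = float(X[:, i] @ X[:, j]) / n
        if r * r < r2_max:
            return int(min(i, j)), int(max(i, j))
    raise ParameterError("could not place two low-LD causal SNPs")


def _pick_moderate_ld_pair(panel: LdPanel, rng: np.random.Generator,
                           r2_lo: float = 0.2, r2_hi: float = 0.5,
                           tries: int = 2000) -> tuple[int, int]:
    X = _standardize(panel.dosages)
    n = X.shape[0]
    for _ in range(tries):
        i, j = rng.choice(X.shape[1], size=2, replace=False)
        r2 = (float(X[:, i] @ X[:, j]) / n) ** 2
        if r2_lo <= r2 <= r2_hi:
            return int(min(i, j)), int(max(i, j))
    raise ParameterError("could not place two moderate-LD causal SNPs")


def _feature_truth_model(feature_id: str, panel: LdPanel, truth: pd.DataFrame,
                         span: tuple[str, int, int],
                         modality: str = "expression",
                         tissue: str = "sim_tissue") -> WeightModel:
    entries = panel.snps.set_index("snp_id").loc[
        truth["snp_id"], ["A1", "A2"]
    ].reset_index()
    entries["weight"] = truth["beta"].to_numpy()
    return WeightModel(feature_id=feature_id, modality=modality,
                       tissue=tissue, gene_span=span, entries=entries,
                       training_r2=float("nan"))


def make_scenario(spec: ScenarioSpec) -> ScenarioBundle:
    """Build a named scenario bundle with its ground-truth oracle.

    Scenarios:

    ``null``
        no causal SNPs for feature or trait; sumstats are pure noise.
    ``single_shared``
        one causal SNP drives both the feature and (through mediation with
        effect ``alpha_mediation``) the trait — the colocalization H4 case.
    ``distinct_in_ld``
        feature and trait have different causal SNPs in moderate LD
        (r^2 ~ 0.2-0.5) — the H3 case.
    ``two_signals``
        two low-LD causal trait SNPs; the feature shares only the first —
        exactly one of the two independent trait signals colocalizes.
    ``coregulated_pair``
        two features sharing a causal SNP with effect ratio chosen to give
        cis genetic correlation ~ ``rho_target``; both mediate the trait.
    """
    rng = np.random.default_rng(spec.seed)
    panel = simulate_ld_panel(spec, rng)
    qtl_spec = dataclasses.replace(spec, n_panel=spec.n_qtl)
    qtl_panel = LdPanel(
        panel.snps.copy(),
        _draw_qtl_dosages(panel, qtl_spec, rng),
    )
    models: list[WeightModel] = []
    features: dict[str, np.ndarray] = {}
    sumstats: dict[str, GwasSumstats] = {}
    p = spec.p_snps
    span = _gene_span(panel)

    if spec.name == "null":
        truth_f, feat = simulate_feature(
            qtl_panel, dataclasses.replace(spec, h2_cis=1e-6), rng,
            causal_idx=[0], betas=np.array([0.0]))
        features["feature_1"] = feat
        sumstats["trait_1"] = simulate_gwas_sumstats(
            panel, np.zeros(p), spec.n_gwas, rng, "trait_1")
        truth = TruthRecord(
            causal_snps_by_feature={"feature_1": []},
            causal_snps_by_trait={"trait_1": []},
            true_rho=None, expected_coloc={("feature_1", "trait_1"): "H0"})
        # a truth weight model is undefined under the null; none emitted
        return ScenarioBundle(spec, panel, qtl_panel, models, features,
                              sumstats, truth)

    if spec.name == "single_shared":
        ci = [int(p // 2)]
        truth_f, feat = simulate_feature(qtl_panel, spec, rng, causal_idx=ci)
        features["feature_1"] = feat
        models.append(_feature_truth_model("feature_1", panel, truth_f, span))
        b_trait = np.zeros(p)
        b_trait[ci[0]] = spec.alpha_mediation * np.sqrt(spec.h2_cis) * \
            np.sign(truth_f["beta"].iloc[0])
        sumstats["trait_1"] = simulate_gwas_sumstats(
            panel, b_trait, spec.n_gwas, rng, "trait_1")
        truth = TruthRecord(
            causal_snps_by_feature={"feature_1": truth_f["snp_id"].tolist()},
            causal_snps_by_trait={"trait_1": truth_f["snp_id"].tolist()},
            true_rho=None, expected_coloc={("feature_1", "trait_1"): "H4"})
        return ScenarioBundle(spec, panel, qtl_panel, models, features,
                              sumstats, truth)

    if spec.name == "distinct_in_ld":
        i, j = _pick_moderate_ld_pair(panel, rng)
        truth_f, feat = simulate_feature(qtl_panel, spec, rng, causal_idx=[i])
        features["feature_1"] = feat
        models.append(_feature_truth_model("feature_1", panel, truth_f, span))
        b_trait = np.zeros(p)
        b_trait[j] = spec.alpha_mediation * np.sqrt(spec.h2_cis)
        sumstats["trait_1"] = simulate_gwas_sumstats(
            panel, b_trait, spec.n_gwas, rng, "trait_1")
        truth = TruthRecord(
            causal_snps_by_feature={"feature_1": [panel.snp_ids[i]]},
            causal_snps_by_trait={"trait_1": [panel.snp_ids[j]]},
            true_rho=None, expected_coloc={("feature_1", "trait_1"): "H3"})
        return ScenarioBundle(spec, panel, qtl_panel, models, features,
                              sumstats, truth)

    if spec.name == "two_signals":
        i, j = _pick_low_ld_pair(panel, rng)
        truth_f, feat = simulate_feature(qtl_panel, spec, rng, causal_idx=[i])
        features["feature_1"] = feat
        models.append(_feature_truth_model("feature_1", panel, truth_f, span))
        b_trait = np.zeros(p)
        eff = spec.alpha_mediation * np.sqrt(spec.h2_cis)
        b_trait[i] = eff
        b_trait[j] = eff
        sumstats["trait_1"] = simulate_gwas_sumstats(
            panel, b_trait, spec.n_gwas, rng, "trait_1")
        truth = TruthRecord(
            causal_snps_by_feature={"feature_1": [panel.snp_ids[i]]},
            causal_snps_by_trait={"trait_1": [panel.snp_ids[i],
                                              panel.snp_ids[j]]},
            true_rho=None,
            expected_coloc={("feature_1", "trait_1"): "H4_signal_A_only"})
        return ScenarioBundle(spec, panel, qtl_panel, models, features,
                              sumstats, truth)

    if spec.name == "coregulated_pair":
        ci = int(p // 2)
        rho = spec.rho_target
        if not (-1 <= rho <= 1):
            raise ParameterError("rho_target must be in [-1, 1]")
        # both features driven by one shared causal SNP plus (for |rho|<1) a
        # private causal SNP each; sharing fraction rho of genetic SD gives
        # cor(g_a, g_b) = rho when private components are uncorrelated
        k = abs(rho)
        sgn = np.sign(rho) if rho != 0 else 1.0
        priv_a = (ci + max(2, p // 10)) % p
        priv_b = (ci - max(2, p // 10)) % p
        w_shared = np.sqrt(k)
        w_priv = np.sqrt(max(0.0, 1 - k))
        ta, fa = simulate_feature(
            qtl_panel, spec, rng, causal_idx=[ci, priv_a],
            betas=np.array([w_shared, w_priv]))
        tb, fb = simulate_feature(
            qtl_panel, spec, rng, causal_idx=[ci, priv_b],
            betas=np.array([sgn * w_shared, w_priv]))
        features["feature_a"] = fa
        features["feature_b"] = fb
        models.append(_feature_truth_model("feature_a", panel, ta, span))
        models.append(_feature_truth_model("feature_b", panel, tb, span))
        b_trait = np.zeros(p)
        b_trait[ci] = spec.alpha_mediation * np.sqrt(spec.h2_cis)
        for trait in ("trait_1", "trait_2"):
            sumstats[trait] = simulate_gwas_sumstats(
                panel, b_trait, spec.n_gwas, rng, trait)
        truth = TruthRecord(
            causal_snps_by_feature={"feature_a": ta["snp_id"].tolist(),
                                    "feature_b": tb["snp_id"].tolist()},
            causal_snps_by_trait={t: [panel.snp_ids[ci]]
                                  for t in ("trait_1", "trait_2")},
            true_rho=rho,
            expected_coloc={("feature_a", "trait_1"): "H4",
                            ("feature_b", "trait_1"): "H4"})
        return ScenarioBundle(spec, panel, qtl_panel, models, features,
                              sumstats, truth)

    raise ParameterError(f"unknown scenario {spec.name!r}")


def marginal_sumstats_from_individuals(panel: LdPanel, y: np.ndarray,
                                       trait_id: str) -> GwasSumstats:
    """Per-SNP simple-regression summary statistics of phenotype ``y`` on
    each dosage column of ``panel`` — the in-sample summary-statistic view
    used by the exact-regression oracles."""
    X = panel.dosages
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    vx = (xc**2).sum(axis=0) / n
    b = (xc.T @ yc) / n / vx
    resid_var = np.maximum(yc @ yc / n - b**2 * vx, 1e-12)
    se = np.sqrt(resid_var / (n * vx) * n / max(n - 2, 1))
    freq = panel.frequencies()
    records = panel.snps[["snp_id", "chromosome", "position",
                          "A1", "A2"]].copy()
    records["freq_A1"] = freq
    records["beta"] = b
    records["se"] = se
    records["z"] = b / se
    records["n"] = float(n)
    return GwasSumstats(trait_id, records[
        ["snp_id", "chromosome", "position", "A1", "A2",
         "freq_A1", "beta", "se", "z", "n"]])


def feature_qtl_sumstats(bundle: "ScenarioBundle",
                         feature_id: str) -> GwasSumstats:
    """Marginal QTL summary statistics for one simulated feature: the
    summary-statistic view a QTL consortium would release."""
    if feature_id not in bundle.features:
        raise KeyError(f"unknown feature {feature_id!r}")
    return marginal_sumstats_from_individuals(
        bundle.qtl_panel, bundle.features[feature_id], f"qtl_{feature_id}")


def _draw_qtl_dosages(panel: LdPanel, spec: ScenarioSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Independent individuals from the same LD process as ``panel``."""
    mafs = panel.snps["freq_A1"].to_numpy(float)
    hap1 = _draw_haplotypes(rng, spec.n_panel, mafs, spec.ld_decay)
    hap2 = _draw_haplotypes(rng, spec.n_panel, mafs, spec.ld_decay)
    dosages = (hap1 + hap2).astype(float)
    const = dosages.std(axis=0) == 0
    for j in np.flatnonzero(const):
        dosages[:, j] = rng.binomial(2, max(mafs[j], 0.02), spec.n_panel)
        if dosages[:, j].std() == 0:
            dosages[0, j] = 2 - dosages[0, j]
    return dosages
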