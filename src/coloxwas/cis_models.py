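"""Elastic-net cis prediction models and feature imputation.

Weights are trained on column-standardized dosages within a cis window
around the gene span (default +/- 500 kb), with the penalty chosen by
cross-validated prediction correlation over a log-spaced grid.  A feature
whose best cross-validated correlation is not positive is flagged
untrainable (empty model), the standard heritability gate of TWAS weight
pipelines.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from coloxwas.io_formats import LdPanel, ValidationError, WeightModel

DEFAULT_CIS_WINDOW_BP = 500_000


class WindowError(ValueError):
    """No SNPs fall in the requested cis window."""


class ImputationError(KeyError):
    """A model SNP is absent from the imputation panel."""


@dataclasses.dataclass
class CisTrainingConfig:
    cis_window_bp: int = DEFAULT_CIS_WINDOW_BP
    l1_ratio: float = 0.5
    cv_folds: int = 5
    penalty_grid: tuple[float, ...] = tuple(np.logspace(-3, 0.5, 20))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 3:
            raise ValueError("cv_folds must be >= 3")
        if not len(self.penalty_grid):
            raise ValueError("penalty_grid must be nonempty")
        if not (0 < self.l1_ratio <= 1):
            raise ValueError("l1_ratio must be in (0, 1]")


def cis_snp_mask(panel: LdPanel, gene_span: tuple[str, int, int],
                 window_bp: int) -> np.ndarray:
    """Boolean mask of panel SNPs within ``window_bp`` of the gene span
    (1-based inclusive coordinates)."""
    chrom, start, stop = gene_span
    pos = panel.snps["position"].to_numpy()
    on_chr = panel.snps["chromosome"].astype(str).to_numpy() == str(chrom)
    return on_chr & (pos >= start - window_bp) & (pos <= stop + window_bp)


def fit_weights(
    panel: LdPanel,
    feature: np.ndarray,
    gene_span: tuple[str, int, int],
    config: CisTrainingConfig | None = None,
    feature_id: str = "feature",
    modality: str = "expression",
    tissue: str = "sim_tissue",
) -> WeightModel:
    """Train an elastic-net cis model for one feature.

    The penalty with the best cross-validated prediction correlation wins;
    ``training_r2`` records that correlation squared (signed: negative CV
    correlation yields the untrainable empty model).
    """
    config = config or CisTrainingConfig()
    feature = np.asarray(feature, dtype=float)
    if feature.std() == 0:
        raise ValidationError("constant feature cannot be modelled")
    if len(feature) != panel.n_individuals:
        raise ValidationError("feature length must match panel individuals")
    if panel.n_individuals < config.cv_folds * 5:
        raise ValidationError(
            f"need >= {config.cv_folds * 5} individuals for "
            f"{config.cv_folds}-fold training")
    mask = cis_snp_mask(panel, gene_span, config.cis_window_bp)
    if not mask.any():
        raise WindowError(f"no SNPs within cis window of {gene_span}")
    idx = np.flatnonzero(mask)
    X = panel.dosages[:, idx]
    sd = X.std(axis=0)
    keep = sd > 0
    idx, X, sd = idx[keep], X[:, keep], sd[keep]
    if X.shape[1] == 0:
        raise WindowError("all cis SNPs are monomorphic")
    Xs = (X - X.mean(axis=0)) / sd
    y = (feature - feature.mean()) / feature.std()

    kf = KFold(n_splits=config.cv_folds, shuffle=True,
               random_state=config.seed)
    splits = list(kf.split(Xs))
    grid = sorted(config.penalty_grid)
    best_alpha, best_cv_r = None, -np.inf
    for alpha in grid:
        preds = np.zeros_like(y)
        for tr, te in splits:
            en = ElasticNet(alpha=alpha, l1_ratio=config.l1_ratio,
                            max_iter=5000)
            en.fit(Xs[tr], y[tr])
            preds[te] = en.predict(Xs[te])
        if preds.std() == 0:
            cv_r = 0.0
        else:
            cv_r = float(np.corrcoef(preds, y)[0, 1])
        if cv_r > best_cv_r:
            best_cv_r, best_alpha = cv_r, alpha

    # trainability gate: the CV prediction correlation must be positive and
    # nominally significant (one-sided p < 0.01), the usual guard against
    # noise features acquiring spurious weights
    trainable = best_cv_r > 0
    if trainable:
        n = len(y)
        t = best_cv_r * np.sqrt((n - 2) / max(1e-12, 1 - best_cv_r**2))
        from scipy import stats as sps
        trainable = sps.t.sf(t, df=n - 2) < 0.01
    if not trainable:
        return WeightModel(
            feature_id=feature_id, modality=modality, tissue=tissue,
            gene_span=gene_span,
            entries=pd.DataFrame(columns=["snp_id", "A1", "A2", "weight"]),
            training_r2=0.0)

    en = ElasticNet(alpha=best_alpha, l1_ratio=config.l1_ratio, max_iter=10000)
    en.fit(Xs, y)
    w = en.coef_
    nz = w != 0
    if not nz.any():
        return WeightModel(
            feature_id=feature_id, modality=modality, tissue=tissue,
            gene_span=gene_span,
            entries=pd.DataFrame(columns=["snp_id", "A1", "A2", "weight"]),
            training_r2=0.0)
    sel = idx[nz]
    entries = panel.snps.iloc[sel][["snp_id", "A1", "A2"]].copy()
    entries["weight"] = w[nz]
    return WeightModel(
        feature_id=feature_id, modality=modality, tissue=tissue,
        gene_span=gene_span, entries=entries.reset_index(drop=True),
        training_r2=float(np.sign(best_cv_r) * best_cv_r**2))


def impute_feature(panel: LdPanel, model: WeightModel) -> np.ndarray:
    """Impute the feature as X_std @ w over the model's SNPs.

    Dosages are standardized with panel-estimated means and SDs.  Raises
    :class:`ImputationError` if any model SNP is missing from the panel.
    """
    if model.untrainable:
        return np.zeros(panel.n_individuals)
    try:
        idx = panel.index_of(model.snp_ids)
    except KeyError as exc:
        raise ImputationError(str(exc)) from None
    panel_alleles = panel.snps.iloc[idx][["A1", "A2"]].to_numpy()
    w = model.weights.copy()
    for k, (a1, a2) in enumerate(model.entries[["A1", "A2"]].to_numpy()):
        pa1, pa2 = panel_alleles[k]
        if (a1, a2) == (pa1, pa2):
            continue
        if (a2, a1) == (pa1, pa2):
            w[k] = -w[k]
        else:
            raise ImputationError(
                f"alleles for {model.snp_ids[k]!r} irreconcilable with panel")
    X = panel.dosages[:, idx]
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = model.snp_ids[int(np.argmax(sd == 0))]
        raise ImputationError(f"monomorphic panel SNP {bad!r}")
    Xs = (X - X.mean(axis=0)) / sd
    return Xs @ w
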