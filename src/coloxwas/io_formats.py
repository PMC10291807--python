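"""On-disk dialects and in-memory containers for summary statistics, cis
weight models, and LD reference panels, with strict allele harmonization.

Coordinates are 1-based inclusive throughout, following the GWAS and weight
file convention.  SNP matching is by identifier plus allele pair, never by
position alone.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: strand-ambiguous (palindromic) allele pairs
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a type invariant."""


class HarmonizationError(ValueError):
    """Sumstats and panel cannot be reconciled (e.g. empty intersection)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_SUMSTAT_COLUMNS = [
    "snp_id", "chromosome", "position", "A1", "A2",
    "freq_A1", "beta", "se", "z", "n",
]


@dataclasses.dataclass
class GwasSumstats:
    """Marginal per-SNP association statistics for one trait.

    ``records`` is a DataFrame with columns snp_id, chromosome, position,
    A1 (effect allele), A2, freq_A1, beta, se, z, n.  beta/se may be NaN in
    the z-only (``fusion_sumstats``) dialect.
    """

    trait_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.records
        missing = [c for c in _SUMSTAT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sumstats missing columns: {missing}")
        dup = df["snp_id"][df["snp_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate snp_id in trait {self.trait_id!r}: {dup.iloc[0]!r}"
            )
        freq = df["freq_A1"].to_numpy(float)
        ok = np.isnan(freq) | ((freq > 0) & (freq < 1))
        if not ok.all():
            bad = df["snp_id"].iloc[int(np.argmin(ok))]
            raise ValidationError(f"freq_A1 out of (0,1) at {bad!r}")
        n = df["n"].to_numpy(float)
        if not (np.isnan(n) | (n >= 1)).all():
            raise ValidationError("per-SNP n must be >= 1")
        beta = df["beta"].to_numpy(float)
        se = df["se"].to_numpy(float)
        z = df["z"].to_numpy(float)
        have = ~np.isnan(beta) & ~np.isnan(se) & ~np.isnan(z)
        if have.any():
            if (se[have] <= 0).any():
                raise ValidationError("se must be > 0")
            resid = np.abs(z[have] - beta[have] / se[have])
            # z is stored at finite precision; tolerance scales with |z|
            tol = 1e-6 * np.maximum(1.0, np.abs(z[have]))
            if (resid > tol).any():
                bad = df["snp_id"].to_numpy()[have][resid > tol][0]
                raise ValidationError(f"z != beta/se at {bad!r}")

    @property
    def snp_ids(self) -> list[str]:
        return self.records["snp_id"].tolist()

    def subset(self, snp_ids: Sequence[str]) -> "GwasSumstats":
        keep = self.records[self.records["snp_id"].isin(set(snp_ids))]
        return GwasSumstats(self.trait_id, keep.copy())


@dataclasses.dataclass
class WeightModel:
    """cis SNP weights predicting one standardized molecular feature.

    ``entries`` has columns snp_id, A1, A2, weight; weights apply to
    standardized A1 dosage.
    """

    feature_id: str
    modality: str  # "expression" | "protein"
    tissue: str
    gene_span: tuple[str, int, int]  # chromosome, start, stop (1-based incl.)
    entries: pd.DataFrame
    training_r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.modality not in ("expression", "protein"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        self.entries = self.entries.reset_index(drop=True)
        if self.entries["snp_id"].duplicated().any():
            dup = self.entries["snp_id"][self.entries["snp_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate SNP {dup!r} in model {self.feature_id!r}")
        if len(self.entries) and not (self.entries["weight"] != 0).any():
            raise ValidationError(f"model {self.feature_id!r} has no nonzero weight")

    @property
    def untrainable(self) -> bool:
        return len(self.entries) == 0

    @property
    def snp_ids(self) -> list[str]:
        return self.entries["snp_id"].tolist()

    @property
    def weights(self) -> np.ndarray:
        return self.entries["weight"].to_numpy(float)


@dataclasses.dataclass
class LdPanel:
    """Reference genotypes: SNP metadata plus an individuals x SNPs dosage
    matrix of effect-allele (A1) counts in [0, 2]."""

    snps: pd.DataFrame  # snp_id, chromosome, position, A1, A2, freq_A1
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snps):
            raise ValidationError("dosage columns must match SNP metadata rows")
        if self.snps["snp_id"].duplicated().any():
            raise ValidationError("duplicate snp_id in panel")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp_id"].tolist()

    def index_of(self, snp_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snps["snp_id"])}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]!r} not in panel") from None

    def frequencies(self, snp_ids: Sequence[str] | None = None) -> np.ndarray:
        """Sample A1 frequencies estimated from the dosage matrix."""
        idx = slice(None) if snp_ids is None else self.index_of(snp_ids)
        return self.dosages[:, idx].mean(axis=0) / 2.0

    def correlation(
        self, snp_ids: Sequence[str] | None = None, ridge: float = 0.0
    ) -> np.ndarray:
        """Dosage correlation matrix, optionally ridge-stabilized.

        With ``ridge`` > 0 the diagonal is inflated by ``ridge`` and the
        matrix renormalized to unit diagonal, the standard stabilization
        before inverting reference LD.
        """
        idx = slice(None) if snp_ids is None else self.index_of(snp_ids)
        X = self.dosages[:, idx]
        sd = X.std(axis=0)
        if (sd == 0).any():
            raise ValidationError("constant dosage column in correlation request")
        R = np.corrcoef(X, rowvar=False)
        R = np.atleast_2d(R)
        if ridge > 0:
            R = (R + ridge * np.eye(len(R))) / (1.0 + ridge)
        return R

    def subset(self, snp_ids: Sequence[str]) -> "LdPanel":
        idx = self.index_of(snp_ids)
        return LdPanel(self.snps.iloc[idx].copy(), self.dosages[:, idx].copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FULL_HEADER = {
    "SNP": "snp_id", "CHR": "chromosome", "POS": "position", "A1": "A1",
    "A2": "A2", "FREQ": "freq_A1", "BETA": "beta", "SE": "se", "Z": "z",
    "N": "n",
}
_FUSION_REQUIRED = ["SNP", "A1", "A2", "Z", "N"]
_FULL_REQUIRED = list(_FULL_HEADER)


def read_gwas_sumstats(
    path: str | Path,
    dialect: str = "full",
    trait_id: str | None = None,
    study_n: float | None = None,
) -> GwasSumstats:
    """Read a tab-delimited summary-statistics file.

    ``dialect='full'`` requires SNP, CHR, POS, A1, A2, FREQ, BETA, SE, Z, N.
    ``dialect='fusion_sumstats'`` requires SNP, A1, A2, Z, N only; beta/se
    are left unset.  If N is absent in that dialect a study-level
    ``study_n`` must be supplied.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
    if dialect == "full":
        required = _FULL_REQUIRED
    elif dialect == "fusion_sumstats":
        required = [c for c in _FUSION_REQUIRED if c != "N"]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    out = pd.DataFrame({"snp_id": df["SNP"].astype(str)})
    for src, dst in _FULL_HEADER.items():
        if dst == "snp_id":
            continue
        if src in df.columns:
            out[dst] = df[src]
        else:
            out[dst] = np.nan
    if dialect == "fusion_sumstats":
        out["beta"] = np.nan
        out["se"] = np.nan
        if "N" not in df.columns:
            if study_n is None:
                raise FormatError(
                    f"{path.name}: no N column; supply a study-level n"
                )
            out["n"] = float(study_n)
    for col in ("A1", "A2"):
        out[col] = out[col].astype(str).str.upper()
    return GwasSumstats(trait_id or path.stem, out)


def write_gwas_sumstats(sumstats: GwasSumstats, path: str | Path) -> None:
    df = sumstats.records.rename(
        columns={v: k for k, v in _FULL_HEADER.items()}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _allele_key(a1: str, a2: str) -> frozenset:
    return frozenset((a1, a2))


@dataclasses.dataclass
class HarmonizationLog:
    n_input: int = 0
    n_matched: int = 0
    n_flipped: int = 0
    n_ambiguous_dropped: int = 0
    n_irreconcilable: int = 0


def harmonize_alleles(
    sumstats: GwasSumstats,
    panel: LdPanel,
    drop_ambiguous: bool = True,
) -> tuple[GwasSumstats, HarmonizationLog]:
    """Restrict sumstats to panel SNPs and orient effects to the panel's A1.

    Where the sumstats allele pair is swapped relative to the panel, the
    signs of beta and z are flipped and freq_A1 replaced by its complement.
    Strand-ambiguous pairs (A/T, C/G) are dropped when ``drop_ambiguous``;
    irreconcilable allele pairs are dropped and counted.
    """
    log = HarmonizationLog(n_input=len(sumstats.records))
    panel_alleles = {
        row.snp_id: (row.A1, row.A2)
        for row in panel.snps.itertuples()
    }
    rows = []
    for row in sumstats.records.itertuples(index=False):
        ref = panel_alleles.get(row.snp_id)
        if ref is None:
            continue
        pair = _allele_key(row.A1, row.A2)
        if drop_ambiguous and pair in _AMBIGUOUS:
            log.n_ambiguous_dropped += 1
            continue
        rec = row._asdict()
        if (row.A1, row.A2) == ref:
            pass
        elif (row.A2, row.A1) == ref:
            rec["A1"], rec["A2"] = ref
            rec["beta"] = -rec["beta"] if not pd.isna(rec["beta"]) else rec["beta"]
            rec["z"] = -rec["z"] if not pd.isna(rec["z"]) else rec["z"]
            if not pd.isna(rec["freq_A1"]):
                rec["freq_A1"] = 1.0 - rec["freq_A1"]
            log.n_flipped += 1
        else:
            log.n_irreconcilable += 1
            continue
        rows.append(rec)
        log.n_matched += 1
    if not rows:
        raise HarmonizationError(
            f"no SNPs shared between trait {sumstats.trait_id!r} and panel"
        )
    out = pd.DataFrame(rows, columns=_SUMSTAT_COLUMNS)
    if log.n_irreconcilable or log.n_ambiguous_dropped:
        logger.info(
            "harmonize %s: matched=%d flipped=%d ambiguous=%d irreconcilable=%d",
            sumstats.trait_id, log.n_matched, log.n_flipped,
            log.n_ambiguous_dropped, log.n_irreconcilable,
        )
    return GwasSumstats(sumstats.trait_id, out), log


# -- weight files -----------------------------------------------------------

def write_weight_models(models: Iterable[WeightModel], path: str | Path) -> None:
    """Write models as one tab-delimited table (FEATURE, MODALITY, TISSUE,
    CHR, START, STOP, TRAIN_R2, SNP, A1, A2, WEIGHT), one row per SNP."""
    rows = []
    for m in models:
        chrom, start, stop = m.gene_span
        for e in m.entries.itertuples(index=False):
            rows.append({
                "FEATURE": m.feature_id, "MODALITY": m.modality,
                "TISSUE": m.tissue, "CHR": chrom, "START": start,
                "STOP": stop, "TRAIN_R2": m.training_r2,
                "SNP": e.snp_id, "A1": e.A1, "A2": e.A2, "WEIGHT": e.weight,
            })
    pd.DataFrame(
        rows,
        columns=["FEATURE", "MODALITY", "TISSUE", "CHR", "START", "STOP",
                 "TRAIN_R2", "SNP", "A1", "A2", "WEIGHT"],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_weight_models(path: str | Path) -> list[WeightModel]:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str,
                                            "FEATURE": str, "CHR": str})
    models = []
    for (feat, modality, tissue, chrom, start, stop, r2), grp in df.groupby(
        ["FEATURE", "MODALITY", "TISSUE", "CHR", "START", "STOP", "TRAIN_R2"],
        sort=False, dropna=False,
    ):
        entries = pd.DataFrame({
            "snp_id": grp["SNP"].astype(str),
            "A1": grp["A1"].str.upper(),
            "A2": grp["A2"].str.upper(),
            "weight": grp["WEIGHT"].astype(float),
        })
        models.append(WeightModel(
            feature_id=feat, modality=modality, tissue=tissue,
            gene_span=(str(chrom), int(start), int(stop)),
            entries=entries, training_r2=float(r2),
        ))
    return models


# -- LD panel ---------------------------------------------------------------

def write_ld_panel(panel: LdPanel, prefix: str | Path) -> None:
    """Write ``<prefix>.snps.tsv`` (metadata) and ``<prefix>.dosage.tsv``
    (individuals x SNPs, header = snp ids)."""
    prefix = Path(prefix)
    panel.snps.to_csv(Path(str(prefix) + ".snps.tsv"), sep="\t", index=False)
    pd.DataFrame(panel.dosages, columns=panel.snp_ids).to_csv(
        Path(str(prefix) + ".dosage.tsv"), sep="\t", index=False,
        float_format="%.6g",
    )


def read_ld_panel(prefix: str | Path) -> LdPanel:
    prefix = Path(prefix)
    snps = pd.read_csv(Path(str(prefix) + ".snps.tsv"), sep="\t",
                       dtype={"snp_id": str, "chromosome": str,
                              "A1": str, "A2": str})
    dos = pd.read_csv(Path(str(prefix) + ".dosage.tsv"), sep="\t")
    if list(dos.columns) != snps["snp_id"].tolist():
        raise FormatError("dosage column order does not match SNP metadata")
    X = dos.to_numpy(float)
    if ((X < 0) | (X > 2)).any():
        raise ValidationError("dosages outside [0, 2]")
    return LdPanel(snps, X)


# -- generic result tables --------------------------------------------------

def write_results_table(rows: Sequence[Mapping] | pd.DataFrame,
                        path: str | Path) -> None:
    """Tab-delimited UTF-8 with header; deterministic column order;
    p-value columns rendered in scientific notation."""
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(list(rows))
    for col in df.columns:
        if str(col).lower().startswith("p") and df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda v: f"{v:.6e}" if pd.notna(v) else "")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g",
              encoding="utf-8")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
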