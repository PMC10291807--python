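import numpy as np
import pandas as pd
import pytest

from coloxwas.io_formats import GwasSumstats, LdPanel, WeightModel
from coloxwas.synthetic import ScenarioSpec, simulate_ld_panel


@pytest.fixture
def small_panel() -> LdPanel:
    """Deterministic 200 x 10 panel with moderate AR(1) LD."""
    spec = ScenarioSpec(p_snps=10, n_panel=200, ld_decay=0.5, seed=42)
    return simulate_ld_panel(spec)


@pytest.fixture
def big_panel() -> LdPanel:
    spec = ScenarioSpec(p_snps=50, n_panel=2000, ld_decay=0.6, seed=7)
    return simulate_ld_panel(spec)


def make_sumstats(panel: LdPanel, z: np.ndarray, n: float = 1e5,
                  trait_id: str = "trait") -> GwasSumstats:
    """Sumstats with given z over a panel's SNPs, consistent beta/se."""
    freq = panel.frequencies()
    se = 1.0 / np.sqrt(n * 2 * freq * (1 - freq))
    rec = panel.snps[["snp_id", "chromosome", "position", "A1", "A2"]].copy()
    rec["freq_A1"] = freq
    rec["se"] = se
    rec["z"] = np.asarray(z, float)
    rec["beta"] = rec["z"] * se
    rec["n"] = n
    return GwasSumstats(trait_id, rec[
        ["snp_id", "chromosome", "position", "A1", "A2",
         "freq_A1", "beta", "se", "z", "n"]])


def single_snp_model(panel: LdPanel, snp_id: str, weight: float = 1.0,
                     feature_id: str = "feat") -> WeightModel:
    row = panel.snps.set_index("snp_id").loc[snp_id]
    pos = int(row["position"])
    return WeightModel(
        feature_id=feature_id, modality="expression", tissue="t",
        gene_span=(str(row["chromosome"]), max(1, pos - 1000), pos + 1000),
        entries=pd.DataFrame({"snp_id": [snp_id], "A1": [row["A1"]],
                              "A2": [row["A2"]], "weight": [weight]}))
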