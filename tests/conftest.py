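import numpy as np
import pandas as pd
import pytest

from evcargo import simulate as sim
from evcargo.datatypes import OmicsMatrix, SampleMeta


def small_spec(seed: int = 1, **overrides) -> sim.SimSpec:
    """Desk-scale simulation: same design structure, fewer features."""
    spec = sim.SimSpec(seed=seed)
    spec.layers = {
        "protein": sim.LayerSpec(n_features=120, n_technical_replicates=3),
        "mirna": sim.LayerSpec(n_features=60),
        "metabolite": sim.LayerSpec(
            n_features=20, n_processing_replicates=5, fraction_differential=0.5
        ),
        "lipid": sim.LayerSpec(n_features=30),
    }
    spec.n_planted_hubs = 5
    spec.n_decoy_edges = 40
    for key, value in overrides.items():
        setattr(spec, key, value)
    return spec


def noncentral_t_power(effect: float, sd: float, n: int, alpha: float = 0.05) -> float:
    """Closed-form two-sided power of the pooled t test (noncentral t)."""
    from scipy import stats

    df = 2 * n - 2
    ncp = effect / (sd * np.sqrt(2.0 / n))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    return float(stats.nct.sf(tcrit, df, ncp) + (0.0 if np.isnan(lower) else lower))


def truth_tables(study) -> dict[str, pd.DataFrame]:
    """Oracle differential tables built from planted truth (no estimation)."""
    tables = {}
    for layer in ("protein", "mirna", "metabolite"):
        ids = study.matrices[layer].feature_ids
        eff = study.truth.differential[layer]
        df = pd.DataFrame(
            {
                "log2fc": [eff.get(i, 0.0) for i in ids],
                "p_value": [1e-9 if i in eff else 1.0 for i in ids],
            },
            index=ids,
        )
        df["direction"] = np.where(
            (df["p_value"] <= 0.05) & (df["log2fc"] > 0), "up",
            np.where((df["p_value"] <= 0.05) & (df["log2fc"] < 0), "down", "ns"))
        tables[layer] = df
    return tables


@pytest.fixture(scope="session")
def study():
    """One small simulated study shared by read-only tests."""
    return sim.generate_study(small_spec(seed=7))


def make_matrix(values, groups, layer="protein", feature_ids=None) -> OmicsMatrix:
    """Hand-built matrix: ``values`` feature x sample, one group label per column."""
    values = np.asarray(values, dtype=float)
    counters: dict[str, int] = {}
    samples = []
    for g in groups:
        counters[g] = counters.get(g, 0) + 1
        samples.append(SampleMeta(f"{g}_p{counters[g]}", g, counters[g], 1))
    if feature_ids is None:
        feature_ids = [f"F{i + 1}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, index=feature_ids, columns=[s.sample_id for s in samples])
    return OmicsMatrix(layer=layer, data=data, samples=samples)
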