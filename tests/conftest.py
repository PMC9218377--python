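import numpy as np
import pandas as pd
import pytest

from augtrial.synthetic_data import (
    CountTraitConfig,
    QualitativeTraitConfig,
    QuantitativeTraitConfig,
    SimulationConfig,
    paper_like_config,
    simulate_trial,
)
from augtrial.trial_data import LONG_COLUMNS, TraitSpec, TrialDataset


def make_long(rows):
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


@pytest.fixture
def toy_dataset():
    """2 checks x 2 blocks + 2 unreplicated tests, one trait.

    Check block means are 12 (B1) and 14 (B2); grand check mean 13, so the
    block adjustments are -1 and +1.
    """
    rows = [
        ("C1", "check", "LOC", "B1", "Y", 10.0),
        ("C2", "check", "LOC", "B1", "Y", 14.0),
        ("C1", "check", "LOC", "B2", "Y", 12.0),
        ("C2", "check", "LOC", "B2", "Y", 16.0),
        ("T1", "test", "LOC", "B1", "Y", 20.0),
        ("T2", "test", "LOC", "B2", "Y", 20.0),
    ]
    traits = {"Y": TraitSpec("Y", "quantitative", "kg")}
    return TrialDataset(make_long(rows), traits, ("C1", "C2"))


@pytest.fixture
def small_config():
    """Fast simulation config: 30 tests, 5 blocks, 2 locations."""
    return SimulationConfig(
        n_test=30,
        n_blocks=5,
        n_locations=2,
        check_ids=("CK1", "CK2"),
        quantitative=(
            QuantitativeTraitConfig("YLD", 3000.0, 250000.0, var_gxe=20000.0,
                                    var_res=40000.0, var_block=10000.0, var_loc=30000.0),
            QuantitativeTraitConfig("Fe", 37.5, 37.0, var_gxe=8.0, var_res=8.0,
                                    var_block=2.0, var_loc=4.0),
            QuantitativeTraitConfig("Zn", 18.0, 11.5, var_gxe=1.6, var_res=1.6,
                                    var_block=0.5, var_loc=1.0),
        ),
        count=(CountTraitConfig("SF", 4.4, var_g_log=0.1),),
        qualitative=(
            QualitativeTraitConfig("awn", ("present", "absent"), (0.075, 0.925)),
            QualitativeTraitConfig("grain_color",
                                   ("white", "yellow", "red", "brown", "buff"),
                                   (0.165, 0.188, 0.273, 0.354, 0.020)),
        ),
        genotype_correlations={("Fe", "Zn"): 0.32, ("YLD", "Fe"): -0.26},
        seed=7,
    )


@pytest.fixture
def small_dataset(small_config):
    return simulate_trial(small_config)


@pytest.fixture(scope="session")
def paper_scale_dataset():
    """Full-dimension synthetic trial (341 tests, 4 checks, 22 blocks, 2 locations)."""
    return simulate_trial(paper_like_config(seed=11))


def ls_genotype_means(obs: pd.DataFrame) -> pd.Series:
    """Independent least-squares oracle for one location/trait.

    Fits y = block + genotype with full dummy coding (min-norm solution) and
    returns each genotype's estimable mean averaged over blocks:
    tau_g + mean_j(beta_j).
    """
    blocks = pd.get_dummies(obs["block"], dtype=float)
    genos = pd.get_dummies(obs["genotype"], dtype=float)
    design = np.hstack([blocks.to_numpy(), genos.to_numpy()])
    coef, *_ = np.linalg.lstsq(design, obs["value"].to_numpy(dtype=float), rcond=None)
    n_blocks = blocks.shape[1]
    beta_bar = coef[:n_blocks].mean()
    return pd.Series(coef[n_blocks:] + beta_bar, index=genos.columns)
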