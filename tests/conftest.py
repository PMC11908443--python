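import numpy as np
import pytest

import allomkit as ak


@pytest.fixture
def inventory_csv(tmp_path):
    """Three-row inventory in the canonical dialect."""
    p = tmp_path / "inv.csv"
    p.write_text(
        "plot_id,tree_tag,family,genus,species,dbh_cm,height_m,forest_type\n"
        "P1,t1,Fabaceae,Mora,paraensis,12.5,14.2,varzea\n"
        "P1,t2,Lecythidaceae,Eschweilera,coriacea,30.0,25.0,varzea\n"
        "P2,t3,Fabaceae,Pentaclethra,macroloba,55.5,31.0,varzea\n"
    )
    return p


@pytest.fixture
def wood_density_csv(tmp_path):
    p = tmp_path / "wd.csv"
    p.write_text(
        "family,genus,binomial,wood_density_g_cm3\n"
        "Fabaceae,Mora,Mora paraensis,0.6\n"
        "Fabaceae,Mora,Mora paraensis,0.8\n"
        "Fabaceae,Pentaclethra,Pentaclethra macroloba,0.55\n"
        "Lecythidaceae,Lecythis,Lecythis chartacea,0.72\n"
    )
    return p


@pytest.fixture(scope="session")
def tf_stand():
    """One terra-firme-like synthetic stand with its ground truth."""
    return ak.generate_stand(ak.terra_firme_like(seed=11))


@pytest.fixture(scope="session")
def vz_stand():
    return ak.generate_stand(ak.varzea_like(seed=11))


@pytest.fixture(scope="session")
def mm_stand():
    """A stand whose true height law is Michaelis-Menten (no species effect)."""
    cfg = ak.varzea_like(seed=5)
    cfg.true_height_model = ("michaelis_menten", (33.09, 18.43))
    cfg.height_noise_sd = 4.16
    cfg.species_height_intercept_sd = 0.0
    return ak.generate_stand(cfg)


def make_dataset(dbh, height=None, forest="terra_firme", **kw):
    """Minimal single-plot dataset from raw vectors."""
    records = []
    for i, d in enumerate(dbh):
        records.append(ak.TreeRecord(
            plot_id="P1", tag=f"t{i}", family="Fam", genus="Gen",
            species=f"sp{i % 5}", dbh=float(d),
            height=None if height is None else float(height[i]),
            forest_type=forest, **kw,
        ))
    return ak.ForestDataset(records, {"P1": 0.5})
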