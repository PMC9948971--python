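import numpy as np
import pandas as pd
import pytest

from avican import records, synth


def make_records(rows):
    """Build a necropsy frame from (species, sex, age, text, neo, mal, repro, origin)."""
    df = pd.DataFrame(rows, columns=[
        "species", "sex", "age_months", "age_text",
        "neoplasia", "malignancy", "reproductive", "origin"])
    df["common_name"] = df["species"]
    df["institution"] = "test_zoo"
    return records.validate_records(df[records.RECORD_COLUMNS])


def make_meta(rows):
    """Build a species-meta frame from (species, order, f_mat, m_mat, lifespan, dom)."""
    return records.validate_meta(pd.DataFrame(rows, columns=records.META_COLUMNS))


@pytest.fixture(scope="session")
def basic_meta():
    return make_meta([
        ("Anas alpha", "Anseriformes", 10, 14, 120, 0),
        ("Anas beta", "Anseriformes", 12, 12, 240, 0),
        ("Gallus gallus", "Galliformes", 5, 5, 96, 1),
        ("Columba gamma", "Columbiformes", 6, None, 180, 0),
    ])


@pytest.fixture(scope="session")
def small_study():
    """A deterministic synthetic study shared across tests."""
    cfg = synth.SynthConfig(n_species=40, seed=7, necropsy_range=(30, 200))
    return synth.generate_study(cfg), cfg


def full_trait_table(species, rng, clutch_driver=None):
    """A complete life-history table with every trait column populated."""
    n = len(species)
    clutch = np.exp(rng.normal(1.0, 0.3, n))
    if clutch_driver is not None:
        clutch = np.exp(0.5 * np.asarray(clutch_driver) + rng.normal(1.0, 0.2, n))
    return pd.DataFrame({
        "species": species,
        "mass_g": np.exp(rng.normal(5, 1, n)),
        "lifespan_months": np.exp(rng.normal(4.5, 0.5, n)),
        "incubation_months": np.exp(rng.normal(0, 0.3, n)),
        "clutch": clutch,
        "brightness_m": rng.uniform(2, 9, n),
        "brightness_f": rng.uniform(2, 9, n),
        "hue_m": rng.uniform(2, 9, n),
        "hue_f": rng.uniform(2, 9, n),
        "massdim_m": np.exp(rng.normal(5, 1, n)),
        "massdim_f": np.exp(rng.normal(5, 1, n)),
        "tail_m": rng.uniform(2, 30, n),
        "tail_f": rng.uniform(2, 30, n),
    })
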