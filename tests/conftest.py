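import numpy as np
import pytest

from radioser.clonogenic import ColonyRecord
from radioser.models import LQParams
from radioser.pipeline import fit_groups
from radioser.simulate import generate_clonogenic, study_design_config

# LQ truths used throughout: a control arm and a sensitized arm whose
# analytic 10%-survival dose ratio is 1.1900
CTRL_TRUTH = LQParams(0.45, 0.05)
GNP_TRUTH = LQParams(0.5686, 0.06)


def make_records(dose_sf_pairs, pe=0.5, n_seeded=1000, modality="HDR-BT",
                 dose_rate=1.1, arm="CTRL"):
    """Colony records whose replicate SFs equal the requested values exactly
    (control plates included so that the pooled PE equals ``pe``)."""
    records = [
        ColonyRecord(modality, dose_rate, arm, 0.0, rep, n_seeded,
                     int(round(pe * n_seeded)))
        for rep in (1, 2, 3)
    ]
    for dose, sfs in dose_sf_pairs:
        for rep, sf in enumerate(sfs, start=1):
            records.append(
                ColonyRecord(modality, dose_rate, arm, dose, rep, n_seeded,
                             int(round(sf * pe * n_seeded)))
            )
    return records


@pytest.fixture(scope="session")
def paired_dataset():
    """One synthetic paired-arm clonogenic dataset at the triplicate design."""
    config = study_design_config(CTRL_TRUTH, GNP_TRUTH)
    return generate_clonogenic(config, seed=20260921)


@pytest.fixture(scope="session")
def paired_fits(paired_dataset):
    _, fits = fit_groups(paired_dataset, model="lq", max_dose=6.0)
    return fits[("HDR-BT", 1.1, "CTRL")], fits[("HDR-BT", 1.1, "GNP")]
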