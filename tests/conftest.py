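"""Shared fixtures: case-study peptide sequences and small helpers.

The four case-study peptides are a human neuropeptide (NPY), a food-derived
cathelicidin fragment (BMAP-28), a human antimicrobial lactoferricin
fragment (LfcinH) and a gut-microbiome bacteriocin (OR-7). Region
coordinates are 1-based inclusive.
"""

import numpy as np
import pytest

# Mature human neuropeptide Y, 36 residues.
NPY_FULL = "YPSKPDNPGEDAPAEDMARYYSALRHYINLITRQRY"
# Its C-terminal inhibitory region, positions 16-36.
NPY_REGION = "DMARYYSALRHYINLITRQRY"
BMAP28 = "GGLRSLGRKILRAWKKYG"
LFCIN_REGION = "QWCAVSQPEATKCFQWQRNMRKVRGPPVSCIKRDSPIQ"
OR7_REGION = "MGRLQDILLGWATGAFGKTF"

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def case_sequences():
    return {
        "NPY_full": NPY_FULL,
        "NPY_region": NPY_REGION,
        "BMAP28": BMAP28,
        "LfcinH_region": LFCIN_REGION,
        "OR7_region": OR7_REGION,
    }


def random_peptide(rng: np.random.Generator, length: int) -> str:
    """Random sequence with a composition mixing helix formers and charges."""
    weights = np.array([
        3.0, 1.0, 1.5, 2.0, 1.5, 1.5, 0.5, 1.5, 2.5, 3.0,
        1.0, 1.0, 0.8, 1.5, 2.5, 1.5, 1.0, 1.0, 0.8, 1.0,
    ])
    probs = weights / weights.sum()
    return "".join(rng.choice(list(AA20), size=length, p=probs))
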