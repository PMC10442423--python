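import numpy as np
import pytest

from oa_phenopower.simulate.cohort import generate_cohort
from oa_phenopower.simulate.genotypes import PanelConfig, simulate_genotypes
from oa_phenopower.simulate.phantoms import PhantomSpec, generate_knee_phantom


@pytest.fixture(scope="session")
def small_panel():
    """500 subjects x 100 SNPs in 10-SNP LD blocks."""
    return simulate_genotypes(PanelConfig(n_subjects=500, n_snps=100), seed=11)


@pytest.fixture(scope="session")
def independent_panel():
    """2000 subjects x 500 unlinked SNPs."""
    return simulate_genotypes(PanelConfig(n_subjects=2000, n_snps=500, rho=0.0), seed=12)


@pytest.fixture(scope="session")
def cohort_2k():
    return generate_cohort(2000, seed=13)


@pytest.fixture
def flat_gap_scan():
    """Right-knee phantom with a constant 4 mm gap at 0.25 mm/px (16 px)."""
    spec = PhantomSpec(
        image_width=640, image_height=840, pixel_spacing=0.25, side="right",
        gap_mm={"lateral": 4.0, "center": 4.0, "medial": 4.0}, seed=3,
    )
    return generate_knee_phantom(spec)


def brute_force_gap_scan(mask):
    """Independent per-column femur-bottom/tibia-top scan of a mask.

    Direct transcription of the gap definition; returns (columns, gaps)
    for columns containing both bones.
    """
    cols, gaps = [], []
    for x in range(mask.shape[1]):
        femur_rows = np.flatnonzero(mask[:, x] == 1)
        tibia_rows = np.flatnonzero(mask[:, x] == 2)
        if len(femur_rows) and len(tibia_rows):
            cols.append(x)
            gaps.append(max(tibia_rows.min() - femur_rows.max() - 1, 0))
    return np.array(cols), np.array(gaps)
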