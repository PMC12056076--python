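import warnings

import numpy as np
import pytest

import dtiharm as dh
from dtiharm.simulate import SyntheticConfig, SiteSpec, simulate_multisite

# FA-bound warnings from synthetic edge cases are expected noise in tests
warnings.filterwarnings("ignore", message="FA values outside")

ROIS5 = ["AverageFA", "ACR", "ALIC", "CGC", "FX"]


@pytest.fixture(scope="session")
def bundle25():
    """Reference bundle over 25 ROIs, both sexes, ages 3-95.

    Built from one large clean synthetic site (no site effects) so the
    bundle's mean/SD curves track the generating trajectories closely.
    Median/10th/90th centiles included for coverage checks.
    """
    rois = SyntheticConfig().rois
    cfg = SyntheticConfig(sites=[SiteSpec("ref", 6000)], rois=rois, seed=11)
    ft, ct, truth = simulate_multisite(cfg)
    pooled = ft.to_frame().reset_index()
    pooled["age"] = ct.age
    pooled["sex"] = ct.sex
    curve_sets = dh.fit_lifespan_curves(pooled, rois, quantile_grid=[0.1, 0.5, 0.9])
    bundle = dh.assemble_reference(
        curve_sets, meta={"version": "1.0.0", "datasets": ["ref"]})
    bundle._truth = truth  # generating parameters, for tests only
    return bundle


@pytest.fixture()
def three_site_data():
    """3 sites x 5 ROIs with known shifts/scales (residual-mode site effects)."""
    sites = [SiteSpec("A", 150, 0.02, 1.2), SiteSpec("B", 150, -0.015, 0.85),
             SiteSpec("C", 150, 0.0, 1.0)]
    cfg = SyntheticConfig(sites=sites, rois=ROIS5,
                          site_effect_on="residual", seed=42)
    return simulate_multisite(cfg)
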