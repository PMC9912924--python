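"""Shared fixtures: all test data are generated programmatically."""

import numpy as np
import pytest

import sasreport as sr

# the doubly 5-methylated 27-mer duplex used in the worked DNA example
DNA_STRAND_1 = "GCACTCATCGGCGCAGATCAGCTAGCC"
DNA_STRAND_2 = "GGCTAGCTGATCTGCGCCGATGAGTGC"

# printed SANS Guinier I(0) +/- sigma per D2O fraction (all at 11.9 mg/ml)
SANS_I0_SERIES = [
    (0.00, 0.545, 0.006),
    (0.10, 0.364, 0.005),
    (0.20, 0.2204, 0.0007),
    (0.40, 0.0677, 0.0015),
    (0.80, 0.1865, 0.0024),
    (0.90, 0.322, 0.003),
    (1.00, 0.530, 0.002),
]


@pytest.fixture
def duplex_dna():
    s1 = sr.Component("strand1", "dna", DNA_STRAND_1, modifications=[("5mC", 2)])
    s2 = sr.Component("strand2", "dna", DNA_STRAND_2, modifications=[("5mC", 2)])
    return sr.Assembly([s1, s2])


@pytest.fixture
def exact_guinier_profile():
    """Pure Guinier decay: I = 100 exp(-q^2 30^2 / 3) with tiny sigma."""
    q = np.linspace(1e-3, 0.06, 120)
    I = 100.0 * np.exp(-(q**2) * 30.0**2 / 3.0)
    return sr.SASProfile(q=q, I=I, sigma=np.full_like(q, 1e-6),
                         intensity_scale="absolute_cm")


@pytest.fixture
def sphere30():
    """Noiseless sphere R = 30 A on a grid reaching qR = 12."""
    q = np.linspace(2e-3, 0.4, 500)
    p = sr.sphere_profile(30.0, 2.0e10, 1.0e12, q_grid=q)
    return sr.SASProfile(q=p.q, I=p.I, sigma=p.I * 1e-3 + 1e-15,
                         intensity_scale="absolute_cm")


@pytest.fixture
def printed_i0_series():
    pts = []
    for f, i0, s in SANS_I0_SERIES:
        g = sr.GuinierResult(I0=i0, sigma_I0=s, Rg=25.0, sigma_Rg=0.5,
                             first_point=1, last_point=20,
                             qRg_min=0.9, qRg_max=1.3, pearson_r=-0.99)
        pts.append(sr.ContrastPoint(f_d2o=f, c=11.9, guinier=g))
    return sr.ContrastSeries(pts)
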