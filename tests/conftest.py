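"""Shared fixtures.

The two pooled count tables below are reference data from a published
validation of an automatic sleep scorer on 40 clinical polysomnograms:
epoch cross-tabulations of the machine staging (columns) against the
three-technician majority vote and against the clinical staging (rows),
together with the point estimates (bootstrap medians) printed alongside
them.  They serve as arithmetic fixtures: totals, consensus percentages and
plug-in statistics are recomputed from the cell counts.
"""

from __future__ import annotations

import numpy as np
import pytest

from hypnoval.hypnogram import STAGES


@pytest.fixture(scope="session")
def majority_reference():
    """Machine vs three-technician majority vote, pooled over 40 recordings."""
    return {
        # rows: reference (majority vote) W, N1, N2, N3, R; cols: machine
        "counts": np.array([
            [6478, 902, 190, 10, 37],
            [174, 1501, 879, 1, 176],
            [59, 636, 12888, 559, 221],
            [5, 0, 539, 5412, 0],
            [14, 61, 239, 0, 4556],
        ]),
        "nonconsensus_row": np.array([48, 201, 144, 21, 79]),
        "row_totals": np.array([7617, 2731, 14363, 5956, 4870]),
        "nonconsensus_total": 493,
        "col_totals": np.array([6778, 3301, 14879, 6003, 5069]),
        "grand_total": 36030,
        "n_full_agreement": 26963,
        "n_partial_agreement": 8574,
        "printed": {
            "opa": 86.78,
            "kappa": 0.8205,
            "ppa": dict(zip(STAGES, [85.11, 54.90, 89.78, 90.90, 93.69])),
            "npa": dict(zip(STAGES, [99.10, 95.15, 91.28, 98.11, 98.60])),
            "ppv": dict(zip(STAGES, [96.26, 48.47, 87.49, 90.69, 91.36])),
        },
    }


@pytest.fixture(scope="session")
def clinical_reference():
    """Machine vs clinical staging, pooled over the same 40 recordings."""
    return {
        "counts": np.array([
            [6410, 1067, 307, 20, 56],
            [316, 1343, 808, 4, 157],
            [89, 797, 12659, 677, 328],
            [4, 0, 770, 5302, 0],
            [18, 95, 357, 0, 4528],
        ]),
        "row_totals": np.array([7860, 2628, 14550, 6076, 4998]),
        "col_totals": np.array([6837, 3302, 14901, 6003, 5069]),
        "grand_total": 36112,
        "printed": {
            "opa": 83.74,
            "kappa": 0.7796,
            "ppa": dict(zip(STAGES, [81.61, 50.98, 87.03, 87.32, 90.71])),
            "npa": dict(zip(STAGES, [98.50, 94.18, 89.63, 97.70, 98.28])),
            "ppv": dict(zip(STAGES, [93.78, 40.69, 84.98, 88.40, 89.43])),
        },
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20231205)
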