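import numpy as np
import pandas as pd
import pytest

from lysoquant.image import LabelMask, MultiChannelImage
from lysoquant.lipidomics import LipidTable
from lysoquant.simulate import ImageSimParams, generate_cell_image


def disk_label_mask(shape, disks, kind="nucleus") -> LabelMask:
    """Rasterize labelled disks (center_r, center_c, radius), pixels rho <= r."""
    labels = np.zeros(shape, dtype=np.int32)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    for i, (r0, c0, rad) in enumerate(disks, start=1):
        labels[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = i
    return LabelMask(labels=labels, kind=kind)


@pytest.fixture
def two_cell_scene():
    """Noiseless two-cell field with five puncta per cell."""
    params = ImageSimParams(
        shape=(300, 300), n_cells=2, puncta_count=5, kappa=0.0, seed=11
    )
    image, truth = generate_cell_image(params)
    return params, image, truth


@pytest.fixture
def small_lipid_table():
    """Hand-built four-species intensity table with per-class standards.

    Intensities are species mol x 1000 counts/pmol; the IS rows carry the
    same response, so the true quantities below are exactly recoverable.
    """
    species = pd.DataFrame(
        {
            "class": ["PC", "PC", "SM", "LPC"],
            "carbons": [34, 34, 34, 16],
            "double_bonds": [1, 2, 1, 0],
        },
        index=["PC 34:1", "PC 34:2", "SM 34:1", "LPC 16:0"],
    )
    true_mol = pd.DataFrame(
        {
            "ctrl_1": [40.0, 40.0, 15.0, 5.0],
            "ctrl_2": [42.0, 38.0, 15.0, 5.0],
            "ua_1": [40.0, 40.0, 30.0, 10.0],
            "ua_2": [42.0, 38.0, 30.0, 10.0],
        },
        index=species.index,
    )
    response = pd.Series([1000.0, 900.0, 1100.0, 1000.0], index=true_mol.columns)
    samples = pd.DataFrame(
        {
            "group": ["ctrl", "ctrl", "UA", "UA"],
            "batch": ["b1", "b2", "b1", "b2"],
            "replicate": [1, 1, 1, 1],
        },
        index=true_mol.columns,
    )
    is_amount = pd.Series({"PC": 20.0, "SM": 10.0, "LPC": 5.0})
    is_intensity = pd.DataFrame(
        {s: is_amount * response[s] for s in true_mol.columns}
    )
    table = LipidTable(
        data=true_mol * response,
        species=species,
        samples=samples,
        unit="intensity",
        is_intensity=is_intensity,
        is_amount=is_amount,
    )
    return table, true_mol
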