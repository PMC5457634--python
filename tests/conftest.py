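import numpy as np
import pytest

from arcdose.grids import DoseGrid, StructureMask


def sphere_mask(radius_mm: float, spacing_mm: float, margin_vox: int = 3,
                centre=(0.0, 0.0, 0.0)) -> StructureMask:
    """Digitized sphere: voxel centres within the radius, grid centred on 0."""
    half = radius_mm + margin_vox * spacing_mm
    n = 2 * int(np.ceil(half / spacing_mm)) + 1
    ax = spacing_mm * (np.arange(n) - (n - 1) / 2)
    Z, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
    cz, cy, cx = centre
    inside = (Z - cz) ** 2 + (Y - cy) ** 2 + (X - cx) ** 2 <= radius_mm ** 2
    return StructureMask(inside, spacing=(spacing_mm,) * 3,
                         origin=(float(ax[0]),) * 3, name="sphere")


def uniform_dose(mask: StructureMask, inside_gy: float, outside_gy: float = 0.0) -> DoseGrid:
    values = np.where(mask.values, inside_gy, outside_gy)
    return DoseGrid(values, spacing=mask.spacing, origin=mask.origin)


@pytest.fixture
def small_sphere():
    return sphere_mask(10.0, 1.0)


@pytest.fixture
def smooth_field_pair():
    """Factory for seeded pairs of smooth correlated 2D dose fields."""
    from scipy import ndimage
    from arcdose.grids import PlanarDose

    def make(seed: int, shape=(32, 32), spacing=2.0):
        rng = np.random.default_rng(seed)
        ref = ndimage.gaussian_filter(rng.random(shape), 4)
        ref = 2.0 * ref / ref.max()
        ev = ndimage.gaussian_filter(rng.random(shape), 4)
        ev = 2.0 * ev / ev.max()
        ev = 0.7 * ref + 0.3 * ev
        return (PlanarDose(ref, spacing=(spacing, spacing)),
                PlanarDose(ev, spacing=(spacing, spacing)))

    return make
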