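import numpy as np
import pytest

import adipoquant as aq


@pytest.fixture(scope="session")
def small_region():
    """A small good-quality synthetic region (~70 cells) with ground truth."""
    spec = aq.TissueSpec(region_width_um=800.0, region_height_um=600.0, seed=7)
    image, truth = aq.generate_tissue(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_annotations(small_region):
    _, image, truth = small_region
    return aq.annotations_from_truth(image, truth, n_per_class=500, seed=1)


@pytest.fixture(scope="session")
def small_model(small_region, small_annotations):
    """Classifier trained on the small region at the native 1 µm working grid."""
    _, image, _ = small_region
    return aq.train_classifier([(image, small_annotations)], seed=0)


@pytest.fixture(scope="session")
def survey_model():
    """Classifier at the 2 µm analysis scale used for large-region surveys,
    trained on its own region so evaluation regions stay unseen."""
    spec = aq.TissueSpec(seed=1000)
    image, truth = aq.generate_tissue(spec)
    annotations = aq.annotations_from_truth(image, truth, n_per_class=500, seed=1)
    return aq.train_classifier(
        [(image, annotations)], working_pixel_size_um=2.0, seed=0
    )


def make_object(area_um2: float, object_id: int = 1, centroid=(0.0, 0.0)):
    """Minimal AdipocyteObject for morphometry tests."""
    from adipoquant.morphometry import circular_diameter
    from adipoquant.objects import AdipocyteObject

    r = max(circular_diameter(area_um2) / 2.0, 0.5)
    ring = np.array(
        [
            [centroid[0] - r, centroid[1] - r],
            [centroid[0] + r, centroid[1] - r],
            [centroid[0] + r, centroid[1] + r],
            [centroid[0] - r, centroid[1] + r],
            [centroid[0] - r, centroid[1] - r],
        ]
    )
    return AdipocyteObject(
        object_id=object_id,
        pixel_count=max(1, int(round(area_um2))),
        area_um2=area_um2,
        diameter_um=circular_diameter(area_um2),
        centroid_um=centroid,
        boundary_polygon_um=ring,
    )
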