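import numpy as np
import pytest

from lvflow import phantoms


@pytest.fixture(scope="session")
def small_image_spec():
    return phantoms.PhantomSpec(kind="image_stack", n_slices=3, n_phases=4,
                                snr=10.0, rng_seed=7)


@pytest.fixture(scope="session")
def small_image_stack(small_image_spec):
    return phantoms.make_image_stack(small_image_spec)


@pytest.fixture(scope="session")
def dicom_dir(tmp_path_factory, small_image_spec):
    out = tmp_path_factory.mktemp("dicom")
    phantoms.make_image_stack(small_image_spec, out_dir=out)
    return out


@pytest.fixture(scope="session")
def clean_disk_frame():
    """Noise-free single frame plus ground truth (radius in px, center)."""
    spec = phantoms.PhantomSpec(kind="image_stack", n_slices=1, n_phases=2,
                                snr=1e9, rng_seed=0)
    st = phantoms.make_image_stack(spec)
    r_px = st.radii[0, 0] / spec.pixel_spacing
    return st.frames[0, 0].astype(float), st.masks[0, 0], r_px, st.center_px


@pytest.fixture(scope="session")
def piston_case():
    return phantoms.make_benchmark_case(phantoms.PhantomSpec(kind="piston_box"))


@pytest.fixture(scope="session")
def ellipsoid_case_coarse():
    spec = phantoms.PhantomSpec(kind="half_ellipsoid_lv", n_rings=8, n_theta=24)
    return phantoms.make_benchmark_case(spec)


def circle_points(center, radius, n=100):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.sin(th),
                            center[1] + radius * np.cos(th)])
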