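import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_section():
    """One rendered sham-like section at default geometry (shared; ~2 s)."""
    from dorsalhorn.geometry import GeometryConfig, generate_geometry
    from dorsalhorn.synth import NoiseModel, render_micrograph, sample_puncta

    geom = generate_geometry(GeometryConfig(), seed=7)
    fields = {"IB4": [], "GAD65": []}
    for side_geom in (geom, geom.mirrored()):
        for marker, dens in (("IB4", 20.0), ("GAD65", 18.0)):
            for lamina in ("LI", "LII"):
                fields[marker].append(
                    sample_puncta(
                        side_geom.band_rect(lamina),
                        dens,
                        0.3 if marker == "IB4" else 0.2,
                        0.5,
                        np.random.default_rng((hash((marker, lamina, side_geom.side)) & 0xFFFF,)),
                        marker,
                    )
                )
    micro = render_micrograph(geom, fields, NoiseModel(), seed=11)
    return geom, fields, micro
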