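import pytest
from shapely.geometry import box

from occurclean.geovalidate import CountryPolygonSet
from occurclean.synth import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def two_countries():
    """Two 2°x2° countries side by side on the equator, ocean to the west.

    XAA spans lon 10-12, XAB lon 12-14, both lat -1..1; they share the
    meridian border at lon=12. Everything at lon<10 is ocean.
    """
    return CountryPolygonSet({"XAA": box(10, -1, 12, 1), "XAB": box(12, -1, 14, 1)})


@pytest.fixture(scope="session")
def three_countries(two_countries):
    """Adds a non-adjacent country XAC (lon 16-18) separated by XAB."""
    return CountryPolygonSet(
        {
            "XAA": box(10, -1, 12, 1),
            "XAB": box(12, -1, 14, 1),
            "XAC": box(16, -1, 18, 1),
        }
    )


@pytest.fixture(scope="session")
def small_fixture():
    return make_fixture(FixtureSpec(n_countries=4, n_species=20, n_records=200, seed=11))
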