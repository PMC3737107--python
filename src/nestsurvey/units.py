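"""Unit conversions used throughout the package.

Convention: perpendicular distances and strip widths in metres, transect
lengths and effort in kilometres, densities per square kilometre.  Every
m/km conversion goes through this module so the 1e6 area factor of the
line-transect estimator lives in exactly one place.
"""

M_PER_KM = 1000.0


def m_to_km(x: float) -> float:
    return x / M_PER_KM


def km_to_m(x: float) -> float:
    return x * M_PER_KM


def per_m_per_km_to_per_km2(x: float) -> float:
    """Convert a quantity with units 1/(m·km) to 1/km²."""
    return x * M_PER_KM
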