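"""Anatomical indentation sites of the upper and lower extremities.

Site codes combine limb (arm/leg), segment relative to the hinge joint
(upper/lower) and aspect (anterior/posterior), e.g. ``LA_A`` = lower arm,
anterior.
"""

SITE_CODES: tuple[str, ...] = (
    "LA_A",
    "LA_P",
    "LL_A",
    "LL_P",
    "UA_A",
    "UA_P",
    "UL_A",
    "UL_P",
)


def validate_site(site: str) -> str:
    """Return ``site`` if it is one of the eight valid codes, else raise."""
    if site not in SITE_CODES:
        raise ValueError(
            f"unknown site code {site!r}; expected one of {', '.join(SITE_CODES)}"
        )
    return site
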