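"""Background (other-cause) mortality defaults.

A 15-year cohort model of 71-year-old men cannot ignore background
mortality.  ``US_MALE_QX_FROM_AGE_71`` is a synthetic per-year death
probability slice for ages 71-85, constructed to approximate the shape and
level of a recent US male period life table (roughly Gompertz growth from
~2.8% at 71 to ~11% at 85).  It is a stand-in default, not transcribed from
any published table, and can be overridden by ``mortality.p_death_other`` in
a spec file.
"""

from __future__ import annotations

__all__ = ["US_MALE_QX_FROM_AGE_71", "qx_schedule"]

US_MALE_QX_FROM_AGE_71: list[float] = [
    0.0277,  # age 71
    0.0306,
    0.0335,
    0.0367,
    0.0405,
    0.0447,
    0.0494,
    0.0546,
    0.0604,
    0.0670,
    0.0744,
    0.0827,
    0.0919,
    0.1022,
    0.1137,  # age 85
]


def qx_schedule(horizon: int) -> list[float]:
    """First ``horizon`` entries of the default schedule (max 15 cycles)."""
    if horizon > len(US_MALE_QX_FROM_AGE_71):
        raise ValueError(
            f"default life-table slice covers {len(US_MALE_QX_FROM_AGE_71)} cycles, "
            f"requested {horizon}"
        )
    return list(US_MALE_QX_FROM_AGE_71[:horizon])
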