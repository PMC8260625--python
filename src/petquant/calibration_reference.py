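"""Published multi-workstation phantom calibration, kept as a reference
fixture.

A sphere-phantom study of three commercial PET workstations reported, per
sphere volume, the optimal %-of-max threshold(s) found in each software (a
software may report two equally good adjacent thresholds) and the rounded
consensus of their equal-weight average.  The entries below reproduce that
calibration and are used to validate the consensus arithmetic
(:func:`petquant.calibration.average_thresholds`) against published numbers:
the five consensus thresholds are 64, 48, 44, 44 and 45 percent, with
unrounded means 63.75 and 43.75 for the smallest and middle spheres.
"""

from __future__ import annotations

#: sphere volume (cm³) -> per-software optimal threshold percents
PUBLISHED_PHANTOM_THRESHOLDS: dict[float, dict[str, tuple[int, ...]]] = {
    1.150: {"software_1": (65,), "software_2": (65,), "software_3": (62, 63)},
    2.572: {"software_1": (57,), "software_2": (44, 45), "software_3": (47, 48)},
    5.575: {"software_1": (48,), "software_2": (42,), "software_3": (42, 43)},
    11.494: {"software_1": (44,), "software_2": (44,), "software_3": (44,)},
    26.522: {"software_1": (45,), "software_2": (44,), "software_3": (47,)},
}
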